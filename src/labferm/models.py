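"""Model containers: polynomial response surfaces and one-hidden-layer networks.

Both model families map a process point ``(time h, WF %, SF %)`` to predicted
viability in log10 CFU/mL.  Containers are plain dataclasses with lossless
JSON round-tripping (``serialize_model`` / ``deserialize_model``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

SCHEMA_VERSION = 1

#: Monomial exponent triples (e1, e2, e3) meaning x1^e1 * x2^e2 * x3^e3 with
#: x1 = time (h), x2 = wheat flour (%), x3 = soy flour (%).
Term = tuple[int, int, int]

CONSTANT: Term = (0, 0, 0)
LINEAR_TERMS: tuple[Term, ...] = ((1, 0, 0), (0, 1, 0), (0, 0, 1))
INTERACTION_TERMS: tuple[Term, ...] = ((1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1))
QUADRATIC_TERMS: tuple[Term, ...] = ((2, 0, 0), (0, 2, 0), (0, 0, 2))
CUBIC_TERMS: tuple[Term, ...] = ((3, 0, 0), (0, 3, 0), (0, 0, 3))

#: The full cubic family, in the hierarchical order used by sequential ANOVA.
FULL_CUBIC_TERMS: tuple[Term, ...] = (
    (CONSTANT,) + LINEAR_TERMS + INTERACTION_TERMS + QUADRATIC_TERMS + CUBIC_TERMS
)

#: Term set of the pruned response-surface models (no intercept): the flour
#: percentages are complementary (x2 + x3 = 100), so the constant, the linear
#: flour terms, every interaction, and one redundant square are removed.
PRUNED_TERMS: tuple[Term, ...] = (
    (1, 0, 0), (2, 0, 0), (3, 0, 0), (0, 2, 0), (0, 3, 0), (0, 0, 3),
)


def term_name(term: Term) -> str:
    """Human-readable monomial name, e.g. ``(2, 0, 0)`` -> ``'x1^2'``."""
    if term == CONSTANT:
        return "1"
    parts = []
    for var, exp in zip(("x1", "x2", "x3"), term):
        if exp == 1:
            parts.append(var)
        elif exp > 1:
            parts.append(f"{var}^{exp}")
    return "*".join(parts)


class ModelFormatError(ValueError):
    """Raised when a serialized model file cannot be understood."""


def _as_points(x) -> np.ndarray:
    """Coerce a single (t, wf, sf) triple or an (n, 3) batch to (n, 3)."""
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError(f"expected points with 3 coordinates, got shape {pts.shape}")
    return pts


@dataclass(frozen=True)
class RSMModel:
    """Polynomial response surface over raw (unscaled) process variables.

    Prediction is exactly ``sum_j coef[j] * x1^e1_j * x2^e2_j * x3^e3_j``;
    there is no hidden intercept unless the constant term is present.
    """

    terms: tuple[Term, ...]
    coef: np.ndarray
    response_name: str = "viability_log10cfu_ml"
    notes: str = ""

    def __post_init__(self):
        coef = np.asarray(self.coef, dtype=float)
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        if len(self.terms) != len(set(self.terms)):
            raise ValueError("duplicate terms in model")
        if coef.shape != (len(self.terms),):
            raise ValueError("one coefficient per term required")
        if not np.all(np.isfinite(coef)):
            raise ValueError("non-finite coefficient")

    def predict(self, x) -> np.ndarray:
        """Evaluate the polynomial at one point or an (n, 3) batch."""
        pts = _as_points(x)
        cols = np.stack(
            [np.prod(pts ** np.asarray(t, dtype=float), axis=1) for t in self.terms],
            axis=1,
        )
        return cols @ self.coef

    def coefficient(self, term: Term) -> float:
        return float(self.coef[self.terms.index(tuple(term))])

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "rsm",
            "terms": [list(t) for t in self.terms],
            "coef": self.coef.tolist(),
            "response_name": self.response_name,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RSMModel":
        return cls(
            terms=tuple(tuple(t) for t in d["terms"]),
            coef=np.asarray(d["coef"], dtype=float),
            response_name=d.get("response_name", "viability_log10cfu_ml"),
            notes=d.get("notes", ""),
        )


@dataclass(frozen=True)
class ScalingSpec:
    """Linear variable scaling applied around network evaluation.

    ``inputs_scaled`` maps each input from ``[in_lo, in_hi]`` to [-1, 1];
    ``inputs_and_output_scaled`` additionally maps the network's raw output
    back from [-1, 1] to ``[out_lo, out_hi]``.  ``raw`` is the identity.
    The output map is affine and is *not* clipped, so network outputs beyond
    +/-1 descale to values beyond the output range.
    """

    mode: Literal["raw", "inputs_scaled", "inputs_and_output_scaled"] = "raw"
    in_lo: tuple[float, float, float] = (0.0, 90.0, 0.0)
    in_hi: tuple[float, float, float] = (24.0, 100.0, 10.0)
    out_lo: float = 7.0
    out_hi: float = 9.7

    def __post_init__(self):
        if self.mode not in ("raw", "inputs_scaled", "inputs_and_output_scaled"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")
        if self.mode != "raw":
            lo, hi = np.asarray(self.in_lo), np.asarray(self.in_hi)
            if not np.all(hi > lo):
                raise ValueError("in_hi must exceed in_lo in every dimension")
        if self.mode == "inputs_and_output_scaled" and not self.out_hi > self.out_lo:
            raise ValueError("out_hi must exceed out_lo")

    def scale_inputs(self, pts: np.ndarray) -> np.ndarray:
        if self.mode == "raw":
            return pts
        lo = np.asarray(self.in_lo, dtype=float)
        hi = np.asarray(self.in_hi, dtype=float)
        return 2.0 * (pts - lo) / (hi - lo) - 1.0

    def descale_output(self, y: np.ndarray) -> np.ndarray:
        if self.mode != "inputs_and_output_scaled":
            return y
        return (y + 1.0) / 2.0 * (self.out_hi - self.out_lo) + self.out_lo

    def scale_output(self, y: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`descale_output`, used to put targets in net space."""
        if self.mode != "inputs_and_output_scaled":
            return y
        return 2.0 * (y - self.out_lo) / (self.out_hi - self.out_lo) - 1.0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "in_lo": list(self.in_lo),
            "in_hi": list(self.in_hi),
            "out_lo": self.out_lo,
            "out_hi": self.out_hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingSpec":
        return cls(
            mode=d["mode"],
            in_lo=tuple(d["in_lo"]),
            in_hi=tuple(d["in_hi"]),
            out_lo=float(d["out_lo"]),
            out_hi=float(d["out_hi"]),
        )


def _activation(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "neg_half_tanh":
        # 2/(exp(z)+1) - 1, a sigmoid bounded in (-1, 1); equals -tanh(z/2).
        return -np.tanh(z / 2.0)
    if kind == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {kind!r}")


def _activation_deriv(f: np.ndarray, kind: str) -> np.ndarray:
    """Derivative expressed through the activation value ``f = f(z)``."""
    if kind == "neg_half_tanh":
        return (f * f - 1.0) / 2.0
    if kind == "tanh":
        return 1.0 - f * f
    raise ValueError(f"unknown activation {kind!r}")


@dataclass(frozen=True)
class ANNModel:
    """One-hidden-layer network  y = A . f(B x + bi) + bii  with <=10 neurons.

    ``A`` is the output weight row (n,), ``B`` the hidden weight matrix
    (n, 3), ``bi`` the hidden bias (n,), ``bii`` the scalar output bias.
    The hidden transfer function is either the form ``f(z) = 2/(exp(z)+1)-1``
    (``activation='neg_half_tanh'``) or the conventional hyperbolic tangent
    (``activation='tanh'``); both are bounded in (-1, 1), so the network
    output before output descaling always lies within ``bii +/- sum|A|``.
    """

    A: np.ndarray
    B: np.ndarray
    bi: np.ndarray
    bii: float
    scaling: ScalingSpec = field(default_factory=ScalingSpec)
    activation: Literal["neg_half_tanh", "tanh"] = "neg_half_tanh"
    notes: str = ""

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float).reshape(-1)
        B = np.asarray(self.B, dtype=float)
        bi = np.asarray(self.bi, dtype=float).reshape(-1)
        if B.ndim != 2 or B.shape[1] != 3:
            raise ValueError(f"B must be (n_hidden, 3), got {B.shape}")
        n = B.shape[0]
        if A.shape != (n,) or bi.shape != (n,):
            raise ValueError("A, B, bi shapes inconsistent")
        if n > 10:
            raise ValueError("at most 10 hidden neurons supported")
        for arr in (A, B, bi):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weight")
        if not np.isfinite(self.bii):
            raise ValueError("non-finite output bias")
        _activation(np.zeros(1), self.activation)  # validates the name
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "bi", bi)
        object.__setattr__(self, "bii", float(self.bii))

    @property
    def n_hidden(self) -> int:
        return self.B.shape[0]

    def forward_core(self, pts: np.ndarray) -> np.ndarray:
        """Network output before output descaling; ``pts`` already scaled."""
        z = pts @ self.B.T + self.bi
        return _activation(z, self.activation) @ self.A + self.bii

    def predict(self, x) -> np.ndarray:
        """Evaluate at one raw (t, wf, sf) point or an (n, 3) batch."""
        pts = _as_points(x)
        return self.scaling.descale_output(
            self.forward_core(self.scaling.scale_inputs(pts))
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "kind": "ann",
            "A": self.A.tolist(),
            "B": self.B.tolist(),
            "bi": self.bi.tolist(),
            "bii": self.bii,
            "scaling": self.scaling.to_dict(),
            "activation": self.activation,
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANNModel":
        return cls(
            A=np.asarray(d["A"], dtype=float),
            B=np.asarray(d["B"], dtype=float),
            bi=np.asarray(d["bi"], dtype=float),
            bii=float(d["bii"]),
            scaling=ScalingSpec.from_dict(d["scaling"]),
            activation=d.get("activation", "neg_half_tanh"),
            notes=d.get("notes", ""),
        )


def serialize_model(model: RSMModel | ANNModel, path) -> Path:
    """Write a model to JSON; lossless for all coefficients and metadata."""
    path = Path(path)
    path.write_text(json.dumps(model.to_dict(), indent=1), encoding="utf-8")
    return path


def deserialize_model(path) -> RSMModel | ANNModel:
    """Read a model written by :func:`serialize_model`.

    Raises :class:`ModelFormatError` on unparseable files, unknown kinds, or
    schema-version mismatches — never returns a silently zeroed model.
    """
    path = Path(path)
    try:
        d = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(d, dict) or "kind" not in d:
        raise ModelFormatError(f"{path} is not a model file")
    version = d.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelFormatError(
            f"{path}: schema_version {version!r} unsupported (expected {SCHEMA_VERSION})"
        )
    if d["kind"] == "rsm":
        return RSMModel.from_dict(d)
    if d["kind"] == "ann":
        return ANNModel.from_dict(d)
    raise ModelFormatError(f"{path}: unknown model kind {d['kind']!r}")
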