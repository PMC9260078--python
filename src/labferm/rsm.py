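"""Response-surface track: cubic polynomial regression with sequential ANOVA.

The viability response is regressed on raw (unscaled) fermentation time x1,
wheat-flour percentage x2 and soy-flour percentage x3 using the cubic family

    y = a0 + sum ai xi + sum aii xi^2 + sum aij xi xj + sum aii xi^3
        + sum aijk xi xj xk.

Because the flour fractions are complementary (x2 + x3 = 100), the full
family is rank-deficient on any real dataset; the sequential ANOVA measures
each hierarchy block by its rank increment, and the pruned final model drops
the structurally redundant terms, keeping {x1, x1^2, x1^3, x2^2, x2^3, x3^3}
with no intercept.  Diagnostics (Cook's distance, normal-probability pairs)
follow the usual OLS definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dataio import ViabilityDataset
from .models import (
    CONSTANT,
    CUBIC_TERMS,
    INTERACTION_TERMS,
    LINEAR_TERMS,
    QUADRATIC_TERMS,
    RSMModel,
    Term,
    term_name,
)

__all__ = [
    "AnovaTable",
    "CoefficientReport",
    "build_design_matrix",
    "cooks_distance",
    "fit_ols",
    "fit_rsm",
    "normal_probability",
    "predict_rsm",
    "prune_terms",
    "sequential_anova",
]


def build_design_matrix(
    ds: ViabilityDataset, terms: Sequence[Term]
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and response vector for a monomial term list.

    Column j is the j-th monomial evaluated on the raw regressors; the
    response is the viability column.  Rank deficiency is not checked here.
    """
    terms = [tuple(t) for t in terms]
    if len(terms) != len(set(terms)):
        raise ValueError("duplicate terms")
    pts = ds.points
    X = np.stack(
        [np.prod(pts ** np.asarray(t, dtype=float), axis=1) for t in terms], axis=1
    )
    return X, ds.viability


@dataclass(frozen=True)
class CoefficientReport:
    """Per-term inference and per-observation diagnostics of one OLS fit."""

    terms: tuple[Term, ...]
    estimate: np.ndarray
    se: np.ndarray
    tstat: np.ndarray
    pvalue: np.ndarray
    rmse: float
    r_squared: float
    adj_r_squared: float
    f_stat: float
    model_pvalue: float
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    leverage: np.ndarray = field(repr=False)
    sigma2: float = 0.0
    n_obs: int = 0

    @property
    def n_params(self) -> int:
        return len(self.terms)

    @property
    def has_constant(self) -> bool:
        return CONSTANT in self.terms

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table shaped like a regression report."""
        return pd.DataFrame(
            {
                "term": [term_name(t) for t in self.terms],
                "estimate": self.estimate,
                "se": self.se,
                "tstat": self.tstat,
                "pvalue": self.pvalue,
            }
        )


def fit_ols(
    design: np.ndarray, response: np.ndarray, terms: Sequence[Term]
) -> tuple[RSMModel, CoefficientReport]:
    """Ordinary least squares through a QR decomposition.

    Raises on rank-deficient designs, naming the collinear columns (the
    expected failure when x2 and x3 both enter linearly next to a constant,
    since x2 + x3 = 100).  Standard errors come from the unbiased residual
    variance and the inverse cross-product matrix; R-squared is measured
    against the mean-corrected total SS when a constant term is present and
    against the uncorrected total SS otherwise (through-origin fits).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float)
    terms = tuple(tuple(t) for t in terms)
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    if len(terms) != p:
        raise ValueError("one term per design column required")

    Q, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = sorted(term_name(terms[j]) for j in piv[rank:])
        raise ValueError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(bad)
        )

    beta = linalg.solve_triangular(R, Q.T @ y)[np.argsort(piv)]
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof if dof > 0 else np.nan
    Rinv = linalg.solve_triangular(R, np.eye(p))
    xtx_inv = (Rinv @ Rinv.T)[np.ix_(np.argsort(piv), np.argsort(piv))]
    se = np.sqrt(np.maximum(np.diag(xtx_inv), 0.0) * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tstat), dof) if dof > 0 else np.full(p, np.nan)

    has_const = CONSTANT in terms
    if has_const:
        tss = float(np.sum((y - y.mean()) ** 2))
        df_model = p - 1
    else:
        tss = float(y @ y)
        df_model = p
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    if dof > 0 and np.isfinite(r2):
        denom = n - 1 if has_const else n
        adj_r2 = 1.0 - (1.0 - r2) * denom / dof
    else:
        adj_r2 = np.nan
    if dof > 0 and df_model > 0 and rss > 0:
        f_stat = ((tss - rss) / df_model) / (rss / dof)
        model_p = float(stats.f.sf(f_stat, df_model, dof))
    else:
        f_stat, model_p = np.inf if rss == 0 else np.nan, 0.0 if rss == 0 else np.nan

    leverage = np.sum(Q * Q, axis=1)
    model = RSMModel(terms=terms, coef=beta)
    report = CoefficientReport(
        terms=terms,
        estimate=beta,
        se=se,
        tstat=np.asarray(tstat),
        pvalue=np.asarray(pval),
        rmse=float(np.sqrt(sigma2)) if dof > 0 else 0.0,
        r_squared=float(r2),
        adj_r_squared=float(adj_r2),
        f_stat=float(f_stat),
        model_pvalue=float(model_p),
        residuals=resid,
        fitted=fitted,
        leverage=leverage,
        sigma2=float(sigma2),
        n_obs=n,
    )
    return model, report


def fit_rsm(
    ds: ViabilityDataset, terms: Sequence[Term]
) -> tuple[RSMModel, CoefficientReport]:
    """Convenience wrapper: build the design from a dataset, then fit."""
    ds.check_fittable()
    X, y = build_design_matrix(ds, terms)
    return fit_ols(X, y, terms)


def predict_rsm(model: RSMModel, x) -> np.ndarray:
    """Exact polynomial evaluation on raw (time, WF, SF) inputs."""
    return model.predict(x)


#: Hierarchy blocks of the sequential decomposition, in fitting order.
ANOVA_BLOCKS: tuple[tuple[str, tuple[Term, ...]], ...] = (
    ("Mean", (CONSTANT,)),
    ("Linear", LINEAR_TERMS),
    ("2FI", INTERACTION_TERMS),
    ("Quadratic", QUADRATIC_TERMS),
    ("Cubic", CUBIC_TERMS),
)


@dataclass(frozen=True)
class AnovaTable:
    """Sequential (hierarchical) ANOVA of the cubic response surface."""

    table: pd.DataFrame

    def row(self, source: str) -> pd.Series:
        match = self.table[self.table["source"] == source]
        if match.empty:
            raise KeyError(f"no source {source!r}")
        return match.iloc[0]

    @property
    def residual_ms(self) -> float:
        r = self.row("Residual")
        return float(r["ss"] / r["df"])


def _projection_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual SS of the least-squares projection, tolerant of rank
    deficiency (minimum-norm solution), plus the design rank."""
    if X.shape[1] == 0:
        return float(y @ y), 0
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)


def sequential_anova(ds: ViabilityDataset) -> AnovaTable:
    """Hierarchical SS decomposition over Mean/Linear/2FI/Quadratic/Cubic.

    Each block's sum of squares is the drop in residual SS when the block's
    terms join the cumulative design; its degrees of freedom are the rank
    increment (smaller than the term count here, because wf + sf = 100 makes
    several columns redundant).  Every block F uses the full cubic model's
    residual mean square as denominator; blocks that add no rank are
    reported as NA with a warning.  Total row: uncorrected sum of squares
    over all n observations, the Mean row being the grand-mean component.
    """
    ds.check_fittable()
    y = ds.viability
    n = len(y)
    total_ss = float(y @ y)

    cumulative: list[Term] = []
    rss_prev, rank_prev = total_ss, 0
    rows = []
    for name, block in ANOVA_BLOCKS:
        cumulative.extend(block)
        X, _ = build_design_matrix(ds, cumulative)
        rss, rank = _projection_rss(X, y)
        d_ss, d_df = rss_prev - rss, rank - rank_prev
        rows.append([name, d_ss, d_df])
        rss_prev, rank_prev = rss, rank

    resid_df = n - rank_prev
    if resid_df <= 0:
        raise ValueError("not enough observations for a cubic fit")
    resid_ms = rss_prev / resid_df

    out = []
    for name, d_ss, d_df in rows:
        if d_df <= 0:
            warnings.warn(
                f"{name} block adds no estimable dimension; F reported as NA",
                stacklevel=2,
            )
            out.append((name, d_ss, d_df, np.nan, np.nan, np.nan))
        else:
            ms = d_ss / d_df
            f = ms / resid_ms if resid_ms > 0 else np.inf
            p = float(stats.f.sf(f, d_df, resid_df)) if np.isfinite(f) else 0.0
            out.append((name, d_ss, d_df, ms, f, p))
    out.append(("Residual", rss_prev, resid_df, resid_ms, np.nan, np.nan))
    out.append(("Total", total_ss, n, np.nan, np.nan, np.nan))
    return AnovaTable(
        pd.DataFrame(out, columns=["source", "ss", "df", "ms", "F", "p"])
    )


#: Terms removed structurally because x2 + x3 = 100 makes them redundant
#: with the retained set: the constant, both linear flour terms, every
#: interaction, and the soy square.
STRUCTURAL_REMOVALS: frozenset[Term] = frozenset(
    {CONSTANT, (0, 1, 0), (0, 0, 1), (0, 0, 2)} | set(INTERACTION_TERMS)
)


def prune_terms(full_report: CoefficientReport, alpha: float = 1.0) -> tuple[Term, ...]:
    """Reduce the full cubic family to the retained final term set.

    The complementarity rule (x2 + x3 = 100) removes the structurally
    redundant terms first, regardless of significance.  Afterwards, terms
    whose two-sided p-value reaches ``alpha`` are dropped; a term with
    p < alpha is never removed, and ``alpha = 1`` (the default) keeps every
    structurally admissible term — reproducing the six-term final models.
    """
    kept = []
    for term, p in zip(full_report.terms, full_report.pvalue):
        if term in STRUCTURAL_REMOVALS:
            continue
        if np.isfinite(p) and p >= alpha:
            continue
        kept.append(term)
    return tuple(kept)


def cooks_distance(report: CoefficientReport) -> np.ndarray:
    """Cook's distance  D_i = r_i^2 h_i / (p s^2 (1 - h_i)^2).

    Observations with leverage 1 get infinite distance and a warning.
    """
    r, h = report.residuals, report.leverage
    p, s2 = report.n_params, report.sigma2
    ones = h >= 1.0 - 1e-12
    if np.any(ones):
        warnings.warn("leverage of 1 encountered; Cook's distance is infinite",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = r**2 * h / (p * s2 * (1.0 - h) ** 2)
    d = np.where(r == 0, 0.0, d)  # a zero residual never influences the fit
    d = np.where(ones & (r != 0), np.inf, d)
    return d


def normal_probability(report: CoefficientReport | np.ndarray):
    """Normal-probability pairs and a straightness score for residuals.

    Returns ``(sorted standardized residuals, theoretical quantiles, r)``
    using the (i - 0.5)/n plotting-position convention; ``r`` is the Pearson
    correlation of the pairs (near 1 for normal errors).  Standardization
    uses the internally studentized form when leverages are available.
    """
    if isinstance(report, CoefficientReport):
        s = np.sqrt(report.sigma2 * (1.0 - report.leverage))
        with np.errstate(divide="ignore", invalid="ignore"):
            std_resid = report.residuals / s
    else:
        resid = np.asarray(report, dtype=float)
        sd = resid.std(ddof=1) if resid.size > 1 else 0.0
        if sd == 0:
            raise ValueError("residuals have zero variance")
        std_resid = resid / sd
    n = std_resid.size
    if n < 3:
        raise ValueError("need at least 3 residuals")
    if not np.all(np.isfinite(std_resid)):
        raise ValueError("non-finite standardized residual")
    if np.ptp(std_resid) == 0:
        raise ValueError("residuals have zero variance")
    ordered = np.sort(std_resid)
    quantiles = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    r = float(np.corrcoef(ordered, quantiles)[0, 1])
    return ordered, quantiles, r
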