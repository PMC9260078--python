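"""Lattice maximization of fitted viability surfaces.

The experimental domain is fermentation time 0-24 h crossed with wheat-flour
fraction 90-100 % of the flour mass; soy flour is the complement
(SF = 100 - WF), so the search space is two-dimensional.  The default mesh
is 49 x 49, i.e. time steps of 0.5 h and WF steps of 10/48 % — the mesh on
which the reported optimal conditions lie exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

DEFAULT_TIME_RANGE = (0.0, 24.0)
DEFAULT_WF_RANGE = (90.0, 100.0)


@dataclass(frozen=True)
class OptimizationResult:
    """Lattice maximum of a response surface and where it is attained."""

    optimum: float
    time_h: float
    wf_pct: float
    grid_points: int
    time_range: tuple[float, float] = DEFAULT_TIME_RANGE
    wf_range: tuple[float, float] = DEFAULT_WF_RANGE
    grid: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def sf_pct(self) -> float:
        return 100.0 - self.wf_pct


def _evaluate_grid(predict: Callable, times: np.ndarray, wfs: np.ndarray) -> np.ndarray:
    T, W = np.meshgrid(times, wfs, indexing="ij")
    pts = np.column_stack([T.ravel(), W.ravel(), 100.0 - W.ravel()])
    y = np.asarray(predict(pts), dtype=float).reshape(T.shape)
    if not np.all(np.isfinite(y)):
        i = np.unravel_index(int(np.argmin(np.isfinite(y))), y.shape)
        raise ValueError(
            f"non-finite prediction at time={times[i[0]]:g} h, wf={wfs[i[1]]:g} %"
        )
    return y


def _lattice_argmax(y: np.ndarray) -> tuple[int, int]:
    # np.argmax on the row-major array breaks ties toward the smallest time
    # index, then the smallest WF index — exactly the documented tie rule.
    return np.unravel_index(int(np.argmax(y)), y.shape)  # type: ignore[return-value]


def maximize_response(
    predict: Callable,
    time_range: tuple[float, float] = DEFAULT_TIME_RANGE,
    wf_range: tuple[float, float] = DEFAULT_WF_RANGE,
    grid_points: int = 49,
    keep_grid: bool = False,
) -> OptimizationResult:
    """Maximize ``predict(t, wf, sf)`` on a regular lattice.

    Parameters
    ----------
    predict : callable
        Maps an (n, 3) array of raw (time, WF, SF) points to predictions;
        any :class:`~labferm.models.RSMModel` or
        :class:`~labferm.models.ANNModel` ``predict`` method qualifies.
    time_range, wf_range : (float, float)
        Domain bounds; SF is always 100 - WF.
    grid_points : int
        Lattice points per axis (>= 2).
    keep_grid : bool
        Attach the full (grid_points, grid_points) value array to the result
        for surface export.

    Ties are broken toward the smallest time, then the smallest WF.
    """
    if grid_points < 2:
        raise ValueError("grid_points must be >= 2")
    times = np.linspace(*time_range, grid_points)
    wfs = np.linspace(*wf_range, grid_points)
    y = _evaluate_grid(predict, times, wfs)
    i, j = _lattice_argmax(y)
    return OptimizationResult(
        optimum=float(y[i, j]),
        time_h=float(times[i]),
        wf_pct=float(wfs[j]),
        grid_points=grid_points,
        time_range=tuple(time_range),
        wf_range=tuple(wf_range),
        grid=y if keep_grid else None,
    )


def refine_optimum(
    predict: Callable,
    coarse: OptimizationResult,
    factor: int = 10,
) -> OptimizationResult:
    """Re-grid a one-cell neighborhood of a coarse argmax at finer resolution.

    The refined search covers +/- one coarse cell around the coarse argmax
    (clipped to the original domain) with ``factor`` times the point density,
    and the coarse optimum is kept if the fine lattice does not improve on
    it, so refinement is monotonically non-decreasing.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    dt = (coarse.time_range[1] - coarse.time_range[0]) / (coarse.grid_points - 1)
    dw = (coarse.wf_range[1] - coarse.wf_range[0]) / (coarse.grid_points - 1)
    t_lo = max(coarse.time_range[0], coarse.time_h - dt)
    t_hi = min(coarse.time_range[1], coarse.time_h + dt)
    w_lo = max(coarse.wf_range[0], coarse.wf_pct - dw)
    w_hi = min(coarse.wf_range[1], coarse.wf_pct + dw)
    n = 2 * factor + 1
    fine = maximize_response(
        predict, time_range=(t_lo, t_hi), wf_range=(w_lo, w_hi), grid_points=n
    )
    if fine.optimum >= coarse.optimum:
        best = (fine.optimum, fine.time_h, fine.wf_pct)
    else:
        best = (coarse.optimum, coarse.time_h, coarse.wf_pct)
    return OptimizationResult(
        optimum=best[0],
        time_h=best[1],
        wf_pct=best[2],
        grid_points=n,
        time_range=(t_lo, t_hi),
        wf_range=(w_lo, w_hi),
    )
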