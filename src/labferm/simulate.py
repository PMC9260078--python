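"""Synthetic viability datasets with the structure of the dough study.

The original experiment fermented three wheat/soy flour blends (100/0, 95/5,
90/10 % WF/SF) at 37 C, sampling viable counts at 0, 2, 4, 6, 8, 10 and 24 h
in triplicate, for two single cultures and one co-culture.  The generator
emulates that design: a logistic rise in log10 CFU/mL from the inoculation
level to a culture-specific 24-h plateau, a small linear shift of the
plateau with soy content, and i.i.d. Gaussian replicate noise on the log
scale.  It makes every downstream stage testable without the authors' raw
data; it is an empirical stand-in, not a mechanistic kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import CULTURES, ViabilityDataset

#: Sampling grid of the study (h).
DEFAULT_TIMES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 24.0)

#: Wheat-flour percentages of the three dough blends.
DEFAULT_MIXTURES = (100.0, 95.0, 90.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings for one culture case.

    Parameters
    ----------
    culture : str
        Label written into the dataset (``Lp``, ``Lc`` or ``LpLc``).
    initial : float
        Viability at inoculation, log10 CFU/mL.
    asymptote : float
        24-h plateau at 100 % WF, log10 CFU/mL; must exceed ``initial``.
    lag_h : float
        Center of the logistic rise (h); larger means slower early growth.
    rate : float
        Maximum specific rise rate of the logistic, 1/h.
    sf_slope : float
        Additive shift of the plateau per % soy flour (log10 CFU/mL per %).
    noise_sd : float
        Replicate standard deviation, log10 CFU/mL.
    """

    culture: str = "Lp"
    initial: float = 7.0
    asymptote: float = 9.61
    lag_h: float = 4.0
    rate: float = 0.5
    sf_slope: float = -0.005
    noise_sd: float = 0.04
    times: tuple[float, ...] = DEFAULT_TIMES
    mixtures_wf: tuple[float, ...] = DEFAULT_MIXTURES
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.culture not in CULTURES:
            raise ValueError(f"unknown culture {self.culture!r}")
        if not self.asymptote > self.initial:
            raise ValueError("asymptote must exceed the initial level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def growth_curve(t, initial: float, asymptote: float, lag_h: float, rate: float):
    """Logistic growth in log10-CFU space, anchored at the inoculation level.

    The curve is the logistic sigmoid ``s(t) = 1/(1 + exp(-rate (t - lag)))``
    renormalized so that the value at t = 0 is exactly ``initial`` and the
    t -> infinity limit is exactly ``asymptote``::

        v(t) = initial + (asymptote - initial) * (s(t) - s(0)) / (1 - s(0))

    Working in log-count space keeps the simulated observable on the same
    scale the study reports and makes the surfaces smooth in that scale.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    s = 1.0 / (1.0 + np.exp(-rate * (t - lag_h)))
    s0 = 1.0 / (1.0 + np.exp(rate * lag_h))
    return initial + (asymptote - initial) * (s - s0) / (1.0 - s0)


def simulate_dataset(config: SyntheticConfig) -> ViabilityDataset:
    """One row per (mixture x time x replicate), reproducible from the seed.

    Viability = growth curve + plateau shift ``sf_slope * SF`` + Gaussian
    noise with sd ``noise_sd``.  The mixture shift scales with the curve's
    progress so that all mixtures start at the common inoculation level.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for wf in config.mixtures_wf:
        sf = 100.0 - wf
        base = growth_curve(
            np.asarray(config.times),
            config.initial,
            config.asymptote + config.sf_slope * sf,
            config.lag_h,
            config.rate,
        )
        for t, v in zip(config.times, base):
            for rep in range(1, config.replicates + 1):
                rows.append((t, wf, sf, config.culture, rep, v))
    df = pd.DataFrame(
        rows,
        columns=[
            "time_h", "wf_pct", "sf_pct", "culture", "replicate",
            "viability_log10cfu_ml",
        ],
    )
    noise = rng.normal(0.0, config.noise_sd, size=len(df)) if config.noise_sd > 0 else 0.0
    df["viability_log10cfu_ml"] = df["viability_log10cfu_ml"] + noise
    return ViabilityDataset(df)


#: Per-culture presets emulating the study conditions: plateaus at the
#: observed 24-h endpoints (9.61 / 9.54 / 9.67 log10 CFU/mL), replicate sd at
#: the reported half-widths, and a longer lag for L. casei, whose early
#: growth was slower.
_PRESETS = {
    "Lp": SyntheticConfig(culture="Lp", asymptote=9.61, lag_h=3.0, rate=0.45,
                          noise_sd=0.04),
    "Lc": SyntheticConfig(culture="Lc", asymptote=9.54, lag_h=6.0, rate=0.55,
                          noise_sd=0.11),
    "LpLc": SyntheticConfig(culture="LpLc", asymptote=9.67, lag_h=3.5, rate=0.5,
                            noise_sd=0.10),
}


def culture_preset(case: str, seed: int = 0) -> SyntheticConfig:
    """Study-condition preset for a culture case, with the given seed."""
    if case not in _PRESETS:
        raise KeyError(f"unknown culture case {case!r}; expected Lp, Lc or LpLc")
    return replace(_PRESETS[case], seed=seed)
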