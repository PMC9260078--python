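"""Reading, writing and validation of viability tables.

A viability table records colony counts (log10 CFU/mL) of a *Lactobacillus*
culture fermenting a wheat/soy dough, against fermentation time and flour
composition.  Files are plain CSV with '.' decimals and a mandatory header::

    time_h,wf_pct,sf_pct,culture,replicate,viability_log10cfu_ml

Culture labels are ``Lp`` (*L. plantarum*), ``Lc`` (*L. casei*) and ``LpLc``
(the co-culture).  Wheat and soy flour percentages are complementary
(``wf + sf = 100``) by construction of the dough blends.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = [
    "time_h",
    "wf_pct",
    "sf_pct",
    "culture",
    "replicate",
    "viability_log10cfu_ml",
]

CULTURES = ("Lp", "Lc", "LpLc")


class SchemaError(ValueError):
    """A table is missing required columns."""


class ValidationError(ValueError):
    """A table violates a dataset invariant; the message names the row."""


@dataclass(frozen=True)
class ViabilityDataset:
    """Validated viability observations, row order preserved.

    Invariants enforced at construction: ``wf + sf = 100`` (within 1e-9) per
    row, ``time >= 0``, ``viability > 0``, positive integer replicates, and
    known culture labels.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df[COLUMNS].reset_index(drop=True)
        for col in ("time_h", "wf_pct", "sf_pct", "viability_log10cfu_ml"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["culture"] = df["culture"].astype(str)

        comp = df["wf_pct"] + df["sf_pct"]
        bad = np.flatnonzero(np.abs(comp - 100.0) > 1e-9)
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"row {i}: wf_pct + sf_pct = {comp.iloc[i]:g}, expected 100"
            )
        bad = np.flatnonzero(df["time_h"].to_numpy() < 0)
        if bad.size:
            raise ValidationError(f"row {int(bad[0])}: negative time")
        bad = np.flatnonzero(df["viability_log10cfu_ml"].to_numpy() <= 0)
        if bad.size:
            raise ValidationError(f"row {int(bad[0])}: viability must be positive")
        bad = np.flatnonzero(df["replicate"].to_numpy() < 1)
        if bad.size:
            raise ValidationError(f"row {int(bad[0])}: replicate must be >= 1")
        unknown = set(df["culture"]) - set(CULTURES)
        if unknown:
            raise ValidationError(
                f"unknown culture label(s) {sorted(unknown)}; expected {CULTURES}"
            )
        object.__setattr__(self, "df", df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def points(self) -> np.ndarray:
        """(n, 3) array of raw (time h, WF %, SF %) regressors."""
        return self.df[["time_h", "wf_pct", "sf_pct"]].to_numpy(dtype=float)

    @property
    def viability(self) -> np.ndarray:
        return self.df["viability_log10cfu_ml"].to_numpy(dtype=float)

    def select(self, culture: str) -> "ViabilityDataset":
        """Rows of a single culture, order preserved."""
        if culture not in CULTURES:
            raise KeyError(f"unknown culture {culture!r}")
        return ViabilityDataset(self.df[self.df["culture"] == culture])

    def check_fittable(self) -> None:
        """Require >= 2 distinct times and >= 2 distinct WF levels."""
        if self.df["time_h"].nunique() < 2 or self.df["wf_pct"].nunique() < 2:
            raise ValidationError(
                "fitting needs at least 2 distinct time values and 2 distinct "
                "wf_pct values"
            )

    def equals(self, other: "ViabilityDataset") -> bool:
        return self.df.equals(other.df)


def read_viability_table(path, dialect: str = ",") -> ViabilityDataset:
    """Read a delimited viability table into a validated dataset.

    Parameters
    ----------
    path : path-like
        CSV file with the six-column header.
    dialect : str
        Field delimiter, ``','`` by default.
    """
    df = pd.read_csv(path, sep=dialect, float_precision="round_trip")
    return ViabilityDataset(df)


def write_viability_table(ds: ViabilityDataset, path, dialect: str = ",") -> Path:
    """Write a dataset as delimited text at full float precision."""
    path = Path(path)
    ds.df.to_csv(path, sep=dialect, index=False, float_format="%.17g")
    return path


def empty_dataset() -> ViabilityDataset:
    """A valid dataset with zero rows (header-only on write)."""
    return ViabilityDataset(pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS, [float, float, float, str, int, float])}))
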