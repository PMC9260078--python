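import numpy as np
import pandas as pd
import pytest

from labferm import ViabilityDataset, culture_preset, simulate_dataset


@pytest.fixture(scope="session")
def lp_dataset() -> ViabilityDataset:
    """Triplicate synthetic L. plantarum dataset on the study design."""
    return simulate_dataset(culture_preset("Lp", seed=11))


@pytest.fixture(scope="session")
def lc_dataset() -> ViabilityDataset:
    return simulate_dataset(culture_preset("Lc", seed=12))


@pytest.fixture()
def single_replicate_dataset() -> ViabilityDataset:
    """63 rows: 3 cultures x 3 mixes x 7 times, one replicate each."""
    rows = []
    for culture in ("Lp", "Lc", "LpLc"):
        for wf in (100.0, 95.0, 90.0):
            for t in (0, 2, 4, 6, 8, 10, 24):
                rows.append((t, wf, 100.0 - wf, culture, 1, 7.0 + 0.1 * t))
    return ViabilityDataset(
        pd.DataFrame(rows, columns=[
            "time_h", "wf_pct", "sf_pct", "culture", "replicate",
            "viability_log10cfu_ml",
        ])
    )
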