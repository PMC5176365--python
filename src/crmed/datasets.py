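"""Packaged reference data from the neonatal omeprazole dose-finding trial.

The under-32-week stratum's recorded cohort history and printed sequential
posterior rows, and the combined over-32-week strata's per-dose outcome
counts. These are the canonical replay/pooling fixtures; the printed
posterior rows also serve as the calibration anchor for the prior scale.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .design import DoseGrid, default_design
from .engine import TrialHistory
from .model import DoseOutcomeData
from .io import read_history

__all__ = [
    "lt32_history",
    "lt32_posterior_rows",
    "lt32_med_path",
    "ge32_pooled_counts",
]

#: Printed sequential posterior rows (one per cohort, per-dose means) of the
#: under-32-week stratum, to the table's 3-decimal precision.
_LT32_ROWS = np.array(
    [
        [0.931, 0.985, 0.997, 1.0, 1.0],
        [0.730, 0.893, 0.965, 0.993, 1.0],
        [0.540, 0.741, 0.879, 0.963, 1.0],
        [0.568, 0.769, 0.897, 0.970, 1.0],
        [0.589, 0.787, 0.909, 0.975, 1.0],
        [0.606, 0.802, 0.918, 0.978, 1.0],
        [0.638, 0.828, 0.933, 0.983, 1.0],
        [0.633, 0.848, 0.943, 0.986, 1.0],
        [0.586, 0.784, 0.907, 0.974, 1.0],
        [0.591, 0.789, 0.910, 0.975, 1.0],
        [0.598, 0.795, 0.914, 0.977, 1.0],
    ]
)

#: Dose index highlighted as the running MED estimate after each cohort.
_LT32_MED_PATH = (0, 2, 3, 3, 2, 2, 2, 2, 3, 3, 3)


def _data_path(name: str):
    return resources.files("crmed.data").joinpath(name)


def lt32_history(grid: DoseGrid | None = None) -> TrialHistory:
    """Recorded cohort history of the under-32-week stratum (30 neonates).

    Cohort 10 enrolled only 2 neonates; cohort 11's single neonate received
    2 mg/kg through a dose-allocation error and is flagged forced.
    """
    if grid is None:
        grid = default_design().grid
    with resources.as_file(_data_path("lt32_history.tsv")) as p:
        return read_history(p, grid, stratum_label="GA<32wk")


def lt32_posterior_rows() -> np.ndarray:
    """Printed per-dose posterior means after each cohort (11 x 5)."""
    return _LT32_ROWS.copy()


def lt32_med_path() -> tuple:
    """Printed running MED estimate (dose index) after each cohort."""
    return _LT32_MED_PATH


def ge32_pooled_counts() -> DoseOutcomeData:
    """Combined per-dose outcomes of the two over-32-week strata.

    18 neonates at 1 mg/kg (one failure) and 6 at 2 mg/kg (none).
    """
    import pandas as pd

    with resources.as_file(_data_path("ge32_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return DoseOutcomeData(df["n_success"].to_numpy(float), df["n_failure"].to_numpy(float))
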