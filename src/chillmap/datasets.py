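"""Packaged assay tables and published parameter estimates.

The two chill-tolerance assay tables for the alligatorweed agents ship as
plain CSVs: cell-mean mortalities by temperature and exposure time for
*Amynothrips andersoni* (incomplete cross, 50 thrips per populated cell)
and *Agasicles hygrophila* (complete 4x5 cross; per-cell replication was
unequal and unreported, so the packaged n of 68 per cell is the study
total spread evenly and can be overridden).

``THRIPS_PARAMS`` / ``BEETLE_PARAMS`` are the published nonlinear
least-squares estimates for the two species (standard errors are half the
published +/-2 SD intervals), used as reference inputs for derived
quantities such as SIT and LT50 contrasts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import ChillParams

__all__ = [
    "load_thrips_assays",
    "load_beetle_assays",
    "asos_sample_path",
    "THRIPS_PARAMS",
    "BEETLE_PARAMS",
]

THRIPS_PARAMS = ChillParams(
    a=1.367, b=4.45e-3, c=-2.941,
    se_a=0.348 / 2, se_b=1.36e-3 / 2, se_c=0.717 / 2,
    species_label="Amynothrips andersoni",
)

BEETLE_PARAMS = ChillParams(
    a=2.895, b=0.01152, c=4.520,
    se_a=0.325 / 2, se_b=0.00169 / 2, se_c=0.411 / 2,
    species_label="Agasicles hygrophila",
)


def _load(name: str) -> pd.DataFrame:
    with resources.files("chillmap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_thrips_assays() -> pd.DataFrame:
    """The *Am. andersoni* assay table (33 populated cells, n=50 each)."""
    return _load("assays_amynothrips_andersoni.csv")


def load_beetle_assays(n_per_cell: int | None = None) -> pd.DataFrame:
    """The *Ag. hygrophila* assay table (20 cells); ``n_per_cell``
    overrides the default 68."""
    df = _load("assays_agasicles_hygrophila.csv")
    if n_per_cell is not None:
        df["n_exposed"] = int(n_per_cell)
    return df


def asos_sample_path():
    """Path to the packaged synthetic 10-line ASOS one-minute sample."""
    return resources.files("chillmap.data").joinpath("asos_onemin_synthetic.txt")
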