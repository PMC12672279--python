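"""Packaged reference tables from a published 37-genotype okra PEG-6000 screen.

The screen phenotyped 37 okra genotypes under 0/10/20 % PEG 6000 in three
replicates and published (i) per trait × treatment descriptive statistics,
(ii) the mu±SD score card, and (iii) the seven stress-tolerance indices per
genotype at each stress level. The raw replicate-level data were not
deposited, so these printed tables are the only reference: the descriptives
calibrate the synthetic cohort generator, and the index and score tables are
audited by algebraic back-derivation (:mod:`droughtscreen.indices`).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .traits import load_summaries

__all__ = [
    "load_published_descriptives",
    "load_published_scorecard",
    "load_published_indices",
    "PERCENT_CLAIMS",
    "INDEX_COLUMNS",
]

#: Column order of the published index tables.
INDEX_COLUMNS = ("SSI", "MPI", "GMPI", "HMI", "STI", "TI", "SI")

#: Published percent-change claims (T0 -> T2), signed. Keys are traits,
#: values are the printed percentages with the sign of the change.
PERCENT_CLAIMS: dict[str, float] = {
    "DSG": +116.5,
    "NOL": -36.92,
    "TFW": -40.04,
    "TDW": -41.59,
    "SR": -70.47,
    "NSR": -51.99,
    "RL": -20.85,
    "SL": -29.06,
    "RFW": -18.72,
    "R/S": +11.94,
    "Chla": +47.99,
    "Chlb": +65.85,
    "TChl": +55.53,
    "CAR": +61.42,
    "Pro": +418.72,
    "MDA": +313.04,
    "H2O2": +167.09,
}


def _path(name: str):
    return resources.files("droughtscreen").joinpath("data", name)


def load_published_descriptives() -> pd.DataFrame:
    """Descriptive statistics (17 traits × treatments measured; 49 rows).

    The SL/T0 row prints min 6 > max 4.4 (an apparent typo in the source
    table); it is kept as printed and carries ``suspect = True``.
    """
    with resources.as_file(_path("published_descriptives.csv")) as p:
        return load_summaries(p)


def load_published_scorecard() -> pd.DataFrame:
    """Published mu±SD score card: per-treatment category and total, overall."""
    with resources.as_file(_path("published_scorecard.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("genotype")


def load_published_indices(stress: str) -> pd.DataFrame:
    """Published seven-index matrix (+ STS column) for stress level T1 or T2."""
    if stress not in ("T1", "T2"):
        raise ValueError("stress must be 'T1' or 'T2'")
    with resources.as_file(_path(f"published_indices_{stress}.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("genotype")
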