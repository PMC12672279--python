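"""Core phenotype data model for PEG-6000 seedling drought screens.

A screen applies polyethylene-glycol (PEG 6000) osmotic stress at three
levels — T0 (0 %, control), T1 (10 %) and T2 (20 % w/v) — to a panel of
genotypes grown in a completely randomized design, and records growth,
root and biochemical traits per replicate. This module defines the trait
schema, the long-format :class:`TraitTable` container with its validation
rules, derived traits (root-to-shoot ratio, photosynthetic pigments),
descriptive statistics and percent-change summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TREATMENTS",
    "TraitMeta",
    "TRAIT_SCHEMA",
    "SCORED_TRAITS",
    "GROWTH_ROOT_TRAITS",
    "TraitTable",
    "TraitSummary",
    "PigmentResult",
    "SchemaError",
    "IntegrityError",
    "load_trait_table",
    "write_trait_table",
    "derive_ratio_trait",
    "with_ratio_trait",
    "pigment_concentrations",
    "summarize_trait",
    "summarize_all",
    "percent_change",
    "percent_change_interval",
    "load_summaries",
]

#: treatment code -> percent w/v PEG 6000 (fixed by the screen design)
TREATMENTS: dict[str, int] = {"T0": 0, "T1": 10, "T2": 20}

ALL_TREATMENTS = ("T0", "T1", "T2")


class SchemaError(ValueError):
    """Unknown trait, bad treatment code, or trait measured off-schedule."""


class IntegrityError(ValueError):
    """Duplicate observation keys or values violating trait constraints."""


@dataclass(frozen=True)
class TraitMeta:
    """Static description of one measured or derived trait."""

    name: str
    unit: str
    polarity: str  # "higher_is_better" | "lower_is_better"
    kind: str = "measured"  # "measured" | "derived"
    treatments: tuple[str, ...] = ALL_TREATMENTS
    family: str = "positive_continuous"  # count | proportion | ratio | positive_continuous


def _meta(name, unit, polarity="higher_is_better", **kw) -> TraitMeta:
    return TraitMeta(name=name, unit=unit, polarity=polarity, **kw)


#: The 17 traits of the screen. MDA and H2O2 (oxidative-stress markers) are
#: measured only under control and severe stress; R/S is derived per
#: replicate from root and shoot length.
TRAIT_SCHEMA: dict[str, TraitMeta] = {
    m.name: m
    for m in [
        _meta("DSG", "days", "lower_is_better", family="count"),
        _meta("NOL", "count", family="count"),
        _meta("TFW", "g"),
        _meta("TDW", "g"),
        _meta("SR", "fraction", family="proportion"),
        _meta("NSR", "count", family="count"),
        _meta("RL", "cm"),
        _meta("SL", "cm"),
        _meta("RFW", "g"),
        _meta("R/S", "ratio", kind="derived", family="ratio"),
        _meta("Chla", "mg/g"),
        _meta("Chlb", "mg/g"),
        _meta("TChl", "mg/g"),
        _meta("CAR", "ug/mL"),
        _meta("Pro", "umol/g"),
        _meta("MDA", "nmol/g", "lower_is_better", treatments=("T0", "T2")),
        _meta("H2O2", "umol/g", "lower_is_better", treatments=("T0", "T2")),
    ]
}

#: The 15 parameters entering the mu±SD score card (oxidative markers are
#: measured under two treatments only and are excluded).
SCORED_TRAITS: tuple[str, ...] = (
    "DSG", "NOL", "TFW", "TDW", "SR", "NSR", "RL", "SL", "RFW", "R/S",
    "Chla", "Chlb", "TChl", "CAR", "Pro",
)

#: Growth and root traits that are strongly positively correlated among
#: genotypes under well-watered conditions.
GROWTH_ROOT_TRAITS: tuple[str, ...] = (
    "NOL", "TFW", "TDW", "SR", "NSR", "RL", "SL", "RFW",
)

_COLUMNS = ["genotype", "treatment", "replicate", "trait", "value"]


class TraitTable:
    """Long-format replicate-level observations, validated on construction.

    Parameters
    ----------
    data
        DataFrame with columns ``genotype, treatment, replicate, trait,
        value``.
    schema
        Trait metadata; observations for unknown traits are rejected.
    require_balanced
        When true (default), genotypes missing any genotype × treatment ×
        replicate cell for a trait measured in that treatment are dropped
        entirely (listwise) with a logged warning, mirroring a screen in
        which only fully phenotyped genotypes are analyzed.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        schema: Mapping[str, TraitMeta] = TRAIT_SCHEMA,
        require_balanced: bool = True,
    ):
        df = data.loc[:, _COLUMNS].copy()
        df["genotype"] = df["genotype"].astype(str)
        df["treatment"] = df["treatment"].astype(str)
        df["trait"] = df["trait"].astype(str)

        bad_tr = set(df["treatment"]) - set(TREATMENTS)
        if bad_tr:
            raise SchemaError(f"unknown treatment codes: {sorted(bad_tr)}")
        bad_trait = set(df["trait"]) - set(schema)
        if bad_trait:
            raise SchemaError(f"unknown traits: {sorted(bad_trait)}")

        try:
            df["replicate"] = df["replicate"].astype(int)
            df["value"] = df["value"].astype(float)
        except (TypeError, ValueError) as exc:
            raise IntegrityError(f"non-numeric replicate/value: {exc}") from None
        if df["value"].isna().any():
            rows = df.index[df["value"].isna()].tolist()[:5]
            raise IntegrityError(f"non-numeric value in rows {rows}")

        dup = df.duplicated(["genotype", "treatment", "replicate", "trait"])
        if dup.any():
            keys = df.loc[dup, ["genotype", "treatment", "replicate", "trait"]]
            raise IntegrityError(
                f"duplicate observation keys, e.g. {keys.iloc[0].tolist()}"
            )

        for trait, meta in schema.items():
            sub = df[df["trait"] == trait]
            if sub.empty:
                continue
            off = set(sub["treatment"]) - set(meta.treatments)
            if off:
                raise SchemaError(
                    f"{trait} measured under {sorted(off)} but its schedule "
                    f"is {list(meta.treatments)}"
                )
            if (sub["value"] < 0).any():
                raise IntegrityError(f"negative values for {trait}")
            if meta.family == "count":
                frac = sub["value"] % 1
                if not np.allclose(frac, np.round(frac), atol=1e-9):
                    raise IntegrityError(f"{trait} must be integer-valued")
            if meta.family == "proportion" and (sub["value"] > 1).any():
                raise IntegrityError(f"{trait} must lie in [0, 1]")

        if require_balanced:
            df = self._drop_incomplete(df, schema)

        self.data = df.reset_index(drop=True)
        self.schema = dict(schema)

    @staticmethod
    def _drop_incomplete(df: pd.DataFrame, schema) -> pd.DataFrame:
        reps = sorted(df["replicate"].unique())
        dropped: set[str] = set()
        for trait in df["trait"].unique():
            meta = schema[trait]
            sub = df[df["trait"] == trait]
            present = set(
                map(tuple, sub[["genotype", "treatment", "replicate"]].itertuples(index=False))
            )
            for g in sub["genotype"].unique():
                for t in meta.treatments:
                    for r in reps:
                        if (g, t, r) not in present:
                            dropped.add(g)
        if dropped:
            logger.warning(
                "dropping %d genotype(s) with incomplete cells: %s",
                len(dropped), sorted(dropped),
            )
            df = df[~df["genotype"].isin(dropped)]
        return df

    # -- basic views --------------------------------------------------

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.data["genotype"].unique(), key=_genotype_key)

    @property
    def design(self) -> tuple[int, int, int]:
        """(n_genotypes, n_treatments, n_replicates)."""
        d = self.data
        return (
            d["genotype"].nunique(),
            d["treatment"].nunique(),
            d["replicate"].nunique(),
        )

    def trait_frame(self, trait: str) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no observations for trait {trait!r}")
        return sub

    def genotype_means(self, trait: str, treatment: str) -> pd.Series:
        """Per-genotype mean over replicates for one trait × treatment."""
        sub = self.trait_frame(trait)
        sub = sub[sub["treatment"] == treatment]
        if sub.empty:
            raise KeyError(f"{trait} has no observations under {treatment}")
        means = sub.groupby("genotype")["value"].mean()
        return means.reindex(sorted(means.index, key=_genotype_key))

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        a = self.data.sort_values(_COLUMNS[:4]).reset_index(drop=True)
        b = other.data.sort_values(_COLUMNS[:4]).reset_index(drop=True)
        return a.equals(b)


def _genotype_key(g: str):
    tail = g[1:] if g[:1] in ("G", "g") else g
    return (0, int(tail)) if tail.isdigit() else (1, g)


def load_trait_table(
    path: str | Path,
    schema: Mapping[str, TraitMeta] = TRAIT_SCHEMA,
    require_balanced: bool = True,
) -> TraitTable:
    """Read a long-format CSV (genotype,treatment,replicate,trait,value)."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return TraitTable(df, schema=schema, require_balanced=require_balanced)


def write_trait_table(table: TraitTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


# -- derived traits ----------------------------------------------------


def derive_ratio_trait(rl: float, sl: float) -> float:
    """Root-to-shoot ratio: root length divided by shoot length.

    Computed per replicate, before any summarization, because a mean of
    ratios is not the ratio of means.
    """
    if sl <= 0:
        raise ValueError(f"shoot length must be positive, got {sl}")
    return rl / sl


def with_ratio_trait(table: TraitTable) -> TraitTable:
    """Return a table with the R/S trait appended (computed per replicate)."""
    df = table.data
    if (df["trait"] == "R/S").any():
        return table
    rl = df[df["trait"] == "RL"].set_index(["genotype", "treatment", "replicate"])["value"]
    sl = df[df["trait"] == "SL"].set_index(["genotype", "treatment", "replicate"])["value"]
    if (sl <= 0).any():
        bad = sl.index[sl <= 0].tolist()[:5]
        raise ValueError(f"R/S undefined: zero shoot length at {bad}")
    ratio = (rl / sl).rename("value").reset_index()
    ratio["trait"] = "R/S"
    out = pd.concat([df, ratio[_COLUMNS]], ignore_index=True)
    return TraitTable(out, schema=table.schema, require_balanced=False)


@dataclass(frozen=True)
class PigmentResult:
    """Pigment concentrations from acetone-extract absorbances.

    ``tchl`` is chlorophyll a + b by definition. ``out_of_range`` marks
    results where a pigment concentration came out negative, which can
    only arise from absorbance readings outside the calibration range of
    the equations; the values are returned unchanged for inspection.
    """

    chla: float  # mg/g
    chlb: float  # mg/g
    tchl: float  # mg/g
    car: float  # ug/mL
    out_of_range: bool = False


def pigment_concentrations(a663_2: float, a646_8: float, a470: float) -> PigmentResult:
    """Chlorophyll a/b, total chlorophyll and carotenoids from absorbances.

    Uses the standard 80 %-acetone spectrophotometric equations::

        Chla = 12.25*A663.2 - 2.79*A646.8          [mg/g]
        Chlb = 21.21*A646.8 - 5.10*A663.2          [mg/g]
        TChl = Chla + Chlb                         [mg/g]
        CAR  = (1000*A470 - 1.82*Chla - 85.02*Chlb) / 198   [ug/mL]
    """
    for name, a in (("a663_2", a663_2), ("a646_8", a646_8), ("a470", a470)):
        if a < 0:
            raise ValueError(f"absorbance {name} must be >= 0, got {a}")
    chla = 12.25 * a663_2 - 2.79 * a646_8
    chlb = 21.21 * a646_8 - 5.1 * a663_2
    car = (1000.0 * a470 - 1.82 * chla - 85.02 * chlb) / 198.0
    flagged = chla < 0 or chlb < 0 or car < 0
    return PigmentResult(chla, chlb, chla + chlb, car, out_of_range=flagged)


# -- descriptive statistics --------------------------------------------


@dataclass(frozen=True)
class TraitSummary:
    """Per trait × treatment descriptives over all genotype × replicate values."""

    trait: str
    treatment: str
    mean: float
    sd: float
    cv: float  # percent; NaN when the mean is 0
    min: float
    max: float
    n: int
    suspect: bool = False


def summarize_trait(
    table: TraitTable, trait: str, treatment: str, ddof: int = 1
) -> TraitSummary:
    """Mean, sample SD (n-1), CV %, min, max, n for one trait × treatment."""
    sub = table.trait_frame(trait)
    vals = sub.loc[sub["treatment"] == treatment, "value"].to_numpy()
    if len(vals) < 2:
        raise ValueError(f"need >= 2 observations for {trait}/{treatment}")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=ddof))
    if mean == 0.0:
        cv = math.nan
        logger.warning("CV undefined for %s/%s (mean = 0)", trait, treatment)
    else:
        cv = 100.0 * sd / mean
    return TraitSummary(
        trait, treatment, mean, sd, cv, float(vals.min()), float(vals.max()), len(vals)
    )


def summarize_all(table: TraitTable, ddof: int = 1) -> pd.DataFrame:
    """Descriptive table (one row per trait × treatment measured)."""
    rows = []
    for trait in table.schema:
        if not (table.data["trait"] == trait).any():
            continue
        for t in table.schema[trait].treatments:
            s = summarize_trait(table, trait, t, ddof=ddof)
            rows.append(vars(s))
    return pd.DataFrame(rows)


# -- percent change ----------------------------------------------------


def percent_change(before: float, after: float) -> float:
    """Signed percent change 100*(after-before)/before."""
    if before == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (after - before) / before


def percent_change_interval(
    before: float, after: float, before_decimals: int, after_decimals: int
) -> tuple[float, float]:
    """Range of percent changes consistent with the printed rounding.

    When ``before`` and ``after`` are values printed with a fixed number
    of decimals, the true underlying values lie within half a printing
    unit; this returns the (min, max) percent change over that rectangle,
    used when auditing percent claims recomputed from rounded tables.
    """
    hb = 0.5 * 10.0 ** (-before_decimals)
    ha = 0.5 * 10.0 ** (-after_decimals)
    lo_b, hi_b = before - hb, before + hb
    lo_a, hi_a = after - ha, after + ha
    if lo_b <= 0:
        raise ValueError("baseline rounding interval reaches 0")
    corners = [
        percent_change(b, a) for b in (lo_b, hi_b) for a in (lo_a, hi_a)
    ]
    return min(corners), max(corners)


# -- published-summary I/O ---------------------------------------------


def load_summaries(path: str | Path) -> pd.DataFrame:
    """Load a descriptive-statistics table (trait, treatment, mean, sd, ...).

    Rows with max < min are rejected unless marked ``suspect`` (printed
    tables occasionally carry such typos; the fixture keeps them flagged
    rather than silently corrected).
    """
    raw = pd.read_csv(path, dtype=str)
    df = raw.copy()
    for col in ("mean", "sd", "cv", "min", "max"):
        df[col] = df[col].astype(float)
    df["suspect"] = raw.get("suspect", "").fillna("").str.len() > 0
    # printed decimals, for rounding-aware audits
    df["mean_decimals"] = raw["mean"].map(_decimals)
    bad = (df["max"] < df["min"]) & ~df["suspect"]
    if bad.any():
        rows = df.loc[bad, ["trait", "treatment"]].to_records(index=False).tolist()
        raise IntegrityError(f"max < min in summary rows {rows} (not flagged suspect)")
    return df


def _decimals(s: str) -> int:
    s = s.strip()
    return len(s.split(".")[1]) if "." in s else 0
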