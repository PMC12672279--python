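"""mu±SD efficiency classification and cumulative genotype scoring.

Each trait × treatment defines thresholds from the population mean (mu)
and SD of the genotype means: a genotype scoring above mu + SD is
Efficient (E, score 3), below mu - SD Inefficient (I, score 1), and in
between — bounds inclusive, the inequalities are strict — Medium (M,
score 2). Scores over the 15 screened traits are summed per treatment
(15-45) and across the three treatments (45-135); a per-treatment E/M/I
letter is then assigned by applying the same mu±SD rule to the
distribution of treatment totals themselves, a reconstruction that
reproduces the published score card exactly.

The classification rule is applied literally (higher value -> E) to every
trait by default, matching the published card even for days-to-germination
where a smaller value is agronomically better; pass
``polarity_aware=True`` to let each trait's polarity swap E and I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import SCORED_TRAITS, TRAIT_SCHEMA, TraitTable

__all__ = [
    "EmiThresholds",
    "GenotypeScoreCard",
    "compute_thresholds",
    "classify_emi",
    "score_card",
    "rank_genotypes",
    "SCORES",
]

SCORES = {"E": 3, "M": 2, "I": 1}
_TREATMENTS = ("T0", "T1", "T2")


@dataclass(frozen=True)
class EmiThresholds:
    """mu±SD classification bounds over genotype means."""

    trait: str
    treatment: str
    mu: float
    sd: float

    @property
    def upper(self) -> float:
        return self.mu + self.sd

    @property
    def lower(self) -> float:
        return self.mu - self.sd


def compute_thresholds(
    table: TraitTable, trait: str, treatment: str, ddof: int = 0
) -> EmiThresholds:
    """mu and SD over the genotype means for one trait × treatment.

    The population SD (ddof=0) is the default since the thresholds
    describe the screened population itself, not a sample from it.
    """
    means = table.genotype_means(trait, treatment)
    if len(means) < 2:
        raise ValueError(f"need >= 2 genotypes for {trait}/{treatment}")
    return EmiThresholds(
        trait, treatment, float(means.mean()), float(means.std(ddof=ddof))
    )


def classify_emi(
    value: float, thresholds: EmiThresholds, polarity: str = "higher_is_better"
) -> str:
    """E / M / I for one genotype mean; boundary values are Medium."""
    if value > thresholds.upper:
        cat = "E"
    elif value < thresholds.lower:
        cat = "I"
    else:
        cat = "M"
    if polarity == "lower_is_better" and cat != "M":
        cat = "E" if cat == "I" else "I"
    return cat


@dataclass(frozen=True)
class GenotypeScoreCard:
    """One genotype's categories, scores and totals.

    ``categories``/``scores`` are trait × treatment frames;
    ``treatment_totals`` sum the per-trait scores within a treatment
    (max 3 per trait), ``overall_total`` sums the three treatment totals,
    and ``treatment_category`` is the E/M/I letter of each treatment
    total relative to the cohort's totals.
    """

    genotype: str
    categories: pd.DataFrame
    scores: pd.DataFrame
    treatment_totals: pd.Series
    overall_total: int
    treatment_category: pd.Series


def score_card(
    table: TraitTable,
    traits: tuple[str, ...] = SCORED_TRAITS,
    polarity_aware: bool = False,
) -> dict[str, GenotypeScoreCard]:
    """Score every genotype on the given traits under all three treatments."""
    missing = [
        t for t in traits
        if not set(_TREATMENTS) <= set(np.unique(
            table.data.loc[table.data["trait"] == t, "treatment"]
        ))
    ]
    if missing:
        raise ValueError(f"traits absent or not measured under T0/T1/T2: {missing}")

    genos = table.genotypes
    cats = {t: pd.DataFrame(index=traits, columns=_TREATMENTS, dtype=object) for t in genos}
    for trait in traits:
        polarity = (
            table.schema[trait].polarity if polarity_aware else "higher_is_better"
        )
        for tr in _TREATMENTS:
            thr = compute_thresholds(table, trait, tr)
            means = table.genotype_means(trait, tr)
            for g in genos:
                cats[g].loc[trait, tr] = classify_emi(means[g], thr, polarity)

    totals = pd.DataFrame(
        {
            g: [sum(SCORES[c] for c in cats[g][tr]) for tr in _TREATMENTS]
            for g in genos
        },
        index=_TREATMENTS,
    ).T

    # per-treatment E/M/I letter from the distribution of totals
    letters = {}
    for tr in _TREATMENTS:
        col = totals[tr].astype(float)
        thr = EmiThresholds("total", tr, float(col.mean()), float(col.std(ddof=0)))
        letters[tr] = {g: classify_emi(float(col[g]), thr) for g in genos}

    out = {}
    for g in genos:
        scores = cats[g].apply(lambda col: col.map(SCORES))
        out[g] = GenotypeScoreCard(
            genotype=g,
            categories=cats[g],
            scores=scores,
            treatment_totals=totals.loc[g],
            overall_total=int(totals.loc[g].sum()),
            treatment_category=pd.Series({tr: letters[tr][g] for tr in _TREATMENTS}),
        )
    return out


def rank_genotypes(overall_totals: pd.Series | dict) -> pd.DataFrame:
    """Dense ranking by descending overall total; ties share a rank and
    are listed alphabetically (natural genotype order) for display.
    """
    s = pd.Series(dict(overall_totals) if not isinstance(overall_totals, pd.Series) else overall_totals)
    if s.empty:
        raise ValueError("no score cards to rank")
    df = s.rename("overall_total").to_frame()
    df["rank"] = s.rank(method="dense", ascending=False).astype(int)
    key = df.index.map(_natural_key)
    return df.assign(_k=key).sort_values(["rank", "_k"]).drop(columns="_k")


def cards_to_frame(cards: dict[str, GenotypeScoreCard]) -> pd.DataFrame:
    """Score-card table mirroring the published layout (category + total
    per treatment, overall)."""
    rows = {}
    for g, c in cards.items():
        row = {}
        for tr in _TREATMENTS:
            row[f"category_{tr}"] = c.treatment_category[tr]
            row[f"total_{tr}"] = int(c.treatment_totals[tr])
        row["overall"] = c.overall_total
        rows[g] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genotype"
    return df.loc[sorted(df.index, key=_natural_key)]


def _natural_key(g: str):
    tail = g[1:] if g[:1] in ("G", "g") else g
    return (0, int(tail)) if tail.isdigit() else (1, g)
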