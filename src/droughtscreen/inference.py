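"""Factorial ANOVA, Tukey HSD across treatments, per-treatment correlations.

The screen's design is a balanced CRD with genotype and treatment as
crossed fixed effects and replication as a crossed blocking factor, so
the fixed-effects decomposition has sources Genotypes, Treatments,
Replication, Genotypes × Treatments, and Error, with every F computed
against the error mean square. On a balanced design sequential and
marginal sums of squares coincide; unbalanced tables are refused rather
than silently switched to another SS type.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .traits import TraitTable

__all__ = [
    "AnovaTable",
    "TukeyResult",
    "CorrelationMatrix",
    "UnbalancedDesignError",
    "anova_glm",
    "tukey_treatments",
    "correlation_by_treatment",
    "correlation_shift_summary",
    "format_p",
]

_SOURCES = ["Genotypes", "Treatments", "Replication", "Genotypes x Treatments", "Error", "Total"]


class UnbalancedDesignError(ValueError):
    """Raised when the genotype × treatment × replicate grid is incomplete."""


@dataclass(frozen=True)
class AnovaTable:
    """Fixed-effects decomposition for one trait.

    ``table`` has one row per source with columns df, ss, ms, f, p; f and
    p are NaN where undefined (Error and Total rows, or every source when
    the error mean square is zero).
    """

    trait: str
    table: pd.DataFrame
    degenerate: bool = False  # zero error SS: F undefined

    def __getitem__(self, source: str) -> pd.Series:
        return self.table.loc[source]


def _check_balanced(df: pd.DataFrame, trait: str) -> tuple[int, int, int]:
    counts = df.pivot_table(
        index="genotype", columns="treatment", values="value", aggfunc="size",
        fill_value=0,
    )
    n_rep = counts.values.max()
    bad = counts.values != n_rep
    if bad.any():
        cells = [
            (g, t, int(counts.loc[g, t]))
            for g in counts.index for t in counts.columns
            if counts.loc[g, t] != n_rep
        ]
        raise UnbalancedDesignError(
            f"{trait}: unbalanced design; expected {n_rep} replicates per "
            f"cell, deviating cells (genotype, treatment, n): {cells[:10]}"
        )
    reps_per_combo = df.groupby(["genotype", "treatment"])["replicate"].nunique()
    if (reps_per_combo != n_rep).any():
        raise UnbalancedDesignError(f"{trait}: duplicate replicate labels within a cell")
    return counts.shape[0], counts.shape[1], int(n_rep)


def anova_glm(table: TraitTable, trait: str) -> AnovaTable:
    """Balanced fixed-effects ANOVA with a replication block.

    Sources: Genotypes, Treatments, Replication, Genotypes × Treatments,
    Error, Total. For a 37 × 3 × 3 design the dfs are (36, 2, 2, 72, 220)
    with Total 332; traits measured under two treatments have a single
    Treatments df. A constant response yields all-zero SS and undefined F
    (reported as NaN with ``degenerate=True``).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.trait_frame(trait).copy()
    n_g, n_t, n_r = _check_balanced(df, trait)
    if n_t < 2 or n_g < 2 or n_r < 2:
        raise UnbalancedDesignError(
            f"{trait}: need >= 2 levels of genotype, treatment and replicate"
        )

    if df["value"].nunique() == 1:
        # degenerate: zero variance everywhere
        N = len(df)
        dfs = [n_g - 1, n_t - 1, n_r - 1, (n_g - 1) * (n_t - 1)]
        dfs.append(N - 1 - sum(dfs))
        out = pd.DataFrame(
            {
                "df": dfs + [N - 1],
                "ss": [0.0] * 5 + [0.0],
                "ms": [0.0] * 5 + [np.nan],
                "f": [np.nan] * 4 + [np.nan, np.nan],
                "p": [np.nan] * 6,
            },
            index=_SOURCES,
        )
        return AnovaTable(trait, out, degenerate=True)

    model = smf.ols(
        "value ~ C(genotype) + C(treatment) + C(replicate) "
        "+ C(genotype):C(treatment)",
        data=df,
    ).fit()
    aov = sm.stats.anova_lm(model, typ=1)

    key = {
        "C(genotype)": "Genotypes",
        "C(treatment)": "Treatments",
        "C(replicate)": "Replication",
        "C(genotype):C(treatment)": "Genotypes x Treatments",
        "Residual": "Error",
    }
    aov = aov.rename(index=key)
    err_ms = aov.loc["Error", "sum_sq"] / aov.loc["Error", "df"]
    rows = {}
    for src in _SOURCES[:-1]:
        r = aov.loc[src]
        ms = r["sum_sq"] / r["df"]
        if src == "Error":
            f = p = np.nan
        elif err_ms > 0:
            f = ms / err_ms
            p = stats.f.sf(f, r["df"], aov.loc["Error", "df"])
        else:
            f = p = np.nan
        rows[src] = (int(r["df"]), r["sum_sq"], ms, f, p)
    total_ss = aov["sum_sq"].sum()
    rows["Total"] = (int(aov["df"].sum()), total_ss, np.nan, np.nan, np.nan)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "ss", "ms", "f", "p"]
    ).loc[_SOURCES]
    return AnovaTable(trait, out, degenerate=bool(err_ms == 0))


def format_p(p: float) -> str:
    """Report extremely small p-values as a bound rather than 0."""
    if np.isnan(p):
        return "NA"
    return "<1e-16" if p < 1e-16 else f"{p:.3g}"


# -- Tukey HSD ---------------------------------------------------------


@dataclass(frozen=True)
class TukeyResult:
    """All pairwise treatment comparisons with the studentized range.

    Uses the factorial-model error mean square (not a one-way pooled
    variance). ``letters`` is the compact letter display: treatments
    sharing a letter do not differ at the given alpha.
    """

    trait: str
    alpha: float
    comparisons: pd.DataFrame  # a, b, diff, q, p_adj, ci_low, ci_high
    letters: dict[str, str]
    means: pd.Series


def tukey_treatments(table: TraitTable, trait: str, alpha: float = 0.05) -> TukeyResult:
    aov = anova_glm(table, trait)
    if aov.degenerate:
        raise ValueError(f"{trait}: zero error mean square; Tukey undefined")
    ms_err = aov["Error"]["ms"]
    df_err = int(aov["Error"]["df"])

    df = table.trait_frame(trait)
    means = df.groupby("treatment")["value"].mean().sort_index()
    k = len(means)
    if k < 2:
        raise ValueError("need >= 2 treatments")
    n_per = df.groupby("treatment").size()
    if n_per.nunique() != 1:
        raise UnbalancedDesignError(f"{trait}: unequal treatment group sizes")
    n = int(n_per.iloc[0])

    se = np.sqrt(ms_err / n)
    q_crit = stats.studentized_range.ppf(1 - alpha, k, df_err)
    rows = []
    for a, b in combinations(means.index, 2):
        diff = means[a] - means[b]
        q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df_err))
        rows.append(
            {
                "a": a, "b": b, "diff": diff, "q": q, "p_adj": min(p_adj, 1.0),
                "ci_low": diff - q_crit * se, "ci_high": diff + q_crit * se,
            }
        )
    comp = pd.DataFrame(rows)
    letters = _compact_letters(means, comp, alpha)
    return TukeyResult(trait, alpha, comp, letters, means)


def _compact_letters(means: pd.Series, comp: pd.DataFrame, alpha: float) -> dict[str, str]:
    """Greedy compact letter display from the largest mean downward.

    Ties broken by descending mean, then label order.
    """
    order = sorted(means.index, key=lambda t: (-means[t], t))
    differs = {
        frozenset((r.a, r.b)) for r in comp.itertuples() if r.p_adj < alpha
    }
    groups: list[set[str]] = []
    for t in order:
        placed = False
        for grp in groups:
            if all(frozenset((t, u)) not in differs for u in grp):
                grp.add(t)
                placed = True
        if not placed:
            groups.append({t})
    # absorb redundant groups (subsets)
    groups = [g for i, g in enumerate(groups)
              if not any(g < h for j, h in enumerate(groups) if i != j)]
    letters = {t: "" for t in means.index}
    for letter, grp in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for t in grp:
            letters[t] += letter
    return {t: "".join(sorted(s)) for t, s in letters.items()}


# -- correlations ------------------------------------------------------


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pearson correlations among traits within one treatment.

    By default computed on genotype means (one point per genotype), the
    scale on which trait relationships among genotypes are described;
    replicate-level mode is available behind ``level``. Zero-variance
    traits yield NaN entries and are listed in ``degenerate``.
    """

    treatment: str
    traits: tuple[str, ...]
    r: pd.DataFrame
    n: int
    degenerate: tuple[str, ...] = ()


def correlation_by_treatment(
    table: TraitTable,
    traits: list[str],
    treatment: str,
    level: str = "genotype",
) -> CorrelationMatrix:
    if level not in ("genotype", "replicate"):
        raise ValueError("level must be 'genotype' or 'replicate'")
    cols = {}
    for tr in traits:
        sub = table.trait_frame(tr)
        sub = sub[sub["treatment"] == treatment]
        if sub.empty:
            raise KeyError(f"{tr} has no observations under {treatment}")
        if level == "genotype":
            cols[tr] = sub.groupby("genotype")["value"].mean()
        else:
            cols[tr] = sub.set_index(["genotype", "replicate"])["value"]
    wide = pd.DataFrame(cols).dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 paired observations per trait pair")
    degenerate = tuple(c for c in wide.columns if wide[c].nunique() == 1)
    r = wide.corr(method="pearson")
    return CorrelationMatrix(
        treatment, tuple(traits), r, len(wide), degenerate=degenerate
    )


def correlation_shift_summary(matrices: dict[str, CorrelationMatrix]) -> pd.DataFrame:
    """Per trait pair, the correlation under each treatment and how it
    moves with stress intensity.

    Classification: 'increasing' when r strictly rises along the
    treatment order, 'decreasing' when it strictly falls, otherwise
    'non-monotone' (identical values give non-monotone with zero span).
    """
    codes = sorted(matrices)
    base = matrices[codes[0]].traits
    for c in codes[1:]:
        if matrices[c].traits != base:
            raise ValueError("matrices cover different trait sets")
    rows = []
    for i, a in enumerate(base):
        for b in base[i + 1:]:
            rs = [float(matrices[c].r.loc[a, b]) for c in codes]
            diffs = np.diff(rs)
            if np.all(diffs > 0):
                cls = "increasing"
            elif np.all(diffs < 0):
                cls = "decreasing"
            else:
                cls = "non-monotone"
            rows.append(
                {"trait_a": a, "trait_b": b,
                 **{f"r_{c}": r for c, r in zip(codes, rs)},
                 "span": max(rs) - min(rs), "classification": cls}
            )
    return pd.DataFrame(rows)
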