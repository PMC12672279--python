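"""Drought stress-tolerance indices, the composite score, and a table auditor.

Seven classical indices compare a genotype's productivity (here: total
seedling dry weight) under control (C) and stress (T), relative to the
cohort means xC and xT:

    SSI  = (1 - T/C) / (1 - xT/xC)     stress susceptibility (Fischer-Maurer)
    MPI  = (C + T) / 2                 mean productivity [g]
    GMPI = sqrt(C*T)                   geometric mean productivity [g]
    HMI  = 2*C*T / (C + T)             harmonic mean [g]
    STI  = C*T / xC^2                  stress tolerance index
    TI   = C - T                       tolerance (absolute loss) [g]
    SI   = T / C                       stress index (fraction retained)

and the composite Stress Tolerance Score STS = SSI + MPI + GMPI + HMI +
STI + TI + SI.

GMPI has two modes because published index tables in this literature do
not always match the stated definition: ``formula`` computes sqrt(C*T);
``as_published`` computes the raw product C*T, which is what the packaged
reference tables actually contain (verified cell by cell by the auditor).
The discrepancy is surfaced, never silently reconciled.

The auditor exploits that MPI and SI are an invertible 2×2 system in
(C, T): C = 2*MPI/(1+SI), T = SI*C. From each published row it recovers
(C, T), recomputes every index, infers the cohort means from the STI and
SSI columns by least squares, and reports per-cell deviations at printed
precision together with an input-rounding envelope (the printed MPI and
SI are 3-dp roundings, and that alone moves recomputed cells).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .datasets import INDEX_COLUMNS
from .traits import TraitTable

__all__ = [
    "DryWeightPair",
    "CohortMeans",
    "IndexVector",
    "compute_indices",
    "compute_sts",
    "index_matrix",
    "cohort_means",
    "recover_c_t",
    "audit_published_table",
    "AuditReport",
]

GmpiMode = Literal["formula", "as_published"]

#: half a printing unit at 3 decimals, slightly loosened for input rounding
PRINT_TOL = 0.0015


@dataclass(frozen=True)
class DryWeightPair:
    """Dry weight under control (c) and under stress (t), grams."""

    c: float
    t: float

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError(f"control dry weight must be positive, got {self.c}")
        if self.t < 0:
            raise ValueError(f"stress dry weight must be >= 0, got {self.t}")


@dataclass(frozen=True)
class CohortMeans:
    """Cohort-average dry weights under control (xc) and stress (xt)."""

    xc: float
    xt: float

    def __post_init__(self):
        if self.xc <= 0:
            raise ValueError("cohort control mean must be positive")
        if self.xt < 0:
            raise ValueError("cohort stress mean must be >= 0")


@dataclass(frozen=True)
class IndexVector:
    ssi: float
    mpi: float
    gmpi: float
    hmi: float
    sti: float
    ti: float
    si: float
    mode: GmpiMode = "formula"

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.ssi, self.mpi, self.gmpi, self.hmi, self.sti, self.ti, self.si],
            index=list(INDEX_COLUMNS),
        )


def compute_indices(
    pair: DryWeightPair, means: CohortMeans, mode: GmpiMode = "formula"
) -> IndexVector:
    """All seven indices for one genotype at one stress level.

    SSI requires xt != xc (no cohort-level stress effect leaves the
    susceptibility scale undefined).
    """
    c, t = pair.c, pair.t
    xc, xt = means.xc, means.xt
    if xt == xc:
        raise ZeroDivisionError("SSI undefined when cohort means are equal (xt == xc)")
    si = t / c
    ssi = (1.0 - si) / (1.0 - xt / xc)
    mpi = (c + t) / 2.0
    gmpi = float(np.sqrt(c * t)) if mode == "formula" else c * t
    hmi = 2.0 * c * t / (c + t) if (c + t) > 0 else 0.0
    sti = c * t / xc**2
    ti = c - t
    return IndexVector(ssi, mpi, gmpi, hmi, sti, ti, si, mode=mode)


def compute_sts(v: IndexVector | pd.DataFrame, mode: str = "as_published"):
    """Stress Tolerance Score.

    ``as_published`` is the plain sum of the seven components, which is
    what published STS columns equal; ``standardized`` sums per-column
    z-scores across the cohort (only defined for a matrix) and is offered
    because the method is sometimes described that way.
    """
    if isinstance(v, IndexVector):
        if mode != "as_published":
            raise ValueError("standardized STS needs the whole cohort matrix")
        return float(v.as_series().sum())
    m = v.loc[:, list(INDEX_COLUMNS)]
    if mode == "as_published":
        return m.sum(axis=1)
    if mode == "standardized":
        z = (m - m.mean()) / m.std(ddof=0)
        return z.sum(axis=1)
    raise ValueError(f"unknown STS mode {mode!r}")


def cohort_means(table: TraitTable, stress: str, trait: str = "TDW") -> CohortMeans:
    """Cohort-average dry weight (mean of genotype means) under control
    and the given stress level."""
    return CohortMeans(
        xc=float(table.genotype_means(trait, "T0").mean()),
        xt=float(table.genotype_means(trait, stress).mean()),
    )


def index_matrix(
    table: TraitTable,
    stress: str,
    trait: str = "TDW",
    mode: GmpiMode = "formula",
    sts_mode: str = "as_published",
) -> pd.DataFrame:
    """Seven-index matrix (+ STS) for every genotype at one stress level.

    C and T are genotype means of the dry-weight trait under T0 and the
    stress treatment; xc/xt are per-stress-level cohort means.
    """
    if stress not in ("T1", "T2"):
        raise ValueError("stress must be 'T1' or 'T2'")
    cs = table.genotype_means(trait, "T0")
    ts = table.genotype_means(trait, stress)
    means = cohort_means(table, stress, trait)
    rows = {}
    for g in cs.index:
        v = compute_indices(DryWeightPair(cs[g], ts[g]), means, mode=mode)
        rows[g] = v.as_series()
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "genotype"
    out["STS"] = compute_sts(out, mode=sts_mode)
    return out


def recover_c_t(mpi: float, si: float) -> DryWeightPair:
    """Invert the MPI/SI definitions: C = 2*MPI/(1+SI), T = SI*C."""
    if mpi <= 0:
        raise ValueError(f"MPI must be positive to invert, got {mpi}")
    if si <= -1:
        raise ValueError(f"SI must exceed -1 to invert, got {si}")
    c = 2.0 * mpi / (1.0 + si)
    return DryWeightPair(c=c, t=si * c)


# -- auditor -----------------------------------------------------------


@dataclass(frozen=True)
class AuditReport:
    """Outcome of back-deriving a published index table.

    ``recomputed`` holds the indices recomputed from the recovered
    (C, T); ``deviations`` the absolute printed-minus-recomputed gaps;
    ``envelope_exceeded`` marks cells whose gap cannot be explained by
    the 3-dp rounding of the printed MPI/SI inputs plus half a printing
    unit of the audited cell itself; ``flagged`` marks cells beyond the
    plain printed-precision tolerance.
    """

    recovered: pd.DataFrame  # c, t per genotype
    recomputed: pd.DataFrame
    deviations: pd.DataFrame
    flagged: pd.DataFrame
    envelope_exceeded: pd.DataFrame
    inferred_xc: float
    inferred_xt: float
    gmpi_matches_product: bool
    sts_is_row_sum: bool
    max_sts_dev: float
    non_invertible: tuple[str, ...]

    def summary(self) -> str:
        lines = [
            f"inferred cohort means: xc = {self.inferred_xc:.4f} g, "
            f"xt = {self.inferred_xt:.4f} g",
            f"GMPI column matches C*T (not sqrt): {self.gmpi_matches_product}",
            f"STS column equals the row sum (max dev {self.max_sts_dev:.4f}): "
            f"{self.sts_is_row_sum}",
        ]
        for col in self.flagged.columns:
            n = int(self.flagged[col].sum())
            n_env = int(self.envelope_exceeded[col].sum())
            lines.append(
                f"{col}: {n}/{len(self.flagged)} rows beyond ±{PRINT_TOL}, "
                f"{n_env} beyond the input-rounding envelope"
            )
        if self.non_invertible:
            lines.append(f"non-invertible rows: {list(self.non_invertible)}")
        return "\n".join(lines)


def audit_published_table(
    matrix: pd.DataFrame, means: CohortMeans | None = None
) -> AuditReport:
    """Verify a published index table by algebraic back-derivation.

    ``matrix`` must contain the seven index columns (an STS column, if
    present, is checked against the row sum). When ``means`` is omitted,
    xc is inferred per row from STI (xc^2 = C*T/STI, median across rows)
    and xt from the SSI column by least squares of (1 - SI) on SSI.
    """
    m = matrix.loc[:, list(INDEX_COLUMNS)].astype(float)
    ok = (m["MPI"] > 0) & (m["SI"] > -1)
    non_invertible = tuple(m.index[~ok])
    m = m[ok]

    c = 2.0 * m["MPI"] / (1.0 + m["SI"])
    t = m["SI"] * c
    recovered = pd.DataFrame({"c": c, "t": t})

    if means is None:
        xc = float(np.sqrt((c * t / m["STI"]).median()))
        # (1 - si) = ssi * (1 - xt/xc): least squares through the origin
        slope = float(np.sum(m["SSI"] * (1.0 - m["SI"])) / np.sum(m["SSI"] ** 2))
        xt = xc * (1.0 - slope)
    else:
        xc, xt = means.xc, means.xt

    denom = 1.0 - xt / xc
    recomputed = pd.DataFrame(
        {
            "SSI": (1.0 - m["SI"]) / denom,
            "MPI": (c + t) / 2.0,
            "GMPI": c * t,  # as published: the product
            "HMI": 2.0 * c * t / (c + t),
            "STI": c * t / xc**2,
            "TI": c - t,
            "SI": t / c,
        }
    )
    deviations = (m - recomputed).abs()
    flagged = deviations > PRINT_TOL
    envelope_exceeded = flagged & ~_within_rounding_envelope(m, xc, denom)

    gmpi_prod_dev = (m["GMPI"] - c * t).abs().max()
    gmpi_sqrt_dev = (m["GMPI"] - np.sqrt(c * t)).abs().max()

    if "STS" in matrix.columns:
        sts_dev = (matrix.loc[m.index, "STS"] - m.sum(axis=1)).abs()
        max_sts_dev = float(sts_dev.max())
    else:
        max_sts_dev = float("nan")

    return AuditReport(
        recovered=recovered,
        recomputed=recomputed,
        deviations=deviations,
        flagged=flagged,
        envelope_exceeded=envelope_exceeded,
        inferred_xc=xc,
        inferred_xt=xt,
        gmpi_matches_product=bool(gmpi_prod_dev < 10 * PRINT_TOL < gmpi_sqrt_dev),
        sts_is_row_sum=bool(max_sts_dev <= 3.5e-3),  # sum of seven 3-dp roundings
        max_sts_dev=max_sts_dev,
        non_invertible=non_invertible,
    )


def _within_rounding_envelope(m: pd.DataFrame, xc: float, denom: float) -> pd.DataFrame:
    """Per-cell interval check: could the printed cell and the recomputed
    cell differ only because the printed MPI/SI are 3-dp roundings?

    Evaluates the recomputation at the four corners of the MPI × SI
    rounding rectangle and allows half a printing unit on the audited
    cell itself.
    """
    half = 0.0005
    lo = pd.DataFrame(np.inf, index=m.index, columns=list(INDEX_COLUMNS))
    hi = pd.DataFrame(-np.inf, index=m.index, columns=list(INDEX_COLUMNS))
    for dm in (-half, half):
        for ds in (-half, half):
            mpi = m["MPI"] + dm
            si = m["SI"] + ds
            c = 2.0 * mpi / (1.0 + si)
            t = si * c
            corner = pd.DataFrame(
                {
                    "SSI": (1.0 - si) / denom,
                    "MPI": mpi,
                    "GMPI": c * t,
                    "HMI": 2.0 * c * t / (c + t),
                    "STI": c * t / xc**2,
                    "TI": c - t,
                    "SI": si,
                }
            )
            lo = np.minimum(lo, corner)
            hi = np.maximum(hi, corner)
    return (m >= lo - half) & (m <= hi + half)
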