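"""End-to-end orchestration: load or simulate, analyze, audit, report.

A run executes the full screening analysis in order — trait table,
descriptives, percent changes, ANOVA + Tukey, per-treatment correlations,
mu±SD score card, tolerance indices + STS, PCA, published-table audit —
writing one output file per stage plus a manifest capturing the config,
package version, input checksum, per-stage status/timing, warnings and
output checksums. A fixed (config, seed) pair yields byte-identical
numeric outputs; all randomness flows from the single seed through
numpy's SeedSequence spawning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import (
    PERCENT_CLAIMS,
    load_published_descriptives,
    load_published_indices,
    load_published_scorecard,
)
from .indices import audit_published_table, index_matrix
from .inference import (
    anova_glm,
    correlation_by_treatment,
    correlation_shift_summary,
    format_p,
    tukey_treatments,
)
from .pca import pca_on_indices, scree_data
from .scoring import cards_to_frame, rank_genotypes, score_card
from .simulate import default_config, generate_cohort
from .traits import (
    SCORED_TRAITS,
    load_trait_table,
    percent_change,
    percent_change_interval,
    summarize_all,
    write_trait_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineError", "run_pipeline", "render_report"]

#: traits of the published correlation heatmap
_CORR_TRAITS = ["DSG", "NOL", "SL", "TFW", "TDW", "SR", "NSR", "RL", "RFW", "R/S"]


class PipelineError(RuntimeError):
    """A stage failed; the manifest records which and why."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full run.

    Exactly one of ``input_path`` (a long-format trait CSV) or
    ``synthetic`` must be set; synthetic runs require a seed.
    """

    outdir: str | Path
    input_path: str | Path | None = None
    synthetic: bool = False
    seed: int | None = None
    n_genotypes: int = 37
    replicates: int = 3
    variance_partition: tuple[float, float, float] = (0.4, 0.2, 0.4)
    polarity_aware: bool = False
    gmpi_mode: str = "formula"
    sts_mode: str = "as_published"
    pca_scaling: str = "correlation"
    alpha: float = 0.05
    audit_published: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if bool(self.input_path) == bool(self.synthetic):
            raise ValueError("set exactly one of input_path / synthetic")
        if self.synthetic and self.seed is None:
            raise ValueError("synthetic runs require a seed")


@dataclass
class RunManifest:
    config: dict
    version: str
    input_checksum: str = ""
    stages: dict = field(default_factory=dict)  # name -> {status, seconds, error?}
    warnings: list = field(default_factory=list)
    output_checksums: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    manifest = RunManifest(config=dataclasses.asdict(config), version=__version__)
    manifest_path = out / "manifest.json"

    handler = _WarningCollector(manifest.warnings)
    logging.getLogger("droughtscreen").addHandler(handler)
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:  # record, then surface with nonzero exit at CLI
        stage = manifest.stages and list(manifest.stages)[-1]
        logger.error("stage %s failed: %s", stage, exc)
        manifest_path.write_text(manifest.to_json())
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("droughtscreen").removeHandler(handler)

    for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if p != manifest_path:
            manifest.output_checksums[p.name] = _sha256(p)
    manifest_path.write_text(manifest.to_json())
    return manifest


class _WarningCollector(logging.Handler):
    def __init__(self, sink: list):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(self.format(record))


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            manifest.stages[name] = {"status": "running"}
            self.t0 = time.perf_counter()

        def __exit__(self, et, ev, tb):
            entry = manifest.stages[name]
            entry["seconds"] = round(time.perf_counter() - self.t0, 3)
            if et is None:
                entry["status"] = "ok"
            else:
                entry["status"] = "failed"
                entry["error"] = str(ev)
            return False

    return _Ctx()


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    with _stage(manifest, "input"):
        if config.synthetic:
            seeds = np.random.SeedSequence(config.seed).spawn(1)
            cohort_cfg = default_config(
                n_genotypes=config.n_genotypes,
                replicates=config.replicates,
                variance_partition=config.variance_partition,
            )
            table = generate_cohort(cohort_cfg, seed=seeds[0])
            write_trait_table(table, out / "trait_table.csv")
            manifest.input_checksum = _sha256(out / "trait_table.csv")
        else:
            table = load_trait_table(config.input_path)
            manifest.input_checksum = _sha256(Path(config.input_path))

    with _stage(manifest, "descriptives"):
        summaries = summarize_all(table)
        summaries.to_csv(out / "descriptives.csv", index=False)

    with _stage(manifest, "percent_changes"):
        rows = []
        for trait in summaries["trait"].unique():
            sub = summaries[summaries["trait"] == trait].set_index("treatment")
            pair = ("T0", "T2") if "T2" in sub.index else None
            if pair and sub.loc["T0", "mean"] != 0:
                rows.append(
                    {
                        "trait": trait,
                        "from": pair[0],
                        "to": pair[1],
                        "pct_change": percent_change(
                            sub.loc["T0", "mean"], sub.loc["T2", "mean"]
                        ),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "percent_changes.csv", index=False)

    with _stage(manifest, "anova_tukey"):
        aov_rows, letter_rows = [], []
        for trait in SCORED_TRAITS + ("MDA", "H2O2"):
            if not (table.data["trait"] == trait).any():
                continue
            aov = anova_glm(table, trait)
            for src, r in aov.table.iterrows():
                aov_rows.append(
                    {"trait": trait, "source": src, "df": r["df"], "ss": r["ss"],
                     "ms": r["ms"], "f": r["f"], "p": r["p"],
                     "p_display": format_p(r["p"])}
                )
            if not aov.degenerate and table.schema[trait].treatments == ("T0", "T1", "T2"):
                tk = tukey_treatments(table, trait, alpha=config.alpha)
                for t, letter in tk.letters.items():
                    letter_rows.append(
                        {"trait": trait, "treatment": t,
                         "mean": tk.means[t], "letters": letter}
                    )
        pd.DataFrame(aov_rows).to_csv(out / "anova.csv", index=False)
        pd.DataFrame(letter_rows).to_csv(out / "tukey_letters.csv", index=False)

    with _stage(manifest, "correlations"):
        mats = {}
        traits = [t for t in _CORR_TRAITS if (table.data["trait"] == t).any()]
        for t in ("T0", "T1", "T2"):
            mats[t] = correlation_by_treatment(table, traits, t)
            mats[t].r.to_csv(out / f"correlation_{t}.csv")
        correlation_shift_summary(mats).to_csv(out / "correlation_shifts.csv", index=False)

    with _stage(manifest, "scoring"):
        cards = score_card(table, polarity_aware=config.polarity_aware)
        frame = cards_to_frame(cards)
        frame.to_csv(out / "scorecard.csv")
        rank_genotypes(frame["overall"]).to_csv(out / "score_ranking.csv")

    with _stage(manifest, "indices"):
        for stress in ("T1", "T2"):
            im = index_matrix(
                table, stress, mode=config.gmpi_mode, sts_mode=config.sts_mode
            )
            im.to_csv(out / f"indices_{stress}.csv")

    with _stage(manifest, "pca"):
        for stress in ("T1", "T2"):
            im = pd.read_csv(out / f"indices_{stress}.csv", index_col=0)
            res = pca_on_indices(im.drop(columns="STS"), scaling=config.pca_scaling)
            scree_data(res).to_csv(out / f"pca_scree_{stress}.csv", index=False)
            res.loadings.to_csv(out / f"pca_loadings_{stress}.csv")
            res.contributions_pct.to_csv(out / f"pca_contributions_{stress}.csv")

    if config.audit_published:
        with _stage(manifest, "audit"):
            audit = run_published_audit()
            (out / "audit.json").write_text(json.dumps(audit, indent=2))


def run_published_audit() -> dict:
    """Audit the packaged published tables: index back-derivation per
    stress level, score-card arithmetic, percent-change claims."""
    report: dict = {}
    for stress in ("T1", "T2"):
        pub = load_published_indices(stress)
        a = audit_published_table(pub)
        report[f"indices_{stress}"] = {
            "inferred_xc": a.inferred_xc,
            "inferred_xt": a.inferred_xt,
            "gmpi_matches_product": a.gmpi_matches_product,
            "sts_is_row_sum": a.sts_is_row_sum,
            "max_sts_dev": a.max_sts_dev,
            "cells_beyond_print_tol": {
                c: int(a.flagged[c].sum()) for c in a.flagged.columns
            },
            "cells_beyond_rounding_envelope": {
                c: int(a.envelope_exceeded[c].sum())
                for c in a.envelope_exceeded.columns
            },
            "summary": a.summary(),
        }

    card = load_published_scorecard()
    totals_ok = (
        card[["total_T0", "total_T1", "total_T2"]].sum(axis=1) == card["overall"]
    )
    ranking = rank_genotypes(card["overall"])
    report["scorecard"] = {
        "overall_equals_sum": bool(totals_ok.all()),
        "mismatched_rows": list(card.index[~totals_ok]),
        "top_rank": list(ranking.index[ranking["rank"] == 1]),
    }

    desc = load_published_descriptives()
    claims = []
    for trait, claimed in PERCENT_CLAIMS.items():
        sub = desc[desc["trait"] == trait].set_index("treatment")
        before, after = sub.loc["T0"], sub.loc["T2"]
        recomputed = percent_change(before["mean"], after["mean"])
        lo, hi = percent_change_interval(
            before["mean"], after["mean"],
            int(before["mean_decimals"]), int(after["mean_decimals"]),
        )
        claims.append(
            {
                "trait": trait,
                "claimed_pct": claimed,
                "recomputed_pct": round(recomputed, 3),
                "abs_dev": round(abs(recomputed - claimed), 3),
                "within_half_point": bool(abs(recomputed - claimed) <= 0.5),
                # claim consistent with SOME unrounding of the printed means
                "within_rounding_envelope": bool(lo - 0.5 <= claimed <= hi + 0.5),
            }
        )
    report["percent_claims"] = claims
    return report


# -- report ------------------------------------------------------------


def render_report(outdir: str | Path) -> str:
    """Human-readable markdown summary of a completed (or partial) run."""
    out = Path(outdir)

    def section(title: str, fname: str, render) -> str:
        p = out / fname
        body = render(p) if p.exists() else "_not run_"
        return f"## {title}\n\n{body}\n"

    def table_md(p: Path, n: int | None = None, **kw) -> str:
        df = pd.read_csv(p, **kw)
        if n:
            df = df.head(n)
        return "```\n" + df.to_string(index=False) + "\n```"

    parts = ["# Drought screening report\n"]
    parts.append(section("Descriptive statistics", "descriptives.csv",
                         lambda p: table_md(p)))
    parts.append(section("Percent change (control to severe stress)",
                         "percent_changes.csv", _percent_paragraphs))
    parts.append(section("ANOVA (mean squares and significance)", "anova.csv",
                         _anova_wide))
    parts.append(section("Tukey letters", "tukey_letters.csv",
                         lambda p: table_md(p)))
    parts.append(section("Score card (mu±SD classification)", "scorecard.csv",
                         _scorecard_md))
    for stress in ("T1", "T2"):
        parts.append(section(f"Tolerance indices under {stress}",
                             f"indices_{stress}.csv",
                             lambda p: table_md(p, index_col=0)))
        parts.append(section(f"PCA scree under {stress}",
                             f"pca_scree_{stress}.csv", lambda p: table_md(p)))
    parts.append(section("Published-table audit", "audit.json",
                         lambda p: "```json\n" + p.read_text() + "\n```"))
    report = "\n".join(parts)
    (out / "report.md").write_text(report)
    return report


def _percent_paragraphs(p: Path) -> str:
    df = pd.read_csv(p)
    bits = []
    for _, r in df.iterrows():
        word = "increased" if r["pct_change"] > 0 else "decreased"
        bits.append(
            f"{r['trait']} {word} by {abs(r['pct_change']):.2f}% "
            f"from {r['from']} to {r['to']}."
        )
    return " ".join(bits)


def _anova_wide(p: Path) -> str:
    df = pd.read_csv(p)
    wide = df.pivot(index="trait", columns="source", values="ms")
    return "```\n" + wide.to_string(float_format=lambda x: f"{x:.4g}") + "\n```"


def _scorecard_md(p: Path) -> str:
    df = pd.read_csv(p, index_col=0).sort_values("overall", ascending=False)
    return "```\n" + df.to_string() + "\n```"
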