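"""Synthetic cohort generator calibrated to published descriptive statistics.

The published screen did not deposit replicate-level data, so downstream
stages are exercised on synthetic cohorts with the same design (balanced
genotype × treatment × replicate CRD) and the same per trait × treatment
marginal mean and SD as the published descriptives. The generative model is
a two-moment Gaussian decomposition

    value(g, t, r) = mean(trait, t)
                     + sd(trait, t) * ( sqrt(f_G)*gamma_g
                                      + sqrt(f_GT)*delta_{g,t}
                                      + sqrt(f_E)*eps_{g,t,r} )

with gamma, delta, eps independent standard normals and (f_G, f_GT, f_E)
the variance partition among genotype, genotype × treatment and residual
components. Treatment is a fixed effect absorbed into the per-treatment
target means. Trait families add post-processing: counts are rounded to
non-negative integers, proportions clipped to [0, 1], positive continuous
traits resampled at the residual level when negative. The root-to-shoot
ratio is derived by dividing generated root length by shoot length, never
simulated independently.

Genotype archetypes (known-truth tolerant/susceptible lines) can be
injected by shifting stress-treatment means, giving scoring and index
recovery tests a ground truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import (
    GROWTH_ROOT_TRAITS,
    TRAIT_SCHEMA,
    TraitMeta,
    TraitTable,
    with_ratio_trait,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "EffectDecomposition",
    "calibrate_from_summaries",
    "default_config",
    "generate_cohort",
    "inject_archetypes",
]

_RESAMPLE_LIMIT = 100


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``targets`` maps (trait, treatment) to (mean, sd) on the trait's own
    scale. ``archetypes`` maps genotype labels to +1 (tolerant) or -1
    (susceptible); their stress-treatment means are shifted by
    ``archetype_shift`` target SDs in the direction given by the trait's
    polarity (control is untouched).
    """

    n_genotypes: int = 37
    replicates: int = 3
    targets: Mapping[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    variance_partition: tuple[float, float, float] = (0.4, 0.2, 0.4)
    schema: Mapping[str, TraitMeta] = field(default_factory=lambda: dict(TRAIT_SCHEMA))
    cross_trait_correlation: float = 0.7
    correlated_traits: tuple[str, ...] = GROWTH_ROOT_TRAITS
    archetypes: Mapping[str, int] = field(default_factory=dict)
    archetype_shift: float = 0.0

    def __post_init__(self):
        f = self.variance_partition
        if len(f) != 3 or any(x < 0 or x > 1 for x in f) or abs(sum(f) - 1) > 1e-9:
            raise ValueError(f"variance partition must be 3 fractions summing to 1, got {f}")
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        if any(sd < 0 for _, sd in self.targets.values()):
            raise ValueError("target SDs must be >= 0")
        if not 0 <= self.cross_trait_correlation < 1:
            raise ValueError("cross-trait correlation must be in [0, 1)")
        if any(d not in (-1, +1) for d in self.archetypes.values()):
            raise ValueError("archetype directions must be +1 or -1")

    @property
    def genotype_labels(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genotypes)]

    @property
    def simulated_traits(self) -> list[str]:
        """Measured traits with targets, in schema order (derived excluded)."""
        return [
            t for t, m in self.schema.items()
            if m.kind == "measured" and any(k[0] == t for k in self.targets)
        ]


@dataclass(frozen=True)
class EffectDecomposition:
    """Latent effects behind one generated trait.

    Genotype and interaction effects are on the standardized (unit-SD)
    scale — the generator multiplies them by the treatment-specific
    target SD, so a single per-genotype effect on the raw scale does not
    exist when SDs differ across treatments. ``residual_sd`` is on the
    trait's scale, per treatment.
    """

    genotype_effects: pd.Series  # indexed by genotype, unit scale
    interaction_effects: pd.DataFrame  # genotype × treatment, unit scale
    residual_sd: pd.Series  # per treatment, trait scale


def calibrate_from_summaries(
    summaries: pd.DataFrame,
    variance_partition: tuple[float, float, float] = (0.4, 0.2, 0.4),
    n_genotypes: int = 37,
    replicates: int = 3,
    schema: Mapping[str, TraitMeta] = TRAIT_SCHEMA,
) -> CohortConfig:
    """Build a config whose marginal mean/SD per trait × treatment equal
    the given descriptive table (columns trait, treatment, mean, sd).

    Raises if a measured trait in the table is missing any treatment of
    its measurement schedule.
    """
    targets: dict[tuple[str, str], tuple[float, float]] = {}
    for row in summaries.itertuples(index=False):
        if row.trait not in schema:
            raise ValueError(f"summary row for unknown trait {row.trait!r}")
        targets[(row.trait, row.treatment)] = (float(row.mean), float(row.sd))
    for trait, meta in schema.items():
        if meta.kind != "measured":
            continue
        have = {t for (tr, t) in targets if tr == trait}
        if have and have != set(meta.treatments):
            raise ValueError(
                f"calibration for {trait} missing treatments "
                f"{sorted(set(meta.treatments) - have)}"
            )
    return CohortConfig(
        n_genotypes=n_genotypes,
        replicates=replicates,
        targets=targets,
        variance_partition=variance_partition,
        schema=dict(schema),
    )


def default_config(**kw) -> CohortConfig:
    """Config calibrated to the packaged published descriptives."""
    from .datasets import load_published_descriptives

    return calibrate_from_summaries(load_published_descriptives(), **kw)


def inject_archetypes(
    config: CohortConfig,
    tolerant_ids: Iterable[str],
    susceptible_ids: Iterable[str],
    shift: float,
) -> CohortConfig:
    """Return a config with known tolerant/susceptible genotypes.

    Tolerant genotypes get +``shift`` target SDs on higher-is-better
    traits under stress treatments (and -shift on lower-is-better);
    susceptible genotypes the reverse. Control means are untouched.
    """
    tol, sus = set(tolerant_ids), set(susceptible_ids)
    if tol & sus:
        raise ValueError(f"overlapping archetype IDs: {sorted(tol & sus)}")
    labels = set(config.genotype_labels)
    unknown = (tol | sus) - labels
    if unknown:
        raise ValueError(f"archetype IDs outside the cohort: {sorted(unknown)}")
    if shift < 0:
        raise ValueError("shift must be >= 0")
    arch = {g: +1 for g in tol}
    arch.update({g: -1 for g in sus})
    return dataclasses.replace(config, archetypes=arch, archetype_shift=float(shift))


# -- generation --------------------------------------------------------


def generate_cohort(
    config: CohortConfig,
    seed: int,
    return_effects: bool = False,
):
    """Draw one balanced cohort; identical (config, seed) gives an
    identical table.

    Returns a :class:`TraitTable` (with the derived R/S trait appended
    when RL and SL are simulated), or ``(table, effects)`` with per-trait
    :class:`EffectDecomposition` when ``return_effects`` is true.
    """
    if seed is None:
        raise ValueError("a seed is mandatory; cohorts must be reproducible")
    rng = np.random.default_rng(seed)
    f_g, f_i, f_r = config.variance_partition
    genos = config.genotype_labels
    n_g, n_r = config.n_genotypes, config.replicates
    rho = config.cross_trait_correlation
    traits = config.simulated_traits
    corr_set = set(config.correlated_traits) & set(traits)

    # shared factors inducing cross-trait correlation at every level
    shared = {
        "g": rng.standard_normal(n_g),
        "i": rng.standard_normal((n_g, 3)),
        "r": rng.standard_normal((n_g, 3, n_r)),
    }

    frames = []
    effects: dict[str, EffectDecomposition] = {}
    clipped_cells = 0
    for trait in traits:
        meta = config.schema[trait]
        tr_codes = list(meta.treatments)
        own = {
            "g": rng.standard_normal(n_g),
            "i": rng.standard_normal((n_g, 3)),
            "r": rng.standard_normal((n_g, 3, n_r)),
        }
        if trait in corr_set:
            mix = {
                k: np.sqrt(rho) * shared[k] + np.sqrt(1 - rho) * own[k]
                for k in own
            }
        else:
            mix = own

        means = np.array([config.targets[(trait, t)][0] for t in tr_codes])
        sds = np.array([config.targets[(trait, t)][1] for t in tr_codes])
        t_idx = [("T0", "T1", "T2").index(t) for t in tr_codes]

        # archetype shifts on stress treatments only
        shift = np.zeros((n_g, len(tr_codes)))
        if config.archetype_shift:
            sign = 1.0 if meta.polarity == "higher_is_better" else -1.0
            for gi, g in enumerate(genos):
                d = config.archetypes.get(g)
                if d:
                    for tj, t in enumerate(tr_codes):
                        if t != "T0":
                            shift[gi, tj] = d * sign * config.archetype_shift * sds[tj]

        gamma = mix["g"][:, None]  # unit scale, shared across treatments
        delta = mix["i"][:, t_idx]
        eps = mix["r"][:, t_idx, :]
        cell_base = (
            means[None, :] + shift
            + sds[None, :] * (np.sqrt(f_g) * gamma + np.sqrt(f_i) * delta)
        )
        vals = cell_base[..., None] + sds[None, :, None] * np.sqrt(f_r) * eps

        if meta.family in ("positive_continuous", "count"):
            vals, n_clip = _resample_negative(
                vals, cell_base[..., None], sds[None, :, None], f_r, rng,
            )
            clipped_cells += n_clip
        if meta.family == "count":
            vals = np.maximum(np.round(vals), 0.0)
        elif meta.family == "proportion":
            vals = np.clip(vals, 0.0, 1.0)

        idx = pd.MultiIndex.from_product(
            [genos, tr_codes, range(1, n_r + 1)],
            names=["genotype", "treatment", "replicate"],
        )
        frame = pd.DataFrame(
            {"value": vals.reshape(-1)}, index=idx
        ).reset_index()
        frame["trait"] = trait
        frames.append(frame[["genotype", "treatment", "replicate", "trait", "value"]])

        if return_effects:
            effects[trait] = EffectDecomposition(
                genotype_effects=pd.Series(
                    np.sqrt(f_g) * mix["g"], index=genos, name=trait
                ),
                interaction_effects=pd.DataFrame(
                    np.sqrt(f_i) * mix["i"][:, t_idx], index=genos, columns=tr_codes
                ),
                residual_sd=pd.Series(np.sqrt(f_r) * sds, index=tr_codes),
            )

    if clipped_cells:
        logger.warning(
            "%d cell(s) fell back to exact truncated-normal draws after "
            "%d residual redraws (high-CV traits truncate with documented bias)",
            clipped_cells, _RESAMPLE_LIMIT,
        )

    table = TraitTable(
        pd.concat(frames, ignore_index=True),
        schema=dict(config.schema),
        require_balanced=False,
    )
    if "RL" in traits and "SL" in traits:
        table = with_ratio_trait(table)
    if return_effects:
        return table, effects
    return table


def _resample_negative(vals, base, sds, f_r, rng):
    """Redraw the residual component of negative cells (truncation at 0).

    Cells still negative after the redraw budget are drawn from the
    residual distribution conditioned on being non-negative (an exact
    truncated normal), so positive-continuous traits never collapse to
    an exact 0 unless the residual variance is itself 0.
    """
    if not (vals < 0).any():
        return vals, 0
    scale = np.sqrt(f_r) * sds
    for _ in range(_RESAMPLE_LIMIT):
        neg = vals < 0
        if not neg.any():
            break
        redraw = base + scale * rng.standard_normal(vals.shape)
        vals = np.where(neg, redraw, vals)
    neg = vals < 0
    n_exact = int(neg.sum())
    if n_exact:
        if np.all(scale > 0):
            from scipy.stats import truncnorm

            b_base = np.broadcast_to(base, vals.shape)[neg]
            b_scale = np.broadcast_to(scale, vals.shape)[neg]
            draws = truncnorm.rvs(
                a=-b_base / b_scale, b=np.inf, loc=b_base, scale=b_scale,
                random_state=rng,
            )
            vals = vals.copy()
            vals[neg] = draws
        else:
            vals = np.where(neg, 0.0, vals)  # degenerate residual-free config
    return vals, n_exact
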