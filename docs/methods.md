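# Methods

`droughtscreen` implements the statistical layer of a seedling-stage
drought screen: a panel of genotypes grown in a balanced completely
randomized design under three PEG-6000 osmotic-stress levels — T0 (0 %,
control), T1 (10 %) and T2 (20 % w/v) — with growth, root and
biochemical traits recorded per replicate. The package ships with the
published summary tables of a 37-genotype okra screen (descriptive
statistics, score card, and index tables) and uses them both as
calibration targets for the synthetic-cohort generator and as the
object of an algebraic audit.

## Data model

Observations are long-format records (genotype, treatment, replicate,
trait, value). Seventeen traits are covered: days to seed germination
(DSG), number of leaves (NOL), total fresh/dry weight (TFW/TDW, g),
survival rate (SR, fraction), number of secondary roots (NSR), root and
shoot length (RL/SL, cm), root fresh weight (RFW, g), the derived
root-to-shoot ratio (R/S = RL/SL, computed per replicate because a mean
of ratios is not a ratio of means), chlorophyll a/b, total chlorophyll,
carotenoids, proline, and the oxidative-stress markers MDA and H2O2.
The markers are measured only under T0 and T2; the loader rejects them
under T1. Validation enforces non-negative values, integer counts,
proportions in [0, 1], unique observation keys, and (by default)
listwise removal of genotypes with any missing design cell — the
analysis assumes a balanced table throughout.

Pigment concentrations follow the standard 80 %-acetone equations
(Chla = 12.25·A663.2 − 2.79·A646.8; Chlb = 21.21·A646.8 − 5.1·A663.2;
TChl = Chla + Chlb; CAR = (1000·A470 − 1.82·Chla − 85.02·Chlb)/198).
Negative pigment outputs are returned but flagged as out-of-range
input rather than clipped.

One packaged descriptive row (SL under T0) prints a maximum smaller
than its minimum; the fixture keeps the row exactly as published with a
`suspect` flag, and the loader rejects such rows only when unflagged.

## Synthetic cohorts

No replicate-level data accompany the published tables, so downstream
stages are exercised on synthetic cohorts. The generator uses a
two-moment Gaussian decomposition per trait,

    y(g,t,r) = m(t) + s(t) · ( √f_G·γ_g + √f_GT·δ_{g,t} + √f_E·ε_{g,t,r} ),

where m and s are the published per-treatment mean and SD (treatment is
a fixed effect absorbed into m), and (f_G, f_GT, f_E) partition the
variance among genotype, genotype × treatment and residual components
(default 0.4 / 0.2 / 0.4 — a declared assumption, not an inferred
value, loosely motivated by the relative mean squares of the published
ANOVA; fully configurable). A two-moment model is the most
parsimonious choice consistent with the available targets, which are
means and SDs only.

Cross-trait structure: the eight growth/root traits (NOL, TFW, TDW, SR,
NSR, RL, SL, RFW) share a common factor at every level, giving their
genotype means a target correlation of +0.7 — the strong positive
coupling a well-watered screen shows. The same correlation therefore
appears under all treatments; the stress-dependent weakening and sign
reversal seen in real screens is *not* emulated, so correlation-shift
classifications on synthetic data only exercise the bookkeeping, not
the biology.

Family post-processing: counts (DSG, NOL, NSR) are rounded to
non-negative integers; proportions (SR) are clipped to [0, 1]; positive
continuous traits are resampled at the residual level when negative,
with a final exact truncated-normal draw for cells whose
genotype-level component is itself below zero. Truncation biases the
realized mean upward for very high-CV cells (RFW under T2 has CV
120 %); the generator logs how many cells took the fallback path. R/S
is always derived by dividing the generated RL by SL, never simulated.

Archetype injection adds ±shift·SD to the stress-treatment means of
designated tolerant/susceptible genotypes (sign following each trait's
polarity; control untouched), providing a known ground truth for
recovery experiments. Note a structural limit measured honestly by the
acceptance suite: a 2-SD stress-only shift competes with natural
genotype main effects of √0.4·SD that act in *all three* treatments and
are correlated across the growth traits, so naturally-good genotypes
often out-rank archetypes on the cumulative score (top-4 recovery
≈ 50 % of seeds, not ≳ 95 %), and the composite STS — which adds
susceptibility components (SSI) to tolerance components — barely
separates the two groups at all (mean gap ≈ 0). This is a property of
the scoring rules under these conditions, not a generator defect.

All randomness flows from a single integer seed through numpy
`SeedSequence`; identical (config, seed) gives a bit-identical table.

## Inference

ANOVA is the balanced fixed-effects decomposition with sources
Genotypes, Treatments, Replication (a crossed 2-df block, not nested),
Genotypes × Treatments, and Error; every F uses the error mean square.
On the full 37 × 3 × 3 design the dfs are (36, 2, 2, 72, 220; total
332); the two-treatment markers give Treatments df 1 and total 221.
Sequential and marginal sums of squares coincide on balanced data (the
engine refuses unbalanced tables rather than switching SS types), and
the implementation (statsmodels OLS + anova_lm) is cross-checked in the
tests against a first-principles mean-sums oracle. Constant responses
yield zero SS everywhere and F reported as undefined. p-values below
1e-16 are displayed as "<1e-16".

Tukey HSD compares treatment means with the studentized range using the
factorial model's error term (not a one-way pooled variance); the
compact letter display is assigned greedily from the largest mean, with
ties broken by descending mean then label.

Pearson correlations are computed per treatment on genotype means
(n = one point per genotype), the scale on which genotype-level trait
relationships are described; replicate-level mode is available.
Zero-variance traits produce flagged NaN entries, never silent zeros.
The shift summary classifies each trait pair's (r_T0, r_T1, r_T2)
triple as increasing / decreasing / non-monotone using strict
monotonicity.

## mu±SD scoring

For each trait × treatment, thresholds are the mean and population SD
of the genotype means. A genotype above mu + SD is Efficient (score 3),
below mu − SD Inefficient (score 1), otherwise Medium (score 2);
boundary values are Medium because the defining inequalities are
strict. Fifteen traits enter the card (the two-treatment markers are
excluded); treatment totals run 15–45 and the overall total 45–135.

Two documented choices:

- The rule is applied literally (higher → E) to every trait by default,
  which matches the published card even for DSG where fewer days are
  agronomically better; a polarity-aware mode (DSG, MDA, H2O2 reversed)
  is switchable.
- The published card's single per-treatment E/M/I letter is not defined
  anywhere in the source description. Applying the same mu±SD rule to
  the distribution of treatment totals reproduces the published letters
  for all 37 genotypes under all three treatments (verified in the test
  suite), so that reconstruction is adopted.

Ranking is dense (ties share a rank, natural genotype order within a
tie).

## Tolerance indices and the composite score

With C and T the genotype's dry weight (TDW) under control and stress,
and xC, xT the cohort means (per stress level):

    SSI = (1 − T/C)/(1 − xT/xC)   MPI = (C+T)/2    GMPI = √(C·T)
    HMI = 2CT/(C+T)               STI = CT/xC²     TI = C − T
    SI  = T/C                     STS = SSI+MPI+GMPI+HMI+STI+TI+SI

GMPI has two modes. The stated definition is √(C·T) (`formula`, the
default, which keeps the harmonic ≤ geometric ≤ arithmetic ordering
exact). But every cell of the packaged published index tables matches
the raw product C·T instead — the auditor detects this cell-by-cell —
so an `as_published` mode computes the product. The discrepancy is
surfaced, never silently reconciled, and it propagates into STS, whose
published values equal the plain row sums of the printed columns. An
alternative `standardized` STS mode sums per-column z-scores (the
composite is sometimes described that way); note it changes the
ranking, so the two modes are never mixed.

The auditor inverts the MPI/SI pair exactly (C = 2·MPI/(1+SI),
T = SI·C), recomputes every index, and infers xC from the STI column
(median of √(CT/STI)) and xT from the SSI column by least squares of
(1 − SI) on SSI. Deviations are reported against two tolerances: half a
printing unit at three decimals (0.0015), and an input-rounding
envelope obtained by interval arithmetic over the ±0.0005 rounding
rectangle of the printed MPI and SI (STI, with magnitude near 1,
legitimately moves by ~0.005 under that rounding). On the packaged
tables TI, HMI, GMPI-as-product and STI all reproduce within the
envelope; the SSI column does not reproduce from the SI column under
any common denominator (two rows with identical SI print very different
SSI), which the audit reports as a genuine internal inconsistency of
the published table, and which also corrupts the xT inference.

## PCA

PCA of the 37 × 7 index matrix uses the explicit correlation matrix by
default (the indices span orders of magnitude, so covariance-mode PCA
would be dominated by STI); eigendecomposition of the correlation
matrix keeps the eigenvalue sum exactly equal to the number of
variables. Loadings are eigenvectors scaled by √eigenvalue with the
sign fixed so each component's largest-magnitude loading is positive;
a variable's contribution to a component is its squared loading as a
percentage of the component's squared-loading total; components with
eigenvalue > 1 carry the Kaiser retention flag. On the packaged T1
table this yields PC1 = 71.2 % and PC1+PC2 = 97.1 % of the variance
with exactly two Kaiser components, MPI the top PC1 contributor, and —
contrary to the published narrative — SI (≈ 52 %) rather than TI
(≈ 43 %) as the top PC2 contributor under every standard contribution
definition.

## Pipeline

`run_pipeline` executes input → descriptives → percent changes →
ANOVA/Tukey → correlations → scoring → indices → PCA → audit, writing
one file per stage plus a manifest (config snapshot, version, input
checksum, per-stage status and timing, warnings, output checksums).
Stages never rewrite another stage's files; a stage failure is recorded
in the manifest before the error propagates (nonzero exit at the CLI).
The report layer alone applies display rounding; all numeric outputs
carry full precision so audits never compare doubly rounded values.

## Problem sizes used in the tests

The test suite runs the full 37 × 3 × 3 design for all df/ANOVA checks,
10 000 replicates for the marginal-calibration check (3-SE tolerance
with SE derived from the variance partition), 1 000 genotypes for the
large-sample correlation check (±0.05), 200 seeds for the
archetype-recovery rates, and 10 000 random pairs for the index
round-trip property (1e-12 tolerance).

## Known limitations

- The generator matches first and second moments and one correlation
  block only; skewness, stress-dependent correlation decay, and seed
  mortality are not emulated.
- The balanced-only ANOVA refuses incomplete tables by design; there is
  no mixed-model path.
- The scoring and index stages assume genotype means over exactly the
  three treatment levels of this design.
- Passing synthetic-data tests demonstrates correctness of the
  computations under the calibrated model, not biological validity on
  real screens.
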