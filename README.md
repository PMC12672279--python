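# droughtscreen

Statistical toolkit for seedling-stage drought screening of genotype
panels under PEG-6000 osmotic stress.

Breeding programs screen large genotype panels for drought tolerance by
growing seedlings in a balanced genotype × treatment × replicate design
under increasing polyethylene-glycol (PEG 6000) concentrations — T0
(0 %, control), T1 (10 %) and T2 (20 % w/v) — and recording growth,
root and biochemical traits. This package implements the full analysis
layer of such a screen for breeders and quantitative biologists:

- **Trait tables** — validated long-format ingestion, derived traits
  (root-to-shoot ratio per replicate, pigment equations), descriptive
  statistics and percent-change summaries.
- **Inference** — balanced factorial ANOVA (genotype, treatment,
  replication block, G×T; F against the error mean square), Tukey HSD
  across treatments with a compact letter display, and per-treatment
  Pearson correlation matrices on genotype means.
- **mu±SD scoring** — each trait × treatment classifies genotypes as
  Efficient (> mu+SD, score 3), Medium (score 2) or Inefficient
  (< mu−SD, score 1); scores are summed per treatment (…/45) and
  overall (…/135) to rank the panel.
- **Stress-tolerance indices** — from control and stress dry weight
  (C, T) and cohort means (xC, xT):

      SSI = (1 − T/C)/(1 − xT/xC)    MPI  = (C+T)/2     GMPI = √(C·T)
      HMI = 2CT/(C+T)                STI  = CT/xC²      TI   = C − T
      SI  = T/C                      STS  = sum of the seven

- **Index PCA** — correlation-matrix PCA of the genotype × index
  matrix: eigenvalues, explained variance, loadings, per-variable
  contributions, Kaiser flags.
- **Synthetic cohorts** — a calibrated generator reproducing the
  published per-trait means/SDs with a configurable genotype / G×T /
  residual variance partition, trait families (counts, proportions,
  positive continuous), a correlated growth-trait block, and known
  tolerant/susceptible archetype injection.
- **Auditor** — published index tables rarely ship raw data; the
  auditor back-derives (C, T) from each printed MPI/SI pair
  (C = 2·MPI/(1+SI), T = SI·C), recomputes all indices, infers the
  cohort means, and reports every cell's deviation at printed
  precision. On the packaged tables it shows, among other things, that
  the printed GMPI column is the raw product C·T rather than the stated
  √(C·T), and that the SSI column is internally inconsistent with SI.

The package ships the published summary tables of a 37-genotype okra
screen (descriptives, score card, index tables under both stress
levels) as fixtures used for calibration and auditing.

## Worked example

```python
import droughtscreen as ds

# published 37 x 7 index table under 10 % PEG
pub = ds.datasets.load_published_indices("T1")

# composite Stress Tolerance Score = row sum of the seven indices
sts = ds.compute_sts(pub)
print(sts.sort_values(ascending=False).head(3))
# genotype
# G45    4.464
# G51    4.107
# G14    3.650

# back-derive dry weights from the printed MPI and SI of one genotype
audit = ds.audit_published_table(pub)
print(audit.recovered.loc["G45"])          # c 0.0935, t 0.1905
# stress dry weight above control: consistent with the printed TI −0.097

# correlation-scaled PCA of the index matrix
res = ds.pca_on_indices(pub[list(ds.datasets.INDEX_COLUMNS)])
print(res.variance_pct[:2])                # [71.18  25.92]
print(res.cumulative_pct[1])               # 97.10
print(ds.variable_contributions(res, 1).idxmax())   # MPI
```

The top scorer G45 owes its lead to a stress dry weight exceeding its
control (SI > 1), the first two components capture 97 % of the index
variance, and mean productivity dominates PC1.

A full pipeline run on a synthetic cohort:

```sh
droughtscreen analyze --synthetic --seed 1 --outdir out/
droughtscreen report --outdir out/
```

writes per-stage CSVs (descriptives, ANOVA, Tukey letters,
correlations, score card, index matrices, PCA tables), an audit of the
packaged published tables (`audit.json`), a manifest with per-stage
status and output checksums, and a readable `report.md`. Identical
config and seed give byte-identical outputs.

## Layout

```
src/droughtscreen/
  traits.py      data model, I/O, derived traits, descriptives
  datasets.py    packaged published tables + percent-change claims
  simulate.py    calibrated synthetic-cohort generator
  inference.py   ANOVA, Tukey HSD, correlations
  scoring.py     mu±SD classification and cumulative scoring
  indices.py     tolerance indices, STS, table auditor
  pca.py         index-matrix PCA
  pipeline.py    orchestration, manifest, report
  cli.py         `droughtscreen` simulate / analyze / audit / report
docs/methods.md  model, assumptions, numerical choices, limitations
```
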