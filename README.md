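# g4snv

Spatial association of G-quadruplex (G4) loci with cancer single-nucleotide
variants, as a tested, reusable pipeline over synthetic cohorts with planted
ground truth.

G-quadruplexes are four-stranded DNA structures that form in G-rich
sequence and are implicated in replication stalling, R-loop stabilisation
and locally elevated mutagenesis. This package implements the statistical
machinery needed to ask whether somatic variants from cancer exomes (cSNVs)
cluster around G4 loci in a way that common population variants (dbSNVs) do
not, and whether a patient's G4 exposure predicts survival:

- **Interval engine** (`g4snv.intervals`) — native 0-based half-open
  interval arithmetic: BED I/O, *signed* nearest-feature distances
  (negative = upstream/5′ of the reference, 0 on overlap), overlap
  counting, fixed-end and sliding window tiling, and uniform random
  placement within a mask.
- **Sequence layer** (`g4snv.sequences`) — FASTA access, per-interval GC
  counting, and a consensus PQS scanner for the motif
  G<sub>x</sub>N<sub>y</sub>G<sub>x</sub>N<sub>y</sub>G<sub>x</sub>N<sub>y</sub>G<sub>x</sub>
  (x ≥ 3, 1 ≤ y ≤ 7) on both strands.
- **Synthetic studies** (`g4snv.simulate`) — genomes with gene/exon
  structure, exonic G4 maps (optionally clustered into cancer genes),
  SNV cohorts with planted Gaussian positional offsets
  (cSNV N(+227, 84) bp downstream; dbSNV N(−1295, 433) bp upstream), a
  planted linear window-level law E[cSNV | c G4s] ∝ 2 + 3c, and survival
  times from hazard h₀·exp(β·G4-average) with β = 0.32.
- **Cohort preprocessing** (`g4snv.preprocess`) — germline-coincidence
  filtering, exclusion of cancer types with fewer than 10 patients,
  the >15-G4 window cap, and gene±flank window restriction.
- **Spatial statistics** (`g4snv.spatial`) — signed distance-density
  profiles, nonlinear least-squares Gaussian fits with 95% intervals
  (μ ± 1.96σ), fold-compression between fits, Pearson window correlation.
- **Window statistics** (`g4snv.windows`) — exonic per-window counting,
  {0, 1+, 10+} G4 stratification with Welch-t and chi-squared tests, GC
  normalisation, partial correlation controlling for GC fraction,
  per-exon gene analyses and cancer/non-cancer gene comparison.
- **Bootstrap regression** (`g4snv.bootstrap`) — incomplete categorical
  bootstrapping: N averaged subsets of size I per G4-count category,
  equalising category influence before OLS; sweeps of I trace how R²
  climbs as within-category variance shrinks like s²/I.
- **Survival** (`g4snv.survival`) — per-patient G4-average, normalized
  G4-average and cSNV-average; intra-cancer variance; a hand-authored Cox
  partial-likelihood Newton solver (Breslow ties by default, Efron as an
  option) with Wald inference and Harrell's concordance.
- **Pipeline & CLI** (`g4snv.pipeline`, `g4snv` console script) —
  `simulate` / `analyze` / `report` subcommands, deterministic under a
  single seed.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_spatial_profiles.py
```

prints (seed 1):

```
cSNV: mu=+228 bp, sigma=86 bp, 95% interval [+60, +396] bp
dbSNV: mu=-1293 bp, sigma=436 bp, 95% interval [-2147, -438] bp
somatic fit is 5.1-fold compressed versus the common cohort
random-locus control: max/min bin ratio 1.27 (flat)
```

The somatic cohort sits in a narrow band just downstream of G4s while the
common cohort spreads broadly upstream; the 5.1-fold width ratio
quantifies how much tighter the somatic association is. Against random
200-bp loci the profile is flat — the association is specific to G4s.
Continuing the chain:

```sh
python analysis/03_window_enrichment.py   # stratified enrichment + GC control
python analysis/04_bootstrap_regression.py
python analysis/05_patient_survival.py
```

```
cSNV: mean per window 0-G4 1.00 vs 10+-G4 31.60
G4-cSNV correlation r=0.921; controlling for GC: r=0.921
planted_linear: slope 3.02, r2 0.998 at I=100
planted_null: slope -0.01, r2 0.014 at I=100
Cox: G4-average coefficient +0.210 (p=0.011) -> hazard +23.4% per unit
```

Windows rich in G4s carry far more somatic variants; the correlation
survives GC control because GC content is not the driver in the planted
model. The bootstrap sweep recovers the planted slope 3 with R² → 1,
while the no-relation column never supports a line. The Cox fit recovers
a positive hazard effect of the G4-average at this cohort size (the
planted coefficient is 0.32; at 281 patients the Wald interval spans it).
Raw simulated data land under `scratch/`, tables under `results/`.

The same stages are available as a CLI:

```sh
g4snv simulate out/data --seed 1
g4snv analyze out/data out/analysis --seed 1
g4snv report out/analysis/summary.json out/tables
```

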