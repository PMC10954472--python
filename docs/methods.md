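# Methods

This note documents the models, conventions and numerical choices behind
`g4snv`, and what the synthetic studies do and do not establish.

## Coordinates and signed distances

All intervals are 0-based, half-open (BED dialect); SNVs are length-1
intervals. The nearest-feature distance is *signed* relative to the
reference genome: 0 when query and reference overlap (or are book-ended),
negative when the query lies 5′ (left, upstream) of the reference,
positive when 3′ (downstream); the magnitude is the gap in bp between the
closest edges. This extends the absolute distance of the classic
`closest`-style tools, which is needed because upstream and downstream
accumulation are scientifically distinct here. An optional strand-aware
mode flips the sign for minus-strand references so "downstream" follows
the feature rather than the assembly; the default is assembly-oriented
because G4 maps are commonly reported without usable strand semantics.
Ties between equal gaps on both sides, or among several overlapping
references, resolve to the leftmost reference — deterministic and
matching the `-t first` convention of the field's tools. Fixed-end window
tiling emits the truncated final tile (the `makewindows` dialect), so
window counts match tables prepared with those tools. Chromosome names
are compared as exact strings.

The nearest-distance scan is a sorted-array sweep (binary searches on
start-sorted and end-sorted views plus a cumulative-maximum of ends for
overlap detection), O((n+m) log m); the tests compare it against an
exhaustive all-pairs oracle on a thousand random instances.

## PQS consensus scanning

The scanner implements the intramolecular G4 consensus
G(x) N(y) G(x) N(y) G(x) N(y) G(x) with x ≥ 3 and 1 ≤ y ≤ 7 by default.
Matching is leftmost and greedy (longer G-runs and loops preferred),
non-overlapping by default (scanning resumes after each match), with
options for overlapping matches and for tolerating N inside loops
(disallowed by default — conservative, since N is not evidence of a
G-run). The minus strand is scanned on the reverse complement and mapped
back. This consensus scanner is deliberately simple: it is the in-package
source of PQS annotations for synthetic runs, not an imperfection-tolerant
scoring predictor, and it will not reproduce the hit counts of such
predictors on real genomes.

## Synthetic studies and their planted truth

The generator produces a miniature study whose every downstream
observable has a known planted value:

- **Genome** — random sequence at a configurable GC fraction (default
  0.45), with equal-length genes placed non-overlapping in per-gene slots
  and exons tiled inside genes. Defaults: 2 chromosomes x 2 Mb, 40 genes
  of 5 x 8 kb exons.
- **G4 map** — 800 G4s (length ~Poisson(30) bp) placed within exons; a
  clustering knob directs a fraction (default 0.5) into the 20% of genes
  labelled "cancer", which both mirrors the elevated G4 content of cancer
  genes and populates the high-count window strata (windows span 0..15
  G4s) that the enrichment and bootstrap stages stratify on. An optional
  minimum spacing and edge margin support the spatial geometry below.
- **SNV cohorts** — each SNV is either G4-associated (probability
  `assoc_fraction`, default 0.7) or background. Associated SNVs land at a
  Gaussian signed offset from a chosen G4 — downstream of its end for
  positive draws, upstream of its start for negative — with defaults
  cSNV N(+227, 84) bp and dbSNV N(−1295, 433) bp. These values are the
  ones implied by 95% intervals of 63..391 bp and −2143..−447 bp, and
  give a width ratio of 5.17. Background SNVs are placed uniformly in
  exon space with windows weighted by the planted linear intensity
  a + b·c (defaults a = 2, b = 3 per 5 kb window with c G4s) for the
  somatic kind and uniformly for the common kind; associated SNVs choose
  a G4 with probability proportional to its window's intensity divided by
  the window's G4 count, so both layers contribute linearly in c. Because
  the cohort size is itself a parameter, the law is planted as a
  proportionality — E[count | c] ∝ a + b·c — with the absolute scale set
  by the cohort size; the direct window-table generator
  (`simulate_window_table`) plants the exact law E[count | c] = a + b·c
  with Poisson noise and geometrically decaying category sizes, and is
  the substrate for the bootstrap-regression checks.
- **Patients and survival** — patients are assigned uniformly (with an
  optional skew) to cancer types; per-patient cSNV counts are
  Poisson(10). Cancer types differ in their G4-association strength (a
  linear spread around `assoc_fraction`), planting the cancer-type
  disparities that the per-type summaries and intra-cancer variance
  measure. Survival times are exponential with hazard
  h₀·exp(β·x) where x is the patient's G4-average computed exactly as
  the analysis stage computes it (β = 0.32, h₀ = 10⁻³ per day).
  Censoring is an independent exponential whose rate is calibrated to the
  requested censoring fraction (0.3) at the cohort's mean hazard — an
  approximation that is exact only for a homogeneous cohort. A small
  fraction of records is marked as non-cancer deaths (5%) or given
  missing times (2%) to exercise the cohort-selection filter.

A dedicated `spatial_study_config` provides the geometry for clean
distance-profile recovery: single-exon genes (40 kb), 120 G4s with 9 kb
minimum spacing and 4 kb edge margins, association probability 1, and
50 000 SNVs per cohort. The spacing guarantees that the nearest G4 to
each SNV is the one it was placed against (offset tails < 3 kb), and the
margins keep offsets inside exon space, so the fitted Gaussian parameters
estimate the planted ones without truncation bias.

**What the generator does not emulate:** trinucleotide mutational
signatures, chromatin state, copy-number structure, realistic gene-length
and G4-length distributions, or correlated GC/G4 confounding (GC content
is uniform by construction, so the partial correlation controlling for GC
barely moves — the pipeline demonstrates the *machinery* of GC control,
not a realistic confounder). Passing tests show the statistics recover
planted structure under these idealised conditions; they do not certify
behaviour on real cohorts. One deliberate divergence between scales: in
the genomic generator both cohorts are spatially G4-associated, and any
spatial association mechanically induces some window-level relation even
for the "null" cohort; the flat-null window behaviour is therefore
planted (and tested) in the direct window-table generator.

## Distance profiles and Gaussian fits

Signed distances are binned over ±5000 bp in 50 bp bins by default (both
exposed); out-of-range distances are dropped from the profile but counted
in its metadata. Normalisation is unit-area by default, with peak-at-one
and raw-count modes. A single Gaussian A·exp(−(x−μ)²/2σ²) is fitted to
the binned density by nonlinear least squares (trust-region with bounds
A ≥ 0, μ within the profile range, σ above a tenth of the bin width),
initialised from the profile's empirical moments, with tight optimizer
tolerances so the recovered μ and σ are invariant to the normalisation
choice. Fitting the binned density rather than maximising a likelihood on
raw distances keeps the procedure a curve fit on the profile; binning
inflates σ by at most binwidth²/12 in variance (≈0.5% at the default
geometry). The "95% interval" attached to a fit is μ ± 1.96σ — a
property of the fitted distribution, not a confidence interval on μ. A
goodness flag is raised when the residual sum of squares exceeds 10% of
the density's total sum of squares (e.g. bimodal profiles). Profiles with
fewer than five occupied bins are rejected with a pointer to smaller bin
widths. One Gaussian is fitted to the full signed range.

The random-locus control places uniform SNVs against random 200-bp
intervals. Two systematic effects make even a perfect null non-flat: the
exact-zero atom (any SNV inside or book-ended to a reference inflates the
0-bin by roughly 200/binwidth) and the nearest-neighbour exponential
falloff exp(−2λ|d|) for reference density λ. The control geometry
(references at ~100 kb mean spacing over 10 Mb, 2000-bp bins over
±5000 bp) bounds both effects near 10%, so the max/min bin ratio of a
genuinely flat null stays well below 1.5.

## Window statistics

Only features inside the intersection of a window with (merged) exonic
sequence are counted. Windows are tiled over the union of gene ± flank
regions (2 kb flank by default, 5 kb as the documented alternative) and
labelled by maximal-overlap gene; windows overlapping no exon, or
spanning a gap between consecutive exons larger than the window size,
are excluded as uninformative. Windows with more than 15 G4s are removed
(strictly more; a 15-G4 window stays), and cancer types with fewer than
10 distinct patients are dropped (strictly fewer; an exactly-10 type
stays).

Stratified enrichment compares the {0, 1+, 10+} strata (1+ contains 10+)
with Welch's two-sample t-test by default — group variances across
strata are certainly unequal — with the pooled-variance variant behind a
flag, and a chi-squared contingency test on SNV presence/absence as the
secondary test (the contingency definition is a documented choice; binned
counts would be an alternative). Raw p-values are reported;
Benjamini–Hochberg is applied across the comparisons within one report.
The partial correlation r(xy·z) = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))
controls for GC fraction (GC base pairs / window length) with a t-based
p-value on n−3 degrees of freedom; it matches an established
implementation to machine precision in the tests. Gene-level G4 content
is reported both raw and per kbp of gene, since the normalisation target
of "length-normalized" gene content is genuinely ambiguous.

## Incomplete categorical bootstrapping

Within each G4-count category (0..15), N subsets of I windows are drawn
with replacement and each subset reduced to its mean, yielding exactly N
points per category regardless of category size — this equalises the
influence of rare high-count categories against the overwhelming zero
category. A line is fitted to the pooled (category count, subset mean)
points by OLS, with the raw count as the x-value. As I grows the
within-category variance shrinks like s²/I, so R² climbs toward the R²
of the exact category means — the sweep traces this. The three printed
parameter levels are exposed as presets: small (N=250, 10 cycles, I in
steps of 10), medium (500/20/5), large (1000/50/1), all to I = 100. One
wording conflict is resolved in favour of the reduction rule: each
category contributes N averaged points per I (not N·I raw points), since
only that reading is realisable after the reduction step. Classical OLS
standard errors are invalid on resampled points, so uncertainty is
summarised by quantiles over cycles instead. The 70/30 train/test
regression on the raw window table uses the standard linear-model
implementation of scikit-learn with the held-out R² reported (which may
be negative for a worthless fit).

## Patient metrics and survival

For each patient, the windows holding at least one of that patient's
cSNVs are selected from the post-filter window table (germline-filtered
cohort, ≤15-G4 windows, fixed-end 5 kb tiling — patient mapping requires
non-overlapping windows). The G4-average is the mean G4 count over those
windows; the normalized G4-average divides it by the summed G4 count over
the same windows (undefined and flagged when the sum is 0); the
cSNV-average is the mean of the patient's per-window counts (≥ 1 by
construction). Note the normalized variant is *not* invariant to
duplicating windows — duplicating every selected window halves it while
the plain average is unchanged; this is a property of the definition, and
the tests assert it. Intra-cancer variance is the per-type sample
standard deviation of G4-averages divided by the type mean.

The Cox model maximises the partial likelihood by Newton's method with
step-halving, Breslow's approximation for tied event times by default and
Efron's as an option (Efron matches the reference implementation in
lifelines to ~10⁻⁵ on tied data; without ties the two coincide). Wald
standard errors come from the inverse observed information; hazard ratios
are exp(β); concordance is Harrell's C over comparable pairs (computed
via lifelines' utility). Covariates enter unstandardized so a coefficient
reads as log-hazard per unit of G4-average, with a z-scoring flag
available. Because "a coefficient of 0.38" and "hazard increases by 38%"
sit on different scales (exp(0.32) − 1 ≈ 38% — the two coincide only
near zero), both the coefficient and exp(β)−1 are reported. Monotone
likelihoods (a covariate that perfectly orders events) have no finite
maximiser; the solver then terminates at a large |β| when the likelihood
plateaus numerically, as reference implementations do with a warning.

## Determinism and problem sizes

Every stochastic stage derives an independent stream from a single seed
(per-stage seed sequences), so a full simulate+analyze run is
byte-identical across repetitions. The shipped study sizes — 2 x 2 Mb
genomes, 50 k SNVs per cohort for spatial fits, ~8 k windows for the
bootstrap table, 24 cohorts of 3000 patients for survival recovery — were
chosen so each estimate's sampling error is several times smaller than
the effect being recovered (e.g. Cox per-cohort standard error ≈ 0.024
against a planted 0.32; Gaussian μ standard error < 1 bp against planted
offsets of hundreds of bp) while a complete run stays in the minutes
range on a single CPU.

## Known limitations

- The interval engine targets desk-scale sets (10⁵–10⁶ intervals); it has
  no indexing or streaming for chromosome-scale production data.
- The PQS scanner is the strict consensus only — no bulges, two-quartet
  stacks, or long loops.
- Germline filtering matches on (chromosome, position) only; alleles are
  not compared.
- The censoring-rate calibration is approximate under covariate
  heterogeneity (realised censoring drifts a few percentage points from
  the nominal rate).
- The survival analysis assumes fixed-end windows; sliding windows would
  require a different patient-to-window mapping.
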