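# Methods

## Scope and data model

`anchorsig` operates on already-normalized log2 expression matrices (probes ×
samples), e.g. RMA output from Affymetrix arrays. No normalization, CEL
parsing, or array QC is performed; values are assumed log2 throughout
(`core_data.ASSUME_LOG2`). Missing entries are allowed and propagate as NaN;
all correlations use pairwise-complete observations and records with fewer
than 3 complete pairs are excluded (logged). Matrix orientation is fixed —
probes in rows, samples in columns — and a transposed file fails validation
rather than being guessed. Identifiers are case-sensitive and
whitespace-stripped.

## Anchor screen

Within the tumor group, every probe is correlated (Pearson) against the
anchor probe. A zero-variance anchor is a hard error; zero-variance probes
are flagged undefined and excluded. Differential expression contrasts tumors
against controls:

* **T/C ratio** = mean(log2 tumor) / mean(log2 control). This is a ratio of
  log-scale means, not a linear fold change — the convention of the
  microarray tables the screen reproduces, where values run ~1.05–1.7. A
  non-positive control mean is rejected since the ratio would be
  uninterpretable.
* **One-tailed t-test**: two-sample *t* with the alternative following the
  observed direction, i.e. half the two-sided p (0.5 at t = 0). Both the
  classic pooled-variance Student test (default) and the Welch variant are
  available; the choice is recorded in the run manifest. The default is the
  pooled test because the analysis environment this mirrors (spreadsheet
  two-sample t-test) uses equal variances unless told otherwise.
* **Direction rule**: "up" requires T/C > 1 *and* p ≤ p_max (default 0.05);
  symmetric for "down"; otherwise "flat". A T/C-only rule is available by
  configuration. No multiple-testing correction is applied to screen
  p-values (none is applied in the analyses this reproduces); an FDR column
  can be added as annotation but never filters.

Thresholds: up-correlated = up-regulated with r ≥ r_up (0.6 broad, 0.72
stringent); down-correlated = down-regulated with r ≤ r_down (−0.6). Ranking
is r descending with ties broken by p ascending then probe id, for
determinism. Gene-level collapse keeps the probe of maximal |r| per gene
symbol — per-context best-probe selection, matching observed practice where
different tables select different probes for the same gene.

`ratio_concordance` correlates two per-gene ratio vectors (e.g. tumor/control
vs an independent condition contrast) over their shared genes and exports the
scatter table; at least 3 shared genes are required.

## Fold enrichment

`fold_enrichment(k, m, K, N)` keeps the two fractions as exact rationals
(`fractions.Fraction`) so fold × (K/N) ≡ k/m holds identically before any
float rendering. Percentages are rendered half-up — hit percent at 0
decimals, background percent at 1 decimal — reproducing the conventional
printing of such chains (117/341 → 34%, 2,044/54,613 → 3.7%). The
hypergeometric upper-tail p (scipy) is attached as optional context and never
gates output. Hit and background fractions must be computed at one declared
identifier level each (probe or gene); a probe→gene bridge must be supplied
explicitly to mix levels. Categories are flat sets — no ontology graph
traversal or term propagation.

## Cut-points, co-occurrence, clustering

Cut-points are the cohort median or 25% quartile with **linear interpolation
between order statistics** (the numpy default; declared because "25%
quartile" admits several conventions). The default scope is the full cohort —
tumors and controls compared against a single cut-off, as in co-dysregulation
counting — with arbitrary scopes (e.g. tumors only, survival samples only)
available per call. Ties follow a strict policy by default: a value exactly
at the cut-point is `at_cutpoint`, excluded from both hit and non-hit counts
("higher than"/"lower than" read literally); an inclusive policy is
available. A constant marker leaves all samples at the cut-point with a
warning. Conservation holds by construction: hit + non-hit + at-cutpoint =
scope size.

Co-occurrence counts evaluate marker conjunctions (a sample qualifies when
every listed marker is a hit) per group; the empty conjunction is vacuously
true. For two independent markers the both-hit fraction is ~25% by the
product rule; for a planted anti-correlated pair the expected fraction is the
bivariate-normal orthant probability 1/4 + arcsin(ρ)/(2π), which the test
suite checks against the generator.

Clustering is scipy agglomerative hierarchical clustering of samples on the
signature submatrix: Euclidean distance, complete linkage, per-gene row
standardization on by default (mirroring common heat-map defaults), tree cut
at a user-declared k — k is never inferred. Cluster ids are relabeled by
first appearance in sample order so output is deterministic across library
versions; cluster numbering is arbitrary and should be matched to
composition, not order. Composition tables report counts and integer
half-up percentages per stage, with unlabeled samples tallied separately and
excluded from the percentage denominator.

## Survival

`km_estimate` and `logrank_test` are implemented directly on the risk-set
tabulation because the per-time at-risk/event counts and per-group
observed/expected totals are first-class outputs; lifelines serves as an
independent cross-check in the test suite (agreement to 1e-8 or better on
random fixtures), alongside a brute-force risk-set recomputation. Ties:
events at an instant are processed before censorings (standard convention).
The k-group log-rank statistic uses the hypergeometric covariance and k−1
degrees of freedom; zero events overall is a hard error. "Chi-square
analysis" of survival strata is interpreted as the log-rank test — the
standard Kaplan-Meier companion; a literal contingency chi-square on
surviving past a fixed time is provided (`survival_past_time_chisq`) for
fidelity auditing only.

Marker prognosis dichotomizes at the median computed **over the samples with
survival data** (a prognosis cohort typically has no controls), then tests
high vs low (single scheme) or the four high/low combinations of two markers
(combined scheme). The combined scheme additionally reports the
A-high&B-high vs A-high&B-low contrast, which asks whether the second marker
adds prognostic value among samples already high for the first. Degenerate
contrasts (empty strata, duplicate markers) are skipped with a logged reason
while the rest proceed. An optional 60-month administrative-censoring horizon
is available (off by default).

## Synthetic cohorts

The generator emulates the statistical structure the screen assumes, with
known truth:

* **Correlation block**: per sample a latent factor f ~ N(0,1); module genes
  (anchor included) take x = μ + δ_g·1[tumor] + β_G·f + ε with
  ε ~ N(0, σ²) and β_G = σ√(ρ_G/(1−ρ_G)), so any two equal-loading genes have
  analytic within-group correlation ρ_G. Anti-regulated (FBP1-like) genes
  carry −β_G and −δ; background genes are pure noise.
* **Defaults as study conditions**: n = 150 tumors + 150 controls,
  ρ_tumor = 0.75, ρ_control = 0.35 (within the 0.2–0.5 range typical of
  control tissue), 25 module genes + 3 anti-genes + 500 background probes,
  μ = 8, σ = 1. The mean shift δ = 1.0 gives T/C = 9/8 = 1.125, inside the
  1.05–1.7 range of real tumor/control tables; per-gene shifts are spread
  evenly over [0.6δ, 1.4δ] (`delta_spread = 0.4`) because real modules show
  heterogeneous fold changes — this is what makes cross-cohort ratio
  concordance meaningful. The module category label is applied to module
  genes with probability 0.7 and to background genes at 0.037, the platform
  fraction of cell-cycle probe sets.
* **Stage**: ordinal equal-frequency bins of the standardized anchor score
  plus N(0, 0.5²) noise, so mean signature expression increases with stage
  in expectation and is deterministic at zero noise.
* **Survival**: exponential event times with rate λ₀·exp(γ·z), z the
  standardized anchor expression among tumors; λ₀ = 0.02/month (median ~35
  months at z = 0), γ = log 2.5 per SD, uniform administrative censoring on
  (0, 120] months; months reported at 0.1 resolution. Exponential + uniform
  censoring was chosen for closed-form calibration; under these defaults
  ~60% of tumors have observed events.
* **Determinism**: one integer seed; expression, survival, and stage draws
  use separate spawned child streams so each operation is individually
  reproducible and bit-identical across runs.

What the generator does **not** model: probe-level microarray noise (PM/MM,
spatial artifacts), batch effects between merged cohorts, non-Gaussian
expression marginals, more than one latent module, and informative
censoring. Passing recovery tests therefore demonstrates correctness of the
screening machinery under the declared model, not robustness to those
real-data complications.

## Numerical choices and problem sizes

* Correlations are clipped to [−1, 1] after computation; profile equality
  with a brute-force two-pass implementation is tested to 1e-10.
* Quantiles: numpy linear interpolation; percent rendering: decimal half-up.
* Pipeline TSVs are written with floats at 6 significant digits and
  LF line endings, making reruns with the same config and seed
  byte-identical.
* Test and acceptance problem sizes are scaled for a laptop-class single
  CPU: recovery uses 20 cohorts of 150+150 samples × 529 probes; log-rank
  size is estimated from 2,000 null simulations of 200 tumors with small
  probe panels (survival depends only on the anchor, so extra background
  probes would add nothing but runtime); power uses 200 replicates. The
  log-rank type-I band of [0.04, 0.06] at 2,000 replicates has a binomial
  standard error of ~0.005, so the check has a small inherent false-alarm
  rate even for a perfectly calibrated test.

## Known limitations

* The screen's headline counts on real cohorts (e.g. 341 up-correlated
  genes) depend on the specific microarray datasets and are not reproduced
  here; the bundled ranked tables validate the threshold/enrichment
  arithmetic instead.
* Gene-level vs probe-level ambiguity is inherited from the field: the
  package reports both levels and refuses to mix them silently.
* No Cox regression or hazard-ratio confidence intervals — Kaplan-Meier and
  log-rank only, by design.
* GMT categories are flat; no GO graph semantics.
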