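# Methods

This note documents the models, estimators and design choices behind
`ntsig`, and what the synthetic experiments do and do not demonstrate.

## Synthetic cohort generator

No public generative model exists for the underlying microarray
cohorts, so the generator is an explicit stand-in on the log2 scale of
gcRMA-style normalised data.  Per gene g, sample j of subgroup k in
dataset d:

    x_gj = baseline_g + effect(k, g) + shift_gd + λ_g f_j + ε_gj

- `baseline_g ~ U(5, 12)` log2 units (configurable; tests that exercise
  the detection filter lower the left edge so baselines straddle it);
- `effect(k, g)`: planted log2 shifts.  Defaults encode the subgroup
  biology: r4 low in all six signature genes and very high in ERBB3
  (+7.5 log2, matching fold changes in the hundreds); r2/r3
  proliferative (BIRC5, CCND1 up; a 30-gene cell-cycle block +1.5/+2.0);
  r3 MYCN-driven with a 20-gene tumour-suppressor block at −1.5;
  r1 NTRK1/PHOX2B high.  Hub partners additionally carry a +1.5 r4
  shift (`hub_partner_r4_shift`): the hub network is differentially
  expressed as a block, not merely co-fluctuating, which is what makes
  network enrichment in the r4 contrast a meaningful target.
- `λ_g f_j`: a per-sample standard-Gaussian latent factor shared by the
  hub gene and its 38 partners, loading 0.8 (loadings are capped at 1).
- `ε ~ N(0, 0.7)` log2 units of per-measurement noise and a
  per-gene, per-dataset shift `N(0, 0.3)` modelling the two-platform
  (preamplified vs not) design.
- Histology: r4 samples split GN/GNB (default 50/50); GN samples get an
  extra +3.0 log2 on ERBB3 (`gn_erbb3_bonus`) since GN shows the
  highest ERBB3 — this is what lets the two r4 tiers of the 7-gene
  signature be separable at all.  r1–r3 are all NB.

Default sizes are 20 samples per subgroup per dataset (n = 80), two
datasets, 2000 genes.  What the generator does **not** model: probe-level
effects and cross-hybridisation, intensity-dependent noise, copy-number
events (MYCN amplification and deletions are labels, not simulated
lesions), correlated background modules beyond the planted blocks, or
non-Gaussian outliers.  Tests passing on these cohorts show the
pipeline's operations are correct and mutually consistent under the
assumed structure — not that the biological conclusions transfer to any
real cohort.

## SAM differential expression

d_g = (x̄_b − x̄_a)/(s_g + s₀) with the pooled scatter
s_g = sqrt((1/n_a + 1/n_b)(SS_a + SS_b)/(n_a + n_b − 2)); positive d
means higher in the second-named group.  s₀ is chosen by scanning the
percentiles 0, 5, …, 100 of {s_g} and minimising the coefficient of
variation of the d-spread (window-wise MAD/0.64 over up to 100
s-quantile windows) — the classical exchangeability-factor recipe;
median(s) for fewer than 20 genes.  Significance permutes group labels:
all C(n, n_a) balanced splits when there are at most `n_perm` of them
(making p seed-free), else `n_perm` seeded random splits; by default
the permuted d of all genes form one pooled null.  The original
publication states neither its permutation count nor s₀ settings; these
defaults are reconstructions.  Fold change is 2^(mean difference),
reported as its reciprocal in down-lists so folds read ≥ 1.

## Cross-dataset combination

SE_i is taken as the gene's pooled scatter s (the standard error of the
between-group mean log2 difference) — the printed description ("standard
error of the mean log2 expression values") is ambiguous; this reading
weights the quantity whose fold is being combined.  P_i entering the
combination are one-sided (directional lists; two-sided permutation p
halved), floored at 1e-6 because a permutation p of 0 is an information
limit, not evidence of zero.  The probit combination is implemented
exactly as printed, with weights N_i/(N₁+N₂) that sum to one; it is
therefore conservative relative to Stouffer's root-sum-square weighting
(equal inputs are returned unchanged), which is available behind
`stouffer=True`.

## MI networks and DPI

MI is estimated on rank-transformed profiles discretised into
B = ⌊1 + log2 n⌋ equal-frequency bins, plug-in entropy with
Miller–Madow correction, floored at 0, in bits.  This deliberately
replaces the original kernel estimator: simpler, exactly testable, and
the asserted properties (Markov-chain pruning, null calibration) are
estimator-robust.  The edge threshold at a p-value cut is calibrated
from a permutation null (independent Gaussian surrogates): cut-offs
down to 0.1 use the empirical quantile; smaller ones use an exponential
fit to the upper decile (mean-excess rate), since 1e-7 is unreachable
by direct permutation at feasible null sizes.

DPI: in every triangle, edge (i,j) is marked when
mi(i,j) < (1−τ)·mi(i,k) and mi(i,j) < (1−τ)·mi(j,k); all marked edges
are removed simultaneously after the full scan, so the result is
scan-order independent; τ defaults to 0.15.

A scale caveat: at n = 80 samples, with loadings capped at 1 and noise
0.7, the calibrated 1e-7 threshold (≈1.0 bit) exceeds the MI of any
planted correlation (≈0.3–0.6 bit), so a global network at that cut is
empty on synthetic cohorts.  The library default remains 1e-7; the
analysis drivers and the default pipeline use 1e-3, which still holds
the expected number of false edges at desk scale well below one while
resolving the planted hub block.  The original network was built from a
larger real dataset with far stronger co-expression; reproducing its
network sizes is out of scope.

## GSEA

Signal2Noise score (μ_A − μ_B)/(σ_A + σ_B), each σ floored at 0.2·|μ|
(0.2 when μ = 0) per the desktop convention — the original run's floor
is not documented, so this is a reconstruction.  The weighted (p = 1)
running sum adds |score|^p/N_R at hits and subtracts 1/(N − N_h) at
misses; ES is the extreme of either sign ("real" sorting mode; the
|score| ordering used for both-tail contrasts sits behind `sort_abs`).
Gene-set permutation draws random same-size sets from the ranked
universe; p_nominal is the same-sign tail fraction, NES divides by the
same-sign null mean (reported as NaN below 10 same-sign null values),
and FDR q is the null-vs-observed extreme-fraction ratio clamped to
[0, 1].  Set size bounds 10–500.

## SD-rule signature classifier

Expression is z-scored per gene across all samples of a dataset
(ddof = 1; zero-SD genes map to z = 0), making classification invariant
to per-gene affine transforms.  A rule is UP (z ≥ θ), DOWN (z ≤ −θ) or
ANY; θ defaults to 0.5 SD.  A class qualifies when at least `min_rules`
rules hold and every mandatory rule holds; the winner has the most
rules met, ties broken by the largest summed satisfaction margin,
unresolved ties give "nd".  The published per-gene thresholds and
no-exception cells are not in the public full text, so the bundled
tables are reconstructions from the narrative subgroup descriptions and
must not be cited as the published signature.

For the 7-gene table the ERBB3 rule is mandatory in every class
(trivially ANY for the NB classes) and `min_rules` = 6 of 7, which
encodes "the ERBB3 rule plus at least 5 of the remaining 6".  The two
r4 tiers partition the ERBB3 axis: GNB-r4 requires z ∈ [0.5, 1.5), GN-r4
z ≥ 1.5.  The band (an upper bound on the GNB tier) is a deliberate
design choice: with two nested one-sided UP rules a GN-like sample
would satisfy both classes with equal rule counts, and any
summed-margin tie-break systematically favours the lower threshold,
making the GN tier unreachable.

## Agreement statistics

Cohen's κ = (p_o − p_e)/(1 − p_e) on a predicted × observed crosstab
squared by label union.  Significance uses the null-variance standard
error se₀ = sqrt([p_e + p_e² − Σ r_i c_i (r_i + c_i)]/(n(1 − p_e)²)),
z = κ/se₀, two-sided normal p — the classical crosstab-tool test; the
non-null asymptotic SE is computed alongside for intervals.  Degenerate
marginals (se₀ = 0 after zero-filling) yield NaN z/p rather than an
error.  Pearson correlation and the Welch t-test delegate to scipy with
the input validation the pipeline needs.

## Numerical choices and degenerate inputs

- Low-expression filter keeps rows with max exactly at the threshold
  (strict reading of "< 5 removed"); boundary behaviour is an argument.
- Probes missing from the probe map are dropped with a warning by
  default (`on_missing="error"` to raise).
- p-values of exactly 0/1 entering the probit combination are clamped
  to the open interval with a warning.
- Zero-variance vectors give MI 0 with a warning; zero-variance genes
  give z = 0.
- Ranking ties in Signal2Noise break by gene symbol for determinism.
- The pipeline expands one global seed into per-stage seeds via fixed
  spawn keys, so toggling a stage never shifts another stage's draws.

## Problem sizes

Tests and the acceptance script run at desk scale chosen for an
ordinary single-CPU machine: cohorts of 300–2000 genes and 48–160
samples, 100–1000 permutations for SAM and GSEA, 2000–100000 null draws
for MI calibration, 20–50 replicate seeds for Monte-Carlo rate checks.
These sizes are the package's own defaults for its synthetic study
conditions; the library accepts arbitrary sizes.

## Known limitations

- The MI estimator and null-tail extrapolation differ from the original
  kernel-based implementation; absolute MI values are not comparable,
  only the calibrated decisions are.
- The rule tables are reconstructions; on real data the thresholds
  would need re-deriving against reference histopathology.
- The combined p-value inherits the permutation resolution of its
  inputs (floor 1e-6 by default).
- FDR q-values at very small observed-set counts follow the pooled-null
  recipe and are noisy; nominal p is the primary statistic.
- No probe-level simulation: preprocess's collapse step is exercised on
  constructed probe fixtures, not on the cohort generator's output,
  which is already gene-level.
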