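# Methods

This note documents the models, algorithms, defaults and design choices in
`spdchg`, and what the synthetic-data tests do and do not establish.

## Breeding scheme

The package implements a sparse partial diallel between heterotic groups:
n inbred parents define n(n−1)/2 potential single crosses (no selfs,
reciprocals collapsed; pairs are stored in lexicographic parent order). A
sparse, phenotyped subset of crosses — every parent appearing at least once,
with a configurable between-group fraction — trains a genomic model that
predicts the complete hybrid space; per-parent general combining ability
(GCA) is derived from the predicted table.

## Synthetic population generator

The generator produces the study conditions every downstream stage assumes;
its defaults are fixed once and are not tuning knobs.

- **Genotypes.** Balding–Nichols: per SNP an ancestral frequency
  p ~ U(0.05, 0.95); per heterotic group a frequency drawn from
  Beta(p(1−f)/f, (1−p)(1−f)/f) with differentiation `fst` (default 0.2;
  under this parameterization a two-group Hudson-style estimator recovers f
  directly). Inbred lines are fully homozygous: one allele is drawn at the
  group frequency and doubled, so dosages are {0, 2}. Residual
  heterozygosity in real inbreds is a concern of the genotype-inference
  step (tolerance below), not of the generator. Markers are split evenly
  over `n_chromosomes` (default 10) with equally spaced bp positions
  (~200 Mb per chromosome); the generator makes no attempt at
  coalescent-realistic LD, so LD-decay analyses are exercised on separately
  constructed autocorrelated genotypes in the tests.
- **Traits.** `n_qtl` QTL sit at evenly spaced marker indices, the first at
  floor(spacing/2). |Additive effects| are gamma(shape 1, scale 1) with
  Rademacher (±1) signs; the distribution's parameters and the sign
  convention are exposed in the config since only the gamma family itself
  is canonical. Dominance effects are d = `dominance_ratio` × |a| with
  default ratio 0.5, so heterosis exists but additive variance dominates;
  a purely additive trait is `dominance_ratio=0`. A hybrid's genetic value
  is Σ a·x_add + Σ d·x_dom with x_add the mean parental dosage at the QTL
  and x_dom the parental-difference indicator.
- **Heritability.** Residual variance is calibrated *empirically* on the
  realized hybrid set: Var(e) = Var(g)(1−h²)/h², making the sample-level
  signal ratio exact in expectation and within ±0.05 of the target for
  ≥1000 hybrids. An analytic calibration would be exact only for the
  idealized population, not the sampled one.
- **True GCA.** Defined on the complete diallel of the panel: a line's mean
  hybrid genetic value minus the all-hybrid mean. Summed over lines this is
  exactly zero (each pair enters twice), which the tests assert at machine
  precision; it is the oracle for GCA-recovery checks.

## Genotype handling

- Dosages count the panel **minor** allele. VCF and HapMap input is
  re-oriented to the minor allele computed on the panel; a dosage TSV is
  taken at face value so write/read round-trips are the identity.
- QC removes markers with missing rate **> 0.20** or MAF **< 0.05** (both
  strict, MAF computed before imputation), then mean-imputes remaining
  missing calls per marker. The filter is idempotent.
- Hybrid inference requires essentially homozygous parents: heterozygosity
  above a 5% tolerance is an error naming the line; residual heterozygous
  calls below it are resolved to the major-allele homozygote (the likelier
  genotype when the minor-allele frequency is below one half) with a
  warning. Codings: Z_a = (g₁+g₂)/2, Z_d = 1[g₁≠g₂]; for homozygous
  parents Z_d = 1 exactly where Z_a = 1.
- Kinships: K_a = W_aW_a′/m with VanRaden-style frequency centering
  (W_a = Z_a − 2p), K_d = W_dW_d′/m with column mean-centering. The
  denominator is m — not Σ2pq — so that kernel GBLUP is *identical* to the
  marker-effect model with per-marker variance φ²/m; the equivalence with
  generalized ridge (penalty mσ²/φ² per block) is asserted to 1e−8 on
  random instances. Centering statistics come from the training panel and
  are reused for test rows.

## Mixed models

- **EM-REML.** V = φ_aK_a + φ_dK_d + σ²I. Classical EM updates
  (φ′ = [φ²y′PKPy + φr − φ²tr(PK)]/r with r = rank(K); σ² analogous with
  divisor n) are monotone in the restricted likelihood, asserted at every
  iteration with a 1e−5 relative slack. Convergence: |Δ log-lik| < 1e−6 or
  500 iterations (EM approaches the optimum slowly near the boundary; the
  cap is reported via a convergence flag, and variance floors of
  1e−10·Var(y) keep kernels valid). A single-kernel model is rotated into
  the kernel's eigenbasis so each iteration is O(np²); a degenerate
  constant response short-circuits to all-zero components. Asymptotic
  standard errors come from the inverse REML Fisher information
  ½tr(PV_iPV_j).
- **Prediction.** β̂ by GLS at the converged components; marker effects
  backsolved as γ = (φ/m)W′V⁻¹(y−Xβ̂), so any hybrid is scored as
  β̂₀ + W_aγ_a + W_dγ_d. This is algebraically identical to the kernel route
  K*,train[V]⁻¹(y−Xβ̂) (tested) and lets `predict_all_hybrids` stream the
  pair space in chunks with constant peak memory per chunk.
- **BayesB.** y = μ + Wβ + e with β_j = 0 with prior probability π
  (default 0.95) and otherwise N(0, σ_j²), σ_j² scaled-inverse-χ²(ν=4, S).
  S is matched so the prior genetic variance is r²·Var(y) with r² = 0.5
  split over the expected (1−π)m nonzero markers; the residual prior is
  scaled-inverse-χ²(4, ·) matched to (1−r²)Var(y). The Gibbs sampler
  marginalizes β_j when sampling its inclusion indicator, then samples the
  effect, its variance, μ and σ_e². Defaults: 10,000 iterations, 2,000
  burn-in, thinning 5 — declared package defaults. Chains are deterministic
  given the config seed; the inner loop is numba-compiled.
- **LASSO.** Cyclic coordinate descent with soft thresholding on
  standardized columns, warm-started down a 50-point log-spaced λ grid from
  λ_max = max|X′y|/n over three decades; λ chosen by inner 5-fold CV
  (minimum held-out MSE) and the model refit on all data; coefficients are
  returned on the original scale. λ = 0 in a user-supplied grid falls back
  to least squares (coordinate descent requires a positive penalty).
  Zero-variance columns are dropped with a warning.
- **Entry BLUPs.** Multi-environment data are fitted as value = mean +
  environment (fixed) + genotype (random) + G×E (random) + residual using
  the same kernel EM-REML on incidence-matrix kernels. This is O(n³) in the
  number of plots — adequate at the sizes used here; a Henderson
  mixed-model-equations backend would be the scaling path for much larger
  trials. Reported entry values are grand fixed-effect mean + genotype
  BLUP; the accompanying variance analysis is the fixed-effects type-II F
  test for genotype and environment.
- **Cross-validation.** Random folds re-drawn each repeat (default 5 × 20);
  accuracy is the Pearson correlation between observed values and the
  held-out predictions *pooled over folds within a repeat* — one r per
  repeat, mean ± sd across repeats — because the scheme's headline accuracy
  is a single correlation. Hybrid prediction folds partition hybrids; GCA
  prediction folds partition **lines**, so no line contributes to both
  training and testing (parent-sharing leakage would otherwise inflate GCA
  accuracy). Repeats with a constant observed vector are flagged and
  excluded.

## Combining ability

GCA_i = mean over partners j≠i of ŷ_ij minus the grand mean of all
predictions, with the average taken over **all** potential partners (between-
and within-group alike) of the complete enumerated diallel; selfs are
excluded. Centering on the all-hybrid mean makes complete-diallel GCAs sum
to zero by construction. On a complete no-self diallel the least-squares
(Griffing method-4 style) solution is exactly (n−1)/(n−2) times this
mean-deviation estimator — the tests verify that identity numerically.
Group summaries use one-way ANOVA plus Tukey HSD at α = 0.05 with a greedy
compact-letter display. Parent ranking breaks ties lexicographically by
line id so results are order-independent.

## Marker analysis

- Significance threshold: −log10(1/m) = log10(m) for p-value-scored scans;
  LOD-scored tables use their own cutoff (3) before import. Externally
  produced association tables are first-class inputs; the built-in
  PC-corrected single-marker scan (`lm_pc{k}`) is plumbing so the consensus
  pipeline runs end to end on synthetic data — it does not emulate any
  particular multi-locus method.
- Consensus: SNPs significant for the same trait/target in ≥ k distinct
  methods; consensus sets are nested in k by construction.
- Marker sets: the nine named sets — All SNPs; GCA/trait consensus at
  levels 1 and 2; and for each consensus set a random counterpart of
  exactly the same size drawn uniformly without replacement
  (seed-deterministic). Random sets match count only, not MAF or
  chromosome.
- Superior genotypes: per significant SNP, the dosage class with the most
  favorable mean (direction is per trait: larger-is-better for yield/ear
  traits, smaller-is-better for plant architecture and cob diameter;
  configurable), classes under 5 individuals ignored; hybrids are then
  scored by how many superior genotypes they carry.
- Type I–V classification: inbred two-class Welch t-test and hybrid one-way
  ANOVA + Tukey at α = 0.05 (the tests are declared conventions, exposed in
  the API). The hybrid "superior set" is the best class plus any class not
  significantly worse than it. Type I: both tests significant, a single
  superior hybrid homozygote equal to the inbred superior; Type II:
  superior set = {heterozygote, that same homozygote}; Type III: the
  heterozygote alone; Type IV: the superior hybrid homozygote differs from
  the inbred superior; Type V: neither test significant. Patterns outside
  the tree are labelled `unclassified` with diagnostics rather than forced.

## Selection gain

Gains are computed over validated entries only: top-vs-bottom =
(mean_top − mean_bottom)/mean_bottom × 100, and gain-vs-mean uses the mean
of *all* validated hybrids as the baseline. Check comparisons count
validated hybrids exceeding the check value and exceeding it by more than
5%. Both percentages are invariant to unit rescaling.

## Design-efficiency study

`sim_design_study` holds a candidate panel fixed (the panel whose GCAs are
wanted) and varies how many lines are *involved* in crosses and how many
crosses are made; accuracy is the correlation between estimated and true
GCA over the whole panel, so uninvolved lines are predicted purely through
genomic relationship. The study reproduces the qualitative pattern that the
number of involved lines matters far more than the number of crosses once
each involved line appears a handful of times. Cells that violate their own
feasibility bound (more crosses than the involved diallel contains, or too
few to cover every line) raise by default; `on_infeasible="skip"` records
them as NaN so rectangular grids containing an infeasible corner can run.
The packaged study uses a 120-line panel, 400 SNPs, 80 QTL, h² = 0.7,
involved lines {30, 60, 120} × crosses {150, 300, 450}, 20 replicates, with
the REML iteration cap at 40 — GCA correlations are insensitive to late EM
refinement, which the cap exploits; variance-component point estimates in
this study are not interpreted.

## Numerical and degenerate-input conventions

Negative NJ branch lengths are clamped to zero (logged); LD-decay bin means
are smoothed by monotone non-increasing isotonic regression before
thresholding, and the decay distance is the first bin midpoint below the
r² threshold (NaN if never reached). PCA scores are SVD-based and defined
up to sign. Selection and ranking ties break lexicographically. Constant
SNPs score 0 in scans; constant responses short-circuit REML; empty marker
sets are errors at evaluation but empty consensus inputs are valid (empty
output, with the random counterpart empty and a warning).

## Problem sizes used in the packaged checks

The test-suite and acceptance-script simulations run at reduced scale —
panels of 80–150 lines, 150–2000 SNPs, plans of 280–1050 crosses, CV with
2–3 repeats, the design study as above — sizes chosen so the full loop
(simulation → plan → REML → all-hybrid prediction → GCA → marker sets →
selection) is exercised end to end with stable Monte-Carlo margins. Passing
them shows the machinery is correct and well calibrated under the
generator's assumptions (independent markers given group structure, evenly
spaced QTL, gamma effects, homozygous parents); it does not certify
accuracy levels on real panels, whose LD structure, allele-frequency
spectra and G×E the generator deliberately does not emulate.

## Known limitations

No specific-combining-ability or reciprocal effects; no G×E or multi-trait
prediction models; imputation is mean-fill only; the entry-BLUP backend is
O(n³) in plots; the association scan is single-marker and is not a
substitute for multi-locus GWAS; plan generation satisfies coverage and mix
targets by randomized construction rather than optimal-design search.
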