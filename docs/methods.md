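# Methods

## Scope and data model

`mrkit` performs two-sample Mendelian randomization entirely at the
summary-statistics level: every computation consumes per-SNP association
records (rsID, alleles, β, SE, p, effect-allele frequency, N) read from
tab-separated text with `NA` for missing values.  SNPs are keyed by rsID;
positions are 1-based; indels and multi-allelic records are rejected at
read time.  Pairwise LD enters as an explicit long-format r² table (the
package never computes LD from genotypes), proxies as an explicit table
carrying an allele-orientation flag, and trait annotations as a local
catalogue snapshot.

## Instrument selection

Selection applies, in order: a strict genome-wide significance filter
(p < 5×10⁻⁸), greedy LD clumping, proxy substitution, a per-SNP
instrument-strength filter, and harmonization.  Defaults and conventions:

| parameter | default | meaning |
|---|---|---|
| `pval_threshold` | 5×10⁻⁸ | strict `<`; genome-wide significance |
| `clump_r2` / `clump_window_bp` | 0.01 / 10⁷ bp | discard when r² **>** 0.01 within ±10 Mb of an index SNP |
| `proxy_r2` | 0.8 | substitute only when proxy r² **>** 0.8 and the proxy is in the outcome GWAS |
| `f_min` | 10 | keep F = (β/SE)² **≥** 10, computed per SNP |
| `palindrome_maf` | 0.42 | drop A/T–C/G variants with min(EAF, 1−EAF) > 0.42 on either side |

Clumping is greedy by ascending p-value with lexicographic-rsID
tie-breaking, which makes the output invariant to input row order.  Proxy
ties at equal r² resolve to the lexicographically smallest rsID.  The F
statistic is computed per SNP from the exposure association; the boundary
case F = f_min is kept (the rule discards F *below* the threshold).

Harmonization aligns each shared SNP's outcome effect to the exposure's
effect allele: identical pairs pass unchanged; swapped pairs negate β_Y and
reflect EAF; strand-complemented pairs are flipped (with the swap logic
reapplied); palindromic pairs are oriented by which side of 0.5 the two
EAFs fall on, and are dropped when either frequency is within the
ambiguity band (MAF > 0.42) or missing.  Harmonizing an already-aligned
dataset is the identity, and on simulated data with planted swaps and
strand flips the aligned outcome effect is restored exactly for every
retained non-palindromic SNP (this is asserted in the tests).

## Estimators and numerical choices

All estimates are reported on the outcome's log-odds scale with normal 95%
CIs using the full-precision quantile 1.959964; `to_odds_scale`
exponentiates point estimate and CI.

**IVW.**  Weighted through-origin regression with weights 1/SE²_Yj.
Heterogeneity is Cochran's Q over the Wald ratios at the pooled estimate;
the overdispersion factor is φ = Q/(J−1).  MRE-IVW multiplies the analytic
SE by √φ *without* flooring at 1 — the pure multiplicative random-effects
convention — because both conventions circulate in the field and the
unfloored form is the one that names the method; `floor_phi=True` restores
the conservative max(1, φ).  IVW p-values are two-sided normal.

**MR-Egger.**  Weighted least squares with intercept, after orienting every
instrument to β_X ≥ 0 (the model is defined only up to allele orientation,
so a fixed rule is required for determinism).  Both SEs carry
√max(1, φ) with φ = weighted RSS/(J−2), and p-values use t(J−2) — the
dominant convention for Egger, in contrast to the normal-based IVW.
J ≥ 3 is required (J−2 residual df).

**Weighted median.**  Ratios sorted ascending; with normalized weights w_j
the cumulative rank is S_j = Σ_{i≤j} w_i − w_j/2 and the estimate
interpolates linearly to S = 0.5 between bracketing order statistics.  The
SE is the standard deviation over parametric-bootstrap replicates
(default 1000) in which both β̂_X and β̂_Y are redrawn from
normal(observed, SE); the bootstrap is seeded, so results are reproducible
and row-order independent.

**MR-PRESSO.**  The observed residual sum of squares uses a leave-one-out
IVW slope for each SNP (so an outlier cannot mask itself); the null
distribution redraws β*_X ~ N(β_X, SE_X) and β*_Y ~ N(θ̂_{−j}β_X, SE_Y)
and recomputes the same statistic.  Empirical p-values use the plus-one
correction, so they are bounded below by 1/(n_sim+1) and never zero.  The
per-SNP outlier test Bonferroni-adjusts the raw empirical p by J and flags
adjusted p < 0.05; note the adjustment implies outliers are only flaggable
when n_sim > J/α − 1 (with J = 30 and α = 0.05 the default n_sim = 1000
suffices; 200 would not).  All simulation draws are keyed to rows sorted by
rsID, making every result invariant to row shuffling at a fixed seed.  The
residual comparison is one-sided (≥), matching the RSS construction.  The
distortion test reports the percent change in the IVW estimate after
removing flagged outliers, with an empirical p from random re-assignments
of the outlier labels.  The pipeline runs a single detect-and-discard pass
(no iteration).

**Multivariable MR.**  The design matrix holds each complete-case SNP's
effects on all K exposures, aligned pairwise to the first exposure's
effect allele with the same harmonization rules.  `assemble_mvmr` takes one
association table per exposure covering the candidate-instrument union and
keeps SNPs present in all of them and in the outcome.  The solve uses a
pseudoinverse, so degenerate designs (e.g. an all-zero exposure column in
the nested-reduction identity) are handled; SEs carry √max(1, φ) with
φ = RSS/(J−K) — floored by default, since only the generic
"inverse-variance weighted" method is being emulated and the floor is the
conservative choice; `floor_phi=False` disables it.  With K = 1 and the
floor off, the result equals univariable MRE-IVW to machine precision
(tested).

**Power.**  The binary-outcome non-centrality calculation attenuates the
per-SD odds ratio to the probability scale (b_MR = K(OR/(1+K(OR−1))−1)),
forms NCP = b²_MR·N·R²_XZ/(K(1−K)−b²_MR), and takes the non-central
χ²(1, NCP) mass beyond the central critical value.  At OR = 1 the power is
exactly α.  Infeasible parameter sets (implied variance ≤ 0, reachable for
extreme ORs when K < 0.5) raise an error.  Only the binary-outcome branch
is implemented.

## The synthetic generator

`simulate_two_sample` draws, per SNP: MAF ~ U(maf_range) (default
0.1–0.4); instrument strength γ_j ~ N(gamma_mean, gamma_sd) (default
0.1 ± 0.02, giving per-SNP F ≈ 50–120 at the default exposure N); a direct
effect α_j that is zero (`none`), mean-zero (`balanced`) or mean-μ_α
(`directional`), optionally restricted to a fraction of SNPs and optionally
correlated with γ_j to violate InSIDE.  Standard errors use the
standardized-trait approximation SE = (2N·MAF(1−MAF))^(−1/2), inflated by
1/√(k(1−k)) for a binary outcome with case fraction k.  Observed effects
are β̂_X ~ N(γ, SE_X) and β̂_Y ~ N(θγ + α, SE_Y); planted outliers multiply
the β_Y mean.  Default sample sizes (23,210 exposure; 173,005 outcome with
case fraction 0.346) match a moderately sized autoimmune-disease exposure
GWAS paired with a large psychiatric outcome GWAS, the regime this kind of
analysis typically runs in.  LD blocks are emitted directly as a pairwise
r² table (clumping consumes only pairwise r², so inducing LD through
genotypes would add nothing the pipeline could see).  Allele corruption —
swaps, strand flips, palindromic substitutions — is applied only to the
outcome table's presentation and logged in the truth table, which records
every latent value needed to verify recovery exactly.

What the generator does **not** emulate: realistic genome-wide LD
structure, population stratification, sample overlap between the two
GWASs, winner's-curse bias in instrument selection, or binary-trait
non-collapsibility (effects are generated on a linear latent scale).
Passing tests therefore demonstrate correctness of the estimators and the
selection/harmonization logic under the stated generative model, not
robustness to those real-data complications.

## Calibration studies and their design

The calibration module measures frequentist operating characteristics on
fresh replicates (seeds spawned from one master seed):

- **MRE-IVW coverage**: 500 replicates, J = 50, θ = 0.15, no pleiotropy;
  coverage lands near 93–95% — slightly below nominal, as expected when the
  overdispersion factor is estimated from 49 df and normal quantiles are
  used.
- **Egger intercept type-I error**: 1000 replicates under balanced
  pleiotropy with InSIDE holding *and* NOME satisfied (γ_sd = 0.05,
  exposure N = 200,000 so SE_X ≪ sd(γ)).  The NOME condition matters: with
  weak instruments, regression dilution transfers part of θ·E[β_X] into the
  intercept and the test is genuinely anti-conservative (we measured ~8–10%
  at the generator defaults).  That inflation is a property of MR-Egger
  under measurement error, not an implementation artifact, so the null
  study is run where the estimator's assumptions hold.
- **MR-PRESSO global type-I error**: 500 replicates, J = 30, θ = 0.2,
  n_sim = 300, no pleiotropy.
- **Weighted-median robustness**: single dataset from the 30%-invalid
  directional-pleiotropy scenario (J = 100); the estimate must sit within
  3 bootstrap SEs of the truth.
- **Harmonization recovery** and **planted-outlier detection** against the
  generator's truth tables.
- **Power**: analytic power against the Monte-Carlo rejection rate of a
  Wald test in a generative binary-outcome model (n = 4,000, R² = 0.05,
  OR = 1.15, 2000 replicates) — scaled down from study-sized n purely so
  the Monte-Carlo arm stays cheap; the analytic formula is n-agnostic.

The multivariable-MR recovery analysis likewise simulates its exposures in
the strong-instrument regime (exposure N = 200,000), because multivariable
IVW regresses on *estimated* exposure effects and is attenuated by
regression dilution when SE_X is non-negligible relative to the spread of
true effects (at the generator's default exposure N we measure ~0.16 for a
true direct effect of 0.2).

## Degenerate inputs and edge rules

J = 1 instruments: IVW refuses and directs to the per-SNP Wald ratio.
J = 2: IVW works, Egger and leave-one-out refuse (no residual df).
J < 4: MR-PRESSO refuses.  β_X = 0 rows are excluded from Wald ratios with
a log entry.  An SE of exactly 0 anywhere is rejected at the data model.
Empty outlier list: the distortion test refuses rather than reporting 0/0.
The pipeline asserts instrument conservation
(final = clumped − each category of drops) on every run and logs one line
per dropped SNP with the rule that removed it.

## Reproducibility

Every stochastic component (weighted-median bootstrap, MR-PRESSO
simulations, the generator itself) accepts a seed; the pipeline derives
per-component streams from a single top-level seed via spawned seed
sequences.  Two runs with the same config produce byte-identical report
directories (asserted in the tests).
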