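# Methods

`xwaskit` implements a sex-stratified X-chromosome-wide DNA-methylation
association analysis for mother–father–newborn trio studies contrasting
ART-conceived with naturally conceived newborns, together with a synthetic
data generator that reproduces the statistical structure the analysis
assumes. This note documents the models, the defaults and why they were
chosen, the numerical details, and what the synthetic benchmarks do and do
not demonstrate.

## Why the X chromosome needs its own pipeline

X-linked CpGs violate the assumptions of standard autosomal EWAS tooling.
Males carry one X, so their beta values are essentially bimodal (near 0 or
near 1). Females carry two, one silenced by X-chromosome inactivation (XCI):
at a typical probe the measured methylated fraction averages an active-X
allelic state with a methylated inactive-X state, producing an intermediate
"bump" in the female beta density. A minority of loci escape XCI and stay
hypomethylated in both sexes. Because the two sexes have different mixture
structure, all analysis here is stratified: no QC or modelling step combines
information across sexes.

## Quality control and normalization

The fixed stage order is:

1. **Flagged-probe exclusion** — cross-reactive probes and probes whose last
   three bases overlap a SNP are dropped.
2. **Detection-p masking** (threshold 0.01) — failing cells become missing;
   probes missing everywhere are dropped. Masking (rather than dropping a
   probe on any failure) preserves data; the strict behaviour is available
   via the greedy filter threshold.
3. **Greedy probe/sample filtering** — iteratively remove the single probe
   *or* sample with the highest unreliable-entry fraction, recomputing after
   each removal, until the worst fraction is ≤ 0.05. Ties break
   deterministically (probe before sample, lowest index). This is a simple,
   testable operationalization of greedy QC-driven removal; the stopping
   threshold is exposed.
4. **Per-sex multimodality scan** — sorted-gap detection per probe
   (gap > 0.05 splits groups; flagged when ≥ 2 groups each hold > 1% of
   samples). Flag-only by default: flagged probes are reported, not removed,
   with `--drop-flagged` available, since inspection rather than removal is
   the conservative default for gap signals that may be genuine biology.
5. **Beta-mixture quantile normalization** — per sample, a three-state
   (unmethylated / hemimethylated / methylated) beta mixture is fit by EM
   separately to type I and type II probe betas; type I is the reference.
   Type II values in the U and M states are quantile-mapped (CDF match) onto
   the corresponding type I component; middle-state values are rescaled by
   the monotone dilation interpolating between the mapped boundaries.
   Within-type rank order is enforced exactly.
6. **logit2 transform** — M = log2(beta/(1−beta)), with betas clipped to
   (1e-6, 1−1e-6); effects are estimated on the M scale throughout.

EM numerical choices: states are initialized by assigning each value to the
nearest of the per-sample 0.1/0.5/0.9 beta quantiles. Quantile anchoring
(rather than fixed beta cutoffs) finds the three states even when a probe
type's distribution is strongly compressed toward 0.5 — fixed cutoffs leave
the outer states empty in that regime and the normalization degenerates to
identity. M-steps use weighted method-of-moments updates for the beta
parameters (guarded away from degenerate variance); at most 100 iterations
with a relative log-likelihood tolerance of 1e-6; non-converged samples fall
back to identity with a logged warning. Components are re-sorted by mean
after fitting so state labels are canonical.

Two stabilizations keep the per-sample maps from injecting technical noise:

- **Pooled shrinkage prior.** The mixture is first fit to the pooled values
  of each sample group, and every per-sample EM receives 1,000
  pseudo-observations of that fit. An unshrunken per-sample fit carries
  estimation noise that perturbs the whole map, and because the map is
  shared by all of a sample's probes this noise acts as a latent
  sample-level factor with probe-specific loadings — the classic source of
  bias and inflation in genome-wide statistics. Shrinkage caps that
  variance while leaving genuine per-sample adaptation (the point of
  per-sample normalization) intact; on full-size arrays the data dominate
  the prior. Pooling groups are the sex of the sample's X methylation
  profile (children by recorded sex, mothers female, fathers male), so no
  information is combined across the sexes. The pooled fit itself is
  multi-started (data-quantile anchors and fixed 0.1/0.5/0.9 anchors,
  higher likelihood kept): a single quantile start can miss a small outer
  component — typically the minority of hypomethylated escape loci in
  females — and losing a state degrades every downstream map.
- **Non-degenerate tails.** Outside a component's usable quantile range
  (CDF within 1e-6 of 0 or 1) the quantile map continues as a constant
  shift, and a middle-state dilation with a degenerate span falls back to a
  rigid shift. Both guards keep the map strictly monotone and stop clumps
  of tail values from being pinned onto a single output value, which would
  put spurious point masses into the downstream statistics.

The normalization is idempotent on the bulk of values (median absolute
change of a second application < 1e-3 in the test suite). It is *not*
exactly idempotent at middle-state boundaries: a handful of cells near the
state borders can change assignment between applications because the EM fit
is re-estimated from finite data. This is inherent to finite-sample
EM-based quantile maps and is why the idempotence check uses the median.

## Per-CpG association models

Four nested linear models estimate the ART–non-ART difference in child
M-values at each CpG, separately for girls and boys, each with plate as a
random intercept:

- **M1 (main):** CpG ~ ART + maternal age + maternal smoking + maternal BMI
  + primiparity
- **M2:** M1 + parental M-values at the same CpG — maternal only in the boys
  stratum, maternal *and* paternal in the girls stratum (a boy's X is
  maternal in origin)
- **M3:** M1 + birthweight + gestational age
- **M4:** M2 ∪ M3

Smoking is dummy-coded with reference level *Never* (four levels total);
parental methylation enters on the M scale, the analysis scale. Children
with any missing required covariate are excluded (complete-case), mirroring
exclusion rather than imputation of incomplete exposure records.

**Estimator.** The random-intercept model y = Xβ + u[plate] + ε is fit by
profiled REML: the variance ratio λ = σ²_u/σ²_ε is the only free parameter;
V(λ) = I + λZZ′ is block compound-symmetric, so the GLS normal equations
decompose exactly into within-plate deviations plus weighted plate means,
making one criterion evaluation O(G·p²) after a one-off O(n·p) transform.
λ is optimized by bounded scalar search on the log scale ([e⁻¹², e⁸]) with
an explicit λ = 0 boundary comparison; at the boundary the fit *equals*
ordinary least squares exactly. With fewer than two plates the model
degenerates and OLS is used with a logged notice. Inference uses the
standard normal reference on z = β̂/se(β̂), matching the downstream
empirical-null rescaling of z-statistics. The implementation is
contract-checked against `statsmodels` MixedLM (coefficients to ~1e-6) and
against the OLS closed form at the boundary; simulation shows the planted
effect is recovered without bias and 95% Wald intervals cover at ~0.95.

## Empirical-null inflation correction

Genome-wide z-statistics are modelled as a three-component Gaussian mixture
π₀N(μ₀, σ₀²) + π₊N(μ₊, σ₊²) + π₋N(μ₋, σ₋²) with μ₋ < μ₀ < μ₊; the null
component's bias μ₀ and inflation σ₀ rescale the statistics,
z_adj = (z − μ₀)/σ₀ and p_adj = 2Φ(−|z_adj|), before FDR selection
(Benjamini–Hochberg, within each sex stratum, threshold 0.01).

The posterior is explored by a conjugate Gibbs sampler: 5,000 iterations,
1,000 burn-in, fixed seed, posterior means reported. Priors are anchored on
the robust location/scale of the data (median, 1.4826·MAD): null mean
~ N(median, (2·MAD)²); signal means ~ N(median ± 4·MAD, (0.3·MAD)²),
truncated to preserve the ordering; variances ~ InvGamma(2, MAD²); weights
~ Dirichlet(90, 5, 5). The tight, far-out anchors on the signal means and
the null-favouring Dirichlet stop the signal components from absorbing the
null's tails — with diffuse priors σ₀ is systematically ~5% low on pure-null
data. These settings were validated by simulation (pure N(0,1); shifted
inflated N(0.3, 1.5²); 90/5/5 contaminated mixture) before freezing. A
robust median/MAD estimate of (μ₀, σ₀) is always computed alongside and
retained as an internal cross-check; the two agree within 0.05 whenever the
null dominates.

## Regions

**DMR candidates** are maximal runs of position-consecutive CpGs with
nominal adjusted p < 0.05, identical effect sign, and inter-CpG gaps
≤ 500 bp (all four knobs exposed). Each candidate is summarized by the
correlation-adjusted inverse-variance combination

  w_i = 1/se_i², B = Σw_i b_i / Σw_i,
  var(B) = ΣΣ w_i w_j R_ij se_i se_j / (Σw)²,

with R the empirical pairwise-complete Pearson correlation of member
M-values across the stratum's children (pairs with < 10 complete
observations are zeroed with a warning). With R = I this is classical
fixed-effect meta-analysis; with perfectly correlated members, se_B equals
the member se (no precision gain) — both limits are tested. By default
every contiguous sub-run of a candidate is evaluated, the best kept, and
its p-value Bonferroni-corrected by the number of sub-runs scanned. Beyond
localizing the signal, this correction compensates for the candidate having
been *selected* for small member p-values: in simulation, the unscanned
two-stage procedure produces ~0.5 significant null regions per run over
co-methylated null blocks (a shared within-block fluctuation yields a
same-sign run whose combined statistic looks too clean), while the scanned
default brings that to ~0.07 (`--no-scan-subregions` disables it).
Candidates are then BH-adjusted jointly; a region is significant iff it has
≥ 3 CpGs and q < 0.01. When called from the pipeline, member SEs are scaled
by the stratum's σ₀ so region statistics share the single-CpG calibration.
Member
effects enter as estimated; the small μ₀ shift is not propagated to regions
(it cancels to first order in same-sign runs and is absorbed by the joint
BH step).

**Co-methylation** reports collect all probes within a 50-kb total window
(± 25 kb, closed at the boundary; `--window-half` switches to ± 50 kb) around
a center CpG: pairwise Pearson correlations, two-sided p-values, and
Benjamini–Yekutieli adjustment over the upper triangle, with adjusted
p ≥ 0.05 marked non-significant.

**Coordinates** are 1-based inclusive everywhere inside the library; the
BED writer is the single conversion point to 0-based half-open.

## Bootstrap stability

Stability of FDR-selected CpGs is assessed by stratified resampling: trios
(child with its parents, so the parental-adjustment models stay well
defined) are drawn with replacement separately within the ART and non-ART
groups, keeping the original group sizes exactly. The full single-CpG chain
— scan, empirical-null estimation (re-run inside each replicate), rescale,
BH — is repeated per replicate (default 1,000; the benchmark suite uses
100), and each CpG's selection proportion and rank are reported. Replicate
seeds are spawned deterministically from the master seed.

## The synthetic trio generator

Everything operates on the M scale — probe-level sex-specific means, plate
intercepts, covariate slopes, planted deltas and residual noise — and betas
derive through the inverse-logit2 map, clipped to (1e-6, 1−1e-6). Defaults:

| parameter | default | meaning |
|---|---|---|
| n_trios_art / n_trios_nonart | 100 / 100 | trios per exposure group |
| n_cpgs | 1000 | probes |
| frac_type2 | 0.8 | EPIC-like type II predominance |
| frac_escape | 0.12 | ~12% of X-linked loci escape XCI |
| block_size / block_rho | 5 / 0.4 | co-methylation blocks, latent corr. |
| n_plates / plate_sd | 8 / 0.15 | plate intercepts, M scale |
| noise_sd | 0.35 | residual SD, M scale |
| parent_child_rho | 0.25 | trio residual coupling |
| type2_compression | 0.9 | shrink type II betas toward 0.5 |

Probe architecture: each non-escape probe has an active-X allelic state
(low or high, p = 0.5, base betas ~U(0.03, 0.10) and ~U(0.88, 0.96)); males
express the state directly (bimodal), females average it with a methylated
inactive-X state (the XCI bump at ~0.5); escape probes are low in both
sexes. Plate intercepts are drawn once per (plate, probe) — batch effects
are probe-specific in practice, and the per-CpG plate random intercept is
exactly the model for this. Residuals share a per-trio latent factor
(parent–child correlation; as a side effect mother–father residuals carry
the same correlation) nested over per-block latent factors (within-
individual co-methylation). Covariates are anchored to the characteristics
of a large ART trio cohort: ART mothers older (33 vs 30 y), more often
primiparous (70% vs 47%) and past smokers, BMI median 23 in both groups,
ART newborns lighter (3540 vs 3650 g). Planted ART effects (single CpGs or
spans, per sex) are added on the M scale to ART children and recorded in a
truth table (delta = 0 entries excluded). Detection p-values are
U(0, 0.001) for good cells and U(0.01, 1) for failures, which can be
clustered on configurable bad-sample/bad-probe sets.

**What the generator does not emulate:** realistic EPIC probe annotation,
genomic position distributions (probes sit in regular blocks), imprinting,
cell-composition heterogeneity, skewed or tissue-variable XCI, age-related
X loss, or dye/background artefacts requiring raw intensities. Passing
benchmarks therefore demonstrate the *statistical machinery* — calibration,
recovery, stability — under the assumed structure, not robustness to every
failure mode of real array data.

## Benchmark problem sizes

The test suite and acceptance script run reduced-scale versions of the full
design, chosen to exercise each property at meaningful power: null
calibration with 2,000 CpGs and 200 children per group over 50 seeds;
effect recovery with 200 replicates at 150 girls per group; DMR recovery
with five planted 4-CpG regions at 150 girls per group; bootstrap stability
with 100 replicates at 120 girls per group. Recovery-style benchmarks
(effect bias/coverage; bootstrap stability) use uncompressed probes
(`type2_compression = 1.0`) so they isolate the estimator from the
normalization stage, whose correction of probe-type compression is
benchmarked separately by the KS-distance check; with compressed probes and
no normalization, an M-scale delta is attenuated by construction and the
bias measurement would conflate the two stages. The DMR benchmark aligns
correlation blocks with the planted regions (block_size = 4) so that "no
significant call outside the planted spans" is well defined; with planted
regions inside larger blocks, an adjacent null CpG passing the nominal
screen by chance legitimately extends the candidate span.

## Known limitations

- The REML fit profiles a single variance ratio; crossed or nested random
  effects (e.g. row within plate) are out of scope.
- The Gibbs sampler reports posterior means without convergence diagnostics;
  the robust cross-check is the guard against gross misfit.
- The empirical μ₀ is not propagated into region-level effect estimates
  (only σ₀ scales the SEs).
- Complete-case covariate handling; no imputation.
- p-values below ~5e-324 are floored rather than represented in log space.
- Per-sample quantile normalization needs a rich probe panel. With only a
  few hundred reference (type I) probes, the per-sample map is itself noisy;
  that noise is shared across a sample's probes and surfaces as bias and
  underdispersion of the z-statistics — mostly, but at very small panels not
  entirely, absorbed by the empirical-null correction. Full arrays carry
  thousands of type I probes per chromosome, so this matters for reduced
  synthetic panels: benchmarks here either use ≥ 2,000 probes or bypass
  normalization when the target is a downstream stage.
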