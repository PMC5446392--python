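# Methods

This note records what the package actually computes, the generative model
behind its synthetic data, the parameter choices that matter, and the known
limits of both.

## The association model

Beta values (methylated / total signal, in [0,1]) are transformed to
M-values, M = log₂(β/(1−β)), with β clipped to [10⁻⁶, 1−10⁻⁶] before the
logit. Inference is on the M scale — variance there is closer to constant
across the methylation range — while effects are reported on the raw beta
scale as mean(case) − mean(control), the convention replication tables use
(negative = lower methylation in cases).

Per probe, ordinary least squares of M on intercept + group + sex + age +
the selected batch-marker probes' betas + k surrogate components; the raw
p-value is the two-sided t-test on the group coefficient with n − q
degrees of freedom. Probes with zero outcome variance get p = 1. Collinear
design columns are dropped (never the intercept or the group contrast).
Re-hybridised duplicate samples exist only for batch-marker discovery and
are always excluded from association fits. Benjamini–Hochberg step-up
adjustment (statsmodels) converts raw p-values to adjusted ones; MVPs are
positions with adjusted p < 10⁻⁷. The threshold can be applied to raw
p-values instead (`ModelSpec.threshold_on="raw"`); the adjusted reading is
the stricter and the default.

No empirical-Bayes variance moderation is applied: with ≥60 samples per
arm the per-probe variance estimates are stable, and plain OLS keeps the
null calibration transparent (verified by the permutation-null uniformity
test).

## Surrogate components for cell heterogeneity

Whole blood is a mixture of cell types with distinct methylomes; if the
mixture proportions differ between groups, every probe with cell-specific
methylation becomes spuriously associated. The package estimates k
surrogate components (default k = 2) by SVD, with two properties that both
matter in practice:

1. **The nuisance residualisation excludes the group contrast.** Components
   orthogonalised against group cannot, by construction, correct
   group-correlated composition differences — the ablation experiment (no
   components: ~93% of null probes at p < 0.05 under a strong planted
   confounder; k = 2: ~5%) only works with group left in the residuals.
2. **Signal protection.** Probes associated with group at p ≤ 0.2 in a
   preliminary fit are excluded from the SVD. Without this, planted true
   signal drags the leading components toward the case/control direction
   (observed correlations up to 0.6), and partialling them out distorts
   null probes into false genome-wide hits. With protection the first
   component tracks the planted cell proportions at r ≈ 0.98.

This is a deterministic, testable stand-in for reference-free
heterogeneity correction: it fulfils the same contract (adjusting the
association model for unmeasured cellular structure) with a simpler,
fully specified algorithm.

## Batch-effect markers and the covariate selection

Twelve samples (six per group) are re-hybridised in a later run; the
paired t-test of original vs re-batch beta values per probe (df = 11)
flags batch-sensitive probes at p < 10⁻⁷. Reaching that threshold from 12
pairs requires |t| ≥ 12.2 — only probes whose shift is many times larger
than their technical noise can qualify, which constrains the generative
model (below).

The iterative ranking then picks the most significant candidate, and
re-tests every other candidate after regressing its paired differences on
those of the selected probes (two-sided t-test on the residual-model
intercept); selection stops when no remaining candidate is significant,
and the selected probes' betas enter the association model as covariates.

**The stopping level is its own parameter** (default 0.001), not the
discovery threshold, for a structural reason worth recording. Every batch
marker's differences carry a near-constant component (the systematic shift
between runs); in a regression with an intercept that component is
collinear with the intercept, so for a candidate driven by a factor truly
independent of the selection, the adjusted intercept t-statistic is
bounded near √n ≈ 3.5 at 12 pairs regardless of effect size. Adjusted
p-values therefore live on a nominal scale: candidates explained by the
selection behave as nulls (uniform p), unexplained ones bottom out around
p ≈ 0.006. With ~50 candidates re-tested per round, a stopping level of
0.001 keeps the probability of a spurious extra covariate near 5% per run
— one planted factor yields exactly one covariate in ≈95% of simulations.
The flip side is a genuine limitation: **several mutually independent
factors cannot all be recovered at 12 pairs**, because their adjusted
p-values can never separate cleanly from the null floor. The acceptance
suite asserts the five-factor recovery target faithfully and it fails;
the one-factor behaviour, which is what the re-hybridisation design can
support, is robust. With constructed low-noise instances (see the unit
tests) a lenient stopping level (0.05) does follow independent factors.

## Probe filters

Applied in fixed order with per-rule counts logged: SNP-affected;
sex-chromosome; detection failures; non-CpG context; batch-unstable
(paired-batch p < 0.01, with the selected covariate probes retained in
the matrix as covariates but excluded from the tested set). The detection
filter is a greedy worst-offender elimination: repeatedly remove the probe
row or sample column with the largest **fraction** of cells at detection
p > 0.05 until none fail. Fractions, not raw counts, are the scoring —
with raw counts any sample column (one failure per ~10⁴ probes) outscores
every probe row and the filter deletes samples wholesale; ties prefer the
probe. Between-sample quantile normalization (map each sample's sorted
values onto the mean sorted profile) is available but off by default: the
synthetic world has no dye/design bias for it to fix, and rank-preserving
renormalisation is not neutral for planted effect sizes.

## The synthetic cohort

Defaults mirror the modelled study design: 67 cases vs 59 controls, three
hybridisation batches, 6 + 6 re-submitted samples, at 20k probes (desk
scale). The generative model, per probe and sample:

- **Baselines**: three-component M-scale mixture centred at logit₂(0.08),
  logit₂(0.92) and 0 (weights 0.42/0.42/0.16, sd 0.8) — the familiar
  bimodal methylome. Planted MVP probes, their block mates and batch
  probes are drawn with intermediate baselines (β ∈ [0.20, 0.65]) so
  beta-scale shifts of 0.10–0.15 survive without clipping, and are kept
  off the SNP/sex/non-CpG flag lists.
- **Co-methylation blocks**: probes come in blocks of 1–5 spanning at most
  500 bp, separated by 10 kb, rotating over 22 autosomes; each block
  shares a per-sample latent (M-scale sd 0.05). Planted case effects are
  block-level: the MVP probe carries the full effect, block mates 3% of it
  (`neighbor_effect_frac` = 0.03 of the beta-scale target) — enough for
  sign concordance well above the ~0.6 background produced by the shared
  latent, while staying about four orders of magnitude away from
  genome-wide significance at n = 60+60, so neighbours never contaminate
  MVP precision.
- **Case effects** are specified as beta-scale differences and applied on
  the logit of the mixed clean signal, with the shift calibrated at each
  probe's realised mean baseline, making the planted difference exact in
  expectation (calibrating at the pre-mixture baseline left ~7%
  probe-persistent error). Per-MVP magnitudes can be heterogeneous
  (`effect_heterogeneity` h draws magnitudes uniformly from
  [(1−h)·effect, effect]), which is what gives the |difference| > 7%
  co-methylation restriction something to select.
- **Cell composition**: k cell types (default 5) with per-probe M-scale
  profile offsets (sd 0.5); per-sample Dirichlet proportions
  (concentration 60) whose mean shifts between groups by
  `confound_strength` (default 0 — confounding is opt-in for the
  ablation experiments).
- **Batch effects**: re-batch copies of a sample reuse its clean signal
  with fresh noise plus, at the 50 batch probes, a planted offset =
  loading × per-pair factor, loading = batch_shift × U(0.75, 1.25) ×
  random sign (mean magnitude exactly `batch_shift` = 0.15), factor ~
  N(1, 0.15) shared across the probes of one latent factor. Original
  batches carry no inter-batch offsets: the paired test only ever
  contrasts original vs re-batch, and the three-batch split of the
  originals is design metadata. Multiple independent factors partition
  the batch probes.
- **Noise**: i.i.d. N(0, 0.06) on the M scale. This is deliberately tight:
  discovering 50 planted markers at p < 10⁻⁷ from 12 pairs — the regime
  the re-hybridisation design implies — requires technical noise at least
  this small relative to the planted shifts.
- **Detection p-values**: Beta(1, 200) baseline; failures cluster in
  "bad probes" (0.2% of probes failing in ~40% of samples) plus a 10⁻⁵
  isolated background, as on real arrays. Uniform random failures at
  realistic rates would, under the zero-failing-cells contract of the
  greedy filter, delete ~12% of the array.
- A single master seed spawns independent sub-streams per component, so
  every artifact is reproducible in isolation.

What the generator does **not** emulate: Infinium type I/II chemistry and
dye bias, probe cross-hybridisation, genomic context beyond the block
structure (no CpG-island geography), age/sex effects on methylation, and
correlated (non-Dirichlet) cell-type dynamics. Passing tests demonstrate
that the pipeline recovers structure of the planted kinds at the planted
magnitudes — not that real 450K data meet these assumptions.

## Amplicon reads, clones and paired tissue

Reads are bisulfite conversions of the amplicon reference: non-CpG
cytosines convert C→T unless conversion fails (per-site rate), CpG
cytosines stay C with their true methylation probability; substitution
and indel noise follow; Phred qualities are clipped normal (mean 37, sd 3);
an 8-mer sample barcode is prepended (exact-prefix demultiplexing, no
error correction). The generator returns the planted per-CpG state counts,
which are the recovery oracle: the caller is judged against the states the
reads actually carry, with the binomial standard error at the observed
read depth as the yardstick. Amplicons used in the demo pipeline and in
acceptance runs are built cytosine-rich (~25% lone-C backbone): with only
a handful of non-CpG cytosines, a single conversion failure drops a read
below the 90% conversion threshold and the filter removal rate reflects
denominator coarseness rather than chemistry.

Clones are independent Bernoulli vectors (32 clones × 33 CpGs per sample)
with group-specific methylation probability; per-sample methylation pools
all non-missing calls. Paired blood/lip values draw blood from a bimodal
Beta(0.4, 0.4) and add Gaussian noise to produce a target pooled Pearson
correlation, then clip to [0,1]; clipping nudges the realised R² slightly
above the square of the target.

## The bisulfite-aware aligner

Semi-global dynamic programming (reference overhangs free, read aligned
end to end) with match +1, mismatch −1, linear gap −2. Bisulfite
asymmetry: read T opposite reference C is a match at non-CpG positions;
at CpG offsets both C and T match and are recorded as calls. Identity is
matching columns over the aligned reference span (reference bases deleted
from the read count against it), and conversions count as matches —
otherwise a fully converted read could never reach 90% identity.
Conversion rate is T/(C+T) over aligned non-CpG reference cytosines; the
CpG gap fraction counts panel CpGs aligned to a gap or not covered.
Both the read and its reverse complement are tried; ties prefer forward
orientation and the alignment ending earliest on the reference. The DP
fill is vectorised row-wise (the horizontal gap chain is a prefix-max
scan), and its scores are verified against exhaustive enumeration on
small instances in the test suite. Paired-end mates are treated as
independent single reads; no four-stranded search (amplicon primers fix
the strand); primers are assumed trimmed from the reference.

## Statistical kernels

Standard tests are delegated to scipy/statsmodels behind thin, documented
entry points: Welch's t (with a summary-statistics mode taking group mean,
SEM and n exactly as result tables print them — the two modes agree to
1e-12 when summaries come from the raw data), Fisher's exact (two-sided,
hypergeometric), chi-square with Yates continuity correction (explicit
formula, cross-checked against scipy), tie-corrected Kruskal–Wallis (with
an optional permutation reference for small samples), and OLS for the
tissue regression (R² = squared Pearson r over pooled site × individual
pairs). The test suite carries independent brute-force oracles —
hypergeometric enumeration, permutation tests, a hand-rolled BH step-up,
exhaustive alignment enumeration — so the library routes never certify
themselves. The pooled-amplicon comparison is paired by site (per-site
group means across all CpGs of all amplicons, paired t-test); an unpaired
Welch variant is available since the pairing convention is a judgment
call. In the published-style replication summaries bundled with the
package, the "±" values are standard errors of the mean: only under that
reading do the printed Welch p-values re-derive from the printed summaries
at n = 171/177 (the two-decimal entries appear to be truncated rather than
rounded; the tests allow one unit in the last printed digit).

## Problem sizes and determinism

Simulated experiments run at 4k–10k probes and 60–126 samples per cohort,
10–20 seed replicates per stochastic claim, and 5000 reads per sample for
amplicon recovery — sizes chosen so every planted effect is comfortably
identifiable and a full verification pass completes in minutes on one
CPU. Cohort-scale counts from 450k-probe studies (hundreds of MVPs,
hundreds of batch markers) are not reproduction targets at these sizes;
the acceptance checks are property-based (recovery, calibration, oracle
equivalence) plus worked examples computed from published-style summary
tables. All randomness flows from explicit seeds; the pipeline writes a
manifest of seed and thresholds, and identical configs produce
byte-identical outputs.

## Known limitations

- Covariate selection cannot resolve multiple independent batch factors
  from 12 re-hybridised pairs (analysis above); it reliably finds one.
- The surrogate protection step assumes true signal is sparse; if a large
  fraction of probes were truly associated, too few null probes would
  remain and the components would degrade (a warning fires below a floor).
- The aligner's linear gap penalty and fixed scoring are adequate for
  amplicon reads but are not a general-purpose bisulfite mapper.
- Beta values are treated as exact fractions; measurement-intensity noise
  models (detection p as a function of intensity) are out of scope.
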