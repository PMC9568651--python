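# Methods

## The paired design and the conditional likelihood

The unit of analysis is a disease-discordant monozygotic twin pair: one
affected twin ("case") and one unaffected co-twin ("control") measured on
the same methylation array. Conditioning on one case per pair removes the
pair-level nuisance parameters exactly; for 1:1 matching the conditional
likelihood of the case/control labels reduces to an intercept-free
logistic regression on within-pair covariate differences with the outcome
fixed at 1:

    ℓ(b) = Σ_pairs −log(1 + exp(−dᵀb)),   d = x_case − x_control.

Per probe, `d` stacks the within-pair M-value difference (the exposure of
interest), one-hot plate differences, and differences of six of the seven
estimated cell-type proportions (granulocytes serve as the reference type;
including all seven would be collinear with the sum constraint). Covariates
that are constant within every pair — sex, chiefly — difference to zero and
are dropped with a logged note: they cannot contribute to a conditional
likelihood, even though a marginal model would list them.

The maximizer is found by Newton–Raphson with step-halving, batched across
probes (the covariate block is shared, so the per-probe Hessian assembles
from shared matrix products). Convergence requires a score norm below 1e-8
within 50 iterations. Standard errors come from the inverse observed
information at the optimum; p-values are two-sided Wald. Three failure
modes are flagged per probe rather than reported as results:

- `degenerate` — all methylation differences are exactly zero;
- `separated` — the likelihood is effectively monotone; we flag any fit
  whose methylation coefficient passes |b| > 15 on the M-value scale,
  where Wald inference is meaningless;
- `not_converged` — iteration cap reached or the information matrix is
  numerically singular (possible when the parameter count approaches the
  number of pairs; the fitter refuses outright when parameters ≥ pairs).

FDR (Benjamini–Hochberg) is computed over `ok` probes only.

Two properties of this model matter for interpreting everything
downstream, and we verified both against independent implementations
(`survival::clogit` in R during development; `statsmodels` ConditionalLogit
in the test suite):

1. **Wald saturation.** With n pairs, the Wald z of the conditional
   logistic model is non-monotone in the effect size (Hauck–Donner): as the
   within-pair effect grows past roughly 0.5–0.7 of the within-pair noise
   sd, |b̂| grows but its standard error grows faster, and the attainable
   |z| plateaus (around 2.5 at 40 pairs). Very strong probes end up
   `separated`. Robust (sandwich) standard errors would lift this ceiling
   but are deliberately out of scope; the package reports what the
   conditional likelihood itself supports.
2. **Small-sample inflation.** Fitting ~7 nuisance covariates on 40 pairs
   inflates the null Wald statistics; the genomic-inflation factor on null
   cohorts sits near 1.2–1.3 rather than 1. This is a property of
   observed-information Wald inference at this ratio of parameters to
   matched sets, not a bug; λ is reported so users can see it.

## Region detection

Neighbouring CpGs carry correlated evidence. Following the comb-p
approach: (i) the autocorrelation of probit-transformed p-values,
z = Φ⁻¹(1−p), is estimated in 50-bp distance bins up to 750 bp, pooled
across chromosomes (bins with <10 probe pairs fall back to 0);
(ii) each probe's p is replaced by the Stouffer–Liptak combination of all
probes within ±750 bp, z_comb = Σz_j / sqrt(k + 2Σ_{j<l} σ(d_jl));
(iii) probes with corrected p below a seeding threshold are clustered
while consecutive sub-threshold probes are ≤ 750 bp apart, clusters with
fewer than two probes are discarded; (iv) each region is scored by the
Stouffer–Liptak combination of its members' raw p-values and adjusted by
a Šidák correction, 1 − (1 − p)^(total_bases / width).

Numerical conventions: p-values are clipped to [1e-300, 1−1e-16] before
the probit; a non-positive combined variance (pathological estimated
autocorrelation) falls back to independence with a log message; the Šidák
step uses `-expm1(k·log1p(−p))` so tiny combined p-values survive;
isolated probes keep their original p exactly.

Two defaults deserve justification because they control the
power/false-positive balance:

- **Šidák search space** (`DmrParams.sidak_total`): the default counts the
  bases covered by assayed CpG sites (2 bp each), the convention of the
  region-combination tool this module follows. The alternative "span"
  convention (summed per-chromosome genomic span of analyzed probes) is
  ~800× more conservative on sparse designs; under it, region-level
  evidence of the depth this model can produce at 40 pairs (bounded by the
  Wald plateau above) essentially never clears α = 0.05, and published
  region tables from comparable studies could not exist. Both conventions
  are available; results should always be reported with the convention
  used.
- **Seeding threshold** (`seed_p = 1e-4` on the corrected p): calibrated
  on matched null cohorts so that chance probe clusters essentially never
  become significant regions (at most one false region across twenty
  40-pair null cohorts in the replication study), while planted regions —
  whose members' corrected p are orders of magnitude smaller — are
  unaffected.

Direction strings ("- - +") report the genomic-order signs of member
coefficients; "consistent direction" means strict unanimity.

## Context-bias analysis

A negative conditional-logistic coefficient means lower methylation in
cases. For each annotation stratum (full array; Island / Shore / Shelf /
OpenSea, plus the collapsed Shelf/shore; each RefGene group; each
regulatory-feature group; each class of any supplied BED track) the module
counts strictly negative and strictly positive coefficients (exact zeros
are excluded from both and logged — continuous MLEs essentially never hit
zero, so an exact zero indicates something worth seeing) and tests the
split with an exact two-sided binomial test against 0.5, computed by
log-space tail summation so epigenome-scale counts do not underflow.

The sign analysis is confirmed on the raw beta scale: per stratum, the
per-pair median of Δβ over member probes is tested against zero with a
one-sample Wilcoxon signed-rank test (exact for ≤25 nonzero tie-free
values, otherwise normal approximation with continuity correction; zero
differences are dropped; all-zero inputs give p = 1; a single nonzero
difference is untestable and reported missing).

Island-relation strata partition the tested probes, so their counts add up
to the full-array row (a tested invariant). RefGene strata do not — probes
annotated to several groups count once in each. FDR is applied within
analysis families (core annotation strata, repeats, TF motifs, ...), sign
tests and delta-beta tests each forming their own family, mirroring how
such analyses are corrected per table or figure panel rather than
globally.

## Deconvolution

Cell proportions are estimated per subject by constrained projection: p
minimizes ‖y − Rp‖² subject to p ≥ 0 and Σp ≤ 1, where R holds reference
beta profiles of purified cell types at deconvolution-informative probes.
Plain NNLS is tried first; if the solution violates the sum constraint the
equality-constrained problem is solved by a heavily weighted penalty row,
which the active-set NNLS treats as a hard constraint. The residual norm
is reported, not rescaled away — an unexplained fraction is diagnostic of
reference mismatch. A rank-deficient reference is rejected with the
collinear cell types named.

## QC conventions

- Detection-p masking is strict: entries with detection p **>** 0.05 are
  masked; exactly 0.05 is retained.
- Missingness filtering is probes first (strict > 5%), then subjects
  recomputed and filtered by the same rule. Probes dominate missingness on
  arrays; fixing the order makes the count trail auditable, and it is
  recorded in the run report.
- kNN imputation (k = 10): distance between probes is the RMS difference
  over commonly observed subjects; an entry is the mean over the k nearest
  probes observed for that subject, clipped to [0, 1]; a probe with no
  usable neighbour falls back to its row mean with a log message.
- M-transform clips betas to [1e-6, 1−1e-6]; beta→M→beta round-trips to
  1e-9 away from the clip.
- Pair-level QC: a pair is excluded when either member's mean detection p
  exceeds 0.01 or exceeds the cohort median by 3 MADs (the source analyses
  say only "significantly elevated"; this default is conservative and
  configurable).

## The synthetic cohort generator

Real disease-discordant twin methylation data are restricted by statute,
so the generator is first-class, tested code: it defines the conditions
under which every downstream property is demonstrated.

Model: logit(β) = baseline + pair effect + plate effect + case·δ, then
inverse-logit (logits clipped to ±12), plus measurement noise added on the
beta scale. Components:

- **Baselines** are bimodal by CpG context (islands unmethylated, mean
  logit −2.8; open sea methylated, +2.6; shores intermediate), sd ~1.2–1.8,
  reproducing the characteristic two-mode beta distribution.
- **Noise** is near-constant on the *beta* scale: per-probe sd τ_j is
  lognormal (median 0.014, log-sd 0.3) clipped to [0.008, 0.02]. This
  single choice simultaneously reproduces three observed features that a
  homoskedastic logit-noise model cannot: per-pair Spearman correlations
  in the 0.97–0.99 band (rank shuffling concentrates inside the dense
  modes), per-probe delta-beta SDs of order 0.01, and a recurrence screen
  at |Δβ| ≥ 0.15 that is empty in the absence of signal (the clip keeps
  within-pair noise below the screen essentially surely).
- **Pair effect** (shared by both twins, logit sd 0.3) carries the
  between-pair biological variance. It cancels exactly within pairs, but
  it moves each pair's realized beta, and because beta-scale noise maps to
  the M scale through 1/(β(1−β)), a large pair effect makes within-pair
  M noise heavy-tailed across pairs; 0.3 keeps that amplification mild.
- **Case effects** are drawn per probe on the beta scale with
  context-specific means (open sea −0.0019, shelf/shore −0.0016, islands
  0; sd 0.006) and converted to logit shifts through the slope at the
  probe's expected realized beta (logistic-normal shrinkage of the
  baseline), capped at ±1 logit. The means match the 1e-3-scale stratum
  delta-beta medians of array studies; the dispersion sets the
  negative-coefficient fractions near the high-50s% (open sea) versus ~50%
  (islands).
- **Planted DMRs** are disjoint runs of ≥8 probes within 500 bp whose
  members all have mid-range baselines (beta in [0.03, 0.97] — a uniform
  beta shift at a boundary probe is physically truncated). Members receive
  a shared beta-scale shift (default −0.022, the magnitude of the
  strongest regions reported in comparable studies), capped per probe at
  its own noise sd τ_j: beyond roughly one noise sd per pair the
  conditional likelihood turns monotone and the probe carries no Wald
  evidence, so *detectable* regions — the ground truth this generator is
  meant to plant — live below that ceiling. The regional effect replaces
  the independent probe-level case effect on members, making the region's
  ground truth exactly the configured shift.
- **Cell mixtures**: proportions are Dirichlet (α = 6, 12, 12, 10, 55, 3,
  2 for B, CD4T, CD8T, Mono, Gran, NK, nRBC — a plausible cord-blood
  composition) drawn per *pair* with a small multiplicative within-pair
  jitter (log-sd 0.05), since twins share the in-utero environment. At 500
  designated informative probes the beta value is the proportion-weighted
  linear mixture of per-cell-type profiles (expit of baseline plus
  N(0, 1.5²) logit offsets) — linear because a beta *is* a methylated-cell
  fraction, which keeps reference-based deconvolution well specified.
  Informative probes carry no pair or case effect, mirroring how
  deconvolution libraries select low-variability discriminator probes.
- **Design**: equal-sex pairs (60% female), cases and controls always on
  different plates (two plates by default, emulating a small
  block-randomized cohort), chips of eight nested in plates.

One integer seed determines everything; each component draws from its own
fixed-offset substream so components regenerate identically in isolation.

What the generator does *not* emulate: probe-type (I/II) chemistry, SNP-
affected probes, sex chromosomes, spatially varying annotation structure
(contexts are i.i.d. across probes), or cell-composition effects outside
the informative subset. Consequently, passing recovery tests demonstrate
the statistical machinery under a faithful noise/effect geometry, not
performance on raw-array artefacts.

## Replication-study problem sizes

The property suites run the full chain on cohorts of 40 pairs × 20,000
probes — large enough that cluster geometry, FDR behaviour and the Šidák
search space are in their asymptotic regime, while 20 signal plus 20
matched null cohorts complete in a few minutes on one CPU. The acceptance
script reports DMR recovery, false regions on nulls, the stratified
sign-bias pattern, null-calibration summaries and the per-pair correlation
range from exactly this study.

## Known limitations

- Wald inference inherits the saturation and small-sample inflation
  discussed above; likelihood-ratio or robust alternatives are not
  provided.
- The exact Wilcoxon path requires tie-free inputs; tied data fall back to
  the normal approximation even at small n.
- The region caller scores the probes that seeded a region (selection and
  scoring share data), the known mild anticonservativeness of this family
  of methods; the seeding threshold default compensates empirically.
- `impute_knn` is quadratic in the number of probes with missing entries
  and intended for the post-filter missingness levels (<5%).
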