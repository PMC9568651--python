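# twinewas

Paired epigenome-wide association analysis for disease-discordant
monozygotic twins.

Monozygotic twins discordant for a disease are a natural matched
case-control design: the twins share genotype, sex, ancestry and most birth
factors, so methylation differences between the affected and unaffected
twin isolate non-genetic contributions to disease risk. `twinewas`
implements the full analysis chain for Illumina-style methylation-array
beta values from such cohorts:

- **Paired EWAS** — per-probe conditional logistic regression. For 1:1
  matched pairs the conditional likelihood depends only on the within-pair
  covariate difference d = x_case − x_control:

      ℓ(b) = Σ_pairs −log(1 + exp(−dᵀb))

  maximized by Newton–Raphson (batched across probes), with
  observed-information Wald inference, Benjamini–Hochberg FDR, and the
  genomic-inflation factor λ. The methylation exposure enters as an
  M-value, M = log2(β/(1−β)); plate and cell-composition covariates enter
  as within-pair differences; pair-constant covariates (e.g. sex) drop out
  automatically.
- **DMR detection** — autocorrelation-weighted Stouffer–Liptak combination
  of neighbouring probe p-values, seeded region extension, and a Šidák
  correction for the effective number of regions, following the comb-p
  approach.
- **Genomic-context bias** — stratifies regression-coefficient signs and
  per-pair median delta-beta (Δβ = β_case − β_control) by CpG-island
  relation, RefGene group, regulatory feature and external BED tracks
  (repeats, CoRSIVs, cCREs, TF motifs), testing each stratum with an exact
  binomial test against 0.5 and a one-sample Wilcoxon signed-rank test;
  this localizes where in the genome case hypomethylation concentrates.
- **Cell-type deconvolution** — reference-based constrained projection
  (non-negative least squares with Σp ≤ 1) of each subject's methylome onto
  purified nucleated-cell profiles (B, CD4T, CD8T, Mono, Gran, NK, nRBC),
  with a paired Wilcoxon comparison of case versus control proportions.
- **Within-pair statistics** — delta-beta matrices, the |Δβ| ≥ 0.15
  recurrence screen, per-pair correlation QC and the global
  methylation-content comparison.
- **Cross-platform concordance** — Pearson correlation and
  direction-concordance tests against an orthogonal per-site assay
  (methylation-specific droplet digital PCR fractional abundance).
- **Synthetic twin cohorts** — a fully seeded generator with known ground
  truth (planted context-specific hypomethylation, contiguous DMR blocks,
  cell mixtures, plate effects), because real twin-registry methylation
  data are legally restricted. Every downstream stage is tested against
  this ground truth.

## Worked example

```python
from twinewas.simulate import SimConfig, generate_manifest, generate_cohort
from twinewas.deconvolution import estimate_proportions
from twinewas.ewas import run_ewas
from twinewas.dmr import call_dmrs
from twinewas.context import run_bias_suite
from twinewas.pairwise import delta_beta, pair_correlation

cfg = SimConfig(n_pairs=40, n_probes=20000, seed=7)
manifest = generate_manifest(cfg)
beta, sheet, truth, cell_ref = generate_cohort(cfg, manifest)

props = estimate_proportions(beta, cell_ref)
ewas = run_ewas(beta, sheet, props)
dmrs = call_dmrs(ewas, manifest)
bias = run_bias_suite(ewas, delta_beta(beta, sheet), manifest)
```

With the default configuration this prints (seed 7):

```
pair Spearman range: 0.982-0.983
probes fit ok: 19104 of 20000
significant DMRs (Sidak < 0.05): 12 (planted: 5)
All probes: 56.6% negative coefficients (binomial p = 1.54e-74)
OpenSea: 59.0% negative coefficients (binomial p = 3.57e-76)
Island: 49.8% negative coefficients (binomial p = 0.775)
```

Reading the output: the per-pair Spearman correlations sit in the
high-0.97s, as expected for genetically identical twins; the paired
regression flags a strong genome-wide excess of negative coefficients
(hypomethylation in cases) that is concentrated in open-sea probes and
absent from CpG islands — the planted regional specificity — and the
region scan recovers all five planted DMR blocks (the additional called
regions are chance clusters of the genuine probe-level case effects the
generator plants array-wide). Probes that are not `ok` were flagged as
quasi-separated (monotone likelihood), where Wald inference is
meaningless.

A shell interface wraps the same machinery:

```bash
twinewas simulate -c sim.yaml -o cohort/      # write a fixture + truth
twinewas run -c run.yaml -o results/          # full pipeline + run report
twinewas ewas|dmr|bias ...                    # single stages
```

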