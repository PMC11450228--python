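# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical decisions a maintainer should know about.

## Differential expression

The DE stage is a fully specified negative-binomial Wald procedure, not a
re-implementation of DESeq2's internals. Per stage-pair comparison (each
pairwise comparison uses only its own samples):

- **Normalization** — median-of-ratios: factor_s = median over reference
  genes of count_gs / geometric-mean_g, where reference genes are nonzero
  in every sample. If no such gene exists the caller must opt into a
  positive-count pseudo-reference (`use_pseudo_reference=True`); silent
  fallback would hide library problems. Note the exact scaling law: when
  one library's counts are multiplied by a constant c, its factor gains
  c^((S−1)/S) and the others lose c^(1/S) — only factor *ratios* scale by
  exactly c — so normalized counts, and every downstream call, are
  invariant, which is the property that matters.
- **Fold change** — log2FC = log2((m_B + 0.5)/(m_A + 0.5)) on normalized
  group means; the 0.5 pseudo-count stabilizes genes with zeros.
- **Dispersion** — pooled within-group method-of-moments for the NB
  var = μ + αμ², floored at 1e−8. No shrinkage, no independent filtering,
  no outlier handling; results will differ from DESeq2 gene by gene, but
  the selector is deterministic and testable.
- **Test** — delta-method SE of log2FC, two-sided normal p, BH step-up
  adjustment (via statsmodels; an independent brute-force implementation of
  the step-up definition is the test oracle). Genes with all-zero counts in
  both groups are flagged untestable and excluded from multiple testing.
- **Selection** — q < 0.001 and |log2FC| ≥ 1.5. The FDR cutoff is applied
  to the adjusted p-value; a flag applies it to the raw p instead. The
  fold-change threshold is on |log2FC| (the literal reading), not on the
  fold change itself.

## PCIT network inference

For every unordered gene pair (x, y) and every third gene z, the three
first-order partial correlations of the trio are computed, and the trio
tolerance is the signed mean of the partial-to-direct ratios
ε = (r_xy.z/r_xy + r_xz.y/r_xz + r_yz.x/r_yz)/3. Edge (x, y) is discarded
if, for at least one z, |r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|.
Zero-correlation pairs are discarded outright; with fewer than three genes
every nonzero edge survives.

Numerical decisions: trios containing a conditioning correlation at
|r| = 1 (denominator collapse) or a zero direct correlation inside a ratio
are skipped; pairs at |r| = 1 (duplicated genes) can never be discarded by
such trios and are retained. Correlations are computed on
log2(median-of-ratios-normalized counts + 1), by default over the two
compared stages' samples (configurable to all stages). The scan is O(n³)
in genes and vectorized per conditioning gene; a literal triple-loop
oracle checks equality on every instance up to 12 genes. Networks are
meant to be built over DE genes only (hundreds, not tens of thousands).

Whether the signed or absolute mean defines ε is not observable from the
published description; the signed form is used and isolated in one
function, so flipping the convention is a one-line change covered by the
oracle test.

## Clusters and SNP groups

A cluster is every gene within unweighted shortest-path distance k of a
nucleus gene, k ∈ {1, 2, 3} (larger k warns). The nucleus is a member at
distance 0: its own SNPs are the best-motivated ones, so excluding it
would be perverse. Multiple nuclei give separate clusters; a union
operation exists for joint groups.

SNP-to-gene mapping is a pure interval test on 1-based inclusive
coordinates: SNP position ∈ [start − f, end + f] on the same chromosome,
both flanks, strand ignored. Flank f ∈ {0, 1000, 10000} bp are the
standard settings; monotonicity (smaller flank ⊆ larger flank) is a tested
invariant. A SNP may map to several genes but the group G is a set, so
double-weighting cannot occur. An empty G is warned about and collapses
the weighted model to the baseline. In the pipeline, the all-DE-genes
scenario uses flank 0, and the cluster scenario defaults to 10 kb (the
flank yielding SNP-group sizes on the scale where weighting has been
reported to matter).

## Weighted Bayes C

Model and priors are in the README. Implementation notes:

- **Full conditionals** — (a) intercept (flat prior); (b) year and
  experiment random-effect levels, each block variance from a scaled
  inverse chi-square full conditional; (c) per marker: residualized
  inclusion Bayes factor, Bernoulli draw of γ_j, then β_j from its normal
  full conditional if included; (d) per-group slab variance
  σ²_g = (df·S0_g + Σ_{j∈g,γ=1} β_j²) / χ²(df + m_g); (e)
  π ~ Beta(p₀π₀ + m, p₀(1−π₀) + p − m); (f) residual variance
  σ²_e = (df_e·S0_e + e'e) / χ²(df_e + n).
- **Hyperparameters** — df = 5 and S0 = var(y)·R²·(df+2)/MSx with
  R² = 0.5. MSx is computed **per group** (sum of that group's column
  sample variances), so each group's scale delivers its intended variance
  share; this is the one place where a single published symbol admits two
  readings (global vs per-group MSx), and the per-group reading is the one
  that makes the 25/50/75% weight semantics exact. Residual prior:
  df_e = 5, S0_e = var(y)·(1−R²)·(df_e+2). Year/experiment variance
  priors take the same form with a 5% variance share each (configurable);
  nothing downstream is sensitive to these weak priors.
- **One shared π** — the weighting changes only the slab variances, not
  the Bernoulli component, so π is common to both groups.
- **Determinism** — the whole sweep runs inside one numba kernel seeded
  once per fit; the marker update order is a fixed permutation drawn from
  the seed. Identical (data, prior, schedule, seed) gives bit-identical
  chains. Constant genotype columns are dropped with a warning (alignment
  is preserved for prediction); missing genotypes are mean-imputed per
  column before fitting.
- **Schedule** — defaults are the full-study schedule: 10,000 burn-in,
  20,000 further iterations thinned every 20th, i.e. exactly 1,000
  retained draws. Tests and the acceptance script use a desk-scale
  schedule (1,000 burn-in, 2,000 iterations thinned by 2), which the ridge
  and directional checks show is ample at desk-scale n and p.
- **Prediction** — GEBV = posterior-mean intercept + X·posterior-mean β.
  Year and experiment effects are excluded: new-season lines carry unseen
  levels.

Two analytic limits anchor the sampler: with π fixed at 1 and fixed
variances the posterior mean equals the closed-form ridge solution
(checked to 0.05 at n = 20, p = 3, and typically agreeing to ~2e−3); and
the thinning bookkeeping retains exactly 1,000 draws under the full
schedule.

### When does neutral weighting equal standard Bayes C?

With (R²_G, R²_nonG) = (0.25, 0.25) and G a variance-balanced half of the
panel, the two-group prior scales coincide with the single-group ones.
Equality of *predictions* additionally requires that the two slab-variance
posteriors have nothing distinct to learn, and that is only true in
expectation over datasets:

- On a very sparse trait the two-group model is genuinely more adaptive:
  whichever group happens to hold more causal SNPs inflates its slab
  variance and the weighted model predicts *better*. This is an adaptive
  property of the model, observable in the recorded σ²_b chains, not an
  implementation asymmetry.
- Even on a polygenic trait, any one simulated dataset leaves the two
  halves differing by chance in realized causal content, giving the
  two-group model a small data-conditional accuracy offset of either sign
  (a few hundredths either way in our simulations). Repeating the fit on
  that one dataset while varying only the MCMC seed shrinks the noise
  around this fixed offset, so a t-test across MCMC-seed repeats will
  eventually flag it no matter how correct the sampler is.

The reduction check therefore replicates over *fresh* polygenic datasets
(300 causal SNPs among ~1,000; each replicate re-simulates and fits both
models once): across replicates the offsets average out, the equality null
is actually true, and the two-sided t-test across replicates is the
meaningful "indistinguishable" statement. Any persistent one-sided
difference there would indicate a coding asymmetry between the two-group
and single-group paths.

## Evaluation

The train/test split is forward by harvest year (test = years ≥ cutoff),
mimicking prediction of new-season lines. Accuracy is the Pearson
correlation between GEBV and observed test phenotypes. The fit is repeated
(60 by default; tests use fewer) varying only the MCMC seed — the split is
fixed — so the comparison isolates sampler noise; the two models share
seeds per repeat. The default test is Welch's two-sided t on the two
accuracy vectors at α = 0.05; a paired t is available since repeats share
seeds. Identical accuracy vectors are reported as p = 1 (no difference)
rather than NaN.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, at
desk scale (defaults: a few hundred lines and genes, 1–2k SNPs; a real
panel's scale — thousands of lines, ~12k SNPs — is configuration):

- **Annotation** — non-overlapping genes laid left-to-right per
  chromosome, lengths 1–5 kb, gaps 0.5–10 kb: gaps short enough that the
  1 kb and 10 kb flank classes are all populated.
- **Genotypes** — per-SNP MAF uniform on (0.05, 0.5], Hardy–Weinberg
  class probabilities, codes −1/0/1. SNPs are placed inside gene bodies
  (Poisson, mean 2/gene) and in near-flank / mid-flank / intergenic
  positions. Optional missingness is masked and mean-imputed downstream.
- **Expression** — negative-binomial counts (var = μ + αμ²) around
  log2-space means composed of a gene baseline (log-normal-ish, spanning
  low to abundant genes), a per-module latent stage profile times a
  positive gene loading (this makes within-module correlation exceed
  between-module correlation, the property PCIT needs), per-sample module
  wobble (sd 0.3, which correlates replicates within a stage so module
  structure is estimable from few libraries), and planted ± log2FC step
  shifts at a random onset stage. Module genes always carry a planted
  shift — they model developmentally co-regulated genes — and extra genes
  are shifted to reach the requested DE fraction. Truth records the full
  expected log2 difference per stage pair for genes whose planted shift
  changes in that pair. Three stages × three replicates by default
  (7/16/25 days post-anthesis); an "averaged" layout collapses replicates
  into two pseudo-libraries per stage for sensitivity checks.
- **Phenotypes** — y = β₀ + Xβ + year + experiment + e with effects drawn
  N(0, 1) on the causal SNPs and rescaled so var(Xβ)/var(y) hits the
  requested h² in expectation (σ²_e = 1; year and experiment effects
  N(0, 1) and N(0, 0.5²) by default over 4 seasons × 3 batches). Each
  line gets one season, which drives the forward split.

Not emulated: allotetraploid homeolog structure, realistic linkage
disequilibrium decay, pedigree relatedness, genotype-by-environment
interaction, and read-level sequencing noise. Passing tests therefore
demonstrate the pipeline's internal correctness and the weighting
mechanism's behaviour when its assumptions hold — not performance on a
real breeding population, where LD between G and non-G SNPs will dilute
group contrasts.

## Problem sizes used by the checks

The repeated-fit checks run at desk scale: the neutral-weighting
comparison at n = 300 lines, ~1,000 SNPs, 10 seed repeats; the directional
check at n = 500 lines, ~2,000 SNPs, 30 causal SNPs all inside G, h² = 0.5,
20 seed repeats; both with the desk-scale MCMC schedule. These sizes give
the comparisons enough replication for the t-tests while keeping a full
run in minutes on one core.

## Known limitations

- The NB Wald test is anti-conservative for very low counts compared to
  exact or shrinkage-based tests; the stringent q < 0.001 threshold
  absorbs most of this in practice (null false-positive rate ≤ 0.5% is a
  tested bound).
- The PCIT scan's O(n³) cost makes whole-transcriptome networks
  impractical by design; restrict to DE genes.
- Single trait, single environment; no G×E terms.
- The VCF reader assumes biallelic records and rejects others.
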