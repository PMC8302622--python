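# Methods

## Design under analysis

Three cell lines — a parental wild-type population and two independent
single-gene knockout clones — each sequenced in 4 biological replicates,
with counts for ~25,000 genes. The quantity of interest is the set of genes
whose expression responds to loss of *either* knocked-out gene in the same
direction, on the hypothesis that the two genes act in one pathway. The
observed variance decomposes into genotype effects, clonal (line-to-line)
drift, and counting noise; the analysis is built to separate the first from
the other two.

## Normalization and differential expression

Size factors use the median-of-ratios rule restricted to zero-free genes:
`s_j = median_g (y_gj / geomean_k y_gk)`. There is no pseudo-reference
fallback — a matrix without any zero-free gene raises an error rather than
silently switching estimators.

Dispersion is estimated per gene by method of moments on normalized counts
(`alpha = max(0, (pooled within-group variance − mean) / mean²)`), a robust
trend `alpha(mu) = a0/mu + a1` is fitted across genes by soft-L1 least
squares with non-negativity bounds, and the working value is the geometric
mean of the raw estimate and the trend, floored at 1e-8. This 50/50 blend is
a deliberately simple stand-in for empirical-Bayes shrinkage: with 4
replicates the raw estimate is far too noisy to use alone, while the trend
alone would ignore genuine gene-specific overdispersion. Consequences: the
null type-I error rate at p < 0.05 sits near 0.06–0.07 (slightly
anticonservative, as expected for a Wald test without a degrees-of-freedom
correction at n = 4), and the DE flag — which also requires |LFC| >= 1 —
has a null rate around 5 x 10⁻⁴.

Each gene's test is a two-parameter NB GLM (intercept + genotype indicator,
log size-factor offset) fitted by iteratively reweighted least squares at
the fixed working dispersion, vectorized across genes (the 2x2 normal
equations are solved in closed form). Convergence tolerance 1e-8 on the
coefficients, cap 100 iterations; fits whose |log-fold-change coefficient|
exceeds 25 natural-log units (a group with essentially no counts) are
reported unconverged with missing p. Genes with mean normalized count below
1 are reported untested. The reported LFC is the unshrunken MLE because the
|LFC| >= 1 rule is applied to it directly. BH adjustment uses m = number of
tested genes; missing p-values pass through untouched.

Invariance properties worth knowing: inference is exactly invariant to a
global rescaling of the size factors (it only shifts the intercept), and
normalized values are invariant to scaling a sample's counts together with
its size factor. It is *not* invariant to rescaling one sample's raw counts
with size factors re-estimated — that genuinely changes the sample's weight
in the likelihood — though in practice the fold-change estimates move by
well under one standard error.

## Variable genes, PCA, and loading selection

The 10% most variable genes (floor rounding) enter a PCA of samples; genes
are then ranked by squared loading on the selection component and the top
20% (floor) are kept. Floor rounding is fixed by the reference pair of set
sizes the design reproduces (2,506 from 25,062; 501 from 2,506). Ties break lexicographically by
gene id so runs are reproducible.

Variance ranking scale: the standalone operation defaults to
log2(normalized + 1), but the pipeline ranks variance on a closed-form
variance-stabilizing transform (VST) derived from the fitted dispersion
trend: with `Var(mu) = (1 + a0) mu + a1 mu²`, integrating `1/sqrt(Var)`
gives `vst(x) = log2(2 sqrt(a1 (b x + a1 x²)) + 2 a1 x + b)`, `b = 1 + a0`,
which approaches `log2(x) + const` for large counts and equalizes technical
variance across genes. The distinction matters: on the plain log scale the
variance ranking is dominated by shot noise of 1–10-count genes, and the
genes carrying real genotype effects are displaced from the top-variance
list; on the VST scale every gene contributes about the same technical
variance, so ranking picks up excess (biological or genotype-driven)
variance. This is also the convention of the standard DE packages whose PCA
utilities run on variance-stabilized data.

The PCA is an SVD of the gene-centered sample × gene matrix, no per-gene
scaling. "Contribution" = squared loading (rank-equivalent to |loading|).
Each loading vector is oriented so its largest-magnitude entry is positive.
The selection component defaults to 2 — in this design the leading component
is typically the contrast between the two knockout clones (clonal drift),
while the second separates both knockouts from wild type — and an automatic
mode instead picks the component whose sample scores have maximal absolute
point-biserial correlation with the knockout-vs-wild-type indicator, which
makes the pipeline robust to component reordering.

## Concordance and the core set

Concordance requires passing both thresholds (FDR < 0.05, |LFC| >= 1) in
*both* contrasts with equal LFC sign; there is no pooled test, matching a
filter-then-intersect workflow. Genes untested or unconverged in either
contrast are excluded (conservative). The core set is the intersection of
the concordant set with the PCA selection, inheriting directions; an empty
core is allowed with a warning.

## Differential exon usage

For each exon, the focal count against the gene total is modelled as an
overdispersed binomial with a genotype term on the logit scale — the same
null hypothesis (genotype-dependent relative exon usage) as per-exon GLM
packages, in a self-contained quasi-likelihood form. Overdispersion is the
Pearson statistic over its degrees of freedom, floored at 1; the floor makes
the test mildly conservative (null rate ~0.035 at p < 0.05). Exons are
tested only when the gene has >= 2 exons, the exon's mean count is >= 5
across samples (stability filter), and gene totals are non-zero in >= 2
samples per group. Swapping which exon is "focal" only flips the sign of the
usage shift. Cross-genotype overlap takes exons significant (FDR < 0.05) in
both contrasts and reports the distinct-gene count.

## Replication and enrichment

Gene symbols are harmonized by uppercasing, after an optional user-supplied
ortholog/synonym map — cross-species comparisons mix mouse-cased and
human-cased symbols and no mapping procedure can be inferred from symbol
lists alone, so the rule is deliberately minimal and explicit.

Replication counts presence in any direction; direction agreement is a
separate classification (a gene replicated three times with conflicting
signs is "replicated" but "discordant"). The three classes partition the
core set by construction. ORA uses the hypergeometric upper tail through the
numerically stable survival function; the universe defaults to all genes
tested for DE and is configurable because the background choice materially
changes p-values. A transcription factor is "enriched" at FDR < 0.05 when
its target set is over-represented in the core set, and cascade edges join
enriched TFs to core-set targets with cluster labels taken from an input
table (network clustering itself is out of scope).

## The synthetic-data generator

Defaults emulate the study conditions: 3 genotypes × 4 replicates, 25,000
genes (tests use 2,000–10,000 for speed; the recovery suite uses 10,000),
log-normal baselines (natural-log mean 4.0, sd 1.5), NB counts with
dispersion trend `3/mu + 0.02`, size factors log-uniform on [0.7, 1.4], and
gene classes: concordant-up 0.15%, concordant-down 0.85% (concordant
responses in this design skew strongly down), discordant 0.5%, single-knockout 2%,
remainder null. Planted effects are ±2 log2 units and land on genes with
baseline >= 50 normalized counts (redrawn from the same log-normal):
detected DE genes are by construction expressed genes, and planting 2-log2
effects on ~1-count genes would turn "recovery" into a statement about
sequencing depth rather than about the pipeline.

Clonal drift is modelled as an independent per-gene N(0, clonal_sd) log2
offset of each *knockout clone* relative to the parental wild-type line —
the wild type is the parental population, the knockouts are single-cell
clones, so the drift is attributed to the derived lines. This choice also
makes the PCA structure stable: the between-line subspace is spanned by the
two (nearly orthogonal) drift vectors, whose antisymmetric combination
(clone 1 vs clone 2) carries more scatter than the symmetric one, so the
leading PC is an inter-clone contrast and the knockout-vs-wild-type signal
appears on a later component whenever drift dominates the planted effects.

The default clonal_sd is 0.25. Two regimes are genuinely in tension: a
drift scale large enough to dominate the genotype effect reproduces the
"PC1 = clonal variation" structure but, because drift offsets are fixed
per line, it also produces many spurious concordant |LFC| >= 1 calls that
no statistical test can reject (they are real, reproducible differences
between these particular clone pairs — exactly why single-clone designs are
confounded). The default therefore keeps drift at a level where concordance
filtering stays clean; the dominant-drift regime (clonal_sd = 2.0) is
exercised explicitly by the PCA-structure tests. This mirrors the
scientific situation: with only one clone per genotype, concordance across
two *independent* knockouts — not statistics within one clone — is the
protection against clonal artifacts.

Exon tables draw 2–12 exons per gene with Dirichlet(5) base proportions and
split each gene's per-sample totals multinomially, so exon counts conserve
gene totals exactly. Planted differential-usage genes (2%) get a +1.5 logit
shift on one exon in both knockout genotypes. External study lists include
each true-effect gene with a per-study sensitivity (default 0.7), flip its
direction with probability 0.05, and admit null genes at a false-hit rate
of 0.002.

What the generator does *not* emulate: GC/length biases, batch effects
beyond the single clonal offset, correlated gene modules, outlier samples,
annotation errors, or the heavy asymmetry in exon-usage counts seen between
real knockouts. Passing recovery tests therefore demonstrates correctness
of the statistical machinery under the stated model, not robustness to
every artifact of real libraries.

## Numerical choices and degenerate inputs

Gamma–Poisson sampling for NB counts (exact, vectorized, stable for tiny
dispersions). IRLS linear systems solved in closed form; degenerate
information matrices yield missing results rather than crashes. BH is a
single vectorized pass with NaN passthrough. Hypergeometric tails come from
the survival function evaluated in log space. PCA drops components with
singular values below 1e-12 of the largest; a constant matrix is an error.
All output tables are TSV with a provenance comment line (package version +
config hash), and a fixed seed makes the whole pipeline byte-reproducible.

## Known limitations

- The Wald test with moment/trend dispersions is slightly anticonservative
  at n = 4 (null p < 0.05 rate ~0.065); the two-threshold DE rule keeps the
  practical false-call rate very low, but single-gene p-values near 0.05
  should not be over-read.
- No shrunken LFC estimator, covariates, outlier refitting, or adaptive
  independent filtering.
- The uppercase-symbol harmonization cannot resolve genuine one-to-many
  orthology; supply an explicit map for anything beyond symbol-identical
  comparisons.
- The exon-usage test conditions on gene totals and ignores per-sample
  size factors (they cancel in proportions only approximately when totals
  vary strongly).
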