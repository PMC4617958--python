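# Methods

`riboreg` re-implements, as a tested pipeline over synthetic data with
known ground truth, an integrative analysis of inter-individual variation
in RNA expression, ribosome occupancy (RO), translation efficiency (TE)
and protein levels, including sequence-level tests for upstream open
reading frame (uORF) variants and Kozak-region variants. This note
documents the models, the generator, the numerical choices, and what the
passing tests do and do not establish.

## The synthetic study

The generator (`riboreg.synthetic_data`) emulates a multi-individual,
multi-replicate, multi-assay design: by default 30 individuals, 3 RNA-seq
and 2 ribosome-profiling libraries each, and 120 transcripts. Counts for
gene *g* in library *l* are negative binomial with mean
`lib_size_l x proportion of 2^eta_gl` and gene-specific dispersion
`phi_g ~ LogNormal(ln 0.05, 0.3)`, where

    eta_gl = mu_g + TE_g * [ribo] + b_assay(g, individual)
             + sum(planted effects x dosage)

with baselines `mu_g ~ N(5, 1.5)` (log2) and gene-level TE
`TE_g ~ N(0, 0.5)` plus a +0.5 log2 bonus when the base at Kozak
position -3 is A (the planted per-position initiation-context effect).
Library sizes are log-uniform over a 3x range so TMM normalization has
work to do; the per-library proportion normalization makes counts
compositional, as sequencing is.

**Variability classes.** Disjoint gene subsets carry per-individual
effects `b ~ N(0, 0.7)` (about twice the replicate-level log2 noise at
these depths): 20% in RNA only, 1% in RO only, and 6% in both assays.
Genes variable in both assays draw one shared effect, modelling
transcriptional variation that propagates to translation. The defaults
follow the composition reported for lymphoblastoid lines (~27% of genes
RNA-variable, ~7% RO-variable, under 1% RO-only). Additionally every gene
receives a small universal translational component
(`te_individual_sd_log2 = 0.15`, about half the replicate noise and far
below the variance test's detection threshold at 2-3 replicates). This
encodes the biological premise that translation rates differ somewhat
between individuals for essentially all genes; it is what makes ribosome
occupancy — not RNA — the proximal driver of protein levels, so the
RO-protein > RNA-protein correlation ordering is recoverable rather than
an artifact of replicate counts.

**Protein levels.** Per gene, protein is a gene-level component
(`mu_g + TE_g` plus N(0, 0.8) gene noise, standing in for degradation
and other post-translational variation) plus a monotone (rank) function
of the individual's true RO deviation, plus N(0, 0.3) noise. Protein is
deliberately generated from RO, never from RNA.

**Sequence construction.** 5'UTRs (60-180 nt) are assembled from a
background rejected against any ATG/CTG or stop trigram in any frame,
with designed elements inserted: uORFs (`ATG + A/C-only codons +
TAA/TAG`; TGA is never used because after an A/C codon it would embed a
spurious start one base upstream of the stop), latent uORFs for gain
variants (ACG start restored to ATG by the SNV), premature-stop sites
(a TCA body codon mutable to TAA), and merge architectures (two in-frame
uORFs whose first stop is ablated by one of two convergent SNVs, so the
carrier-pooling logic is exercised). The Kozak 8-mer (positions -6..-1,
+4, +5) is sampled with a 0.45 consensus bias (gccAcc...GC), so the PWM
built downstream recapitulates the consensus. Each construct is verified
with an internal trigram walk that is written independently of the
analysis scanner. Planted variants are drawn at MAF 0.2-0.4 under
Hardy-Weinberg with phased genotypes (so at least 3 of 30 individuals
carry them, matching the analysis' carrier threshold); neutral 3'UTR
variants use MAF 0.1-0.5 and are unphased with probability 0.08 to
exercise phase randomization. Planted effects default to +/-0.8 log2 per
uORF event copy (gain and premature-stop repress; loss and merge
increase, echoing the worked examples the design follows) and
+/-0.6 log2 per Kozak allele (65% weakening), acting on ribosome
occupancy only.

## Normalization and weights

Genes are kept when cpm > 1 in at least ceil(0.9 x n) libraries of each
assay — the proportional analogue of absolute thresholds that encode
~90% of libraries. TMM factors follow the published recipe exactly:
reference = library whose 75th-percentile count fraction is closest to
the mean; per-gene M and A values against the reference doubly trimmed
(30% / 5%); inverse asymptotic-binomial-variance weighted mean;
geometric mean rescaled to 1. The voom transform uses
`log2((count + 0.5) / (lib x factor + 1) x 1e6)`, residual sd from a
linear fit on (individual x assay) replicate-group indicators, a lowess
(span 0.5, 3 robustness iterations) of sqrt(sd) on average log2 count,
and weights = trend^-4 at each observation's fitted log2 count, clipped
below at 1e-4 and implicitly capped by a 1e-2 floor on the fitted
sqrt-sd (so zero-noise fixtures get large, equal weights). RNA and ribo
libraries are normalized jointly (one TMM pool) because TE contrasts
them; `per_assay=True` switches to separate pools.

## Translation efficiency

Per gene, weighted least squares of log2-cpm on individual cell means
plus per-individual ribo indicators; `TE_i` is individual *i*'s ribo
coefficient (a log2 ribo/RNA ratio), with equal weights reducing exactly
to the mean difference. The global TE is the precision-weighted mean of
the `TE_i`. A common-assay-effect parameterization (one ribo coefficient
over individual main effects) supplies the single TE per gene used by
the Kozak position tests, since those compare transcripts, not
individuals.

## Variance components and the exact LRT

Per gene and assay, `y_ij = mu + b_i + e_ij` with `b_i ~ N(0, s2_ind)`
and `e_ij ~ N(0, s2_res / w_ij)`; voom weights are treated as fixed known
precisions, and both models are fitted by maximum likelihood (not REML).
Because `s2_ind = 0` sits on the boundary, the LRT statistic has an atom
of ~1/2 at zero and chi-square p-values fail; p-values therefore come
from a parametric bootstrap: simulate from the fitted null with the same
design and weights, refit both models per replicate, and use the add-one
estimator `p = (1 + #{sim >= obs}) / (1 + n_sim)`, which cannot return
zero and returns exactly 1 at a zero statistic. The refits are
vectorized through the profile likelihood in `lambda = s2_ind / s2_res`:
after profiling out `mu` and `s2_res`, the likelihood depends on the
data only through per-group weighted sums, so thousands of bootstrap
replicates are evaluated on a shared lambda grid ({0} plus 80 log-spaced
points in [1e-4, 1e3]) at once. The same grid statistic is used for the
observed and simulated values, so the bootstrap compares like with like;
the reported variance estimates use a bounded scalar optimizer instead
(verified against a 4000-point grid to 1e-4). Holm correction is applied
separately per assay over the converged genes; the p-value floor
`1/(n_sim + 1)` must be below `alpha / n_genes` for Holm to be able to
reject, hence the pipeline default `n_sim = 5000` at ~120 genes (and
10,000 as the library default). Genes in class "both" are split into
comparable / RNA-dominant / RO-dominant subsets by a factor-2 ratio of
the two variance estimates — a labeled default, not an inferred rule.

## uORF analysis

uORFs start at any ATG or CTG strictly upstream of the annotated start
and run to the first in-frame TAA/TAG/TGA, which may lie inside the CDS
(`overlaps_cds` is retained; a config switch excludes such uORFs, and no
minimum length is imposed beyond start+stop). Per transcript, every
observed haplotype allele combination over 5'UTR variants is
materialized, scanned, and grouped by configuration signature, so
distinct variants producing the same architecture pool their carriers
into one event (the convergent-merge logic). Architecture changes are
classified on *maximal* uORFs — uORFs sharing a stop are collapsed to
the earliest start — which is what lets a stop-loss that runs one uORF
into the next register as a merge (net loss of one uORF) rather than an
extension plus an unrelated nested start. Events carried by fewer than
3 individuals are dropped, mirroring the carrier convention used for
Kozak variants. Association uses (1) precision-weighted linear
regression of per-library RO log2-cpm on event dosage and (2) a
conservative linear mixed model with an individual random intercept
(replicates as technical replicates), with BH FDR at 5% over events and
a translation-specificity flag (RNA p > 0.05 or opposite-signed RNA
coefficient).

## Kozak analysis

The Kozak region is the 6 nt before plus 2 nt after the start codon;
the start codon itself is excluded from the PWM and from variant scoring
(a start-ablating variant is an ORF disruption, not a context change).
PWM probabilities use pseudocount 0.5 per cell and log2 odds against a
uniform background — all config-exposed, since none of these constants
is canonical. Scores are sums of per-position log-odds, so a variant's
`delta_pwm` is the single changed position's log-odds difference and
negates exactly under allele swap. Variants are coded as
`delta_pwm x alt-allele copies`, summed over a transcript's Kozak
variants (additivity), tested against RO with the same two regressions
as uORFs but BH at 10% and a stricter RNA threshold (p > 0.01) for the
translation-specific flag. Per-position Kruskal-Wallis tests on the
global TE use Bonferroni x8; positions with one observed nucleotide get
p = NA but still count in the correction.

## Integration and enrichment

RO, RNA, TE and protein are each converted to empirical-CDF percentiles
across genes (ties share a value), and a 14x10 hexagonal online SOM
(sample-initialized codebook; Gaussian neighborhood with radius
annealed from half the grid diameter to 0.05 and learning rate 0.3 to
0.01 over 20 epochs; deterministic under seed) maps genes to 140 units.
The codebook is clustered by affinity propagation on negative squared
Euclidean similarities (median-similarity preference, damping 0.9,
convergence after 50 stable iterations), and each cluster is summarized
by its exemplar unit's rank profile and gene count. Note that the number
of AP clusters is non-decreasing in the preference parameter (preference
is the exemplar self-similarity). Per-gene Spearman correlations between
expression and protein across individuals (>= 8 paired individuals) get
BH FDR at 5% and are summarized by variability class. cis-QTLs use OLS
of replicate-averaged expression on 0/1/2 dosage at MAF > 10%, BH FDR
(level 30% for the RO phenotype, a labeled choice). Enrichment follows
the FuncAssociate logic: one-sided Fisher tests against an explicit
background, min-p permutation adjustment over random same-size queries
(add-one estimator, 1000 permutations), significance = odds ratio > 2
and adjusted p < 0.05, Haldane 0.5 correction for zero cells, terms with
< 3 background genes excluded, and a Cohen-kappa term graph with edges
above 0.1.

## Problem sizes and determinism

The default pipeline configuration (120 transcripts, 30 individuals,
5000 LRT bootstrap draws, 1000 enrichment permutations) runs end-to-end
in well under a minute on one CPU; the statistical test suite uses 1000
null genes at 2000 bootstrap draws for LRT calibration, 300 genes for
class recovery, and 40-50 simulation replicates for association
calibration and power. All randomness flows from one seed through
deterministic `SeedSequence` spawning, per stage; reruns are
byte-identical, which the run manifest (config hash, per-stage seeds,
output checksums) makes checkable.

## What the synthetic results do and do not show

Passing tests establish that the implementations are correct against
independent oracles (exhaustive uORF enumeration, literal TMM
transcription, closed-form TE and ANOVA solutions, exact hypergeometric
enumeration), that the tests are calibrated under their null models, and
that planted signals of realistic size are recovered at the study's
sample sizes. They do not reproduce the original study's real-data
values: those depend on the human annotation, measured genotypes, and
mass-spectrometry data. The generator omits, among other things:
alignment and mappability artifacts, GC/length biases, footprint
periodicity, isoform structure (one transcript per gene, identity
genome-to-transcript map), linkage disequilibrium between variants,
population structure, and indels/multi-allelic sites (SNVs only, by
design). Quantities like "percent of genes RNA-variable" therefore echo
the study's composition because the generator plants it, not because the
pipeline rediscovered human biology.
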