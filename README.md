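# riboreg

Inter-individual variation in gene expression is regulated at several
layers: RNA abundance, translation, and protein turnover. Joint
measurements of RNA-seq, ribosome profiling, and proteomics across a
panel of individuals make it possible to ask which genes vary between
people at each layer, whether ribosome occupancy (RO) predicts protein
levels better than RNA does, and which genetic variants act specifically
on translation — in particular variants that create, destroy, or reshape
upstream open reading frames (uORFs) in 5'UTRs, and variants that change
the Kozak context around the start codon.

`riboreg` implements that analysis as a reusable, tested pipeline and
exercises it end-to-end on a synthetic study generator with planted
ground truth, so every statistical claim the pipeline makes can be
checked against what was actually simulated. It is aimed at people
developing or evaluating translation-genomics analyses: each stage is a
plain library function, the pipeline is a set of TSV-in/TSV-out stages,
and the generator is first-class, configurable code.

## The statistics at the core

* **Normalization:** TMM scaling factors and the voom transform —
  `log2-cpm` with observation weights `w = trend(fitted log-count)^-4`
  from a lowess fit of `sqrt(residual sd)` on abundance, with replicate
  structure encoded in the residual design.
* **Translation efficiency:** per gene, weighted least squares
  `logcpm ~ individual + individual:ribo`; TE_i is individual *i*'s ribo
  coefficient, a log2 RO/RNA ratio.
* **Inter-individual variance:** `y_ij = mu + b_i + e_ij` with
  `b_i ~ N(0, sigma_b^2)`, `e_ij ~ N(0, sigma_e^2 / w_ij)`, ML fits, and
  an exact (parametric-bootstrap) likelihood-ratio test of
  `sigma_b^2 = 0` with Holm correction per assay — the boundary null
  puts ~half the LRT mass at 0, so chi-square approximations are
  avoided.
* **uORF events:** scan every haplotype 5'UTR for ORFs (ATG/CTG starts,
  UAA/UAG/UGA stops), classify reference-to-alternate architecture
  changes (gain, loss, premature stop, stop-loss extension, merge), pool
  carriers by configuration, and regress RO of the main coding region on
  event copy number (plus a conservative mixed model), BH FDR 5%, with a
  translation-specificity flag from the RNA phenotype.
* **Kozak variants:** a position weight matrix over positions -6..-1,
  +4, +5; per-position Kruskal-Wallis tests of TE (Bonferroni x8);
  variants coded by their PWM score change times allele count, tested
  against RO at BH FDR 10%.
* **Integration:** rank-percentile profiles of RO, RNA, TE and protein;
  a 14x10 hexagonal self-organizing map; affinity-propagation clustering
  of the codebook; per-gene expression-protein Spearman correlations
  stratified by variability class; cis-QTL mapping (additive dosage,
  MAF > 10%); permutation-corrected gene-set enrichment with a
  kappa-similarity term graph.

See `docs/methods.md` for the full model descriptions, defaults, and
limitations.

## Worked example

Run the whole pipeline on the default synthetic study (30 individuals,
120 transcripts, 150 libraries; a few seconds per stage):

```sh
riboreg run-all --outdir results/run --seed 1
```

or stage by stage through the numbered drivers:

```sh
cd analysis
python 01_simulate.py --seed 1 --outdir ../results/run
python 04_variance_components.py --seed 1 --outdir ../results/run
python 05_uorf_associations.py --seed 1 --outdir ../results/run
python 08_protein_correlation.py --seed 1 --outdir ../results/run
```

With seed 1 the drivers print:

```
27.5% of 120 genes vary between individuals in RNA expression; 12.5% in
ribosome occupancy (Holm < 0.05)

4 uORF events observed ({'gain': 1, 'loss': 1, 'premature_stop': 1,
'merge': 1})
4 events associated with ribosome occupancy at 5% FDR, 4
translation-specific (RNA p > 0.05 or opposite sign)
                    unit_id     event_type  beta_ribo       p_ribo
            t0000|51:60:ATG           gain  -0.846242 4.422996e-18
                 t0001|null           loss   0.825875 1.060620e-20
            t0002|89:95:ATG premature_stop  -0.604517 6.256168e-09
t0003|70:103:ATG;94:103:ATG          merge   0.868176 3.188532e-14

median rho(ribosome occupancy, protein) = 0.37; median rho(RNA, protein)
= -0.02 over 120 genes
```

Reading these numbers: the variance-component test recovers the planted
composition (about 27% of genes RNA-variable between individuals, far
fewer RO-variable); all four planted uORF architecture changes are
detected with the planted effect signs (an extra or prematurely
terminated uORF lowers ribosome occupancy of the main ORF, losing or
merging uORFs raises it) and are flagged translation-specific because
their RNA association is null; and protein levels track ribosome
occupancy much better than RNA, with the strongest RNA-protein coupling
confined to the genes that vary in both assays (`08`'s stratified
table).

Each stage writes plain TSVs plus a `manifest.json` with the config
hash, per-stage seeds, the analysis decisions in effect, and output
checksums; rerunning with the same config is byte-identical.

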