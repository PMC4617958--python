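"""cis-QTL mapping of ribosome occupancy and RNA expression on variant
dosage, and gene-set enrichment of the variable-gene classes with the
kappa-similarity term graph."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
for stage in ("simulate", "normalize", "varcomp"):
    pipeline.run_stage(stage, config, outdir)
pipeline.run_stage("qtl", config, outdir, force=force)
pipeline.run_stage("enrich", config, outdir, force=force)

for assay in ("ribo", "rna"):
    qtl = pd.read_csv(f"{outdir}/qtl_{assay}.tsv", sep="\t")
    n_sig = int(qtl["significant"].sum()) if len(qtl) else 0
    print(f"{assay}: {len(qtl)} gene-variant tests (MAF > 10%), "
          f"{n_sig} significant at 30% FDR")
enrich = pd.read_csv(f"{outdir}/enrichment.tsv", sep="\t", index_col=0)
sig = enrich[enrich["significant"]]
print(f"{len(sig)} of {len(enrich)} terms enriched "
      "(odds ratio > 2, permutation-adjusted p < 0.05):")
print(sig[["n_query", "term_size", "odds_ratio", "p_adjusted"]].to_string())
edges = pd.read_csv(f"{outdir}/term_graph.tsv", sep="\t")
print(f"{len(edges)} kappa-similarity edges (> 0.1) in the term graph")
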