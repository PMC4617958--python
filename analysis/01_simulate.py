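"""Generate the synthetic study: transcripts, phased genotypes,
RNA-seq and ribosome-profiling count libraries, and protein levels,
with planted uORF/Kozak/eQTL effects and variable-gene classes."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
pipeline.run_stage("simulate", config, outdir, force=force)

samples = pd.read_csv(f"{outdir}/samples.tsv", sep="\t")
counts = pd.read_csv(f"{outdir}/counts.tsv", sep="\t", index_col=0)
print(f"simulated {counts.shape[0]} transcripts x {counts.shape[1]} libraries "
      f"({samples['individual'].nunique()} individuals; "
      f"{(samples['assay'] == 'rna').sum()} RNA-seq, "
      f"{(samples['assay'] == 'ribo').sum()} ribosome-profiling)")
print(f"outputs in {outdir}/: transcripts.fasta, variants.vcf, counts.tsv, "
      "protein.tsv, ground_truth.json")
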