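"""Estimate per-individual and global translation efficiency (the
ribo-vs-RNA contrast from the weighted linear model)."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
for stage in ("simulate", "normalize"):
    pipeline.run_stage(stage, config, outdir)
pipeline.run_stage("te", config, outdir, force=force)

te = pd.read_csv(f"{outdir}/te_by_individual.tsv", sep="\t", index_col=0)
print(f"TE estimated for {te.shape[0]} genes x {te.shape[1]} individuals")
print(f"median per-gene TE spread (sd across individuals): "
      f"{te.std(axis=1).median():.3f} log2")
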