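"""Test every gene for inter-individual variance in RNA expression and
ribosome occupancy (exact bootstrap LRT, Holm correction) and classify
genes into variability classes."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
for stage in ("simulate", "normalize"):
    pipeline.run_stage(stage, config, outdir)
pipeline.run_stage("varcomp", config, outdir, force=force)

classes = pd.read_csv(f"{outdir}/variability_classes.tsv", sep="\t",
                      index_col=0)
n = len(classes)
pct_rna = 100 * (classes["p_holm_rna"] < 0.05).mean()
pct_ribo = 100 * (classes["p_holm_ribo"] < 0.05).mean()
print(f"{pct_rna:.1f}% of {n} genes vary between individuals in RNA "
      f"expression; {pct_ribo:.1f}% in ribosome occupancy (Holm < 0.05)")
print(classes["class"].value_counts().to_string())
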