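"""Integrate RO, RNA, TE and protein as rank percentiles, train the SOM,
and cluster its codebook with affinity propagation."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
for stage in ("simulate", "normalize", "te"):
    pipeline.run_stage(stage, config, outdir)
pipeline.run_stage("som", config, outdir, force=force)

clusters = pd.read_csv(f"{outdir}/som_clusters.tsv", sep="\t", index_col=0)
print(f"SOM ({config['som_grid'][0]}x{config['som_grid'][1]} units) grouped "
      f"into {len(clusters)} affinity-propagation clusters")
print("exemplar rank profiles (RO / RNA / TE / protein) and gene counts:")
print(clusters.round(2).to_string())
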