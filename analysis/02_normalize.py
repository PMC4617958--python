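"""Filter low-expression genes, compute TMM factors, and run the voom
transform to get log2-cpm with precision weights."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
pipeline.run_stage("simulate", config, outdir)
pipeline.run_stage("normalize", config, outdir, force=force)

logcpm = pd.read_csv(f"{outdir}/logcpm.tsv", sep="\t", index_col=0)
nf = pd.read_csv(f"{outdir}/norm_factors.tsv", sep="\t", index_col=0).iloc[:, 0]
print(f"{logcpm.shape[0]} genes pass the cpm filter across "
      f"{logcpm.shape[1]} libraries")
print(f"TMM factors span {nf.min():.3f}..{nf.max():.3f} "
      f"(geometric mean {nf.prod() ** (1 / len(nf)):.6f})")
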