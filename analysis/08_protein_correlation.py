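"""Per-gene Spearman correlation between expression and protein levels
across individuals, stratified by variability class."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
for stage in ("simulate", "normalize", "varcomp"):
    pipeline.run_stage(stage, config, outdir)
pipeline.run_stage("protcor", config, outdir, force=force)

corr = pd.read_csv(f"{outdir}/protein_correlation.tsv", sep="\t", index_col=0)
print(f"median rho(ribosome occupancy, protein) = "
      f"{corr['rho_ribo'].median():.2f}; "
      f"median rho(RNA, protein) = {corr['rho_rna'].median():.2f} "
      f"over {len(corr)} genes")
strata = pd.read_csv(f"{outdir}/correlation_strata.tsv", sep="\t", index_col=0)
print("RNA-protein correlation by variability class:")
print(strata.round(3).to_string())
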