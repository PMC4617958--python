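"""Scan haplotype 5'UTRs for uORF architecture changes and test event
copy number against ribosome occupancy of the main coding region."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
for stage in ("simulate", "normalize"):
    pipeline.run_stage(stage, config, outdir)
pipeline.run_stage("uorf", config, outdir, force=force)

events = pd.read_csv(f"{outdir}/uorf_events.tsv", sep="\t")
assoc = pd.read_csv(f"{outdir}/uorf_associations.tsv", sep="\t")
print(f"{len(events)} uORF events observed "
      f"({events['event_type'].value_counts().to_dict()})")
sig = assoc[assoc["significant"]]
print(f"{len(sig)} events associated with ribosome occupancy at 5% FDR, "
      f"{int(sig['translation_specific'].sum())} translation-specific "
      "(RNA p > 0.05 or opposite sign)")
if len(sig):
    print(sig[["unit_id", "event_type", "beta_ribo", "p_ribo",
               "p_lmm_ribo"]].to_string(index=False))
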