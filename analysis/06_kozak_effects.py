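"""Build the Kozak PWM, test per-position nucleotide effects on
translation efficiency, score Kozak variants by PWM change, and test
their association with ribosome occupancy."""

import pandas as pd

from _util import stage_args
from riboreg import pipeline

config, outdir, force = stage_args(__doc__)
for stage in ("simulate", "normalize", "te"):
    pipeline.run_stage(stage, config, outdir)
pipeline.run_stage("kozak", config, outdir, force=force)

positions = pd.read_csv(f"{outdir}/kozak_positions.tsv", sep="\t", index_col=0)
best = positions["p_value"].idxmin()
print("Kruskal-Wallis TE effect by Kozak position (Bonferroni x8):")
print(positions.to_string())
print(f"strongest position: {best}")
scores = pd.read_csv(f"{outdir}/kozak_variant_scores.tsv", sep="\t")
frac_weak = 100 * (scores["delta_pwm"] < 0).mean()
print(f"{len(scores)} Kozak variants scored; {frac_weak:.0f}% weaken the "
      "reference context")
assoc = pd.read_csv(f"{outdir}/kozak_associations.tsv", sep="\t")
sig = assoc[assoc["significant"] & assoc["translation_specific"]]
print(f"{len(sig)} transcripts with translation-specific Kozak-variant "
      "effects at 10% FDR")
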