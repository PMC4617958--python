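"""Shared argument handling for the numbered analysis drivers."""

import argparse

from riboreg import pipeline


def stage_args(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/run")
    ap.add_argument("--force", action="store_true")
    args = ap.parse_args()
    config = pipeline.default_config(seed=args.seed)
    return config, args.outdir, args.force
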