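"""End-to-end orchestration: simulate -> normalize -> te -> varcomp ->
uorf -> kozak -> som/protcor -> qtl -> enrich.

Stages communicate through plain TSV/JSON files in one output directory
and are individually skippable: a stage reruns only if any of its output
files is missing (or ``force``).  ``run_all`` records a manifest with the
config hash, per-stage seeds, the labeled analysis decisions in effect,
and a checksum of every file it read or wrote, so a rerun from the same
manifest reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import (
    association_enrichment,
    integrative_som,
    kozak_analysis,
    normalization,
    sequence_model,
    synthetic_data,
    translation_efficiency,
    uorf_analysis,
    variance_decomposition,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


def default_config(seed: int = 0) -> dict:
    cfg = dataclasses.asdict(synthetic_data.SimulationConfig(seed=seed))
    cfg.update({
        "varcomp_nsim": 5000,
        "varcomp_alpha": 0.05,
        "uorf_min_carriers": 3,
        "uorf_fdr": 0.05,
        "kozak_min_carriers": 3,
        "kozak_fdr": 0.10,
        "kozak_pseudocount": 0.5,
        "som_grid": [14, 10],
        "som_epochs": 20,
        "qtl_maf_min": 0.10,
        "enrich_n_perm": 1000,
    })
    return cfg


def _sim_config(config: dict) -> synthetic_data.SimulationConfig:
    fields = {f.name for f in dataclasses.fields(synthetic_data.SimulationConfig)}
    kwargs = {k: v for k, v in config.items() if k in fields}
    for key in ("utr5_length_range", "cds_codons_range", "maf_range",
                "planted_maf_range", "library_size_range",
                "planted_uorf_event_types"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return synthetic_data.SimulationConfig(**kwargs)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _outputs_exist(outdir: str, names: List[str]) -> bool:
    return all(os.path.exists(os.path.join(outdir, n)) for n in names)


def _write(df: pd.DataFrame, outdir: str, name: str) -> None:
    df.to_csv(os.path.join(outdir, name), sep="\t", float_format=FLOAT_FMT)


def _load_study(outdir: str):
    transcripts = sequence_model.load_transcripts(
        os.path.join(outdir, "transcripts.fasta"),
        os.path.join(outdir, "annotation.tsv"))
    variants, hsets, counters = sequence_model.map_vcf_to_transcripts(
        os.path.join(outdir, "variants.vcf"), transcripts)
    return transcripts, variants, hsets


def _load_expr(outdir: str) -> normalization.ExpressionSet:
    expr = normalization.load_expression(os.path.join(outdir, "counts.tsv"),
                                         os.path.join(outdir, "samples.tsv"))
    lg = os.path.join(outdir, "logcpm.tsv")
    if os.path.exists(lg):
        expr2 = normalization.ExpressionSet(
            counts=pd.read_csv(lg, sep="\t", index_col=0),
            samples=expr.samples.loc[
                pd.read_csv(lg, sep="\t", index_col=0, nrows=0).columns],
        )
        expr2.logcpm = expr2.counts
        expr2.counts = expr.counts.loc[expr2.logcpm.index, expr2.logcpm.columns]
        expr2.weights = pd.read_csv(os.path.join(outdir, "weights.tsv"),
                                    sep="\t", index_col=0)
        expr2.norm_factors = pd.read_csv(
            os.path.join(outdir, "norm_factors.tsv"), sep="\t", index_col=0
        ).iloc[:, 0]
        return expr2
    return expr


STAGES = ["simulate", "normalize", "te", "varcomp", "uorf", "kozak", "som",
          "protcor", "qtl", "enrich"]

_STAGE_OUTPUTS = {
    "simulate": ["transcripts.fasta", "annotation.tsv", "variants.vcf",
                 "counts.tsv", "samples.tsv", "protein.tsv",
                 "ground_truth.json", "terms.tsv"],
    "normalize": ["logcpm.tsv", "weights.tsv", "norm_factors.tsv"],
    "te": ["te_by_individual.tsv", "te_global.tsv"],
    "varcomp": ["varcomp_rna.tsv", "varcomp_ribo.tsv", "variability_classes.tsv"],
    "uorf": ["uorf_events.tsv", "uorf_associations.tsv"],
    "kozak": ["kozak_pwm.tsv", "kozak_positions.tsv",
              "kozak_variant_scores.tsv", "kozak_associations.tsv"],
    "som": ["rank_profiles.tsv", "som_codebook.tsv", "som_units.tsv",
            "som_clusters.tsv"],
    "protcor": ["protein_correlation.tsv", "correlation_strata.tsv"],
    "qtl": ["qtl_ribo.tsv", "qtl_rna.tsv"],
    "enrich": ["enrichment.tsv", "term_graph.tsv"],
}


def run_stage(stage: str, config: dict, outdir: str, force: bool = False) -> None:
    """Run one pipeline stage (skipped when its outputs already exist)."""
    os.makedirs(outdir, exist_ok=True)
    if not force and _outputs_exist(outdir, _STAGE_OUTPUTS[stage]):
        logger.info("stage %s: outputs present, skipping", stage)
        return
    t0 = time.time()
    globals()[f"_stage_{stage}"](config, outdir)
    logger.info("stage %s done in %.1fs", stage, time.time() - t0)


def _stage_simulate(config: dict, outdir: str) -> None:
    sim_cfg = _sim_config(config)
    study = synthetic_data.simulate_study(sim_cfg, outdir=outdir)
    terms = simulate_term_map(study["truth"].gene_flags, seed=sim_cfg.seed)
    rows = [(t, g) for t, genes in terms.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(
        os.path.join(outdir, "terms.tsv"), sep="\t", index=False)


def simulate_term_map(gene_flags: pd.DataFrame, seed: int,
                      n_random_terms: int = 25) -> Dict[str, set]:
    """Synthetic functional-term map: random terms plus two terms enriched
    in the variable-gene strata, so the enrichment stage has signal."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(9)[-1])
    genes = list(gene_flags.index)
    terms: Dict[str, set] = {}
    for k in range(n_random_terms):
        size = int(rng.integers(8, 30))
        terms[f"TERM{k:03d}"] = set(rng.choice(genes, size=size, replace=False))
    both = [g for g in genes
            if gene_flags.loc[g, "rna_variable"] and gene_flags.loc[g, "ro_variable"]]
    rna_var = [g for g in genes if gene_flags.loc[g, "rna_variable"]]
    for name, pool in (("TERM_VARBOTH", both), ("TERM_VARRNA", rna_var)):
        if len(pool) >= 3:
            core = list(rng.choice(pool, size=max(3, int(0.7 * len(pool))),
                                   replace=False))
            pad = list(rng.choice(genes, size=max(2, len(core) // 3),
                                  replace=False))
            terms[name] = set(core) | set(pad)
    return terms


def _stage_normalize(config: dict, outdir: str) -> None:
    expr = normalization.load_expression(os.path.join(outdir, "counts.tsv"),
                                         os.path.join(outdir, "samples.tsv"))
    expr = normalization.cpm_filter(expr)
    expr.norm_factors = normalization.tmm_factors(expr)
    expr = normalization.voom_transform(expr)
    _write(expr.logcpm, outdir, "logcpm.tsv")
    _write(expr.weights, outdir, "weights.tsv")
    _write(expr.norm_factors.to_frame(), outdir, "norm_factors.tsv")


def _stage_te(config: dict, outdir: str) -> None:
    expr = _load_expr(outdir)
    results = translation_efficiency.estimate_te(expr)
    _write(translation_efficiency.te_matrix(results), outdir, "te_by_individual.tsv")
    te_common = translation_efficiency.estimate_te_common(expr)
    te_global = translation_efficiency.te_global_series(results)
    _write(pd.DataFrame({"te_global": te_global, "te_common": te_common}),
           outdir, "te_global.tsv")


def _stage_varcomp(config: dict, outdir: str) -> None:
    expr = _load_expr(outdir)
    nsim = int(config.get("varcomp_nsim", 1000))
    seed = int(config["seed"])
    res_rna = variance_decomposition.varcomp_scan(expr, "rna", n_sim=nsim,
                                                  seed=seed + 1)
    res_ribo = variance_decomposition.varcomp_scan(expr, "ribo", n_sim=nsim,
                                                   seed=seed + 2)
    classes = variance_decomposition.classify_variability(
        res_rna, res_ribo, alpha=float(config.get("varcomp_alpha", 0.05)))
    _write(res_rna, outdir, "varcomp_rna.tsv")
    _write(res_ribo, outdir, "varcomp_ribo.tsv")
    _write(classes, outdir, "variability_classes.tsv")


def _stage_uorf(config: dict, outdir: str) -> None:
    transcripts, variants, hsets = _load_study(outdir)
    sequence_model.resolve_phase(hsets, seed=int(config["seed"]) + 3)
    expr = _load_expr(outdir)
    events = uorf_analysis.enumerate_events(
        transcripts, variants, hsets,
        min_carriers=int(config.get("uorf_min_carriers", 3)))
    ev_rows = [{
        "event_id": e.event_id, "transcript_id": e.transcript_id,
        "gene_id": e.gene_id, "event_type": e.event_type,
        "defining_variants": ",".join(e.defining_variants),
        "n_carriers": e.n_carriers(),
        **{f"dosage_{i}": d for i, d in sorted(e.dosage.items())},
    } for e in events]
    pd.DataFrame(ev_rows).to_csv(os.path.join(outdir, "uorf_events.tsv"),
                                 sep="\t", index=False)
    assoc = uorf_analysis.test_uorf_association(
        events, expr, fdr_level=float(config.get("uorf_fdr", 0.05)))
    assoc.to_csv(os.path.join(outdir, "uorf_associations.tsv"), sep="\t",
                 index=False, float_format=FLOAT_FMT)


def _stage_kozak(config: dict, outdir: str) -> None:
    transcripts, variants, hsets = _load_study(outdir)
    sequence_model.resolve_phase(hsets, seed=int(config["seed"]) + 4)
    expr = _load_expr(outdir)
    by_id = {t.transcript_id: t for t in transcripts}
    pwm = kozak_analysis.build_pwm(
        transcripts, pseudocount=float(config.get("kozak_pseudocount", 0.5)))
    pwm_out = pd.concat({"count": pwm.counts, "prob": pwm.probs,
                         "log_odds": pwm.log_odds}, axis=1)
    _write(pwm_out, outdir, "kozak_pwm.tsv")

    te = pd.read_csv(os.path.join(outdir, "te_global.tsv"), sep="\t",
                     index_col=0)["te_common"]
    _write(kozak_analysis.test_position_effects(transcripts, te),
           outdir, "kozak_positions.tsv")

    kz_vars = kozak_analysis.kozak_variants(variants, by_id)
    scores, predictors = kozak_analysis.score_kozak_variants(
        kz_vars, pwm, by_id, hsets,
        min_carriers=int(config.get("kozak_min_carriers", 3)))
    pd.DataFrame([dataclasses.asdict(s) for s in scores]).to_csv(
        os.path.join(outdir, "kozak_variant_scores.tsv"), sep="\t",
        index=False, float_format=FLOAT_FMT)
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    assoc = kozak_analysis.test_kozak_association(
        predictors, expr, gene_of,
        fdr_level=float(config.get("kozak_fdr", 0.10)))
    assoc.to_csv(os.path.join(outdir, "kozak_associations.tsv"), sep="\t",
                 index=False, float_format=FLOAT_FMT)


def _mean_by_individual(expr, assay: str) -> pd.DataFrame:
    libs = expr.libraries(assay)
    inds = expr.samples.loc[libs, "individual"]
    return expr.logcpm[libs].T.groupby(inds.values).mean().T


def _stage_som(config: dict, outdir: str) -> None:
    expr = _load_expr(outdir)
    protein = pd.read_csv(os.path.join(outdir, "protein.tsv"), sep="\t",
                          index_col=0)
    te = pd.read_csv(os.path.join(outdir, "te_global.tsv"), sep="\t",
                     index_col=0)["te_global"]
    measures = {
        "ribosome_occupancy": expr.logcpm[expr.libraries("ribo")].mean(axis=1),
        "rna_expression": expr.logcpm[expr.libraries("rna")].mean(axis=1),
        "translation_efficiency": te,
        "protein_level": protein.mean(axis=1),
    }
    profiles = integrative_som.rank_transform(measures)
    _write(profiles, outdir, "rank_profiles.tsv")
    grid = tuple(config.get("som_grid", (14, 10)))
    som = integrative_som.train_som(profiles, grid_shape=grid,
                                    epochs=int(config.get("som_epochs", 20)),
                                    seed=int(config["seed"]) + 5)
    _write(pd.DataFrame(som.codebook, columns=som.feature_names), outdir,
           "som_codebook.tsv")
    summary = integrative_som.cluster_codebook(som)
    units = pd.DataFrame({"unit": som.unit_of_gene,
                          "cluster": som.cluster_of_unit[som.unit_of_gene]})
    _write(units, outdir, "som_units.tsv")
    _write(summary, outdir, "som_clusters.tsv")


def _stage_protcor(config: dict, outdir: str) -> None:
    expr = _load_expr(outdir)
    protein = pd.read_csv(os.path.join(outdir, "protein.tsv"), sep="\t",
                          index_col=0)
    classes = pd.read_csv(os.path.join(outdir, "variability_classes.tsv"),
                          sep="\t", index_col=0)["class"]
    rna_by_ind = _mean_by_individual(expr, "rna")
    ro_by_ind = _mean_by_individual(expr, "ribo")
    corr_rna = integrative_som.gene_protein_correlation(rna_by_ind, protein)
    corr_ro = integrative_som.gene_protein_correlation(ro_by_ind, protein)
    both = corr_rna.join(corr_ro, lsuffix="_rna", rsuffix="_ribo")
    _write(both, outdir, "protein_correlation.tsv")
    strata = integrative_som.summarize_by_stratum(corr_rna, classes)
    _write(strata, outdir, "correlation_strata.tsv")


def _stage_qtl(config: dict, outdir: str) -> None:
    transcripts, variants, hsets = _load_study(outdir)
    expr = _load_expr(outdir)
    individuals = sorted(hsets)
    geno = pd.DataFrame(
        {ind: [hsets[ind].dosage(v.variant_id) for v in variants]
         for ind in individuals},
        index=[v.variant_id for v in variants])
    gene_of_variant = {}
    gene_of = {t.transcript_id: t.gene_id for t in transcripts}
    for v in variants:
        gene_of_variant[v.variant_id] = gene_of.get(v.transcript_id)
    maf_min = float(config.get("qtl_maf_min", 0.10))
    for assay in ("ribo", "rna"):
        expr_avg = _mean_by_individual(expr, assay)
        qtl = association_enrichment.cis_qtl(expr_avg, geno, gene_of_variant,
                                             maf_min=maf_min, phenotype=assay)
        qtl.to_csv(os.path.join(outdir, f"qtl_{assay}.tsv"), sep="\t",
                   index=False, float_format=FLOAT_FMT)


def _stage_enrich(config: dict, outdir: str) -> None:
    classes = pd.read_csv(os.path.join(outdir, "variability_classes.tsv"),
                          sep="\t", index_col=0)["class"]
    term_df = pd.read_csv(os.path.join(outdir, "terms.tsv"), sep="\t")
    term_to_genes = {t: set(sub["gene_id"]) for t, sub in
                     term_df.groupby("term_id")}
    background = list(classes.index)
    query = list(classes.index[classes == "both"])
    if len(query) < 3:
        query = list(classes.index[classes != "none"])
    results, edges = association_enrichment.go_enrichment(
        query, background, term_to_genes,
        n_perm=int(config.get("enrich_n_perm", 1000)),
        seed=int(config["seed"]) + 6)
    _write(results, outdir, "enrichment.tsv")
    edges.to_csv(os.path.join(outdir, "term_graph.tsv"), sep="\t", index=False,
                 float_format=FLOAT_FMT)


def run_all(config: dict, outdir: str, force: bool = False) -> dict:
    """Run every stage and write the run manifest; returns the manifest."""
    os.makedirs(outdir, exist_ok=True)
    for stage in STAGES:
        run_stage(stage, config, outdir, force=force)
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    manifest = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "config": config,
        "seeds": {stage: int(config["seed"]) + k
                  for k, stage in enumerate(STAGES)},
        "decisions": {
            "tmm_trim": [0.30, 0.05],
            "voom": {"prior_count": 0.5, "lib_offset": 1, "lowess_span": 0.5,
                     "weight_floor": 1e-4},
            "uorf_min_carriers": config.get("uorf_min_carriers", 3),
            "kozak": {"pseudocount": config.get("kozak_pseudocount", 0.5),
                      "log_base": 2, "background": "uniform",
                      "fdr": config.get("kozak_fdr", 0.10)},
            "som_grid": list(config.get("som_grid", (14, 10))),
            "ap": {"damping": 0.9, "preference": "median"},
            "qtl_fdr_method": "bh",
        },
        "checksums": {
            name: _sha256(os.path.join(outdir, name))
            for outputs in _STAGE_OUTPUTS.values() for name in outputs
            if os.path.exists(os.path.join(outdir, name))
        },
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
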