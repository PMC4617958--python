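"""Synthetic multi-individual, multi-replicate, multi-assay study generator.

Emulates the design of a ribosome-profiling + RNA-seq + proteomics study
of lymphoblastoid lines from ~30 individuals: phased diploid genotypes
over transcript-resident SNVs, negative-binomial sequencing counts with
gene-specific dispersion and replicate structure, and per-individual
relative protein levels driven by ribosome occupancy.  Every planted
signal is recorded in a GroundTruth object so downstream stages can be
scored for recovery:

* a subset of genes with inter-individual variance in RNA expression,
  ribosome occupancy, or both (genes variable in both assays share one
  individual effect, encoding transcriptional variation that propagates
  to translation);
* uORF-modifying variants (start gain, start loss, premature stop, and
  the two-uORFs-merge architecture) acting on ribosome occupancy only;
* Kozak-region variants, mostly PWM-weakening, acting on ribosome
  occupancy only;
* cis variants acting on both assays (eQTL-like).

5'UTR sequences are built from a background free of AUG/CUG starts and
of stop trigrams, with designed elements inserted, so the reference uORF
architecture of every transcript is known by construction.  The
generator verifies each construct with its own trigram walk, independent
of the analysis scanner.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .normalization import ExpressionSet
from .sequence_model import (
    HaplotypeVariantSet,
    TranscriptModel,
    TranscriptVariant,
)

logger = logging.getLogger(__name__)

_FORBIDDEN = {"ATG", "CTG", "TAA", "TAG", "TGA"}
_BASES = ("A", "C", "G", "T")
# codons over {A, C} only: can never form a start or stop trigram, even
# across codon junctions
_SAFE_CODONS = ("AAA", "AAC", "ACA", "ACC", "CAA", "CAC", "CCA", "CCC")
_NONSTOP_CODONS = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_KOZAK_CONSENSUS = {-6: "G", -5: "C", -4: "C", -3: "A", -2: "C", -1: "C",
                    4: "G", 5: "C"}
_KOZAK_CONSENSUS_PROB = 0.45

UORF_EVENT_TYPES = ("gain", "loss", "premature_stop", "merge")


@dataclass
class SimulationConfig:
    """Study-design parameters; the defaults define the emulated study."""

    seed: int
    n_individuals: int = 30
    n_transcripts: int = 120
    replicates_rna: int = 3
    replicates_ribo: int = 2
    utr5_length_range: Tuple[int, int] = (60, 180)
    utr3_length: int = 30
    cds_codons_range: Tuple[int, int] = (40, 90)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    te_log2_sd: float = 0.5
    kozak_minus3_te_shift: float = 0.5  # TE bonus for A at -3
    # small universal per-individual translational component, well below
    # the variance test's detection threshold at this replicate depth;
    # makes ribosome occupancy (not RNA) the proximal driver of protein
    te_individual_sd_log2: float = 0.15
    nb_dispersion_mean: float = 0.05
    nb_dispersion_log_sd: float = 0.3
    # disjoint class fractions; the defaults echo the studied design
    # (~27% of genes RNA-variable overall, ~7% RO-variable, ~0.7% RO-only)
    frac_genes_rna_variable: float = 0.20
    frac_genes_ro_variable: float = 0.01
    frac_genes_both_variable: float = 0.06
    individual_sd_log2: float = 0.7
    planted_uorf_event_types: Tuple[str, ...] = UORF_EVENT_TYPES
    uorf_effect_log2: float = 0.8
    merge_convergent_variants: bool = True
    n_kozak_variants: int = 3
    frac_kozak_weakening: float = 0.65
    kozak_effect_log2: float = 0.6
    variant_effects_hit_rna: bool = False
    n_eqtl: int = 2
    eqtl_effect_log2: float = 0.8
    maf_range: Tuple[float, float] = (0.10, 0.50)
    planted_maf_range: Tuple[float, float] = (0.20, 0.40)
    neutral_utr3_variant_rate: float = 0.7
    frac_unphased: float = 0.08
    library_size_range: Tuple[float, float] = (2e5, 6e5)
    protein_rank_scale: float = 1.0
    protein_gene_noise_sd: float = 0.8
    protein_noise_sd: float = 0.3
    min_planted_carriers: int = 3

    def validate(self) -> None:
        for name in ("frac_genes_rna_variable", "frac_genes_ro_variable",
                     "frac_genes_both_variable", "frac_kozak_weakening",
                     "frac_unphased"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for lo, hi in (self.maf_range, self.planted_maf_range):
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError("MAF ranges must lie in (0, 0.5]")
        n_planted = (len(self.planted_uorf_event_types) + self.n_kozak_variants
                     + self.n_eqtl)
        if n_planted > self.n_transcripts:
            raise ValueError(
                f"{n_planted} planted effects exceed {self.n_transcripts} transcripts"
            )


@dataclass
class GroundTruth:
    """Everything planted, resolvable against the emitted files."""

    gene_flags: pd.DataFrame                  # rna_variable / ro_variable
    individual_effects_rna: pd.DataFrame      # genes x individuals, log2
    individual_effects_ribo: pd.DataFrame
    planted_uorf: List[dict]
    planted_kozak: List[dict]
    planted_eqtl: List[dict]
    true_te: pd.DataFrame                     # genes x individuals, log2
    mu_log2: pd.Series
    te_log2: pd.Series
    dispersion: pd.Series

    def to_json(self, path: str) -> None:
        payload = {
            "gene_flags": self.gene_flags.to_dict(orient="index"),
            "individual_effects_rna": self.individual_effects_rna.to_dict(orient="index"),
            "individual_effects_ribo": self.individual_effects_ribo.to_dict(orient="index"),
            "planted_uorf": self.planted_uorf,
            "planted_kozak": self.planted_kozak,
            "planted_eqtl": self.planted_eqtl,
            "true_te": self.true_te.to_dict(orient="index"),
            "mu_log2": self.mu_log2.to_dict(),
            "te_log2": self.te_log2.to_dict(),
            "dispersion": self.dispersion.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# sequence construction


def _background(rng: np.random.Generator, length: int, left: str = "") -> str:
    """Random sequence with no start (ATG/CTG) or stop trigram anywhere,
    including across the junction with ``left``."""
    out: List[str] = []
    context = left[-2:]
    for _ in range(length):
        choices = [b for b in _BASES if (context + b)[-3:] not in _FORBIDDEN]
        out.append(choices[rng.integers(len(choices))])
        context = (context + out[-1])[-2:]
    return "".join(out)


def _safe_body(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(_SAFE_CODONS[i] for i in rng.integers(len(_SAFE_CODONS),
                                                         size=n_codons))


@dataclass
class _PlannedVariant:
    offset: int          # within the element
    ref: str
    alt: str


@dataclass
class _Element:
    """A designed 5'UTR segment with its uORFs and mutable sites."""

    seq: str
    ref_uorfs: List[Tuple[int, int]] = field(default_factory=list)  # (start, stop)
    variants: List[_PlannedVariant] = field(default_factory=list)
    alt_uorfs: Optional[List[Tuple[int, int]]] = None  # after applying variants


def _element_uorf(rng, n_body: int, stop: str = "TAA") -> _Element:
    # TGA is never used after an A/C body: "...A|TGA" would embed an ATG
    seq = "ATG" + _safe_body(rng, n_body) + stop
    return _Element(seq, ref_uorfs=[(0, 3 + 3 * n_body)])


def _element_gain(rng, n_body: int) -> _Element:
    # latent uORF: broken start ACG; the SNV restores ATG
    seq = "ACG" + _safe_body(rng, n_body) + "TAA"
    stop = 3 + 3 * n_body
    return _Element(seq, ref_uorfs=[],
                    variants=[_PlannedVariant(1, "C", "T")],
                    alt_uorfs=[(0, stop)])


def _element_loss(rng, n_body: int) -> _Element:
    e = _element_uorf(rng, n_body)
    e.variants = [_PlannedVariant(1, "T", "C")]  # ATG -> ACG
    e.alt_uorfs = []
    return e


def _element_premature(rng, n_body: int, stop_at_codon: int) -> _Element:
    body = list(_safe_body(rng, n_body))
    body[3 * stop_at_codon : 3 * stop_at_codon + 3] = "TCA"
    seq = "ATG" + "".join(body) + "TAA"
    full_stop = 3 + 3 * n_body
    new_stop = 3 + 3 * stop_at_codon
    return _Element(seq, ref_uorfs=[(0, full_stop)],
                    variants=[_PlannedVariant(new_stop + 1, "C", "A")],  # TCA->TAA
                    alt_uorfs=[(0, new_stop)])


def _element_merge(rng, n_body1: int, gap_codons: int, n_body2: int,
                   convergent: bool) -> _Element:
    u1 = "ATG" + _safe_body(rng, n_body1) + "TAA"
    gap = _background(rng, 3 * gap_codons, left=u1)
    u2 = "ATG" + _safe_body(rng, n_body2) + "TAA"
    # re-draw the gap if its junction with u2 forms a start/stop trigram
    for _ in range(20):
        tail = (u1 + gap + u2)
        if not any(tail[i:i+3] in _FORBIDDEN
                   for i in range(len(u1) + len(gap) - 2, len(u1) + len(gap) + 2)):
            break
        gap = _background(rng, 3 * gap_codons, left=u1)
    seq = u1 + gap + u2
    s1_stop = 3 + 3 * n_body1
    u2_start = len(u1) + len(gap)
    u2_stop = u2_start + 3 + 3 * n_body2
    variants = [_PlannedVariant(s1_stop, "T", "C")]           # TAA -> CAA
    if convergent:
        variants.append(_PlannedVariant(s1_stop + 1, "A", "C"))  # TAA -> TCA
    return _Element(
        seq,
        ref_uorfs=[(0, s1_stop), (u2_start, u2_stop)],
        variants=variants,
        alt_uorfs=[(0, u2_stop), (u2_start, u2_stop)],
    )


def _architecture(seq: str, cds_start: int) -> List[Tuple[int, int]]:
    """Independent trigram walk used to verify constructs (start, stop)."""
    found = []
    for p in range(cds_start):
        if seq[p:p+3] in ("ATG", "CTG"):
            for q in range(p + 3, len(seq) - 2, 3):
                if seq[q:q+3] in ("TAA", "TAG", "TGA"):
                    found.append((p, q))
                    break
    return found


def _sample_kozak(rng: np.random.Generator) -> str:
    bases = []
    for label in (-6, -5, -4, -3, -2, -1, 4, 5):
        cons = _KOZAK_CONSENSUS[label]
        others = [b for b in _BASES if b != cons]
        if rng.random() < _KOZAK_CONSENSUS_PROB:
            bases.append(cons)
        else:
            bases.append(others[rng.integers(3)])
    return "".join(bases)


def _creates_start(utr: str, cds_start: int) -> bool:
    lo = max(0, cds_start - 8)
    return any(utr[i:i+3] in ("ATG", "CTG") for i in range(lo, cds_start - 2))


class _TranscriptBuilder:
    """Assembles one transcript: 5'UTR elements + Kozak + CDS + 3'UTR."""

    def __init__(self, rng: np.random.Generator, config: SimulationConfig,
                 tid: str, gid: str):
        self.rng, self.config, self.tid, self.gid = rng, config, tid, gid

    def build(self, elements: Sequence[_Element]) -> Tuple[
            TranscriptModel, List[Tuple[int, int]],
            List[Tuple[_PlannedVariant, int]], Optional[List[Tuple[int, int]]]]:
        rng, cfg = self.rng, self.config
        lo, hi = cfg.utr5_length_range
        elem_len = sum(len(e.seq) for e in elements)
        min_len = elem_len + 3 * (len(elements) + 1) + 8
        target = max(int(rng.integers(lo, hi + 1)), min_len)

        for attempt in range(60):
            free = target - 6 - elem_len
            n_gaps = len(elements) + 1
            cuts = np.sort(rng.integers(0, free - 3 * n_gaps + 1, size=n_gaps - 1)) \
                if n_gaps > 1 else np.array([], dtype=int)
            gap_lens = np.diff(np.concatenate([[0], cuts, [free - 3 * n_gaps]])) + 3

            utr = ""
            ref_uorfs: List[Tuple[int, int]] = []
            alt_uorfs: Optional[List[Tuple[int, int]]] = None
            planned: List[Tuple[_PlannedVariant, int]] = []
            for e_i, element in enumerate(elements):
                utr += _background(rng, int(gap_lens[e_i]), left=utr)
                offset = len(utr)
                utr += element.seq
                ref_uorfs += [(s + offset, t + offset) for s, t in element.ref_uorfs]
                if element.alt_uorfs is not None:
                    base = [(s, t) for s, t in ref_uorfs
                            if (s - offset, t - offset) not in element.ref_uorfs]
                    alt_uorfs = base + [(s + offset, t + offset)
                                        for s, t in element.alt_uorfs]
                for pv in element.variants:
                    planned.append((pv, pv.offset + offset))
            utr += _background(rng, int(gap_lens[-1]), left=utr)

            kozak = _sample_kozak(rng)
            utr = utr + kozak[:6]
            cds_start = len(utr)

            n_codons = int(rng.integers(*cfg.cds_codons_range))
            codon2 = kozak[6:8] + _BASES[rng.integers(4)]
            while codon2 in ("TAA", "TAG", "TGA"):
                codon2 = kozak[6:8] + _BASES[rng.integers(4)]
            cds = "ATG" + codon2 + "".join(
                _NONSTOP_CODONS[i]
                for i in rng.integers(len(_NONSTOP_CODONS), size=n_codons)
            ) + "TAA"
            utr3 = "".join(_BASES[i] for i in rng.integers(4, size=cfg.utr3_length))
            seq = utr + cds + utr3

            if _creates_start(seq, cds_start) and not any(
                    s >= cds_start - 8 for s, _ in ref_uorfs):
                continue
            if sorted(_architecture(seq, cds_start)) != sorted(ref_uorfs):
                continue
            ok = True
            for pv, pos in planned:
                if seq[pos] != pv.ref:
                    ok = False
                    break
                alt_seq = seq[:pos] + pv.alt + seq[pos + 1:]
                expected = alt_uorfs if alt_uorfs is not None else ref_uorfs
                if sorted(_architecture(alt_seq, cds_start)) != sorted(expected):
                    ok = False
                    break
            if not ok:
                continue
            model = TranscriptModel(self.tid, self.gid, seq, cds_start,
                                    cds_start + len(cds))
            model.validate()
            return model, ref_uorfs, planned, alt_uorfs
        raise RuntimeError(f"could not assemble transcript {self.tid}")


# ---------------------------------------------------------------------------
# study simulation


def _draw_genotypes(rng, maf: float, n: int) -> np.ndarray:
    """Hardy-Weinberg phased haplotype pairs, shape (n, 2)."""
    return (rng.random((n, 2)) < maf).astype(int)


def simulate_transcriptome(config: SimulationConfig) -> Tuple[
        List[TranscriptModel], List[TranscriptVariant],
        Dict[str, HaplotypeVariantSet], GroundTruth]:
    """Transcripts, phased genotypes, and the planted ground truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seq_rng, geno_rng, param_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    individuals = [f"ind{i:02d}" for i in range(config.n_individuals)]
    n_t = config.n_transcripts
    tids = [f"t{i:04d}" for i in range(n_t)]
    gids = [f"g{i:04d}" for i in range(n_t)]

    roles: Dict[int, Tuple[str, str]] = {}
    idx = 0
    for et in config.planted_uorf_event_types:
        roles[idx] = ("uorf", et)
        idx += 1
    for k in range(config.n_kozak_variants):
        weakening = k < round(config.frac_kozak_weakening * config.n_kozak_variants)
        roles[idx] = ("kozak", "weakening" if weakening else "strengthening")
        idx += 1
    for _ in range(config.n_eqtl):
        roles[idx] = ("eqtl", "")
        idx += 1

    transcripts: List[TranscriptModel] = []
    variants: List[TranscriptVariant] = []
    hsets = {ind: HaplotypeVariantSet(ind) for ind in individuals}
    planted_uorf: List[dict] = []
    planted_kozak: List[dict] = []
    planted_eqtl: List[dict] = []
    uorf_effect_sign = {"gain": -1.0, "loss": +1.0, "premature_stop": -1.0,
                        "merge": +1.0}
    vid_counter = 0

    def _new_vid() -> str:
        nonlocal vid_counter
        vid_counter += 1
        return f"v{vid_counter:05d}"

    def _plant_genotypes(vids: Sequence[str], phased: bool = True) -> np.ndarray:
        """Joint dosage (carriers of ANY listed variant); retried so at
        least min_planted_carriers individuals carry the configuration."""
        lo, hi = config.planted_maf_range
        for _ in range(200):
            maf = geno_rng.uniform(lo, hi)
            haps = [
                _draw_genotypes(geno_rng, maf / len(vids), config.n_individuals)
                for _ in vids
            ]
            any_alt = np.clip(np.sum(haps, axis=0), 0, 1)  # (n, 2)
            dosage = any_alt.sum(axis=1)
            per_variant_carriers = [
                int((h.sum(axis=1) > 0).sum()) for h in haps
            ]
            if ((dosage > 0).sum() >= config.min_planted_carriers
                    and np.ptp(dosage) > 0
                    and all(c >= 1 for c in per_variant_carriers)):
                for vid, h in zip(vids, haps):
                    for i, ind in enumerate(individuals):
                        hsets[ind].genotypes[vid] = (int(h[i, 0]), int(h[i, 1]))
                        hsets[ind].phased_flags[vid] = phased
                return dosage
        raise RuntimeError("failed to draw genotypes with enough carriers")

    def _neutral_genotypes(vid: str) -> None:
        lo, hi = config.maf_range
        maf = geno_rng.uniform(lo, hi)
        h = _draw_genotypes(geno_rng, maf, config.n_individuals)
        for i, ind in enumerate(individuals):
            phased = geno_rng.random() >= config.frac_unphased
            hsets[ind].genotypes[vid] = (int(h[i, 0]), int(h[i, 1]))
            hsets[ind].phased_flags[vid] = phased

    for i in range(n_t):
        role, detail = roles.get(i, ("generic", ""))
        builder = _TranscriptBuilder(seq_rng, config, tids[i], gids[i])

        if role == "uorf":
            if detail == "gain":
                elements = [_element_gain(seq_rng, int(seq_rng.integers(2, 6)))]
            elif detail == "loss":
                elements = [_element_loss(seq_rng, int(seq_rng.integers(2, 6)))]
            elif detail == "premature_stop":
                nb = int(seq_rng.integers(5, 9))
                elements = [_element_premature(seq_rng, nb,
                                               int(seq_rng.integers(1, nb - 2)))]
            elif detail == "merge":
                elements = [_element_merge(
                    seq_rng, int(seq_rng.integers(2, 5)),
                    int(seq_rng.integers(2, 5)), int(seq_rng.integers(2, 5)),
                    config.merge_convergent_variants)]
            else:
                raise ValueError(f"unknown uORF event type {detail}")
        elif role == "generic":
            n_uorfs = int(seq_rng.choice([0, 1, 2, 3], p=[0.45, 0.3, 0.15, 0.1]))
            elements = [_element_uorf(seq_rng, int(seq_rng.integers(2, 7)),
                                      stop=("TAA", "TAG")[seq_rng.integers(2)])
                        for _ in range(n_uorfs)]
        else:
            elements = []

        model, ref_uorfs, planned, alt_uorfs = builder.build(elements)

        if role == "kozak":
            model = _plant_kozak_base(model, detail, seq_rng)
        transcripts.append(model)

        if role == "uorf":
            vids = []
            for pv, pos in planned:
                vid = _new_vid()
                vids.append(vid)
                variants.append(TranscriptVariant(model.transcript_id, pos,
                                                  pv.ref, pv.alt, vid))
            dosage = _plant_genotypes(vids)
            planted_uorf.append({
                "transcript_id": model.transcript_id, "gene_id": model.gene_id,
                "event_type": detail, "variant_ids": vids,
                "ref_uorfs": ref_uorfs, "alt_uorfs": alt_uorfs,
                "effect_log2": uorf_effect_sign[detail] * config.uorf_effect_log2,
                "dosage": {ind: int(d) for ind, d in zip(individuals, dosage)},
            })
        elif role == "kozak":
            v, label, weakening = _plant_kozak_variant(model, detail, seq_rng,
                                                       _new_vid())
            variants.append(v)
            dosage = _plant_genotypes([v.variant_id])
            planted_kozak.append({
                "variant_id": v.variant_id, "transcript_id": model.transcript_id,
                "gene_id": model.gene_id, "position_label": label,
                "weakening": weakening,
                "effect_log2": (-1.0 if weakening else 1.0) * config.kozak_effect_log2,
                "dosage": {ind: int(d) for ind, d in zip(individuals, dosage)},
            })
        elif role == "eqtl":
            pos = model.cds_start + 10
            ref = model.sequence[pos]
            alt = [b for b in _BASES if b != ref][int(seq_rng.integers(3))]
            vid = _new_vid()
            variants.append(TranscriptVariant(model.transcript_id, pos, ref,
                                              alt, vid))
            dosage = _plant_genotypes([vid])
            planted_eqtl.append({
                "variant_id": vid, "transcript_id": model.transcript_id,
                "gene_id": model.gene_id, "effect_log2": config.eqtl_effect_log2,
                "dosage": {ind: int(d) for ind, d in zip(individuals, dosage)},
            })

        # neutral 3'UTR variants on every transcript
        n_neutral = seq_rng.poisson(config.neutral_utr3_variant_rate)
        used = set()
        for _ in range(int(n_neutral)):
            pos = int(seq_rng.integers(model.cds_end, len(model.sequence)))
            if pos in used:
                continue
            used.add(pos)
            ref = model.sequence[pos]
            alt = [b for b in _BASES if b != ref][int(seq_rng.integers(3))]
            vid = _new_vid()
            variants.append(TranscriptVariant(model.transcript_id, pos, ref,
                                              alt, vid))
            _neutral_genotypes(vid)

    truth = _draw_expression_truth(config, transcripts, individuals, param_rng,
                                   planted_uorf, planted_kozak, planted_eqtl)
    return transcripts, variants, hsets, truth


def _plant_kozak_base(model: TranscriptModel, detail: str,
                      rng: np.random.Generator) -> TranscriptModel:
    """Force the -3 base toward/away from consensus so the planted variant
    has an unambiguous reference state.  -2/-1 are pinned to consensus CC
    so that no -3 allele can complete an ATG/CTG start trigram."""
    pos = model.cds_start - 3
    cons = _KOZAK_CONSENSUS[-3]
    base = cons if detail == "weakening" else "T"
    seq = (model.sequence[:pos] + base + "CC" + model.sequence[pos + 3:])
    model = dataclasses.replace(model, sequence=seq)
    if _creates_start(seq, model.cds_start):  # cannot happen by construction
        raise RuntimeError(f"Kozak plant created a start on {model.transcript_id}")
    return model


def _plant_kozak_variant(model: TranscriptModel, detail: str,
                         rng: np.random.Generator, vid: str):
    """A Kozak SNV at -3: consensus -> T (weakening) or T/other -> consensus."""
    pos = model.cds_start - 3
    ref = model.sequence[pos]
    cons = _KOZAK_CONSENSUS[-3]
    weakening = detail == "weakening"
    if weakening:
        candidates = [b for b in ("T", "C") if b != ref]
    else:
        candidates = [cons] if ref != cons else ["G"]
    alt = None
    for cand in candidates:
        alt_seq = model.sequence[:pos] + cand + model.sequence[pos + 1:]
        if not _creates_start(alt_seq, model.cds_start):
            alt = cand
            break
    if alt is None:
        alt = candidates[0]
    return TranscriptVariant(model.transcript_id, pos, ref, alt, vid), -3, weakening


def _draw_expression_truth(config, transcripts, individuals, rng,
                           planted_uorf, planted_kozak, planted_eqtl) -> GroundTruth:
    gids = [t.gene_id for t in transcripts]
    n_g, n_i = len(gids), len(individuals)

    mu = pd.Series(rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                              n_g), index=gids, name="mu_log2")
    te = pd.Series(rng.normal(0.0, config.te_log2_sd, n_g), index=gids,
                   name="te_log2")
    for t in transcripts:
        if t.cds_start >= 3 and t.sequence[t.cds_start - 3] == "A":
            te[t.gene_id] += config.kozak_minus3_te_shift
    phi = pd.Series(np.exp(rng.normal(np.log(config.nb_dispersion_mean),
                                      config.nb_dispersion_log_sd, n_g)),
                    index=gids, name="dispersion")

    planted_genes = ({d["gene_id"] for d in planted_uorf}
                     | {d["gene_id"] for d in planted_kozak}
                     | {d["gene_id"] for d in planted_eqtl})
    eligible = [g for g in gids if g not in planted_genes]
    rng.shuffle(eligible)
    n_rna = round(config.frac_genes_rna_variable * n_g)
    n_ro = round(config.frac_genes_ro_variable * n_g)
    n_both = round(config.frac_genes_both_variable * n_g)
    if n_rna + n_ro + n_both > len(eligible):
        raise ValueError("variable-gene fractions exceed available transcripts")
    rna_only = set(eligible[:n_rna])
    ribo_only = set(eligible[n_rna:n_rna + n_ro])
    both = set(eligible[n_rna + n_ro:n_rna + n_ro + n_both])

    flags = pd.DataFrame({
        "rna_variable": [g in rna_only or g in both for g in gids],
        "ro_variable": [g in ribo_only or g in both for g in gids],
    }, index=gids)

    b_rna = np.zeros((n_g, n_i))
    b_ribo = np.zeros((n_g, n_i))
    sd = config.individual_sd_log2
    for gi, g in enumerate(gids):
        if g in rna_only:
            b_rna[gi] = rng.normal(0.0, sd, n_i)
        elif g in ribo_only:
            b_ribo[gi] = rng.normal(0.0, sd, n_i)
        elif g in both:
            shared = rng.normal(0.0, sd, n_i)
            b_rna[gi] = shared
            b_ribo[gi] = shared
    if config.te_individual_sd_log2 > 0:
        b_ribo = b_ribo + rng.normal(0.0, config.te_individual_sd_log2,
                                     (n_g, n_i))
    eff_rna = pd.DataFrame(b_rna, index=gids, columns=individuals)
    eff_ribo = pd.DataFrame(b_ribo, index=gids, columns=individuals)

    true_te = eff_ribo - eff_rna
    true_te = true_te.add(te, axis=0)
    for d in planted_uorf + planted_kozak:
        dos = pd.Series(d["dosage"])
        true_te.loc[d["gene_id"]] += d["effect_log2"] * dos[individuals].to_numpy()

    return GroundTruth(flags, eff_rna, eff_ribo, planted_uorf, planted_kozak,
                       planted_eqtl, true_te, mu, te, phi)


def simulate_counts(
    transcripts: Sequence[TranscriptModel],
    haplotype_sets: Mapping[str, HaplotypeVariantSet],
    truth: GroundTruth,
    config: SimulationConfig,
) -> Tuple[ExpressionSet, pd.DataFrame]:
    """Negative-binomial count libraries plus the protein matrix.

    count[g, l] ~ NB(mean = lib_size_l x proportion of 2^eta, phi_g) with
    eta = mu_g + TE_g[ribo] + per-individual effects + planted variant
    effects x dosage (ribo only unless configured).  Protein level is a
    noisy monotone (rank) function of per-individual ribosome occupancy
    plus gene-level noise.  Deterministic given the config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    _, _, _, count_rng, prot_rng = (np.random.default_rng(s) for s in ss.spawn(5))
    gids = [t.gene_id for t in transcripts]
    individuals = sorted(haplotype_sets)
    n_g = len(gids)

    lib_rows = []
    for ind in individuals:
        for r in range(config.replicates_rna):
            lib_rows.append((f"{ind}_rna{r+1}", ind, "rna", r + 1))
        for r in range(config.replicates_ribo):
            lib_rows.append((f"{ind}_ribo{r+1}", ind, "ribo", r + 1))
    samples = pd.DataFrame(lib_rows, columns=["library_id", "individual",
                                              "assay", "replicate"]
                           ).set_index("library_id")
    n_l = len(samples)
    lo, hi = config.library_size_range
    lib_sizes = np.exp(count_rng.uniform(np.log(lo), np.log(hi), n_l))

    mu = truth.mu_log2[gids].to_numpy()
    te = truth.te_log2[gids].to_numpy()
    phi = truth.dispersion[gids].to_numpy()
    eta = np.tile(mu[:, None], (1, n_l)).astype(float)
    gene_pos = {g: i for i, g in enumerate(gids)}

    is_ribo = (samples["assay"] == "ribo").to_numpy()
    eta[:, is_ribo] += te[:, None]
    for li, (lib, row) in enumerate(samples.iterrows()):
        ind = row["individual"]
        if row["assay"] == "rna":
            eta[:, li] += truth.individual_effects_rna[ind].to_numpy()
        else:
            eta[:, li] += truth.individual_effects_ribo[ind].to_numpy()

    for d in truth.planted_uorf + truth.planted_kozak:
        gi = gene_pos[d["gene_id"]]
        dos = np.array([d["dosage"][ind] for ind in samples["individual"]])
        hit = is_ribo | config.variant_effects_hit_rna
        eta[gi, hit] += d["effect_log2"] * dos[hit]
    for d in truth.planted_eqtl:
        gi = gene_pos[d["gene_id"]]
        dos = np.array([d["dosage"][ind] for ind in samples["individual"]])
        eta[gi, :] += d["effect_log2"] * dos

    expr_rel = 2.0 ** eta
    props = expr_rel / expr_rel.sum(axis=0, keepdims=True)
    mean = props * lib_sizes[None, :]
    size = 1.0 / phi[:, None]
    p_nb = size / (size + mean)
    counts = count_rng.negative_binomial(size, p_nb)
    counts_df = pd.DataFrame(counts, index=gids, columns=samples.index)

    # protein: gene-level component + rank of per-individual RO deviation
    ro_dev = truth.individual_effects_ribo.loc[gids, individuals].to_numpy().copy()
    for d in truth.planted_uorf + truth.planted_kozak:
        gi = gene_pos[d["gene_id"]]
        ro_dev[gi] += d["effect_log2"] * np.array(
            [d["dosage"][ind] for ind in individuals])
    n_i = len(individuals)
    pct = np.zeros_like(ro_dev)
    for gi in range(n_g):
        if np.ptp(ro_dev[gi]) > 0:
            pct[gi] = rankdata(ro_dev[gi]) / n_i - 0.5
    gene_level = (mu + te + prot_rng.normal(0.0, config.protein_gene_noise_sd, n_g))
    protein = (gene_level[:, None]
               + config.protein_rank_scale * pct
               + prot_rng.normal(0.0, config.protein_noise_sd, (n_g, n_i)))
    protein_df = pd.DataFrame(protein, index=gids, columns=individuals)

    return ExpressionSet(counts=counts_df, samples=samples), protein_df


def simulate_study(config: SimulationConfig, outdir: Optional[str] = None):
    """Full study: transcripts, genotypes, counts, protein, ground truth.

    If ``outdir`` is given, writes FASTA, annotation TSV, VCF, counts
    TSV, sample sheet TSV, protein TSV, and ground-truth JSON.
    """
    transcripts, variants, hsets, truth = simulate_transcriptome(config)
    expr, protein = simulate_counts(transcripts, hsets, truth, config)
    if outdir is not None:
        import os

        from .sequence_model import write_transcripts, write_vcf

        os.makedirs(outdir, exist_ok=True)
        write_transcripts(transcripts, f"{outdir}/transcripts.fasta",
                          f"{outdir}/annotation.tsv")
        write_vcf(f"{outdir}/variants.vcf", variants, hsets)
        expr.counts.to_csv(f"{outdir}/counts.tsv", sep="\t")
        expr.samples.to_csv(f"{outdir}/samples.tsv", sep="\t")
        protein.to_csv(f"{outdir}/protein.tsv", sep="\t")
        truth.to_json(f"{outdir}/ground_truth.json")
    return {
        "transcripts": transcripts,
        "variants": variants,
        "haplotype_sets": hsets,
        "truth": truth,
        "expression": expr,
        "protein": protein,
    }
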