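"""Kozak-region PWM, per-position TE tests, and variant-effect association.

The Kozak region is the 6 nt preceding the start codon plus the 2 nt
following it (positions -6..-1 and +4,+5 in the +1 = first base of ATG
convention; the start codon itself is excluded).  A position weight
matrix over all transcripts is used both to test per-position nucleotide
effects on translation efficiency (Kruskal-Wallis with Bonferroni over
the eight positions) and to code Kozak SNVs by their PWM score change,
assuming additivity across positions and allele copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from statsmodels.stats.multitest import multipletests

from .sequence_model import HaplotypeVariantSet, TranscriptModel, TranscriptVariant
from ._regression import dosage_association

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
POSITION_LABELS = (-6, -5, -4, -3, -2, -1, 4, 5)


def kozak_offset_to_transcript(cds_start: int, label: int) -> int:
    """Transcript position of a Kozak position label (+1 = first ATG base)."""
    if label < 0:
        return cds_start + label
    if label >= 4:
        return cds_start + label - 1
    raise ValueError(f"position {label} is inside the start codon")


def transcript_to_kozak_offset(cds_start: int, position: int) -> Optional[int]:
    """Inverse map; None if the position is outside the Kozak region.

    Positions inside the start codon itself return None as well — such
    variants disrupt the ORF rather than its initiation context.
    """
    delta = position - cds_start
    if -6 <= delta <= -1:
        return delta
    if 3 <= delta <= 4:
        return delta + 1
    return None


def extract_kozak(transcript: TranscriptModel) -> Optional[str]:
    """The 8-mer at the Kozak positions, or None if the transcript is too
    short (5'UTR < 6 nt or < 2 nt after the start codon)."""
    c = transcript.cds_start
    if c < 6 or c + 5 > len(transcript.sequence):
        return None
    return transcript.sequence[c - 6 : c] + transcript.sequence[c + 3 : c + 5]


@dataclass
class KozakPwm:
    """Position weight matrix over the 8 Kozak positions.

    ``log_odds`` is log2(prob / 0.25); a sequence score is the sum of
    per-position lookups, so scores are additive across positions.
    """

    counts: pd.DataFrame
    probs: pd.DataFrame
    log_odds: pd.DataFrame
    n_transcripts: int
    n_excluded: int
    pseudocount: float

    def score(self, kozak_seq: str) -> float:
        if len(kozak_seq) != len(POSITION_LABELS):
            raise ValueError("Kozak sequence must be 8 nt")
        return float(sum(
            self.log_odds.loc[label, base]
            for label, base in zip(POSITION_LABELS, kozak_seq)
        ))


def build_pwm(
    transcripts: Sequence[TranscriptModel], pseudocount: float = 0.5
) -> KozakPwm:
    kozaks = []
    n_excluded = 0
    for t in transcripts:
        kz = extract_kozak(t)
        if kz is None:
            n_excluded += 1
        else:
            kozaks.append(kz)
    n_used = len(kozaks)
    if n_used == 0:
        raise ValueError("no transcript with a complete Kozak region")
    chars = np.frombuffer("".join(kozaks).encode(), dtype="S1").reshape(n_used, 8)
    counts = pd.DataFrame(
        {nt: (chars == nt.encode()).sum(axis=0).astype(float)
         for nt in NUCLEOTIDES},
        index=list(POSITION_LABELS),
    )
    probs = (counts + pseudocount).div(counts.sum(axis=1) + 4 * pseudocount, axis=0)
    log_odds = np.log2(probs / 0.25)
    return KozakPwm(counts, probs, log_odds, n_used, n_excluded, pseudocount)


def test_position_effects(
    transcripts: Sequence[TranscriptModel], te_global: pd.Series
) -> pd.DataFrame:
    """Kruskal-Wallis of global TE across nucleotide groups, per position.

    A position with fewer than two observed nucleotide groups yields
    p = NaN but still counts toward the Bonferroni x8 correction.
    """
    kozaks = {}
    for t in transcripts:
        kz = extract_kozak(t)
        if kz is not None and t.gene_id in te_global.index:
            kozaks[t.gene_id] = kz
    rows = []
    for k, label in enumerate(POSITION_LABELS):
        groups = {}
        for gene, kz in kozaks.items():
            groups.setdefault(kz[k], []).append(float(te_global[gene]))
        samples = [np.asarray(v) for v in groups.values() if len(v) > 0]
        if len(samples) < 2:
            rows.append({"position": label, "h_statistic": np.nan, "p_value": np.nan})
            continue
        with np.errstate(invalid="ignore"):
            try:
                h, p = kruskal(*samples)
            except ValueError:
                h, p = 0.0, 1.0
        if not np.isfinite(h):  # all values identical -> no evidence
            h, p = 0.0, 1.0
        rows.append({"position": label, "h_statistic": float(h), "p_value": float(p)})
    out = pd.DataFrame(rows).set_index("position")
    out["p_bonferroni"] = np.minimum(out["p_value"] * len(POSITION_LABELS), 1.0)
    return out


@dataclass
class KozakVariantScore:
    variant_id: str
    transcript_id: str
    gene_id: str
    position_label: int
    ref_allele: str
    alt_allele: str
    delta_pwm: float
    n_carriers: int
    direction: str  # "weakening" if delta_pwm < 0 else "strengthening"
    included: bool  # carried by >= min_carriers individuals


def kozak_variants(
    variants: Sequence[TranscriptVariant],
    transcripts: Mapping[str, TranscriptModel],
) -> List[TranscriptVariant]:
    """Subset of variants lying in annotated Kozak regions (start codon
    positions excluded)."""
    out = []
    for v in variants:
        t = transcripts.get(v.transcript_id)
        if t is None or extract_kozak(t) is None:
            continue
        if transcript_to_kozak_offset(t.cds_start, v.position) is not None:
            out.append(v)
    return out


def score_kozak_variants(
    variants: Sequence[TranscriptVariant],
    pwm: KozakPwm,
    transcripts: Mapping[str, TranscriptModel],
    haplotype_sets: Mapping[str, HaplotypeVariantSet],
    min_carriers: int = 3,
) -> Tuple[List[KozakVariantScore], Dict[str, Dict[str, float]]]:
    """Score variants by PWM change; build per-transcript predictors.

    delta_pwm = log_odds(alt) - log_odds(ref) at the variant's position
    (swapping ref and alt negates it).  The per-individual predictor for
    a transcript is the sum over its included Kozak variants of
    delta_pwm x alt-allele copies.  Variants carried by fewer than
    ``min_carriers`` individuals are reported with their direction but
    excluded from the predictor.
    """
    scores: List[KozakVariantScore] = []
    predictors: Dict[str, Dict[str, float]] = {}
    individuals = sorted(haplotype_sets)
    for v in variants:
        t = transcripts[v.transcript_id]
        label = transcript_to_kozak_offset(t.cds_start, v.position)
        if label is None:
            raise ValueError(
                f"{v.variant_id} at {v.transcript_id}:{v.position} is not in the "
                "Kozak region; filter variants with kozak_variants() first"
            )
        delta = float(pwm.log_odds.loc[label, v.alt_allele]
                      - pwm.log_odds.loc[label, v.ref_allele])
        dosages = {i: haplotype_sets[i].dosage(v.variant_id) for i in individuals}
        n_car = sum(1 for d in dosages.values() if d > 0)
        included = n_car >= min_carriers
        scores.append(KozakVariantScore(
            v.variant_id, v.transcript_id, t.gene_id, label,
            v.ref_allele, v.alt_allele, delta, n_car,
            "weakening" if delta < 0 else "strengthening", included,
        ))
        if included:
            pred = predictors.setdefault(v.transcript_id, {i: 0.0 for i in individuals})
            for i in individuals:
                pred[i] += delta * dosages[i]
    return scores, predictors


def test_kozak_association(
    predictors: Mapping[str, Mapping[str, float]],
    expr,
    gene_of_transcript: Mapping[str, str],
    fdr_level: float = 0.10,
    rna_p_threshold: float = 0.01,
    use_lmm: bool = True,
) -> pd.DataFrame:
    """Linear model of RO log2-cpm on the PWM-coded Kozak predictor.

    BH FDR at 10% over transcripts; translation-specificity requires the
    RNA association p-value to exceed ``rna_p_threshold`` (stricter than
    the uORF rule) or an opposite-signed RNA coefficient.
    """
    rows = []
    for tid, pred in predictors.items():
        if len(set(pred.values())) < 2:
            logger.warning("skipping %s: constant Kozak predictor", tid)
            continue
        gene = gene_of_transcript.get(tid, tid)
        res = dosage_association(expr, gene, pred, use_lmm=use_lmm)
        if res is None:
            continue
        rows.append({"unit_id": tid, "gene_id": gene, **res})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr_ribo"] = multipletests(out["p_ribo"], method="fdr_bh")[1]
    out["significant"] = out["fdr_ribo"] < fdr_level
    out["translation_specific"] = (out["p_rna"] > rna_p_threshold) | (
        np.sign(out["beta_rna"]) != np.sign(out["beta_ribo"])
    )
    return out
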