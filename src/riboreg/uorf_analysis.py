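"""Upstream ORF scanning, architecture diffing, and association testing.

A uORF initiates at an ATG or CTG strictly upstream of the annotated
start codon and runs to the first in-frame stop (TAA/TAG/TGA), which may
lie inside the CDS (``overlaps_cds``).  Haplotype-specific 5'UTR
sequences are scanned and grouped by uORF architecture; architecture
changes relative to the reference (gain, loss, premature stop, stop-loss
extension, merge of adjacent uORFs) are tested for association with
ribosome occupancy of the main coding region, with RNA expression as the
specificity control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .sequence_model import (
    HaplotypeVariantSet,
    TranscriptModel,
    TranscriptVariant,
    haplotype_sequence,
)
from ._regression import dosage_association

logger = logging.getLogger(__name__)

START_CODONS = ("ATG", "CTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

EVENT_GAIN = "gain"
EVENT_LOSS = "loss"
EVENT_PREMATURE_STOP = "premature_stop"
EVENT_STOP_LOSS = "stop_loss_extension"
EVENT_MERGE = "merge"
EVENT_OTHER = "other"


@dataclass(frozen=True)
class Uorf:
    """One upstream ORF: ``start`` and ``stop`` are 0-based offsets of the
    first base of the start and stop codon respectively."""

    start: int
    stop: int
    start_codon: str
    overlaps_cds: bool

    @property
    def frame(self) -> int:
        return self.start % 3


@dataclass
class UorfConfiguration:
    """The ordered set of uORFs on one haplotype sequence."""

    transcript_id: str
    haplotype_label: str
    uorfs: List[Uorf] = field(default_factory=list)

    @property
    def signature(self) -> str:
        return ";".join(f"{u.start}:{u.stop}:{u.start_codon}" for u in self.uorfs)


@dataclass
class UorfEvent:
    """A reference->alternate uORF architecture change with carriers.

    ``dosage`` counts, per individual, the haplotypes carrying the
    non-reference configuration (0/1/2).
    """

    transcript_id: str
    gene_id: str
    event_type: str
    event_types: Tuple[str, ...]
    defining_variants: Tuple[str, ...]
    alt_signature: str
    dosage: Dict[str, int] = field(default_factory=dict)

    @property
    def event_id(self) -> str:
        return f"{self.transcript_id}|{self.alt_signature or 'null'}"

    def n_carriers(self) -> int:
        return sum(1 for d in self.dosage.values() if d > 0)


def scan_uorfs(
    sequence: str,
    cds_start: int,
    start_codons: Sequence[str] = START_CODONS,
    allow_cds_overlap: bool = True,
    min_length: int = 0,
) -> List[Uorf]:
    """Enumerate uORFs starting upstream of ``cds_start``.

    Each ATG/CTG at a position < ``cds_start`` yields a uORF ending at
    the first in-frame stop codon anywhere downstream; starts with no
    in-frame stop are dropped.  ``allow_cds_overlap=False`` additionally
    drops uORFs whose stop codon begins at or beyond ``cds_start``.
    ``min_length`` is a minimum start-to-stop distance in nucleotides.
    """
    seq = sequence.upper()
    uorfs: List[Uorf] = []
    for p in range(0, min(cds_start, len(seq) - 2)):
        codon = seq[p : p + 3]
        if codon not in start_codons:
            continue
        stop = None
        for q in range(p + 3, len(seq) - 2, 3):
            if seq[q : q + 3] in STOP_CODONS:
                stop = q
                break
        if stop is None:
            continue
        if stop - p < min_length:
            continue
        overlaps = stop >= cds_start
        if overlaps and not allow_cds_overlap:
            continue
        uorfs.append(Uorf(p, stop, codon, overlaps))
    return uorfs


def _maximal(uorfs: Sequence[Uorf]) -> Dict[int, int]:
    """Collapse uORFs sharing a stop codon to the most upstream start.

    Returns a start -> stop map of the maximal uORFs.  Nested uORFs that
    terminate at the same stop (as after a stop-loss that runs a uORF
    into the next one) are absorbed by the longest one, which is what
    makes a merge recognizable as a net loss of one uORF.
    """
    by_stop: Dict[int, int] = {}
    for u in uorfs:
        if u.stop not in by_stop or u.start < by_stop[u.stop]:
            by_stop[u.stop] = u.start
    return {start: stop for stop, start in by_stop.items()}


def diff_configurations(
    ref_config: UorfConfiguration, alt_config: UorfConfiguration
) -> List[str]:
    """Classify the architecture change between two configurations.

    Classification compares maximal uORFs by (start, stop):
    new start -> gain; removed start -> loss; same start with a smaller
    stop -> premature_stop; same start with a larger stop ->
    stop_loss_extension, or merge when the extension runs to (or past)
    the stop of a downstream reference uORF that disappears from the
    maximal set.  Anything else is "other".
    """
    ref_m = _maximal(ref_config.uorfs)
    alt_m = _maximal(alt_config.uorfs)
    events: List[str] = []
    consumed: set = set()

    for start in sorted(set(ref_m) & set(alt_m)):
        r_stop, a_stop = ref_m[start], alt_m[start]
        if a_stop == r_stop:
            continue
        if a_stop < r_stop:
            events.append(EVENT_PREMATURE_STOP)
            continue
        # extension: does it swallow a downstream reference uORF?
        swallowed = [
            s2
            for s2, e2 in ref_m.items()
            if s2 > start and e2 <= a_stop and s2 not in alt_m
        ]
        if swallowed:
            consumed.update(swallowed)
            events.append(EVENT_MERGE)
        else:
            events.append(EVENT_STOP_LOSS)

    for start in sorted(set(alt_m) - set(ref_m)):
        events.append(EVENT_GAIN)
    for start in sorted(set(ref_m) - set(alt_m)):
        if start not in consumed:
            events.append(EVENT_LOSS)

    if not events and ref_config.signature != alt_config.signature:
        events.append(EVENT_OTHER)
    return events


def enumerate_events(
    transcripts: Sequence[TranscriptModel],
    variants: Sequence[TranscriptVariant],
    haplotype_sets: Mapping[str, HaplotypeVariantSet],
    min_carriers: int = 3,
    gene_of_transcript: Optional[Mapping[str, str]] = None,
    allow_cds_overlap: bool = True,
) -> List[UorfEvent]:
    """Materialize every observed haplotype, scan it, and pool by signature.

    Haplotypes sharing a changed uORF configuration are pooled into a
    single event regardless of which variant produced it, so convergent
    changes (two different SNVs ablating the same stop codon) contribute
    carriers to one event.  Events seen in fewer than ``min_carriers``
    individuals are dropped.
    """
    if gene_of_transcript is None:
        gene_of_transcript = {t.transcript_id: t.gene_id for t in transcripts}
    events: List[UorfEvent] = []
    individuals = sorted(haplotype_sets)

    for transcript in transcripts:
        utr_variants = sorted(
            (v for v in variants
             if v.transcript_id == transcript.transcript_id
             and v.position < transcript.cds_start),
            key=lambda v: v.position,
        )
        if not utr_variants:
            continue
        ref_uorfs = scan_uorfs(
            transcript.sequence, transcript.cds_start,
            allow_cds_overlap=allow_cds_overlap,
        )
        ref_config = UorfConfiguration(transcript.transcript_id, "ref", ref_uorfs)

        # unique allele combinations observed across all haplotypes
        hap_tuples: Dict[str, List[Tuple[int, ...]]] = {}
        observed: Dict[Tuple[int, ...], str] = {}
        for ind in individuals:
            hs = haplotype_sets[ind]
            for hap_idx in (0, 1):
                alleles = tuple(
                    hs.genotypes.get(v.variant_id, (0, 0))[hap_idx]
                    for v in utr_variants
                )
                if alleles not in observed:
                    if any(alleles):
                        seq = haplotype_sequence(transcript, utr_variants, alleles)
                        cfg = UorfConfiguration(
                            transcript.transcript_id, "alt",
                            scan_uorfs(seq, transcript.cds_start,
                                       allow_cds_overlap=allow_cds_overlap),
                        )
                        observed[alleles] = cfg.signature
                    else:
                        observed[alleles] = ref_config.signature
                sig = observed[alleles]
                if sig != ref_config.signature:
                    hap_tuples.setdefault(sig, []).append(alleles)

        for sig, tuples in hap_tuples.items():
            alt_uorfs = [
                Uorf(int(s.split(":")[0]), int(s.split(":")[1]), s.split(":")[2],
                     int(s.split(":")[1]) >= transcript.cds_start)
                for s in sig.split(";") if s
            ]
            alt_config = UorfConfiguration(transcript.transcript_id, "alt", alt_uorfs)
            types = tuple(diff_configurations(ref_config, alt_config))
            event_type = types[0] if len(types) == 1 else EVENT_OTHER
            defining = tuple(sorted({
                utr_variants[i].variant_id
                for alleles in set(tuples)
                for i, a in enumerate(alleles) if a == 1
            }))
            dosage: Dict[str, int] = {}
            tup_set = set(tuples)
            for ind in individuals:
                hs = haplotype_sets[ind]
                d = 0
                for hap_idx in (0, 1):
                    alleles = tuple(
                        hs.genotypes.get(v.variant_id, (0, 0))[hap_idx]
                        for v in utr_variants
                    )
                    if observed.get(alleles) == sig:
                        d += 1
                dosage[ind] = d
            event = UorfEvent(
                transcript.transcript_id,
                gene_of_transcript.get(transcript.transcript_id,
                                       transcript.transcript_id),
                event_type, types, defining, sig, dosage,
            )
            if event.n_carriers() >= min_carriers:
                events.append(event)
            else:
                logger.info(
                    "dropping event %s: %d carriers < %d",
                    event.event_id, event.n_carriers(), min_carriers,
                )
    return events


def test_uorf_association(
    events: Sequence[UorfEvent],
    expr,
    fdr_level: float = 0.05,
    rna_p_threshold: float = 0.05,
    use_lmm: bool = True,
) -> pd.DataFrame:
    """Test uORF event copy number against ribosome occupancy of the CDS.

    Per event: weighted linear regression of per-library ribosome
    occupancy log2-cpm on the event dosage (0/1/2), plus a conservative
    linear mixed model with an individual random intercept.  The same
    regression on RNA expression provides the translation-specificity
    control: an event is translation-specific if its RNA association is
    non-significant at ``rna_p_threshold`` or oppositely signed.  BH FDR
    is applied over events on the ribosome-occupancy p-values.
    """
    rows = []
    for event in events:
        if len(set(event.dosage.values())) < 2:
            logger.warning("skipping %s: dosage has no variance", event.event_id)
            continue
        res = dosage_association(expr, event.gene_id, event.dosage, use_lmm=use_lmm)
        if res is None:
            continue
        rows.append({"unit_id": event.event_id, "gene_id": event.gene_id,
                     "event_type": event.event_type, **res})
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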