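"""Transcript-centric sequence and variant data model.

Everything downstream (uORF scanning, Kozak scoring, haplotype
reconstruction) works in transcript coordinates: 0-based, half-open,
5'->3' in transcript orientation.  Genomic VCF coordinates are converted
at the I/O boundary; for synthetic data each transcript lives on its own
contig so the genome->transcript map is the identity.

Only biallelic SNVs are modelled.  Indels and multi-allelic records are
dropped at VCF load time (with counters) so sequence length bookkeeping
stays trivial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

START_CODON = "ATG"
VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: sequence plus the UTR5/CDS coordinate frame.

    ``cds_start`` is the 0-based offset of the first base of the
    annotated start codon; ``cds_end`` is exclusive and includes the
    stop codon.  The 5' UTR is ``sequence[:cds_start]``.
    """

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int

    @property
    def utr5_length(self) -> int:
        return self.cds_start

    @property
    def utr5_sequence(self) -> str:
        return self.sequence[: self.cds_start]

    def validate(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: CDS span [{self.cds_start},{self.cds_end}) "
                f"outside sequence of length {len(self.sequence)}"
            )
        if self.sequence[self.cds_start : self.cds_start + 3] != START_CODON:
            raise ValueError(
                f"{self.transcript_id}: CDS does not start with {START_CODON}"
            )


@dataclass(frozen=True)
class TranscriptVariant:
    """A biallelic SNV in transcript coordinates (0-based)."""

    transcript_id: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_id: str

    def validate(self, transcript: TranscriptModel) -> None:
        if transcript.sequence[self.position] != self.ref_allele:
            raise ValueError(
                f"{self.variant_id}: reference allele {self.ref_allele} does not "
                f"match transcript base {transcript.sequence[self.position]} at "
                f"{self.transcript_id}:{self.position}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref == alt")


@dataclass
class HaplotypeVariantSet:
    """Per-individual phased diploid genotypes over known variants.

    ``genotypes`` maps variant_id -> (allele on haplotype A, allele on
    haplotype B), each 0 (ref) or 1 (alt).  ``phased_flags`` records
    whether the VCF asserted the phase; :func:`resolve_phase` randomizes
    unphased heterozygotes so downstream code can treat everything as
    phased.
    """

    individual_id: str
    genotypes: Dict[str, Tuple[int, int]] = field(default_factory=dict)
    phased_flags: Dict[str, bool] = field(default_factory=dict)

    def dosage(self, variant_id: str) -> int:
        a, b = self.genotypes.get(variant_id, (0, 0))
        return a + b


def load_transcripts(fasta_path: str, annotation_path: str) -> List[TranscriptModel]:
    """Read transcript sequences (FASTA) plus a BED6-like annotation TSV.

    The annotation has columns ``transcript_id, gene_id, cds_start,
    cds_end`` (0-based half-open, transcript coordinates; ``cds_start``
    equals the 5'UTR length).  Transcripts violating the model
    invariants (e.g. CDS not starting with ATG) are skipped with a
    warning; a transcript annotated but absent from the FASTA is a hard
    error.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_path, "fasta")}
    models: List[TranscriptModel] = []
    with open(annotation_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            tid, gid = parts[0], parts[1]
            cds_start, cds_end = int(parts[2]), int(parts[3])
            if tid not in seqs:
                raise KeyError(f"transcript {tid} annotated but missing from FASTA")
            model = TranscriptModel(tid, gid, seqs[tid], cds_start, cds_end)
            try:
                model.validate()
            except ValueError as exc:
                logger.warning("skipping transcript: %s", exc)
                continue
            models.append(model)
    return models


def write_transcripts(
    transcripts: Sequence[TranscriptModel], fasta_path: str, annotation_path: str
) -> None:
    with open(fasta_path, "w") as fa:
        for t in transcripts:
            fa.write(f">{t.transcript_id}\n{t.sequence}\n")
    with open(annotation_path, "w") as an:
        an.write("#transcript_id\tgene_id\tcds_start\tcds_end\n")
        for t in transcripts:
            an.write(f"{t.transcript_id}\t{t.gene_id}\t{t.cds_start}\t{t.cds_end}\n")


IdentityMap = Callable[[str, int], Optional[Tuple[str, int]]]


def identity_contig_map(transcripts: Iterable[TranscriptModel]) -> IdentityMap:
    """Genome->transcript map for the one-contig-per-transcript layout."""
    known = {t.transcript_id for t in transcripts}

    def _map(contig: str, pos0: int) -> Optional[Tuple[str, int]]:
        if contig in known:
            return contig, pos0
        return None

    return _map


def map_vcf_to_transcripts(
    vcf_path: str,
    transcripts: Sequence[TranscriptModel],
    genome_to_transcript_map: Optional[IdentityMap] = None,
) -> Tuple[List[TranscriptVariant], Dict[str, HaplotypeVariantSet], Dict[str, int]]:
    """Load biallelic SNVs overlapping transcripts from a VCF.

    Returns ``(variants, haplotype_sets, counters)``.  ``counters``
    reports dropped records: ``indel``, ``multiallelic``,
    ``allele_mismatch``, ``off_transcript``.  VCF ``|`` separators are
    parsed as phased, ``/`` as unphased.
    """
    from cyvcf2 import VCF

    if genome_to_transcript_map is None:
        genome_to_transcript_map = identity_contig_map(transcripts)
    by_id = {t.transcript_id: t for t in transcripts}

    vcf = VCF(vcf_path)
    individuals = list(vcf.samples)
    hsets = {ind: HaplotypeVariantSet(ind) for ind in individuals}
    variants: List[TranscriptVariant] = []
    counters = {"indel": 0, "multiallelic": 0, "allele_mismatch": 0, "off_transcript": 0}

    for rec in vcf:
        if len(rec.ALT) != 1:
            counters["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
            counters["indel"] += 1
            continue
        mapped = genome_to_transcript_map(rec.CHROM, rec.POS - 1)
        if mapped is None:
            counters["off_transcript"] += 1
            continue
        tid, pos = mapped
        transcript = by_id.get(tid)
        if transcript is None or not (0 <= pos < len(transcript.sequence)):
            counters["off_transcript"] += 1
            continue
        if transcript.sequence[pos] != ref:
            counters["allele_mismatch"] += 1
            logger.warning(
                "dropping %s: REF %s mismatches transcript %s base %s at %d",
                rec.ID, ref, tid, transcript.sequence[pos], pos,
            )
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{tid}_{pos}_{ref}_{alt}"
        variants.append(TranscriptVariant(tid, pos, ref, alt, vid))
        gts = rec.genotypes  # [[a, b, phased], ...]
        for ind, gt in zip(individuals, gts):
            a = 1 if gt[0] == 1 else 0
            b = 1 if gt[1] == 1 else 0
            hsets[ind].genotypes[vid] = (a, b)
            hsets[ind].phased_flags[vid] = bool(gt[2])
    return variants, hsets, counters


def write_vcf(
    path: str,
    variants: Sequence[TranscriptVariant],
    haplotype_sets: Mapping[str, HaplotypeVariantSet],
) -> None:
    """Emit a plain-text VCF v4.2 with one contig per transcript.

    Phase separators follow each individual's phased flag so unphased
    genotypes survive a round trip.
    """
    individuals = list(haplotype_sets)
    ordered = sorted(variants, key=lambda v: (v.transcript_id, v.position))
    contigs = []
    for v in ordered:
        if v.transcript_id not in contigs:
            contigs.append(v.transcript_id)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=riboreg\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(individuals)
            + "\n"
        )
        for v in ordered:
            gt_fields = []
            for ind in individuals:
                hs = haplotype_sets[ind]
                a, b = hs.genotypes.get(v.variant_id, (0, 0))
                sep = "|" if hs.phased_flags.get(v.variant_id, True) else "/"
                gt_fields.append(f"{a}{sep}{b}")
            fh.write(
                f"{v.transcript_id}\t{v.position + 1}\t{v.variant_id}\t"
                f"{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt_fields)
                + "\n"
            )


def resolve_phase(
    haplotype_sets: Mapping[str, HaplotypeVariantSet], seed: int
) -> Mapping[str, HaplotypeVariantSet]:
    """Randomly assign a phase to every unphased heterozygote (in place).

    Homozygotes are phase-invariant and only have their flag set.  The
    assignment is deterministic given ``seed``; the fraction of
    heterozygotes placed on haplotype A is Bernoulli(1/2) per call.
    """
    rng = np.random.default_rng(seed)
    for ind in sorted(haplotype_sets):
        hs = haplotype_sets[ind]
        for vid in sorted(hs.genotypes):
            if hs.phased_flags.get(vid, True):
                continue
            a, b = hs.genotypes[vid]
            if a != b and rng.random() < 0.5:
                hs.genotypes[vid] = (b, a)
            hs.phased_flags[vid] = True
    return haplotype_sets


def haplotype_sequence(
    transcript: TranscriptModel,
    variants: Sequence[TranscriptVariant],
    haplotype_alleles: Sequence[int],
) -> str:
    """Substitute alt alleles (where allele == 1) into the transcript.

    SNV-only, so the returned sequence has the reference length.  Two
    variants at the same position are a hard error.
    """
    if len(variants) != len(haplotype_alleles):
        raise ValueError("variants and haplotype_alleles length mismatch")
    seen = set()
    seq = list(transcript.sequence)
    for variant, allele in zip(variants, haplotype_alleles):
        if variant.transcript_id != transcript.transcript_id:
            raise ValueError(
                f"{variant.variant_id} does not lie on {transcript.transcript_id}"
            )
        if variant.position in seen:
            raise ValueError(f"overlapping variants at position {variant.position}")
        seen.add(variant.position)
        if allele == 1:
            if seq[variant.position] != variant.ref_allele:
                raise ValueError(
                    f"{variant.variant_id}: ref allele mismatch at {variant.position}"
                )
            seq[variant.position] = variant.alt_allele
    return "".join(seq)
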