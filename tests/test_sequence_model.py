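import numpy as np
import pytest

from riboreg.sequence_model import (
    HaplotypeVariantSet,
    TranscriptModel,
    TranscriptVariant,
    haplotype_sequence,
    load_transcripts,
    map_vcf_to_transcripts,
    resolve_phase,
    write_transcripts,
    write_vcf,
)


def _write(tmp_path, fasta, annot):
    fa = tmp_path / "t.fasta"
    an = tmp_path / "t.tsv"
    fa.write_text(fasta)
    an.write_text(annot)
    return str(fa), str(an)


class TestLoadTranscripts:
    def test_minimal_valid_record(self, tmp_path):
        fa, an = _write(tmp_path, ">t1\nGGATGGCCTAA\n", "t1\tg1\t2\t11\n")
        models = load_transcripts(fa, an)
        assert len(models) == 1
        assert models[0].utr5_length == 2
        assert models[0].sequence[2:5] == "ATG"

    def test_non_atg_cds_is_skipped_with_warning(self, tmp_path, caplog):
        fa, an = _write(tmp_path, ">t1\nGGCTGGCCTAA\n", "t1\tg1\t2\t11\n")
        with caplog.at_level("WARNING"):
            models = load_transcripts(fa, an)
        assert models == []
        assert any("skipping transcript" in r.message for r in caplog.records)

    def test_missing_sequence_is_hard_error(self, tmp_path):
        fa, an = _write(tmp_path, ">t1\nGGATGGCCTAA\n", "t2\tg2\t2\t11\n")
        with pytest.raises(KeyError):
            load_transcripts(fa, an)

    def test_synthetic_round_trip(self, tmp_path, small_study):
        transcripts = small_study["transcripts"]
        fa, an = str(tmp_path / "rt.fasta"), str(tmp_path / "rt.tsv")
        write_transcripts(transcripts, fa, an)
        reread = load_transcripts(fa, an)
        assert len(reread) == len(transcripts)
        for a, b in zip(transcripts, reread):
            assert (a.transcript_id, a.cds_start, a.cds_end, a.sequence) == \
                   (b.transcript_id, b.cds_start, b.cds_end, b.sequence)


class TestVcf:
    def test_coordinate_conversion_and_phase_parsing(self, tmp_path):
        t = TranscriptModel("t1", "g1", "GGATGGCCTAA", 2, 11)
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=t1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "t1\t3\tv1\tA\tG\t.\tPASS\t.\tGT\t0|1\t0/1\n"
            "t1\t4\tv2\tT\tTG\t.\tPASS\t.\tGT\t0|0\t0|0\n"
        )
        variants, hsets, counters = map_vcf_to_transcripts(str(vcf), [t])
        assert len(variants) == 1
        v = variants[0]
        assert (v.position, v.ref_allele, v.alt_allele) == (2, "A", "G")
        assert hsets["s1"].genotypes["v1"] == (0, 1)
        assert hsets["s1"].phased_flags["v1"] is True
        assert hsets["s2"].phased_flags["v1"] is False
        assert counters["indel"] == 1

    def test_allele_mismatch_dropped(self, tmp_path):
        t = TranscriptModel("t1", "g1", "GGATGGCCTAA", 2, 11)
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=t1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "t1\t3\tv1\tC\tG\t.\tPASS\t.\tGT\t0|1\n"
        )
        variants, _, counters = map_vcf_to_transcripts(str(vcf), [t])
        assert variants == []
        assert counters["allele_mismatch"] == 1

    def test_write_read_identity(self, tmp_path, small_study):
        variants = small_study["variants"]
        hsets = small_study["haplotype_sets"]
        transcripts = small_study["transcripts"]
        path = str(tmp_path / "rt.vcf")
        write_vcf(path, variants, hsets)
        variants2, hsets2, counters = map_vcf_to_transcripts(path, transcripts)
        assert counters["indel"] == counters["multiallelic"] == 0
        key = lambda v: (v.transcript_id, v.position)
        assert sorted(map(key, variants)) == sorted(map(key, variants2))
        by_id = {v.variant_id: v for v in variants}
        for v2 in variants2:
            v = by_id[v2.variant_id]
            assert (v.ref_allele, v.alt_allele) == (v2.ref_allele, v2.alt_allele)
        for ind in hsets:
            for vid, gt in hsets[ind].genotypes.items():
                assert hsets2[ind].genotypes[vid] == gt
                assert hsets2[ind].phased_flags[vid] == hsets[ind].phased_flags[vid]


class TestResolvePhase:
    def _het(self, phased):
        hs = HaplotypeVariantSet("i1", {"v1": (0, 1)}, {"v1": phased})
        return {"i1": hs}

    def test_deterministic_given_seed(self):
        a = resolve_phase(self._het(False), seed=1)["i1"].genotypes["v1"]
        b = resolve_phase(self._het(False), seed=1)["i1"].genotypes["v1"]
        assert a == b

    def test_homozygote_unchanged(self):
        hs = {"i1": HaplotypeVariantSet("i1", {"v1": (1, 1)}, {"v1": False})}
        out = resolve_phase(hs, seed=3)
        assert out["i1"].genotypes["v1"] == (1, 1)
        assert out["i1"].phased_flags["v1"] is True

    def test_haplotype_assignment_is_balanced(self):
        n = 10_000
        hsets = {
            f"i{k}": HaplotypeVariantSet(f"i{k}", {"v": (0, 1)}, {"v": False})
            for k in range(n)
        }
        resolve_phase(hsets, seed=42)
        frac_a = np.mean([hsets[f"i{k}"].genotypes["v"][0] for k in range(n)])
        se = np.sqrt(0.25 / n)
        assert abs(frac_a - 0.5) < 3 * se


class TestHaplotypeSequence:
    t = TranscriptModel("t1", "g1", "GGATGGCCTAA", 2, 11)

    def test_reference_identity(self):
        assert haplotype_sequence(self.t, [], []) == self.t.sequence

    def test_single_substitution(self):
        v = TranscriptVariant("t1", 0, "G", "C", "v1")
        assert haplotype_sequence(self.t, [v], [1]) == "CGATGGCCTAA"
        assert haplotype_sequence(self.t, [v], [0]) == self.t.sequence

    def test_apply_then_revert_is_involution(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        t = TranscriptModel("t", "g", "A" * 10 + "ATG" + seq + "TAA",
                            10, 13 + len(seq) + 3)
        positions = rng.choice(len(t.sequence), size=20, replace=False)
        variants = []
        for i, p in enumerate(sorted(positions)):
            ref = t.sequence[p]
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref]
            variants.append(TranscriptVariant("t", int(p), ref, alt, f"v{i}"))
        alt_seq = haplotype_sequence(t, variants, [1] * len(variants))
        t_alt = TranscriptModel("t", "g", alt_seq, t.cds_start, t.cds_end)
        back = [TranscriptVariant("t", v.position, v.alt_allele, v.ref_allele,
                                  v.variant_id) for v in variants]
        assert haplotype_sequence(t_alt, back, [1] * len(back)) == t.sequence

    def test_overlapping_variants_error(self):
        v1 = TranscriptVariant("t1", 0, "G", "C", "v1")
        v2 = TranscriptVariant("t1", 0, "G", "T", "v2")
        with pytest.raises(ValueError, match="overlapping"):
            haplotype_sequence(self.t, [v1, v2], [1, 1])
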