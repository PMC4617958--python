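import numpy as np
import pandas as pd
import pytest

from riboreg.kozak_analysis import test_position_effects as run_position_effects
from riboreg.kozak_analysis import test_kozak_association as run_kozak_association
from riboreg.kozak_analysis import (
    POSITION_LABELS,
    build_pwm,
    extract_kozak,
    kozak_offset_to_transcript,
    kozak_variants,
    score_kozak_variants,
    transcript_to_kozak_offset,
)
from riboreg.sequence_model import (
    HaplotypeVariantSet,
    TranscriptModel,
    TranscriptVariant,
    resolve_phase,
)


def _transcript(tid, kozak6, after2, utr_pad="CACCAC"):
    """Transcript with a chosen Kozak context; CDS = ATG + <after2>C + ..."""
    utr = utr_pad + kozak6
    cds = "ATG" + after2 + "C" + "CAC" * 5 + "TAA"
    return TranscriptModel(tid, tid.replace("t", "g"), utr + cds,
                           len(utr), len(utr) + len(cds))


class TestCoordinates:
    @pytest.mark.parametrize("label,offset", [(-6, -6), (-1, -1), (4, 3), (5, 4)])
    def test_label_round_trip(self, label, offset):
        cds = 20
        pos = kozak_offset_to_transcript(cds, label)
        assert pos == cds + offset
        assert transcript_to_kozak_offset(cds, pos) == label

    def test_start_codon_positions_are_not_kozak(self):
        for pos in (20, 21, 22):
            assert transcript_to_kozak_offset(20, pos) is None

    def test_extract_kozak_too_short(self):
        t = TranscriptModel("t", "g", "ACATGCCC" + "TAA", 2, 11)
        assert extract_kozak(t) is None


class TestPwm:
    def test_shared_kozak_dominates_pwm(self):
        transcripts = [_transcript(f"t{i}", "GCCACC", "GC") for i in range(50)]
        pwm = build_pwm(transcripts, pseudocount=0.5)
        assert pwm.probs.loc[-3, "A"] > 0.9
        assert pwm.score("GCCACCGC") == pytest.approx(
            pwm.log_odds.to_numpy().max(axis=1).sum(), abs=1e-9)

    def test_score_is_sum_of_per_position_lookups(self):
        transcripts = [_transcript(f"t{i}", "GCCACC", "GC") for i in range(10)]
        transcripts += [_transcript(f"u{i}", "TTTTTT", "AT") for i in range(5)]
        pwm = build_pwm(transcripts)
        seq = "GTCATCGA"
        by_hand = sum(pwm.log_odds.loc[lab, base]
                      for lab, base in zip(POSITION_LABELS, seq))
        assert pwm.score(seq) == pytest.approx(by_hand, abs=1e-12)

    def test_log_odds_vanish_on_uniform_sequences(self, rng):
        # law of large numbers: with uniform Kozak sequences every log-odds
        # entry shrinks toward 0 (the 0.05 bound is ~4 sigma at this n)
        n = 40_000
        kzs = rng.choice(list("ACGT"), size=(n, 8))
        transcripts = [_transcript(f"t{i}", "".join(kzs[i, :6]),
                                   "".join(kzs[i, 6:8])) for i in range(n)]
        pwm = build_pwm(transcripts)
        assert np.abs(pwm.log_odds.to_numpy()).max() < 0.05

    def test_no_usable_transcript_is_hard_error(self):
        t = TranscriptModel("t", "g", "ACATGCCCTAA", 2, 11)
        with pytest.raises(ValueError):
            build_pwm([t])


class TestVariantScoring:
    def _setup(self, rng, n_carriers=5):
        transcripts = [_transcript(f"t{i}", "GCCACC", "GC") for i in range(20)]
        transcripts += [_transcript(f"u{i}", "TTCTTC", "AA") for i in range(10)]
        pwm = build_pwm(transcripts)
        t = transcripts[0]
        pos = kozak_offset_to_transcript(t.cds_start, -3)
        v = TranscriptVariant(t.transcript_id, pos, "A", "T", "v1")
        hsets = {}
        for k in range(10):
            gt = (1, 1) if k < 2 else ((1, 0) if k < n_carriers else (0, 0))
            hsets[f"i{k}"] = HaplotypeVariantSet(f"i{k}", {"v1": gt},
                                                 {"v1": True})
        return transcripts, pwm, t, v, hsets

    def test_delta_matches_log_odds_difference_and_predictor_adds(self, rng):
        transcripts, pwm, t, v, hsets = self._setup(rng)
        by_id = {x.transcript_id: x for x in transcripts}
        scores, predictors = score_kozak_variants([v], pwm, by_id, hsets)
        (s,) = scores
        expected = pwm.log_odds.loc[-3, "T"] - pwm.log_odds.loc[-3, "A"]
        assert s.delta_pwm == pytest.approx(expected, abs=1e-12)
        assert s.direction == "weakening"
        # homozygote carries twice the delta
        assert predictors[t.transcript_id]["i0"] == pytest.approx(2 * expected)
        assert predictors[t.transcript_id]["i9"] == 0.0

    def test_ref_alt_swap_negates_delta(self, rng):
        transcripts, pwm, t, v, hsets = self._setup(rng)
        by_id = {x.transcript_id: x for x in transcripts}
        swapped = TranscriptVariant(v.transcript_id, v.position,
                                    v.alt_allele, v.ref_allele, "v1s")
        hsets2 = {i: HaplotypeVariantSet(i, {"v1s": hsets[i].genotypes["v1"]},
                                         {"v1s": True}) for i in hsets}
        (s1,), _ = score_kozak_variants([v], pwm, by_id, hsets)
        (s2,), _ = score_kozak_variants([swapped], pwm, by_id, hsets2)
        assert s1.delta_pwm == pytest.approx(-s2.delta_pwm, abs=1e-12)

    def test_two_variants_on_one_transcript_sum(self, rng):
        transcripts, pwm, t, v, hsets = self._setup(rng)
        by_id = {x.transcript_id: x for x in transcripts}
        pos5 = kozak_offset_to_transcript(t.cds_start, 5)
        v2 = TranscriptVariant(t.transcript_id, pos5, t.sequence[pos5], "T", "v2")
        for i in hsets:
            hsets[i].genotypes["v2"] = hsets[i].genotypes["v1"]
            hsets[i].phased_flags["v2"] = True
        scores, predictors = score_kozak_variants([v, v2], pwm, by_id, hsets)
        d1, d2 = scores[0].delta_pwm, scores[1].delta_pwm
        assert predictors[t.transcript_id]["i0"] == pytest.approx(2 * (d1 + d2))

    def test_rare_variant_reported_but_excluded(self, rng):
        transcripts, pwm, t, v, hsets = self._setup(rng, n_carriers=2)
        by_id = {x.transcript_id: x for x in transcripts}
        scores, predictors = score_kozak_variants([v], pwm, by_id, hsets,
                                                  min_carriers=3)
        assert not scores[0].included
        assert scores[0].direction == "weakening"
        assert t.transcript_id not in predictors

    def test_non_kozak_position_is_hard_error(self, rng):
        transcripts, pwm, t, v, hsets = self._setup(rng)
        by_id = {x.transcript_id: x for x in transcripts}
        bad = TranscriptVariant(t.transcript_id, 0, t.sequence[0], "T", "vx")
        with pytest.raises(ValueError, match="Kozak"):
            score_kozak_variants([bad], pwm, by_id, hsets)

    def test_kozak_variants_filter(self, rng):
        transcripts, pwm, t, v, hsets = self._setup(rng)
        by_id = {x.transcript_id: x for x in transcripts}
        bad = TranscriptVariant(t.transcript_id, 0, t.sequence[0], "T", "vx")
        start = TranscriptVariant(t.transcript_id, t.cds_start, "A", "T", "vs")
        assert kozak_variants([v, bad, start], by_id) == [v]


class TestPositionEffects:
    def test_identical_group_values_give_h_zero(self):
        transcripts = [_transcript(f"t{i}", "GCCACC" if i % 2 else "GCCGCC",
                                   "GC") for i in range(20)]
        te = pd.Series(1.0, index=[t.gene_id for t in transcripts])
        out = run_position_effects(transcripts, te)
        assert out.loc[-3, "h_statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out.loc[-3, "p_value"] == pytest.approx(1.0)

    def test_single_group_positions_get_nan_but_count_in_correction(self, rng):
        transcripts = [_transcript(f"t{i}", "GCC" + "ACC", "GC")
                       for i in range(30)]
        te = pd.Series(rng.normal(0, 1, 30),
                       index=[t.gene_id for t in transcripts])
        out = run_position_effects(transcripts, te)
        assert out["p_value"].isna().all()  # every position is monomorphic
        assert len(out) == 8

    def test_planted_minus3_effect_found(self, rng):
        transcripts, te = [], {}
        for i in range(800):
            kz = "".join(rng.choice(list("ACGT"), size=8))
            t = _transcript(f"t{i}", kz[:6], kz[6:8])
            transcripts.append(t)
            te[t.gene_id] = rng.normal(0.5 if kz[3] == "A" else 0.0, 0.3)
        out = run_position_effects(transcripts, pd.Series(te))
        assert out["p_value"].idxmin() == -3
        assert out.loc[-3, "p_bonferroni"] < 0.05


class TestAssociationOnGenerator:
    def test_planted_kozak_effects_recovered(self, small_study, voomed):
        transcripts = small_study["transcripts"]
        by_id = {t.transcript_id: t for t in transcripts}
        hsets = small_study["haplotype_sets"]
        resolve_phase(hsets, seed=3)
        pwm = build_pwm(transcripts)
        kz = kozak_variants(small_study["variants"], by_id)
        planted = {d["variant_id"]: d for d in small_study["truth"].planted_kozak}
        assert set(v.variant_id for v in kz) == set(planted)
        scores, predictors = score_kozak_variants(kz, pwm, by_id, hsets)
        for s in scores:
            assert (s.delta_pwm < 0) == planted[s.variant_id]["weakening"]
        gene_of = {t.transcript_id: t.gene_id for t in transcripts}
        out = run_kozak_association(predictors, voomed, gene_of)
        assert out["significant"].all()
        assert out["translation_specific"].all()
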