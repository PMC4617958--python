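import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboreg.sequence_model import (
    HaplotypeVariantSet,
    TranscriptModel,
    TranscriptVariant,
    resolve_phase,
)
from riboreg.uorf_analysis import test_uorf_association as run_uorf_association
from riboreg.uorf_analysis import (
    Uorf,
    UorfConfiguration,
    diff_configurations,
    enumerate_events,
    scan_uorfs,
)
from riboreg.synthetic_data import SimulationConfig, simulate_study


def brute_force_uorfs(seq, cds_start):
    """Exhaustive enumeration of (start, stop) pairs by codon walking,
    written as a dumb double loop independent of the scanner."""
    starts = [p for p in range(min(cds_start, len(seq) - 2))
              if seq[p:p + 3] in ("ATG", "CTG")]
    out = []
    for p in starts:
        stops = [q for q in range(p + 3, len(seq) - 2)
                 if (q - p) % 3 == 0 and seq[q:q + 3] in ("TAA", "TAG", "TGA")]
        if stops:
            out.append((p, min(stops), seq[p:p + 3]))
    return out


class TestScan:
    def test_minimal_uorf(self):
        seq = "ATGTAA" + "GGG" + "ATG" + "CCC" * 5 + "TAA"
        uorfs = scan_uorfs(seq, cds_start=9)
        assert len(uorfs) == 1
        u = uorfs[0]
        assert (u.start, u.stop, u.start_codon) == (0, 3, "ATG")
        assert not u.overlaps_cds

    def test_two_uorf_architecture(self):
        # two short uORFs in one 5'UTR, the second terminating downstream
        utr = "ATG" + "CCC" + "TGA" + "ACC" + "ATG" + "CCC" + "TAA"
        seq = utr + "ATG" + "CAC" * 10 + "TAA"
        uorfs = scan_uorfs(seq, cds_start=len(utr))
        assert [(u.start, u.stop) for u in uorfs] == [(0, 6), (12, 18)]

    def test_start_without_stop_is_dropped(self):
        seq = "ATGCC" + "CATGC"  # no stop anywhere
        assert scan_uorfs(seq, cds_start=5) == []

    def test_cds_overlap_flag_and_exclusion(self):
        utr = "CCATGCC"  # ATG at 2, no stop before CDS
        seq = utr + "ATGAAATAACCC"
        # in-frame stop for the uORF falls inside the CDS region
        uorfs = scan_uorfs(seq, cds_start=len(utr))
        assert len(uorfs) == 1 and uorfs[0].overlaps_cds
        assert scan_uorfs(seq, cds_start=len(utr), allow_cds_overlap=False) == []

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(300):
            n = int(rng.integers(30, 300))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            cds_start = int(rng.integers(0, n - 3))
            got = [(u.start, u.stop, u.start_codon)
                   for u in scan_uorfs(seq, cds_start)]
            assert got == brute_force_uorfs(seq, cds_start)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=6, max_size=120),
           st.integers(min_value=0, max_value=120))
    def test_scanner_equals_oracle_property(self, seq, cds_start):
        cds_start = min(cds_start, len(seq))
        got = [(u.start, u.stop, u.start_codon)
               for u in scan_uorfs(seq, cds_start)]
        assert got == brute_force_uorfs(seq, cds_start)


def _cfg(pairs):
    return UorfConfiguration("t", "x", [Uorf(s, e, "ATG", False)
                                        for s, e in pairs])


class TestDiff:
    def test_identical_configurations_give_no_events(self):
        assert diff_configurations(_cfg([(0, 9)]), _cfg([(0, 9)])) == []

    def test_gain_and_loss(self):
        assert diff_configurations(_cfg([]), _cfg([(3, 12)])) == ["gain"]
        assert diff_configurations(_cfg([(3, 12)]), _cfg([])) == ["loss"]

    def test_premature_stop_shortens_existing_uorf(self):
        assert diff_configurations(_cfg([(5, 20)]), _cfg([(5, 11)])) == \
            ["premature_stop"]

    def test_stop_loss_extension_without_merge(self):
        assert diff_configurations(_cfg([(5, 11)]), _cfg([(5, 20)])) == \
            ["stop_loss_extension"]

    def test_merge_of_two_uorfs_after_stop_loss(self):
        # after losing the first stop the first uORF runs to the second's
        # stop; the second start is still present but nested (same stop)
        ref = _cfg([(0, 9), (15, 24)])
        alt = _cfg([(0, 24), (15, 24)])
        assert diff_configurations(ref, alt) == ["merge"]


class TestEnumerate:
    def _fixture(self):
        utr = "ATG" + "CCC" + "TAA" + "ACCACC" + "ATG" + "CCC" + "TAA"
        seq = utr + "ATG" + "CAC" * 10 + "TAA" + "GGGGG"
        t = TranscriptModel("t1", "g1", seq, len(utr), len(utr) + 36)
        # two distinct SNVs each ablate the first stop codon (TAA at 6)
        v1 = TranscriptVariant("t1", 6, "T", "C", "v1")
        v2 = TranscriptVariant("t1", 7, "A", "C", "v2")
        hsets = {}
        for k in range(8):
            gt = {"v1": (0, 0), "v2": (0, 0)}
            if k < 3:
                gt["v1"] = (1, 0)
            elif k < 5:
                gt["v2"] = (0, 1)
            hsets[f"i{k}"] = HaplotypeVariantSet(
                f"i{k}", gt, {"v1": True, "v2": True})
        return t, [v1, v2], hsets

    def test_convergent_variants_pool_into_one_event(self):
        t, vs, hsets = self._fixture()
        events = enumerate_events([t], vs, hsets, min_carriers=3)
        assert len(events) == 1
        e = events[0]
        assert e.event_type == "merge"
        assert set(e.defining_variants) == {"v1", "v2"}
        assert e.n_carriers() == 5
        assert all(d in (0, 1, 2) for d in e.dosage.values())
        assert sum(e.dosage.values()) == 5

    def test_min_carriers_filter(self):
        t, vs, hsets = self._fixture()
        assert enumerate_events([t], vs, hsets, min_carriers=6) == []

    def test_neutral_variant_creates_no_event(self):
        utr = "CACCACCAC"
        seq = utr + "ATG" + "CAC" * 5 + "TAA"
        t = TranscriptModel("t1", "g1", seq, len(utr), len(seq))
        v = TranscriptVariant("t1", 1, "A", "C", "v1")
        hsets = {f"i{k}": HaplotypeVariantSet(f"i{k}", {"v1": (1, 0)},
                                              {"v1": True})
                 for k in range(5)}
        assert enumerate_events([t], [v], hsets, min_carriers=1) == []

    def test_generator_round_trip_recovers_planted_events(self, small_study):
        hsets = small_study["haplotype_sets"]
        resolve_phase(hsets, seed=3)
        events = enumerate_events(small_study["transcripts"],
                                  small_study["variants"], hsets)
        planted = {(d["transcript_id"], d["event_type"])
                   for d in small_study["truth"].planted_uorf}
        recovered = {(e.transcript_id, e.event_type) for e in events}
        assert planted == recovered
        # carriers of either convergent merge variant share the event
        merge_plant = next(d for d in small_study["truth"].planted_uorf
                           if d["event_type"] == "merge")
        merge_event = next(e for e in events if e.event_type == "merge")
        assert set(merge_event.defining_variants) == set(
            merge_plant["variant_ids"])


class TestAssociation:
    def test_planted_effect_detected_and_translation_specific(
            self, small_study, voomed):
        hsets = small_study["haplotype_sets"]
        resolve_phase(hsets, seed=3)
        events = enumerate_events(small_study["transcripts"],
                                  small_study["variants"], hsets)
        out = run_uorf_association(events, voomed)
        truth = {d["transcript_id"]: d["effect_log2"]
                 for d in small_study["truth"].planted_uorf}
        assert out["significant"].all()
        assert out["translation_specific"].all()
        for _, row in out.iterrows():
            tid = row["unit_id"].split("|")[0]
            assert np.sign(row["beta_ribo"]) == np.sign(truth[tid])
            assert row["beta_ribo"] == pytest.approx(truth[tid], abs=0.4)
            assert row["p_lmm_ribo"] < 0.05

    def test_constant_dosage_event_is_skipped(self, voomed, small_study):
        events = enumerate_events(small_study["transcripts"],
                                  small_study["variants"],
                                  small_study["haplotype_sets"])
        e = events[0]
        for ind in e.dosage:
            e.dosage[ind] = 0
        out = run_uorf_association([e], voomed)
        assert out.empty
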