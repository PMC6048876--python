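"""MITE scanning: plant/scan round trips, full-length calls, TIR/TSD checks."""

from __future__ import annotations

import random

import pytest

from pandorapan import plant_mites
from pandorapan.mite import MiteHit, call_full_length, scan, verify_tir_tsd
from pandorapan.utils import reverse_complement


def plant_and_scan(seed, n_mites=3, copy_identity=1.0, scaffold_length=8000):
    scaffold, truth = plant_mites(
        scaffold_length=scaffold_length,
        n_mites=n_mites,
        mite_length=300,
        tir_length=20,
        tsd_length=4,
        seed=seed,
        copy_identity=copy_identity,
    )
    hits = scan({"G1": scaffold}, {"mite1": truth.mite_consensus})
    for h in hits:
        call_full_length(h)
        verify_tir_tsd(scaffold, h)
    return scaffold, truth, hits


class TestRoundTrip:
    def test_exact_copies_recovered_at_100_pct_identity(self):
        _, truth, hits = plant_and_scan(seed=11)
        full = [h for h in hits if h.full_length]
        assert len(full) == 3
        found = {(h.start, h.end) for h in full}
        planted = {(m.start, m.end) for m in truth.mites}
        assert found == planted
        for h in full:
            assert h.pct_identity == pytest.approx(100.0)
            assert h.strand == "+"

    def test_shuffled_scaffold_yields_no_hits(self):
        scaffold, truth, _ = plant_and_scan(seed=13)
        shuffled = list(scaffold)
        random.Random(0).shuffle(shuffled)  # same composition, no structure
        hits = scan({"G1": "".join(shuffled)}, {"mite1": truth.mite_consensus})
        assert [h for h in hits if call_full_length(h)] == []

    def test_diverged_copies_identity_near_target(self):
        _, truth, hits = plant_and_scan(seed=17, copy_identity=0.85)
        full = [h for h in hits if h.full_length]
        assert len(full) == 3
        mean_ident = sum(h.pct_identity for h in full) / len(full)
        assert abs(mean_ident - 85.0) < 5.0

    def test_reverse_strand_copy_found(self):
        scaffold, truth = plant_mites(4000, 1, 300, 20, 4, seed=19)
        (mp,) = truth.mites
        # scan with the reverse complement of the consensus as the query
        hits = scan({"G1": scaffold}, {"rcq": reverse_complement(truth.mite_consensus)})
        best = max(hits, key=lambda h: h.score)
        assert best.strand == "-"
        assert (best.start, best.end) == (mp.start, mp.end)

    def test_recall_and_false_positives_over_seeds(self):
        recalled, false_calls = 0, 0
        for seed in range(6):
            scaffold, truth, hits = plant_and_scan(
                seed=100 + seed, n_mites=2, copy_identity=0.9, scaffold_length=5000
            )
            full = {(h.start, h.end) for h in hits if h.full_length}
            planted = {(m.start, m.end) for m in truth.mites}
            recalled += len(full & planted)
            false_calls += len(full - planted)
        assert recalled == 12  # 100% recall of planted elements
        assert false_calls == 0


class TestFullLengthCall:
    def mk(self, start, end, q_span, qlen):
        return MiteHit("G1", "q", start, end, "+", 99.0, 500, 1e-30, q_span, qlen)

    def test_coverage_and_size_window(self):
        assert call_full_length(self.mk(0, 300, (0, 300), 300))
        assert not call_full_length(self.mk(0, 150, (0, 150), 300))  # 50% cov
        assert not call_full_length(self.mk(0, 90, (0, 90), 90))  # < 100 bp
        assert not call_full_length(self.mk(0, 700, (0, 700), 700))  # > 600 bp

    def test_coverage_boundary_exact(self):
        assert call_full_length(self.mk(0, 270, (0, 270), 300))  # exactly 90%
        assert not call_full_length(self.mk(0, 269, (0, 269), 300))

    def test_partial_copies_not_called(self):
        scaffold, truth = plant_mites(9000, 3, 300, 20, 4, seed=23)
        consensus = truth.mite_consensus
        # append two half-elements in free regions well away from the plants
        frag = consensus[: len(consensus) // 2]
        extended = scaffold + "ACGT" * 10 + frag + "TTTT" * 10 + frag
        hits = scan({"G1": extended}, {"mite1": consensus})
        full = [h for h in hits if call_full_length(h)]
        partial = [h for h in hits if not h.full_length and h.query_coverage > 0.3]
        assert len(full) == 3
        assert len(partial) >= 2


class TestTirTsd:
    def test_planted_structure_verified(self):
        scaffold, truth, hits = plant_and_scan(seed=29)
        for h in (h for h in hits if h.full_length):
            # the reported arm is the longest with <= 2 mismatches, so it is
            # at least the planted exact 20 bp arm and may extend past it
            assert h.tir_length >= 20
            assert h.tir_mismatches <= 2
            planted = next(m for m in truth.mites if m.start == h.start)
            assert h.tsd == planted.tsd
            assert h.tsd_reason is None

    def test_element_without_tir_flagged(self):
        rng = random.Random(5)
        scaffold = "".join(rng.choice("ACGT") for _ in range(600))
        hit = MiteHit("G1", "q", 100, 400, "+", 99.0, 500, 1e-30, (0, 300), 300)
        verify_tir_tsd(scaffold, hit, tir_min=10)
        assert (hit.tir_length or 0) < 10

    def test_mismatched_flanks_give_no_tsd(self):
        tir = "ACGTACGTACGTACGTACGT"
        element = tir + "A" * 260 + reverse_complement(tir)
        left, right = "GGCC", "GGCA"  # differ in one base -> no exact TSD
        scaffold = "T" * 100 + left + element + right + "T" * 100
        hit = MiteHit("G1", "q", 104, 404, "+", 100.0, 600, 1e-40, (0, 300), 300)
        verify_tir_tsd(scaffold, hit)
        assert hit.tir_length >= 20
        assert hit.tsd is None
        assert hit.tsd_reason == "no_exact_duplication"

    def test_contig_edge_reason(self):
        tir = "ACGTACGTACGTACGTACGT"
        element = tir + "A" * 260 + reverse_complement(tir)
        hit = MiteHit("G1", "q", 0, 300, "+", 100.0, 600, 1e-40, (0, 300), 300)
        verify_tir_tsd(element + "T" * 50, hit)
        assert hit.tsd is None
        assert hit.tsd_reason == "contig_edge"

    def test_tir_tolerates_up_to_two_mismatches(self):
        tir = "ACGTACGTACGTACGTACGT"
        right = list(reverse_complement(tir))
        right[3] = "A" if right[3] != "A" else "C"
        right[7] = "A" if right[7] != "A" else "C"
        element = tir + "G" * 260 + "".join(right)
        scaffold = "T" * 50 + "CCAA" + element + "CCAA" + "T" * 50
        hit = MiteHit("G1", "q", 54, 354, "+", 100.0, 600, 1e-40, (0, 300), 300)
        verify_tir_tsd(scaffold, hit)
        assert hit.tir_length >= 20
        assert hit.tir_mismatches <= 2
        assert hit.tsd == "CCAA"


class TestScanMechanics:
    def test_overlapping_hits_merged_keeping_higher_score(self):
        scaffold, truth = plant_mites(4000, 1, 300, 20, 4, seed=31)
        # two queries: the consensus and a 90% fragment of it; hits overlap
        consensus = truth.mite_consensus
        hits = scan(
            {"G1": scaffold}, {"full": consensus, "frag": consensus[:270]}
        )
        spans = [(h.start, h.end) for h in hits]
        # merged: at most one hit covering the planted locus
        (mp,) = truth.mites
        covering = [s for s in spans if s[0] < mp.end and s[1] > mp.start]
        assert len(covering) == 1
        best = next(h for h in hits if (h.start, h.end) == covering[0])
        assert best.query_id == "full"  # the longer query scores higher

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            scan({}, {"q": "ACGT"})
        with pytest.raises(ValueError):
            scan({"G1": "ACGT"}, {})
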