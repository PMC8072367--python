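import numpy as np
import pytest

from oracles import classify_states, elements_exhaustive, elements_scan
from ece_screen.conserved_caller import (
    CallerParams,
    call_elements,
    mask_intersect,
)
from ece_screen.genome_model import GenomicInterval, IntervalSet
from ece_screen.synthetic_data import random_track


def tad_for(track):
    return track.region


def spans(elements):
    return [(e.interval.start, e.interval.end) for e in elements]


class TestBasicRuns:
    def test_uniform_high_track_is_one_maximal_element(self, track_factory):
        t = track_factory([0.99] * 200)
        els = call_elements(t, CallerParams(tad=tad_for(t)))
        assert spans(els) == [(0, 200)]
        assert els[0].n_gap_bases == 0
        assert els[0].mean_score == pytest.approx(0.99)

    def test_all_subthreshold_yields_nothing(self, track_factory):
        t = track_factory([0.50] * 200)
        assert call_elements(t, CallerParams(tad=tad_for(t))) == []

    def test_threshold_is_inclusive_at_exactly_098(self, track_factory):
        t = track_factory([0.98] * 60)
        els = call_elements(t, CallerParams(tad=tad_for(t)))
        assert spans(els) == [(0, 60)]

    def test_low_scores_are_never_bridged(self, track_factory):
        # 60 good, 3 sub-threshold, 60 good: two elements, not one
        t = track_factory([0.99] * 60 + [0.979] * 3 + [0.99] * 60)
        els = call_elements(t, CallerParams(tad=tad_for(t)))
        assert spans(els) == [(0, 60), (63, 123)]


class TestGapBridging:
    def _gapped(self, track_factory):
        # 47 good / 5 missing / 48 good = 100 bases
        return track_factory([0.99] * 47 + [None] * 5 + [0.99] * 48)

    def test_interior_gap_within_max_gap_is_bridged(self, track_factory):
        t = self._gapped(track_factory)
        els = call_elements(t, CallerParams(tad=tad_for(t), max_gap=10))
        assert spans(els) == [(0, 100)]
        assert els[0].n_gap_bases == 5
        assert els[0].length == 100

    def test_gap_beyond_max_gap_splits_and_length_filter_applies(
        self, track_factory
    ):
        t = self._gapped(track_factory)
        # the 47/48 bp flanks fall below the 50 bp minimum
        els = call_elements(t, CallerParams(tad=tad_for(t), max_gap=4))
        assert els == []
        els = call_elements(
            t, CallerParams(tad=tad_for(t), max_gap=4, min_length=40)
        )
        assert spans(els) == [(0, 47), (52, 100)]

    def test_exact_boundary_max_gap_bridged_plus_one_not(self, track_factory):
        for gap, expected in [(10, [(0, 110)]), (11, [(0, 50), (61, 111)])]:
            vals = [0.99] * 50 + [None] * gap + [0.99] * 50
            t = track_factory(vals)
            els = call_elements(
                t, CallerParams(tad=tad_for(t), max_gap=10, min_length=50)
            )
            assert spans(els) == expected, f"gap={gap}"

    def test_elements_never_start_or_end_on_missing(self, track_factory):
        t = track_factory([None] * 5 + [0.99] * 60 + [None] * 5)
        els = call_elements(t, CallerParams(tad=tad_for(t)))
        assert spans(els) == [(5, 65)]

    def test_mean_score_excludes_gap_bases(self, track_factory):
        t = track_factory([1.0] * 30 + [None] * 4 + [0.98] * 30)
        els = call_elements(
            t, CallerParams(tad=tad_for(t), min_length=50, max_gap=5)
        )
        assert els[0].mean_score == pytest.approx((30 * 1.0 + 30 * 0.98) / 60)


class TestExonMask:
    def test_exon_splits_element_with_hard_break(self, track_factory):
        t = track_factory([0.99] * 300, start=0)
        mask = IntervalSet([GenomicInterval("chrT", 150, 160)], label="exons")
        els = call_elements(
            t, CallerParams(tad=tad_for(t), exon_mask=mask, min_length=50)
        )
        assert spans(els) == [(0, 150), (160, 300)]

    def test_exon_break_is_not_bridgeable(self, track_factory):
        # a 3 bp exon inside a good run: shorter than max_gap but still splits
        t = track_factory([0.99] * 120)
        mask = IntervalSet([GenomicInterval("chrT", 60, 63)], label="exons")
        els = call_elements(
            t, CallerParams(tad=tad_for(t), exon_mask=mask, max_gap=10)
        )
        assert spans(els) == [(0, 60), (63, 120)]

    def test_element_entirely_inside_exon_removed(self, track_factory):
        t = track_factory([0.5] * 20 + [0.99] * 60 + [0.5] * 20)
        mask = IntervalSet([GenomicInterval("chrT", 15, 90)], label="exons")
        assert call_elements(
            t, CallerParams(tad=tad_for(t), exon_mask=mask)
        ) == []

    def test_mask_intersect_set_difference(self):
        el = GenomicInterval("chr1", 100, 200)
        mask = IntervalSet([GenomicInterval("chr1", 150, 160)])
        pieces = mask_intersect([el], mask, min_length=40)
        assert [(p.start, p.end) for p in pieces] == [(100, 150), (160, 200)]
        # pieces below min_length dropped: (160, 200) is only 40 bp
        pieces = mask_intersect([el], mask, min_length=50)
        assert [(p.start, p.end) for p in pieces] == [(100, 150)]
        assert mask_intersect([el], mask, min_length=51) == []

    def test_mask_intersect_empty_mask_is_identity(self):
        el = GenomicInterval("chr1", 100, 200)
        assert mask_intersect([el], IntervalSet([])) == [el]


class TestErrors:
    def test_tad_outside_track_region(self, track_factory):
        t = track_factory([0.99] * 100)
        with pytest.raises(ValueError, match="outside"):
            call_elements(
                t, CallerParams(tad=GenomicInterval("chrT", 500, 600))
            )
        with pytest.raises(ValueError, match="outside"):
            call_elements(
                t, CallerParams(tad=GenomicInterval("chrX", 0, 100))
            )

    def test_invalid_params(self, track_factory):
        tad = GenomicInterval("chrT", 0, 100)
        with pytest.raises(ValueError):
            CallerParams(tad=tad, threshold=0.0)
        with pytest.raises(ValueError):
            CallerParams(tad=tad, threshold=1.2)
        with pytest.raises(ValueError):
            CallerParams(tad=tad, min_length=0)
        with pytest.raises(ValueError):
            CallerParams(tad=tad, max_gap=-1)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_enumerator_on_tiny_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 60))
        t = random_track(rng, n, p_missing=0.25, p_high=0.45)
        params = CallerParams(
            tad=t.region,
            min_length=int(rng.integers(1, 8)),
            max_gap=int(rng.integers(0, 5)),
        )
        got = spans(call_elements(t, params))
        states = classify_states(t.values, params.threshold)
        assert got == elements_exhaustive(states, params.min_length,
                                          params.max_gap)

    @pytest.mark.parametrize("seed", range(10))
    def test_scan_oracle_with_exon_masks(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 2000
        t = random_track(rng, n, p_missing=0.15, p_high=0.35)
        exons = []
        for _ in range(5):
            s = int(rng.integers(0, n - 50))
            exons.append(GenomicInterval("chrT", s, s + int(rng.integers(5, 50))))
        params = CallerParams(
            tad=t.region,
            min_length=20,
            max_gap=int(rng.integers(0, 8)),
            exon_mask=IntervalSet(exons, label="exons"),
        )
        got = spans(call_elements(t, params))
        states = classify_states(
            t.values, params.threshold,
            exon_spans=[(e.start, e.end) for e in exons],
        )
        expected = [
            (s, e) for s, e in
            elements_scan(states, params.min_length, params.max_gap)
        ]
        assert got == expected


class TestPlantedRecovery:
    def test_planted_blocks_recovered_with_exact_boundaries(self, track_factory):
        vals = [0.2] * 100 + [0.99] * 50 + [0.3] * 80 + [0.985] * 120 + [0.1] * 50
        t = track_factory(vals)
        els = call_elements(t, CallerParams(tad=tad_for(t)))
        assert spans(els) == [(100, 150), (230, 350)]
        assert [e.id for e in els] == ["CE1", "CE2"]

    def test_block_one_base_short_never_reported(self, track_factory):
        vals = [0.2] * 100 + [0.99] * 49 + [0.3] * 100
        t = track_factory(vals)
        assert call_elements(t, CallerParams(tad=tad_for(t))) == []

    def test_min_length_monotonicity(self):
        t = random_track(5, 3000, p_missing=0.2, p_high=0.4)
        counts = [
            len(call_elements(t, CallerParams(tad=t.region, min_length=m,
                                              max_gap=5)))
            for m in (1, 10, 25, 50, 100)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_determinism(self):
        t = random_track(9, 5000)
        p = CallerParams(tad=t.region)
        assert spans(call_elements(t, p)) == spans(call_elements(t, p))

    def test_restricted_to_tad(self, track_factory):
        t = track_factory([0.99] * 300)
        tad = GenomicInterval("chrT", 100, 200)
        els = call_elements(t, CallerParams(tad=tad))
        assert spans(els) == [(100, 200)]
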