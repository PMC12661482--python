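"""ROH callers: window scan, pruning, HMM, gap-merging, length filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hmm_path_oracle, ld_prune_oracle, window_scan_oracle
from rohbench.rohcall import (
    HmmParams,
    RohParams,
    RohSegment,
    call_roh_hmm,
    call_roh_window,
    filter_min_length,
    gap_merge,
    ld_prune,
)
from rohbench.seqsim import CalledGenotypes
from rohbench.synthpop import HET, HOM_ALT, HOM_REF, MISSING


def _called(pos, gts, individual="s1", chrom="chr1"):
    pos = np.asarray(pos, np.int64)
    return CalledGenotypes(
        individual, [chrom], {chrom: pos},
        {chrom: np.asarray(gts, np.int8)},
        {chrom: np.full(len(pos), 20, np.int64)},
    )


def random_instance(rng, max_sites=200):
    m = int(rng.integers(5, max_sites + 1))
    pos = np.cumsum(rng.integers(1, 40_000, size=m)).astype(np.int64)
    gt = rng.choice(
        [HOM_REF, HOM_ALT, HET, MISSING], size=m, p=[0.55, 0.25, 0.12, 0.08]
    ).astype(np.int8)
    p = RohParams(
        window_snps=int(rng.integers(3, 25)),
        window_het_allow=int(rng.integers(0, 3)),
        window_missing_allow=int(rng.integers(0, 4)),
        window_hit_threshold=float(rng.uniform(0.03, 0.9)),
        min_kb=float(rng.choice([5, 50, 200])),
        min_snps=int(rng.integers(2, 30)),
        density_kb_per_snp=float(rng.choice([10, 50, 1e6])),
        max_internal_gap_kb=float(rng.choice([20, 100, 1000])),
    )
    return pos, gt, p


class TestWindowCaller:
    def test_uniform_hom_run_single_segment(self):
        pos = np.arange(0, 3_000_000, 10_000, dtype=np.int64)  # 300 sites
        cg = _called(pos, [HOM_ALT] * len(pos))
        segs = call_roh_window(cg, RohParams())
        assert len(segs) == 1
        s = segs[0]
        assert s.start == 0 and s.end == pos[-1] + 1
        assert s.n_snps == len(pos)

    def test_alternating_het_hom_yields_nothing(self):
        pos = np.arange(0, 2_000_000, 5_000, dtype=np.int64)
        gts = [HET if i % 2 else HOM_REF for i in range(len(pos))]
        assert call_roh_window(_called(pos, gts), RohParams()) == []

    def test_contig_below_window_size_skipped(self):
        cg = _called([100, 200], [HOM_REF, HOM_REF])
        assert call_roh_window(cg, RohParams(window_snps=50)) == []

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(150):
            pos, gt, p = random_instance(rng)
            got = call_roh_window(_called(pos, gt), p)
            want = window_scan_oracle(pos, gt, p)
            assert [(s.start, s.end, s.n_snps) for s in got] == want


class TestLdPrune:
    def _params(self, **kw):
        base = dict(prune_window=50, prune_step_snps=1, prune_r2=0.8)
        base.update(kw)
        return RohParams(**base)

    def test_identical_columns_later_removed(self):
        gt = np.array([[0, 2, 1, 0], [0, 2, 1, 0], [2, 0, 0, 1]], np.int8)
        pos = np.array([10, 20, 30], np.int64)
        kept = ld_prune(gt, pos, self._params())
        assert list(kept) == [0, 2]

    def test_orthogonal_columns_survive(self):
        gt = np.array(
            [[2, 0, 0, 0], [0, 2, 0, 0], [0, 0, 2, 0], [0, 0, 0, 2]], np.int8
        ).T.copy()  # 4 sites x 4 samples, mutually weakly correlated
        # build explicitly: sites as rows
        gt = np.array(
            [[2, 0, 0, 0], [0, 2, 0, 0], [0, 0, 2, 0], [0, 0, 0, 2]], np.int8
        )
        pos = np.array([10, 20, 30, 40], np.int64)
        kept = ld_prune(gt, pos, self._params(prune_r2=0.5))
        assert list(kept) == [0, 1, 2, 3]

    def test_single_sample_noop(self):
        gt = np.array([[1], [1], [1]], np.int8)
        kept = ld_prune(gt, np.array([1, 2, 3], np.int64), self._params())
        assert list(kept) == [0, 1, 2]

    def test_pruning_disabled_by_default(self):
        gt = np.array([[0, 2], [0, 2]], np.int8)
        kept = ld_prune(gt, np.array([1, 2], np.int64), RohParams())
        assert list(kept) == [0, 1]

    @pytest.mark.parametrize("unit", ["snp", "kb"])
    def test_matches_greedy_oracle(self, rng, unit):
        for _ in range(60):
            m = int(rng.integers(2, 30))
            gt = rng.choice(
                [HOM_REF, HET, HOM_ALT, MISSING], size=(m, 8), p=[0.4, 0.25, 0.25, 0.1]
            ).astype(np.int8)
            pos = np.cumsum(rng.integers(1, 30_000, size=m)).astype(np.int64)
            p = RohParams(
                prune_window=int(rng.integers(2, 12)),
                prune_window_unit=unit,
                prune_step_snps=int(rng.integers(1, 4)),
                prune_r2=float(rng.uniform(0.2, 0.95)),
            )
            assert list(ld_prune(gt, pos, p)) == ld_prune_oracle(gt, pos, p)


class TestHmmCaller:
    def test_long_hom_run_single_segment(self):
        pos = np.arange(0, 1_000_000, 1_000, dtype=np.int64)
        cg = _called(pos, [HOM_REF] * len(pos))
        segs = call_roh_hmm(cg, HmmParams())
        assert len(segs) == 1
        assert segs[0].caller == "hmm"

    def test_equal_emissions_rejected(self):
        with pytest.raises(ValueError):
            HmmParams(p_het_in_roh=1e-3, p_het_outside=1e-3)

    def test_viterbi_matches_exhaustive_enumeration(self, rng):
        h = HmmParams(
            p_het_in_roh=0.01, p_het_outside=0.4,
            mean_roh_len=300_000, mean_non_roh_len=200_000,
        )
        for _ in range(40):
            m = int(rng.integers(2, 12))
            pos = np.cumsum(rng.integers(500, 200_000, size=m)).astype(np.int64)
            gt = rng.choice([HOM_REF, HET, MISSING], size=m, p=[0.6, 0.3, 0.1]).astype(np.int8)
            segs = call_roh_hmm(_called(pos, gt), h)
            path = np.ones(m, dtype=int)
            for s in segs:
                inside = (pos >= s.start) & (pos < s.end)
                path[inside] = 0
            assert list(path) == hmm_path_oracle(pos.tolist(), gt.tolist(), h)


def _seg(start_kb, end_kb, n_snps=50, ind="s1", contig="chr1"):
    return RohSegment(ind, contig, int(start_kb * 1000), int(end_kb * 1000), n_snps)


class TestGapMerge:
    def test_long_flank_bridges_short_gap(self):
        # 5 Mb + 3.77 Mb with a 300 kb gap: flank >= 4 Mb, gap <= 500 kb
        segs = [_seg(0, 5_000), _seg(5_300, 9_070)]
        merged = gap_merge(segs)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 9_070_000)
        assert merged[0].n_snps == 100

    def test_short_flanks_stay_fragmented(self):
        segs = [_seg(0, 3_000), _seg(3_300, 6_300)]
        assert len(gap_merge(segs)) == 2

    def test_long_gap_stays_fragmented(self):
        segs = [_seg(0, 5_000), _seg(5_600, 9_070)]
        assert len(gap_merge(segs)) == 2

    def test_single_segment_unchanged(self):
        segs = [_seg(0, 1_000)]
        assert gap_merge(segs) == segs

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gap_merge([_seg(0, 1_000), _seg(900, 2_000)])

    def test_chained_merging_reaches_fixpoint(self):
        # growing flank enables the next merge
        segs = [_seg(0, 4_100), _seg(4_200, 4_400), _seg(4_500, 4_700)]
        merged = gap_merge(segs)
        assert len(merged) == 1 and merged[0].end == 4_700_000

    @given(
        st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 60), st.integers(1, 50)),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_idempotent_and_length_nondecreasing(self, raw):
        # build sorted non-overlapping segments from (gap, length, snps) triples
        segs, cursor = [], 0
        for gap_kb, len_kb, n in raw:
            start = cursor + gap_kb * 1000 + 1
            segs.append(RohSegment("s1", "chr1", start, start + len_kb * 1000, n))
            cursor = start + len_kb * 1000
        once = gap_merge(segs)
        twice = gap_merge(once)
        assert once == twice
        assert sum(s.span for s in once) >= sum(s.span for s in segs)
        for a, b in zip(once, once[1:]):
            assert b.start >= a.end  # never overlapping


class TestFilterMinLength:
    def test_threshold_is_strict(self):
        kept = filter_min_length([_seg(0, 499), _seg(1_000, 1_501)], 500)
        assert [s.start for s in kept] == [1_000_000]

    def test_mixed_list_count(self, rng):
        segs = [_seg(i * 2_000, i * 2_000 + int(L)) for i, L in
                enumerate(rng.integers(100, 1_500, size=20))]
        kept = filter_min_length(segs, 500)
        assert len(kept) == sum(1 for s in segs if s.kb > 500)
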