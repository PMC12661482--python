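"""Gap insertion, contiguity statistics, fragmentation effects, divergence."""

import numpy as np
import pytest

from oracles import n50_oracle
from rohbench.reffrag import (
    ContigStats,
    FragmentationEffect,
    GapMap,
    apply_fragmentation,
    contig_stats,
    diverge_reference,
    fragment_to_ladder,
    insert_gaps,
)
from rohbench.seqsim import CalledGenotypes
from rohbench.synthpop import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneratorConfig,
    Reference,
    make_reference,
)

N = ord("N")


def _ref(n_contigs=1, contig_len=1_000_000, seed=21):
    return make_reference(GeneratorConfig(n_contigs=n_contigs, contig_len=contig_len, seed=seed))


class TestInsertGaps:
    def test_zero_insertions_identity(self):
        ref = _ref()
        out, gm = insert_gaps(ref, 0, seed=1)
        assert np.array_equal(out.seq("chr1"), ref.seq("chr1"))
        assert gm.n_gaps == 0

    def test_single_insertion_splits_contig(self):
        ref = _ref()
        out, gm = insert_gaps(ref, 1, gap_len=300, seed=1)
        assert int(np.sum(out.seq("chr1") == N)) == 300
        st = contig_stats(out)
        assert st.n_contigs == 2

    def test_coordinates_preserved_outside_gaps(self):
        ref = _ref()
        out, gm = insert_gaps(ref, 5, seed=2)
        mask = out.seq("chr1") != N
        assert np.array_equal(out.seq("chr1")[mask], ref.seq("chr1")[mask])
        assert len(out.seq("chr1")) == len(ref.seq("chr1"))

    def test_interval_bookkeeping(self):
        ref = _ref(contig_len=2_000_000)
        k = 10
        out, gm = insert_gaps(ref, k, gap_len=300, seed=3)
        st = contig_stats(out)
        assert st.n_contigs <= k + 1
        non_n = int(np.sum(out.seq("chr1") != N))
        assert non_n >= 2_000_000 - 300 * k
        assert non_n == 2_000_000 - gm.total_n_bases()

    def test_capacity_guard(self):
        ref = _ref(contig_len=1_000_000)
        with pytest.raises(Exception, match="capacity"):
            insert_gaps(ref, 5_000, gap_len=300, seed=1)


class TestContigStats:
    def test_single_contig(self):
        ref = _ref(contig_len=1_000_000)
        st = contig_stats(ref)
        assert st == ContigStats(1_000_000, 1_000_000, 1)

    def test_forced_definition(self):
        gm = GapMap({"chr1": np.array([[40, 41], [71, 72], [92, 93]])}, gap_len=1)
        ref = Reference([("chr1", np.full(103, ord("A"), np.uint8))])
        # segments 40, 30, 20, 10 -> cumulative 40, 70 >= 50 -> N50 = 30
        st = contig_stats(gm, ref)
        assert st.contig_n50 == 30 and st.max_contig == 40 and st.n_contigs == 4

    def test_random_segmentations_match_oracle(self, rng):
        for _ in range(200):
            segs = rng.integers(1, 10_000, size=rng.integers(1, 40)).tolist()
            seq = []
            for s in segs:
                seq.extend([ord("A")] * s)
                seq.append(N)
            ref = Reference([("chr1", np.array(seq[:-1], np.uint8))])
            assert contig_stats(ref).contig_n50 == n50_oracle(segs)

    def test_all_n_rejected(self):
        ref = Reference([("chr1", np.full(100, N, np.uint8))])
        with pytest.raises(ValueError):
            contig_stats(ref)


class TestLadder:
    def test_full_length_target_returns_unfragmented(self):
        ref = _ref(contig_len=2_000_000)
        ladder = fragment_to_ladder(ref, [2_000_000], seed=1)
        assert ladder[0][2].contig_n50 == 2_000_000

    def test_descending_targets_descending_achieved(self):
        ref = _ref(n_contigs=2, contig_len=5_000_000)
        targets = [10_000_000, 2_000_000, 600_000, 100_000]
        ladder = fragment_to_ladder(ref, targets, seed=2)
        achieved = [st.contig_n50 for _, _, st in ladder]
        assert achieved == sorted(achieved, reverse=True)
        for t, a in zip(targets[1:], achieved[1:]):
            assert t / 2 <= a <= t * 2

    def test_target_below_gap_resolution_rejected(self):
        from rohbench.synthpop import GenerationError

        ref = _ref(contig_len=1_000_000)
        with pytest.raises(GenerationError, match="resolution"):
            fragment_to_ladder(ref, [1_000], seed=0)

    def test_unsorted_targets_rejected(self):
        ref = _ref()
        with pytest.raises(ValueError):
            fragment_to_ladder(ref, [100_000, 500_000], seed=0)


def _called(pos, gts):
    pos = np.asarray(pos, np.int64)
    return CalledGenotypes(
        "s1", ["chr1"], {"chr1": pos},
        {"chr1": np.asarray(gts, np.int8)},
        {"chr1": np.full(len(pos), 20, np.int64)},
    )


class TestApplyFragmentation:
    def test_empty_gapmap_unchanged(self):
        cg = _called([10, 20, 30], [HOM_REF, HET, HOM_ALT])
        out = apply_fragmentation(cg, GapMap({}), FragmentationEffect(), seed=1)
        assert np.array_equal(out.gt["chr1"], cg.gt["chr1"])

    def test_site_inside_gap_becomes_missing(self):
        cg = _called([100, 5_000, 9_000], [HOM_REF, HOM_REF, HOM_REF])
        gm = GapMap({"chr1": np.array([[4_900, 5_200]])})
        out = apply_fragmentation(cg, gm, FragmentationEffect(edge_err=0.0), seed=1)
        assert out.gt["chr1"][1] == MISSING
        assert out.gt["chr1"][0] == HOM_REF and out.gt["chr1"][2] == HOM_REF

    def test_certain_edge_error_flips_genotypes(self):
        # het at a gap edge becomes hom; hom at the edge becomes het
        cg = _called([4_000, 6_000, 50_000], [HET, HOM_REF, HET])
        gm = GapMap({"chr1": np.array([[4_900, 5_200]])})
        fe = FragmentationEffect(edge_window=5_000, edge_err=1.0)
        out = apply_fragmentation(cg, gm, fe, seed=1)
        assert out.gt["chr1"][0] in (HOM_REF, HOM_ALT)
        assert out.gt["chr1"][1] == HET
        assert out.gt["chr1"][2] == HET  # far from the gap: untouched

    def test_input_not_mutated(self):
        cg = _called([5_000], [HOM_REF])
        gm = GapMap({"chr1": np.array([[4_900, 5_200]])})
        apply_fragmentation(cg, gm, FragmentationEffect(), seed=1)
        assert cg.gt["chr1"][0] == HOM_REF


class TestDivergeReference:
    def test_identity_at_zero(self):
        ref = _ref(contig_len=100_000)
        out, effect = diverge_reference(ref, 0.0, 0, seed=1)
        assert np.array_equal(out.seq("chr1"), ref.seq("chr1"))
        assert effect["implied_gapmap"].n_gaps == 0
        assert len(effect["subst_positions"]["chr1"]) == 0

    def test_breakpoint_count_in_effect_map(self):
        ref = _ref(contig_len=100_000)
        _, effect = diverge_reference(ref, 0.0, 7, seed=2)
        assert effect["implied_gapmap"].n_gaps == 7

    def test_substitution_rate(self):
        ref = _ref(contig_len=500_000)
        out, effect = diverge_reference(ref, 0.01, 0, seed=3)
        n_sub = int(np.sum(out.seq("chr1") != ref.seq("chr1")))
        assert abs(n_sub - 5_000) < 4 * np.sqrt(5_000)

    def test_rate_out_of_range(self):
        ref = _ref(contig_len=100_000)
        with pytest.raises(ValueError):
            diverge_reference(ref, 0.2, 0, seed=1)
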