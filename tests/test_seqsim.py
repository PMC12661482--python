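"""Read simulation coverage arithmetic and the pileup genotype caller."""

import numpy as np
import pytest

from rohbench.haplotypes import build_haplotypes
from rohbench.seqsim import (
    CallConfig,
    CalledGenotypes,
    ReadSim,
    expected_pairs_per_haplotype,
    het_dropout_closed_form,
    pileup_call,
    simulate_reads,
    snp_error_ratio,
    subsample_depth,
)
from rohbench.synthpop import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GeneratorConfig,
    VariantSet,
    make_reference,
)


@pytest.fixture(scope="module")
def one_mb_hp():
    cfg = GeneratorConfig(n_contigs=1, contig_len=1_000_000, seed=11)
    ref = make_reference(cfg)
    pos = np.arange(5_000, 995_000, 500, dtype=np.int64)  # dense het sites
    seq = ref.seq("chr1")
    rf = seq[pos]
    alt = np.where(rf == ord("A"), ord("C"), ord("A")).astype(np.uint8)
    gt = np.full((len(pos), 1), HET, np.int8)
    vs = VariantSet(["s1"], {"chr1": (pos, rf, alt, gt)})
    hp = build_haplotypes(ref, vs, "s1", seed=2)
    return ref, vs, hp


class TestSimulateReads:
    def test_pair_count_coverage_arithmetic(self, one_mb_hp):
        _, _, hp = one_mb_hp
        assert expected_pairs_per_haplotype(10.0, 1_000_000, 100) == 25_000
        rs = simulate_reads(hp, ReadSim(depth=10, read_len=100, seed=1))
        by_hap = rs.n_pairs_by_hap()
        assert by_hap == {"A": 25_000, "B": 25_000}
        assert rs.n_pairs == 50_000

    def test_mean_site_depth_matches_target(self, one_mb_hp):
        _, vs, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=10, read_len=100, seed=1))
        cg = pileup_call(rs, vs, hp, CallConfig(), seed=0)
        mean_depth = float(np.mean(cg.depth["chr1"]))
        se = np.sqrt(10.0 / len(cg.depth["chr1"])) * 3
        assert abs(mean_depth - 10.0) < max(3 * se, 0.1)

    def test_error_free_mates_match_source(self, one_mb_hp):
        _, _, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=0.01, read_len=50, seed=3))
        checked = 0
        for rec in rs.iter_pairs(hp):
            src = hp.haps[rec.contig][0 if rec.hap == "A" else 1]
            assert rec.mate1 == src[rec.start : rec.start + 50].tobytes()
            checked += 1
            if checked > 20:
                break
        assert checked > 0

    def test_haplotype_balance(self, one_mb_hp):
        _, _, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=10, seed=4))
        by_hap = rs.n_pairs_by_hap()
        total = by_hap["A"] + by_hap["B"]
        assert abs(by_hap["A"] - total / 2) <= 3 * np.sqrt(total / 4) + 1

    def test_read_len_exceeding_fragment_rejected(self):
        with pytest.raises(ValueError):
            ReadSim(depth=10, read_len=600, frag_mean=500)


class TestSubsample:
    def test_fraction_one_is_identity(self, one_mb_hp):
        _, _, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=5, seed=5))
        assert subsample_depth(rs, 1.0, seed=1) is rs

    def test_binomial_keep_count(self, one_mb_hp):
        _, _, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=10, seed=6))
        sub = subsample_depth(rs, 0.5, seed=2)
        n, k = rs.n_pairs, sub.n_pairs
        assert abs(k - 0.5 * n) < 2.6 * np.sqrt(n * 0.25)  # 99% CI

    def test_deterministic(self, one_mb_hp):
        _, _, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=5, seed=7))
        a = subsample_depth(rs, 0.3, seed=9)
        b = subsample_depth(rs, 0.3, seed=9)
        for key in rs.frags:
            assert np.array_equal(a.frags[key][0], b.frags[key][0])

    @pytest.mark.parametrize("frac", [0.0, 1.5, -0.2])
    def test_bad_fraction_rejected(self, one_mb_hp, frac):
        _, _, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=2, seed=8))
        with pytest.raises(ValueError):
            subsample_depth(rs, frac, seed=0)


class TestPileupCall:
    def test_high_depth_hets_called_het(self, one_mb_hp):
        _, vs, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=100, seed=10))
        cg = pileup_call(rs, vs, hp, CallConfig(), seed=1)
        truth = vs.genotypes("s1")["chr1"]
        err = np.mean(cg.gt["chr1"] != truth)
        assert err < 1e-3

    def test_single_read_below_min_depth_is_missing(self, one_mb_hp):
        _, vs, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=0.5, seed=11))
        cg = pileup_call(rs, vs, hp, CallConfig(min_depth=2), seed=1)
        gt, dp = cg.gt["chr1"], cg.depth["chr1"]
        assert np.all(gt[dp < 2] == MISSING)
        assert np.all(gt[dp >= 2] != MISSING)

    @pytest.mark.parametrize("depth", [2.0, 4.0, 6.0])
    def test_het_dropout_matches_closed_form(self, one_mb_hp, depth):
        _, vs, hp = one_mb_hp
        rs = simulate_reads(hp, ReadSim(depth=depth, seed=int(depth)))
        cc = CallConfig(min_depth=1)
        cg = pileup_call(rs, vs, hp, cc, seed=1)
        gt = cg.gt["chr1"]
        called = gt != MISSING
        n = int(called.sum())
        frac_hom = float(np.mean(gt[called] != HET))
        expect = het_dropout_closed_form(depth, cc.min_depth)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(frac_hom - expect) < 3 * se + 1e-9

    def test_base_err_creates_hom_to_het_errors(self, one_mb_hp):
        ref, vs, hp = one_mb_hp
        # all-hom-ref truth at the same sites
        pos, rf, alt, _ = vs.data["chr1"]
        vs0 = VariantSet(["s1"], {"chr1": (pos, rf, alt, np.zeros((len(pos), 1), np.int8))})
        hp0 = build_haplotypes(ref, vs0, "s1", seed=3)
        rs = simulate_reads(hp0, ReadSim(depth=30, seed=12))
        clean = pileup_call(rs, vs0, hp0, CallConfig(base_err=0.0), seed=1)
        noisy = pileup_call(rs, vs0, hp0, CallConfig(base_err=0.05), seed=1)
        assert np.all(clean.gt["chr1"] == HOM_REF)
        assert np.any(noisy.gt["chr1"] == HET)


class TestSnpErrorRatio:
    def _called(self, gts, vs):
        pos = vs.positions("chr1")
        return CalledGenotypes(
            "s1",
            ["chr1"],
            {"chr1": pos},
            {"chr1": np.asarray(gts, np.int8)},
            {"chr1": np.full(len(pos), 10, np.int64)},
        )

    def _vs(self, n=10):
        pos = np.arange(100, 100 + n * 100, 100, dtype=np.int64)
        rf = np.full(n, ord("A"), np.uint8)
        alt = np.full(n, ord("C"), np.uint8)
        gt = np.full((n, 1), HET, np.int8)
        return VariantSet(["s1"], {"chr1": (pos, rf, alt, gt)})

    def test_identical_calls_zero_error(self):
        vs = self._vs()
        cg = self._called([HET] * 10, vs)
        assert snp_error_ratio(cg, vs, "s1") == (0.0, 0.0)

    def test_two_of_ten_miscalled(self):
        vs = self._vs()
        cg = self._called([HET] * 8 + [HOM_ALT, HOM_REF], vs)
        err, miss = snp_error_ratio(cg, vs, "s1")
        assert err == pytest.approx(0.2)
        assert miss == 0.0

    def test_missing_counted_separately(self):
        vs = self._vs()
        cg = self._called([HET] * 5 + [MISSING] * 5, vs)
        err, miss = snp_error_ratio(cg, vs, "s1")
        assert err == 0.0 and miss == pytest.approx(0.5)

    def test_error_decreases_with_depth(self, one_mb_hp):
        _, vs, hp = one_mb_hp
        errs = []
        for depth in (2.0, 30.0):
            rs = simulate_reads(hp, ReadSim(depth=depth, seed=13))
            cg = pileup_call(rs, vs, hp, CallConfig(), seed=1)
            errs.append(snp_error_ratio(cg, vs, "s1")[0])
        assert errs[0] > errs[1]
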