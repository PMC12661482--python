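"""Error-free paired-end read simulation and origin-aware genotype calling.

Reads are drawn wgsim-style: fragments of Normal(frag_mean, frag_sd) length
placed uniformly along each haplotype, with the two mates read from the
fragment ends.  Because reads are simulated (not sequenced), each carries
its true origin, so genotypes can be called by an exact pileup without an
alignment stage: per site, reads from each haplotype contribute that
haplotype's allele.  Heterozygote->homozygote allele dropout then arises
naturally at low depth — a site covered by n reads shows only one haplotype
with probability 2^(1-n) — which is the mechanism behind the depth bias the
benchmark measures.

Depth accounting is diploid: ``depth`` is the pooled coverage of both
haplotypes, so each haplotype is simulated at depth/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .haplotypes import HaplotypePair
from .synthpop import HET, HOM_ALT, HOM_REF, MISSING, VariantSet

__all__ = [
    "ReadSim",
    "ReadSet",
    "ReadPairRecord",
    "CallConfig",
    "CalledGenotypes",
    "simulate_reads",
    "subsample_depth",
    "pileup_call",
    "snp_error_ratio",
]

log = logging.getLogger(__name__)

READ_LENGTHS = (30, 50, 75, 100, 150)


@dataclass(frozen=True)
class ReadSim:
    """wgsim-like simulation parameters (defaults mirror `-1 100 -2 100 -e 0`)."""

    depth: float = 20.0
    read_len: int = 100
    frag_mean: int = 500
    frag_sd: int = 50
    err_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_len > self.frag_mean:
            raise ValueError("read_len must not exceed frag_mean")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.err_rate < 1):
            raise ValueError("err_rate must lie in [0,1)")


@dataclass(frozen=True)
class ReadPairRecord:
    """One simulated pair; the id encodes the true origin, wgsim-style."""

    individual: str
    hap: str  # "A" or "B"
    contig: str
    start: int  # fragment start, 0-based
    frag_len: int
    mate1: bytes
    mate2: bytes  # reverse-complemented

    @property
    def name(self) -> str:
        return f"{self.individual}|{self.hap}|{self.contig}|{self.start}"


_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y


@dataclass
class ReadSet:
    """Column-oriented store of simulated pairs for one individual.

    Per (contig, haplotype): sorted fragment start positions and fragment
    lengths.  Mate 1 covers [start, start+read_len), mate 2 covers
    [start+frag_len-read_len, start+frag_len).
    """

    individual: str
    read_len: int
    frags: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return int(sum(len(s) for s, _ in self.frags.values()))

    def n_pairs_by_hap(self) -> dict[str, int]:
        out = {"A": 0, "B": 0}
        for (_, hap), (s, _) in self.frags.items():
            out[hap] += len(s)
        return out

    def iter_pairs(self, hp: HaplotypePair):
        """Materialise ReadPairRecords (small-scale export; mate2 revcomp)."""
        rl = self.read_len
        for (contig, hap), (starts, flens) in self.frags.items():
            seq = hp.haps[contig][0 if hap == "A" else 1]
            for s, f in zip(starts.tolist(), flens.tolist()):
                m1 = seq[s : s + rl].tobytes()
                m2 = _COMP[seq[s + f - rl : s + f]][::-1].tobytes()
                yield ReadPairRecord(self.individual, hap, contig, s, f, m1, m2)


def expected_pairs_per_haplotype(depth: float, hap_len: int, read_len: int) -> int:
    """Pair count per haplotype so pooled diploid coverage equals ``depth``."""
    return int(round(depth * hap_len / (2 * 2 * read_len)))


def simulate_reads(hp: HaplotypePair, sim: ReadSim) -> ReadSet:
    """Draw fragments uniformly along each haplotype of each contig."""
    rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 331007]))
    rs = ReadSet(hp.individual, sim.read_len)
    for contig, (a, b) in hp.haps.items():
        clen = len(a)
        if clen < sim.frag_mean:
            log.warning("contig %s shorter than frag_mean; skipped", contig)
            continue
        for hap in ("A", "B"):
            n = expected_pairs_per_haplotype(sim.depth, clen, sim.read_len)
            flen = np.rint(rng.normal(sim.frag_mean, sim.frag_sd, size=n)).astype(np.int64)
            np.clip(flen, 2 * sim.read_len, clen, out=flen)
            start = (rng.random(n) * (clen - flen + 1)).astype(np.int64)
            order = np.argsort(start, kind="stable")
            rs.frags[(contig, hap)] = (start[order], flen[order])
    return rs


def subsample_depth(rs: ReadSet, fraction: float, seed: int) -> ReadSet:
    """Bernoulli thinning of read pairs; expected depth scales by ``fraction``."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return rs
    rng = np.random.default_rng(np.random.SeedSequence([seed, 904523]))
    out = ReadSet(rs.individual, rs.read_len)
    for key, (starts, flens) in rs.frags.items():
        keep = rng.random(len(starts)) < fraction
        out.frags[key] = (starts[keep], flens[keep])
    return out


@dataclass(frozen=True)
class CallConfig:
    """Threshold genotype-calling rule applied to the exact pileup.

    ``min_depth`` reads are required for a call at all (fewer -> missing);
    an allele counts as observed once ``min_allele_reads`` reads carry it;
    ``base_err`` flips each read's allele at pileup (0 = error-free).
    """

    min_depth: int = 1
    min_allele_reads: int = 1
    base_err: float = 0.0

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class CalledGenotypes:
    """One individual's calls over a shared site list, with per-site depth."""

    individual: str
    chroms: list[str]
    pos: dict[str, np.ndarray]
    gt: dict[str, np.ndarray]  # int8 codes; MISSING where depth < min_depth
    depth: dict[str, np.ndarray]

    def copy(self) -> "CalledGenotypes":
        return CalledGenotypes(
            self.individual,
            list(self.chroms),
            {c: p.copy() for c, p in self.pos.items()},
            {c: g.copy() for c, g in self.gt.items()},
            {c: d.copy() for c, d in self.depth.items()},
        )


def _coverage_counts(
    starts: np.ndarray, flens: np.ndarray, sites: np.ndarray, read_len: int
) -> np.ndarray:
    """Reads (mates counted individually) overlapping each site position."""
    # mate1 [s, s+rl): covers p  <=>  s in (p-rl, p]
    n1 = np.searchsorted(starts, sites, side="right") - np.searchsorted(
        starts, sites - read_len, side="right"
    )
    # mate2 [e-rl, e) with e = s+f: covers p  <=>  e in (p, p+rl]
    ends = np.sort(starts + flens)
    n2 = np.searchsorted(ends, sites + read_len, side="right") - np.searchsorted(
        ends, sites, side="right"
    )
    return n1 + n2


def pileup_call(
    rs: ReadSet,
    vs: VariantSet,
    hp: HaplotypePair,
    cc: CallConfig = CallConfig(),
    seed: int = 0,
) -> CalledGenotypes:
    """Call genotypes at every VariantSet site from true read origins.

    Allele per read is its source haplotype's base, flipped with probability
    ``base_err``.  Genotype rule: depth < min_depth -> missing; both alleles
    observed >= min_allele_reads -> het; otherwise homozygote of the
    majority allele.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 662113]))
    j = vs.sample_index(rs.individual)
    pos_d, gt_d, dp_d = {}, {}, {}
    for chrom, (pos, _, _, gt_mat) in vs.data.items():
        if len(pos) and pos[-1] >= len(hp.haps[chrom][0]):
            raise ValueError(f"{chrom}: site outside contig bounds")
        truth = gt_mat[:, j]
        zero = np.zeros(0, dtype=np.int64)
        sa, fa = rs.frags.get((chrom, "A"), (zero, zero))
        sb, fb = rs.frags.get((chrom, "B"), (zero, zero))
        n_a = _coverage_counts(sa, fa, pos, rs.read_len)
        n_b = _coverage_counts(sb, fb, pos, rs.read_len)
        depth = n_a + n_b

        # reads carrying the alt allele, before sequencing error
        alt_on_a = hp.alt_on_a[chrom]
        alt_reads = np.where(
            truth == HOM_ALT, depth, np.where(truth == HET, np.where(alt_on_a, n_a, n_b), 0)
        )
        ref_reads = depth - alt_reads
        if cc.base_err > 0:
            flip_to_alt = rng.binomial(ref_reads, cc.base_err)
            flip_to_ref = rng.binomial(alt_reads, cc.base_err)
            alt_reads = alt_reads - flip_to_ref + flip_to_alt
            ref_reads = depth - alt_reads

        called = np.where(alt_reads >= ref_reads, HOM_ALT, HOM_REF).astype(np.int8)
        het = (alt_reads >= cc.min_allele_reads) & (ref_reads >= cc.min_allele_reads)
        called[het] = HET
        called[depth < cc.min_depth] = MISSING
        pos_d[chrom] = pos
        gt_d[chrom] = called
        dp_d[chrom] = depth
    return CalledGenotypes(rs.individual, list(vs.data), pos_d, gt_d, dp_d)


def snp_error_ratio(
    called: CalledGenotypes, truth: VariantSet, individual: str
) -> tuple[float, float]:
    """(error ratio, missingness rate) for one individual.

    Error ratio follows the depth-response convention: erroneously called
    SNPs over the number of SNPs genotyped (non-missing calls).  The
    missingness rate — sites with no call over all truth sites — is reported
    alongside.
    """
    j = truth.sample_index(individual)
    wrong = ngeno = nmiss = ntot = 0
    for chrom, (pos, _, _, gt_mat) in truth.data.items():
        t = gt_mat[:, j]
        c = called.gt[chrom]
        if len(c) != len(t):
            raise ValueError(f"{chrom}: call/truth site universes differ")
        nonmiss = c != MISSING
        wrong += int(np.count_nonzero(nonmiss & (c != t)))
        ngeno += int(np.count_nonzero(nonmiss))
        nmiss += int(np.count_nonzero(~nonmiss))
        ntot += len(t)
    if ntot == 0:
        return 0.0, 0.0
    return (wrong / ngeno if ngeno else 0.0), nmiss / ntot


def het_dropout_closed_form(depth: float, min_depth: int = 1) -> float:
    """P(het called hom | called) under Poisson(depth) site coverage.

    Sum over n >= min_depth of Pois(n; depth) * 2^(1-n), renormalised by
    P(n >= min_depth).
    """
    from scipy.stats import poisson

    n = np.arange(min_depth, max(int(depth * 6) + 20, 60))
    num = float(np.sum(poisson.pmf(n, depth) * 2.0 ** (1 - n)))
    den = float(poisson.sf(min_depth - 1, depth))
    return num / den
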