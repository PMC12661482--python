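"""Reference-genome degradation: contiguity ladders and divergence.

Contiguity is degraded by iterative random insertion of 300-bp N runs.  Ns
REPLACE bases (rather than extending the sequence) so that coordinates —
and therefore truth-ROH intervals and variant positions — remain valid
across the whole ladder; with coordinates preserved, the comparisons are
equivalent to insertion with a lift-over step.

Fragmentation acts on called genotypes as an error channel (the mapping
stage itself is not re-run): sites inside N runs become missing ("omitted")
and sites within an edge window of a gap boundary are flipped hom<->het
with a small probability ("erroneous"), which is the stated mechanism by
which low-contiguity references break long ROH during detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqsim import CalledGenotypes
from .synthpop import HET, HOM_ALT, HOM_REF, MISSING, GenerationError, Reference

__all__ = [
    "GapMap",
    "ContigStats",
    "FragmentationEffect",
    "insert_gaps",
    "contig_stats",
    "fragment_to_ladder",
    "apply_fragmentation",
    "diverge_reference",
]

_N = np.uint8(ord("N"))


@dataclass
class GapMap:
    """N-run intervals (0-based half-open) per contig of a fragmented reference."""

    runs: dict[str, np.ndarray] = field(default_factory=dict)
    gap_len: int = 300

    @property
    def n_gaps(self) -> int:
        return int(sum(len(r) for r in self.runs.values()))

    def total_n_bases(self) -> int:
        return int(sum((r[:, 1] - r[:, 0]).sum() for r in self.runs.values() if len(r)))


@dataclass(frozen=True)
class ContigStats:
    contig_n50: int
    max_contig: int
    n_contigs: int


@dataclass(frozen=True)
class FragmentationEffect:
    """Per-site error process near assembly gaps.

    ``edge_window`` bases on each side of a gap boundary see hom<->het flips
    with probability ``edge_err``; sites inside the gap itself are missing.
    """

    edge_window: int = 5_000
    edge_err: float = 0.02

    def __post_init__(self) -> None:
        if not (0 <= self.edge_err <= 1):
            raise ValueError("edge_err must lie in [0,1]")


def _runs_of_n(seq: np.ndarray) -> np.ndarray:
    mask = seq == _N
    if not mask.any():
        return np.zeros((0, 2), dtype=np.int64)
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        ends = np.concatenate([ends, [len(seq)]])
    return np.stack([starts, ends], axis=1).astype(np.int64)


def insert_gaps(
    ref: Reference, n_insertions: int, gap_len: int = 300, seed: int = 0
) -> tuple[Reference, GapMap]:
    """Replace ``gap_len`` bases with Ns at uniform non-N positions.

    Returns a new Reference (same coordinates) and the full GapMap of the
    result, including pre-existing N runs.
    """
    if gap_len < 1:
        raise ValueError("gap_len must be >= 1")
    new = ref.copy()
    lengths = np.array([new.length(n) for n in new.names], dtype=np.float64)
    if n_insertions * gap_len > 0.5 * lengths.sum():
        raise GenerationError("n_insertions exceeds genome capacity")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 118209]))
    if n_insertions > 0:
        p = lengths / lengths.sum()
        picks = rng.choice(len(lengths), size=n_insertions, p=p)
        for ci in picks:
            name, seq = new.contigs[ci]
            for _ in range(100):  # resample if landing on existing Ns
                s = int(rng.integers(0, len(seq) - gap_len + 1))
                if seq[s] != _N and seq[s + gap_len - 1] != _N:
                    seq[s : s + gap_len] = _N
                    break
    gm = GapMap({name: _runs_of_n(seq) for name, seq in new.contigs}, gap_len)
    return new, gm


def _segment_lengths(ref_or_gapmap, ref: Reference | None = None) -> np.ndarray:
    """Non-N segment lengths, from a Reference or a (GapMap, Reference) pair."""
    if isinstance(ref_or_gapmap, Reference):
        segs = []
        for _, seq in ref_or_gapmap.contigs:
            runs = _runs_of_n(seq)
            bounds = np.concatenate([[0], runs.ravel(), [len(seq)]])
            segs.append(bounds[1::2] - bounds[0::2])
        return np.concatenate(segs)
    gm: GapMap = ref_or_gapmap
    if ref is None:
        raise ValueError("contig lengths needed alongside a GapMap")
    segs = []
    for name in ref.names:
        runs = gm.runs.get(name, np.zeros((0, 2), dtype=np.int64))
        bounds = np.concatenate([[0], runs.ravel(), [ref.length(name)]])
        segs.append(bounds[1::2] - bounds[0::2])
    return np.concatenate(segs)


def contig_stats(ref_or_gapmap, ref: Reference | None = None) -> ContigStats:
    """Contig N50, longest contig and contig count of the non-N segments.

    N50 is the segment length at which the descending cumulative sum first
    reaches half the total non-N length.
    """
    seg = _segment_lengths(ref_or_gapmap, ref)
    seg = seg[seg > 0]
    if len(seg) == 0:
        raise ValueError("all-N reference has no contigs")
    seg = np.sort(seg)[::-1]
    half = seg.sum() / 2
    idx = int(np.searchsorted(np.cumsum(seg), half))
    return ContigStats(int(seg[idx]), int(seg[0]), int(len(seg)))


def fragment_to_ladder(
    ref: Reference, targets: list[int], seed: int = 0, gap_len: int = 300
) -> list[tuple[Reference, GapMap, ContigStats]]:
    """Iterative N-insertion cycles snapshotted to match a descending N50 ladder.

    Each cycle roughly doubles the number of contigs; for each target the
    snapshot with the closest achieved N50 (within a factor of two) is
    returned.  The unfragmented reference itself is snapshot 0.
    """
    if list(targets) != sorted(targets, reverse=True):
        raise ValueError("targets must be descending")
    snapshots = [(ref.copy(), GapMap({n: _runs_of_n(s) for n, s in ref.contigs}, gap_len))]
    stats = [contig_stats(ref)]
    lowest = min(targets)
    if lowest < 20 * gap_len:
        raise GenerationError("target N50 below gap-spacing resolution")
    current = ref
    cycle = 0
    while stats[-1].contig_n50 > lowest / 1.4 and cycle < 40:
        cycle += 1
        n_ins = max(4, stats[-1].n_contigs)
        current, gm = insert_gaps(current, n_ins, gap_len, seed=seed * 1000 + cycle)
        snapshots.append((current, gm))
        stats.append(contig_stats(current))

    out = []
    achieved = np.array([s.contig_n50 for s in stats], dtype=np.float64)
    for t in targets:
        k = int(np.argmin(np.abs(np.log(achieved / t))))
        if not (t / 2 <= achieved[k] <= t * 2):
            raise GenerationError(
                f"no snapshot within x2 of target N50 {t} (best {int(achieved[k])})"
            )
        out.append((snapshots[k][0], snapshots[k][1], stats[k]))
    return out


def _near_gap_masks(
    pos: np.ndarray, runs: np.ndarray, window: int
) -> tuple[np.ndarray, np.ndarray]:
    """(inside an N run, within ``window`` of a run boundary) per site."""
    if len(runs) == 0:
        z = np.zeros(len(pos), dtype=bool)
        return z, z
    starts, ends = runs[:, 0], runs[:, 1]
    k = np.searchsorted(ends, pos, side="right")  # index of first run ending after pos
    in_gap = (k < len(runs)) & (pos >= starts[np.minimum(k, len(runs) - 1)])
    wide_lo = np.searchsorted(ends + window, pos, side="right")
    near = (wide_lo < len(runs)) & (
        pos >= starts[np.minimum(wide_lo, len(runs) - 1)] - window
    )
    return in_gap, near & ~in_gap


def apply_fragmentation(
    called: CalledGenotypes,
    gm: GapMap,
    fe: FragmentationEffect = FragmentationEffect(),
    seed: int = 0,
) -> CalledGenotypes:
    """Degrade calls as a fragmented reference would.

    Sites inside N runs become missing; sites within ``fe.edge_window`` of a
    gap boundary are flipped hom<->het with probability ``fe.edge_err``
    (het -> hom-alt, hom -> het).  Coordinates are shared because gap
    insertion preserves them.
    """
    out = called.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 430817]))
    for chrom in out.chroms:
        runs = gm.runs.get(chrom, np.zeros((0, 2), dtype=np.int64))
        pos, gt = out.pos[chrom], out.gt[chrom]
        in_gap, near = _near_gap_masks(pos, runs, fe.edge_window)
        gt[in_gap] = MISSING
        flip = near & (gt != MISSING) & (rng.random(len(pos)) < fe.edge_err)
        was_het = flip & (gt == HET)
        was_hom = flip & ((gt == HOM_REF) | (gt == HOM_ALT))
        gt[was_het] = HOM_ALT
        gt[was_hom] = HET
    return out


def diverge_reference(
    ref: Reference, subst_rate: float, n_breakpoints: int, seed: int = 0
) -> tuple[Reference, dict]:
    """Phenomenological related-species reference.

    Substitutes bases at ``subst_rate`` and cuts the genome at
    ``n_breakpoints`` random positions, shuffling segment order and
    orientation ("mosaic-like collinearity").  The returned effect map is
    what downstream consumes: substituted positions appear as extra
    homozygous-difference sites, and the breakpoints act as an implied
    GapMap (zero-length runs) whose edge effects break long ROH exactly as
    a fragmented reference does.
    """
    if not (0 <= subst_rate <= 0.05):
        raise ValueError("subst_rate must lie in [0, 0.05]")
    if n_breakpoints < 0:
        raise ValueError("n_breakpoints must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 208911]))
    _BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

    subst: dict[str, np.ndarray] = {}
    new_contigs = []
    lengths = np.array([ref.length(n) for n in ref.names], dtype=np.float64)
    per_contig_bp = rng.multinomial(n_breakpoints, lengths / lengths.sum())
    implied = GapMap({}, gap_len=0)
    for (name, seq), nbp in zip(ref.contigs, per_contig_bp):
        seq = seq.copy()
        n_sub = rng.poisson(subst_rate * len(seq))
        sp = np.unique(rng.integers(0, len(seq), size=n_sub))
        shift = rng.integers(1, 4, size=len(sp)).astype(np.uint8)
        code = np.searchsorted(_BASES, seq[sp])
        seq[sp] = _BASES[(code + shift) % 4]
        subst[name] = sp

        cuts = np.sort(rng.integers(1, len(seq), size=nbp))
        implied.runs[name] = np.stack([cuts, cuts], axis=1).astype(np.int64)
        pieces = np.split(seq, cuts)
        if len(pieces) > 1:
            order = rng.permutation(len(pieces))
            pieces = [pieces[i][:: rng.choice([1, -1])] for i in order]
        new_contigs.append((name, np.concatenate(pieces)))

    effect = {"subst_positions": subst, "implied_gapmap": implied, "subst_rate": subst_rate}
    return Reference(new_contigs), effect
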