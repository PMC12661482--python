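"""Synthetic diploid genomes with planted runs of homozygosity (ROH).

The generator emulates a small inbred population: a multi-chromosome
reference, and one diploid individual per target inbreeding level.  Each
individual carries planted homozygous-by-descent intervals (the truth ROH)
whose total length over the genome matches its target F_ROH, heterozygous
SNPs as a Poisson process at rate ``het_rate_theta`` strictly outside the
ROH, and homozygous-alternate SNPs at rate ``hom_alt_rate_phi`` genome-wide
(so ROH contain informative homozygous sites, as real genomes do).

Coordinates are 0-based half-open internally; VCF/BED export shifts to the
respective standards.  All randomness flows from ``GeneratorConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Reference",
    "GeneratorConfig",
    "TruthROH",
    "VariantSet",
    "GenerationError",
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "make_reference",
    "plant_individual",
    "plant_population",
    "truth_f_roh",
    "DEFAULT_F_ROH_LEVELS",
]

# genotype codes used throughout the package
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")

#: the eight-level inbreeding ladder of the emulated study population
DEFAULT_F_ROH_LEVELS = (0.0566, 0.1237, 0.1717, 0.2210, 0.2841, 0.3543, 0.3854, 0.4773)


class GenerationError(RuntimeError):
    """Raised when planting cannot satisfy its target within bounded retries."""


@dataclass
class Reference:
    """A genome as an ordered list of named contigs.

    Sequences are stored as uint8 ASCII arrays over {A,C,G,T,N}; this is the
    shared coordinate system of every downstream stage.
    """

    contigs: list[tuple[str, np.ndarray]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for n, s in self.contigs:
            if len(s) == 0:
                raise ValueError(f"contig {n!r} is empty")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    @property
    def total_len(self) -> int:
        return int(sum(len(s) for _, s in self.contigs))

    def seq(self, name: str) -> np.ndarray:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(name)

    def length(self, name: str) -> int:
        return len(self.seq(name))

    def copy(self) -> "Reference":
        return Reference([(n, s.copy()) for n, s in self.contigs])


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic population.

    ``roh_length_mix`` is a list of ``(lo_bases, hi_bases, weight)`` length
    classes mirroring the reporting classes (0.5-1, 1-5, 5-10, 10-25 Mb);
    drawn lengths are capped at 60% of the longest contig so every class is
    usable on small genomes.
    """

    n_contigs: int = 2
    contig_len: int = 25_000_000
    het_rate_theta: float = 1e-3
    hom_alt_rate_phi: float = 1e-3
    roh_length_mix: tuple[tuple[int, int, float], ...] = (
        (500_000, 1_000_000, 0.25),
        (1_000_000, 5_000_000, 0.50),
        (5_000_000, 10_000_000, 0.20),
        (10_000_000, 25_000_000, 0.05),
    )
    target_f_roh_levels: tuple[float, ...] = DEFAULT_F_ROH_LEVELS
    min_roh_len: int = 500_000
    min_separation: int = 600_000  # keeps distinct truth ROH beyond the merge gap
    f_roh_tolerance: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.contig_len < 10_000:
            raise ValueError("need >=1 contig of >=10 kb")
        if not (0 < self.het_rate_theta < 1 and 0 < self.hom_alt_rate_phi < 1):
            raise ValueError("rates must lie in (0,1)")
        w = sum(w for _, _, w in self.roh_length_mix)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("roh_length_mix weights must sum to 1")
        for t in self.target_f_roh_levels:
            if not (0 <= t < 0.95):
                raise ValueError("target F_ROH must lie in [0, 0.95)")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class TruthROH:
    """Planted homozygous intervals for one individual (the ground truth).

    ``intervals`` maps contig name -> (k, 2) int array of sorted,
    non-overlapping 0-based half-open intervals.
    """

    individual: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    min_len: int = 500_000

    def total_length(self) -> int:
        return int(
            sum((iv[:, 1] - iv[:, 0]).sum() for iv in self.intervals.values() if len(iv))
        )

    def n_segments(self) -> int:
        return int(sum(len(iv) for iv in self.intervals.values()))

    def validate(self, ref: Reference) -> None:
        for chrom, iv in self.intervals.items():
            if len(iv) == 0:
                continue
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError(f"{self.individual}/{chrom}: empty interval")
            if np.any(iv[1:, 0] < iv[:-1, 1]):
                raise ValueError(f"{self.individual}/{chrom}: overlapping intervals")
            if np.any(iv[:, 1] - iv[:, 0] < self.min_len):
                raise ValueError(f"{self.individual}/{chrom}: interval below min_len")
            if iv[0, 0] < 0 or iv[-1, 1] > ref.length(chrom):
                raise ValueError(f"{self.individual}/{chrom}: interval out of bounds")


class VariantSet:
    """Sorted biallelic SNPs with per-sample genotypes.

    Per contig: ``pos`` (0-based, strictly increasing), ``ref``/``alt``
    (uint8 ASCII bases) and a genotype matrix ``gt`` of shape
    (n_sites, n_samples) with codes HOM_REF/HET/HOM_ALT/MISSING.
    """

    def __init__(
        self,
        samples: list[str],
        data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    ) -> None:
        self.samples = list(samples)
        self.data = data  # chrom -> (pos, ref, alt, gt)
        for chrom, (pos, ref, alt, gt) in data.items():
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: positions must be strictly increasing")
            if gt.shape != (len(pos), len(self.samples)):
                raise ValueError(f"{chrom}: genotype matrix shape mismatch")
            if len(pos) and np.any(ref == alt):
                raise ValueError(f"{chrom}: ref and alt allele identical")

    @property
    def chroms(self) -> list[str]:
        return list(self.data.keys())

    @property
    def n_sites(self) -> int:
        return int(sum(len(pos) for pos, *_ in self.data.values()))

    def sample_index(self, individual: str) -> int:
        try:
            return self.samples.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def genotypes(self, individual: str) -> dict[str, np.ndarray]:
        j = self.sample_index(individual)
        return {c: gt[:, j].copy() for c, (_, _, _, gt) in self.data.items()}

    def positions(self, chrom: str) -> np.ndarray:
        return self.data[chrom][0]

    def validate_against(self, ref: Reference) -> None:
        for chrom, (pos, rf, _, _) in self.data.items():
            seq = ref.seq(chrom)
            if len(pos) and (pos[0] < 0 or pos[-1] >= len(seq)):
                raise ValueError(f"{chrom}: variant position out of bounds")
            if len(pos) and np.any(seq[pos] != rf):
                bad = int(pos[np.nonzero(seq[pos] != rf)[0][0]])
                raise ValueError(f"{chrom}:{bad}: ref allele does not match reference base")


def make_reference(cfg: GeneratorConfig) -> Reference:
    """i.i.d.-uniform A/C/G/T contigs named chr1..chrN; deterministic per seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 982451]))
    contigs = []
    for i in range(cfg.n_contigs):
        seq = _BASES[rng.integers(0, 4, size=cfg.contig_len)]
        contigs.append((f"chr{i + 1}", seq))
    return Reference(contigs)


def _sample_roh_intervals(
    ref: Reference, target: float, cfg: GeneratorConfig, rng: np.random.Generator
) -> dict[str, list[tuple[int, int]]]:
    """Rejection-sample non-overlapping intervals until total/L hits target.

    Lengths come from the configured class mix; the final interval is cut to
    the exact remaining deficit (always >= min_roh_len by construction) so the
    realised F_ROH lands within tolerance of the target.
    """
    total_len = ref.total_len
    lengths = np.array([ref.length(n) for n in ref.names])
    cap = int(0.6 * lengths.max())
    deficit0 = int(round(target * total_len))
    tol = int(cfg.f_roh_tolerance * total_len)
    weights = np.array([w for _, _, w in cfg.roh_length_mix])
    pad = cfg.min_separation

    def draw_length() -> int:
        lo, hi, _ = cfg.roh_length_mix[rng.choice(len(weights), p=weights)]
        return min(int(rng.integers(lo, hi)), cap)

    def free_slots(placed) -> list[tuple[str, int, int]]:
        """Maximal regions where a new interval keeps >= pad to neighbours."""
        slots = []
        for name, clen in zip(ref.names, lengths):
            bounds = [0]
            for s, e in sorted(placed[name]):
                bounds.extend([s - pad, e + pad])
            bounds.append(int(clen))
            for a, b in zip(bounds[0::2], bounds[1::2]):
                if b - a >= cfg.min_roh_len:
                    slots.append((name, max(a, 0), min(b, int(clen))))
        return slots

    class _Stuck(Exception):
        pass

    def attempt() -> dict[str, list[tuple[int, int]]]:
        placed: dict[str, list[tuple[int, int]]] = {n: [] for n in ref.names}
        deficit = deficit0
        while deficit > tol:
            slots = free_slots(placed)
            if not slots:
                raise _Stuck
            max_slot = max(b - a for _, a, b in slots)
            length = draw_length()
            if deficit - length < cfg.min_roh_len:
                # cut the last interval to land exactly on target
                length = min(max(deficit, cfg.min_roh_len), cap)
                if length - deficit > tol:
                    raise _Stuck  # deficit below one-minimum-ROH resolution
            length = min(length, max_slot)
            feas = np.array([max(b - a - length + 1, 0) for _, a, b in slots])
            k = rng.choice(len(slots), p=feas / feas.sum())
            chrom, a, _ = slots[k]
            start = a + int(rng.integers(0, feas[k]))
            placed[chrom].append((start, start + length))
            deficit -= length
        return placed

    for _ in range(20):
        try:
            return attempt()
        except _Stuck:
            continue
    raise GenerationError(
        f"could not reach target F_ROH {target} with the configured length "
        f"mix and separation on contigs {ref.names}"
    )


def _sample_complement_positions(
    clen: int, roh: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n uniform positions over [0, clen) minus the ROH intervals."""
    if len(roh) == 0:
        return rng.integers(0, clen, size=n)
    bounds = np.concatenate([[0], roh.ravel(), [clen]])
    seg_lo, seg_hi = bounds[0::2], bounds[1::2]
    seg_len = seg_hi - seg_lo
    keep = seg_len > 0
    seg_lo, seg_len = seg_lo[keep], seg_len[keep]
    offs = np.concatenate([[0], np.cumsum(seg_len)])
    u = rng.integers(0, offs[-1], size=n)
    k = np.searchsorted(offs, u, side="right") - 1
    return seg_lo[k] + (u - offs[k])


def plant_individual(
    ref: Reference,
    target_f_roh: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    individual: str = "ind01",
) -> tuple[TruthROH, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    """Plant ROH plus SNPs for one individual.

    Returns the truth intervals and, per contig, ``(pos, gt, alt)`` arrays.
    Heterozygous sites never fall inside truth ROH; homozygous-alternate
    sites are planted genome-wide so ROH remain detectable by a window scan.
    """
    if not (0 <= target_f_roh < 0.95):
        raise ValueError("target_f_roh must lie in [0, 0.95)")
    if target_f_roh == 0.0:
        roh_map: dict[str, list[tuple[int, int]]] = {n: [] for n in ref.names}
    else:
        roh_map = _sample_roh_intervals(ref, target_f_roh, cfg, rng)

    truth = TruthROH(individual, min_len=cfg.min_roh_len)
    variants: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in ref.names:
        seq = ref.seq(chrom)
        clen = len(seq)
        iv = np.array(sorted(roh_map[chrom]), dtype=np.int64).reshape(-1, 2)
        truth.intervals[chrom] = iv
        roh_len = int((iv[:, 1] - iv[:, 0]).sum()) if len(iv) else 0

        n_het = rng.poisson(cfg.het_rate_theta * (clen - roh_len))
        het_pos = _sample_complement_positions(clen, iv, n_het, rng)
        n_hom = rng.poisson(cfg.hom_alt_rate_phi * clen)
        hom_pos = rng.integers(0, clen, size=n_hom)

        pos = np.concatenate([het_pos, hom_pos])
        gt = np.concatenate(
            [np.full(n_het, HET, np.int8), np.full(n_hom, HOM_ALT, np.int8)]
        )
        order = np.argsort(pos, kind="stable")
        pos, gt = pos[order], gt[order]
        keep = np.concatenate([[True], np.diff(pos) > 0])  # drop colliding sites
        pos, gt = pos[keep], gt[keep]

        # alt allele: uniform over the three non-reference bases
        refb = seq[pos]
        shift = rng.integers(1, 4, size=len(pos)).astype(np.uint8)
        code = np.searchsorted(_BASES, refb)
        alt = _BASES[(code + shift) % 4]
        variants[chrom] = (pos, gt, alt)

    truth.validate(ref)
    return truth, variants


def plant_population(
    ref: Reference, cfg: GeneratorConfig
) -> tuple[list[TruthROH], VariantSet]:
    """One individual per target level, merged into a multi-sample VariantSet.

    The site universe is the union across individuals; at sites an individual
    does not carry, its genotype is hom-ref (as in a jointly called VCF).
    """
    if not cfg.target_f_roh_levels:
        raise ValueError("need at least one target F_ROH level")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 771239]))
    samples = [f"ind{i + 1:02d}" for i in range(len(cfg.target_f_roh_levels))]
    truths, per_ind = [], []
    for name, target in zip(samples, cfg.target_f_roh_levels):
        truth, variants = plant_individual(ref, target, cfg, rng, individual=name)
        truths.append(truth)
        per_ind.append(variants)

    data = {}
    for chrom in ref.names:
        all_pos = np.concatenate([v[chrom][0] for v in per_ind])
        union = np.unique(all_pos)
        gt = np.zeros((len(union), len(samples)), dtype=np.int8)
        alt = np.zeros(len(union), dtype=np.uint8)
        seen = np.zeros(len(union), dtype=bool)
        for j, variants in enumerate(per_ind):
            pos, g, a = variants[chrom]
            idx = np.searchsorted(union, pos)
            gt[idx, j] = g
            first = ~seen[idx]
            alt[idx[first]] = a[first]  # first individual's alt wins (biallelic)
            seen[idx[first]] = True
        data[chrom] = (union, ref.seq(chrom)[union], alt, gt)
    return truths, VariantSet(samples, data)


def truth_f_roh(truth: TruthROH, ref: Reference) -> float:
    """Total planted ROH length (>= min_len intervals) over genome length."""
    truth.validate(ref)
    total = 0
    for iv in truth.intervals.values():
        if len(iv):
            ln = iv[:, 1] - iv[:, 0]
            total += int(ln[ln >= truth.min_len].sum())
    return total / ref.total_len
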