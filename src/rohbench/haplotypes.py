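"""Diploid-to-haploid genome construction for read simulation.

An individual's genotypes are substituted into the reference to produce two
full-length haploid sequences: homozygous-alternate sites carry the
alternate allele on both haplotypes, heterozygous sites on exactly one
(chosen by a seeded fair coin — the input is unphased, and phase is
irrelevant to ROH truth).  Missing genotypes leave the reference base
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthpop import HET, HOM_ALT, Reference, VariantSet

__all__ = ["HaplotypePair", "build_haplotypes", "rederive_genotypes"]


@dataclass
class HaplotypePair:
    """Two haploid sequences parallel to the reference, for one individual.

    ``alt_on_a`` records, per contig and variant site, whether the alternate
    allele of a heterozygous site landed on haplotype A (True) or B; it lets
    the pileup caller attribute alleles to read origins without sequence
    lookups.
    """

    individual: str
    haps: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (hapA, hapB)
    sites: dict[str, np.ndarray] = field(default_factory=dict)  # variant positions
    alt_on_a: dict[str, np.ndarray] = field(default_factory=dict)

    def lengths(self) -> dict[str, int]:
        return {c: len(a) for c, (a, _) in self.haps.items()}


def build_haplotypes(
    ref: Reference, vs: VariantSet, individual: str, seed: int
) -> HaplotypePair:
    """Substitute one individual's variants into the reference.

    Raises ``ValueError`` when a record's ref allele disagrees with the
    reference base at its position (with coordinates in the message).
    """
    vs.validate_against(ref)
    j = vs.sample_index(individual)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 550921]))
    haps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    sites: dict[str, np.ndarray] = {}
    alt_on_a: dict[str, np.ndarray] = {}
    for chrom, (pos, _, alt, gt) in vs.data.items():
        a = ref.seq(chrom).copy()
        b = a.copy()
        g = gt[:, j]
        hom = g == HOM_ALT
        a[pos[hom]] = alt[hom]
        b[pos[hom]] = alt[hom]
        het = g == HET
        coin = rng.random(int(het.sum())) < 0.5
        hp, ha = pos[het], alt[het]
        a[hp[coin]] = ha[coin]
        b[hp[~coin]] = ha[~coin]
        on_a = np.zeros(len(pos), dtype=bool)
        on_a[np.nonzero(het)[0][coin]] = True
        haps[chrom] = (a, b)
        sites[chrom] = pos
        alt_on_a[chrom] = on_a
    return HaplotypePair(individual, haps, sites, alt_on_a)


def rederive_genotypes(ref: Reference, hp: HaplotypePair) -> VariantSet:
    """Round-trip validator: scan haplotypes back into a one-sample VariantSet.

    Positions where both haplotypes differ identically from the reference
    become hom-alt; positions where exactly one differs become het.
    """
    data = {}
    for chrom, (a, b) in hp.haps.items():
        seq = ref.seq(chrom)
        if len(a) != len(seq) or len(b) != len(seq):
            raise ValueError(f"{chrom}: haplotype length does not match reference")
        diff = np.nonzero((a != seq) | (b != seq))[0]
        da, db = a[diff] != seq[diff], b[diff] != seq[diff]
        both = da & db
        if np.any(both & (a[diff] != b[diff])):
            raise ValueError(f"{chrom}: haplotypes disagree at a doubly-substituted site")
        gt = np.where(both, HOM_ALT, HET).astype(np.int8)[:, None]
        alt = np.where(da, a[diff], b[diff])
        data[chrom] = (diff, seq[diff], alt, gt)
    return VariantSet([hp.individual], data)
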