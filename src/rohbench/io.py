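"""Readers and writers for the standard formats the pipeline touches.

FASTA (60-column wrap), BED (0-based half-open), minimal VCF v4.2 with
diploid unphased GT (+DP for called genotypes), paired FASTQ with origin-
encoding read names, and the ``.hom``-style segment table.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .reffrag import ContigStats, GapMap
from .rohcall import RohSegment
from .seqsim import CalledGenotypes, ReadSet
from .synthpop import HET, HOM_ALT, HOM_REF, MISSING, Reference, TruthROH, VariantSet

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "write_vcf",
    "read_vcf",
    "write_fastq_pair",
    "write_hom",
    "read_hom",
    "write_ladder_tsv",
]

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_fasta(ref: Reference, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.contigs:
            fh.write(f">{name}\n")
            raw = seq.tobytes().decode("ascii")
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> Reference:
    from pyfaidx import Fasta

    fa = Fasta(str(path), as_raw=True, rebuild=True)
    contigs = [
        (name, np.frombuffer(str(fa[name][:]).upper().encode(), dtype=np.uint8).copy())
        for name in fa.keys()
    ]
    return Reference(contigs)


def write_bed(truth: TruthROH, path: str | os.PathLike) -> None:
    """One truth-ROH BED per individual, 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, iv in truth.intervals.items():
            for a, b in iv.tolist():
                fh.write(f"{chrom}\t{a}\t{b}\t{truth.individual}\n")


def read_bed(path: str | os.PathLike, individual: str, min_len: int = 500_000) -> TruthROH:
    truth = TruthROH(individual, min_len=min_len)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    for chrom, sub in df.groupby("chrom", sort=False):
        truth.intervals[str(chrom)] = sub[["start", "end"]].to_numpy(dtype=np.int64)
    return truth


def write_vcf(
    vs: VariantSet,
    path: str | os.PathLike,
    ref: Reference | None = None,
    depths: dict[str, np.ndarray] | None = None,
) -> None:
    """Minimal VCF v4.2; positions are 1-based on export."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohbench\n")
        if ref is not None:
            for name in ref.names:
                fh.write(f"##contig=<ID={name},length={ref.length(name)}>\n")
        else:
            for name in vs.chroms:
                fh.write(f"##contig=<ID={name}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vs.samples) + "\n")
        fmt = "GT:DP" if depths is not None else "GT"
        for chrom, (pos, rf, alt, gt) in vs.data.items():
            dp = depths.get(chrom) if depths is not None else None
            for k in range(len(pos)):
                cols = [
                    chrom,
                    str(int(pos[k]) + 1),
                    ".",
                    chr(rf[k]),
                    chr(alt[k]),
                    ".",
                    "PASS",
                    ".",
                    fmt,
                ]
                for j in range(len(vs.samples)):
                    g = _GT_STR[int(gt[k, j])]
                    cols.append(f"{g}:{int(dp[k])}" if dp is not None else g)
                fh.write("\t".join(cols) + "\n")


def read_vcf(path: str | os.PathLike) -> VariantSet:
    """Read a (single- or multi-sample) SNP VCF into a VariantSet."""
    from cyvcf2 import VCF

    v = VCF(str(path), gts012=True)
    samples = list(v.samples)
    rows: dict[str, list] = {}
    for rec in v:
        if not rec.is_snp or len(rec.ALT) != 1:
            continue
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        rows.setdefault(rec.CHROM, []).append(
            (rec.POS - 1, ord(rec.REF), ord(rec.ALT[0]), g)
        )
    data = {}
    for chrom, entries in rows.items():
        entries.sort(key=lambda e: e[0])
        pos = np.array([e[0] for e in entries], dtype=np.int64)
        rf = np.array([e[1] for e in entries], dtype=np.uint8)
        alt = np.array([e[2] for e in entries], dtype=np.uint8)
        gt = np.stack([e[3] for e in entries])
        data[chrom] = (pos, rf, alt, gt)
    return VariantSet(samples, data)


def called_to_variantset(cg: CalledGenotypes, vs: VariantSet) -> VariantSet:
    """Wrap one individual's calls as a single-sample VariantSet for export."""
    data = {}
    for chrom, (pos, rf, alt, _) in vs.data.items():
        data[chrom] = (pos, rf, alt, cg.gt[chrom][:, None])
    return VariantSet([cg.individual], data)


def write_fastq_pair(
    rs: ReadSet, hp, prefix: str | os.PathLike, qual_char: str = "I"
) -> tuple[Path, Path]:
    """Paired FASTQ `<prefix>_1.fq` / `<prefix>_2.fq` (Phred 33, constant Q)."""
    p1, p2 = Path(f"{prefix}_1.fq"), Path(f"{prefix}_2.fq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rec in rs.iter_pairs(hp):
            q = qual_char * rs.read_len
            f1.write(f"@{rec.name}/1\n{rec.mate1.decode()}\n+\n{q}\n")
            f2.write(f"@{rec.name}/2\n{rec.mate2.decode()}\n+\n{q}\n")
    return p1, p2


def segments_frame(segs: list[RohSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "IID": s.individual,
                "CHR": s.contig,
                "POS1": s.start + 1,  # 1-based inclusive, .hom convention
                "POS2": s.end,
                "KB": s.kb,
                "NSNP": s.n_snps,
                "CALLER": s.caller,
            }
            for s in segs
        ],
        columns=["IID", "CHR", "POS1", "POS2", "KB", "NSNP", "CALLER"],
    )


def write_hom(segs: list[RohSegment], path: str | os.PathLike) -> None:
    segments_frame(segs).to_csv(path, sep="\t", index=False)


def read_hom(path: str | os.PathLike) -> list[RohSegment]:
    df = pd.read_csv(path, sep="\t")
    return [
        RohSegment(
            r.IID, r.CHR, int(r.POS1) - 1, int(r.POS2), int(r.NSNP), str(r.CALLER)
        )
        for r in df.itertuples()
    ]


def write_ladder_tsv(
    ladder: list[tuple[Reference, GapMap, ContigStats]], path: str | os.PathLike
) -> None:
    rows = [
        {
            "level": i,
            "n50": st.contig_n50,
            "max_contig": st.max_contig,
            "n_contigs": st.n_contigs,
        }
        for i, (_, _, st) in enumerate(ladder)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
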