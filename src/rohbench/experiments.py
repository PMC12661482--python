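"""Experiment drivers: the four sweep groups and the parameter grids.

Each driver chains the full pipeline — plant population, build haplotypes,
simulate reads, (subsample,) pileup-call, optionally degrade for reference
contiguity, scan for ROH, gap-merge, length-filter, summarise — and returns
a tidy DataFrame with one row per (axis value, individual, seed) cell.

Depth ladders are realised by Bernoulli-subsampling a single master read
set per (seed, individual) rather than independent simulations, preserving
across-depth correlation; a sweep run at its master depth is therefore
byte-identical to a direct simulation at that depth, which keeps shared
cells consistent across sweep groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import HaplotypePair, build_haplotypes
from .metrics import LENGTH_CLASS_LABELS, summarize
from .reffrag import FragmentationEffect, apply_fragmentation, fragment_to_ladder
from .rohcall import RohParams, call_roh_window, filter_min_length, gap_merge, ld_prune
from .seqsim import (
    CallConfig,
    CalledGenotypes,
    ReadSim,
    pileup_call,
    simulate_reads,
    snp_error_ratio,
    subsample_depth,
)
from .synthpop import GeneratorConfig, Reference, TruthROH, VariantSet, plant_population

__all__ = [
    "SweepSpec",
    "run_depth_sweep",
    "run_n50_sweep",
    "run_readlen_sweep",
    "run_divergence_sweep",
    "run_param_grid",
    "presets",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: an axis, replicate seeds, and the shared base configs."""

    group: str
    axis: tuple = ()
    seeds: tuple[int, ...] = (0,)
    gen: GeneratorConfig = field(default_factory=GeneratorConfig)
    roh: RohParams = field(default_factory=RohParams)
    call: CallConfig = field(default_factory=CallConfig)
    frag_effect: FragmentationEffect = field(default_factory=FragmentationEffect)
    read_len: int = 100
    fixed_depth: float = 20.0
    merge_gap_kb: float = 500.0
    merge_flank_kb: float = 4000.0
    overlap_q: float = 0.9

    def __post_init__(self) -> None:
        if len(self.axis) < 1:
            raise ValueError("sweep needs at least one axis value")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def _postprocess(segs, spec: SweepSpec, merge: bool = True):
    if merge:
        segs = gap_merge(segs, spec.merge_gap_kb, spec.merge_flank_kb)
    return filter_min_length(segs, spec.roh.min_kb)


def _cell_row(spec, axis_value, seed, rep, extra=None) -> dict:
    row = {
        "group": spec.group,
        "axis": axis_value,
        "seed": seed,
        "individual": rep.individual,
        "f_roh_true": rep.f_roh_true,
        "f_roh": rep.f_roh,
        "f_roh_error_ratio": rep.f_roh_error_ratio,
        "mean_roh_len": rep.mean_roh_len,
        "n_segments": rep.n_segments,
        "snp_error_ratio": rep.snp_error_ratio,
        "missing_rate": rep.missing_rate,
        "error": "",
    }
    for lab in LENGTH_CLASS_LABELS:
        row[f"n_{lab}"] = rep.class_counts[lab]
    if extra:
        row.update(extra)
    return row


def _error_row(spec, axis_value, seed, individual, exc) -> dict:
    log.error("cell (%s, %s, %s) failed: %s", axis_value, individual, seed, exc)
    return {
        "group": spec.group,
        "axis": axis_value,
        "seed": seed,
        "individual": individual,
        "error": f"{type(exc).__name__}: {exc}",
    }


def _plant(spec: SweepSpec, seed: int) -> tuple[Reference, list[TruthROH], VariantSet]:
    from .synthpop import make_reference

    cfg = spec.gen.with_seed(seed)
    ref = make_reference(cfg)
    truths, vs = plant_population(ref, cfg)
    return ref, truths, vs


def _reads_and_calls(
    spec: SweepSpec,
    ref: Reference,
    vs: VariantSet,
    truth: TruthROH,
    seed: int,
    depth: float,
    read_len: int,
) -> tuple[HaplotypePair, "object"]:
    idx = vs.sample_index(truth.individual)
    hp = build_haplotypes(ref, vs, truth.individual, seed=_child_seed(seed, idx, 11))
    sim = ReadSim(
        depth=depth, read_len=read_len, seed=_child_seed(seed, idx, 17)
    )
    rs = simulate_reads(hp, sim)
    return hp, rs


def run_depth_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Depth response at a perfect reference (the 2x-100x axis)."""
    rows = []
    master = float(max(spec.axis))
    for seed in spec.seeds:
        ref, truths, vs = _plant(spec, seed)
        for truth in truths:
            try:
                hp, rs = _reads_and_calls(
                    spec, ref, vs, truth, seed, master, spec.read_len
                )
            except Exception as exc:  # pragma: no cover - defensive
                rows.extend(_error_row(spec, d, seed, truth.individual, exc) for d in spec.axis)
                continue
            for depth in spec.axis:
                try:
                    sub = subsample_depth(
                        rs, float(depth) / master, seed=_child_seed(seed, int(depth * 10), 23)
                    )
                    cg = pileup_call(sub, vs, hp, spec.call, seed=_child_seed(seed, 29))
                    segs = _postprocess(call_roh_window(cg, spec.roh), spec)
                    err, miss = snp_error_ratio(cg, vs, truth.individual)
                    rep = summarize(
                        truth.individual, segs, truth, ref, err, miss, spec.overlap_q
                    )
                    realized = float(
                        np.mean(np.concatenate([cg.depth[c] for c in cg.chroms]))
                    )
                    rows.append(
                        _cell_row(spec, depth, seed, rep, {"realized_depth": realized})
                    )
                except Exception as exc:
                    rows.append(_error_row(spec, depth, seed, truth.individual, exc))
    return pd.DataFrame(rows)


def run_n50_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Contiguity response at fixed depth along a descending N50 ladder.

    Axis values are target N50s in bases; each cell is reported both with
    and without gap-merging (column ``gap_merged``).
    """
    rows = []
    for seed in spec.seeds:
        ref, truths, vs = _plant(spec, seed)
        ladder = fragment_to_ladder(ref, list(spec.axis), seed=_child_seed(seed, 37))
        for truth in truths:
            hp, rs = _reads_and_calls(
                spec, ref, vs, truth, seed, spec.fixed_depth, spec.read_len
            )
            cg0 = pileup_call(rs, vs, hp, spec.call, seed=_child_seed(seed, 29))
            for target, (_, gm, st) in zip(spec.axis, ladder):
                try:
                    cg = apply_fragmentation(
                        cg0, gm, spec.frag_effect, seed=_child_seed(seed, st.n_contigs, 41)
                    )
                    raw = call_roh_window(cg, spec.roh)
                    err, miss = snp_error_ratio(cg, vs, truth.individual)
                    for merged in (True, False):
                        segs = _postprocess(raw, spec, merge=merged)
                        rep = summarize(
                            truth.individual, segs, truth, ref, err, miss, spec.overlap_q
                        )
                        rows.append(
                            _cell_row(
                                spec,
                                target,
                                seed,
                                rep,
                                {
                                    "achieved_n50": st.contig_n50,
                                    "max_contig": st.max_contig,
                                    "n_contigs": st.n_contigs,
                                    "gap_merged": merged,
                                    "truth_segments": truth.n_segments(),
                                },
                            )
                        )
                except Exception as exc:
                    rows.append(_error_row(spec, target, seed, truth.individual, exc))
    return pd.DataFrame(rows)


def run_readlen_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Read-length comparison at fixed depth; same seeds across lengths."""
    for rl in spec.axis:
        if rl > ReadSim().frag_mean:
            raise ValueError(f"read length {rl} exceeds fragment mean")
    rows = []
    for seed in spec.seeds:
        ref, truths, vs = _plant(spec, seed)
        for truth in truths:
            for rl in spec.axis:
                try:
                    hp, rs = _reads_and_calls(
                        spec, ref, vs, truth, seed, spec.fixed_depth, int(rl)
                    )
                    cg = pileup_call(rs, vs, hp, spec.call, seed=_child_seed(seed, 29))
                    segs = _postprocess(call_roh_window(cg, spec.roh), spec)
                    err, miss = snp_error_ratio(cg, vs, truth.individual)
                    rep = summarize(
                        truth.individual, segs, truth, ref, err, miss, spec.overlap_q
                    )
                    rows.append(_cell_row(spec, int(rl), seed, rep))
                except Exception as exc:
                    rows.append(_error_row(spec, int(rl), seed, truth.individual, exc))
    return pd.DataFrame(rows)


def run_divergence_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Related-species-reference emulation: axis = number of breakpoints."""
    from .reffrag import diverge_reference

    rows = []
    for seed in spec.seeds:
        ref, truths, vs = _plant(spec, seed)
        for truth in truths:
            hp, rs = _reads_and_calls(
                spec, ref, vs, truth, seed, spec.fixed_depth, spec.read_len
            )
            cg0 = pileup_call(rs, vs, hp, spec.call, seed=_child_seed(seed, 29))
            for nbp in spec.axis:
                try:
                    _, effect = diverge_reference(
                        ref, 0.0, int(nbp), seed=_child_seed(seed, int(nbp), 43)
                    )
                    cg = apply_fragmentation(
                        cg0,
                        effect["implied_gapmap"],
                        spec.frag_effect,
                        seed=_child_seed(seed, int(nbp), 47),
                    )
                    segs = _postprocess(call_roh_window(cg, spec.roh), spec)
                    rep = summarize(
                        truth.individual, segs, truth, ref,
                        overlap_q=spec.overlap_q,
                    )
                    rows.append(_cell_row(spec, int(nbp), seed, rep))
                except Exception as exc:
                    rows.append(_error_row(spec, int(nbp), seed, truth.individual, exc))
    return pd.DataFrame(rows)


def _population_call_matrix(
    cgs: list[CalledGenotypes], vs: VariantSet
) -> dict[str, np.ndarray]:
    """Stack per-individual calls into (n_sites, n_samples) per contig."""
    return {
        chrom: np.stack([cg.gt[chrom] for cg in cgs], axis=1) for chrom in vs.chroms
    }


def _restrict_sites(cg: CalledGenotypes, kept: dict[str, np.ndarray]) -> CalledGenotypes:
    out = cg.copy()
    for chrom, idx in kept.items():
        out.pos[chrom] = out.pos[chrom][idx]
        out.gt[chrom] = out.gt[chrom][idx]
        out.depth[chrom] = out.depth[chrom][idx]
    return out


def run_param_grid(spec: SweepSpec) -> tuple[pd.DataFrame, RohParams]:
    """Axis-wise parameter grid at a fixed degraded condition (default 5x).

    ``spec.axis`` holds (name, RohParams) pairs.  Returns the tidy result
    plus the setting with the smallest mean |F_ROH error ratio|.
    """
    if not spec.axis:
        raise ValueError("empty parameter grid")
    rows = []
    for seed in spec.seeds:
        ref, truths, vs = _plant(spec, seed)
        cgs, hps = [], []
        for truth in truths:
            hp, rs = _reads_and_calls(
                spec, ref, vs, truth, seed, spec.fixed_depth, spec.read_len
            )
            cgs.append(pileup_call(rs, vs, hp, spec.call, seed=_child_seed(seed, 29)))
            hps.append(hp)
        popmat = _population_call_matrix(cgs, vs)
        for name, params in spec.axis:
            kept = {
                chrom: ld_prune(popmat[chrom], vs.positions(chrom), params)
                for chrom in vs.chroms
            }
            for truth, cg in zip(truths, cgs):
                try:
                    cgk = _restrict_sites(cg, kept)
                    segs = _postprocess(call_roh_window(cgk, params), spec)
                    rep = summarize(
                        truth.individual, segs, truth, ref, overlap_q=spec.overlap_q
                    )
                    rows.append(_cell_row(spec, name, seed, rep))
                except Exception as exc:
                    rows.append(_error_row(spec, name, seed, truth.individual, exc))
    df = pd.DataFrame(rows)
    ok = df[df["error"] == ""]
    score = (
        ok.assign(abs_err=ok["f_roh_error_ratio"].abs())
        .groupby("axis")["abs_err"]
        .mean()
        .sort_values()
    )
    best_name = score.index[0]
    best = dict(spec.axis)[best_name]
    return df, best


def presets() -> dict[str, RohParams]:
    """Named parameter presets.

    - ``plink_default``: the tool's documented defaults (window 50 SNPs,
      100 SNPs / 1000 kb minimum run, density 50 kb/SNP, no pruning).
    - ``lowdepth``: the low-coverage recommendation — pruning 50/1/0.8,
      80-SNP windows, 150-SNP minimum.
    - ``lowdepth_highF``: as above with 70-SNP windows for highly inbred
      individuals (F_ROH around 50%).
    - ``fragmented_ref``: 12-SNP windows for references with contig N50
      below ~100 kb, other knobs at the low-depth optimum.
    """
    base = RohParams()
    return {
        "plink_default": base,
        "lowdepth": base.updated(
            prune_window=50, prune_step_snps=1, prune_r2=0.8, window_snps=80, min_snps=150
        ),
        "lowdepth_highF": base.updated(
            prune_window=50, prune_step_snps=1, prune_r2=0.8, window_snps=70, min_snps=150
        ),
        "fragmented_ref": base.updated(
            prune_window=50, prune_step_snps=1, prune_r2=0.8, window_snps=12, min_snps=150
        ),
    }
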