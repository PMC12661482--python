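"""Independent brute-force oracles used by the test suite.

Everything here is written as literal, loop-based enumeration — windows
materialised one by one, all state paths enumerated, segments sorted by
hand — deliberately sharing no code path with the package implementations
they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


def n50_oracle(segments: list[int]) -> int:
    """Sort-and-scan contig N50."""
    seg = sorted((s for s in segments if s > 0), reverse=True)
    half = sum(seg) / 2
    acc = 0
    for s in seg:
        acc += s
        if acc >= half:
            return s
    raise ValueError("empty segmentation")


def window_scan_oracle(pos, gt, p) -> list[tuple[int, int, int]]:
    """Literal sliding-window ROH scan; returns (start, end, n_snps) tuples.

    Enumerates every window explicitly and applies, in order: window
    homozygosity test, per-site hit rate, run extraction, end trimming,
    gap splitting, and the span/count/density filters.
    """
    pos = [int(x) for x in pos]
    gt = [int(x) for x in gt]
    m = len(pos)
    n4 = p.window_snps
    if m < n4:
        return []
    hom_windows = []
    for i in range(m - n4 + 1):
        g = gt[i : i + n4]
        hom_windows.append(
            sum(1 for x in g if x == HET) <= p.window_het_allow
            and sum(1 for x in g if x == MISSING) <= p.window_missing_allow
        )
    passing = []
    for j in range(m):
        wins = [
            hom_windows[i]
            for i in range(max(0, j - n4 + 1), min(j, m - n4) + 1)
        ]
        passing.append(sum(wins) / len(wins) >= p.window_hit_threshold)

    def finalize(a: int, b: int) -> list[tuple[int, int, int]]:
        homs = [i for i in range(a, b) if gt[i] in (HOM_REF, HOM_ALT)]
        if not homs:
            return []
        a, b = homs[0], homs[-1] + 1
        span = pos[b - 1] - pos[a] + 1
        n_snps = b - a
        if span < p.min_kb * 1000:
            return []
        if n_snps < p.min_snps:
            return []
        if span / 1000.0 / n_snps > p.density_kb_per_snp:
            return []
        return [(pos[a], pos[b - 1] + 1, n_snps)]

    out = []
    j = 0
    while j < m:
        if not passing[j]:
            j += 1
            continue
        k = j
        while k < m and passing[k]:
            k += 1
        homs = [i for i in range(j, k) if gt[i] in (HOM_REF, HOM_ALT)]
        if homs:
            a, b = homs[0], homs[-1] + 1
            piece = a
            for t in range(a + 1, b):
                if pos[t] - pos[t - 1] > p.max_internal_gap_kb * 1000:
                    out.extend(finalize(piece, t))
                    piece = t
            out.extend(finalize(piece, b))
        j = k
    return out


def _r2_oracle(a, b) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if x != MISSING and y != MISSING]
    if len(pairs) < 2:
        return 0.0
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    n = len(pairs)
    mx, my = sum(xs) / n, sum(ys) / n
    vx = sum((x - mx) ** 2 for x in xs) / n
    vy = sum((y - my) ** 2 for y in ys) / n
    if vx == 0 or vy == 0:
        return 0.0
    cov = sum((x - mx) * (y - my) for x, y in pairs) / n
    return cov * cov / (vx * vy)


def ld_prune_oracle(gt, pos, p) -> list[int]:
    """Literal windowed greedy pruning: full pair scan per window position."""
    n_sites, n_samples = gt.shape
    if p.prune_r2 is None:
        return list(range(n_sites))
    if n_samples < 2:
        return list(range(n_sites))
    dos = [[int(g) if g != MISSING else MISSING for g in row] for row in gt]
    kept = [True] * n_sites
    start = 0
    while start < n_sites:
        if p.prune_window_unit == "snp":
            stop = min(start + p.prune_window, n_sites)
        else:
            stop = start
            while stop < n_sites and pos[stop] <= pos[start] + p.prune_window * 1000:
                stop += 1
        for i in range(start, stop):
            if not kept[i]:
                continue
            for j in range(i + 1, stop):
                if not kept[j]:
                    continue
                if _r2_oracle(dos[i], dos[j]) > p.prune_r2:
                    kept[j] = False
        if stop >= n_sites:
            break
        start += p.prune_step_snps
    return [i for i in range(n_sites) if kept[i]]


def hmm_path_oracle(pos, gt, h) -> list[int]:
    """Exhaustive maximisation over all 2^m state paths (m <= ~14)."""
    m = len(pos)
    p_het = [h.p_het_in_roh, h.p_het_outside]
    means = [h.mean_roh_len, h.mean_non_roh_len]
    start = [math.log(means[0] / sum(means)), math.log(means[1] / sum(means))]

    def emis(state, g):
        if g == MISSING:
            return 0.0
        if g == HET:
            return math.log(p_het[state])
        return math.log(1 - p_het[state])

    best, best_lp = None, -math.inf
    for path in itertools.product((0, 1), repeat=m):
        lp = start[path[0]] + emis(path[0], gt[0])
        for t in range(1, m):
            d = pos[t] - pos[t - 1]
            leave = 1.0 - math.exp(-d / means[path[t - 1]])
            lp += math.log(leave if path[t] != path[t - 1] else 1.0 - leave)
            lp += emis(path[t], gt[t])
        if lp > best_lp:
            best_lp, best = lp, path
    return list(best)


def length_class_oracle(spans_mb) -> list[int]:
    """Brute-force binning into the five reporting classes."""
    counts = [0] * 5
    for s in spans_mb:
        if s > 25:
            counts[4] += 1
        elif s > 10:
            counts[3] += 1
        elif s > 5:
            counts[2] += 1
        elif s > 1:
            counts[1] += 1
        else:
            counts[0] += 1
    return counts
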