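"""Summary statistics of detected vs. planted ROH.

Length classes follow the reporting convention (right-closed upper bounds):
ROH > 25 Mb; 25 Mb >= ROH > 10 Mb; 10 Mb >= ROH > 5 Mb; 5 Mb >= ROH > 1 Mb;
1 Mb >= ROH > 500 kb — so a segment of exactly 5 Mb falls in the (1, 5] Mb
class.  F_ROH always uses the original (unfragmented) genome length as its
denominator: gap insertion preserves coordinates, and a fixed denominator
keeps comparisons across the contiguity ladder meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rohcall import RohSegment
from .synthpop import Reference, TruthROH

__all__ = [
    "LENGTH_CLASS_BOUNDS",
    "LENGTH_CLASS_LABELS",
    "MetricsReport",
    "f_roh",
    "f_roh_error_ratio",
    "length_class_table",
    "detection_ratio",
    "mean_roh_length",
    "summarize",
]

# class bounds in bases, left-open/right-closed; last class open-ended
LENGTH_CLASS_BOUNDS = (500_000, 1_000_000, 5_000_000, 10_000_000, 25_000_000)
LENGTH_CLASS_LABELS = (
    "0.5-1Mb",
    "1-5Mb",
    "5-10Mb",
    "10-25Mb",
    ">25Mb",
)


@dataclass
class MetricsReport:
    """Everything reported per (individual, condition)."""

    individual: str
    f_roh: float
    f_roh_true: float
    f_roh_error_ratio: float
    mean_roh_len: float
    n_segments: int
    class_counts: dict[str, int]
    snp_error_ratio: float = float("nan")
    missing_rate: float = float("nan")
    detection_ratio_by_class: dict[str, float] = field(default_factory=dict)


def f_roh(segs: list[RohSegment], ref: Reference) -> float:
    """Total segment span over total genome length."""
    return sum(s.span for s in segs) / ref.total_len


def f_roh_error_ratio(detected: float, real: float) -> float:
    """(detected - real) / real; signed relative error of F_ROH."""
    if real <= 0:
        raise ValueError("real F_ROH must be positive")
    return (detected - real) / real


def _class_of(span: int) -> int:
    """Index into LENGTH_CLASS_LABELS; spans must exceed 500 kb."""
    for k in range(1, len(LENGTH_CLASS_BOUNDS)):
        if span <= LENGTH_CLASS_BOUNDS[k]:
            return k - 1
    return len(LENGTH_CLASS_BOUNDS) - 1


def length_class_table(segs: list[RohSegment]) -> dict[str, int]:
    """Counts per length class; rejects segments at or below 500 kb."""
    counts = dict.fromkeys(LENGTH_CLASS_LABELS, 0)
    for s in segs:
        if s.span <= LENGTH_CLASS_BOUNDS[0]:
            raise ValueError(f"segment of {s.span} bp <= 500 kb; filter first")
        counts[LENGTH_CLASS_LABELS[_class_of(s.span)]] += 1
    return counts


def mean_roh_length(segs: list[RohSegment]) -> float:
    if not segs:
        return 0.0
    return float(np.mean([s.span for s in segs]))


def detection_ratio(
    truth: TruthROH, detected: list[RohSegment], overlap_q: float = 0.9
) -> dict[str, float]:
    """Correct-detection ratio of truth segments, per truth length class.

    A truth interval counts as correctly detected when detected segments
    cover at least ``overlap_q`` of its bases AND those segments extend
    beyond it by at most ``(1-overlap_q)`` of its length (a reciprocal-
    overlap rule; the threshold is a stated convention and is reported with
    results).
    """
    if not (0 < overlap_q <= 1):
        raise ValueError("overlap_q must lie in (0,1]")
    by_contig: dict[str, list[RohSegment]] = {}
    for s in detected:
        if s.individual == truth.individual:
            by_contig.setdefault(s.contig, []).append(s)
    hits = dict.fromkeys(LENGTH_CLASS_LABELS, 0)
    totals = dict.fromkeys(LENGTH_CLASS_LABELS, 0)
    for chrom, iv in truth.intervals.items():
        segs = sorted(by_contig.get(chrom, []), key=lambda s: s.start)
        for t0, t1 in iv.tolist():
            tlen = t1 - t0
            cov = ext = 0
            for s in segs:
                if s.end <= t0 or s.start >= t1:
                    continue
                cov += min(s.end, t1) - max(s.start, t0)
                ext += max(0, t0 - s.start) + max(0, s.end - t1)
            label = LENGTH_CLASS_LABELS[_class_of(tlen)]
            totals[label] += 1
            if cov >= overlap_q * tlen and ext <= (1 - overlap_q) * tlen:
                hits[label] += 1
    return {
        lab: (hits[lab] / totals[lab]) for lab in LENGTH_CLASS_LABELS if totals[lab] > 0
    }


def base_jaccard(truth: TruthROH, detected: list[RohSegment]) -> float:
    """Base-level Jaccard between truth intervals and detected segments."""
    inter = union = 0
    chroms = set(truth.intervals) | {s.contig for s in detected}
    for chrom in chroms:
        tv = truth.intervals.get(chrom, np.zeros((0, 2), dtype=np.int64))
        dv = np.array(
            sorted((s.start, s.end) for s in detected if s.contig == chrom), dtype=np.int64
        ).reshape(-1, 2)
        events = []
        for a, b in tv.tolist():
            events.append((a, 0, 1))
            events.append((b, 0, -1))
        for a, b in dv.tolist():
            events.append((a, 1, 1))
            events.append((b, 1, -1))
        events.sort()
        depth = [0, 0]
        last = None
        for x, which, d in events:
            if last is not None and x > last:
                seg = x - last
                if depth[0] > 0 and depth[1] > 0:
                    inter += seg
                if depth[0] > 0 or depth[1] > 0:
                    union += seg
            depth[which] += d
            last = x
    return inter / union if union else 1.0


def summarize(
    individual: str,
    segs: list[RohSegment],
    truth: TruthROH,
    ref: Reference,
    snp_err: float = float("nan"),
    missing_rate: float = float("nan"),
    overlap_q: float = 0.9,
) -> MetricsReport:
    """Assemble the full per-condition report for one individual."""
    det_f = f_roh(segs, ref)
    true_f = truth.total_length() / ref.total_len
    return MetricsReport(
        individual=individual,
        f_roh=det_f,
        f_roh_true=true_f,
        f_roh_error_ratio=f_roh_error_ratio(det_f, true_f) if true_f > 0 else float("nan"),
        mean_roh_len=mean_roh_length(segs),
        n_segments=len(segs),
        class_counts=length_class_table(segs),
        snp_error_ratio=snp_err,
        missing_rate=missing_rate,
        detection_ratio_by_class=detection_ratio(truth, segs, overlap_q),
    )
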