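"""Assembly and anchoring statistics: N50/L50, coverage, depth, size classes.

Conventions: contig lengths are the estimated lengths (consensus bands x
1.2 kb); N50/L50 are computed by default over reliable contigs only (>= 6
clones); percentages are rounded half-up to integers, fold ratios to one
decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import AssemblyParams

# Contig size groups (kb): lower bounds inclusive, upper bounds inclusive.
SIZE_GROUPS: list[tuple[str, float, float]] = [
    ("200-999", 200.0, 999.0),
    ("1000-3499", 1000.0, 3499.0),
    ("3500-9999", 3500.0, 9999.0),
    (">=10000", 10000.0, math.inf),
]
N_CHROM_INTERVALS = 6


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fold_ratio(a: float, b: float) -> float:
    """Fold change, one decimal (e.g. 7.7)."""
    return round(a / b, 1)


def n50_l50(lengths_kb: list[float]) -> tuple[float, int]:
    """N50 (kb) and L50 (count): sort descending; N50 is the length of the
    first contig at which the cumulative sum reaches half the total, L50
    its 1-based rank."""
    if len(lengths_kb) == 0:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths_kb):
        raise ValueError("lengths must be positive")
    xs = sorted(lengths_kb, reverse=True)
    half = sum(xs) / 2.0
    acc = 0.0
    for rank, x in enumerate(xs, start=1):
        acc += x
        if acc >= half:
            return float(x), rank
    raise AssertionError("unreachable")


def coverage_percent(total_kb: float, chrom_kb: float) -> int:
    """Estimated chromosome coverage, rounded half-up to an integer."""
    if chrom_kb <= 0:
        raise ValueError("chromosome length must be positive")
    return round_half_up(total_kb / chrom_kb * 100.0)


def useful_fingerprint_percent(n_useful: int, n_total: int) -> float:
    """Share of clones yielding quality fingerprints, one decimal."""
    if n_total <= 0:
        raise ValueError("total clone count must be positive")
    return round(n_useful / n_total * 100.0, 1)


def depth_report(contigs, params: AssemblyParams | None = None,
                 outlier_fold: float | None = None) -> dict:
    """Mean assembly depth (calculated length / actual length) and
    depth outliers above ``outlier_fold`` x mean."""
    params = params or AssemblyParams()
    k = outlier_fold if outlier_fold is not None else params.depth_outlier_fold
    total_calc = sum(c.n_clones * params.mean_insert_kb for c in contigs)
    total_est = sum(c.estimated_length_kb for c in contigs)
    mean = total_calc / total_est if total_est > 0 else 0.0
    per = {c.id: c.mean_depth for c in contigs}
    outliers = sorted((c.id for c in contigs if c.mean_depth > k * mean))
    return {"mean_depth": mean, "per_contig": per, "outlier_fold": k,
            "outliers": outliers}


@dataclass
class AssemblyStats:
    useful_fingerprint_pct: float
    n_contigs: int
    n_reliable: int
    n_singletons: int
    total_est_kb: float
    coverage_pct: int
    n50_kb: float
    l50: int
    max_contig_kb: float
    mean_depth: float
    mtp_size: int


def assembly_stats(contigs, singletons, n_total_clones: int, n_useful: int,
                   chrom_kb: float, mtp_size: int,
                   reliable_only: bool = True) -> AssemblyStats:
    """Table of headline assembly statistics.

    ``reliable_only`` restricts N50/L50 and coverage to contigs with >= 6
    clones, matching the convention of reporting "contigs > 5 clones".
    """
    rel = [c for c in contigs if c.reliability == "reliable"]
    pool = rel if reliable_only and rel else list(contigs)
    lengths = [c.estimated_length_kb for c in pool]
    n50, l50 = n50_l50(lengths)
    total = sum(lengths)
    return AssemblyStats(
        useful_fingerprint_pct=useful_fingerprint_percent(n_useful, n_total_clones),
        n_contigs=len(contigs),
        n_reliable=len(rel),
        n_singletons=len(singletons),
        total_est_kb=total,
        coverage_pct=coverage_percent(total, chrom_kb),
        n50_kb=n50,
        l50=l50,
        max_contig_kb=max(lengths),
        mean_depth=depth_report(pool)["mean_depth"],
        mtp_size=mtp_size,
    )


def size_histogram(lengths_kb: list[float]) -> list[dict]:
    """Contig-size histogram: 500-kb bins below 8,000 kb, 1,000-kb bins
    above; each row reports the contig count and summed length."""
    edges = list(np.arange(0.0, 8000.0, 500.0)) + list(
        np.arange(8000.0, max(lengths_kb + [8000.0]) + 1000.0, 1000.0)) + [math.inf]
    rows = []
    for a, b in zip(edges, edges[1:]):
        xs = [x for x in lengths_kb if a <= x < b]
        if b <= 8000 or xs:
            rows.append({"from_kb": a, "to_kb": b, "n": len(xs), "sum_kb": sum(xs)})
    return rows


@dataclass
class SizeClassReport:
    groups: list[tuple[str, float, float]]
    interval_edges_kb: list[float]
    counts: dict[str, list[int]]          # group -> per-interval counts
    unplaced: dict[str, int] = field(default_factory=dict)
    histogram: list[dict] = field(default_factory=list)

    def total(self) -> int:
        return (sum(sum(v) for v in self.counts.values())
                + sum(self.unplaced.values()))


def _size_group(length_kb: float) -> str | None:
    for name, lo, hi in SIZE_GROUPS:
        if lo <= length_kb <= hi:
            return name
    return None  # below 200 kb


def size_class_report(contigs, anchor_mid_kb: dict[str, float],
                      chrom_kb: float) -> SizeClassReport:
    """Positional distribution of contig size classes.

    The chromosome is partitioned into six equal intervals; each anchored
    contig is tallied in the interval containing its anchor midpoint, per
    size group.  Contigs without an anchor go to the ``unplaced`` column;
    contigs below 200 kb are tallied in a ``<200`` group.
    """
    edges = [chrom_kb * i / N_CHROM_INTERVALS for i in range(N_CHROM_INTERVALS + 1)]
    names = [g[0] for g in SIZE_GROUPS] + ["<200"]
    counts = {name: [0] * N_CHROM_INTERVALS for name in names}
    unplaced = {name: 0 for name in names}
    for c in contigs:
        group = _size_group(c.estimated_length_kb) or "<200"
        mid = anchor_mid_kb.get(c.id)
        if mid is None:
            unplaced[group] += 1
            continue
        k = min(int(mid / chrom_kb * N_CHROM_INTERVALS), N_CHROM_INTERVALS - 1)
        counts[group][k] += 1
    return SizeClassReport(groups=list(SIZE_GROUPS), interval_edges_kb=edges,
                           counts=counts, unplaced=unplaced,
                           histogram=size_histogram(
                               [c.estimated_length_kb for c in contigs]))
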