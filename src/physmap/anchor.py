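"""Contig anchoring: pooled marker screening, deletion bins, and in silico
fingerprint comparison against a reference pseudomolecule.

Contigs are placed on the chromosome in three stages: (1) PCR screening of
plate/row/column pools of the BAC library with markers of known position,
(2) markers carrying deletion-bin or external map positions, and (3)
Sulston-score comparison of clone fingerprints against in silico
fingerprints of sliding 100-kb reference windows.  Coverage is accounted
cumulatively, each contig counted once at the earliest stage that anchors
it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .fingerprint import Fingerprint
from .overlap import shared_bands, sulston_log10
from .params import MatchParams
from .simlib import CloneSet
from .stats import round_half_up

# Deletion-bin table for a wheat 5BS-like arm: (name, start fraction, end
# fraction of the arm measured from the centromere).  Bins may overlap
# (5BS8 and 5BS1 do, as printed in the source deletion-line data);
# assignment returns every containing bin.
DEFAULT_BINS: list[tuple[str, float, float]] = [
    ("C-5BS3", 0.00, 0.41),
    ("5BS3", 0.41, 0.42),
    ("5BS2", 0.42, 0.43),
    ("5BS4", 0.43, 0.56),
    ("5BS8", 0.56, 0.71),
    ("5BS1", 0.67, 0.71),
    ("5BS5", 0.71, 0.81),
    ("5BS6", 0.81, 1.00),
]


@dataclass(eq=False)
class AnchorRecord:
    subject: str            # clone or contig id
    evidence: str           # "marker" | "bin" | "reference-window"
    position: object        # bp interval tuple, bp position, or bin name
    stage: int              # 1 | 2 | 3
    score: float | None = None  # Sulston probability (reference evidence only)


@dataclass(eq=False)
class PoolLayout:
    """Plate pools plus per-plate row and column pools of a 384-well library."""

    plate_pools: dict[int, list[str]]
    row_pools: dict[tuple[int, str], list[str]]
    col_pools: dict[tuple[int, int], list[str]]

    @classmethod
    def from_clone_set(cls, clones: CloneSet) -> "PoolLayout":
        plates: dict[int, list[str]] = defaultdict(list)
        rows: dict[tuple[int, str], list[str]] = defaultdict(list)
        cols: dict[tuple[int, int], list[str]] = defaultdict(list)
        for cid, (plate, row, col) in clones.plate_layout.items():
            plates[plate].append(cid)
            rows[(plate, row)].append(cid)
            cols[(plate, col)].append(cid)
        return cls(dict(plates), dict(rows), dict(cols))


def screen_pools(markers: list[tuple[str, int]], clones: CloneSet,
                 layout: PoolLayout | None = None,
                 restrict_to: set | None = None) -> dict[str, dict]:
    """PCR screening of pooled plates with deconvolution.

    A clone is positive iff it is an on-target clone whose interval
    contains the marker locus (and, optionally, belongs to
    ``restrict_to``).  Positive pools are intersected plate by plate:
    a plate with one positive row or one positive column deconvolves
    uniquely; a plate with >= 2 positive rows and >= 2 positive columns
    yields a candidate well set flagged ambiguous.
    """
    layout = layout or PoolLayout.from_clone_set(clones)
    pos_of = {cid: (a, b) for cid, src, a, b in clones.clones if src == "target"}
    well_of = clones.plate_layout
    clone_at = {v: k for k, v in well_of.items()}
    out: dict[str, dict] = {}
    for marker, pos in markers:
        positive = [cid for cid, (a, b) in pos_of.items()
                    if a <= pos < b and (restrict_to is None or cid in restrict_to)]
        plates = sorted({well_of[c][0] for c in positive})
        pools = {"plate": plates,
                 "row": sorted({(well_of[c][0], well_of[c][1]) for c in positive}),
                 "col": sorted({(well_of[c][0], well_of[c][2]) for c in positive})}
        hits: list[str] = []
        candidates: list[str] = []
        ambiguous = False
        for plate in plates:
            rows = sorted({r for p, r in pools["row"] if p == plate})
            cols = sorted({c for p, c in pools["col"] if p == plate})
            wells = [(plate, r, c) for r in rows for c in cols]
            found = [clone_at[w] for w in wells if w in clone_at]
            if len(rows) >= 2 and len(cols) >= 2:
                ambiguous = True
                candidates.extend(found)
            else:
                hits.extend(found)
        out[marker] = {"pools": pools, "hits": sorted(hits),
                       "candidates": sorted(candidates), "ambiguous": ambiguous}
    return out


def assign_bins(fraction: float,
                bins: list[tuple[str, float, float]] | None = None) -> list[str]:
    """All deletion bins whose half-open interval contains the fraction;
    the terminal bin is closed at 1.0."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    bins = DEFAULT_BINS if bins is None else bins
    last_end = max(b for _, _, b in bins)
    out = []
    for name, a, b in bins:
        if a <= fraction < b or (fraction == last_end == b):
            out.append(name)
    return out


def anchor_by_reference(clone_fps: list[Fingerprint],
                        window_fps: list[Fingerprint],
                        params: MatchParams) -> list[AnchorRecord]:
    """Anchor each clone to its best-scoring reference window.

    The single best window at score <= network_cutoff wins; ties are
    broken by leftmost window start.  Windows must carry their interval.
    """
    records: list[AnchorRecord] = []
    w_counts = np.array([w.band_count for w in window_fps], dtype=np.int64)
    starts = np.array([w.interval[0] for w in window_fps])
    order = np.argsort(starts, kind="stable")
    log_cut = np.log10(params.network_cutoff)
    for fp in clone_fps:
        best = None  # (log10 score, window start, window index)
        for k in order:
            w = window_fps[k]
            s = shared_bands(fp, w, params.tolerance)
            if s == 0:
                continue
            nl, nh = sorted((fp.band_count, int(w_counts[k])))
            lg = float(sulston_log10(nl, nh, min(s, nl), params))
            if lg <= log_cut + 1e-12 and (best is None or lg < best[0]):
                best = (lg, int(starts[k]), int(k))
        if best is not None:
            w = window_fps[best[2]]
            records.append(AnchorRecord(fp.owner, "reference-window",
                                        tuple(w.interval), 3,
                                        score=float(10.0 ** best[0])))
    return records


def contig_reference_anchors(records: list[AnchorRecord],
                             contigs, clone_to_contig: dict[str, str]) -> dict[str, dict]:
    """Summarise clone-level reference anchors per contig.

    A contig's anchor is the median window midpoint of its anchored
    clones; with >= 2 anchored clones an orientation is assigned (sign of
    the correlation between contig order and window position); "key"
    contigs are anchored by >= 3 clones with mutually consistent positions
    (span < 2x estimated length).
    """
    by_contig: dict[str, list[tuple[str, float]]] = defaultdict(list)
    for r in records:
        ctg = clone_to_contig.get(r.subject)
        if ctg is not None:
            mid = (r.position[0] + r.position[1]) / 2.0
            by_contig[ctg].append((r.subject, mid))
    out: dict[str, dict] = {}
    for c in contigs:
        if c.id not in by_contig:
            continue
        entries = by_contig[c.id]
        mids = np.array([m for _, m in entries])
        info = {"position": float(np.median(mids)), "n_anchored": len(entries),
                "orientation": 0, "key": False}
        if len(entries) >= 2:
            pos_in_order = {cl: i for i, cl in enumerate(c.clones)}
            xs = np.array([pos_in_order[cl] for cl, _ in entries], dtype=float)
            if np.std(xs) > 0 and np.std(mids) > 0:
                r = float(np.corrcoef(xs, mids)[0, 1])
                info["orientation"] = int(np.sign(r)) if r == r else 0
        if len(entries) >= 3:
            span_kb = (mids.max() - mids.min()) / 1000.0
            info["key"] = bool(span_kb < 2.0 * c.estimated_length_kb)
        out[c.id] = info
    return out


def staged_coverage(stage_of_contig: dict[str, int],
                    contig_kb: dict[str, float],
                    chrom_kb: float) -> list[dict]:
    """Cumulative anchoring coverage by stage.

    Each contig is counted once, at the earliest stage that anchors it
    (callers passing several stages per contig should pre-reduce with
    min; dict input already holds one stage per contig).  Percentages are
    of the chromosome arm length, rounded half-up to integers.
    """
    stages = sorted(set(stage_of_contig.values()))
    rows: list[dict] = []
    cumulative = 0.0
    for st in stages:
        ids = sorted(c for c, s in stage_of_contig.items() if s == st)
        inc = sum(contig_kb[c] for c in ids)
        cumulative += inc
        rows.append({"stage": st, "n_contigs": len(ids),
                     "increment_kb": inc, "cumulative_kb": cumulative,
                     "cumulative_pct": round_half_up(cumulative / chrom_kb * 100.0)})
    return rows


def earliest_stage(anchor_stages: list[tuple[str, int]]) -> dict[str, int]:
    """Reduce (contig, stage) pairs to the earliest stage per contig."""
    out: dict[str, int] = {}
    for ctg, st in anchor_stages:
        out[ctg] = min(st, out.get(ctg, st))
    return out
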