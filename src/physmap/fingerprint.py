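"""In silico HICF SNaPshot fingerprinting.

A fingerprint is the sorted list of encoded band values obtained from a
complete five-enzyme digest of a clone insert (or of a sliding reference
window).  Restriction-site positions of the four labeled 6-cutters (BamHI,
EcoRI, XbaI, XhoI) and the unlabeled 4-cutter HaeIII are merged into one
set of fragment borders; a fragment yields a band iff at least one border
is a labeled-enzyme site and its raw length lies in [50, 500] bp.  Raw
lengths are multiplied by 30 and shifted by a per-enzyme offset
(0 / 15,000 / 30,000 / 45,000) so that the four channels occupy disjoint
intervals of one integer scale.  When both borders are labeled sites the
band is emitted once and labeled by the earlier enzyme in the fixed order
BamHI < EcoRI < XbaI < XhoI (single-band rule; avoids double counting).
HaeIII-HaeIII fragments carry no label and emit no band.  Duplicate
encoded values within one clone are kept as a multiset, mirroring repeated
peaks in capillary profiles.  Sites are located on the given strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import HicfParams

DEFAULT_HICF = HicfParams()

_HAEIII_RANK = 99  # sentinel rank for the unlabeled cutter


@dataclass(eq=False)
class Fingerprint:
    """Sorted multiset of encoded band values belonging to one owner."""

    owner: str
    bands: np.ndarray
    interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.int64)

    @property
    def band_count(self) -> int:
        return int(self.bands.size)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Fingerprint({self.owner!r}, n={self.band_count})"


def _as_u8(sequence: str | bytes | np.ndarray) -> np.ndarray:
    if isinstance(sequence, np.ndarray):
        return sequence.astype(np.uint8, copy=False)
    if isinstance(sequence, str):
        sequence = sequence.encode("ascii")
    return np.frombuffer(sequence, dtype=np.uint8)


def find_sites(sequence: str | bytes | np.ndarray, motif: str) -> np.ndarray:
    """0-based start positions of every (possibly overlapping) motif hit.

    ``N`` (or any non-ACGT symbol) never matches.
    """
    arr = _as_u8(sequence)
    m = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    n = arr.size - m.size + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    mask = arr[:n] == m[0]
    for i in range(1, m.size):
        mask &= arr[i:i + n] == m[i]
    return np.flatnonzero(mask).astype(np.int64)


def digest_sites(sequence: str | bytes | np.ndarray,
                 params: HicfParams = DEFAULT_HICF) -> dict[str, np.ndarray]:
    """Site positions for all five fingerprinting enzymes."""
    sites = {enz: find_sites(sequence, motif)
             for enz, motif in params.labeled_enzymes.items()}
    sites[params.cutter] = find_sites(sequence, params.cutter_site)
    return sites


def encode_band(enzyme: str, raw_len: int,
                params: HicfParams = DEFAULT_HICF) -> int | None:
    """Encoded value for a labeled band, or None if the length is rejected."""
    if enzyme not in params.labeled_enzymes:
        raise KeyError(f"unknown labeled enzyme: {enzyme!r}")
    if not params.min_raw_len <= raw_len <= params.max_raw_len:
        return None
    return raw_len * params.scale_multiplier + params.offsets[enzyme]


def hicf_fingerprint(sequence: str | bytes | np.ndarray, owner: str,
                     params: HicfParams = DEFAULT_HICF,
                     interval: tuple[int, int] | None = None) -> Fingerprint:
    """Fingerprint of a single sequence (pure function of the sequence)."""
    arr = _as_u8(sequence)
    enzymes = list(params.labeled_enzymes)
    positions: list[np.ndarray] = []
    ranks: list[np.ndarray] = []
    for rank, enz in enumerate(enzymes):
        p = find_sites(arr, params.labeled_enzymes[enz])
        positions.append(p)
        ranks.append(np.full(p.size, rank, dtype=np.int64))
    p = find_sites(arr, params.cutter_site)
    positions.append(p)
    ranks.append(np.full(p.size, _HAEIII_RANK, dtype=np.int64))

    pos = np.concatenate(positions)
    rnk = np.concatenate(ranks)
    if pos.size == 0:
        return Fingerprint(owner, np.empty(0, dtype=np.int64), interval)

    # Sort by (position, rank); keep the lowest rank at each distinct border.
    order = np.lexsort((rnk, pos))
    pos, rnk = pos[order], rnk[order]
    keep = np.ones(pos.size, dtype=bool)
    keep[1:] = pos[1:] != pos[:-1]
    pos, rnk = pos[keep], rnk[keep]

    # Fragment borders: sequence start, all site positions, sequence end.
    bpos = np.concatenate(([0], pos, [arr.size]))
    brnk = np.concatenate(([_HAEIII_RANK], rnk, [_HAEIII_RANK]))
    if pos[0] == 0:
        bpos, brnk = bpos[1:], brnk[1:]
    if pos[-1] == arr.size:  # cannot happen for non-empty motifs; kept for safety
        bpos, brnk = bpos[:-1], brnk[:-1]

    raw = np.diff(bpos)
    left, right = brnk[:-1], brnk[1:]
    label = np.minimum(left, right)
    ok = (label < _HAEIII_RANK) & (raw >= params.min_raw_len) & (raw <= params.max_raw_len)
    offs = np.array([params.offsets[e] for e in enzymes], dtype=np.int64)
    values = raw[ok] * params.scale_multiplier + offs[label[ok]]
    values.sort()
    return Fingerprint(owner, values, interval)


def quality_filter(fps: list[Fingerprint],
                   params: HicfParams = DEFAULT_HICF
                   ) -> tuple[list[Fingerprint], list[Fingerprint]]:
    """Partition fingerprints into (retained, rejected) by band count.

    Retained iff ``quality_min_bands <= band_count <= quality_max_bands``
    (boundaries inclusive); the partition is exhaustive and disjoint.
    """
    retained, rejected = [], []
    for fp in fps:
        if params.quality_min_bands <= fp.band_count <= params.quality_max_bands:
            retained.append(fp)
        else:
            rejected.append(fp)
    return retained, rejected


def window_intervals(length: int, params: HicfParams = DEFAULT_HICF
                     ) -> list[tuple[int, int]]:
    """Sliding-window intervals: starts at multiples of the step while the
    window fits, plus a final right-flush window if the end is uncovered."""
    w, s = params.window_size, params.window_step
    if length < w:
        raise ValueError(f"reference length {length} shorter than window size {w}")
    starts = list(range(0, length - w + 1, s))
    if starts[-1] + w < length:
        starts.append(length - w)
    return [(a, a + w) for a in starts]


def fingerprint_windows(reference: str | bytes | np.ndarray,
                        params: HicfParams = DEFAULT_HICF,
                        id_prefix: str = "win") -> list[Fingerprint]:
    """Fingerprint 100-kb sliding windows (BAC analogs) of a reference.

    Window ids record the interval, e.g. ``win:50000-150000``.
    """
    arr = _as_u8(reference)
    out = []
    for a, b in window_intervals(arr.size, params):
        fp = hicf_fingerprint(arr[a:b], f"{id_prefix}:{a}-{b}", params, interval=(a, b))
        out.append(fp)
    return out
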