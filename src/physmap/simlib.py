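"""Synthetic chromosomes, diverged references, and simulated BAC libraries.

The generator emulates the statistical structure a BAC physical-mapping
pipeline assumes for a flow-sorted wheat chromosome arm: a ~GC 0.46 random
backbone carrying exact tandem-repeat blocks (heterochromatin analogue),
marker loci placed uniformly outside the repeat blocks, a HindIII
partial-digest library with 100-200 kb size selection around a 122 kb mean
insert, ~10% off-target (decoy) clones standing in for flow-sorting
impurity, and a fraction of clones with corrupted fingerprint quality.
A diverged homologous reference (~1 substitution / 100 bp) stands in for a
related species' pseudomolecule.  Coordinates are 0-based, half-open
throughout.  All randomness flows from a single integer seed; a fixed seed
yields a bitwise-identical chromosome and clone set.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace

import numpy as np

from .fingerprint import Fingerprint, find_sites

HINDIII_SITE = "AAGCTT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

PLATE_SIZE = 384
PLATE_ROWS = string.ascii_uppercase[:16]  # A..P
PLATE_COLS = 24


@dataclass
class SimConfig:
    """Study conditions for the synthetic library.

    ``repeat_blocks`` is a list of (start_fraction, end_fraction,
    unit_sequence); the block is written as exact tandem copies of the
    unit.  ``marker_density`` maps marker type to loci per Mb.
    """

    chromosome_length: int = 10_000_000
    gc_fraction: float = 0.46
    repeat_blocks: list[tuple[float, float, str]] = field(default_factory=list)
    marker_density: dict[str, float] = field(default_factory=lambda: {"SSR": 2.0, "ISBP": 5.0})
    library_coverage: float = 10.0
    insert_min: int = 100_000
    insert_max: int = 200_000
    insert_mean: int = 122_000
    contamination_fraction: float = 0.10
    quality_dropout: float = 0.26
    divergence_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_fraction < 1.0:
            raise ValueError("contamination_fraction must lie in [0, 1)")
        if not self.insert_min <= self.insert_mean <= self.insert_max:
            raise ValueError("require insert_min <= insert_mean <= insert_max")
        if not 0.0 <= self.quality_dropout < 1.0:
            raise ValueError("quality_dropout must lie in [0, 1)")
        if not 0.0 <= self.divergence_rate < 1.0:
            raise ValueError("divergence_rate must lie in [0, 1)")
        ivals = sorted((a, b) for a, b, _ in self.repeat_blocks)
        for a, b in ivals:
            if not (0.0 <= a < b <= 1.0):
                raise ValueError("repeat-block fractions must satisfy 0 <= start < end <= 1")
        for (_, b1), (a2, _) in zip(ivals, ivals[1:]):
            if a2 < b1:
                raise ValueError("repeat blocks must not overlap")


@dataclass(eq=False)
class SyntheticChromosome:
    """Sequence plus ground-truth annotations (0-based, half-open)."""

    sequence: str
    repeat_annotations: list[tuple[int, int, str]]
    marker_loci: list[tuple[str, str, int]]  # (marker id, type, position bp)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(eq=False)
class CloneSet:
    """Simulated BAC library with plate layout and quality truth.

    ``clones`` rows: (clone_id, source, start, end) with source in
    {"target", "decoy"}; coordinates refer to the source sequence.
    """

    clones: list[tuple[str, str, int, int]]
    plate_layout: dict[str, tuple[int, str, int]]  # clone_id -> (plate, row, col)
    corrupted: set[str] = field(default_factory=set)
    unmappable_regions: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clones)

    def by_id(self) -> dict[str, tuple[str, int, int]]:
        return {cid: (src, a, b) for cid, src, a, b in self.clones}


def random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    arr = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return arr.tobytes().decode("ascii")


def generate_chromosome(config: SimConfig,
                        rng: np.random.Generator | None = None) -> SyntheticChromosome:
    """Random chromosome with tandem-repeat blocks and marker loci.

    Repeat blocks are written as exact tandem copies of their unit
    (truncated at the block end); marker loci are placed uniformly outside
    repeat blocks, with an exact count of ``round(density * Mb)`` per type.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    L = config.chromosome_length
    seq = bytearray(random_sequence(L, config.gc_fraction, rng), "ascii")

    annotations: list[tuple[int, int, str]] = []
    for a_frac, b_frac, unit in sorted(config.repeat_blocks):
        a, b = int(round(a_frac * L)), int(round(b_frac * L))
        tiled = (unit * (-(-(b - a) // len(unit))))[: b - a]
        seq[a:b] = tiled.encode("ascii")
        annotations.append((a, b, "tandem"))

    in_repeat = np.zeros(L, dtype=bool)
    for a, b, _ in annotations:
        in_repeat[a:b] = True
    free = np.flatnonzero(~in_repeat)

    loci: list[tuple[str, str, int]] = []
    for mtype in sorted(config.marker_density):
        dens = config.marker_density[mtype]
        n = int(round(dens * L / 1e6))
        if n == 0:
            continue
        pos = np.sort(rng.choice(free, size=n, replace=False))
        loci.extend((f"{mtype}_{k:04d}", mtype, int(p)) for k, p in enumerate(pos))
    loci.sort(key=lambda m: m[2])
    return SyntheticChromosome(seq.decode("ascii"), annotations, loci)


def generate_decoy(config: SimConfig,
                   rng: np.random.Generator) -> SyntheticChromosome:
    """Independent random sequence of equal length and GC: the contaminating
    chromosomes picked up during flow sorting are non-homologous."""
    return SyntheticChromosome(
        random_sequence(config.chromosome_length, config.gc_fraction, rng), [], [])


def mutate_reference(chrom: SyntheticChromosome, rate: float,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> SyntheticChromosome:
    """Diverged homolog: each base substituted independently with
    probability ``rate`` to a uniformly chosen different base.
    Annotations are preserved."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    rng = np.random.default_rng(seed) if rng is None else rng
    arr = np.frombuffer(chrom.sequence.encode("ascii"), dtype=np.uint8).copy()
    n_mut = rng.binomial(arr.size, rate)
    if n_mut:
        pos = rng.choice(arr.size, size=n_mut, replace=False)
        # shift by 1..3 positions in the base alphabet => always a different base
        base_idx = np.searchsorted(_BASES, arr[pos])
        arr[pos] = _BASES[(base_idx + rng.integers(1, 4, size=n_mut)) % 4]
    return SyntheticChromosome(arr.tobytes().decode("ascii"),
                               list(chrom.repeat_annotations),
                               list(chrom.marker_loci))


def _allowed_starts(sites: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Sites that have at least one partner site a size-selected insert away."""
    lo = np.searchsorted(sites, sites + cfg.insert_min, side="left")
    hi = np.searchsorted(sites, sites + cfg.insert_max, side="right")
    return sites[hi > lo]


def _unmappable(sites: np.ndarray, allowed: np.ndarray, length: int,
                cfg: SimConfig) -> list[tuple[int, int]]:
    """Maximal intervals not reachable by any size-selected insert."""
    cover = np.zeros(length + 1, dtype=np.int32)
    for s in allowed:
        cover[s] += 1
        cover[min(s + cfg.insert_max, length)] -= 1
    covered = np.cumsum(cover[:-1]) > 0
    out = []
    edges = np.flatnonzero(np.diff(np.concatenate(([True], covered, [True]))))
    for a, b in zip(edges[::2], edges[1::2]):
        if not covered[a]:
            out.append((int(a), int(b)))
    # report only regions wider than one insert
    return [(a, b) for a, b in out if b - a > cfg.insert_max]


def simulate_bac_library(chrom: SyntheticChromosome,
                         decoy: SyntheticChromosome,
                         config: SimConfig,
                         rng: np.random.Generator | None = None) -> CloneSet:
    """HindIII partial-digest library with size selection.

    Partial digestion is modelled by sampling an allowed start site
    uniformly, drawing a target insert length from a truncated normal
    around ``insert_mean``, and choosing the HindIII site nearest the
    target within the size-selection window; this reproduces size
    selection without simulating digestion kinetics.  A
    ``contamination_fraction`` share of clones is drawn from the decoy
    sequence; every clone is assigned a unique 384-well plate position.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    sources = {}
    for name, s in (("target", chrom), ("decoy", decoy)):
        sites = find_sites(s.sequence, HINDIII_SITE)
        allowed = _allowed_starts(sites, config)
        if allowed.size == 0:
            raise ValueError(f"no HindIII site pair {config.insert_min}-"
                             f"{config.insert_max} bp apart in {name} sequence")
        # Clone abundance is uniform per bp of mappable DNA, not per site:
        # each allowed start is weighted by the stretch of positions nearest
        # to it, capped at a few typical spacings so that site deserts
        # (repeat blocks, sequence ends) do not pile clones onto their
        # boundary sites.
        mid = (allowed[:-1] + allowed[1:]) / 2.0
        left = np.concatenate(([allowed[0]], mid))
        right = np.concatenate((mid, [allowed[-1] + 1]))
        share = np.minimum(right, allowed + config.insert_min) - left
        # a start cannot represent DNA more than a fraction of an insert
        # away; the cap stops site deserts (sequence ends, HindIII-free
        # blocks) from piling their positions onto one boundary site
        cap = 0.1 * config.insert_min
        cum = np.cumsum(np.clip(share, 1.0, cap))
        sources[name] = (sites, allowed, cum / cum[-1])

    n_clones = int(round(chrom.length * config.library_coverage / config.insert_mean))
    sd = (config.insert_max - config.insert_min) / 6.0
    clones: list[tuple[str, str, int, int]] = []
    layout: dict[str, tuple[int, str, int]] = {}
    for k in range(n_clones):
        src = "decoy" if rng.random() < config.contamination_fraction else "target"
        sites, allowed, cum = sources[src]
        start = int(allowed[np.searchsorted(cum, rng.random(), side="right")])
        target = float(np.clip(rng.normal(config.insert_mean, sd),
                               config.insert_min, config.insert_max))
        lo = np.searchsorted(sites, start + config.insert_min, side="left")
        hi = np.searchsorted(sites, start + config.insert_max, side="right")
        cand = sites[lo:hi]
        end = int(cand[np.argmin(np.abs(cand - (start + target)))])
        cid = f"bac{k:05d}"
        clones.append((cid, src, start, end))
        plate = k // PLATE_SIZE
        well = k % PLATE_SIZE
        layout[cid] = (plate, PLATE_ROWS[well // PLATE_COLS], well % PLATE_COLS + 1)

    n_bad = int(round(config.quality_dropout * n_clones))
    corrupted = set()
    if n_bad:
        idx = rng.choice(n_clones, size=n_bad, replace=False)
        corrupted = {clones[int(i)][0] for i in idx}
    t_sites, t_allowed, _ = sources["target"]
    return CloneSet(clones, layout, corrupted,
                    _unmappable(t_sites, t_allowed, chrom.length, config))


def clone_fingerprints(clone_set: CloneSet, chrom: SyntheticChromosome,
                       decoy: SyntheticChromosome, hicf_params=None) -> list[Fingerprint]:
    """Fingerprint every clone insert from its source sequence."""
    from .fingerprint import DEFAULT_HICF, hicf_fingerprint
    hicf_params = hicf_params or DEFAULT_HICF
    seqs = {"target": chrom.sequence, "decoy": decoy.sequence}
    return [hicf_fingerprint(seqs[src][a:b], cid, hicf_params, interval=(a, b))
            for cid, src, a, b in clone_set.clones]


def corrupt_fingerprints(fps: list[Fingerprint], corrupted: set[str],
                         hicf_params, rng: np.random.Generator) -> list[Fingerprint]:
    """Model fingerprint-quality failure by random band deletion or
    duplication until the band count leaves the quality window (the
    downstream filter acts on band count only)."""
    out = []
    for fp in fps:
        if fp.owner not in corrupted:
            out.append(fp)
            continue
        bands = fp.bands.copy()
        drop = bool(rng.random() < 0.5) or bands.size == 0
        if drop:
            target = hicf_params.quality_min_bands - 1
            keep = min(max(target, 0), bands.size)
            if keep < bands.size:
                bands = np.sort(rng.choice(bands, size=keep, replace=False))
            # fewer bands than the floor already: leave as is (still rejected)
            if bands.size > target:
                bands = bands[:target]
        else:
            target = hicf_params.quality_max_bands + 1
            if bands.size < target:
                extra = rng.choice(bands, size=target - bands.size, replace=True)
                bands = np.sort(np.concatenate([bands, extra]))
        out.append(Fingerprint(fp.owner, bands, fp.interval))
    return out


def clone_midpoints(clone_set: CloneSet) -> dict[str, float]:
    return {cid: (a + b) / 2.0 for cid, src, a, b in clone_set.clones if src == "target"}


__all__ = [
    "SimConfig", "SyntheticChromosome", "CloneSet", "HINDIII_SITE",
    "generate_chromosome", "generate_decoy", "mutate_reference",
    "simulate_bac_library", "clone_fingerprints", "corrupt_fingerprints",
    "random_sequence", "clone_midpoints", "replace",
]
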