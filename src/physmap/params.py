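"""Parameter containers for the physical-mapping pipeline.

Each stage of the pipeline (fingerprinting, overlap scoring, contig
assembly) carries a small frozen set of tunables.  Defaults reproduce the
protocol used for SNaPshot/HICF physical maps of flow-sorted wheat
chromosome arms: five-enzyme in silico digestion with a 50-500 bp band
window encoded onto a single 1,500-60,000 integer scale, a Sulston-score
overlap network at 1e-15, staged Q-clone exclusion at 1e-25/1e-30, and
minimal-tiling-path selection constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


def _default_enzymes() -> dict[str, str]:
    # Labeled (fluorescent) enzymes, in fixed channel order.
    return {
        "BamHI": "GGATCC",
        "EcoRI": "GAATTC",
        "XbaI": "TCTAGA",
        "XhoI": "CTCGAG",
    }


def _default_offsets() -> dict[str, int]:
    return {"BamHI": 0, "EcoRI": 15_000, "XbaI": 30_000, "XhoI": 45_000}


@dataclass
class HicfParams:
    """HICF (high-information-content fingerprinting) digestion/encoding.

    A clone sequence is digested in silico with four labeled 6-cutters plus
    the unlabeled 4-cutter HaeIII.  Fragments of raw length 50-500 bp with
    at least one labeled end become bands; band value =
    ``raw_len * scale_multiplier + offsets[enzyme]`` which places the four
    enzyme channels on disjoint intervals of one integer scale.
    """

    labeled_enzymes: dict[str, str] = field(default_factory=_default_enzymes)
    cutter: str = "HaeIII"
    cutter_site: str = "GGCC"
    min_raw_len: int = 50
    max_raw_len: int = 500
    scale_multiplier: int = 30
    offsets: dict[str, int] = field(default_factory=_default_offsets)
    quality_min_bands: int = 18
    quality_max_bands: int = 207
    window_size: int = 100_000
    window_step: int = 50_000

    def __post_init__(self) -> None:
        offs = [self.offsets[e] for e in self.labeled_enzymes]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("enzyme offsets must be strictly increasing in enzyme order")
        if self.min_raw_len <= 0 or self.max_raw_len <= self.min_raw_len:
            raise ValueError("require 0 < min_raw_len < max_raw_len")
        if self.window_step <= 0 or self.window_size < self.window_step:
            raise ValueError("require 0 < window_step <= window_size")

    @property
    def min_encoded(self) -> int:
        return self.min_raw_len * self.scale_multiplier + min(self.offsets.values())

    @property
    def max_encoded(self) -> int:
        return self.max_raw_len * self.scale_multiplier + max(self.offsets.values())


@dataclass
class MatchParams:
    """Band matching and Sulston-score network parameters.

    ``tolerance`` is in encoded scale units (0 = exact integer matching,
    appropriate for in silico bands).  ``gel_space`` is the number of
    distinguishable values on the encoded scale; the default 60,000 is the
    span of the scale built by the channel offsets.  All cutoff comparisons
    are inclusive (score <= cutoff is significant).
    """

    tolerance: int = 0
    gel_space: int = 60_000
    network_cutoff: float = 1e-15
    q_overlap_cutoff: float = 1e-15
    q_clone_cutoff: float = 1e-25
    split_cutoff: float = 1e-30
    promiscuity_score: float = 1e-50
    promiscuity_degree: int = 500
    mtp_cutoff_range: tuple[float, float] = (1e-15, 1e-33)
    mtp_shared_fraction: tuple[float, float] = (0.30, 0.50)

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.gel_space <= 2 * self.tolerance:
            raise ValueError("gel_space must exceed 2 * tolerance")
        for c in (self.network_cutoff, self.q_overlap_cutoff, self.q_clone_cutoff,
                  self.split_cutoff, self.promiscuity_score):
            if not 0.0 < c < 1.0:
                raise ValueError("cutoffs must lie in (0, 1)")


@dataclass
class AssemblyParams:
    """Contig length/depth conventions and FPC-mode MTP constraints."""

    mean_insert_kb: float = 122.0
    band_to_kb: float = 1.2
    min_reliable_clones: int = 6
    # FPC-style MTP selection: minimum overlap significance, minimum band
    # advance past the previous MTP clone, minimum shared bands.
    fpc_min_overlap: float = 1e-30
    fpc_min_dist_bands: int = 30
    fpc_min_shared: int = 12
    rule_d_cm_threshold: float = 10.0
    depth_outlier_fold: float = 1.5

    def __post_init__(self) -> None:
        for v in (self.mean_insert_kb, self.band_to_kb, self.min_reliable_clones,
                  self.fpc_min_overlap, self.fpc_min_dist_bands, self.fpc_min_shared,
                  self.rule_d_cm_threshold, self.depth_outlier_fold):
            if v <= 0:
                raise ValueError("assembly parameters must be positive")


def params_to_dict(p) -> dict:
    d = asdict(p)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
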