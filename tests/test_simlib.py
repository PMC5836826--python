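"""Synthetic chromosome, diverged reference, and BAC library generator."""

import numpy as np
import pytest
from scipy import stats

from physmap.fingerprint import hicf_fingerprint, quality_filter
from physmap.simlib import (HINDIII_SITE, SimConfig, clone_fingerprints,
                            corrupt_fingerprints, generate_chromosome,
                            generate_decoy, mutate_reference,
                            simulate_bac_library)
from physmap.params import HicfParams
from tests.conftest import LOWBAND_REPEAT_UNIT


class TestGenerateChromosome:
    def test_repeat_block_annotation_and_content(self):
        cfg = SimConfig(chromosome_length=10_000_000,
                        repeat_blocks=[(0.81, 1.00, "GAA")],
                        marker_density={}, seed=3)
        chrom = generate_chromosome(cfg)
        assert chrom.length == 10_000_000
        assert chrom.repeat_annotations == [(8_100_000, 10_000_000, "tandem")]
        assert chrom.sequence[8_100_000:8_100_009] == "GAAGAAGAA"

    def test_marker_counts_and_placement_outside_repeats(self):
        cfg = SimConfig(chromosome_length=10_000_000,
                        repeat_blocks=[(0.81, 1.00, "GAA")],
                        marker_density={"SSR": 2.0}, seed=3)
        chrom = generate_chromosome(cfg)
        ssr = [m for m in chrom.marker_loci if m[1] == "SSR"]
        assert len(ssr) == 20
        assert all(pos < 8_100_000 for _, _, pos in ssr)

    def test_same_seed_reproduces_bitwise(self):
        cfg = SimConfig(chromosome_length=200_000, seed=9)
        a = generate_chromosome(cfg)
        b = generate_chromosome(cfg)
        assert a.sequence == b.sequence
        assert a.marker_loci == b.marker_loci

    def test_overlapping_repeat_blocks_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(repeat_blocks=[(0.1, 0.5, "GAA"), (0.4, 0.6, "TTC")])

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(repeat_blocks=[(0.5, 1.2, "GAA")])


class TestMutateReference:
    def test_rate_zero_is_identity(self):
        chrom = generate_chromosome(SimConfig(chromosome_length=50_000, seed=1))
        out = mutate_reference(chrom, 0.0, seed=2)
        assert out.sequence == chrom.sequence

    def test_hamming_distance_binomial(self):
        chrom = generate_chromosome(SimConfig(chromosome_length=10_000, seed=1))
        out = mutate_reference(chrom, 0.01, seed=2)
        d = sum(a != b for a, b in zip(chrom.sequence, out.sequence))
        sigma = np.sqrt(10_000 * 0.01 * 0.99)
        assert abs(d - 100) <= 3 * sigma

    def test_substitutions_change_base_annotations_kept(self):
        cfg = SimConfig(chromosome_length=100_000,
                        repeat_blocks=[(0.1, 0.2, "GAA")], seed=4)
        chrom = generate_chromosome(cfg)
        out = mutate_reference(chrom, 0.5, seed=5)
        assert out.repeat_annotations == chrom.repeat_annotations
        assert set(out.sequence) <= set("ACGT")

    def test_invalid_rate(self):
        chrom = generate_chromosome(SimConfig(chromosome_length=10_000, seed=1))
        with pytest.raises(ValueError):
            mutate_reference(chrom, 1.5)


@pytest.fixture(scope="module")
def small_library():
    cfg = SimConfig(chromosome_length=3_050_000, library_coverage=20,
                    contamination_fraction=0.10, quality_dropout=0.0, seed=12)
    rng = np.random.default_rng(12)
    chrom = generate_chromosome(cfg, rng)
    decoy = generate_decoy(cfg, rng)
    clones = simulate_bac_library(chrom, decoy, cfg, rng)
    return cfg, chrom, decoy, clones


class TestSimulateLibrary:
    def test_clone_count_matches_coverage(self):
        cfg = SimConfig(chromosome_length=1_000_000, library_coverage=2,
                        contamination_fraction=0.0, seed=1)
        rng = np.random.default_rng(1)
        chrom = generate_chromosome(cfg, rng)
        decoy = generate_decoy(cfg, rng)
        clones = simulate_bac_library(chrom, decoy, cfg, rng)
        assert len(clones) == 16  # round(1e6 * 2 / 122e3)

    def test_contamination_share(self, small_library):
        cfg, chrom, decoy, clones = small_library
        n = len(clones)
        n_decoy = sum(1 for _, src, _, _ in clones.clones if src == "decoy")
        sigma = np.sqrt(n * 0.1 * 0.9)
        assert abs(n_decoy - 0.1 * n) <= 4 * sigma

    def test_clone_ends_on_hindiii_sites_and_size_selected(self, small_library):
        cfg, chrom, decoy, clones = small_library
        seqs = {"target": chrom.sequence, "decoy": decoy.sequence}
        for cid, src, a, b in clones.clones:
            assert seqs[src][a:a + 6] == HINDIII_SITE
            assert seqs[src][b:b + 6] == HINDIII_SITE
            assert cfg.insert_min <= b - a <= cfg.insert_max

    def test_mean_insert_near_target(self, small_library):
        cfg, _, _, clones = small_library
        lengths = [b - a for _, _, a, b in clones.clones]
        assert abs(np.mean(lengths) - cfg.insert_mean) < 10_000

    def test_unique_plate_wells(self, small_library):
        _, _, _, clones = small_library
        wells = list(clones.plate_layout.values())
        assert len(set(wells)) == len(wells)
        assert all(0 <= p and r in "ABCDEFGHIJKLMNOP" and 1 <= c <= 24
                   for p, r, c in wells)

    def test_determinism(self):
        cfg = SimConfig(chromosome_length=1_000_000, library_coverage=3, seed=77)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            chrom = generate_chromosome(cfg, rng)
            decoy = generate_decoy(cfg, rng)
            runs.append(simulate_bac_library(chrom, decoy, cfg, rng))
        assert runs[0].clones == runs[1].clones
        assert runs[0].plate_layout == runs[1].plate_layout
        assert runs[0].corrupted == runs[1].corrupted

    def test_start_positions_uniform_chi_square(self):
        cfg = SimConfig(chromosome_length=5_000_000, library_coverage=122,
                        contamination_fraction=0.0, seed=21)
        rng = np.random.default_rng(21)
        chrom = generate_chromosome(cfg, rng)
        decoy = generate_decoy(cfg, rng)
        clones = simulate_bac_library(chrom, decoy, cfg, rng)
        starts = np.array([a for _, src, a, _ in clones.clones if src == "target"])
        assert starts.size >= 5000
        span = (starts.min(), starts.max() + 1)
        counts, _ = np.histogram(starts, bins=10, range=span)
        p = stats.chisquare(counts).pvalue
        assert p > 0.001


class TestQualityTruth:
    def test_repeat_block_clones_fall_below_quality_floor(self):
        # clonable repeat block (HindIII-positive, fingerprint-site-free):
        # clones mostly inside it carry almost no bands and are rejected
        cfg = SimConfig(chromosome_length=1_000_000, library_coverage=20,
                        contamination_fraction=0.0, quality_dropout=0.0,
                        repeat_blocks=[(0.40, 0.60, LOWBAND_REPEAT_UNIT)], seed=8)
        rng = np.random.default_rng(8)
        chrom = generate_chromosome(cfg, rng)
        decoy = generate_decoy(cfg, rng)
        clones = simulate_bac_library(chrom, decoy, cfg, rng)
        fps = clone_fingerprints(clones, chrom, decoy)
        inside = [fp for fp, (_, _, a, b) in zip(fps, clones.clones)
                  if a >= 400_000 and b <= 600_000]
        assert inside, "library should sample clones inside the clonable block"
        assert all(fp.band_count < 18 for fp in inside)
        retained, rejected = quality_filter(fps)
        assert {f.owner for f in inside} <= {f.owner for f in rejected}

    def test_corruption_pushes_band_count_out_of_window(self, small_library):
        cfg, chrom, decoy, clones = small_library
        fps = clone_fingerprints(clones, chrom, decoy)
        corrupted_ids = {fps[i].owner for i in range(0, len(fps), 7)}
        out = corrupt_fingerprints(fps, corrupted_ids, HicfParams(),
                                   np.random.default_rng(0))
        for fp in out:
            if fp.owner in corrupted_ids:
                assert not 18 <= fp.band_count <= 207
            else:
                assert fp.band_count == next(
                    f for f in fps if f.owner == fp.owner).band_count
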