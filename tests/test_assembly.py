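"""Q exclusion, linear-topology contigs, consensus length, MTP, scaffolds."""

import itertools

import networkx as nx
import numpy as np
import pytest

from physmap.assembly import (Contig, build_contigs, component_is_linear,
                              consensus_band_count, conservation_counts,
                              contig_depth, estimate_length, exclude_q,
                              linearity_violations, merge_scaffolds,
                              select_mtp, validate_scaffolds)
from physmap.params import AssemblyParams, MatchParams
from tests.conftest import make_fp, positional_fp


def edge(score):
    return {"score": score, "log10_score": float(np.log10(score)), "shared": 60}


def chain_graph(n, score=1e-60):
    g = nx.Graph()
    for i in range(n - 1):
        g.add_edge(f"c{i}", f"c{i + 1}", **edge(score))
    return g


def star_graph(n_leaves, score=1e-60):
    g = nx.Graph()
    for i in range(n_leaves):
        g.add_edge("hub", f"leaf{i}", **edge(score))
    return g


def brute_force_linear(g):
    """Exhaustive oracle over all orderings (n <= 9)."""
    nodes = list(g.nodes)
    return any(sum(linearity_violations(g, list(p)).values()) == 0
               for p in itertools.permutations(nodes))


class TestLinearity:
    def test_chain_is_linear(self):
        linear, order = component_is_linear(chain_graph(7))
        assert linear
        assert order in ([f"c{i}" for i in range(7)],
                         [f"c{i}" for i in reversed(range(7))])

    def test_star_is_not_linear(self):
        assert not component_is_linear(star_graph(6))[0]

    def test_clique_is_linear(self):
        g = nx.Graph()
        for a, b in itertools.combinations("abcde", 2):
            g.add_edge(a, b, **edge(1e-40))
        assert component_is_linear(g)[0]

    def test_heuristic_agrees_with_exhaustive_oracle_on_interval_graphs(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 9))
            starts = rng.uniform(0, 100, size=n)
            lengths = rng.uniform(15, 35, size=n)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for i, j in itertools.combinations(range(n), 2):
                if (min(starts[i] + lengths[i], starts[j] + lengths[j])
                        - max(starts[i], starts[j])) > 0:
                    g.add_edge(i, j, **edge(1e-40))
            for comp in nx.connected_components(g):
                sub = g.subgraph(comp)
                assert component_is_linear(sub)[0] == brute_force_linear(sub)

    def test_heuristic_agrees_with_oracle_on_nonlinear_shapes(self):
        for g in (star_graph(4), star_graph(7)):
            assert component_is_linear(g)[0] == brute_force_linear(g) == False


class TestExcludeQ:
    def test_linear_chain_no_exclusions(self):
        g = chain_graph(8)
        cleaned, report = exclude_q(g, MatchParams())
        assert cleaned.number_of_nodes() == 8
        assert report == []

    def test_star_hub_excluded_as_q_clone(self):
        cleaned, report = exclude_q(star_graph(10), MatchParams())
        assert "hub" not in cleaned
        kinds = {(r["stage"], r["id"]) for r in report if r["kind"] == "clone"}
        assert ("q_clone", "hub") in kinds

    def test_q_overlap_edges_dropped_first(self):
        g = chain_graph(5, score=1e-60)
        g.add_edge("c0", "c4", **edge(1e-10))  # weaker than the Q-overlap cutoff
        cleaned, report = exclude_q(g, MatchParams())
        assert not cleaned.has_edge("c0", "c4")
        assert any(r["stage"] == "q_overlap" for r in report)

    def test_idempotent_on_already_linear_components(self):
        g = chain_graph(6)
        once, _ = exclude_q(g, MatchParams())
        twice, report = exclude_q(once, MatchParams())
        assert set(once.nodes) == set(twice.nodes)
        assert report == []


class TestBuildContigs:
    def _fps_for(self, g, n_bands=100):
        return {v: make_fp(v, range(1500, 1500 + n_bands)) for v in g.nodes}

    def test_simulated_positions_recover_order(self, rng):
        # clones every 60 kb with 200 kb inserts: a path-like overlap graph
        from physmap.fingerprint import hicf_fingerprint
        from physmap.overlap import calibrate_match_params, overlap_network
        from physmap.simlib import random_sequence
        seq = random_sequence(500_000, 0.46, rng)
        coords = [(0, 200_000), (60_000, 260_000), (120_000, 320_000),
                  (180_000, 380_000)]
        fps = [hicf_fingerprint(seq[a:b], f"c{k}") for k, (a, b) in enumerate(coords)]
        # calibrate the band-collision probability on an independent,
        # non-overlapping sample (overlapping clones would double-count
        # their truly shared bands as chance collisions)
        bg = random_sequence(1_000_000, 0.46, rng)
        bg_fps = [hicf_fingerprint(bg[k * 100_000:(k + 1) * 100_000], f"w{k}")
                  for k in range(10)]
        params = calibrate_match_params(MatchParams(), bg_fps)
        g = overlap_network(fps, params)
        contigs, singles, report = build_contigs(g, {f.owner: f for f in fps}, params)
        assert len(contigs) == 1 and not singles
        order = contigs[0].clones
        assert order in (["c0", "c1", "c2", "c3"], ["c3", "c2", "c1", "c0"])

    def test_two_clone_contig_questionable(self):
        g = chain_graph(2)
        contigs, _, _ = build_contigs(g, self._fps_for(g), MatchParams())
        assert contigs[0].n_clones == 2
        assert contigs[0].reliability == "questionable"

    def test_six_clone_chain_reliable(self):
        g = chain_graph(6)
        contigs, _, _ = build_contigs(g, self._fps_for(g), MatchParams())
        assert contigs[0].reliability == "reliable"

    def test_isolated_clones_reported_as_singletons(self):
        g = chain_graph(3)
        g.add_node("lone")
        contigs, singles, _ = build_contigs(g, self._fps_for(g), MatchParams())
        assert singles == ["lone"]

    def test_contig_ids_in_decreasing_size_order(self):
        g = chain_graph(3)
        for i in range(3):  # second, smaller component with disjoint bands
            g.add_edge(f"d{i}", f"d{i + 1}", **edge(1e-60))
        fps = {v: make_fp(v, range(1500, 1600)) for v in "c0 c1 c2".split()}
        fps.update({f"d{i}": make_fp(f"d{i}", range(3000, 3030)) for i in range(4)})
        contigs, _, _ = build_contigs(g, fps, MatchParams())
        assert [c.id for c in contigs] == ["ctg1", "ctg2"]
        assert contigs[0].estimated_length_kb >= contigs[1].estimated_length_kb


class TestConsensusAndDepth:
    def test_single_clone_count_and_length(self):
        fps = {"a": make_fp("a", range(1500, 1600))}
        n = consensus_band_count(["a"], fps)
        assert n == 100
        assert estimate_length(n) == pytest.approx(120.0)

    def test_identical_clones_fully_merge(self):
        fps = {"a": make_fp("a", range(1500, 1600)),
               "b": make_fp("b", range(1500, 1600))}
        assert consensus_band_count(["a", "b"], fps) == 100

    def test_band_to_kb_convention(self):
        assert estimate_length(2565) == pytest.approx(3078.0)

    def test_estimate_length_is_linear(self):
        assert (estimate_length(120) + estimate_length(80)
                == pytest.approx(estimate_length(200)))

    def test_partial_overlap_union(self):
        fps = {"a": make_fp("a", range(1500, 1600)),
               "b": make_fp("b", range(1550, 1650))}
        assert consensus_band_count(["a", "b"], fps) == 150

    def test_depth_definition(self):
        assert contig_depth(10, 1220.0) == pytest.approx(1.0)
        assert contig_depth(10, 122.0) == pytest.approx(10.0)

    def test_depth_zero_length_rejected(self):
        with pytest.raises(ValueError):
            contig_depth(5, 0.0)


class TestSelectMtp:
    def _contig(self, clones):
        return Contig(id="ctg1", clones=clones, consensus_band_count=0,
                      estimated_length_kb=1000.0, reliability="reliable",
                      mean_depth=1.0)

    def test_single_clone_contig(self):
        fps = {"a": make_fp("a", range(1500, 1600))}
        sel, warns = select_mtp(self._contig(["a"]), fps, MatchParams())
        assert sel == ["a"] and warns == []

    def test_skips_redundant_middle_clones(self):
        # clones of 200 kb at 0/60/122/180/244 kb; one band per kb =>
        # shared bands equal overlap kb.  0-122 share 78 (39% > 30%),
        # 0-180 share only 20 (10%), so the tiling path is 0, 122, 244.
        starts = [0, 60, 122, 180, 244]
        fps = {f"p{s}": positional_fp(f"p{s}", s, 200) for s in starts}
        contig = self._contig([f"p{s}" for s in starts])
        sel, warns = select_mtp(contig, fps, MatchParams())
        assert sel == ["p0", "p122", "p244"]
        assert warns == []
        # brute-force minimum path cover over qualifying overlaps
        def qualifies(u, v):
            ov = 200 - abs(u - v)
            return ov / 200 >= 0.30 and ov > 0
        dist = {0: 0}
        frontier = [0]
        while frontier and 244 not in dist:
            nxt = []
            for u in frontier:
                for v in starts:
                    if v not in dist and qualifies(u, v):
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        assert len(sel) == dist[244] + 1

    def test_first_and_last_always_included(self):
        starts = [0, 30, 60, 90, 120]
        fps = {f"p{s}": positional_fp(f"p{s}", s, 200) for s in starts}
        sel, _ = select_mtp(self._contig([f"p{s}" for s in starts]),
                            fps, MatchParams())
        assert sel[0] == "p0" and sel[-1] == "p120"

    def test_fpc_mode_low_sharing_forces_consecutive_with_warnings(self):
        fps = {f"c{i}": make_fp(f"c{i}", range(1500 + 95 * i, 1600 + 95 * i))
               for i in range(4)}  # adjacent clones share only 5 bands
        contig = self._contig([f"c{i}" for i in range(4)])
        sel, warns = select_mtp(contig, fps, MatchParams(),
                                AssemblyParams(), mode="fpc")
        assert sel == ["c0", "c1", "c2", "c3"]
        assert len(warns) == 3


class TestScaffolds:
    def _two_contigs(self):
        c1 = Contig("ctg1", ["a1", "a2", "a3", "a4", "a5", "a6"], 600, 720.0,
                    "reliable", 1.0)
        c2 = Contig("ctg2", ["b1", "b2", "b3", "b4", "b5", "b6"], 600, 720.0,
                    "reliable", 1.0)
        g = nx.Graph()
        g.add_nodes_from(c1.clones + c2.clones)
        return c1, c2, g

    def test_marker_at_terminal_clones_merges(self):
        c1, c2, g = self._two_contigs()
        scaffolds, report = merge_scaffolds([c1, c2], g, {"m1": ["a6", "b1"]},
                                            MatchParams())
        merged = [s for s in scaffolds if len(s.contig_ids) == 2]
        assert len(merged) == 1
        assert merged[0].junctions[0][2] == "marker"

    def test_single_linking_clone_merges(self):
        c1, c2, g = self._two_contigs()
        g.add_node("link")
        g.add_edge("link", "a6", **edge(1e-20))
        g.add_edge("link", "b1", **edge(1e-20))
        scaffolds, _ = merge_scaffolds([c1, c2], g, {}, MatchParams())
        merged = [s for s in scaffolds if len(s.contig_ids) == 2]
        assert len(merged) == 1
        assert merged[0].junctions[0][2] == "single-clone"

    def test_three_way_marker_conflict_blocks_merge(self):
        c1, c2, g = self._two_contigs()
        c3 = Contig("ctg3", ["e1", "e2"], 100, 120.0, "questionable", 1.0)
        g.add_nodes_from(c3.clones)
        scaffolds, report = merge_scaffolds(
            [c1, c2, c3], g, {"m1": ["a6", "b1", "e1"]}, MatchParams())
        assert all(len(s.contig_ids) == 1 for s in scaffolds)
        assert any(r["kind"] == "conflict" for r in report)


class TestValidation:
    def _setup(self):
        c1 = Contig("ctg1", [f"a{i}" for i in range(8)], 800, 960.0, "reliable", 1.0)
        c7 = Contig("ctg7", [f"g{i}" for i in range(8)], 800, 960.0, "reliable", 1.0)
        return c1, c7

    def test_rule_b_chimera_flag(self):
        c1, c7 = self._setup()
        hits = {"m1": ["a2", "a3", "a4", "a5", "g3"]}
        flags = validate_scaffolds([], [c1, c7], hits, {})
        chimera = [f for f in flags if f["rule"] == "b"]
        assert len(chimera) == 1
        assert chimera[0]["clone"] == "g3"

    def test_rule_c_non_unique_marker_flag(self):
        c1, c7 = self._setup()
        hits = {"m1": ["a2", "a3", "g3", "g4"]}
        flags = validate_scaffolds([], [c1, c7], hits, {})
        assert [f["rule"] for f in flags] == ["c"]

    def test_rule_d_genetic_distance_split_flag(self):
        from physmap.assembly import Scaffold
        c1, c7 = self._setup()
        scaffold = Scaffold("scf1", ["ctg1", "ctg7"],
                            junctions=[("ctg1", "ctg7", "single-clone")])
        hits = {"m1": ["a2", "a3"], "m2": ["g3", "g4"]}
        gmap = {"m1": 3.0, "m2": 40.0}
        scaffolds = [scaffold]
        flags = validate_scaffolds(scaffolds, [c1, c7], hits, gmap,
                                   apply_splits=True)
        d_flags = [f for f in flags if f["rule"] == "d"]
        assert len(d_flags) == 1
        assert d_flags[0]["split_at"] == ("ctg1", "ctg7")
        assert [s.contig_ids for s in scaffolds] == [["ctg1"], ["ctg7"]]

    def test_rule_d_below_threshold_not_flagged(self):
        from physmap.assembly import Scaffold
        c1, c7 = self._setup()
        scaffold = Scaffold("scf1", ["ctg1", "ctg7"],
                            junctions=[("ctg1", "ctg7", "marker")])
        hits = {"m1": ["a2", "a3"], "m2": ["g3", "g4"]}
        gmap = {"m1": 3.0, "m2": 9.0}
        flags = validate_scaffolds([scaffold], [c1, c7], hits, gmap)
        assert flags == []


def test_conservation_accounting():
    cleaned, report = exclude_q(star_graph(10), MatchParams())
    fps = {v: make_fp(v, range(1500, 1600)) for v in star_graph(10).nodes}
    contigs, singles, b_report = build_contigs(cleaned, fps, MatchParams())
    cons = conservation_counts(11, contigs, singles, report + b_report)
    assert cons["balanced"] == 1
    assert cons["excluded"] == 1 and cons["singletons"] == 10
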