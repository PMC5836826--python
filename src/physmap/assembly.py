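"""Linear-topology contig assembly, scaffolding, validation and MTP selection.

A clone-overlap component is accepted as a contig only if it has *linear
topology*: there exists a clone ordering in which (i) consecutive clones
are connected by a significant overlap and (ii) no overlap "jumps over"
clones unrelated to both of its endpoints.  True interval overlap graphs
always admit such an ordering; chimeric or repeat-rich clones gluing
distant regions do not, and are excluded in stages (Q-overlaps by
significance, then Q-clones detected on the sub-network of highly
significant overlaps at 1e-25 and again at 1e-30, then promiscuous
clones).  Clone order within a component is found by spectral seriation
(Fiedler vector of the -log10(score)-weighted Laplacian) with a greedy
end-extension order as an alternative candidate and a local adjacent-swap
refinement.  Every exclusion, split and merge is logged with its stage so
the audit trail conserves clones.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .fingerprint import Fingerprint
from .overlap import (flag_promiscuous, matched_band_pairs, shared_bands,
                      sulston_log10)
from .params import AssemblyParams, MatchParams

DEFAULT_ASSEMBLY = AssemblyParams()

MAX_LOG_WEIGHT = 1000.0


# ---------------------------------------------------------------------------
# ordering and the linearity test

def _edge_weight(d: dict) -> float:
    return min(-d.get("log10_score", 0.0), MAX_LOG_WEIGHT)


def spectral_order(g: nx.Graph) -> list:
    """Seriation of a connected graph by the Fiedler vector of the
    weighted Laplacian; ties broken by node id for determinism."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n <= 2:
        return nodes
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = _edge_weight(d)
    lap = np.diag(w.sum(axis=1)) - w
    vals, vecs = np.linalg.eigh(lap)
    fiedler = vecs[:, np.argsort(vals)[1]]
    order = np.argsort(fiedler, kind="stable")
    return [nodes[i] for i in order]


def greedy_order(g: nx.Graph) -> list:
    """End-extension order: seed at the most significant overlap, then
    repeatedly append the unplaced clone with the strongest overlap to
    either end; leftover clones are inserted at their best position."""
    nodes = sorted(g.nodes)
    if len(nodes) <= 2:
        return nodes
    wt = {frozenset((u, v)): _edge_weight(d) for u, v, d in g.edges(data=True)}
    seed = max(g.edges(data=True), key=lambda e: (_edge_weight(e[2]), e[0], e[1]))
    path = [seed[0], seed[1]]
    placed = set(path)
    while len(placed) < len(nodes):
        best = None
        for end, insert_at in ((path[0], 0), (path[-1], len(path))):
            for nb in g.neighbors(end):
                if nb in placed:
                    continue
                key = (wt[frozenset((end, nb))], str(nb))
                if best is None or key > best[0]:
                    best = (key, nb, insert_at)
        if best is None:
            # disconnected from both ends (shouldn't happen on connected g);
            # attach the strongest remaining clone next to its best neighbour
            rest = [v for v in nodes if v not in placed]
            v = rest[0]
            pos = max(range(len(path)),
                      key=lambda i: wt.get(frozenset((path[i], v)), 0.0))
            path.insert(pos + 1, v)
            placed.add(v)
            continue
        _, nb, at = best
        path.insert(at, nb)
        placed.add(nb)
    return path


def _refine(order: list, g: nx.Graph, passes: int = 2) -> list:
    """Adjacent-transposition hill climb on the sum of neighbouring
    overlap weights (only strictly improving swaps are applied)."""
    wt = {frozenset((u, v)): _edge_weight(d) for u, v, d in g.edges(data=True)}

    def w(a, b):
        return wt.get(frozenset((a, b)), 0.0)

    order = list(order)
    n = len(order)
    for _ in range(passes):
        improved = False
        for i in range(n - 1):
            a, b = order[i], order[i + 1]
            left = order[i - 1] if i > 0 else None
            right = order[i + 2] if i + 2 < n else None
            cur = (w(left, a) if left else 0.0) + w(a, b) + (w(b, right) if right else 0.0)
            new = (w(left, b) if left else 0.0) + w(a, b) + (w(a, right) if right else 0.0)
            if new > cur + 1e-9:
                order[i], order[i + 1] = b, a
                improved = True
        if not improved:
            break
    return order


def linearity_violations(g: nx.Graph, order: list) -> Counter:
    """Per-clone blame counts for the two linear-topology constraints.

    (i) consecutive clones in the order must overlap: a missing edge
    blames the common neighbours gluing the pair together (the putative
    chimeric clone), or the pair itself if there is none;
    (ii) an overlap spanning distant order positions must be consistent:
    every clone between its endpoints must overlap at least one endpoint,
    otherwise the spanning edge's endpoints are blamed.
    """
    pos = {v: i for i, v in enumerate(order)}
    blame: Counter = Counter()
    for a, b in zip(order, order[1:]):
        if g.has_edge(a, b):
            continue
        common = sorted(set(g.neighbors(a)) & set(g.neighbors(b)))
        for v in common or (a, b):
            blame[v] += 1
    for u, v in g.edges:
        i, j = sorted((pos[u], pos[v]))
        if j - i < 2:
            continue
        for k in range(i + 1, j):
            m = order[k]
            if not (g.has_edge(m, u) or g.has_edge(m, v)):
                blame[u] += 1
                blame[v] += 1
    return blame


def component_is_linear(g: nx.Graph) -> tuple[bool, list]:
    """Try candidate orderings; return (is_linear, best order found)."""
    if g.number_of_nodes() <= 2:
        return True, sorted(g.nodes)
    candidates = []
    for base in (spectral_order(g), greedy_order(g)):
        for order in (base, _refine(base, g)):
            viol = linearity_violations(g, order)
            total = sum(viol.values())
            if total == 0:
                return True, order
            candidates.append((total, order))
    candidates.sort(key=lambda c: c[0])
    return False, candidates[0][1]


def is_linear_order(g: nx.Graph, order: list) -> bool:
    return sum(linearity_violations(g, order).values()) == 0


# ---------------------------------------------------------------------------
# staged Q exclusion

def _resolve_component(h: nx.Graph, nodes: set) -> list:
    """Greedily remove the most-blamed clones until every connected piece
    of the sub-network is linear; returns the removed clones."""
    sub = h.subgraph(nodes).copy()
    removed: list = []
    guard = len(nodes)
    while guard > 0:
        guard -= 1
        worst = None
        for comp in nx.connected_components(sub):
            if len(comp) < 3:
                continue
            cg = sub.subgraph(comp)
            linear, order = component_is_linear(cg)
            if linear:
                continue
            viol = linearity_violations(cg, order)
            cand = max(viol, key=lambda v: (viol[v], cg.degree(v), str(v)))
            if worst is None or viol[cand] > worst[0]:
                worst = (viol[cand], cand)
        if worst is None:
            break
        sub.remove_node(worst[1])
        removed.append(worst[1])
    return removed


def exclude_q(graph: nx.Graph, params: MatchParams
              ) -> tuple[nx.Graph, list[dict]]:
    """Staged Q-overlap / Q-clone exclusion.

    Stage ``q_overlap`` drops edges less significant than the Q-overlap
    cutoff.  Stages ``q_clone`` and ``q_split`` look for clones creating
    non-linear topology on the sub-network of overlaps at the Q-clone
    (1e-25) and split (1e-30) cutoffs respectively — conflicts that
    persist among highly significant overlaps indicate genuinely bad
    clones.  Stage ``promiscuous`` removes clones with over 500 overlaps
    below 1e-50.  Every exclusion is logged with its stage.
    """
    g = graph.copy()
    report: list[dict] = []

    for u, v, d in list(g.edges(data=True)):
        if d["score"] > params.q_overlap_cutoff:
            g.remove_edge(u, v)
            report.append({"stage": "q_overlap", "kind": "edge", "id": (u, v),
                           "detail": f"score {d['score']:.3g} > {params.q_overlap_cutoff:g}"})

    for stage, cutoff in (("q_clone", params.q_clone_cutoff),
                          ("q_split", params.split_cutoff)):
        log_cut = math.log10(cutoff)
        strong = nx.Graph()
        strong.add_nodes_from(g.nodes)
        strong.add_edges_from((u, v, d) for u, v, d in g.edges(data=True)
                              if d["log10_score"] <= log_cut + 1e-12)
        to_remove = []
        for comp in nx.connected_components(g):
            if len(comp) < 3:
                continue
            if component_is_linear(g.subgraph(comp))[0]:
                continue  # stages are no-ops on already-linear components
            to_remove.extend(_resolve_component(strong, comp))
        for v in to_remove:
            g.remove_node(v)
            report.append({"stage": stage, "kind": "clone", "id": v,
                           "detail": f"topology conflict at cutoff {cutoff:g}"})

    for v in flag_promiscuous(g, params):
        g.remove_node(v)
        report.append({"stage": "promiscuous", "kind": "clone", "id": v,
                       "detail": f">{params.promiscuity_degree} overlaps below "
                                 f"{params.promiscuity_score:g}"})
    return g, report


# ---------------------------------------------------------------------------
# contigs

@dataclass(eq=False)
class Contig:
    id: str
    clones: list            # ordered clone ids (orientation arbitrary)
    consensus_band_count: int
    estimated_length_kb: float
    reliability: str        # "reliable" (>= 6 clones) | "questionable" (2-5)
    mean_depth: float

    @property
    def n_clones(self) -> int:
        return len(self.clones)


def consensus_band_count(ordered_clones: list, fps: dict[str, Fingerprint],
                         tolerance: int = 0,
                         graph: nx.Graph | None = None) -> int:
    """Number of consensus bands in a contig.

    Bands of adjacent clones in the contig order are matched within the
    tolerance and matched chains are merged by union-find; each chain is
    one consensus band.  When the overlap ``graph`` is given, bands are
    additionally matched across every significantly overlapping clone pair
    of the contig, so that a band skipped by one short intermediate clone
    is not counted twice (insert lengths vary, so clone i and i+2 can
    share bands that clone i+1 misses).
    """
    offsets = {}
    total = 0
    for cid in ordered_clones:
        offsets[cid] = total
        total += fps[cid].band_count
    parent = list(range(total))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    members = set(ordered_clones)
    pairs = list(zip(ordered_clones, ordered_clones[1:]))
    if graph is not None:
        pairs.extend((u, v) for u, v in graph.edges
                     if u in members and v in members)
    for a, b in pairs:
        for i, j in matched_band_pairs(fps[a], fps[b], tolerance):
            ra, rb = find(offsets[a] + i), find(offsets[b] + j)
            if ra != rb:
                parent[rb] = ra
    return sum(1 for x in range(total) if find(x) == x)


def estimate_length(consensus_bands: int,
                    params: AssemblyParams = DEFAULT_ASSEMBLY) -> float:
    """Contig length in kb from the 1.2 kb average consensus-band length."""
    return consensus_bands * params.band_to_kb


def contig_depth(n_clones: int, estimated_length_kb: float,
                 params: AssemblyParams = DEFAULT_ASSEMBLY) -> float:
    """Assembly depth: clone count x mean insert / estimated length."""
    if estimated_length_kb <= 0:
        raise ValueError("estimated length must be positive")
    return n_clones * params.mean_insert_kb / estimated_length_kb


def build_contigs(cleaned: nx.Graph, fps: dict[str, Fingerprint],
                  match_params: MatchParams,
                  asm_params: AssemblyParams = DEFAULT_ASSEMBLY
                  ) -> tuple[list[Contig], list, list[dict]]:
    """Contigs from the cleaned overlap network.

    Connected components passing the linearity test become contigs with a
    seriation clone order; components still non-linear are split at
    articulation clones (logged).  Returns (contigs, singleton clone ids,
    report).  Contig ids are assigned in decreasing size order.
    """
    report: list[dict] = []
    singletons: list = []
    raw: list[list] = []
    work = [set(c) for c in nx.connected_components(cleaned)]
    g = cleaned.copy()
    while work:
        comp = work.pop()
        if len(comp) == 1:
            singletons.extend(comp)
            continue
        sub = g.subgraph(comp)
        linear, order = component_is_linear(sub)
        if not linear:
            arts = sorted(nx.articulation_points(sub))
            if arts:
                viol = linearity_violations(sub, order)
                cut = max(arts, key=lambda v: (viol.get(v, 0), sub.degree(v), str(v)))
                g.remove_node(cut)
                singletons.append(cut)
                report.append({"stage": "articulation", "kind": "clone", "id": cut,
                               "detail": "non-linear component split at articulation clone"})
                comp.discard(cut)
                work.extend(set(c) for c in nx.connected_components(g.subgraph(comp)))
                continue
            report.append({"stage": "nonlinear", "kind": "note", "id": tuple(sorted(comp)),
                           "detail": "no articulation clone; best ordering accepted"})
        raw.append(order)

    contigs: list[Contig] = []
    for order in raw:
        nb = consensus_band_count(order, fps, match_params.tolerance, graph=cleaned)
        est = estimate_length(nb, asm_params)
        contigs.append(Contig(
            id="", clones=order, consensus_band_count=nb,
            estimated_length_kb=est,
            reliability=("reliable" if len(order) >= asm_params.min_reliable_clones
                         else "questionable"),
            mean_depth=contig_depth(len(order), est, asm_params) if est > 0 else 0.0))
    contigs.sort(key=lambda c: (-c.estimated_length_kb, c.clones[0]))
    for k, c in enumerate(contigs, start=1):
        c.id = f"ctg{k}"
    return contigs, sorted(singletons), report


# ---------------------------------------------------------------------------
# MTP selection

def _pair_score(fa: Fingerprint, fb: Fingerprint, s: int,
                params: MatchParams) -> float:
    nl, nh = sorted((fa.band_count, fb.band_count))
    if s == 0 or nl == 0:
        return 1.0
    return float(10.0 ** sulston_log10(nl, nh, min(s, nl), params))


def select_mtp(contig: Contig, fps: dict[str, Fingerprint],
               match_params: MatchParams,
               asm_params: AssemblyParams = DEFAULT_ASSEMBLY,
               mode: str = "ltc") -> tuple[list, list[str]]:
    """Greedy left-to-right minimal tiling path over the contig order.

    From the current MTP clone, the farthest clone in contig order whose
    overlap satisfies the mode's constraints is chosen; the first and last
    clones are always included.  LTC mode requires a significant overlap
    (score within the MTP cutoff range) sharing at least ~30% of the
    smaller clone's bands; FPC mode requires score <= 1e-30, >= 12 shared
    bands, and an advance of >= 30 new bands.  If no clone qualifies the
    immediate neighbour is used and a warning is emitted.
    """
    order = contig.clones
    warnings: list[str] = []
    if len(order) <= 2:
        return list(order), warnings
    mtp = [order[0]]
    i = 0
    last = len(order) - 1
    while i < last:
        cur = order[i]
        chosen = None
        for j in range(last, i, -1):
            cand = order[j]
            s = shared_bands(fps[cur], fps[cand], match_params.tolerance)
            if s == 0:
                continue
            score = _pair_score(fps[cur], fps[cand], s, match_params)
            if mode == "ltc":
                frac = s / min(fps[cur].band_count, fps[cand].band_count)
                ok = (score <= match_params.mtp_cutoff_range[0]
                      and frac >= match_params.mtp_shared_fraction[0])
            elif mode == "fpc":
                advance = fps[cand].band_count - s
                ok = (score <= asm_params.fpc_min_overlap
                      and s >= asm_params.fpc_min_shared
                      and (advance >= asm_params.fpc_min_dist_bands or j == last))
            else:
                raise ValueError(f"unknown MTP mode: {mode!r}")
            if ok:
                chosen = j
                break
        if chosen is None:
            chosen = i + 1
            warnings.append(f"{contig.id}: no qualifying MTP partner for {cur}; "
                            "falling back to immediate neighbour")
        mtp.append(order[chosen])
        i = chosen
    return mtp, warnings


# ---------------------------------------------------------------------------
# scaffolds and validation

@dataclass(eq=False)
class Scaffold:
    id: str
    contig_ids: list
    junctions: list = field(default_factory=list)  # (left ctg, right ctg, evidence)
    flags: list = field(default_factory=list)      # (rule, detail)


def merge_scaffolds(contigs: list[Contig], graph: nx.Graph,
                    marker_hits: dict[str, list],
                    params: MatchParams) -> tuple[list[Scaffold], list[dict]]:
    """End-to-end merging of contigs into scaffolds.

    Two contigs are linked when (a) the same marker hits a terminal clone
    of each (validation rule a), or a single clone / single clone overlap
    below the network cutoff joins their terminal clones.  Conflicting
    candidates (a marker or linking clone touching three or more contigs,
    or two partners competing for one contig end) block the merge and are
    logged.  Scaffold contig order follows the junction chain.
    """
    report: list[dict] = []
    terminal: dict = {}
    contig_of: dict = {}
    for c in contigs:
        contig_of.update({cl: c.id for cl in c.clones})
        terminal[c.id] = (c.clones[0], c.clones[-1])
    links: list[tuple[str, str, str, str]] = []  # (ctgA, ctgB, evidence, detail)

    term_set = {cl for ends in terminal.values() for cl in ends}

    for marker, hits in sorted(marker_hits.items()):
        ctgs = sorted({contig_of[h] for h in hits
                       if h in term_set and h in contig_of})
        if len(ctgs) == 2:
            links.append((ctgs[0], ctgs[1], "marker", marker))
        elif len(ctgs) > 2:
            report.append({"stage": "merge", "kind": "conflict", "id": marker,
                           "detail": f"marker at terminal clones of {len(ctgs)} contigs"})

    for cl in sorted(set(graph.nodes) - set(contig_of)):
        touched = sorted({contig_of[nb] for nb in graph.neighbors(cl)
                          if nb in term_set and nb in contig_of
                          and graph.edges[cl, nb]["score"] <= params.network_cutoff})
        if len(touched) == 2:
            links.append((touched[0], touched[1], "single-clone", cl))
        elif len(touched) > 2:
            report.append({"stage": "merge", "kind": "conflict", "id": cl,
                           "detail": f"linking clone touches {len(touched)} contigs"})

    for a, b, d in graph.edges(data=True):
        if (a in term_set and b in term_set and a in contig_of and b in contig_of
                and contig_of[a] != contig_of[b]
                and d["score"] <= params.network_cutoff):
            links.append((*sorted((contig_of[a], contig_of[b])), "single-overlap",
                          f"{a}~{b}"))

    lg = nx.Graph()
    lg.add_nodes_from(c.id for c in contigs)
    for a, b, ev, detail in links:
        if lg.has_edge(a, b):
            continue
        lg.add_edge(a, b, evidence=ev, detail=detail)
    # contigs may chain, but a contig with three or more partners is a conflict
    for v in [v for v in lg.nodes if lg.degree(v) > 2]:
        report.append({"stage": "merge", "kind": "conflict", "id": v,
                       "detail": f"contig has {lg.degree(v)} merge partners; none applied"})
        lg.remove_edges_from(list(lg.edges(v)))

    scaffolds: list[Scaffold] = []
    for comp in nx.connected_components(lg):
        sub = lg.subgraph(comp)
        if any(sub.degree(v) > 2 for v in sub) or sub.number_of_edges() >= len(comp):
            # cycle: drop and keep contigs separate
            for v in sorted(comp):
                scaffolds.append(Scaffold(id="", contig_ids=[v]))
            report.append({"stage": "merge", "kind": "conflict", "id": tuple(sorted(comp)),
                           "detail": "cyclic merge candidates; contigs kept separate"})
            continue
        if len(comp) == 1:
            scaffolds.append(Scaffold(id="", contig_ids=sorted(comp)))
            continue
        ends = [v for v in sub if sub.degree(v) == 1]
        path = [min(ends)]
        while len(path) < len(comp):
            nxt = [v for v in sub.neighbors(path[-1]) if v not in path]
            path.append(nxt[0])
        junctions = [(a, b, sub.edges[a, b]["evidence"]) for a, b in zip(path, path[1:])]
        scaffolds.append(Scaffold(id="", contig_ids=path, junctions=junctions))
        for a, b, ev in junctions:
            report.append({"stage": "merge", "kind": "junction", "id": (a, b),
                           "detail": ev})
    scaffolds.sort(key=lambda s: s.contig_ids[0])
    for k, s in enumerate(scaffolds, start=1):
        s.id = f"scf{k}"
    return scaffolds, report


def validate_scaffolds(scaffolds: list[Scaffold], contigs: list[Contig],
                       marker_hits: dict[str, list],
                       genetic_map: dict[str, float],
                       params: AssemblyParams = DEFAULT_ASSEMBLY,
                       apply_splits: bool = False) -> list[dict]:
    """Marker-based validation rules.

    rule b: a marker hitting a group of >= 2 overlapping clones inside one
    contig and also one isolated clone elsewhere flags the isolated clone
    as presumably chimeric.  rule c: a marker present in >= 2 multi-clone
    groups is not unique.  rule d: two markers of one scaffold separated
    by more than the cM threshold on the genetic map flag the scaffold for
    splitting; when requested the split is applied at the junction between
    them whose evidence is weakest (single-clone < single-overlap <
    marker).
    """
    contig_by_id = {c.id: c for c in contigs}
    contig_of = {cl: c.id for c in contigs for cl in c.clones}
    flags: list[dict] = []

    for marker, hits in sorted(marker_hits.items()):
        groups: dict[str, list] = {}
        for h in hits:
            if h in contig_of:
                groups.setdefault(contig_of[h], []).append(h)
        multi = {c: cl for c, cl in groups.items() if len(cl) >= 2}
        single = {c: cl for c, cl in groups.items() if len(cl) == 1}
        if len(multi) >= 2:
            flags.append({"rule": "c", "marker": marker,
                          "detail": f"marker in multi-clone groups of {sorted(multi)}"})
        elif len(multi) == 1 and single:
            for c, cl in sorted(single.items()):
                flags.append({"rule": "b", "marker": marker, "clone": cl[0],
                              "detail": f"isolated hit in {c}; presumably chimeric "
                                        f"(group in {next(iter(multi))})"})

    strength = {"single-clone": 0, "single-overlap": 1, "marker": 2}
    scaffold_of = {}
    for s in scaffolds:
        for c in s.contig_ids:
            scaffold_of[c] = s
    for s in scaffolds:
        placed = []
        for marker, hits in sorted(marker_hits.items()):
            if marker not in genetic_map:
                continue
            in_s = [h for h in hits if contig_of.get(h) in s.contig_ids]
            if in_s:
                placed.append((marker, genetic_map[marker]))
        if len(placed) < 2:
            continue
        cms = [cm for _, cm in placed]
        if max(cms) - min(cms) > params.rule_d_cm_threshold:
            m_lo = min(placed, key=lambda m: m[1])[0]
            m_hi = max(placed, key=lambda m: m[1])[0]
            flag = {"rule": "d", "scaffold": s.id, "markers": (m_lo, m_hi),
                    "detail": f"genetic distance {max(cms) - min(cms):.1f} cM "
                              f"> {params.rule_d_cm_threshold:g} cM"}
            if apply_splits and s.junctions:
                a, b, _ = min(s.junctions, key=lambda j: strength.get(j[2], 0))
                flag["split_at"] = (a, b)
                k = s.contig_ids.index(b)
                head, tail = s.contig_ids[:k], s.contig_ids[k:]
                head_j = [j for j in s.junctions if j[0] in head and j[1] in head]
                tail_j = [j for j in s.junctions if j[0] in tail and j[1] in tail]
                s.contig_ids, s.junctions = head, head_j
                scaffolds.append(Scaffold(id=f"{s.id}b", contig_ids=tail,
                                          junctions=tail_j))
            flags.append(flag)
            s.flags.append(("d", flag["detail"]))
    return flags


def conservation_counts(n_input: int, contigs: list[Contig], singletons: list,
                        report: list[dict]) -> dict[str, int]:
    """Audit: clones in contigs + singletons + excluded == network input."""
    excluded = sum(1 for r in report if r.get("kind") == "clone")
    in_contigs = sum(c.n_clones for c in contigs)
    return {"input": n_input, "in_contigs": in_contigs,
            "singletons": len(singletons), "excluded": excluded,
            "balanced": int(in_contigs + len(singletons) + excluded == n_input)}
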