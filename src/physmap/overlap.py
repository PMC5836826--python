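"""Band matching, Sulston overlap score, and the significant-overlap network.

The Sulston score is the probability that two clones share at least the
observed number of bands by chance.  With a matching tolerance ``t`` on a
scale of ``G`` distinguishable values, a single band of the lower-count
clone matches some band of the higher-count clone with probability
``q = 1 - (1 - p)**nH`` where ``p = (2t + 1) / G`` (the ``2t + 1`` form
keeps t = 0, exact integer matching, well defined).  The score is the
binomial upper tail P(X >= s), X ~ Binomial(nL, q), evaluated in log space
so that tails far below 1e-300 remain ordered.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import networkx as nx
import numpy as np
from scipy.stats import binom

from .fingerprint import Fingerprint
from .params import MatchParams

DEFAULT_MATCH = MatchParams()

_LOG10E = float(np.log10(np.e))


def _bands(fp) -> np.ndarray:
    return fp.bands if isinstance(fp, Fingerprint) else np.asarray(fp, dtype=np.int64)


def _multiset_keys(sorted_bands: np.ndarray) -> np.ndarray:
    # value*4096 + occurrence-index makes a multiset behave as a set.
    occ = np.arange(sorted_bands.size) - np.searchsorted(sorted_bands, sorted_bands)
    return sorted_bands * 4096 + occ


def shared_bands(fp_a, fp_b, tolerance: int = 0) -> int:
    """Greedy leftmost matching of two sorted band lists.

    A pair matches iff ``|a - b| <= tolerance``; each band is used at most
    once.  On sorted lists with a symmetric tolerance the greedy matching
    attains the maximum bipartite matching, and the result is symmetric.
    """
    a, b = _bands(fp_a), _bands(fp_b)
    if tolerance == 0:
        return int(np.intersect1d(_multiset_keys(a), _multiset_keys(b),
                                  assume_unique=True).size)
    i = j = n = 0
    while i < a.size and j < b.size:
        d = int(a[i]) - int(b[j])
        if abs(d) <= tolerance:
            n += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return n


def matched_band_pairs(fp_a, fp_b, tolerance: int = 0) -> list[tuple[int, int]]:
    """Index pairs (i, j) of the greedy matching (used for consensus bands)."""
    a, b = _bands(fp_a), _bands(fp_b)
    i = j = 0
    out: list[tuple[int, int]] = []
    while i < a.size and j < b.size:
        d = int(a[i]) - int(b[j])
        if abs(d) <= tolerance:
            out.append((i, j))
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return out


def match_collision_probability(fps: list, tolerance: int = 0) -> float:
    """Empirical probability that two random bands match within the
    tolerance, estimated from the pooled band-value frequencies.

    In silico band values are quantised (integer raw lengths x 30 per
    enzyme channel), so the chance that two unrelated bands coincide is
    far higher than 1/60,000; this estimate calibrates the Sulston model
    to the actual band-generating process (the in vitro analogue is the
    "gellen" calibration of fingerprinting software).
    """
    allb = np.concatenate([_bands(fp) for fp in fps])
    if allb.size == 0:
        raise ValueError("no bands to calibrate on")
    vals, cnt = np.unique(allb, return_counts=True)
    f = cnt / cnt.sum()
    if tolerance == 0:
        return float((f * f).sum())
    p = 0.0
    for k, v in enumerate(vals):
        lo = np.searchsorted(vals, v - tolerance, side="left")
        hi = np.searchsorted(vals, v + tolerance, side="right")
        p += float(f[k] * f[lo:hi].sum())
    return p


def effective_gel_space(fps: list, tolerance: int = 0) -> int:
    """Gel space G such that (2t+1)/G equals the empirical band-collision
    probability of the data."""
    p = match_collision_probability(fps, tolerance)
    return max(int(round((2 * tolerance + 1) / p)), 2 * tolerance + 3)


def calibrate_match_params(params: MatchParams, fps: list) -> MatchParams:
    """Copy of ``params`` with ``gel_space`` set from the data."""
    import dataclasses
    return dataclasses.replace(
        params, gel_space=effective_gel_space(fps, params.tolerance))


def match_probability(n_high: int, params: MatchParams = DEFAULT_MATCH) -> float:
    p = (2 * params.tolerance + 1) / params.gel_space
    return float(-np.expm1(n_high * np.log1p(-p)))


def _logsf_deep(shared: np.ndarray, n_low: np.ndarray, q: float | np.ndarray
                ) -> np.ndarray:
    """Binomial upper tail by log-sum-exp over the pmf; stays finite for
    tails far below the double-precision floor (~1e-308)."""
    from scipy.special import gammaln, logsumexp
    shared = np.atleast_1d(shared)
    n_low = np.broadcast_to(np.atleast_1d(n_low), shared.shape)
    qa = np.broadcast_to(np.atleast_1d(q), shared.shape)
    out = np.empty(shared.shape)
    for i, (s, n, qq) in enumerate(zip(shared.ravel(), n_low.ravel(), qa.ravel())):
        k = np.arange(s, n + 1)
        logpmf = (gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
                  + k * np.log(qq) + (n - k) * np.log1p(-qq))
        out.ravel()[i] = logsumexp(logpmf)
    return out


def sulston_log10(n_low, n_high, shared, params: MatchParams = DEFAULT_MATCH):
    """log10 of the Sulston score; vectorised over numpy inputs."""
    n_low = np.asarray(n_low, dtype=np.int64)
    n_high = np.asarray(n_high, dtype=np.int64)
    shared = np.asarray(shared, dtype=np.int64)
    if np.any(shared < 0) or np.any(shared > n_low) or np.any(n_low > n_high):
        raise ValueError("require 0 <= shared <= n_low <= n_high")
    p = (2 * params.tolerance + 1) / params.gel_space
    q = -np.expm1(n_high * np.log1p(-p))
    scalar = np.ndim(binom.logsf(shared - 1, n_low, q)) == 0
    logsf = np.atleast_1d(np.asarray(binom.logsf(shared - 1, n_low, q), dtype=float))
    sh = np.broadcast_to(shared, logsf.shape)
    nl = np.broadcast_to(n_low, logsf.shape)
    qq = np.broadcast_to(q, logsf.shape)
    deep = ~np.isfinite(logsf) & (sh > 0)
    if np.any(deep):
        logsf = logsf.copy()
        logsf[deep] = _logsf_deep(sh[deep], nl[deep], qq[deep])
    out = logsf * _LOG10E
    return out[0] if scalar else out


def sulston_score(n_low: int, n_high: int, shared: int,
                  params: MatchParams = DEFAULT_MATCH) -> float:
    """Probability of sharing >= ``shared`` bands by chance (may underflow
    to 0.0 below ~1e-308; use :func:`sulston_log10` for ordering tails)."""
    if shared == 0:
        return 1.0
    return float(10.0 ** sulston_log10(n_low, n_high, shared, params))


def significant(score: float, cutoff: float) -> bool:
    """Inclusive significance rule: score <= cutoff."""
    return score <= cutoff


def _candidate_pairs(fps: list[Fingerprint], params: MatchParams):
    """Pairs that could share at least one band.

    For exact matching (t = 0) an inverted index band value -> clones is
    used; any pair with greedy shared >= 1 has an exact common value and is
    therefore indexed, so no qualifying pair is dropped.  For t > 0 all
    pairs are enumerated.
    """
    if params.tolerance == 0:
        index: dict[int, list[int]] = defaultdict(list)
        for i, fp in enumerate(fps):
            for v in np.unique(fp.bands):
                index[int(v)].append(i)
        pairs = set()
        for clones in index.values():
            if len(clones) > 1:
                pairs.update(itertools.combinations(clones, 2))
        return sorted(pairs)
    n = len(fps)
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def overlap_network(fps: list[Fingerprint],
                    params: MatchParams = DEFAULT_MATCH) -> nx.Graph:
    """Graph with an edge for every clone pair at score <= network_cutoff.

    Edge attributes: ``shared`` (matched bands), ``score`` (Sulston
    probability, 0.0 if underflowed) and ``log10_score``.
    """
    owners = [fp.owner for fp in fps]
    if len(set(owners)) != len(owners):
        raise ValueError("duplicate fingerprint owners")
    g = nx.Graph()
    g.add_nodes_from(owners)
    counts = np.array([fp.band_count for fp in fps], dtype=np.int64)

    rows: list[tuple[int, int, int]] = []
    for i, j in _candidate_pairs(fps, params):
        s = shared_bands(fps[i], fps[j], params.tolerance)
        if s > 0:
            rows.append((i, j, s))
    if not rows:
        return g
    ii = np.array([r[0] for r in rows])
    jj = np.array([r[1] for r in rows])
    ss = np.array([r[2] for r in rows])
    n_low = np.minimum(counts[ii], counts[jj])
    n_high = np.maximum(counts[ii], counts[jj])
    log10s = sulston_log10(n_low, n_high, ss, params)
    scores = 10.0 ** log10s
    cut = np.log10(params.network_cutoff)
    for k in np.flatnonzero(log10s <= cut + 1e-12):
        g.add_edge(owners[ii[k]], owners[jj[k]], shared=int(ss[k]),
                   score=float(scores[k]), log10_score=float(log10s[k]))
    return g


def flag_promiscuous(graph: nx.Graph,
                     params: MatchParams = DEFAULT_MATCH) -> list[str]:
    """Clones with over ``promiscuity_degree`` edges at score strictly below
    ``promiscuity_score`` (repeat-rich or cross-contaminated clones)."""
    log_cut = np.log10(params.promiscuity_score)
    out = []
    for node in graph.nodes:
        k = sum(1 for _, _, d in graph.edges(node, data=True)
                if d["log10_score"] < log_cut)
        if k > params.promiscuity_degree:
            out.append(node)
    return sorted(out)
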