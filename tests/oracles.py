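"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (plain loops, math.comb,
DFS path enumeration) and deliberately shares no code path with the package.
"""

from __future__ import annotations

import math
from statistics import mean, stdev


# --- composite-map enumerations ------------------------------------------

def enumerate_frequency(corpus, phase, procedure=None):
    """Sum n_treated over studies citing each ROI at least once."""
    out = {}
    for study in corpus.studies:
        if procedure is not None and study.procedure != procedure:
            continue
        cited = set()
        for f in corpus.findings:
            if f.study_id == study.study_id and f.phase == phase:
                cited.update(f.rois)
        for roi in cited:
            out[roi] = out.get(roi, 0) + study.n_treated
    return {roi: float(v) for roi, v in out.items()}


def enumerate_directionality(corpus, measure, procedure=None):
    """Weighted mean of distinct (study, roi, direction) sign terms."""
    num, den = {}, {}
    for study in corpus.studies:
        if procedure is not None and study.procedure != procedure:
            continue
        terms = set()
        for f in corpus.findings:
            if (f.study_id == study.study_id and f.phase == "postoperative_change"
                    and f.measure == measure and f.direction is not None):
                for roi in f.rois:
                    terms.add((roi, f.direction))
        for roi, d in terms:
            num[roi] = num.get(roi, 0.0) + study.n_treated * d
            den[roi] = den.get(roi, 0.0) + study.n_treated
    return {roi: num[roi] / den[roi] for roi in num}


def enumerate_outcome(corpus, procedure=None):
    """n-weighted mean Y-BOCS reduction over score-reporting citing studies."""
    acc = {}
    for study in corpus.studies:
        if procedure is not None and study.procedure != procedure:
            continue
        if study.ybocs_pre_mean is None or study.ybocs_post_mean is None:
            continue
        delta = study.ybocs_pre_mean - study.ybocs_post_mean
        cited = set()
        for f in corpus.findings:
            if f.study_id == study.study_id and f.phase == "postoperative_change":
                cited.update(f.rois)
        for roi in cited:
            acc.setdefault(roi, []).append((study.n_treated, delta))
    return {
        roi: sum(n * d for n, d in pairs) / sum(n for n, _ in pairs)
        for roi, pairs in acc.items()
    }


# --- exact tests ----------------------------------------------------------

def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums the probabilities of every 2x2 table with the observed margins
    whose probability does not exceed the observed table's.
    """
    (a, b), (c, d) = table
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2

    def pmf(x):
        return math.comb(n1, x) * math.comb(n2, k - x) / math.comb(n, k)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, k - n2), min(n1, k) + 1):
        p = pmf(x)
        if p <= p_obs * (1.0 + 1e-9):
            total += p
    return min(total, 1.0)


def kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H from the rank-sum formula."""
    pooled = sorted(v for g in groups for v in g)
    n = len(pooled)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        avg = (i + 1 + j) / 2.0
        ranks[pooled[i]] = avg
        i = j
    h = 0.0
    for g in groups:
        r = sum(ranks[v] for v in g)
        h += r * r / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    ties = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j] == pooled[i]:
            j += 1
        t = j - i
        ties += t ** 3 - t
        i = j
    correction = 1.0 - ties / (n ** 3 - n)
    return h / correction if correction > 0 else float("nan")


# --- statistics on volumes ------------------------------------------------

def one_sample_t(values):
    """t = mean / (sd / sqrt(n)) with sample sd (ddof=1)."""
    n = len(values)
    sd = stdev(values)
    if sd == 0.0:
        return float("nan")
    return mean(values) / (sd / math.sqrt(n))


def pearson_r(x, y):
    mx, my = mean(x), mean(y)
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


# --- exhaustive graph centrality -----------------------------------------

def _all_simple_paths(adj, start, goal):
    """DFS enumeration of all simple paths with their total lengths."""
    paths = []

    def walk(node, seen, length, trail):
        if node == goal:
            paths.append((length, tuple(trail)))
            return
        for nxt, w in adj.get(node, {}).items():
            if nxt not in seen:
                walk(nxt, seen | {nxt}, length + w, trail + [nxt])

    walk(start, {start}, 0.0, [start])
    return paths


def exhaustive_centrality(nodes, lengths):
    """Betweenness and closeness by enumerating every simple path.

    ``lengths`` maps frozenset({u, v}) -> path length for existing edges.
    Assumes a connected graph and generic (tie-free) weights up to 1e-9.
    Betweenness uses the 2/((n-1)(n-2)) normalization of undirected graphs;
    closeness is (n-1) / sum of shortest-path lengths.
    """
    adj = {u: {} for u in nodes}
    for edge, w in lengths.items():
        u, v = tuple(edge)
        adj[u][v] = w
        adj[v][u] = w
    n = len(nodes)
    betweenness = {u: 0.0 for u in nodes}
    dist_sum = {u: 0.0 for u in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            paths = _all_simple_paths(adj, s, t)
            best = min(length for length, _ in paths)
            shortest = [trail for length, trail in paths if length <= best + 1e-9]
            dist_sum[s] += best
            dist_sum[t] += best
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for trail in shortest if v in trail)
                betweenness[v] += through / len(shortest)
    scale = 2.0 / ((n - 1) * (n - 2)) if n > 2 else 0.0
    betweenness = {u: b * scale for u, b in betweenness.items()}
    closeness = {u: (n - 1) / dist_sum[u] for u in nodes}
    return betweenness, closeness
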