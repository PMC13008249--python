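"""Independent brute-force oracles used to cross-check the package.

Everything here is written as the obvious O(n*m) enumeration with its own
overlap arithmetic, sharing no code path with the implementations under
test.
"""

from collections import deque


def ivs_overlap(a, b, min_bp=1):
    """(chrom, start, end) triple overlap by >= min_bp shared bp."""
    if a[0] != b[0]:
        return False
    return min(a[2], b[2]) - max(a[1], b[1]) >= min_bp


def brute_overlap_query(query, subjects, min_bp=1):
    """Indices of subjects overlapping query, in (chrom, start, end) order."""
    hits = [i for i, s in enumerate(subjects) if ivs_overlap(query, s, min_bp)]
    hits.sort(key=lambda i: subjects[i])
    return hits


def _components(n_a, n_b, edges):
    """Connected components of a bipartite graph over A-nodes 0..n_a-1 and
    B-nodes 0..n_b-1; returns (components, touched_a, touched_b)."""
    adj = {}
    for i, j in edges:
        adj.setdefault(("a", i), []).append(("b", j))
        adj.setdefault(("b", j), []).append(("a", i))
    seen = set()
    comps = []
    for node in adj:
        if node in seen:
            continue
        comp = []
        queue = deque([node])
        seen.add(node)
        while queue:
            cur = queue.popleft()
            comp.append(cur)
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append(nxt)
        comps.append(comp)
    touched_a = {i for kind, i in seen if kind == "a"}
    touched_b = {j for kind, j in seen if kind == "b"}
    return comps, touched_a, touched_b


def brute_partition(a_ivs, b_ivs, min_bp=1):
    """(n_shared_clusters, a_only_indices, b_only_indices) by all-pairs scan."""
    edges = [
        (i, j)
        for i, a in enumerate(a_ivs)
        for j, b in enumerate(b_ivs)
        if ivs_overlap(a, b, min_bp)
    ]
    comps, touched_a, touched_b = _components(len(a_ivs), len(b_ivs), edges)
    a_only = sorted(set(range(len(a_ivs))) - touched_a)
    b_only = sorted(set(range(len(b_ivs))) - touched_b)
    return len(comps), a_only, b_only


def brute_classify_flags(anchor_iv, grhl2_ivs, pr_ivs, window_ivs, min_bp=1):
    """(has_grhl2, has_pr, has_tss) by all-pairs scan."""
    return (
        any(ivs_overlap(anchor_iv, g, min_bp) for g in grhl2_ivs),
        any(ivs_overlap(anchor_iv, p, min_bp) for p in pr_ivs),
        any(ivs_overlap(anchor_iv, w, min_bp) for w in window_ivs),
    )


def brute_link(loop_anchor_pairs, window_ivs, min_bp=1):
    """Indices of loops with >= 1 anchor overlapping >= 1 window."""
    kept = []
    for i, (a1, a2) in enumerate(loop_anchor_pairs):
        if any(
            ivs_overlap(a, w, min_bp) for a in (a1, a2) for w in window_ivs
        ):
            kept.append(i)
    return kept


def brute_match_loopsets(a_pairs, b_pairs, min_bp=1):
    """(n_a_only, n_b_only, n_shared_components); loops linked iff both
    canonical anchors overlap pairwise."""
    edges = [
        (i, j)
        for i, (a1, a2) in enumerate(a_pairs)
        for j, (b1, b2) in enumerate(b_pairs)
        if ivs_overlap(a1, b1, min_bp) and ivs_overlap(a2, b2, min_bp)
    ]
    comps, touched_a, touched_b = _components(len(a_pairs), len(b_pairs), edges)
    return len(a_pairs) - len(touched_a), len(b_pairs) - len(touched_b), len(comps)


def brute_tss_fraction(points, tss_positions, max_distance):
    """Percentage of (chrom, point) pairs within max_distance of the nearest
    (chrom, tss)."""
    n_close = 0
    for chrom, point in points:
        dists = [abs(point - t) for c, t in tss_positions if c == chrom]
        if dists and min(dists) <= max_distance:
            n_close += 1
    return 100.0 * n_close / len(points)
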