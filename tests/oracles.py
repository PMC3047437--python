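"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations (full dynamic programming,
exhaustive enumeration) kept separate from the library's optimized paths.
"""

from __future__ import annotations

from collections import Counter, deque
from itertools import product


def smith_waterman_score(a: str, b: str, match: float, mismatch: float,
                         gap_open: float, gap_extend: float) -> float:
    """Affine-gap local alignment score by full Gotoh DP.

    Gap of length k costs gap_open + (k - 1) * gap_extend, matching the
    open/extend convention of Bio.Align.PairwiseAligner.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    h = [[0.0] * (m + 1) for _ in range(n + 1)]   # best ending in match state
    e = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in b (a consumed)
    f = [[neg] * (m + 1) for _ in range(n + 1)]   # gap in a (b consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i - 1][j] + gap_open, e[i - 1][j] + gap_extend)
            f[i][j] = max(h[i][j - 1] + gap_open, f[i][j - 1] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def edit_script_multisets(a: str, b: str) -> tuple[int, set[tuple[int, int, int]]]:
    """(edit distance, set of minimal-script operation multisets).

    Each multiset is (n_sub, n_del, n_ins) where deletions remove from ``a``
    and insertions add to ``a``; all co-optimal alignments are enumerated.
    """
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            d[i][j] = min(d[i - 1][j - 1] + cost, d[i - 1][j] + 1,
                          d[i][j - 1] + 1)

    multisets: set[tuple[int, int, int]] = set()

    def back(i: int, j: int, subs: int, dels: int, ins: int) -> None:
        if i == 0 and j == 0:
            multisets.add((subs, dels, ins))
            return
        if i > 0 and j > 0:
            cost = 0 if a[i - 1] == b[j - 1] else 1
            if d[i][j] == d[i - 1][j - 1] + cost:
                back(i - 1, j - 1, subs + cost, dels, ins)
        if i > 0 and d[i][j] == d[i - 1][j] + 1:
            back(i - 1, j, subs, dels + 1, ins)
        if j > 0 and d[i][j] == d[i][j - 1] + 1:
            back(i, j - 1, subs, dels, ins + 1)

    back(n, m, 0, 0, 0)
    return d[n][m], multisets


def classify_pair_oracle(a: str, b: str) -> str | None:
    """Edge type by full edit-distance DP plus script-composition check."""
    if a == b:
        return None
    dist, multisets = edit_script_multisets(a, b)
    if dist == 1 and (1, 0, 0) in multisets:
        return "substitution"
    if dist == 1 and ((0, 1, 0) in multisets or (0, 0, 1) in multisets):
        return "deletion"
    if dist == 2 and ((1, 1, 0) in multisets or (1, 0, 1) in multisets):
        return "deletion_plus_substitution"
    return None


def classify_pair_enumeration(a: str, b: str) -> str | None:
    """Edge type by exhaustive single-deletion enumeration (no DP).

    Used as the oracle for larger repertoires where the DP-with-traceback
    oracle would be too slow.
    """
    if a == b:
        return None
    if len(a) < len(b):
        a, b = b, a
    if len(a) == len(b):
        mism = sum(x != y for x, y in zip(a, b))
        return "substitution" if mism == 1 else None
    if len(a) - len(b) != 1:
        return None
    variants = [a[:i] + a[i + 1:] for i in range(len(a))]
    if b in variants:
        return "deletion"
    for v in variants:
        if sum(x != y for x, y in zip(v, b)) == 1:
            return "deletion_plus_substitution"
    return None


def brute_force_edges(sequences: dict[int, str]) -> set[tuple[int, int, str]]:
    """All-pairs edge set via the enumeration oracle.

    Vectorized with numpy byte arrays (mismatch counts and full
    single-deletion-variant matrices) but still an exhaustive all-pairs
    scan, independent of the library's candidate hashing and of edlib.
    """
    import numpy as np

    ids = sorted(sequences)
    arr = {u: np.frombuffer(sequences[u].encode(), dtype=np.uint8)
           for u in ids}
    edges = set()
    variant_cache: dict[int, "np.ndarray"] = {}

    def variants_matrix(u):
        if u not in variant_cache:
            a = arr[u]
            n = len(a)
            # row i = a with position i deleted
            mat = np.empty((n, n - 1), dtype=np.uint8)
            for i in range(n):
                mat[i, :i] = a[:i]
                mat[i, i:] = a[i + 1:]
            variant_cache[u] = mat
        return variant_cache[u]

    for i, u in enumerate(ids):
        au = arr[u]
        for w in ids[i + 1:]:
            aw = arr[w]
            la, lb = len(au), len(aw)
            if la == lb:
                if int((au != aw).sum()) == 1:
                    edges.add((u, w, "substitution"))
                continue
            if abs(la - lb) != 1:
                continue
            longer, shorter = (u, w) if la > lb else (w, u)
            mism = (variants_matrix(longer) != arr[shorter]).sum(axis=1)
            best = int(mism.min())
            if best == 0:
                edges.add((u, w, "deletion"))
            elif best == 1:
                edges.add((u, w, "deletion_plus_substitution"))
    return edges


def betweenness_enumeration(graph) -> dict:
    """Betweenness as an explicit proportion of enumerated geodesics.

    For every reachable (s, t) pair, all shortest paths are enumerated via
    the BFS predecessor DAG; each vertex's credit for the pair is the
    fraction of those paths passing through it.  The result is normalized by
    the number of reachable pairs excluding the vertex (0 when fewer than
    two other vertices are reachable).
    """
    import networkx as nx

    nodes = list(graph.nodes)
    credit = {v: 0.0 for v in nodes}
    pair_count = {v: 0 for v in nodes}

    for comp in nx.connected_components(graph):
        comp = sorted(comp)
        nc = len(comp)
        for v in comp:
            pair_count[v] = (nc - 1) * (nc - 2) // 2
        for si, s in enumerate(comp):
            # BFS from s
            dist = {s: 0}
            preds: dict = {s: []}
            q = deque([s])
            while q:
                u = q.popleft()
                for w in graph.neighbors(u):
                    if w not in dist:
                        dist[w] = dist[u] + 1
                        preds[w] = [u]
                        q.append(w)
                    elif dist[w] == dist[u] + 1:
                        preds[w].append(u)
            for t in comp[si + 1:]:
                # enumerate all geodesics s -> t
                paths: list[list] = []

                def walk(v, acc):
                    if v == s:
                        paths.append(acc + [v])
                        return
                    for p in preds[v]:
                        walk(p, acc + [v])

                walk(t, [])
                k = len(paths)
                through = Counter()
                for p in paths:
                    for v in p[1:-1]:
                        through[v] += 1
                for v, c in through.items():
                    credit[v] += c / k

    return {v: (credit[v] / pair_count[v] if pair_count[v] else 0.0)
            for v in nodes}
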