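"""Independent oracles used by the test suite.

These deliberately re-derive expected results by exhaustive enumeration or
textbook formulas, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import random

import networkx as nx
import numpy as np

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# -- detector oracle ---------------------------------------------------------


def brute_force_detect(
    read: str,
    sequences: dict[str, str],
    windows,
    min_len: int = 10,
    max_len: int = 99,
    min_flank: int = 10,
) -> tuple[str, int, int] | None:
    """Enumerate every (placement, s, e) decomposition with exact flanks.

    Returns (chromosome, inversion start, inversion end) of the decomposition
    with the smallest start then shortest inverted segment, or None.
    """
    L = len(read)
    best = None
    for win in windows:
        seq = sequences[win.chromosome]
        for a in range(win.start, win.end - L + 1):
            if a < 0 or a + L > len(seq):
                continue
            window = seq[a : a + L]
            for s in range(min_flank, L - min_flank - min_len + 1):
                if read[:s] != window[:s]:
                    continue
                for e in range(s + min_len, min(s + max_len, L - min_flank) + 1):
                    if read[e:] != window[e:]:
                        continue
                    ref_seg = window[s:e]
                    if read[s:e] == ref_seg:
                        continue  # palindromic or identical
                    if read[s:e] == revcomp(ref_seg):
                        key = (win.chromosome, a + s, e - s)
                        if best is None or key < best:
                            best = key
    if best is None:
        return None
    chrom, s, length = best
    return chrom, s, s + length


# -- MIR partition oracle ----------------------------------------------------


def _segment_feasible(intervals: list[tuple[int, int]], tolerance: int) -> bool:
    """A set of calls can form one MIR iff their union is at most ``tolerance``
    longer than the shortest member and every member overlaps the union chain."""
    union_start = min(s for s, _ in intervals)
    union_end = max(e for _, e in intervals)
    min_len = min(e - s for s, e in intervals)
    if union_end - union_start > min_len + tolerance:
        return False
    # all members must pairwise overlap (they nearly span the union)
    for (s1, e1), (s2, e2) in itertools.combinations(intervals, 2):
        if s1 >= e2 or s2 >= e1:
            return False
    return True


def exhaustive_merge(intervals: list[tuple[int, int]], tolerance: int = 4) -> list[list[int]]:
    """Optimal order-respecting partition of sorted calls into MIRs.

    Enumerates every contiguous partition, keeps those whose segments are all
    feasible, selects the minimal segment count, and among those prefers the
    longest first segment, then second, etc. (the greedy tie-break).  Returns
    the list of index segments.
    """
    n = len(intervals)
    assert n >= 1
    best = None
    for cuts in itertools.product([False, True], repeat=n - 1):
        segments = []
        start = 0
        for i, cut in enumerate(cuts, start=1):
            if cut:
                segments.append(list(range(start, i)))
                start = i
        segments.append(list(range(start, n)))
        if not all(_segment_feasible([intervals[i] for i in seg], tolerance) for seg in segments):
            continue
        key = (len(segments), [-len(seg) for seg in segments])
        if best is None or key < best[0]:
            best = (key, segments)
    assert best is not None, "singletons are always feasible"
    return best[1]


# -- random additive trees ---------------------------------------------------


def random_additive_matrix(n_taxa: int, rng: random.Random):
    """Random unrooted binary tree with positive branch lengths and its
    additive leaf-to-leaf distance matrix.

    Returns (labels, matrix, splits): splits is the set of non-trivial leaf
    bipartitions (as frozensets of one side) defining the topology.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    g = nx.Graph()
    center = "I0"
    internal = 1
    for leaf in labels[:3]:
        g.add_edge(center, leaf, weight=rng.uniform(0.5, 2.0))
    for leaf in labels[3:]:
        u, v = rng.choice(list(g.edges))
        w = g[u][v]["weight"]
        t = rng.uniform(0.25, 0.75)
        mid = f"I{internal}"
        internal += 1
        g.remove_edge(u, v)
        g.add_edge(u, mid, weight=w * t)
        g.add_edge(mid, v, weight=w * (1 - t))
        g.add_edge(mid, leaf, weight=rng.uniform(0.5, 2.0))
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    matrix = np.array([[dist[a][b] for b in labels] for a in labels])
    matrix = (matrix + matrix.T) / 2  # remove float asymmetry from path sums
    np.fill_diagonal(matrix, 0.0)
    splits = set()
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u) if x in labels)
        if 2 <= len(side) <= n_taxa - 2:
            splits.add(min(side, frozenset(labels) - side, key=sorted))
    return labels, matrix, splits


def pca_eigh_oracle(X: np.ndarray, n_components: int):
    """PCA via eigendecomposition of the feature covariance (textbook route).

    Returns (coords, explained_variance_ratio, components) with the same sign
    convention as the implementation (largest-magnitude loading positive).
    """
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0, None)
    comps = V[:, :n_components].T.copy()
    for k in range(n_components):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1
    coords = Xc @ comps.T
    evr = w[:n_components] / w.sum()
    return coords, evr, comps
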