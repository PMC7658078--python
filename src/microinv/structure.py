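"""Population structure from MI counts.

Builds the MIR x population count matrix (each cell is the number of
inverted alleles of that population's individuals falling in that MIR) and
derives Euclidean distances between population column vectors, a
neighbor-joining tree, and PCA coordinates (populations as observations,
MIRs as features, centered, unscaled).
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from skbio import TreeNode

from .detect import MICall
from .regions import MIR, AnnotationIndex, classify_mir

logger = logging.getLogger(__name__)

GENIC_CLASSES = frozenset({"CDS", "UTR", "other_exonic", "intronic"})


def groups_from_population_map(
    population_map: Mapping[str, tuple[str, str]], grouping: str = "population"
) -> dict[str, str]:
    """individual -> group, where grouping is 'population' or 'super_population'."""
    idx = {"population": 0, "super_population": 1, "superpopulation": 1}[grouping]
    return {ind: entry[idx] for ind, entry in population_map.items()}


def build_count_matrix(
    calls: Sequence[MICall],
    mirs: Sequence[MIR],
    group_of_individual: Mapping[str, str],
    gene_region_only: bool = False,
    ann: AnnotationIndex | None = None,
) -> pd.DataFrame:
    """MIR x group matrix of inverted-allele counts.

    ``mirs`` must be the pooled MIRs built from exactly ``calls`` (every call
    assigned to one MIR); a call outside the partition is rejected.  With
    ``gene_region_only`` (requires ``ann``), rows are restricted to MIRs
    classified as genic.
    """
    member_set = {c for m in mirs for c in m.members}
    for c in calls:
        if c not in member_set:
            raise ValueError(
                f"call {c.individual}@{c.interval.to_1based()} is not assigned to any MIR"
            )
    if gene_region_only and ann is None:
        raise ValueError("gene_region_only requires an annotation")
    groups = sorted(set(group_of_individual.values()))
    rows = []
    index = []
    for m in mirs:
        if gene_region_only and classify_mir(m, ann) not in GENIC_CLASSES:
            continue
        counts = dict.fromkeys(groups, 0)
        for c in m.members:
            counts[group_of_individual[c.individual]] += 1
        rows.append(counts)
        index.append(m.mir_id)
    return pd.DataFrame(rows, index=index, columns=groups, dtype=int)


def euclidean_distances(
    matrix: pd.DataFrame, sample_sizes: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Pairwise Euclidean distances between population column vectors.

    By default raw counts are used.  Passing ``sample_sizes`` divides each
    column by its population's sample count first (the per-individual
    normalized variant), which is off by default.
    """
    if matrix.shape[1] < 2:
        raise ValueError("at least 2 populations required")
    m = matrix.astype(float)
    if sample_sizes is not None:
        m = m / pd.Series(sample_sizes)[m.columns]
    d = squareform(pdist(m.T.values, metric="euclidean"))
    return pd.DataFrame(d, index=m.columns, columns=m.columns)


def neighbor_joining(distances: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    Ties in the Q criterion are broken by the lexicographically lowest label
    pair.  Negative branch lengths are clamped to zero (with a log note).
    Returns an unrooted tree as a trifurcating-root :class:`skbio.TreeNode`.
    """
    labels = list(distances.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    arr = distances.values.astype(float)
    if list(distances.columns) != labels or not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric with matching labels")
    if np.any(np.diag(arr) != 0):
        raise ValueError("distance matrix diagonal must be zero")

    d: dict[frozenset, float] = {}
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            d[frozenset((a, labels[j]))] = float(arr[i, j])
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    active = sorted(labels)
    counter = 0

    def clamp(x: float) -> float:
        if x < 0:
            logger.info("neighbor joining: negative branch length %.4g clamped to 0", x)
            return 0.0
        return x

    def dist(a: str, b: str) -> float:
        return d[frozenset((a, b))]

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best_pair, best_q = None, None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * dist(a, b) - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                if best_q is None or q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and pair < best_pair):
                    best_q, best_pair = q, pair
        a, b = best_pair
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        counter += 1
        new_label = f"\x00nj{counter}"  # internal; cannot collide with leaf labels
        parent = TreeNode()
        nodes[a].length = clamp(la)
        nodes[b].length = clamp(lb)
        parent.extend([nodes[a], nodes[b]])
        nodes[new_label] = parent
        for k in active:
            if k in (a, b):
                continue
            d[frozenset((new_label, k))] = 0.5 * (dist(a, k) + dist(b, k) - dab)
        active = sorted(x for x in active if x not in (a, b)) + [new_label]
        active.sort()

    a, b, c = active
    root = TreeNode()
    nodes[a].length = clamp(0.5 * (dist(a, b) + dist(a, c) - dist(b, c)))
    nodes[b].length = clamp(0.5 * (dist(a, b) + dist(b, c) - dist(a, c)))
    nodes[c].length = clamp(0.5 * (dist(a, c) + dist(b, c) - dist(a, b)))
    root.extend([nodes[a], nodes[b], nodes[c]])
    return root


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def tree_has_split(tree: TreeNode, group: set[str]) -> bool:
    """True iff some edge of the (unrooted) tree bipartitions the tips into
    ``group`` vs the rest."""
    tips = {t.name for t in tree.tips()}
    group = set(group)
    other = tips - group
    if not group or not other or not group <= tips:
        return False
    for node in tree.non_tips(include_self=True):
        below = {t.name for t in node.tips()}
        if below == group or below == other:
            return True
    return any({t.name} == group or {t.name} == other for t in tree.tips())


@dataclass
class PCAResult:
    """Population coordinates on ordered principal components.

    ``coordinates``: populations x components; ``explained_variance_ratio``:
    non-increasing fractions in [0, 1]; ``loadings``: components x MIRs.
    Component signs are fixed so the largest-magnitude loading is positive.
    """

    coordinates: pd.DataFrame
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame


def pca_populations(matrix: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """PCA of populations in MIR-count space (MIRs as features).

    The count matrix is transposed so populations are observations; features
    are centered but not scaled.
    """
    n_pops = matrix.shape[1]
    if n_pops < 2:
        raise ValueError("at least 2 populations required")
    if n_components > n_pops - 1:
        raise ValueError(
            f"n_components {n_components} too large for {n_pops} populations (max {n_pops - 1})"
        )
    X = matrix.T.values.astype(float)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    # Deterministic sign: make the largest-magnitude loading of each component positive.
    for k in range(n_components):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] *= -1
            coords[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=matrix.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(comps, index=comp_names, columns=matrix.index),
    )
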