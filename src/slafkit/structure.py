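"""Population-structure inference: p-distances, neighbor-joining with
bootstrap, PCA on standardized dosages, genomic relationships and agreement
between alternative sample groupings.

Distances between unphased diploid genotypes are allele-sharing
p-distances: per locus, half the number of allele mismatches between the two
genotypes (0/0 vs 1/1 counts 1.0, 0/0 vs 0/1 counts 0.5), averaged over loci
typed in both samples.  Trees are classical Saitou-Nei neighbor-joining
(scikit-bio backend) with negative intermediate branch lengths clamped to
zero; bootstrap resamples loci with replacement and scores internal-edge
bipartitions.  PCA and the VanRaden-type genomic-relationship matrix share
one standardization: dosages centered by twice the sample allele frequency
and scaled by sqrt(2p(1-p)), missing values mean-imputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

import pandas as pd

from .variants import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "p_distance",
    "neighbor_joining",
    "bootstrap_support",
    "PCAResult",
    "pca",
    "grm",
    "cut_tree",
    "hierarchical_tree",
    "genetic_groups",
    "Partition",
    "partition_concordance",
    "cross_tabulate",
    "write_newick",
]


# ---------------------------------------------------------------------------
# Distances and trees
# ---------------------------------------------------------------------------

def _pairwise_p_distance(dosage: np.ndarray, sample_ids: Sequence[str]) -> np.ndarray:
    n = dosage.shape[0]
    D = np.zeros((n, n))
    d = dosage.astype(float)
    mask = dosage != MISSING
    d[~mask] = np.nan
    for i in range(n - 1):
        diff = np.abs(d[i + 1 :] - d[i]) / 2.0
        shared = mask[i + 1 :] & mask[i]
        counts = shared.sum(axis=1)
        bad = np.where(counts == 0)[0]
        if bad.size:
            j = i + 1 + int(bad[0])
            raise ValueError(
                f"samples {sample_ids[i]!r} and {sample_ids[j]!r} share no typed loci"
            )
        with np.errstate(invalid="ignore"):
            vals = np.nansum(np.where(shared, diff, 0.0), axis=1) / counts
        D[i, i + 1 :] = vals
        D[i + 1 :, i] = vals
    return D


def p_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distance matrix over dosages, excluding missing loci pairwise."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    D = _pairwise_p_distance(matrix.dosage(), matrix.sample_ids)
    return DistanceMatrix(D, ids=matrix.sample_ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    if dm.shape[0] < 2:
        raise ValueError("need at least 2 taxa")
    if dm.shape[0] == 2:
        a, b = dm.ids
        d = float(dm[a, b])
        tree = TreeNode.read([f"({a}:{d},{b}:0.0);"])
        return tree
    return _skbio_nj(dm, neg_as_zero=True)


def _bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Map each informative bipartition (canonical smaller side) to its node."""
    all_tips = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        clade = frozenset(t.name for t in node.tips())
        other = all_tips - clade
        if len(clade) < 2 or len(other) < 2:
            continue  # trivial split
        key = min(clade, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = node
    return out


def bootstrap_support(
    matrix: GenotypeMatrix, replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree with bootstrap supports from locus resampling.

    Loci are resampled with replacement ``replicates`` times; an internal
    edge's support is the fraction of replicate trees containing the same
    leaf bipartition, stored (as a fraction in [0, 1]) on the node name of
    the edge's child, and so emitted as internal node labels in Newick.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    dosage = matrix.dosage()
    tree = neighbor_joining(p_distance(matrix))
    target = _bipartitions(tree)
    counts = {key: 0 for key in target}
    m = matrix.n_sites
    for _ in range(replicates):
        cols = rng.integers(0, m, size=m)
        D = _pairwise_p_distance(dosage[:, cols], matrix.sample_ids)
        rep_tree = _skbio_nj(DistanceMatrix(D, ids=matrix.sample_ids), neg_as_zero=True)
        for key in _bipartitions(rep_tree):
            if key in counts:
                counts[key] += 1
    for key, node in target.items():
        node.name = f"{counts[key] / replicates:g}"
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path))


# ---------------------------------------------------------------------------
# PCA and kinship
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Sample coordinates and per-component variance fractions."""

    sample_ids: list[str]
    coordinates: np.ndarray      # (n_samples, n_components)
    variance_fraction: np.ndarray  # (n_components,)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def _standardized_dosage(matrix: GenotypeMatrix) -> np.ndarray:
    """Mean-imputed dosages centered by 2p and scaled by sqrt(2p(1-p)).

    Monomorphic (or all-missing) columns are dropped.  Multiallelic sites
    participate through their non-reference dosage.
    """
    d = matrix.dosage().astype(float)
    d[d == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    keep = ~np.isnan(p) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("no polymorphic loci")
    d = d[:, keep]
    p = p[keep]
    center = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))
    X = (d - center) / scale
    X = np.where(np.isnan(X), 0.0, X)  # mean imputation == 0 after centering
    return X


def pca(matrix: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of standardized dosages (EIGENSOFT-style).

    Eigendecomposes the sample-by-sample covariance of the standardized
    dosage matrix; the variance fraction of a component is its eigenvalue
    over the trace.  Coordinates are eigenvectors scaled by the square root
    of their eigenvalues.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = _standardized_dosage(matrix)
    m = X.shape[1]
    K = X @ X.T / m
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(n_components, len(evals))
    trace = evals.sum()
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    return PCAResult(
        sample_ids=list(matrix.sample_ids),
        coordinates=coords,
        variance_fraction=evals[:k] / trace,
    )


def grm(matrix: GenotypeMatrix) -> pd.DataFrame:
    """VanRaden-type genomic-relationship matrix from standardized dosages.

    ``G = X X' / m`` with the same standardization as :func:`pca`; under
    Hardy-Weinberg proportions the diagonal averages ~1 and unrelated pairs
    average ~0.
    """
    X = _standardized_dosage(matrix)
    G = X @ X.T / X.shape[1]
    return pd.DataFrame(G, index=matrix.sample_ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# Partitions and concordance
# ---------------------------------------------------------------------------

Partition = Mapping[str, str]


def cut_tree(tree: TreeNode, k: int) -> dict[str, str]:
    """Partition the leaves into ``k`` groups by cutting the longest
    internal edges.

    Internal edges (neither endpoint a leaf) are visited longest-first;
    terminal edges are considered only once internal edges are exhausted
    (needed when ``k`` approaches the leaf count).  An edge is cut only when
    the removal separates an existing leaf group into two non-empty leaf
    groups, so exactly ``k - 1`` effective cuts produce ``k`` groups.
    Groups are labeled C1..Ck in order of their smallest leaf name.
    """
    leaves = [t.name for t in tree.tips()]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(leaves):
        raise ValueError(f"k={k} exceeds leaf count {len(leaves)}")
    G = nx.Graph()
    ids: dict[int, TreeNode] = {}
    for node in tree.traverse(include_self=True):
        ids[id(node)] = node
        for child in node.children:
            G.add_edge(id(node), id(child), length=child.length or 0.0)
    leaf_ids = {id(t): t.name for t in tree.traverse(include_self=True) if t.is_tip()}
    edges = sorted(
        G.edges(data="length"),
        key=lambda e: (e[0] in leaf_ids or e[1] in leaf_ids, -(e[2] or 0.0), min(e[0], e[1])),
    )
    groups = 1
    for u, v, _length in edges:
        if groups == k:
            break
        G.remove_edge(u, v)
        side_u = nx.node_connected_component(G, u)
        side_v = nx.node_connected_component(G, v)
        if any(n in leaf_ids for n in side_u) and any(n in leaf_ids for n in side_v):
            groups += 1
        else:
            G.add_edge(u, v)
    components = []
    for comp in nx.connected_components(G):
        names = sorted(leaf_ids[n] for n in comp if n in leaf_ids)
        if names:
            components.append(names)
    components.sort(key=lambda names: names[0])
    out: dict[str, str] = {}
    for i, names in enumerate(components, start=1):
        for name in names:
            out[name] = f"C{i}"
    return out


def hierarchical_tree(
    coordinates: np.ndarray, ids: Sequence[str], method: str = "ward"
) -> TreeNode:
    """Agglomerative dendrogram over sample coordinates as a tree.

    Branch lengths are merge-height differences, so on well-separated data
    the edges below the top merges are the longest internal edges and
    :func:`cut_tree` recovers the clusters.  Ward linkage is the default:
    its size-weighted merge cost keeps isolated outlying samples from
    dominating the top of the tree, which makes the subsequent edge cutting
    far more robust than cutting a taxon-level NJ tree directly.
    """
    from scipy.cluster.hierarchy import linkage

    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[0] != len(ids):
        raise ValueError("coordinates and ids length mismatch")
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    Z = linkage(coords, method=method)
    n = len(ids)
    heights = {i: 0.0 for i in range(n)}
    nodes: dict[int, TreeNode] = {i: TreeNode(name=str(ids[i])) for i in range(n)}
    for idx, (a, b, h, _count) in enumerate(Z):
        parent = TreeNode()
        for c in (int(a), int(b)):
            child = nodes.pop(c)
            child.length = max(float(h) - heights[c], 0.0)
            parent.append(child)
        nodes[n + idx] = parent
        heights[n + idx] = float(h)
    (root,) = nodes.values()
    return root


def genetic_groups(
    matrix: GenotypeMatrix, k: int, n_components: int = 2
) -> dict[str, str]:
    """Sample grouping from genotype data: PCA, then a Ward dendrogram over
    the leading components, cut into ``k`` groups.

    The leading principal components carry the population structure while
    averaging out per-locus sampling noise; for an expected ``k`` ancestral
    pools the first ``k - 1`` axes suffice, and the default of two matches a
    three-group analysis.
    """
    res = pca(matrix, n_components=n_components)
    tree = hierarchical_tree(res.coordinates, res.sample_ids)
    return cut_tree(tree, k)


def partition_concordance(p1: Partition, p2: Partition) -> float:
    """Fraction of samples on which two partitions agree under the best
    one-to-one matching of cluster labels (Hungarian assignment on the
    contingency table).  Invariant under relabeling either partition."""
    if set(p1) != set(p2):
        raise ValueError("partitions cover different sample sets")
    samples = sorted(p1)
    labels1 = sorted({p1[s] for s in samples})
    labels2 = sorted({p2[s] for s in samples})
    table = np.zeros((len(labels1), len(labels2)), dtype=int)
    i1 = {l: i for i, l in enumerate(labels1)}
    i2 = {l: i for i, l in enumerate(labels2)}
    for s in samples:
        table[i1[p1[s]], i2[p2[s]]] += 1
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum()) / len(samples)


def cross_tabulate(partition: Partition, pop_map: PopulationMap) -> pd.DataFrame:
    """Cluster-by-origin contingency table with totals and row percentages.

    Rows are cluster labels plus an ``All`` totals row; columns are
    population codes plus ``All`` (row total) and ``Ratio(%)`` (row total as
    a percentage of all samples, 2 decimals).
    """
    samples = sorted(partition)
    missing = [s for s in samples if s not in pop_map]
    if missing:
        raise ValueError(f"samples without population code: {missing[:5]}")
    codes = pop_map.codes
    clusters = sorted({partition[s] for s in samples})
    table = pd.DataFrame(0, index=clusters, columns=codes, dtype=int)
    for s in samples:
        table.loc[partition[s], pop_map[s]] += 1
    total = len(samples)
    table["All"] = table.sum(axis=1)
    table["Ratio(%)"] = (100.0 * table["All"] / total).round(2)
    all_row = table.sum(axis=0)
    all_row["Ratio(%)"] = 100.0
    table.loc["All"] = all_row
    table["All"] = table["All"].astype(int)
    return table
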