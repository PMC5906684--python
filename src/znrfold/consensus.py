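"""Dual-evidence consensus trees over clade similarity matrices.

Relationships among fast-diverging small domains are not amenable to
conventional phylogenetics, so they are summarised instead from two
independent evidence channels: profile-profile search E-values and structure
search Z-scores, recorded clade-against-clade. Each channel is turned into a
distance matrix (E-values via -log10, Z-scores as-is), clustered by
single-linkage, and the strict consensus of the two dendrograms — the clades
present in both — is rendered as a rooted tree with support counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CladeNode, CladeTree, SimilarityTable

__all__ = [
    "EvidenceChannel",
    "Dendrogram",
    "build_channel",
    "single_linkage",
    "strict_consensus",
    "build_clade_tree",
]

NEGLOG10_CAP = 300.0  # caps -log10(E) so E = 0 underflow stays finite


@dataclass
class EvidenceChannel:
    """A similarity table processed into a symmetric distance matrix."""

    table: SimilarityTable
    transform: str        # "neglog10" or "identity"
    symmetrization: str   # "mean"
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = self.distances
        assert d.shape[0] == d.shape[1] == len(self.table.labels)
        assert np.allclose(d, d.T) and np.all(d >= -1e-12) and np.all(np.diag(d) == 0)


@dataclass
class Dendrogram:
    """Single-linkage merge list; clusters are label tuples, heights non-decreasing."""

    leaf_labels: list[str]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = field(default_factory=list)

    def clades(self) -> set[frozenset]:
        """Every cluster formed at any merge (the clade set of the dendrogram)."""
        return {frozenset(a) | frozenset(b) for a, b, _ in self.merges}


def build_channel(table: SimilarityTable) -> EvidenceChannel:
    """Convert an E-value or Z-score table into a symmetric distance matrix.

    Similarity is -log10(E) clipped to [0, 300] for E-value tables and the
    Z-score clipped at 0 for Z-score tables. The matrix is symmetrised by the
    pairwise mean, a one-sidedly missing entry contributing just the present
    value; pairs missing in both directions get similarity 0 (no reported hit
    is treated as maximal dissimilarity). Distance is s_max - s', zero on the
    diagonal.
    """
    values = table.values.astype(float).copy()
    n = len(table.labels)
    off_diag = ~np.eye(n, dtype=bool)
    if np.all(np.isnan(values[off_diag])):
        raise ValueError("all off-diagonal entries are missing")
    if table.measure == "evalue":
        transform = "neglog10"
        with np.errstate(divide="ignore"):
            s = np.clip(-np.log10(values), 0.0, NEGLOG10_CAP)
    else:
        transform = "identity"
        s = np.clip(values, 0.0, None)
    # pairwise mean; one-sided missing keeps the present value, double missing -> 0
    st = s.T
    nan_s, nan_t = np.isnan(s), np.isnan(st)
    sym = np.where(nan_s & nan_t, 0.0,
                   np.where(nan_s, st, np.where(nan_t, s, (s + st) / 2.0)))
    np.fill_diagonal(sym, 0.0)
    s_max = float(sym[off_diag].max()) if n > 1 else 0.0
    dist = s_max - sym
    np.fill_diagonal(dist, 0.0)
    return EvidenceChannel(table=table, transform=transform, symmetrization="mean",
                           distances=dist)


def single_linkage(channel: EvidenceChannel) -> Dendrogram:
    """Agglomerative single-linkage clustering with deterministic tie-breaking.

    Among merges of equal distance, the pair whose lexicographically smallest
    member label is smallest wins (then the smallest label of the other
    cluster). Heights are non-decreasing by the single-linkage property.
    """
    labels = list(channel.table.labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    dist = channel.distances
    index = {lab: i for i, lab in enumerate(labels)}
    clusters: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    def linkage(a: tuple[str, ...], b: tuple[str, ...]) -> float:
        return min(dist[index[x], index[y]] for x in a for y in b)

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = linkage(clusters[i], clusters[j])
                lo, hi = sorted((min(clusters[i]), min(clusters[j])))
                key = (d, lo, hi)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        a, b = clusters[i], clusters[j]
        if min(b) < min(a):
            a, b = b, a
        merges.append((a, b, float(d)))
        merged = tuple(sorted(a + b))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return Dendrogram(leaf_labels=labels, merges=merges)


def strict_consensus(d1: Dendrogram, d2: Dendrogram) -> CladeTree:
    """Rooted tree of the clades present in both dendrograms (support count 2).

    The intersection of two hierarchical clade sets is itself nested, so the
    kept clades always assemble into a tree; leaves are always present, and
    the root (the full leaf set) is formed by the last merge of both inputs.
    """
    set1, set2 = set(d1.leaf_labels), set(d2.leaf_labels)
    if set1 != set2:
        diff = sorted(set1 ^ set2)
        raise ValueError(f"leaf sets differ; symmetric difference: {diff}")
    shared = d1.clades() & d2.clades()
    shared.add(frozenset(set1))  # root, present in both by construction

    # assemble nested clades bottom-up, smallest first
    ordered = sorted(shared, key=lambda c: (len(c), sorted(c)))
    nodes: dict[frozenset, CladeNode] = {}
    placed: set[frozenset] = set()
    leaf_nodes = {lab: CladeNode(label=lab) for lab in set1}
    placed_leaves: set[str] = set()
    for clade in ordered:
        children: list[CladeNode] = []
        # maximal already-built clades inside this one
        inner = sorted((c for c in placed if c < clade), key=len, reverse=True)
        used: set[frozenset] = set()
        covered: set[str] = set()
        for c in inner:
            if c & covered:
                continue
            children.append(nodes[c])
            used.add(c)
            covered |= set(c)
        for lab in sorted(clade - covered):
            children.append(leaf_nodes[lab])
        children.sort(key=lambda nd: sorted(nd.leaf_labels())[0])
        node = CladeNode(children=children, support=2)
        nodes[clade] = node
        placed -= used
        placed.add(clade)
    return CladeTree(root=nodes[frozenset(set1)])


def build_clade_tree(evalue_table: SimilarityTable,
                     zscore_table: SimilarityTable) -> CladeTree:
    """E-value channel + Z-score channel -> single linkage each -> strict consensus."""
    if list(evalue_table.labels) != list(zscore_table.labels):
        if set(evalue_table.labels) != set(zscore_table.labels):
            diff = sorted(set(evalue_table.labels) ^ set(zscore_table.labels))
            raise ValueError(f"label sets differ; symmetric difference: {diff}")
    d1 = single_linkage(build_channel(evalue_table))
    d2 = single_linkage(build_channel(zscore_table))
    return strict_consensus(d1, d2)
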