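"""Haplotype networks and locus partitioning.

MHC class II exon 2 in gulls (and many other birds) is amplified from more
than one locus at once.  Two graph-level views help untangle this:

* a **minimum spanning network** (epsilon = 0): a minimum spanning tree over
  Hamming distances that additionally keeps every co-minimal alternative
  edge, so ties are displayed rather than broken arbitrarily;
* a **two-cluster locus partition**: average-linkage hierarchical clustering
  on nucleotide p-distance, with cluster support from site-bootstrap
  replicates, standing in for the deep split a gene tree would show between
  paralogous loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .seqio import CodonAlignment


def hamming_matrix(aln: CodonAlignment) -> np.ndarray:
    """Symmetric matrix of pairwise nucleotide difference counts."""
    mat = np.array([list(s) for s in aln.seqs], dtype="U1")
    n = mat.shape[0]
    D = np.zeros((n, n), dtype=int)
    for i in range(n - 1):
        d = (mat[i] != mat[i + 1 :]).sum(axis=1)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return D


@dataclass(frozen=True)
class NetworkEdge:
    id_a: str
    id_b: str
    distance: int
    in_mst: bool


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[tuple[str, int], ...]  # (haplotype_id, frequency)
    edges: tuple[NetworkEdge, ...]

    @property
    def mst_edges(self) -> list[NetworkEdge]:
        return [e for e in self.edges if e.in_mst]

    def total_mst_weight(self) -> int:
        return sum(e.distance for e in self.mst_edges)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_network(
    aln: CodonAlignment, freqs: Mapping[str, int] | None = None
) -> HaplotypeNetwork:
    """Epsilon-0 minimum spanning network over Hamming distances.

    Kruskal-style growth by distance level: at each level, every edge that
    joins components distinct *at the start of the level* enters the network;
    a deterministic subset of them (ordered by ID pair) forms the spanning
    tree proper (``in_mst=True``), the co-minimal alternatives are kept with
    ``in_mst=False``.
    """
    ids = aln.ids
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate haplotype IDs")
    n = aln.n
    freq = {rid: (freqs.get(rid, 1) if freqs else 1) for rid in ids}
    nodes = tuple((rid, freq[rid]) for rid in ids)
    if n == 1:
        return HaplotypeNetwork(nodes=nodes, edges=())
    D = hamming_matrix(aln)
    if any(D[i, j] == 0 for i in range(n - 1) for j in range(i + 1, n)):
        raise ValueError("haplotypes must be distinct (zero-distance pair found)")
    levels: dict[int, list[tuple[int, int]]] = {}
    for i in range(n - 1):
        for j in range(i + 1, n):
            levels.setdefault(int(D[i, j]), []).append((i, j))
    uf = _UnionFind(n)
    edges: list[NetworkEdge] = []
    n_components = n
    for dist in sorted(levels):
        if n_components == 1:
            break
        # edges bridging components as of the start of this level
        bridging = [
            (i, j) for i, j in sorted(levels[dist]) if uf.find(i) != uf.find(j)
        ]
        for i, j in bridging:
            joined = uf.union(i, j)
            edges.append(
                NetworkEdge(id_a=ids[i], id_b=ids[j], distance=dist, in_mst=joined)
            )
            if joined:
                n_components -= 1
    return HaplotypeNetwork(nodes=nodes, edges=tuple(edges))


@dataclass(frozen=True)
class LocusClusters:
    clusters: dict[str, int]  # haplotype_id -> cluster label (1 = largest)
    support: dict[int, float]  # cluster label -> bootstrap support
    k: int


def _cluster_labels(mat: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage clusters (0-based labels) from a site matrix."""
    n, L = mat.shape
    pdist = np.empty(n * (n - 1) // 2)
    idx = 0
    for i in range(n - 1):
        d = (mat[i] != mat[i + 1 :]).mean(axis=1)
        pdist[idx : idx + n - 1 - i] = d
        idx += n - 1 - i
    Z = linkage(pdist, method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def locus_clusters(
    aln: CodonAlignment,
    k: int = 2,
    bootstrap_reps: int = 100,
    seed: int | None = None,
) -> LocusClusters:
    """Partition haplotypes into ``k`` putative loci with bootstrap support.

    Support for each cluster is the fraction of site-bootstrap replicates in
    which exactly the same haplotype set reappears as a cluster.  Labels are
    assigned by descending cluster size (1 = largest), ties broken by the
    lexicographically smallest member ID.
    """
    if aln.n < k:
        raise ValueError(f"need at least k={k} sequences")
    mat = np.array([list(s) for s in aln.seqs], dtype="U1")
    if len({tuple(row) for row in mat}) == 1 and k > 1:
        raise ValueError("all sequences identical; cannot partition into k > 1 clusters")
    labels = _cluster_labels(mat, k)
    ids = aln.ids
    members: dict[int, frozenset[str]] = {
        lab: frozenset(ids[i] for i in np.where(labels == lab)[0])
        for lab in np.unique(labels)
    }
    order = sorted(members, key=lambda lab: (-len(members[lab]), min(members[lab])))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    clusters = {ids[i]: relabel[labels[i]] for i in range(aln.n)}

    support: dict[int, float] = {relabel[lab]: 0.0 for lab in members}
    if bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        L = mat.shape[1]
        hits = {relabel[lab]: 0 for lab in members}
        for _ in range(bootstrap_reps):
            cols = rng.integers(0, L, size=L)
            bmat = mat[:, cols]
            try:
                blabels = _cluster_labels(bmat, k)
            except ValueError:
                continue
            bsets = {
                frozenset(ids[i] for i in np.where(blabels == lab)[0])
                for lab in np.unique(blabels)
            }
            for lab, mem in members.items():
                if mem in bsets:
                    hits[relabel[lab]] += 1
        support = {lab: hits[lab] / bootstrap_reps for lab in hits}
    return LocusClusters(clusters=clusters, support=support, k=k)
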