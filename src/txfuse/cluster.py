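"""Group pooled contigs into orthogroups by Markov clustering a similarity graph.

Homology between contigs is measured as max-containment of canonical k-mer
sets, ``|K(a) & K(b)| / min(|K(a)|, |K(b)|)``: a fragment of a transcript is
fully contained in its full-length version and therefore connects to it with
weight ~1, which is exactly the behaviour the representative-selection step
relies on (fragments must co-cluster with their parents).  Candidate pairs are
found through a shared-k-mer inverted index, so the quadratic all-vs-all space
is never materialised.

The graph is partitioned with classic Markov clustering (MCL): alternate
expansion (matrix power on the column-stochastic adjacency with self-loops)
and inflation (entrywise power + column renormalisation), with pruning of tiny
entries, until the matrix is stable.  The default inflation of 4 — much higher
than MCL's usual 2 — deliberately yields fine-grained clusters so that
transcript isoforms resist collapsing into a single group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import kmers
from .seqio import Contig, ContigSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MclParams:
    """Markov clustering parameters (inflation default 4)."""

    inflation: float = 4.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class Orthogroup:
    """A cluster of contigs inferred to represent the same transcript/gene."""

    group_id: int
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("orthogroup must be non-empty")


def kmer_similarity(a, b, k: int = 31) -> float:
    """Max-containment of canonical k-mer sets, in [0, 1].

    Symmetric; 1.0 for identical sequences and for a sequence fully contained
    in another.  A sequence shorter than k has no k-mers: similarity 0 with a
    logged warning.
    """
    seq_a = a.seq if isinstance(a, Contig) else a
    seq_b = b.seq if isinstance(b, Contig) else b
    if len(seq_a) < k or len(seq_b) < k:
        logger.warning("sequence shorter than k=%d; similarity set to 0", k)
        return 0.0
    ka = kmers.canonical_kmer_set(seq_a, k)
    kb = kmers.canonical_kmer_set(seq_b, k)
    if ka.size == 0 or kb.size == 0:
        return 0.0
    shared = np.intersect1d(ka, kb, assume_unique=True).size
    return shared / min(ka.size, kb.size)


def build_graph(
    pooled: ContigSet,
    k: int = 31,
    min_similarity: float = 0.1,
    max_kmer_occurrence: int = 256,
) -> nx.Graph:
    """Build the contig similarity graph via a shared-k-mer inverted index.

    Nodes are all contig ids (contigs without any edge stay as isolated
    nodes); an edge joins exactly those pairs whose max-containment is at
    least ``min_similarity``, with the similarity as edge weight.  K-mers
    occurring in more than ``max_kmer_occurrence`` contigs are skipped when
    proposing candidate pairs (repeat guard; such k-mers still count toward
    the containment denominator).
    """
    if len(pooled) == 0:
        raise ValueError("cannot build a graph from an empty contig set")
    ids = pooled.ids()
    sets = []
    for cid in ids:
        seq = pooled[cid].seq
        if len(seq) < k:
            logger.warning("contig %s shorter than k=%d; left isolated", cid, k)
            sets.append(np.zeros(0, dtype=np.uint64))
        else:
            sets.append(kmers.canonical_kmer_set(seq, k))
    sizes = np.array([s.size for s in sets], dtype=np.int64)

    # inverted index: sort all (kmer, contig) postings by kmer
    all_kmers = np.concatenate(sets) if sets else np.zeros(0, dtype=np.uint64)
    owner = np.repeat(np.arange(len(ids), dtype=np.int64), sizes)
    order = np.argsort(all_kmers, kind="stable")
    sk, so = all_kmers[order], owner[order]

    # run boundaries of identical k-mers
    n = len(ids)
    if sk.size:
        boundary = np.flatnonzero(np.diff(sk)) + 1
        starts = np.concatenate(([0], boundary))
        cnt = np.diff(np.concatenate((starts, [sk.size])))
    else:
        starts = np.zeros(0, dtype=np.int64)
        cnt = np.zeros(0, dtype=np.int64)

    # emit all co-occurrence pairs per shared k-mer, vectorised by run length
    keep = (cnt >= 2) & (cnt <= max_kmer_occurrence)
    pair_i: list[np.ndarray] = []
    pair_j: list[np.ndarray] = []
    for c in np.unique(cnt[keep]):
        sel = starts[keep][cnt[keep] == c]
        members = so[sel[:, None] + np.arange(c)]
        members.sort(axis=1)
        iu, ju = np.triu_indices(int(c), 1)
        pair_i.append(members[:, iu].ravel())
        pair_j.append(members[:, ju].ravel())

    G = nx.Graph()
    G.add_nodes_from(ids)
    n_edges = 0
    if pair_i:
        keys = np.concatenate(pair_i) * n + np.concatenate(pair_j)
        uniq, shared = np.unique(keys, return_counts=True)
        ui, uj = np.divmod(uniq, n)
        sims = shared / np.minimum(sizes[ui], sizes[uj])
        for i, j, sim in zip(ui, uj, sims):
            if sim >= min_similarity:
                G.add_edge(ids[i], ids[j], weight=min(float(sim), 1.0))
                n_edges += 1
    logger.info("similarity graph: %d nodes, %d edges", n, n_edges)
    return G


def _mcl_dense(A: np.ndarray, params: MclParams) -> tuple[np.ndarray, bool]:
    """Run MCL on a dense adjacency (self-loops already set); return (M, converged)."""
    M = A / A.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(params.max_iter):
        E = np.linalg.matrix_power(M, params.expansion)
        I = np.power(E, params.inflation)
        colsum = I.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M_new = I / colsum
        # prune after renormalisation so uniform wide columns survive inflation
        M_new[M_new < params.prune_threshold] = 0.0
        colsum = M_new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M_new = M_new / colsum
        delta = np.abs(M_new - M).max()
        M = M_new
        if delta < params.tol:
            converged = True
            break
    return M, converged


def _interpret(M: np.ndarray, eps: float = 1e-6) -> list[list[int]]:
    """Extract clusters from a converged MCL matrix.

    Attractors are rows with positive diagonal mass; attractors sharing any
    attracted node form one attractor system; every node joins the system of
    its highest-mass attractor (ties to the lowest system id, systems ordered
    by smallest attractor index).
    """
    n = M.shape[0]
    attractors = np.flatnonzero(np.diag(M) > eps)
    if attractors.size == 0:
        # non-converged pathological case: everything in one cluster
        return [list(range(n))]
    # union attractors that attract a common node
    parent = {int(a): int(a) for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        owning = attractors[M[attractors, j] > eps]
        for a in owning[1:]:
            ra, rb = find(int(owning[0])), find(int(a))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(int(a)) for a in attractors})
    sys_of_attr = {int(a): roots.index(find(int(a))) for a in attractors}

    clusters: list[list[int]] = [[] for _ in roots]
    claimed = np.zeros(n, dtype=bool)
    mass = M[attractors, :]  # (n_attr, n)
    for j in range(n):
        col = mass[:, j]
        best = col.max()
        if best <= eps:
            continue
        # highest-mass attractor; ties resolved to the lowest system id
        cand = attractors[col >= best - 1e-15]
        sys_id = min(sys_of_attr[int(a)] for a in cand)
        clusters[sys_id].append(j)
        claimed[j] = True
    for j in np.flatnonzero(~claimed):
        clusters.append([int(j)])
    return [c for c in clusters if c]


def markov_cluster(graph: nx.Graph, params: MclParams = MclParams()) -> list[Orthogroup]:
    """Partition a similarity graph into orthogroups with Markov clustering.

    Self-loop weight per node is its maximum incident edge weight (1.0 for
    isolated nodes), MCL standard practice.  Disconnected components are
    clustered independently — MCL can never merge them — which also keeps the
    dense linear algebra small.  Non-convergence at ``max_iter`` returns the
    current interpretation with a logged warning.  The returned groups always
    partition the node set; group ids are provisional (ordered by smallest
    member id) — :func:`cluster_assemblies` applies the final ordering.
    """
    groups: list[frozenset[str]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            groups.append(frozenset(nodes))
            continue
        sub = graph.subgraph(nodes)
        n = len(nodes)
        A = np.zeros((n, n))
        index = {v: i for i, v in enumerate(nodes)}
        for u, v, data in sub.edges(data=True):
            w = float(data.get("weight", 1.0))
            A[index[u], index[v]] = w
            A[index[v], index[u]] = w
        loop = A.max(axis=0)
        loop[loop == 0] = 1.0
        np.fill_diagonal(A, loop)
        M, converged = _mcl_dense(A, params)
        if not converged:
            logger.warning(
                "MCL did not converge in %d iterations on a %d-node component",
                params.max_iter, n,
            )
        for idxs in _interpret(M):
            groups.append(frozenset(nodes[i] for i in idxs))
    groups.sort(key=lambda g: min(g))
    return [Orthogroup(group_id=i, members=g) for i, g in enumerate(groups)]


def cluster_assemblies(
    pooled: ContigSet,
    k: int = 31,
    min_similarity: float = 0.1,
    params: MclParams = MclParams(),
) -> list[Orthogroup]:
    """build_graph -> markov_cluster, with final group-id ordering.

    Group ids are assigned in decreasing order of member count, ties by the
    smallest member id, so output is stable across runs.
    """
    graph = build_graph(pooled, k=k, min_similarity=min_similarity)
    raw = markov_cluster(graph, params)
    raw.sort(key=lambda g: (-len(g.members), min(g.members)))
    out = [Orthogroup(group_id=i, members=g.members) for i, g in enumerate(raw)]
    assert sum(len(g.members) for g in out) == len(pooled), "groups must partition contigs"
    logger.info("clustered %d contigs into %d orthogroups", len(pooled), len(out))
    return out


def write_orthogroups(groups: list[Orthogroup], path) -> None:
    """Write orthogroups as TSV: group_id, member_count, comma-joined members."""
    import pandas as pd

    from .seqio import write_tsv

    df = pd.DataFrame(
        {
            "group_id": [g.group_id for g in groups],
            "member_count": [len(g.members) for g in groups],
            "members": [",".join(sorted(g.members)) for g in groups],
        }
    )
    write_tsv(df, path)
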