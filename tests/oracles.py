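"""Independent reference implementations used as test oracles.

Everything here is deliberately written in the most transparent way possible
(string sets, python loops, dense matrices without pruning) and stays
independent of the library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp_str(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_set_str(seq: str, k: int) -> set[str]:
    """Canonical k-mer set via plain string manipulation."""
    out = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        out.add(min(km, revcomp_str(km)))
    return out


def containment_str(a: str, b: str, k: int) -> float:
    ka, kb = kmer_set_str(a, k), kmer_set_str(b, k)
    if not ka or not kb:
        return 0.0
    return len(ka & kb) / min(len(ka), len(kb))


def jaccard_str(a: str, b: str, k: int) -> float:
    ka, kb = kmer_set_str(a, k), kmer_set_str(b, k)
    if not ka and not kb:
        return 0.0
    return len(ka & kb) / len(ka | kb)


# ---------------------------------------------------------------------------
# Dense MCL reference (no pruning, run to convergence)
# ---------------------------------------------------------------------------

def mcl_reference(
    nodes: list,
    weighted_edges: list[tuple],
    inflation: float = 4.0,
    expansion: int = 2,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> set[frozenset]:
    """Classic MCL on the full dense matrix, no pruning.

    Self-loops are the maximum incident edge weight (1.0 for isolated nodes).
    Attractors (positive diagonal) sharing any attracted node are merged into
    one cluster; every node joins its highest-mass attractor's cluster.
    Returns the partition as a set of frozensets.
    """
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, w in weighted_edges:
        A[pos[u], pos[v]] = w
        A[pos[v], pos[u]] = w
    for i in range(n):
        m = A[:, i].max()
        A[i, i] = m if m > 0 else 1.0
    M = A / A.sum(axis=0)
    for _ in range(max_iter):
        E = np.linalg.matrix_power(M, expansion)
        I = E ** inflation
        Mn = I / I.sum(axis=0)
        if np.abs(Mn - M).max() < tol:
            M = Mn
            break
        M = Mn

    eps = 1e-7
    attractors = [i for i in range(n) if M[i, i] > eps]
    # merge attractors that attract a common node
    clusters: list[set[int]] = []
    attr_cluster: dict[int, int] = {}
    for a in attractors:
        attr_cluster[a] = len(clusters)
        clusters.append({a})
    for j in range(n):
        owning = [a for a in attractors if M[a, j] > eps]
        if len(owning) > 1:
            target = attr_cluster[owning[0]]
            for a in owning[1:]:
                src = attr_cluster[a]
                if src != target:
                    moved = [x for x, c in attr_cluster.items() if c == src]
                    for x in moved:
                        attr_cluster[x] = target
    # assign each node to its highest-mass attractor's cluster
    assignment: dict[int, int] = {}
    for j in range(n):
        best_a, best_m = None, eps
        for a in attractors:
            if M[a, j] > best_m or (M[a, j] == best_m and best_a is None):
                best_a, best_m = a, M[a, j]
        if best_a is not None:
            assignment[j] = attr_cluster[best_a]
    out: dict[int, set] = {}
    singles = []
    for j in range(n):
        if j in assignment:
            out.setdefault(assignment[j], set()).add(nodes[j])
        else:
            singles.append({nodes[j]})
    partition = [frozenset(s) for s in out.values()] + [frozenset(s) for s in singles]
    return set(partition)


# ---------------------------------------------------------------------------
# Coverage-segmentation BIC oracle
# ---------------------------------------------------------------------------

def seg_score_reference(cov) -> float:
    """BIC weight of the 1-segment model, arithmetic spelled out longhand."""
    cov = [float(c) for c in cov]
    n = len(cov)
    if n == 0:
        raise ValueError
    if not any(c > 0 for c in cov):
        return 0.0
    if n == 1:
        return 1.0
    y = [math.log2(c + 1.0) for c in cov]

    def sse(vals):
        m = sum(vals) / len(vals)
        return sum((v - m) ** 2 for v in vals)

    sse1 = sse(y)
    bps = sorted({int(round(n * d / 10)) for d in range(1, 10)} & set(range(1, n)))
    if not bps:
        return 1.0
    sse2 = min(sse(y[:b]) + sse(y[b:]) for b in bps)
    floor = 1e-9 * n
    bic1 = n * math.log(max(sse1, floor) / n) + 2 * math.log(n)
    bic2 = n * math.log(max(sse2, floor) / n) + 4 * math.log(n)
    lo = min(bic1, bic2)
    w1 = math.exp(-(bic1 - lo) / 2.0)
    w2 = math.exp(-(bic2 - lo) / 2.0)
    return w1 / (w1 + w2)


def argmax_winner(members, composites, lengths):
    """Exhaustive winner search: best composite, then longest, then smallest id."""
    best = None
    for cid in members:
        key = (composites[cid], lengths[cid])
        if best is None:
            best = cid
            continue
        bkey = (composites[best], lengths[best])
        if key > bkey or (key == bkey and cid < best):
            best = cid
    return best
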