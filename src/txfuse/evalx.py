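"""Assembly comparison and bias diagnostics.

Three instruments for characterising a set of assemblies:

* **MinHash sketches** — a bottom-s signature (default s=5,000, k=51) of each
  assembly's canonical k-mer set, compared via the bottom-s merge estimator of
  Jaccard similarity; distances ``1 - J`` feed a classical (Torgerson) metric
  MDS embedding that places assemblies in 2-D by algorithmic signature.
* **Expression quantification** — fragment counting over primary alignments
  with equal splitting of multi-best-hit fragments, converted to TPM with an
  effective-length correction.
* **Per-origin expression stratification** — the distribution of log(TPM+1)
  of merged-assembly winners broken down by assembler of origin, the
  diagnostic that exposes expression-dependent assembler bias (an assembler
  that drops low-abundance transcripts contributes only high-expression
  winners).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from . import kmers
from .mapping import MapResult
from .seqio import AlignmentRecord, ContigSet

logger = logging.getLogger(__name__)


@dataclass
class SketchSignature:
    """Bottom-s MinHash summary of an assembly's canonical k-mers."""

    label: str
    k: int
    num_hashes: int
    hashes: np.ndarray  # sorted, strictly increasing uint64

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size > self.num_hashes:
            raise ValueError("signature holds more than num_hashes values")
        if self.hashes.size > 1 and not (np.diff(self.hashes.astype(np.int64)) > 0).all():
            if not (self.hashes[:-1] < self.hashes[1:]).all():
                raise ValueError("signature hashes must be strictly increasing")

    def to_dict(self) -> dict:
        return {
            "label": self.label, "k": self.k, "num_hashes": self.num_hashes,
            "hashes": [int(h) for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SketchSignature":
        return cls(d["label"], d["k"], d["num_hashes"], np.array(d["hashes"], dtype=np.uint64))


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def sketch(contigs: ContigSet, label: str | None = None,
           k: int = 51, num_hashes: int = 5000) -> SketchSignature:
    """Bottom-s MinHash signature over the assembly's canonical k-mers.

    Uses the package's fixed splitmix64 hash, so signatures are deterministic
    across runs and machines.  An assembly with fewer than ``num_hashes``
    distinct k-mers yields a signature holding all of them; an assembly with
    no sequence of length >= k yields an empty signature with a warning.
    """
    if k < 15 or k % 2 == 0:
        raise ValueError("sketch k must be odd and >= 15")
    if label is None:
        labels = contigs.labels
        label = next(iter(labels)) if len(labels) == 1 else "+".join(sorted(labels))
    chunks = []
    for c in contigs:
        if c.length >= k:
            chunks.append(kmers.canonical_hashes(c.seq, k))
    if not chunks:
        logger.warning("no sequence of length >= %d: empty signature for %s", k, label)
        return SketchSignature(label, k, num_hashes, np.zeros(0, dtype=np.uint64))
    hashes = np.unique(np.concatenate(chunks))
    return SketchSignature(label, k, num_hashes, hashes[:num_hashes])


def jaccard_estimate(a: SketchSignature, b: SketchSignature) -> float:
    """Bottom-s merge estimator: |bottom_s(A u B) n A n B| / |bottom_s(A u B)|."""
    if a.k != b.k:
        raise ValueError(f"mixed sketch k: {a.k} vs {b.k}")
    s = min(a.num_hashes, b.num_hashes)
    union = np.union1d(a.hashes, b.hashes)[:s]
    if union.size == 0:
        return 0.0
    inter = np.isin(union, a.hashes, assume_unique=True) & np.isin(
        union, b.hashes, assume_unique=True
    )
    return float(inter.sum() / union.size)


def compare(signatures: list[SketchSignature]) -> DistanceMatrix:
    """Pairwise distance matrix ``1 - estimated Jaccard`` over signatures."""
    if len(signatures) < 2:
        raise ValueError("compare requires at least two signatures")
    ks = {s.k for s in signatures}
    if len(ks) != 1:
        raise ValueError(f"mixed sketch k values: {sorted(ks)}")
    n = len(signatures)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 1.0 - jaccard_estimate(signatures[i], signatures[j])
    return DistanceMatrix(labels=[s.label for s in signatures], d=d)


def mds_embed(dist: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Double-centres ``-d**2/2``, eigendecomposes, and returns the top-``dims``
    coordinates.  Exact for Euclidean-realisable matrices.  Deterministic up
    to sign; each axis is oriented so its largest-magnitude coordinate is
    positive.
    """
    n = len(dist.labels)
    if dims >= n:
        raise ValueError(f"dims={dims} must be smaller than the number of labels ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist.d ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    for a in range(dims):
        col = coords[:, a]
        if col[np.abs(col).argmax()] < 0:
            coords[:, a] = -col
    out = pd.DataFrame(coords, columns=[f"dim{i+1}" for i in range(dims)])
    out.insert(0, "label", dist.labels)
    return out


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def effective_length(length: int, insert_mean: int) -> int:
    return max(length - insert_mean + 1, 1)


def quantify(
    source: Union[MapResult, list[AlignmentRecord]],
    contigs: ContigSet,
    insert_mean: int = 250,
) -> pd.DataFrame:
    """Fragment counts and TPM per contig.

    A fragment (read pair) counts once; a fragment whose best placements tie
    over several contigs is split equally among them.  TPM divides the count
    by the effective length ``max(length - insert_mean + 1, 1)`` and
    renormalises to one million.  Returns a DataFrame with ``contig_id``,
    ``count`` and ``tpm`` (tpm sums to 1e6 whenever any fragment mapped).
    """
    ids = contigs.ids()
    idx_of = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    counts = np.zeros(n)

    if isinstance(source, MapResult):
        for hits_pair in _fragment_tie_sets_arrays(source):
            counts[hits_pair] += 1.0 / len(hits_pair)
    else:
        for tie_set in _fragment_tie_sets_records(source, idx_of):
            for ci in tie_set:
                counts[ci] += 1.0 / len(tie_set)

    lengths = np.array([contigs[c].length for c in ids], dtype=float)
    eff = np.maximum(lengths - insert_mean + 1, 1.0)
    dens = counts / eff
    total = dens.sum()
    tpm = dens / total * 1e6 if total > 0 else dens
    return pd.DataFrame({"contig_id": ids, "count": counts, "tpm": tpm})


def _fragment_tie_sets_arrays(res: MapResult):
    """Per-fragment tied best contig sets from mapper arrays.

    The tie set of a fragment is the intersection of its mates' tied contigs
    (when both mapped and the intersection is non-empty) or the mapped mate's
    set; the fallback for disagreeing mates is the union.
    """
    def per_read_sets(hits):
        sets: dict[int, list[int]] = {}
        for r, c in zip(hits.tie_read, hits.tie_contig):
            sets.setdefault(int(r), []).append(int(c))
        return sets

    t1 = per_read_sets(res.mate1)
    t2 = per_read_sets(res.mate2)
    for i in range(res.n_pairs):
        a = set(t1.get(i, ())) if res.mate1.mapped[i] else set()
        b = set(t2.get(i, ())) if res.mate2.mapped[i] else set()
        if a and b:
            both = a & b
            yield sorted(both) if both else sorted(a | b)
        elif a or b:
            yield sorted(a | b)


def _fragment_tie_sets_records(records: list[AlignmentRecord], idx_of: dict[str, int]):
    by_read: dict[str, dict[bool, list[AlignmentRecord]]] = {}
    for r in records:
        if r.contig_id is not None:
            by_read.setdefault(r.read_id, {}).setdefault(r.is_first, []).append(r)
    for mates in by_read.values():
        tie_sets = []
        for recs in mates.values():
            if not any(r.is_primary for r in recs):
                continue
            best_nm = min(r.n_mismatch for r in recs)
            tie_sets.append({idx_of[r.contig_id] for r in recs if r.n_mismatch == best_nm})
        if not tie_sets:
            continue
        if len(tie_sets) == 2:
            both = tie_sets[0] & tie_sets[1]
            yield sorted(both) if both else sorted(tie_sets[0] | tie_sets[1])
        else:
            yield sorted(tie_sets[0])


def expression_by_origin(
    group_table: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Per-origin summaries of winner expression: n, mean and quartiles of log(TPM+1).

    ``group_table`` is a merge result's table (winner_id, winner_origin);
    ``expression`` a quantification table over the merged assembly.  Origins
    without any quantified winner are omitted with a warning.  Suitable for
    ridge plotting.
    """
    tpm_of = dict(zip(expression["contig_id"], expression["tpm"]))
    rows = []
    for origin, sub in group_table.groupby("winner_origin"):
        vals = np.array([tpm_of[w] for w in sub["winner_id"] if w in tpm_of])
        if vals.size == 0:
            logger.warning("origin %s has no quantified winners; omitted", origin)
            continue
        logv = np.log1p(vals)
        q1, q2, q3 = np.percentile(logv, [25, 50, 75])
        rows.append(
            {
                "origin": origin, "n": int(vals.size), "mean_log_tpm": float(logv.mean()),
                "q25_log_tpm": float(q1), "median_log_tpm": float(q2),
                "q75_log_tpm": float(q3),
            }
        )
    return pd.DataFrame(rows).sort_values("origin").reset_index(drop=True)
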