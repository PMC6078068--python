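"""Read-evidence contig scoring: the ranking used to pick cluster representatives.

Each contig gets four components in [0, 1], combined into a composite by a
geometric mean with a floor:

* ``s_nuc`` — nucleotide fidelity: matched bases / aligned bases over primary
  alignments;
* ``s_cov`` — fraction of contig positions covered by at least one primary
  aligned base;
* ``s_ord`` — among pairs with both mates primary on the contig, the fraction
  in proper FR orientation with a plausible template length
  (``<= insert_mean + 3*insert_sd``); neutral (1.0) when no such pairs exist;
* ``s_seg`` — single-transcript coverage plausibility: the BIC weight of a
  1-segment versus best 2-segment piecewise-constant model of
  ``log2(coverage+1)``; a chimera's coverage step loses to the 2-segment model
  and drives this toward 0.

``composite = (prod max(component, 0.01))**(1/4)``.  An assembly-level score is
the geometric mean of its contig composites times the pair mapping rate —
bounded above by the mapping rate, so an assembly that fails to represent the
reads cannot score well no matter how clean its contigs are.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .mapping import MapResult, builtin_map  # re-exported: builtin_map lives with scoring
from .seqio import AlignmentRecord, ContigSet

logger = logging.getLogger(__name__)

COMPONENT_FLOOR = 0.01
#: free parameters of the 1- and 2-segment coverage models (mean(s) + shared
#: variance; the 2-segment model also pays for its breakpoint)
_SEG_PARAMS_1 = 2
_SEG_PARAMS_2 = 4


@dataclass
class ContigScore:
    contig_id: str
    s_nuc: float
    s_cov: float
    s_ord: float
    s_seg: float

    @property
    def composite(self) -> float:
        comps = [self.s_nuc, self.s_cov, self.s_ord, self.s_seg]
        prod = 1.0
        for c in comps:
            prod *= max(c, COMPONENT_FLOOR)
        return prod ** 0.25


@dataclass
class AssemblyScore:
    mapping_rate: float
    contig_geo_mean: float

    @property
    def score(self) -> float:
        return self.contig_geo_mean * self.mapping_rate


def mapping_rate(alignments: Iterable[AlignmentRecord], n_pairs: int) -> float:
    """Fraction of read pairs in which both mates have a primary mapped record."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    first, second = set(), set()
    for r in alignments:
        if r.is_primary:
            (first if r.is_first else second).add(r.read_id)
    return len(first & second) / n_pairs


def s_nuc(alignments: Iterable[AlignmentRecord]) -> float:
    """Matched bases over aligned bases, primaries only; 0.0 with no primaries."""
    match = aligned = 0
    for r in alignments:
        if r.is_primary:
            match += r.n_match
            aligned += r.aligned_len
    return match / aligned if aligned else 0.0


def s_cov(alignments: Iterable[AlignmentRecord], contig_length: int) -> float:
    """Fraction of contig positions covered by >= 1 primary aligned base."""
    if contig_length < 1:
        raise ValueError("contig_length must be >= 1")
    covered = np.zeros(contig_length, dtype=bool)
    for r in alignments:
        if r.is_primary:
            covered[r.pos : r.pos + r.aligned_len] = True
    return float(covered.mean())


def s_ord(
    alignments: Iterable[AlignmentRecord],
    insert_mean: int = 250,
    insert_sd: int = 50,
) -> float:
    """Pair order/orientation agreement for pairs with both mates on this contig.

    Proper means FR (mates on opposite strands, leftmost mate forward) with
    ``|template_len| <= insert_mean + 3*insert_sd``.  Neutral 1.0 when no
    same-contig pairs exist.
    """
    by_read: dict[str, dict[bool, AlignmentRecord]] = {}
    for r in alignments:
        if r.is_primary:
            by_read.setdefault(r.read_id, {})[r.is_first] = r
    bound = insert_mean + 3 * insert_sd
    n = good = 0
    for mates in by_read.values():
        if True not in mates or False not in mates:
            continue
        a, b = mates[True], mates[False]
        if a.contig_id != b.contig_id:
            continue
        n += 1
        if a.is_reverse == b.is_reverse:
            continue
        left, right = (a, b) if a.pos <= b.pos else (b, a)
        if left.is_reverse:
            continue
        tlen = abs(a.template_len) if a.template_len is not None else (
            right.pos + right.aligned_len - left.pos
        )
        if tlen <= bound:
            good += 1
    if n == 0:
        logger.debug("ord:neutral (no same-contig pairs)")
        return 1.0
    return good / n


def _seg_sse(y: np.ndarray) -> tuple[float, float]:
    """(SSE of the 1-segment model, best SSE over the 2-segment decile grid)."""
    n = y.size
    c1 = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))

    def sse(lo: int, hi: int) -> float:
        s, s2, m = c1[hi] - c1[lo], c2[hi] - c2[lo], hi - lo
        return float(s2 - s * s / m)

    sse1 = sse(0, n)
    # breakpoints on a decile grid restricted to the middle 80% of positions
    bps = sorted({int(round(n * d / 10)) for d in range(1, 10)} & set(range(1, n)))
    if not bps:
        return sse1, math.inf
    sse2 = min(sse(0, b) + sse(b, n) for b in bps)
    return sse1, sse2


def s_seg(coverage: Sequence[float] | np.ndarray) -> float:
    """BIC weight of the 1-segment coverage model versus the best 2-segment one.

    Computed on ``log2(coverage+1)`` under a Gaussian likelihood with shared
    variance.  1.0 when no breakpoint is possible (length-1 vector), 0.0 for
    an entirely uncovered contig (flagged unsupported).
    """
    cov = np.asarray(coverage, dtype=float)
    if cov.size < 1:
        raise ValueError("coverage vector must have length >= 1")
    if not (cov > 0).any():
        logger.debug("unsupported contig (all-zero coverage)")
        return 0.0
    if cov.size == 1:
        return 1.0
    y = np.log2(cov + 1.0)
    n = y.size
    sse1, sse2 = _seg_sse(y)
    if not math.isfinite(sse2):
        return 1.0
    floor = 1e-9 * n  # keeps the log-likelihood finite on zero-variance fits
    bic1 = n * math.log(max(sse1, floor) / n) + _SEG_PARAMS_1 * math.log(n)
    bic2 = n * math.log(max(sse2, floor) / n) + _SEG_PARAMS_2 * math.log(n)
    lo = min(bic1, bic2)
    w1 = math.exp(-(bic1 - lo) / 2)
    w2 = math.exp(-(bic2 - lo) / 2)
    return min(max(w1 / (w1 + w2), 0.0), 1.0)


def contig_score(contig_id: str, components: Sequence[float]) -> ContigScore:
    """Bundle four components; the composite applies the 0.01 floor rule."""
    nuc, cov, ordv, seg = components
    return ContigScore(contig_id=contig_id, s_nuc=nuc, s_cov=cov, s_ord=ordv, s_seg=seg)


def assembly_score(contig_scores: Iterable[ContigScore], rate: float) -> AssemblyScore:
    """Geometric mean of contig composites times the pair mapping rate."""
    comps = [c.composite for c in contig_scores]
    if not comps:
        raise ValueError("assembly score requires at least one contig")
    geo = math.exp(sum(math.log(c) for c in comps) / len(comps))
    return AssemblyScore(mapping_rate=rate, contig_geo_mean=geo)


# ---------------------------------------------------------------------------
# Whole-assembly scoring driver
# ---------------------------------------------------------------------------

def score_contigs(
    source: Union[MapResult, list[AlignmentRecord]],
    contigs: ContigSet,
    insert_mean: int = 250,
    insert_sd: int = 50,
) -> dict[str, ContigScore]:
    """Compute all four components for every contig.

    ``source`` is either a :class:`MapResult` from the builtin mapper (fast
    array path) or a list of :class:`AlignmentRecord` parsed from external
    SAM.  Contigs without any primary alignment score 0 on nuc/cov/seg (and
    neutral on ord), which the composite floor turns into 0.01 per component.
    """
    ids = contigs.ids()
    lengths = np.array([contigs[c].length for c in ids], dtype=np.int64)
    idx_of = {c: i for i, c in enumerate(ids)}
    n = len(ids)
    starts = np.concatenate(([0], np.cumsum(lengths)))
    total = int(starts[-1])

    if isinstance(source, MapResult):
        m1, m2 = source.mate1, source.mate2
        L = source.reads.read_len
        rec_contig = np.concatenate((m1.contig[m1.mapped], m2.contig[m2.mapped]))
        rec_pos = np.concatenate((m1.pos[m1.mapped], m2.pos[m2.mapped]))
        rec_alen = np.full(rec_contig.size, L, dtype=np.int64)
        rec_match = np.concatenate(
            (L - m1.nm[m1.mapped], L - m2.nm[m2.mapped])
        )
        same = m1.mapped & m2.mapped & (m1.contig == m2.contig)
        pair_contig = m1.contig[same]
        proper = source.proper_fr()[same]
        tlen = source.template_lengths()[same]
        pair_good = proper & (tlen <= insert_mean + 3 * insert_sd)
    else:
        prim = [r for r in source if r.is_primary and r.contig_id is not None]
        rec_contig = np.array([idx_of[r.contig_id] for r in prim], dtype=np.int64)
        rec_pos = np.array([r.pos for r in prim], dtype=np.int64)
        rec_alen = np.array([r.aligned_len for r in prim], dtype=np.int64)
        rec_match = np.array([r.n_match for r in prim], dtype=np.int64)
        by_read: dict[str, dict[bool, AlignmentRecord]] = {}
        for r in prim:
            by_read.setdefault(r.read_id, {})[r.is_first] = r
        pc, pg = [], []
        bound = insert_mean + 3 * insert_sd
        for mates in by_read.values():
            if True in mates and False in mates:
                a, b = mates[True], mates[False]
                if a.contig_id != b.contig_id:
                    continue
                pc.append(idx_of[a.contig_id])
                left, right = (a, b) if a.pos <= b.pos else (b, a)
                fr = (a.is_reverse != b.is_reverse) and not left.is_reverse
                t = abs(a.template_len) if a.template_len is not None else (
                    right.pos + right.aligned_len - left.pos
                )
                pg.append(fr and t <= bound)
        pair_contig = np.array(pc, dtype=np.int64)
        pair_good = np.array(pg, dtype=bool)

    # per-contig sums
    match_sum = np.bincount(rec_contig, weights=rec_match, minlength=n)
    alen_sum = np.bincount(rec_contig, weights=rec_alen, minlength=n)
    nuc = np.divide(match_sum, alen_sum, out=np.zeros(n), where=alen_sum > 0)

    # global coverage array via the difference trick
    diff = np.zeros(total + 1, dtype=np.int64)
    g0 = starts[rec_contig] + rec_pos
    np.add.at(diff, g0, 1)
    np.add.at(diff, g0 + rec_alen, -1)
    cov = np.cumsum(diff[:-1])

    covered = (cov > 0).astype(np.int64)
    cum_cov = np.concatenate(([0], np.cumsum(covered)))
    cov_frac = (cum_cov[starts[1:]] - cum_cov[starts[:-1]]) / lengths

    pair_n = np.bincount(pair_contig, minlength=n)
    pair_ok = np.bincount(pair_contig[pair_good], minlength=n)
    ordv = np.where(pair_n > 0, pair_ok / np.maximum(pair_n, 1), 1.0)

    scores: dict[str, ContigScore] = {}
    for i, cid in enumerate(ids):
        seg = s_seg(cov[starts[i] : starts[i + 1]]) if alen_sum[i] > 0 else 0.0
        scores[cid] = ContigScore(
            contig_id=cid,
            s_nuc=float(nuc[i]),
            s_cov=float(cov_frac[i]),
            s_ord=float(ordv[i]),
            s_seg=seg,
        )
    return scores


def score_table(scores: dict[str, ContigScore], contigs: ContigSet) -> pd.DataFrame:
    """Per-contig score report: contig_id, origin, length, components, composite."""
    rows = []
    for cid, s in scores.items():
        c = contigs[cid]
        rows.append(
            {
                "contig_id": cid, "origin": c.origin, "length": c.length,
                "s_nuc": s.s_nuc, "s_cov": s.s_cov, "s_ord": s.s_ord,
                "s_seg": s.s_seg, "composite": s.composite,
            }
        )
    return pd.DataFrame(rows)
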