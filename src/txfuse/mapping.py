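"""Exact-seed, ungapped-extension paired-end read mapper.

A deliberately simple aligner sufficient for read-evidence scoring of
transcriptome contigs at test scale: canonical ``seed_k``-mers (default 31) of
every contig are indexed; each read probes a few evenly spaced k-mer windows,
every seed hit implies one ungapped full-length placement, and the placement
with the fewest mismatches wins.  There is no gapped alignment and no soft
clipping — a placement must fit entirely inside its contig.

Multi-mapping reads (identical contigs pooled from several assemblers are the
common case here) are resolved deterministically: the full set of tied
best-mismatch contigs is recorded, and the primary is drawn from it by a
splitmix64 hash of the pair index, so multireads spread evenly over the tied
copies while runs stay byte-reproducible.  ``tie_break="lowest"`` instead
always picks the lowest contig id.  Both mates of a pair share the hash, so a
pair whose mates tie over the same contigs lands on the same copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import kmers
from .seqio import AlignmentRecord, ContigSet, ReadSet

logger = logging.getLogger(__name__)

_CHUNK = 1 << 18


@dataclass
class MateHits:
    """Per-mate mapping arrays (index -1 / mapped False where unmapped)."""

    mapped: np.ndarray      # (n,) bool
    contig: np.ndarray      # (n,) int32 contig index
    pos: np.ndarray         # (n,) int32 0-based start on contig
    is_rev: np.ndarray      # (n,) bool
    nm: np.ndarray          # (n,) int32 mismatches of the primary placement
    tie_read: np.ndarray    # (t,) int32 read index per tie entry
    tie_contig: np.ndarray  # (t,) int32
    tie_pos: np.ndarray     # (t,) int32
    tie_rev: np.ndarray     # (t,) bool
    tie_chosen: np.ndarray  # (t,) bool — True on the entry promoted to primary


class MapResult:
    """Pairing of a :class:`ReadSet` against a :class:`ContigSet`."""

    def __init__(self, contigs: ContigSet, reads: ReadSet,
                 mate1: MateHits, mate2: MateHits) -> None:
        self.contigs = contigs
        self.contig_ids = contigs.ids()
        self.contig_lengths = np.array([contigs[c].length for c in self.contig_ids])
        self.reads = reads
        self.mate1 = mate1
        self.mate2 = mate2

    @property
    def n_pairs(self) -> int:
        return self.reads.n_pairs

    def mapping_rate(self) -> float:
        """Fraction of pairs with both mates primary-mapped."""
        return float(np.mean(self.mate1.mapped & self.mate2.mapped))

    def template_lengths(self) -> np.ndarray:
        """Signed-magnitude template length per pair; 0 where undefined.

        Defined only for pairs with both mates on the same contig: distance
        from the leftmost start to the rightmost end.
        """
        L = self.reads.read_len
        m = self.mate1.mapped & self.mate2.mapped & (self.mate1.contig == self.mate2.contig)
        left = np.minimum(self.mate1.pos, self.mate2.pos)
        right = np.maximum(self.mate1.pos, self.mate2.pos) + L
        return np.where(m, right - left, 0)

    def proper_fr(self) -> np.ndarray:
        """Pairs on one contig, mates on opposite strands, leftmost mate forward."""
        m = self.mate1.mapped & self.mate2.mapped & (self.mate1.contig == self.mate2.contig)
        opp = self.mate1.is_rev != self.mate2.is_rev
        fwd_mate_pos = np.where(self.mate1.is_rev, self.mate2.pos, self.mate1.pos)
        rev_mate_pos = np.where(self.mate1.is_rev, self.mate1.pos, self.mate2.pos)
        return m & opp & (fwd_mate_pos <= rev_mate_pos)

    # ------------------------------------------------------------------
    def to_records(self, include_ties: bool = False) -> list[AlignmentRecord]:
        """Materialise SAM-like :class:`AlignmentRecord` objects.

        With ``include_ties`` the non-primary tied best placements are added
        as secondary records (``is_primary=False``).
        """
        L = self.reads.read_len
        names = self.reads.names
        cids = self.contig_ids
        tlen = self.template_lengths()
        records: list[AlignmentRecord] = []
        for first, hits, other in ((True, self.mate1, self.mate2),
                                   (False, self.mate2, self.mate1)):
            for i in range(self.n_pairs):
                if not hits.mapped[i]:
                    records.append(AlignmentRecord(
                        read_id=names[i], contig_id=None, pos=0, aligned_len=0,
                        n_match=0, n_mismatch=0, is_primary=False,
                        is_reverse=False, is_first=first))
                    continue
                t = int(tlen[i])
                signed = None
                if t:
                    leftmost = hits.pos[i] <= other.pos[i] if other.mapped[i] else True
                    signed = t if leftmost else -t
                records.append(AlignmentRecord(
                    read_id=names[i],
                    contig_id=cids[hits.contig[i]],
                    pos=int(hits.pos[i]),
                    aligned_len=L,
                    n_match=L - int(hits.nm[i]),
                    n_mismatch=int(hits.nm[i]),
                    is_primary=True,
                    is_reverse=bool(hits.is_rev[i]),
                    is_first=first,
                    mate_contig_id=cids[other.contig[i]] if other.mapped[i] else None,
                    mate_is_reverse=bool(other.is_rev[i]) if other.mapped[i] else None,
                    template_len=signed,
                ))
            if include_ties:
                sec = ~hits.tie_chosen
                for r, c, p, v in zip(hits.tie_read[sec], hits.tie_contig[sec],
                                      hits.tie_pos[sec], hits.tie_rev[sec]):
                    records.append(AlignmentRecord(
                        read_id=names[r], contig_id=cids[c], pos=int(p),
                        aligned_len=L, n_match=L - int(hits.nm[r]),
                        n_mismatch=int(hits.nm[r]), is_primary=False,
                        is_reverse=bool(v), is_first=first))
        return records

    def write_sam(self, path, include_ties: bool = False) -> None:
        """Emit a SAM text file (header with @SQ lines covering all contigs)."""
        L = self.reads.read_len
        qual = "I" * L
        names = self.reads.names
        cids = self.contig_ids
        tlen = self.template_lengths()
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for cid, clen in zip(cids, self.contig_lengths):
                fh.write(f"@SQ\tSN:{cid}\tLN:{clen}\n")
            fh.write("@PG\tID:txfuse\tPN:txfuse\n")
            for first, hits, other, mat in (
                (True, self.mate1, self.mate2, self.reads.mat1),
                (False, self.mate2, self.mate1, self.reads.mat2),
            ):
                mate_bit = 0x40 if first else 0x80
                for i in range(self.n_pairs):
                    name = names[i]
                    seq = kmers.decode(mat[i])
                    flag = 0x1 | mate_bit
                    if not hits.mapped[i]:
                        flag |= 0x4
                        if not other.mapped[i]:
                            flag |= 0x8
                        fh.write(f"{name}\t{flag}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                        continue
                    if hits.is_rev[i]:
                        flag |= 0x10
                        seq = kmers.revcomp(seq)
                    if other.mapped[i]:
                        if other.is_rev[i]:
                            flag |= 0x20
                        rnext = "=" if other.contig[i] == hits.contig[i] else cids[other.contig[i]]
                        pnext = int(other.pos[i]) + 1
                    else:
                        flag |= 0x8
                        rnext, pnext = "*", 0
                    t = int(tlen[i])
                    if t and other.mapped[i] and other.contig[i] == hits.contig[i]:
                        flag |= 0x2
                        signed = t if hits.pos[i] <= other.pos[i] else -t
                    else:
                        signed = 0
                    fh.write(
                        f"{name}\t{flag}\t{cids[hits.contig[i]]}\t{int(hits.pos[i]) + 1}"
                        f"\t60\t{L}M\t{rnext}\t{pnext}\t{signed}\t{seq}\t{qual}"
                        f"\tNM:i:{int(hits.nm[i])}\n"
                    )


class ContigIndex:
    """Sorted canonical seed-k-mer index over a contig set."""

    def __init__(self, contigs: ContigSet, seed_k: int = 31) -> None:
        if seed_k < 15 or seed_k > 32:
            raise ValueError("seed_k must be in [15, 32]")
        self.contigs = contigs
        self.seed_k = seed_k
        ids = contigs.ids()
        lens = np.array([contigs[c].length for c in ids], dtype=np.int64)
        # one N sentinel between contigs invalidates boundary-spanning windows
        parts = []
        for cid in ids:
            parts.append(kmers.encode(contigs[cid].seq))
            parts.append(np.array([4], dtype=np.uint8))
        cat = np.concatenate(parts)[:-1] if parts else np.zeros(0, dtype=np.uint8)
        self.cat = cat
        self.ctg_start = np.concatenate(([0], np.cumsum(lens + 1)))[:-1]
        self.ctg_len = lens
        hi, _lo, is_fwd, valid = kmers.canonical_words(cat, seed_k)
        vpos = np.flatnonzero(valid)
        codes = hi[vpos]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = vpos[order].astype(np.int64)
        self.strand = is_fwd[vpos][order]

    def contig_of(self, gpos: np.ndarray) -> np.ndarray:
        return np.searchsorted(self.ctg_start, gpos, side="right") - 1


def _probe_offsets(read_len: int, k: int, n_probes: int) -> np.ndarray:
    return np.unique(np.linspace(0, read_len - k, n_probes).round().astype(np.int64))


def _pack_windows(mat: np.ndarray, off: int, k: int):
    """Canonical codes + strand + validity of one k-window column of a read matrix."""
    win = mat[:, off : off + k].astype(np.uint64)
    four, three = np.uint64(4), np.uint64(3)
    fwd = np.zeros(mat.shape[0], dtype=np.uint64)
    rc = np.zeros(mat.shape[0], dtype=np.uint64)
    for j in range(k):
        fwd = fwd * four + win[:, j]
        rc = rc * four + (three - win[:, k - 1 - j])
    is_fwd = fwd <= rc
    valid = (mat[:, off : off + k] < 4).all(axis=1)
    return np.where(is_fwd, fwd, rc), is_fwd, valid


def _map_mate(
    mat: np.ndarray,
    index: ContigIndex,
    n_probes: int,
    max_hits_per_seed: int,
    max_ties: int,
    tie_hash: np.ndarray,
    tie_break: str,
) -> MateHits:
    n, L = mat.shape
    k = index.seed_k
    if L < k:
        raise ValueError(f"read length {L} shorter than seed_k {k}")
    offs = _probe_offsets(L, k, n_probes)

    q_read, q_off, q_code, q_fwd = [], [], [], []
    for off in offs:
        code, is_fwd, valid = _pack_windows(mat, int(off), k)
        sel = np.flatnonzero(valid)
        q_read.append(sel)
        q_off.append(np.full(sel.size, off, dtype=np.int64))
        q_code.append(code[sel])
        q_fwd.append(is_fwd[sel])
    q_read = np.concatenate(q_read)
    q_off = np.concatenate(q_off)
    q_code = np.concatenate(q_code)
    q_fwd = np.concatenate(q_fwd)

    left = np.searchsorted(index.codes, q_code, side="left")
    right = np.searchsorted(index.codes, q_code, side="right")
    hits = np.minimum(right - left, max_hits_per_seed)
    tot = int(hits.sum())
    empty = np.zeros(0, dtype=np.int64)
    if tot == 0:
        return MateHits(
            mapped=np.zeros(n, dtype=bool),
            contig=np.full(n, -1, dtype=np.int64), pos=np.zeros(n, dtype=np.int64),
            is_rev=np.zeros(n, dtype=bool), nm=np.zeros(n, dtype=np.int64),
            tie_read=empty, tie_contig=empty, tie_pos=empty,
            tie_rev=np.zeros(0, dtype=bool), tie_chosen=np.zeros(0, dtype=bool),
        )
    rq = np.repeat(np.arange(q_code.size), hits)
    cum = np.concatenate(([0], np.cumsum(hits)))[:-1]
    sidx = np.repeat(left, hits) + (np.arange(tot) - np.repeat(cum, hits))

    p = index.pos[sidx]
    f_idx = index.strand[sidx]
    read = q_read[rq]
    off = q_off[rq]
    f_read = q_fwd[rq]
    fwd_align = f_idx == f_read
    start = np.where(fwd_align, p - off, p - (L - k - off))
    ci = index.contig_of(np.maximum(start, 0))
    ok = (start >= index.ctg_start[ci]) & (start + L <= index.ctg_start[ci] + index.ctg_len[ci])
    read, start, ci, fwd_align = read[ok], start[ok], ci[ok], fwd_align[ok]

    # deduplicate placements proposed by several probes
    key = (read * (index.cat.size + 1) + start) * 2 + fwd_align
    _, uidx = np.unique(key, return_index=True)
    read, start, ci, fwd_align = read[uidx], start[uidx], ci[uidx], fwd_align[uidx]

    # mismatch count per candidate placement
    rc_mat = kmers.complement_codes(mat)[:, ::-1]
    mm = np.empty(read.size, dtype=np.int64)
    span = np.arange(L)
    for lo in range(0, read.size, _CHUNK):
        hi_ = min(lo + _CHUNK, read.size)
        w = index.cat[start[lo:hi_, None] + span]
        rb = np.where(fwd_align[lo:hi_, None], mat[read[lo:hi_]], rc_mat[read[lo:hi_]])
        mm[lo:hi_] = (w != rb).sum(axis=1)

    # best placement per read; ties collected per distinct contig
    order = np.lexsort((start, ci, mm, read))
    r_s, c_s, m_s, st_s, fw_s = read[order], ci[order], mm[order], start[order], fwd_align[order]
    grp_first = np.concatenate(([True], r_s[1:] != r_s[:-1]))
    grp_idx = np.flatnonzero(grp_first)
    grp_sizes = np.diff(np.concatenate((grp_idx, [r_s.size])))
    best = np.repeat(m_s[grp_idx], grp_sizes)
    is_best = m_s == best

    rows = np.flatnonzero(is_best)
    rr, cc = r_s[rows], c_s[rows]
    dfirst = np.concatenate(([True], (rr[1:] != rr[:-1]) | (cc[1:] != cc[:-1])))
    drows = rows[dfirst]  # lowest-start placement per (read, tied contig)
    dr = r_s[drows]
    dgrp_idx = np.flatnonzero(np.concatenate(([True], dr[1:] != dr[:-1])))
    dgrp_sizes = np.diff(np.concatenate((dgrp_idx, [dr.size])))
    rank = np.arange(dr.size) - np.repeat(dgrp_idx, dgrp_sizes)
    keep = rank < max_ties
    drows, dr, rank = drows[keep], dr[keep], rank[keep]
    dgrp_idx = np.flatnonzero(np.concatenate(([True], dr[1:] != dr[:-1])))
    dgrp_sizes = np.diff(np.concatenate((dgrp_idx, [dr.size])))

    mapped_reads = dr[dgrp_idx]
    if tie_break == "lowest":
        chosen_rank = np.zeros(dgrp_idx.size, dtype=np.int64)
    else:
        chosen_rank = (tie_hash[mapped_reads] % dgrp_sizes.astype(np.uint64)).astype(np.int64)
    chosen = drows[dgrp_idx + chosen_rank]

    mapped = np.zeros(n, dtype=bool)
    mapped[mapped_reads] = True
    contig = np.full(n, -1, dtype=np.int64)
    pos = np.zeros(n, dtype=np.int64)
    is_rev = np.zeros(n, dtype=bool)
    nm = np.zeros(n, dtype=np.int64)
    contig[mapped_reads] = c_s[chosen]
    pos[mapped_reads] = st_s[chosen] - index.ctg_start[c_s[chosen]]
    is_rev[mapped_reads] = ~fw_s[chosen]
    nm[mapped_reads] = m_s[chosen]

    tie_chosen = np.zeros(dr.size, dtype=bool)
    tie_chosen[dgrp_idx + chosen_rank] = True
    return MateHits(
        mapped=mapped, contig=contig, pos=pos, is_rev=is_rev, nm=nm,
        tie_read=dr,
        tie_contig=c_s[drows],
        tie_pos=(st_s[drows] - index.ctg_start[c_s[drows]]),
        tie_rev=~fw_s[drows],
        tie_chosen=tie_chosen,
    )


def builtin_map(
    reads: ReadSet,
    contigs: ContigSet,
    seed_k: int = 31,
    n_probes: int = 4,
    max_hits_per_seed: int = 64,
    max_ties: int = 16,
    seed: int = 0,
    tie_break: str = "hash",
    index: Optional[ContigIndex] = None,
) -> MapResult:
    """Map paired reads to contigs; returns a :class:`MapResult`.

    Error-free reads from a transcript present verbatim in the contig set are
    guaranteed to map with NM=0 (the probe at offset 0 is an exact seed).
    Reads sharing no seed k-mer with any contig stay unmapped.
    """
    if tie_break not in ("hash", "lowest"):
        raise ValueError("tie_break must be 'hash' or 'lowest'")
    if index is None:
        index = ContigIndex(contigs, seed_k=seed_k)
    tie_hash = kmers.splitmix64(
        np.arange(reads.n_pairs, dtype=np.uint64) ^ np.uint64(seed & 0x7FFFFFFF)
    )
    mate1 = _map_mate(reads.mat1, index, n_probes, max_hits_per_seed, max_ties,
                      tie_hash, tie_break)
    mate2 = _map_mate(reads.mat2, index, n_probes, max_hits_per_seed, max_ties,
                      tie_hash, tie_break)
    res = MapResult(contigs, reads, mate1, mate2)
    logger.info(
        "mapped %d pairs to %d contigs: pair mapping rate %.4f",
        reads.n_pairs, len(contigs), res.mapping_rate(),
    )
    return res
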