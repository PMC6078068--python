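"""Sequence and alignment I/O plus the containers the pipeline passes around.

The merging pipeline tracks, for every contig, which input assembly it came
from.  Origin is carried both as an attribute and — once assemblies are pooled —
inside the contig id itself as ``"<label>|<original id>"`` (``|`` is reserved),
so it survives round trips through plain FASTA/SAM consumed by external tools.

Conventions
-----------
* Internal coordinates are 0-based half-open; SAM converts at the boundary.
* Sequences are uppercased on input and characters outside ``{A,C,G,T,N}`` are
  normalised to ``N`` (counted and logged): downstream k-mer machinery needs a
  closed alphabet.
* Gzip input is detected by magic bytes, never by file extension.
* Emitted FASTA is single-line per record; wrapped or single-line is accepted.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

from . import kmers

logger = logging.getLogger(__name__)

ORIGIN_SEP = "|"

# uppercase, then map anything outside the closed alphabet to N
_NORM_TABLE = str.maketrans(
    {chr(i): ("N" if chr(i).upper() not in "ACGTN" else chr(i).upper()) for i in range(128)}
)


@dataclass
class Contig:
    """A transcript sequence with a unique id and an assembler-of-origin label."""

    id: str
    origin: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: empty sequence")


class ContigSet:
    """An ordered collection of contigs with unique ids.

    ``labels`` is the set of origin labels present.  Iteration preserves
    insertion order, which downstream stages rely on for reproducibility.
    """

    def __init__(self, contigs: Iterable[Contig] = ()) -> None:
        self._by_id: dict[str, Contig] = {}
        for c in contigs:
            self.add(c)

    def add(self, contig: Contig) -> None:
        if contig.id in self._by_id:
            raise ValueError(f"duplicate contig id {contig.id!r}")
        self._by_id[contig.id] = contig

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Contig]:
        return iter(self._by_id.values())

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def __getitem__(self, contig_id: str) -> Contig:
        return self._by_id[contig_id]

    def ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def labels(self) -> set[str]:
        return {c.origin for c in self}

    def total_bp(self) -> int:
        return sum(c.length for c in self)


@dataclass(slots=True)
class AlignmentRecord:
    """One read's placement on a contig (or an unplaced read).

    ``is_primary`` is True only for mapped primary alignments; unmapped and
    secondary/supplementary records are retained but never enter scoring.
    Coordinates are 0-based half-open on the contig.
    """

    read_id: str
    contig_id: Optional[str]
    pos: int
    aligned_len: int
    n_match: int
    n_mismatch: int
    is_primary: bool
    is_reverse: bool
    is_first: bool = True
    mate_contig_id: Optional[str] = None
    mate_is_reverse: Optional[bool] = None
    template_len: Optional[int] = None


def _open_maybe_gzip(path) -> io.TextIOWrapper:
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _normalise_seq(seq: str, stats: list[int]) -> str:
    s = seq.translate(_NORM_TABLE)
    kept = sum(seq.upper().count(c) for c in "ACGTN")
    stats[0] += len(seq) - kept
    return s


def read_fasta(path, label: str) -> ContigSet:
    """Read a (possibly gzipped) FASTA file into a :class:`ContigSet`.

    Every record becomes a contig with ``origin=label``.  Sequences are
    uppercased; non-ACGTN characters become ``N``.  An empty file is an error
    ("empty assembly"); sequence data before the first header is a parse error
    naming the offending line.
    """
    handle = _open_maybe_gzip(path)
    with handle:
        # locate the first non-blank line to give a line-numbered diagnostic
        text = handle.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break
    else:
        raise ValueError(f"{path}: empty assembly")
    stats = [0]
    contigs = ContigSet()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = _normalise_seq(str(rec.seq), stats)
        contigs.add(Contig(id=rec.id, origin=label, seq=seq))
    if len(contigs) == 0:
        raise ValueError(f"{path}: empty assembly")
    if stats[0]:
        logger.info("%s: normalised %d non-ACGTN characters to N", path, stats[0])
    return contigs


def write_fasta(contigs: ContigSet, path) -> None:
    """Write contigs as single-line-per-record FASTA (fixed wrapping)."""
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n{c.seq}\n")


def split_origin(contig_id: str) -> tuple[Optional[str], str]:
    """Split a pooled id ``label|orig`` into (label, orig); label None if unprefixed."""
    if ORIGIN_SEP in contig_id:
        label, orig = contig_id.split(ORIGIN_SEP, 1)
        return label, orig
    return None, contig_id


def pool_assemblies(assemblies: list[tuple[str, ContigSet]]) -> ContigSet:
    """Concatenate >= 2 labelled assemblies into one pooled contig set.

    Every contig id is rewritten to ``"<label>|<original id>"`` (which forces
    uniqueness across assemblies) and its origin set to the label.
    """
    if len(assemblies) < 2:
        raise ValueError("merging requires at least two assemblies")
    labels = [lab for lab, _ in assemblies]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate assembly labels: {labels}")
    pooled = ContigSet()
    for label, cset in assemblies:
        if ORIGIN_SEP in label:
            raise ValueError(f"label {label!r} contains reserved character {ORIGIN_SEP!r}")
        for c in cset:
            pooled.add(Contig(id=f"{label}{ORIGIN_SEP}{c.id}", origin=label, seq=c.seq))
    logger.info(
        "pooled %d assemblies -> %d contigs (%s)",
        len(assemblies), len(pooled),
        ", ".join(f"{lab}:{len(cs)}" for lab, cs in assemblies),
    )
    return pooled


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(path, contigs: ContigSet) -> list[AlignmentRecord]:
    """Parse a SAM text file against a known contig set.

    Unmapped and secondary/supplementary records are retained with
    ``is_primary=False``.  Match/mismatch counts are derived from CIGAR + NM
    (NM counts substitutions plus inserted/deleted bases, per SAM convention);
    a mapped record with neither NM nor MD is an error.  SAM 1-based POS is
    converted to 0-based.
    """
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name, contig_id=None, pos=0,
                        aligned_len=0, n_match=0, n_mismatch=0,
                        is_primary=False, is_reverse=False,
                        is_first=not aln.is_read2,
                    )
                )
                continue
            ref = aln.reference_name
            if ref not in contigs:
                raise ValueError(f"SAM reference {ref!r} absent from contig set")
            cig = aln.cigartuples or []
            aligned = sum(n for op, n in cig if op in (0, 7, 8))  # M, =, X
            n_ins = sum(n for op, n in cig if op == 1)
            n_del = sum(n for op, n in cig if op == 2)
            if aln.has_tag("NM"):
                nm = aln.get_tag("NM")
                n_mismatch = max(nm - n_ins - n_del, 0)
            elif aln.has_tag("MD"):
                md = str(aln.get_tag("MD"))
                n_mismatch = sum(1 for ch in md if ch in "ACGTN")
            else:
                raise ValueError(
                    f"read {aln.query_name!r}: cannot derive mismatch count "
                    "(missing NM and MD)"
                )
            primary = not (aln.is_secondary or aln.is_supplementary)
            mate_ref = None
            mate_rev = None
            if aln.is_paired and not aln.mate_is_unmapped:
                mate_ref = aln.next_reference_name
                mate_rev = aln.mate_is_reverse
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=ref,
                    pos=aln.reference_start,
                    aligned_len=aligned,
                    n_match=aligned - n_mismatch,
                    n_mismatch=n_mismatch,
                    is_primary=primary,
                    is_reverse=aln.is_reverse,
                    is_first=not aln.is_read2,
                    mate_contig_id=mate_ref,
                    mate_is_reverse=mate_rev,
                    template_len=aln.template_length if aln.template_length else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

class ReadSet:
    """Paired-end reads of uniform length held as 2-bit code matrices.

    ``mat1``/``mat2`` are ``(n_pairs, read_len)`` uint8 arrays in the encoding
    of :mod:`txfuse.kmers`.  ``names`` are the pair names (no /1 /2 suffix).
    """

    def __init__(self, names: list[str], mat1: np.ndarray, mat2: np.ndarray) -> None:
        if mat1.shape != mat2.shape or mat1.ndim != 2:
            raise ValueError("mate matrices must share a (n_pairs, read_len) shape")
        if len(names) != mat1.shape[0]:
            raise ValueError("name count does not match read count")
        self.names = names
        self.mat1 = mat1
        self.mat2 = mat2

    @property
    def n_pairs(self) -> int:
        return self.mat1.shape[0]

    @property
    def read_len(self) -> int:
        return self.mat1.shape[1]

    @classmethod
    def from_fastq(cls, path1, path2) -> "ReadSet":
        def load(path):
            names, seqs = [], []
            with _open_maybe_gzip(path) as fh:
                while True:
                    head = fh.readline()
                    if not head:
                        break
                    seq = fh.readline().strip()
                    fh.readline()
                    fh.readline()
                    name = head[1:].split()[0].strip()
                    if name.endswith("/1") or name.endswith("/2"):
                        name = name[:-2]
                    names.append(name)
                    seqs.append(seq)
            return names, seqs

        n1, s1 = load(path1)
        n2, s2 = load(path2)
        if len(n1) != len(n2):
            raise ValueError("mate FASTQ files differ in read count")
        lens = {len(s) for s in s1} | {len(s) for s in s2}
        if len(lens) != 1:
            raise ValueError(
                "builtin mapper requires uniform read length; "
                f"found lengths {sorted(lens)}"
            )
        L = lens.pop()
        mat1 = np.vstack([kmers.encode(s) for s in s1]) if s1 else np.zeros((0, L), np.uint8)
        mat2 = np.vstack([kmers.encode(s) for s in s2])
        return cls(n1, mat1, mat2)

    def to_fastq(self, path1, path2, qual_char: str = "I") -> None:
        q = qual_char * self.read_len
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i, name in enumerate(self.names):
                f1.write(f"@{name}/1\n{kmers.decode(self.mat1[i])}\n+\n{q}\n")
                f2.write(f"@{name}/2\n{kmers.decode(self.mat2[i])}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

def write_tsv(df, path, comment_lines: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with optional '#'-prefixed comment lines."""
    with open(path, "w") as fh:
        for line in comment_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")
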