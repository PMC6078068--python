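"""Synthetic transcriptomes, reads, and assembler-bias-corrupted assemblies.

Short-read transcriptome assemblers differ systematically in which transcripts
they recover: some drop low-abundance transcripts (information-theoretic
assemblers are the extreme case), and de Bruijn assemblers run at a longer
k-mer recover highly expressed transcripts preferentially relative to a shorter
k.  On top of expression-dependent dropout, real assemblies carry fragmented
transcripts, artificially duplicated contigs, and chimeras that fuse two
transcripts end-to-end.  This module generates a ground-truth transcriptome
with log-normal expression, error-bearing paired-end reads from it, and
per-"assembler" corrupted assemblies exhibiting exactly those failure modes —
with a full provenance table — so the merging pipeline can be tested end to end
without any external data.

Every generator is bit-reproducible under a fixed seed, and a profile with all
rates at zero is an identity map.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import kmers
from .seqio import Contig, ContigSet, ReadSet, write_fasta, write_tsv

logger = logging.getLogger(__name__)


@dataclass
class TruthSet:
    """Ground-truth transcriptome: sequences, true TPM, and gene membership."""

    transcripts: ContigSet
    tpm: dict[str, float]
    gene_of: dict[str, str]

    def __post_init__(self) -> None:
        total = sum(self.tpm.values())
        if not math.isclose(total, 1e6, rel_tol=1e-6):
            raise ValueError(f"TPM sums to {total}, expected 1e6")
        missing = [t.id for t in self.transcripts if t.id not in self.gene_of]
        if missing:
            raise ValueError(f"transcripts without gene assignment: {missing[:3]}")

    @property
    def genes(self) -> set[str]:
        return set(self.gene_of.values())

    def min_length(self) -> int:
        return min(t.length for t in self.transcripts)


@dataclass(frozen=True)
class BiasProfile:
    """Corruption profile emulating one assembler's systematic behaviour.

    Retention of a transcript with abundance ``t`` (TPM) is::

        retain(t) = [1 - p_drop_low * 1(t < dropout_low_tpm)]
                    * [floor + (ceil - floor) * sigmoid(slope * (ln(t+1) - mid))]

    i.e. an optional hard low-abundance dropout plus a smooth logistic
    retention curve in log-abundance (midpoint/slope per profile).  A flat
    curve (floor == ceil) models an unbiased assembler; a high midpoint with a
    low floor models severe bias toward highly expressed transcripts.

    Retained transcripts are then independently duplicated (second copy with
    small extra edits), fragmented (split at a uniform point in the middle 50%
    of the sequence), used to seed a chimera (concatenation with another
    retained transcript), and finally subjected to i.i.d. substitution noise.
    """

    name: str
    dropout_low_tpm: float = 0.0
    p_drop_low: float = 0.0
    retain_floor: float = 1.0
    retain_ceil: float = 1.0
    retain_midpoint: float = 0.0
    retain_slope: float = 0.0
    frag_rate: float = 0.0
    dup_rate: float = 0.0
    chimera_rate: float = 0.0
    error_rate: float = 0.0
    dup_edit_rate: float = 0.002

    def __post_init__(self) -> None:
        for fname in ("p_drop_low", "retain_floor", "retain_ceil", "frag_rate",
                      "dup_rate", "chimera_rate", "error_rate", "dup_edit_rate"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"profile {self.name!r}: {fname}={v} outside [0,1]")

    def retention_prob(self, tpm) -> np.ndarray:
        t = np.asarray(tpm, dtype=float)
        z = self.retain_slope * (np.log1p(t) - self.retain_midpoint)
        curve = self.retain_floor + (self.retain_ceil - self.retain_floor) / (
            1.0 + np.exp(-z)
        )
        hard = np.where(t < self.dropout_low_tpm, 1.0 - self.p_drop_low, 1.0)
        return hard * curve


#: Canned profiles for the four-assembly benchmark.  Magnitudes are this
#: package's calibration; only the qualitative orderings they induce (severe
#: high-expression bias for "shannon", k-mer-length bias between the two
#: "spades" profiles, "trinity" broad and balanced) are contractual.
CANNED_PROFILES: dict[str, BiasProfile] = {
    "trinity": BiasProfile(
        name="trinity", retain_floor=0.87, retain_ceil=0.87,
        frag_rate=0.05, dup_rate=0.08, chimera_rate=0.004, error_rate=0.001,
    ),
    "spades55": BiasProfile(
        name="spades55", retain_floor=0.68, retain_ceil=0.90,
        retain_midpoint=4.0, retain_slope=0.8,
        frag_rate=0.04, dup_rate=0.04, chimera_rate=0.004, error_rate=0.001,
    ),
    "spades75": BiasProfile(
        name="spades75", retain_floor=0.30, retain_ceil=0.95,
        retain_midpoint=6.0, retain_slope=1.0,
        frag_rate=0.04, dup_rate=0.03, chimera_rate=0.004, error_rate=0.001,
    ),
    "shannon": BiasProfile(
        name="shannon", retain_floor=0.02, retain_ceil=0.97,
        retain_midpoint=7.2, retain_slope=1.4,
        frag_rate=0.02, dup_rate=0.02, chimera_rate=0.003, error_rate=0.001,
    ),
}


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64).astype(np.uint8)


def simulate_transcriptome(
    n_genes: int,
    isoforms_per_gene: int | dict[int, float] = 1,
    length_median: int = 1500,
    length_sdlog: float = 0.6,
    length_min: int = 300,
    expr_sdlog: float = 1.5,
    seed: int = 0,
) -> TruthSet:
    """Simulate a ground-truth transcriptome.

    Transcript lengths are log-normal (median ``length_median``, floored at
    ``length_min``); expression is log-normal (``expr_sdlog``) normalised to
    TPM.  ``isoforms_per_gene`` is either a constant or a ``{count: prob}``
    distribution; isoforms of one gene share >= 60% of their sequence (a
    contiguous block of at most 40% is replaced with novel sequence).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)

    if isinstance(isoforms_per_gene, dict):
        counts = np.array(sorted(isoforms_per_gene))
        probs = np.array([isoforms_per_gene[c] for c in counts], dtype=float)
        probs = probs / probs.sum()
        iso_counts = rng.choice(counts, size=n_genes, p=probs)
    else:
        iso_counts = np.full(n_genes, int(isoforms_per_gene))

    contigs = ContigSet()
    gene_of: dict[str, str] = {}
    tx_codes: dict[str, np.ndarray] = {}
    for g in range(n_genes):
        gene = f"g{g:05d}"
        length = max(int(round(rng.lognormal(math.log(length_median), length_sdlog))),
                     length_min)
        base = _random_seq(rng, length)
        for i in range(iso_counts[g]):
            tid = f"{gene}_i{i}"
            if i == 0:
                codes = base
            else:
                # replace a contiguous block of 20-40% with novel sequence:
                # shares >= 60% with the primary isoform
                frac = rng.uniform(0.2, 0.4)
                blk = int(frac * length)
                start = int(rng.integers(0, length - blk + 1))
                codes = base.copy()
                codes[start : start + blk] = _random_seq(rng, blk)
            contigs.add(Contig(id=tid, origin="truth", seq=kmers.decode(codes)))
            gene_of[tid] = gene
            tx_codes[tid] = codes

    n_tx = len(contigs)
    expr = rng.lognormal(mean=0.0, sigma=expr_sdlog, size=n_tx)
    tpm_values = expr / expr.sum() * 1e6
    tpm = {tid: float(v) for tid, v in zip(contigs.ids(), tpm_values)}
    truth = TruthSet(transcripts=contigs, tpm=tpm, gene_of=gene_of)
    truth._codes = tx_codes  # cached 2-bit forms, used by the read simulator
    return truth


def simulate_reads(
    truth: TruthSet,
    n_pairs: int,
    read_len: int = 100,
    insert_mean: int = 250,
    insert_sd: int = 50,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[ReadSet, pd.DataFrame]:
    """Simulate FR paired-end reads with i.i.d. substitution errors.

    Fragments are sampled from transcripts proportional to ``tpm * length``;
    the insert size is normal (clipped to ``[read_len, transcript length]``)
    and the fragment start uniform.  Mate 1 is the forward end of the fragment,
    mate 2 the reverse complement of its 3' end.  Returns the reads plus a
    placement table recording, per pair, the source transcript, fragment
    coordinates and per-mate error counts — the ground truth for every mapping
    and quantification oracle downstream.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    min_len = truth.min_length()
    if read_len >= min_len:
        raise ValueError(
            f"read_len {read_len} must be shorter than the shortest transcript ({min_len})"
        )
    rng = np.random.default_rng(seed)
    ids = truth.transcripts.ids()
    lengths = np.array([truth.transcripts[t].length for t in ids])
    w = np.array([truth.tpm[t] for t in ids]) * lengths
    w = w / w.sum()

    tx_idx = rng.choice(len(ids), size=n_pairs, p=w)
    tlen = lengths[tx_idx]
    insert = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64)
    insert = np.clip(insert, read_len, tlen)
    start = (rng.random(n_pairs) * (tlen - insert + 1)).astype(np.int64)

    codes_by_tx = getattr(truth, "_codes", None)
    if codes_by_tx is None:
        codes_by_tx = {t: kmers.encode(truth.transcripts[t].seq) for t in ids}
    cat = np.concatenate([codes_by_tx[t] for t in ids])
    offsets = np.concatenate(([0], np.cumsum(lengths)))[:-1]

    g1 = offsets[tx_idx] + start
    idx1 = g1[:, None] + np.arange(read_len)
    mat1 = cat[idx1]
    g2 = offsets[tx_idx] + start + insert - read_len
    idx2 = g2[:, None] + np.arange(read_len)
    # mate 2: reverse complement of the fragment's 3' end
    mat2 = kmers.complement_codes(cat[idx2])[:, ::-1].copy()

    def add_errors(mat: np.ndarray) -> np.ndarray:
        if error_rate <= 0:
            return np.zeros(mat.shape[0], dtype=np.int64)
        mask = rng.random(mat.shape) < error_rate
        shift = rng.integers(1, 4, size=mat.shape, dtype=np.int64).astype(np.uint8)
        mat[mask] = (mat[mask] + shift[mask]) % 4
        return mask.sum(axis=1)

    nerr1 = add_errors(mat1)
    nerr2 = add_errors(mat2)

    names = [f"p{i:06d}" for i in range(n_pairs)]
    placements = pd.DataFrame(
        {
            "pair_id": names,
            "transcript": [ids[i] for i in tx_idx],
            "frag_start": start,
            "frag_end": start + insert,
            "n_err1": nerr1,
            "n_err2": nerr2,
        }
    )
    return ReadSet(names, mat1, mat2), placements


def corrupt_assembly(
    truth: TruthSet,
    profile: BiasProfile,
    seed: int = 0,
) -> tuple[ContigSet, pd.DataFrame]:
    """Produce one corrupted assembly plus its provenance table.

    Corruption stages are applied in order: abundance-dependent dropout,
    duplication, fragmentation, chimera formation, per-base substitution
    noise.  The provenance table maps every emitted contig to its source
    transcript(s), gene(s) and corruption kind (``intact``, ``dup``,
    ``frag5``/``frag3``, ``chimera``).  With all rates zero the output is the
    truth set relabelled.
    """
    rng = np.random.default_rng(seed)
    ids = truth.transcripts.ids()
    tpm = np.array([truth.tpm[t] for t in ids])
    retained_mask = rng.random(len(ids)) < profile.retention_prob(tpm)
    retained = [t for t, keep in zip(ids, retained_mask) if keep]

    # (codes, sources, kind) intermediate stream
    entries: list[tuple[np.ndarray, list[str], str]] = []
    for t in retained:
        codes = kmers.encode(truth.transcripts[t].seq)
        entries.append((codes, [t], "intact"))
        if profile.dup_rate > 0 and rng.random() < profile.dup_rate:
            dup = codes.copy()
            if profile.dup_edit_rate > 0:
                mask = rng.random(dup.size) < profile.dup_edit_rate
                shift = rng.integers(1, 4, size=dup.size).astype(np.uint8)
                dup[mask] = (dup[mask] + shift[mask]) % 4
            entries.append((dup, [t], "dup"))

    if profile.frag_rate > 0:
        fragged: list[tuple[np.ndarray, list[str], str]] = []
        for codes, src, kind in entries:
            if rng.random() < profile.frag_rate:
                n = codes.size
                cut = int(rng.integers(int(0.25 * n), int(0.75 * n) + 1))
                fragged.append((codes[:cut], src, "frag5"))
                fragged.append((codes[cut:], src, "frag3"))
            else:
                fragged.append((codes, src, kind))
        entries = fragged

    if profile.chimera_rate > 0 and len(retained) > 1:
        for t in retained:
            if rng.random() < profile.chimera_rate:
                other = retained[int(rng.integers(0, len(retained)))]
                if other == t:
                    continue
                codes = np.concatenate(
                    (kmers.encode(truth.transcripts[t].seq),
                     kmers.encode(truth.transcripts[other].seq))
                )
                entries.append((codes, [t, other], "chimera"))

    contigs = ContigSet()
    rows = []
    for i, (codes, src, kind) in enumerate(entries):
        out = codes.copy()
        if profile.error_rate > 0:
            mask = rng.random(out.size) < profile.error_rate
            shift = rng.integers(1, 4, size=out.size).astype(np.uint8)
            out[mask] = (out[mask] + shift[mask]) % 4
        cid = f"c{i:05d}"
        contigs.add(Contig(id=cid, origin=profile.name, seq=kmers.decode(out)))
        rows.append(
            {
                "contig_id": cid,
                "origin": profile.name,
                "sources": ";".join(src),
                "genes": ";".join(dict.fromkeys(truth.gene_of[s] for s in src)),
                "kind": kind,
            }
        )
    provenance = pd.DataFrame(rows, columns=["contig_id", "origin", "sources", "genes", "kind"])
    logger.info(
        "%s: retained %d/%d transcripts -> %d contigs",
        profile.name, len(retained), len(ids), len(contigs),
    )
    return contigs, provenance


@dataclass
class Benchmark:
    """The packaged four-assembly synthetic study: truth, reads, assemblies."""

    truth: TruthSet
    reads: ReadSet
    placements: pd.DataFrame
    assemblies: dict[str, ContigSet]
    provenance: dict[str, pd.DataFrame]
    seed: int

    def gene_recovery(self, label: str) -> float:
        """Fraction of truth genes with >= 1 contig in the named assembly."""
        prov = self.provenance[label]
        seen = {g for cell in prov["genes"] for g in cell.split(";")}
        return len(seen) / len(self.truth.genes)

    def union_gene_recovery(self) -> float:
        seen: set[str] = set()
        for prov in self.provenance.values():
            seen |= {g for cell in prov["genes"] for g in cell.split(";")}
        return len(seen) / len(self.truth.genes)

    def pooled_gene_partition(self) -> dict[str, str]:
        """Truth gene label per pooled contig id (chimeras by first source)."""
        out = {}
        for label, prov in self.provenance.items():
            for cid, genes in zip(prov["contig_id"], prov["genes"]):
                out[f"{label}|{cid}"] = genes.split(";")[0]
        return out

    def write(self, out_dir) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        tp = out / "truth.fasta"
        write_fasta(self.truth.transcripts, tp)
        paths.append(tp)
        truth_tbl = pd.DataFrame(
            {
                "transcript": self.truth.transcripts.ids(),
                "gene": [self.truth.gene_of[t] for t in self.truth.transcripts.ids()],
                "tpm": [self.truth.tpm[t] for t in self.truth.transcripts.ids()],
            }
        )
        write_tsv(truth_tbl, out / "truth_expression.tsv")
        paths.append(out / "truth_expression.tsv")
        r1, r2 = out / "reads_1.fastq", out / "reads_2.fastq"
        self.reads.to_fastq(r1, r2)
        paths += [r1, r2]
        write_tsv(self.placements, out / "read_placements.tsv")
        paths.append(out / "read_placements.tsv")
        for label, cset in self.assemblies.items():
            fp = out / f"{label}.fasta"
            write_fasta(cset, fp)
            paths.append(fp)
            pp = out / f"{label}.provenance.tsv"
            write_tsv(self.provenance[label], pp)
            paths.append(pp)
        return paths


def standard_benchmark(
    seed: int = 42,
    n_genes: int = 500,
    n_pairs: int = 50_000,
    read_len: int = 100,
    read_error_rate: float = 0.01,
    out_dir=None,
) -> Benchmark:
    """Build the standard four-assembly benchmark bundle.

    Four corrupted assemblies from the canned profiles plus paired reads.  The
    profiles are calibrated so that gene recovery orders
    shannon < spades75 < {spades55 ~ trinity}, every single assembly misses
    genes the union recovers, and the union covers nearly all truth genes.
    """
    root = np.random.SeedSequence(seed)
    subseeds = [int(s) for s in root.generate_state(2 + len(CANNED_PROFILES)) % (2**31)]
    truth = simulate_transcriptome(n_genes=n_genes, isoforms_per_gene=1, seed=subseeds[0])
    reads, placements = simulate_reads(
        truth, n_pairs=n_pairs, read_len=read_len,
        error_rate=read_error_rate, seed=subseeds[1],
    )
    assemblies: dict[str, ContigSet] = {}
    provenance: dict[str, pd.DataFrame] = {}
    for i, (label, profile) in enumerate(sorted(CANNED_PROFILES.items())):
        cset, prov = corrupt_assembly(truth, profile, seed=subseeds[2 + i])
        assemblies[label] = cset
        provenance[label] = prov
    bench = Benchmark(
        truth=truth, reads=reads, placements=placements,
        assemblies=assemblies, provenance=provenance, seed=seed,
    )
    if out_dir is not None:
        bench.write(out_dir)
    return bench
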