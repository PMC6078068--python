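"""The assembly-merging pipeline: pool, cluster, score, select one winner per group.

Merging several de novo transcriptome assemblies exploits their complementary
biases: each assembler misses transcripts the others recover.  The pipeline
concatenates all input assemblies, clusters the pooled contigs into
orthogroups of homologous transcripts, scores every contig against the reads,
and keeps the highest-scoring contig of each orthogroup as its representative.
The result is a non-redundant assembly that represents more of the read data
than any single input.

Winners retain their pooled ``label|id`` names, so the contribution of each
input assembler to the merged assembly is read directly off the ids.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from .cluster import MclParams, Orthogroup, cluster_assemblies, write_orthogroups
from .config import RunConfig
from .mapping import MapResult, builtin_map
from .score import ContigScore, assembly_score, score_contigs, score_table
from .seqio import (
    AlignmentRecord,
    Contig,
    ContigSet,
    ReadSet,
    pool_assemblies,
    read_fasta,
    read_sam,
    split_origin,
    write_fasta,
    write_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class MergeResult:
    merged: ContigSet
    group_table: pd.DataFrame  # group_id, members, winner_id, winner_origin, winner_score
    contribution: dict[str, float]
    params_used: dict

    def __post_init__(self) -> None:
        if len(self.merged) != len(self.group_table):
            raise AssertionError("one merged contig per orthogroup is required")
        total = sum(self.contribution.values())
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"contribution fractions sum to {total}, not 1")


def select_representatives(
    groups: list[Orthogroup],
    scores: dict[str, ContigScore],
    contigs: ContigSet,
) -> MergeResult:
    """Pick the highest-composite contig of each orthogroup.

    Ties break toward the longer contig, then the lexicographically smallest
    id.  Singleton groups keep their only member.  Every group member must
    have a score.
    """
    rows = []
    merged = ContigSet()
    for g in groups:
        best_key = None
        winner = None
        for cid in sorted(g.members):
            if cid not in scores:
                raise ValueError(f"contig {cid!r} in group {g.group_id} has no score")
            key = (scores[cid].composite, contigs[cid].length, _NegStr(cid))
            if best_key is None or key > best_key:
                best_key, winner = key, cid
        merged.add(Contig(id=winner, origin=contigs[winner].origin, seq=contigs[winner].seq))
        rows.append(
            {
                "group_id": g.group_id,
                "member_count": len(g.members),
                "members": ",".join(sorted(g.members)),
                "winner_id": winner,
                "winner_origin": contigs[winner].origin,
                "winner_score": scores[winner].composite,
            }
        )
    table = pd.DataFrame(rows)
    contribution = contribution_from_table(table)
    return MergeResult(
        merged=merged, group_table=table, contribution=contribution, params_used={}
    )


class _NegStr(str):
    """Orders in reverse so that a *smaller* id wins inside a max() key."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def contribution_from_table(table: pd.DataFrame) -> dict[str, float]:
    counts = table["winner_origin"].value_counts()
    return {k: float(v) / len(table) for k, v in counts.items()}


def contribution_report(result: MergeResult) -> dict[str, float]:
    """Fraction of merged contigs contributed by each input assembler."""
    if len(result.merged) == 0:
        raise ValueError("empty merged assembly")
    return dict(result.contribution)


def run_merge(
    assemblies: list[tuple[str, ContigSet]],
    reads: Optional[ReadSet] = None,
    alignments: Optional[list[AlignmentRecord]] = None,
    config: RunConfig = RunConfig(),
    out_dir=None,
) -> MergeResult:
    """Execute the full merge on in-memory inputs.

    Stages: pool -> cluster -> map (builtin mapper on the pooled set, unless
    caller-supplied alignments against the pooled ids are given) -> score ->
    select representatives.  Deterministic given inputs and config.  With
    ``out_dir`` set, writes merged.fasta, groups.tsv, contigscores.tsv,
    contribution.tsv and a manifest.json echoing the configuration.
    """
    t0 = time.time()
    stage = "pool"
    try:
        pooled = pool_assemblies(assemblies)
        stage = "cluster"
        groups = cluster_assemblies(
            pooled,
            k=config.k_cluster,
            min_similarity=config.min_similarity,
            params=MclParams(inflation=config.inflation),
        )
        stage = "map"
        map_result: Optional[MapResult] = None
        if alignments is None:
            if reads is None:
                raise ValueError("either reads or alignments must be provided")
            map_result = builtin_map(
                reads, pooled, seed_k=config.seed_k, seed=config.seed
            )
            source = map_result
            rate = map_result.mapping_rate()
            n_pairs = reads.n_pairs
        else:
            source = alignments
            n_pairs = len({r.read_id for r in alignments})
            from .score import mapping_rate as _mr

            rate = _mr(alignments, n_pairs)
        stage = "score"
        scores = score_contigs(
            source, pooled, insert_mean=config.insert_mean, insert_sd=config.insert_sd
        )
        stage = "select"
        result = select_representatives(groups, scores, pooled)
    except Exception as err:
        raise RuntimeError(f"merge failed at stage {stage!r}: {err}") from err

    result.params_used = {**config.as_dict(), "n_pairs": n_pairs, "mapping_rate": rate}
    logger.info(
        "merge: %d inputs -> %d groups -> %d winners (%.1fs)",
        len(assemblies), len(result.group_table), len(result.merged), time.time() - t0,
    )
    if out_dir is not None:
        write_merge_outputs(result, scores, pooled, out_dir, rate)
    return result


def write_merge_outputs(result, scores, pooled, out_dir, rate) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.merged, out / "merged.fasta")
    write_tsv(result.group_table, out / "groups.tsv")
    write_tsv(score_table(scores, pooled).sort_values("contig_id"), out / "contigscores.tsv")
    contrib = pd.DataFrame(
        sorted(result.contribution.items()), columns=["origin", "fraction"]
    )
    write_tsv(contrib, out / "contribution.tsv")
    manifest = {
        "outputs": ["merged.fasta", "groups.tsv", "contigscores.tsv", "contribution.tsv"],
        "n_groups": int(len(result.group_table)),
        "mapping_rate": rate,
        "params": result.params_used,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def merge_from_paths(
    assemblies: list[tuple[str, str]],
    reads_paths: Optional[tuple[str, str]] = None,
    sam_path: Optional[str] = None,
    config: RunConfig = RunConfig(),
    out_dir=None,
) -> MergeResult:
    """File-based front end: FASTA assemblies + FASTQ reads (or a SAM file).

    A caller-supplied SAM must be aligned against the pooled contig ids
    (``label|id``).
    """
    sets = [(label, read_fasta(path, label)) for label, path in assemblies]
    reads = None
    alignments = None
    if sam_path is not None:
        pooled = pool_assemblies(sets)
        alignments = read_sam(sam_path, pooled)
    elif reads_paths is not None:
        reads = ReadSet.from_fastq(*reads_paths)
    else:
        raise ValueError("provide either reads or a SAM file")
    return run_merge(sets, reads=reads, alignments=alignments, config=config, out_dir=out_dir)


# ---------------------------------------------------------------------------
# Duplication accounting
# ---------------------------------------------------------------------------

def gene_duplication(
    contig_ids: list[str],
    gene_map: dict[str, list[str]],
) -> float:
    """Fraction of represented truth genes carried by more than one contig.

    ``gene_map`` maps contig id -> gene id(s).  A gene split across several
    contigs (fragments, duplicates, or co-selected isoform pieces) counts once
    toward duplication; the denominator is the set of genes represented at
    all, mirroring ortholog-duplication metrics computed on recovered genes.
    """
    counts: dict[str, int] = {}
    for cid in contig_ids:
        for g in dict.fromkeys(gene_map.get(cid, [])):
            counts[g] = counts.get(g, 0) + 1
    if not counts:
        return 0.0
    return sum(1 for v in counts.values() if v > 1) / len(counts)


def duplication_report(
    result: MergeResult,
    gene_map: Optional[dict[str, list[str]]] = None,
    similarity_threshold: float = 0.1,
    k: int = 31,
) -> dict:
    """Duplication summary of the merged assembly.

    With ground-truth provenance (``gene_map``): the fraction of represented
    truth genes covered by more than one merged contig.  Without it: residual
    redundancy, the fraction of merged contigs whose best intra-merged
    similarity reaches the clustering threshold.
    """
    ids = result.merged.ids()
    if gene_map is not None:
        dup = gene_duplication(ids, gene_map)
        return {"mode": "truth", "duplication": dup}
    from .cluster import build_graph

    graph = build_graph(result.merged, k=k, min_similarity=similarity_threshold)
    redundant = sum(1 for cid in ids if graph.degree(cid) > 0)
    return {"mode": "residual", "duplication": redundant / max(len(ids), 1)}
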