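"""Shared fixtures: the synthetic benchmark and cached full pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass

import pytest
from hypothesis import settings

from txfuse import cluster, mapping, merge, score, seqio, simdata
from txfuse.config import RunConfig

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@dataclass
class PipelineRun:
    """All intermediate artefacts of one benchmark merge, for oracle checks."""

    bench: simdata.Benchmark
    pooled: seqio.ContigSet
    groups: list
    map_result: mapping.MapResult
    scores: dict
    result: merge.MergeResult

    def gene_map(self) -> dict[str, list[str]]:
        gm: dict[str, list[str]] = {}
        for lab, prov in self.bench.provenance.items():
            for cid, genes in zip(prov["contig_id"], prov["genes"]):
                gm[f"{lab}|{cid}"] = genes.split(";")
        return gm

    def pooled_ids(self) -> list[str]:
        return self.pooled.ids()


_RUNS: dict[tuple, PipelineRun] = {}


def pipeline_run(seed: int, n_genes: int = 500, n_pairs: int = 50_000) -> PipelineRun:
    key = (seed, n_genes, n_pairs)
    if key not in _RUNS:
        cfg = RunConfig()
        bench = simdata.standard_benchmark(seed=seed, n_genes=n_genes, n_pairs=n_pairs)
        pooled = seqio.pool_assemblies(sorted(bench.assemblies.items()))
        groups = cluster.cluster_assemblies(
            pooled, k=cfg.k_cluster, min_similarity=cfg.min_similarity,
            params=cluster.MclParams(inflation=cfg.inflation),
        )
        map_result = mapping.builtin_map(bench.reads, pooled, seed_k=cfg.seed_k, seed=cfg.seed)
        scores = score.score_contigs(
            map_result, pooled, insert_mean=cfg.insert_mean, insert_sd=cfg.insert_sd
        )
        result = merge.select_representatives(groups, scores, pooled)
        _RUNS[key] = PipelineRun(bench, pooled, groups, map_result, scores, result)
    return _RUNS[key]


@pytest.fixture(scope="session")
def run42() -> PipelineRun:
    """The standard benchmark pipeline at seed 42 (500 genes, 50k pairs)."""
    return pipeline_run(42)


@pytest.fixture(scope="session")
def bench42(run42) -> simdata.Benchmark:
    return run42.bench


@pytest.fixture(scope="session")
def small_truth() -> simdata.TruthSet:
    return simdata.simulate_transcriptome(n_genes=25, seed=11)
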