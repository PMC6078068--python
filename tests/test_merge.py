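"""Representative selection, the merge pipeline, and duplication accounting."""

import numpy as np
import pytest

from oracles import argmax_winner

from txfuse import simdata
from txfuse.cluster import Orthogroup, cluster_assemblies
from txfuse.config import RunConfig
from txfuse.mapping import builtin_map
from txfuse.merge import (
    duplication_report,
    gene_duplication,
    run_merge,
    select_representatives,
)
from txfuse.score import ContigScore, score_contigs
from txfuse.seqio import Contig, ContigSet, pool_assemblies


def make_scores(values: dict[str, float]) -> dict[str, ContigScore]:
    # composite == s_nuc when other components are 1 and s_nuc >= 0.01
    return {cid: ContigScore(cid, v ** 4, 1, 1, 1) for cid, v in values.items()}


class TestSelectRepresentatives:
    def contigs(self, lengths: dict[str, int]) -> ContigSet:
        return ContigSet([Contig(cid, "x", "A" * n) for cid, n in lengths.items()])

    def test_highest_composite_wins(self):
        groups = [Orthogroup(0, frozenset({"A", "B"}))]
        res = select_representatives(
            groups, make_scores({"A": 0.9, "B": 0.5}), self.contigs({"A": 100, "B": 100})
        )
        assert res.group_table["winner_id"].tolist() == ["A"]

    def test_length_breaks_score_ties(self):
        groups = [Orthogroup(0, frozenset({"A", "B"}))]
        res = select_representatives(
            groups, make_scores({"A": 0.7, "B": 0.7}), self.contigs({"A": 500, "B": 800})
        )
        assert res.group_table["winner_id"].tolist() == ["B"]

    def test_id_breaks_remaining_ties(self):
        groups = [Orthogroup(0, frozenset({"B", "A"}))]
        res = select_representatives(
            groups, make_scores({"A": 0.7, "B": 0.7}), self.contigs({"A": 500, "B": 500})
        )
        assert res.group_table["winner_id"].tolist() == ["A"]

    def test_missing_score_is_error(self):
        groups = [Orthogroup(0, frozenset({"A", "B"}))]
        with pytest.raises(ValueError, match="B"):
            select_representatives(
                groups, make_scores({"A": 0.9}), self.contigs({"A": 10, "B": 10})
            )

    def test_matches_exhaustive_argmax_on_benchmark(self, run42):
        """Every winner equals the brute-force per-group argmax."""
        composites = {cid: s.composite for cid, s in run42.scores.items()}
        lengths = {cid: run42.pooled[cid].length for cid in run42.pooled.ids()}
        table = run42.result.group_table
        for _, row in table.iterrows():
            members = row["members"].split(",")
            assert row["winner_id"] == argmax_winner(members, composites, lengths)

    def test_result_invariants(self, run42):
        res = run42.result
        assert len(res.merged) == len(res.group_table)
        assert sum(res.contribution.values()) == pytest.approx(1.0, abs=1e-12)
        for _, row in res.group_table.iterrows():
            assert row["winner_id"] in row["members"].split(",")


class TestPipeline:
    def test_identical_assemblies_collapse(self):
        truth = simdata.simulate_transcriptome(12, seed=4)
        cs = truth.transcripts
        a = ContigSet([Contig(c.id, "X", c.seq) for c in cs])
        b = ContigSet([Contig(c.id, "Y", c.seq) for c in cs])
        reads, _ = simdata.simulate_reads(truth, 2000, error_rate=0.0, seed=5)
        res = run_merge([("X", a), ("Y", b)], reads=reads)
        assert len(res.merged) == len(cs)
        assert (res.group_table["member_count"] == 2).all()

    def test_union_behaviour_with_disjoint_assemblies(self):
        truth = simdata.simulate_transcriptome(14, seed=6)
        ids = truth.transcripts.ids()
        half1 = ContigSet([Contig(t, "A", truth.transcripts[t].seq) for t in ids[:7]])
        half2 = ContigSet([Contig(t, "B", truth.transcripts[t].seq) for t in ids[7:]])
        reads, _ = simdata.simulate_reads(truth, 2000, error_rate=0.0, seed=7)
        res = run_merge([("A", half1), ("B", half2)], reads=reads)
        assert len(res.merged) == 14  # a representative from each side survives
        assert {c.origin for c in res.merged} == {"A", "B"}

    def test_merge_is_idempotent(self):
        truth = simdata.simulate_transcriptome(10, seed=8)
        reads, _ = simdata.simulate_reads(truth, 1500, error_rate=0.0, seed=9)
        a, _ = simdata.corrupt_assembly(truth, simdata.CANNED_PROFILES["trinity"], seed=1)
        b, _ = simdata.corrupt_assembly(truth, simdata.CANNED_PROFILES["spades55"], seed=2)
        first = run_merge([("a", a), ("b", b)], reads=reads)
        strip = ContigSet(
            [Contig(c.id.split("|", 1)[1] + f"_{i}", "m", c.seq)
             for i, c in enumerate(first.merged)]
        )
        again = run_merge([("m1", strip), ("m2", strip)], reads=reads)
        assert sorted(c.seq for c in again.merged) == sorted(c.seq for c in first.merged)

    def test_single_assembly_is_rejected(self):
        cs = ContigSet([Contig("c", "x", "ACGT" * 50)])
        with pytest.raises(RuntimeError, match="at least two"):
            run_merge([("x", cs)], reads=None)

    def test_mapping_rate_dominance_seed42(self, run42):
        """The merged assembly represents the reads at least as well as any input."""
        merged_rate = builtin_map(
            run42.bench.reads, run42.result.merged, seed=0
        ).mapping_rate()
        for lab, cset in run42.bench.assemblies.items():
            rate = builtin_map(run42.bench.reads, cset, seed=0).mapping_rate()
            assert merged_rate >= rate, lab


class TestContribution:
    def test_counting(self):
        import pandas as pd

        from txfuse.merge import contribution_from_table

        table = pd.DataFrame(
            {"winner_origin": ["t"] * 4 + ["s55"] * 2 + ["s75"] + ["sh"]}
        )
        contrib = contribution_from_table(table)
        assert contrib == {"t": 0.5, "s55": 0.25, "s75": 0.125, "sh": 0.125}

    def test_shannon_contributes_fewest_on_benchmark(self, run42):
        contrib = run42.result.contribution
        assert set(contrib) == {"trinity", "spades55", "spades75", "shannon"}
        assert contrib["shannon"] == min(contrib.values())


class TestDuplication:
    def test_one_contig_per_gene_is_zero(self):
        gm = {"a": ["g1"], "b": ["g2"]}
        assert gene_duplication(["a", "b"], gm) == 0.0

    def test_two_fragments_of_one_gene_count_once(self):
        gm = {"a": ["g1"], "b": ["g1"], "c": ["g2"]}
        assert gene_duplication(["a", "b", "c"], gm) == 0.5

    def test_merged_leq_pooled_and_most_duplicated_input(self, run42):
        gm = run42.gene_map()
        merged_dup = gene_duplication(run42.result.merged.ids(), gm)
        pooled_dup = gene_duplication(run42.pooled_ids(), gm)
        single_dups = []
        for lab, prov in run42.bench.provenance.items():
            ids = [f"{lab}|{c}" for c in prov["contig_id"]]
            single_dups.append(gene_duplication(ids, gm))
        assert merged_dup <= pooled_dup
        assert merged_dup <= max(single_dups)

    def test_residual_mode_without_truth(self, run42):
        rep = duplication_report(run42.result)
        assert rep["mode"] == "residual"
        assert 0.0 <= rep["duplication"] <= 1.0


class TestChimeraCluster:
    """The {AB, A, B} case: a chimera co-clusters with its sources."""

    def build(self):
        rng = np.random.default_rng(33)
        A = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
        B = "".join("ACGT"[i] for i in rng.integers(0, 4, 900))
        asm1 = ContigSet([Contig("AB", "asm1", A + B)])
        asm2 = ContigSet([Contig("A", "asm2", A), Contig("B", "asm2", B)])
        truth = simdata.TruthSet(
            transcripts=ContigSet([Contig("A", "truth", A), Contig("B", "truth", B)]),
            tpm={"A": 9e5, "B": 1e5},  # unequal support puts a step in AB's coverage
            gene_of={"A": "gA", "B": "gB"},
        )
        reads, _ = simdata.simulate_reads(truth, 4000, error_rate=0.0, seed=11)
        return asm1, asm2, reads

    def test_selection_contract_and_chimera_loses(self):
        asm1, asm2, reads = self.build()
        res = run_merge([("asm1", asm1), ("asm2", asm2)], reads=reads)
        # find the group holding the chimera
        (row,) = [r for _, r in res.group_table.iterrows()
                  if "asm1|AB" in r["members"].split(",")]
        members = row["members"].split(",")
        assert set(members) >= {"asm1|AB"}
        # the winner maximises the composite (selection contract) ...
        pooled = pool_assemblies([("asm1", asm1), ("asm2", asm2)])
        mres = builtin_map(reads, pooled, seed=RunConfig().seed)
        scores = score_contigs(mres, pooled)
        best = max(members, key=lambda c: (scores[c].composite, pooled[c].length))
        assert row["winner_id"] == best
        # ... and the s_seg deficit of the coverage step dethrones the chimera
        assert row["winner_id"] != "asm1|AB"
        assert scores["asm1|AB"].s_seg < 0.5
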