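"""Contig-score components, composites, and the bundled mapper."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import seg_score_reference

from txfuse import simdata
from txfuse.mapping import builtin_map
from txfuse.score import (
    AssemblyScore,
    ContigScore,
    assembly_score,
    mapping_rate,
    s_cov,
    s_nuc,
    s_ord,
    s_seg,
    score_contigs,
)
from txfuse.seqio import AlignmentRecord, Contig, ContigSet


def rec(read_id="r", contig="c", pos=0, alen=100, nm=0, primary=True, rev=False,
        first=True, tlen=None):
    return AlignmentRecord(
        read_id=read_id, contig_id=contig, pos=pos, aligned_len=alen,
        n_match=alen - nm, n_mismatch=nm, is_primary=primary, is_reverse=rev,
        is_first=first, template_len=tlen,
    )


class TestComponents:
    def test_s_nuc_exact_fractions(self):
        assert s_nuc([rec(nm=0)]) == 1.0
        assert s_nuc([rec(nm=10)]) == pytest.approx(0.9)
        assert s_nuc([]) == 0.0

    def test_s_nuc_equals_per_record_sum_on_simulated_contig(self):
        truth = simdata.simulate_transcriptome(5, seed=2)
        reads, _ = simdata.simulate_reads(truth, 300, error_rate=0.02, seed=3)
        records = builtin_map(reads, truth.transcripts, seed=0).to_records()
        counts = {}
        for r in records:
            if r.is_primary:
                counts[r.contig_id] = counts.get(r.contig_id, 0) + 1
        cid = max(counts, key=counts.get)
        mine = [r for r in records if r.is_primary and r.contig_id == cid]
        expect = sum(r.n_match for r in mine) / sum(r.aligned_len for r in mine)
        assert s_nuc(mine) == pytest.approx(expect)

    def test_s_cov_interval_union(self):
        assert s_cov([rec(pos=0, alen=50)], 100) == 0.5
        assert s_cov([rec(pos=0, alen=60), rec(pos=40, alen=60)], 100) == 1.0
        assert s_cov([], 10) == 0.0

    def test_s_cov_matches_positional_oracle(self):
        rng = np.random.default_rng(4)
        L = 700
        recs = [rec(read_id=f"r{i}", pos=int(p), alen=50)
                for i, p in enumerate(rng.integers(0, L - 50, size=200))]
        per_base = np.zeros(L, dtype=int)
        for r in recs:
            per_base[r.pos : r.pos + 50] += 1
        assert s_cov(recs, L) == pytest.approx((per_base > 0).mean())

    def test_s_ord_fractions(self):
        def pair(i, good=True):
            tl = 250 if good else 900
            return [
                rec(read_id=f"p{i}", pos=0, rev=False, first=True, tlen=tl),
                rec(read_id=f"p{i}", pos=150, rev=good, first=False, tlen=-tl),
            ]

        recs = sum((pair(i) for i in range(4)), [])
        assert s_ord(recs) == 1.0
        recs = sum((pair(i, good=(i > 0)) for i in range(4)), [])
        assert s_ord(recs) == 0.75

    def test_s_ord_neutral_without_pairs(self):
        assert s_ord([rec()]) == 1.0

    def test_s_seg_uniform_coverage_prefers_one_segment(self):
        cov = np.full(1000, 50.0)
        got = s_seg(cov)
        assert got > 0.5
        assert got == pytest.approx(seg_score_reference(cov), abs=1e-12)

    def test_s_seg_step_coverage_flags_chimera(self):
        cov = np.concatenate([np.full(500, 50.0), np.full(500, 1.0)])
        got = s_seg(cov)
        assert got < 0.5
        assert got == pytest.approx(seg_score_reference(cov), abs=1e-12)

    def test_s_seg_degenerate_cases(self):
        assert s_seg([7.0]) == 1.0
        assert s_seg(np.zeros(50)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_s_seg_matches_bic_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        cov = rng.poisson(20, size=int(rng.integers(10, 400))).astype(float)
        assert s_seg(cov) == pytest.approx(seg_score_reference(cov), abs=1e-10)


class TestComposite:
    def test_perfect_components(self):
        assert ContigScore("c", 1, 1, 1, 1).composite == 1.0

    def test_arithmetic_identity(self):
        assert ContigScore("c", 1, 1, 1, 0.0625).composite == pytest.approx(0.5)

    def test_floor_rule(self):
        assert ContigScore("c", 0, 1, 1, 1).composite == pytest.approx(0.01 ** 0.25)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=4, max_size=4))
    def test_composite_equals_floored_geometric_mean(self, comps):
        got = ContigScore("c", *comps).composite
        expect = math.prod(max(c, 0.01) for c in comps) ** 0.25
        assert got == pytest.approx(expect, rel=1e-12)
        assert 0.01 <= got <= 1.0 + 1e-12


class TestAssemblyScore:
    def test_examples(self):
        ones = [ContigScore("a", 1, 1, 1, 1), ContigScore("b", 1, 1, 1, 1)]
        assert assembly_score(ones, 0.9).score == pytest.approx(0.9)
        mix = [ContigScore("a", 1, 1, 1, 0.0625), ContigScore("b", 1, 1, 1, 1)]
        assert assembly_score(mix, 1.0).score == pytest.approx(0.5 ** 0.5)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            assembly_score([], 1.0)

    def test_score_bounded_by_mapping_rate(self):
        s = assembly_score([ContigScore("a", 1, 1, 1, 1)], 0.7)
        assert s.score <= s.mapping_rate

    def test_log_domain_oracle_and_permutation_invariance(self, run42):
        scores = list(run42.scores.values())
        rate = run42.map_result.mapping_rate()
        got = assembly_score(scores, rate).score
        expect = math.exp(np.mean([math.log(s.composite) for s in scores])) * rate
        assert got == pytest.approx(expect, abs=1e-9)
        assert assembly_score(scores[::-1], rate).score == pytest.approx(got, abs=1e-12)


class TestMappingRate:
    def test_trivial_rates(self):
        recs = []
        for i in range(100):
            recs.append(rec(read_id=f"p{i}", first=True))
            recs.append(rec(read_id=f"p{i}", first=False))
        assert mapping_rate(recs, 100) == 1.0
        assert mapping_rate([], 100) == 0.0
        with pytest.raises(ValueError):
            mapping_rate([], 0)

    def test_error_free_reads_all_pair_map(self, small_truth):
        """With exact reads every pair has an exact seed: rate 1 and NM=0."""
        reads, _ = simdata.simulate_reads(small_truth, 500, error_rate=0.0, seed=5)
        res = builtin_map(reads, small_truth.transcripts, seed=0)
        assert res.mapping_rate() == 1.0
        assert res.mate1.nm[res.mate1.mapped].max(initial=0) == 0
        assert res.mate2.nm[res.mate2.mapped].max(initial=0) == 0


class TestBuiltinMapper:
    def test_reads_from_absent_transcript_are_unmapped(self, small_truth):
        reads, placements = simdata.simulate_reads(small_truth, 400, error_rate=0.0, seed=6)
        keep = small_truth.transcripts.ids()[:5]
        subset = ContigSet([Contig(t, "x", small_truth.transcripts[t].seq) for t in keep])
        res = builtin_map(reads, subset, seed=0)
        from_absent = ~placements["transcript"].isin(keep).to_numpy()
        assert not res.mate1.mapped[from_absent].any()
        assert res.mate1.mapped[~from_absent].all()

    def test_nm_matches_placement_table(self, small_truth):
        reads, placements = simdata.simulate_reads(
            small_truth, 10_000, error_rate=0.01, seed=7
        )
        res = builtin_map(reads, small_truth.transcripts, seed=0)
        m = res.mate1.mapped
        agree = (res.mate1.nm[m] == placements["n_err1"].to_numpy()[m]).mean()
        assert agree >= 0.99

    def test_proper_fr_orientation_for_simulated_pairs(self, small_truth):
        reads, _ = simdata.simulate_reads(small_truth, 500, error_rate=0.0, seed=8)
        res = builtin_map(reads, small_truth.transcripts, seed=0)
        assert res.proper_fr().mean() > 0.99

    def test_deterministic_given_seed(self, small_truth):
        reads, _ = simdata.simulate_reads(small_truth, 500, error_rate=0.01, seed=9)
        a = builtin_map(reads, small_truth.transcripts, seed=3)
        b = builtin_map(reads, small_truth.transcripts, seed=3)
        assert np.array_equal(a.mate1.contig, b.mate1.contig)
        assert np.array_equal(a.mate1.pos, b.mate1.pos)


class TestScoreContigs:
    def test_array_path_matches_contract_functions(self, small_truth):
        reads, _ = simdata.simulate_reads(small_truth, 2000, error_rate=0.01, seed=10)
        res = builtin_map(reads, small_truth.transcripts, seed=0)
        fast = score_contigs(res, small_truth.transcripts)
        records = res.to_records()
        slow = score_contigs(records, small_truth.transcripts)
        for cid in small_truth.transcripts.ids():
            for attr in ("s_nuc", "s_cov", "s_ord", "s_seg"):
                assert getattr(fast[cid], attr) == pytest.approx(
                    getattr(slow[cid], attr), abs=1e-9
                ), (cid, attr)
            # and against the per-contig contract functions
            mine = [r for r in records if r.is_primary and r.contig_id == cid]
            assert fast[cid].s_nuc == pytest.approx(s_nuc(mine), abs=1e-12)
            assert fast[cid].s_cov == pytest.approx(
                s_cov(mine, small_truth.transcripts[cid].length), abs=1e-12
            )
            assert fast[cid].s_ord == pytest.approx(s_ord(mine), abs=1e-12)

    def test_exact_fully_covered_copy_scores_perfectly(self):
        truth = simdata.simulate_transcriptome(3, length_median=400, seed=12)
        reads, _ = simdata.simulate_reads(truth, 4000, error_rate=0.0,
                                          insert_sd=0, seed=13)
        res = builtin_map(reads, truth.transcripts, seed=0)
        scores = score_contigs(res, truth.transcripts)
        for cid, s in scores.items():
            assert s.s_nuc == 1.0
            assert s.s_cov == 1.0
            assert s.s_ord == 1.0

    def test_chimeras_score_lower_s_seg_than_sources(self, run42):
        """On the benchmark, chimeric contigs average lower s_seg than intact ones."""
        chim, intact = [], []
        for lab, prov in run42.bench.provenance.items():
            for cid, kind in zip(prov["contig_id"], prov["kind"]):
                pooled_id = f"{lab}|{cid}"
                s = run42.scores[pooled_id]
                if kind == "chimera":
                    chim.append(s.s_seg)
                elif kind == "intact":
                    intact.append(s.s_seg)
        assert chim, "benchmark should contain chimeras"
        assert np.mean(chim) < np.mean(intact)
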