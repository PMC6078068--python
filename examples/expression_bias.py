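"""Expose assembler bias by stratifying winner expression by origin.

Quantifies the merged assembly (fragment counting with equal multi-hit
splitting, TPM with effective-length correction) and summarises log(TPM+1)
of each origin's winners.  An assembler that drops low-abundance transcripts
can only contribute high-expression winners, so its distribution sits far to
the right.
"""

from txfuse import (
    builtin_map,
    expression_by_origin,
    quantify,
    run_merge,
    standard_benchmark,
)

bench = standard_benchmark(seed=42)
result = run_merge(sorted(bench.assemblies.items()), reads=bench.reads)

mapped = builtin_map(bench.reads, result.merged, seed=0)
expr = quantify(mapped, result.merged)

summary = expression_by_origin(result.group_table, expr)
print("log(TPM+1) of merged-assembly winners, by assembler of origin:")
print(summary.round(2).to_string(index=False))
print("\nthe severe-dropout profile (shannon) contributes only "
      "high-expression transcripts; the k=75 profile (spades75) skews higher "
      "than k=55 — the k-mer-length bias.")
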