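"""Sketch-compare assemblies and embed them in 2-D.

Each assembly is summarised by a bottom-5,000 MinHash signature of its
canonical 51-mers; pairwise distances (1 - estimated Jaccard) are embedded
with classical metric MDS.  Assemblies produced by similar corruption
profiles land near each other; the merged assembly, being drawn from all
four, sits centrally.
"""

from txfuse import compare, mds_embed, run_merge, sketch, standard_benchmark

bench = standard_benchmark(seed=42)
result = run_merge(sorted(bench.assemblies.items()), reads=bench.reads)

sigs = [sketch(cs, label=lab) for lab, cs in sorted(bench.assemblies.items())]
sigs.append(sketch(result.merged, label="merged"))

dist = compare(sigs)
print("distance matrix (1 - estimated Jaccard, k=51, s=5000):")
print(dist.to_frame().round(3))

print("\n2-D MDS embedding:")
print(mds_embed(dist).round(3).to_string(index=False))
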