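# txfuse

Merge multiple de novo transcriptome assemblies into one non-redundant
assembly by clustering homologous contigs and keeping the contig with the best
read-evidence score per cluster — plus the tooling to quantify what the merge
buys and which assembler contributed what.

## The problem

De novo transcriptome assembly from short reads is heuristic, and every
assembler's heuristics bias which transcripts it reconstructs: some drop
low-abundance transcripts almost entirely, and de Bruijn assemblers run at a
longer k-mer recover highly expressed transcripts preferentially relative to a
shorter k.  Assemblies built by different tools (or the same tool at different
k) therefore recover complementary fractions of the transcriptome.  Simply
concatenating them recovers the union but leaves massive redundancy — most
transcripts appear once per input assembly, which wrecks downstream abundance
estimation.

`txfuse` implements the merge-and-select strategy for this problem:

1. **Pool** all candidate assemblies, rewriting ids to `label|id` so every
   contig's assembler of origin is tracked.
2. **Cluster** the pooled contigs into orthogroups with Markov clustering
   (MCL) of a similarity graph whose edge weights are the max-containment of
   canonical k-mer sets, `|K(a) ∩ K(b)| / min(|K(a)|, |K(b)|)` (k = 31):
   fragments connect to their full-length parents with weight ≈ 1.  The
   inflation parameter defaults to *I* = 4 — far above MCL's usual 2 — so that
   transcript isoforms resist collapsing into a single group.
3. **Score** every pooled contig from read alignments with four components in
   [0, 1]: nucleotide fidelity *s*<sub>nuc</sub> (matched/aligned bases), base
   coverage *s*<sub>cov</sub>, pair order/orientation agreement
   *s*<sub>ord</sub>, and single-transcript coverage plausibility
   *s*<sub>seg</sub> (the BIC weight of a 1-segment vs best 2-segment model of
   log₂(coverage+1); a chimera's coverage step drives it to 0).  The composite
   is the geometric mean with a 0.01 floor per component, and an assembly's
   score is (geometric mean of composites) × (pair mapping rate).
4. **Select** the highest-composite contig of each orthogroup (ties: longer,
   then smaller id) as its representative in the merged assembly.

The package also ships a synthetic-data module that simulates exactly the
assembler biases above (plus fragmentation, duplication and chimeras, with
full provenance), a vectorised exact-seed read mapper for test-scale
alignment, bottom-s MinHash sketching with classical MDS for comparing
assemblies, and TPM quantification for stratifying expression by assembler of
origin.

## Worked example

```bash
python examples/merge_assemblies.py
```

builds the packaged 500-gene benchmark (four corrupted assemblies, 50,000 read
pairs, seed 42), merges it, and prints:

```
pooled 1548 contigs -> 493 merged representatives

pair mapping rate (fraction of pairs with both mates aligned):
  shannon   76.6%
  spades55  86.6%
  spades75  81.9%
  trinity   88.9%
  merged    94.6%   <- dominates every input

contribution of each assembler to the merged assembly:
  trinity   34.1%
  spades55  32.7%
  spades75  22.9%
  shannon   10.3%
```

The merged assembly represents the reads better than every input while using
a third of the pooled contigs; the severe-dropout profile ("shannon")
contributes the fewest representatives.  The other examples show the
benchmark's per-assembly gene recovery (`simulate_benchmark.py`), sketch
distances and their MDS embedding (`compare_sketches.py`), and per-origin
expression distributions of the winners (`expression_bias.py`) — the last
prints a median log(TPM+1) of 7.7 for shannon-origin winners versus 6.4 for
trinity-origin ones, the signature of expression-dependent dropout.

A `txfuse` console command exposes the same stages for shell use
(`txfuse simulate | cluster | score | merge | sketch | compare | quantify |
report`; see `txfuse --help`).

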