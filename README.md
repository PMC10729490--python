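# pangraphkit

Analysis of haplotype-path pangenome graphs for multi-species (super-)pangenome
studies: node and gene classification into core/dispensable/private
compartments, pangenome growth curves, shared-node-space relatedness,
allele-specific node detection, graph-to-VCF variant deconstruction with
effect-enrichment statistics, and Hill–Weir linkage-disequilibrium decay
fitting. A synthetic pangenome generator with exact ground truth makes every
stage testable without any external data.

## The problem

A pangenome graph (GFA v1, as produced by PGGB/seqwish/smoothxg) stores the
genomes of many individuals — here, diploid genomes of several wild species —
as *nodes* (DNA segments, possibly 1 bp) and *paths* (one oriented walk per
haplotype chromosome). Shared sequence appears once; structural differences
appear as alternative walks. `pangraphkit` turns this topology into the
standard population-level summaries:

- **Node classes.** With N species, a node is *core* when paths of all N
  species traverse it, *private* when exactly one species does, and
  *dispensable* otherwise. Presence is species-level (either haplotype
  counts) and ignores orientation and traversal multiplicity, so all
  length-based totals are over distinct ("unique") nodes.
- **Gene classes.** A gene is core/dispensable/private when more than 80%
  (strict) of its body, in bp of traversed node space, lies in that class;
  otherwise it is *ambiguous*.
- **Growth curves.** For every species subset S, nodes (or genes) are
  reclassified relative to S and per-class totals recorded — the graph-based
  pangenome modeling behind openness estimates.
- **Relatedness.** The total length of nodes shared by two path sets, with
  percentages relative to each side — an alignment-free relatedness metric —
  and *allele-specific nodes*: nodes present in every haplotype of one group
  and absent from all of the other (the rule used to isolate female/male
  alleles of a sex-determining region).
- **Variants.** Reference-guided pairwise deconstruction: a maximal collinear
  chain of shared node occurrences anchors each alternate path to the
  reference, and every differing inter-anchor gap yields one top-level
  variant (SNP/INS/DEL/MNP, VCF left-anchored). Merged bi-allelic,
  multi-sample sites are written as VCF 4.2. Per-effect enrichment uses
  two-sided Fisher tests with Bonferroni correction (significant when the
  enrichment ratio > 1 and adjusted p < 0.05).
- **LD decay.** Least-squares fit of the Hill & Weir (1988)
  drift–recombination expectation
  E[r²] = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))],
  C = ρ·d, reporting ρ, the half-decay distance and the distance at which
  E[r²] < 0.1.

## Worked example

```python
from pangraphkit import parse_gfa
from pangraphkit.classify import classify_nodes, presence_matrix
from pangraphkit.simulate import SimulationConfig, simulate_pangenome

res = simulate_pangenome(SimulationConfig(seed=42))   # 9 species x 2 haplotypes, 100 kb
graph = parse_gfa(res.gfa)
classes = classify_nodes(presence_matrix(graph), graph)
print(classes.groupby("class")["length"].sum())
```

prints (seed 42):

```
core           49596
dispensable    35847
private        15404
```

i.e. 49.2% of the graph's 100.8 kb node space is core, 35.5% dispensable and
15.3% private — recovering the generator's configured 48/36/16% segment
proportions. Each individual haplotype is ~70% core because the other
species' private segments are absent from it. Running
`examples/05_ld_decay_fit.py` fits ρ = 4.96×10⁻⁴ to data generated at
ρ = 5×10⁻⁴ (0.7% off) with a half-decay distance of 4354 bp.

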