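# Methods

## Graph model and coordinates

A pangenome graph is a set of DNA segment nodes, blunt links, and haplotype
paths (oriented node walks), read and written as GFA v1 (S/L/P lines,
overlap `0M` or `*`; GFA v2 and W-lines are rejected). Path names follow the
PanSN convention `sample#haplotype#chromosome`; the scheme is a configurable
regex with three named groups because graph builders differ on this point.

Internal path coordinates are 0-based half-open; VCF output is 1-based;
GFF3 (1-based inclusive) and BED (0-based half-open) are converted on read.
A `-` step contributes the reverse complement of the node sequence to the
path, but presence computations ignore orientation: class metrics are
defined on whether a node is traversed at all. Paths may traverse a node
repeatedly; presence is boolean and length-based summaries count each
distinct node once per path. Segments absent from every P-line are excluded
from class totals and reported separately.

## Node and gene classification

With N species, species-presence of a node is true when any haplotype path
of the species traverses it. Classes: core (count = N), private (count = 1),
dispensable (otherwise); N ≥ 2 is required. Per-haplotype composition sums
distinct-node bp per class; the percentages are guaranteed to sum to 100.
Compression per chromosome is `1 − distinct_bp / Σ path lengths` (the raw
quotient is also emitted), so duplicated content reads as high compression.

Gene bodies are the full gene-feature span (introns included; an exon-only
restriction would need transcript features and is intentionally not the
default). Class fractions are bp-weighted over traversed node space within
the span — node-count weighting, available as an option, would overweight
runs of short nodes. The assignment threshold is strict: a gene is class c
iff fraction(c) > 0.8, so exactly 80% is ambiguous. Untraversed gaps shrink
all fractions and can only push genes toward ambiguous. Raising the
threshold monotonically shrinks the non-ambiguous set.

Growth curves reclassify against each species subset S: core = present in
all |S| members, private = exactly one when |S| ≥ 2. At k = 1 core and
private coincide; the convention here calls all traversed nodes core and
reports zero private — documented because plotted curves elsewhere do not
disambiguate this boundary. Exact enumeration covers all 2^N − 1 subsets
(N ≤ 20); sampled mode draws subsets uniformly per k and requires a seed.
Internally nodes are grouped by their species-presence bitmask, so a subset
evaluation costs O(#distinct masks), not O(#nodes).

## Relatedness and allele-specific nodes

Shared node space between two path sets is the summed length of distinct
nodes traversed by both; percentages are relative to each side's own
distinct-node bp, hence deliberately asymmetric (both directions and node
counts are emitted). Allele-specific nodes use the strict rule
(∩ presence over the in-group) \ (∪ presence over the out-group), applied
symmetrically; the two resulting sets are disjoint by construction.
Positional density tracks tile a path with fixed windows (last window
truncated) and count occurrence bp, so repeated traversal inside a window
counts repeatedly — the track is a positional signal, not a distinct-node
summary.

## Variant deconstruction

Deconstruction is pairwise and reference-guided rather than a full snarl
decomposition: for each alternate path, candidate anchors are same-node,
same-orientation occurrence pairs, and the anchor chain is the weighted
longest increasing subsequence over (alt order, ref order) maximizing total
anchored bp (Fenwick-tree implementation; ties prefer the leftmost reference
occurrence). Every inter-anchor gap whose sequences differ emits exactly one
record, which reproduces top-level (LV = 0) semantics: nested variation
inside a gap is flattened. Inverted shared content cannot anchor (orientation
must match), so it surfaces inside a gap and the record is flagged OTHER for
manual review.

Normalization trims the gap's common suffix then prefix (which left-aligns
the representation within the gap) and left-anchors indels with one
preceding reference base; a difference at the path start is right-anchored
with the following base instead. Types: SNP (1↔1 differing), INS
(len REF < len ALT), DEL (len REF > len ALT), MNP (equal length > 1); size
is the length difference for indels, allele length for SNP/MNP,
max(len REF, len ALT) for OTHER. Size bins default to {1, 2–10, 11–50,
51–1000, >1000} bp and are configurable.

The correctness contract is the reconstruction identity: applying the
emitted records to the reference path sequence must reproduce the alternate
path sequence byte-exactly. The test suite enforces this on >1000 random
simulated pairs, plus exact set-equality against planted truth.

Multi-haplotype merge keys sites by (pos, REF) and keeps distinct ALTs as
separate bi-allelic records. A haplotype carrying the record is genotype 1;
one whose anchor chain spans the site is 0; one not covering the site is
missing — mirroring multi-sample merge semantics, where absence of evidence
is not reference. Equal-length REF disagreement at one position indicates
graph inconsistency and raises. Site classes take the majority-bp class of
the reference nodes under the REF span (ties resolve core > dispensable >
private); pure insertions take the class of the inserted nodes. The
genome fraction covered by variants is the union of REF-span intervals over
the reference length. Effect enrichment builds one 2×2 table per effect
label (effect vs not, subset vs background), applies scipy's two-sided
Fisher exact test, Bonferroni-corrects over the label universe and flags
ratio > 1 with adjusted p < 0.05.

## LD decay and variant rate

The Hill & Weir (1988) drift–recombination sampling expectation is used for
decay fitting (the standard choice for r²-vs-distance data; the defining
publication of the approach does not restate the formula, so it is written
out in `popgen`). Note E[r²] → 5/11 at C = 0 as n → ∞ and decays to a
finite-sample floor of ≈ 1/n (not zero) as C → ∞. The fit is nonlinear
least squares in ρ with log-parameterization enforcing positivity, a fixed
default start ρ₀ = 10⁻³, and deterministic behavior given inputs; it
requires ≥ 10 pairs over ≥ 2 distinct distances. Half-decay solves
E[r²](ρd, n) = E[r²](0, n)/2 by bisection on the fitted curve ("half the
maximum" is read as half the fitted zero-distance value; an
empirical-maximum option exists), and the minimum-decay distance solves
E[r²] = 0.1, reported absent when the curve starts below the threshold.

The divergence-normalized variant rate is
`n_variants / (compared_bp × 2 × divergence_years)`; the factor 2 counts
both lineages accumulating changes since the split and can be switched off
(`per_lineage=True`) since published rates do not always state which
denominator was used.

## The synthetic generator

The generator emulates the statistical structure of a multi-species diploid
pangenome, building the graph directly so truth is exact by construction
(no alignment step, whose reimplementation is out of scope). An ancestral
chromosome is cut into segments (1–3 kb), each given a carrier species
subset: all species (core), one species (private), or a random proper subset
(dispensable). Categories are allocated greedily against bp targets, so
realized graph-space class shares track the configured proportions within
about one segment (~2% at 100 kb). Within segments, anchor blocks shared by
all carriers alternate with variant sites: SNPs and indels at species scope
(a proper species subset carries the alternative) or haplotype scope
(heterozygous single-haplotype changes). Deletions are nodes the deleted
haplotypes skip; insertions are extra nodes only the carriers traverse.
Consecutive sites are separated by ≥ 4 bp shared anchors (a `dense` mode
drops the separation for stress testing), which is what makes pairwise
deconstruction recall provably 1.0.

Defaults (9 species × 2 haplotypes, 100 kb, class shares 48/36/16%,
species-scope SNP spacing ≈ 300 bp, heterozygous SNP spacing ≈ 500 bp,
indel rates 1/2000 and 1/4000 with geometric sizes capped at 200 bp, ~40
genes of 0.8–2.4 kb per chromosome, repeat coverage probabilities
0.40/0.46/0.56 for core/dispensable/private so the private compartment is
~40% more repeat-dense than the core) are chosen to mirror the magnitudes
reported for wild-grape genomes scaled to a desk-size chromosome. Genes are
placed wholly inside single-category segments with endpoints snapped into
anchor blocks, and a placement is kept only if every carrier haplotype's
planted-class fraction exceeds 0.85, so the 0.8-threshold classifier must
recover 100% of planted classes. Repeats are planted per node with
class-dependent probability and emitted per haplotype as BED whole-node
intervals.

The optional sex-determining-region design plants two adjacent divergent
alleles carried by 11 vs 4 haplotypes. Groups are filled so at least one
species straddles them (one haplotype in each), which structurally excludes
any species-level segment or variant node from coinciding with either
group; allele carrier sets drawn at variant sites are additionally rejected
on collision. Detection of the planted sets by the strict allele-specific
rule is therefore exact, not approximate.

Pairwise variant truth is computed by an event walk over the simulator's own
site list — runs of events where two haplotypes traverse different (or no)
nodes merge into one pending difference, flushed at each co-traversed node
and normalized with the same VCF convention — a code path independent of the
GFA parser, path indexing and anchor-chain machinery it validates.

What the generator does *not* emulate: realistic TE sequences, recombination,
selection, tree-structured divergence (the species model is star-like), or
alignment artifacts of real graph construction (spurious micro-nodes,
collapsed repeats). Passing tests therefore demonstrate algorithmic
correctness on graphs with exactly known structure, not robustness to
construction noise in empirical graphs.

## Problem sizes and determinism

The test suite and the acceptance script run on 30–100 kb chromosomes with
18 haplotypes (~1.8 k nodes, ~300–1200 deconstructed pairs, 10⁴ LD pairs,
20 fit replicates), sizes at which every oracle (per-base scans, exhaustive
subset enumeration, exhaustive Fisher enumeration over all margin-≤50
tables by symmetry orbit) stays exact and fast. Every stochastic component
takes an explicit seed; the same seed reproduces byte-identical generator
output and identical downstream numbers.
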