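"""Graph-derived variants: reference-guided deconstruction and statistics.

Variant extraction converts graph topology into positional records against a
chosen reference path. The approach here is pairwise and reference-guided: a
maximal collinear chain of shared node occurrences (a weighted
longest-increasing-subsequence over the alternate path's occurrence order,
maximizing anchored bp, orientation-consistent) anchors the two paths, and
every inter-anchor gap whose sequences differ becomes exactly one top-level
variant. Nested variation inside a gap is deliberately flattened into the one
record, matching top-level (LV=0) semantics; inverted shared content never
anchors and therefore surfaces inside a gap, flagged OTHER.

Indels are left-anchored with one preceding reference base after trimming the
gap's common suffix then prefix (which also left-aligns the representation
within the gap), the usual VCF convention.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CLASSES
from .graph_io import (
    HaplotypePath,
    PangenomeGraph,
    PathIndex,
    build_path_index,
    path_sequence,
)

DEFAULT_SIZE_BINS = (1, 10, 50, 1000)


@dataclass
class VariantRecord:
    """One bi-allelic variant anchored on the reference path.

    ``pos`` is 1-based; ``ref_span`` is the 0-based half-open reference
    interval covered by ``ref_allele``; ``alt_nodes`` lists the alternate-path
    node ids inside the gap (used to class pure insertions).
    """

    chromosome: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    size: int
    ref_span: tuple[int, int] = (0, 0)
    alt_nodes: tuple[str, ...] = ()
    site_class: str | None = None
    genotypes: dict[str, str] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref_allele, self.alt_allele)


def classify_variant(
    ref_allele: str, alt_allele: str, inversion: bool = False
) -> tuple[str, int]:
    """Variant type and size from the two alleles.

    SNP: both length 1 and differing. INS: REF shorter than ALT. DEL: REF
    longer. MNP: equal length > 1. OTHER is reserved for orientation-conflict
    gaps (flattened inversions). Size is the length difference for indels and
    the allele length for SNP/MNP; for OTHER it is max(len REF, len ALT).
    """
    lr, la = len(ref_allele), len(alt_allele)
    if lr == 0 or la == 0:
        raise ValueError("empty allele after normalization")
    if inversion:
        return "OTHER", max(lr, la)
    if lr == la == 1:
        if ref_allele == alt_allele:
            raise ValueError("identical alleles are not a variant")
        return "SNP", 1
    if lr < la:
        return "INS", la - lr
    if lr > la:
        return "DEL", lr - la
    return "MNP", lr


def size_bin(size: int, bins: Sequence[int] = DEFAULT_SIZE_BINS) -> str:
    """Human-readable size bin, default {1, 2-10, 11-50, 51-1000, >1000} bp."""
    prev = 0
    for b in bins:
        if size <= b:
            return str(b) if b == prev + 1 else f"{prev + 1}-{b}"
        prev = b
    return f">{bins[-1]}"


# ---------------------------------------------------------------------------
# Anchor chain: weighted LIS over shared node occurrences
# ---------------------------------------------------------------------------


class _FenwickMax:
    """Prefix-maximum Fenwick tree storing (weight, payload)."""

    def __init__(self, n: int):
        self.n = n
        self.tree: list[tuple[int, int]] = [(0, -1)] * (n + 1)

    def update(self, i: int, value: tuple[int, int]) -> None:
        i += 1
        while i <= self.n:
            if value[0] > self.tree[i][0]:
                self.tree[i] = value
            i += i & -i

    def query(self, i: int) -> tuple[int, int]:
        """Max over positions [0, i)."""
        best = (0, -1)
        while i > 0:
            if self.tree[i][0] > best[0]:
                best = self.tree[i]
            i -= i & -i
        return best


def anchor_chain(
    ref_path: HaplotypePath,
    alt_path: HaplotypePath,
    node_lengths: dict[str, int],
) -> list[tuple[int, int]]:
    """Maximal-bp collinear chain of shared node occurrences.

    Returns (ref step index, alt step index) pairs strictly increasing on both
    sides. Only occurrences with the same orientation on both paths may
    anchor. When a shared node occurs multiple times, the chain maximizes
    total anchored bp (weighted LIS); ties prefer the leftmost reference
    occurrence.
    """
    ref_occ: dict[tuple[str, str], list[int]] = {}
    alt_nodes = {s.node_id for s in alt_path.steps}
    for i, s in enumerate(ref_path.steps):
        if s.node_id in alt_nodes:
            ref_occ.setdefault((s.node_id, s.orient), []).append(i)

    # Candidate (alt index, ref index, weight) pairs in alt order.
    pairs: list[tuple[int, int, int]] = []
    for j, s in enumerate(alt_path.steps):
        for i in ref_occ.get((s.node_id, s.orient), ()):
            pairs.append((j, i, node_lengths[s.node_id]))
    if not pairs:
        raise ValueError(
            f"unalignable paths: {ref_path.name} and {alt_path.name} share no "
            "same-orientation nodes"
        )

    # Weighted LIS on ref index, processing alt index ascending; within one
    # alt index, descend on ref index so same-j pairs cannot chain.
    pairs.sort(key=lambda t: (t[0], -t[1]))
    n_ref = len(ref_path.steps)
    fen = _FenwickMax(n_ref)
    dp = [0] * len(pairs)
    parent = [-1] * len(pairs)
    for idx, (j, i, w) in enumerate(pairs):
        best_w, best_idx = fen.query(i)  # max over ref positions < i
        dp[idx] = best_w + w
        parent[idx] = best_idx
        fen.update(i, (dp[idx], idx))

    # Best chain end; ties -> leftmost ref occurrence.
    best = max(range(len(pairs)), key=lambda t: (dp[t], -pairs[t][1]))
    chain: list[tuple[int, int]] = []
    while best != -1:
        j, i, _ = pairs[best]
        chain.append((i, j))
        best = parent[best]
    chain.reverse()
    return chain


def deconstruct_pair(
    graph: PangenomeGraph,
    ref_path: HaplotypePath,
    alt_path: HaplotypePath,
) -> list[VariantRecord]:
    """Top-level variants between one alternate path and the reference.

    Applying the emitted records to the reference sequence reconstructs the
    alternate sequence exactly (the invariant the test suite enforces).
    """
    node_len = {nid: n.length for nid, n in graph.nodes.items()}
    chain = anchor_chain(ref_path, alt_path, node_len)
    ref_idx = build_path_index(graph, ref_path)
    alt_idx = build_path_index(graph, alt_path)
    ref_seq = path_sequence(graph, ref_path)
    alt_seq = path_sequence(graph, alt_path)

    records: list[VariantRecord] = []
    ref_node_set = {s.node_id for s in ref_path.steps}

    def emit(r0: int, r1: int, a0: int, a1: int) -> None:
        """Handle the gap ref[r0:r1] vs alt[a0:a1] (path offsets)."""
        rg, ag = ref_seq[r0:r1], alt_seq[a0:a1]
        if rg == ag:
            return
        # Gap steps on the alt side, for insertion classing and inversion flag.
        gap_alt_steps = []
        if a1 > a0:
            k = bisect_right(alt_idx.offsets, a0) - 1
            while k < len(alt_path.steps) and alt_idx.offsets[k] < a1:
                if alt_idx.offsets[k] + alt_idx.lengths[k] > a0:
                    gap_alt_steps.append(k)
                k += 1
        inversion = any(alt_path.steps[k].orient == "-" for k in gap_alt_steps)
        # Trim common suffix, then common prefix (left-aligns within the gap).
        ns = 0
        while ns < min(len(rg), len(ag)) and rg[len(rg) - 1 - ns] == ag[len(ag) - 1 - ns]:
            ns += 1
        rg, ag = rg[: len(rg) - ns], ag[: len(ag) - ns]
        np_ = 0
        while np_ < min(len(rg), len(ag)) and rg[np_] == ag[np_]:
            np_ += 1
        rg, ag, r0 = rg[np_:], ag[np_:], r0 + np_
        if len(rg) == 0 or len(ag) == 0:
            if r0 > 0:  # left-anchor with the preceding reference base
                rg, ag, r0 = ref_seq[r0 - 1] + rg, ref_seq[r0 - 1] + ag, r0 - 1
            else:  # gap at path start: right-anchor with the following base
                nxt = ref_seq[r0 + len(rg)]
                rg, ag = rg + nxt, ag + nxt
        vtype, size = classify_variant(rg, ag, inversion=inversion)
        alt_nodes = tuple(
            alt_path.steps[k].node_id
            for k in gap_alt_steps
            if alt_path.steps[k].node_id not in ref_node_set
        )
        records.append(
            VariantRecord(
                chromosome=ref_path.chromosome,
                pos=r0 + 1,
                ref_allele=rg,
                alt_allele=ag,
                vtype=vtype,
                size=size,
                ref_span=(r0, r0 + len(rg)),
                alt_nodes=alt_nodes,
            )
        )

    # Leading gap, inter-anchor gaps, trailing gap.
    first_i, first_j = chain[0]
    emit(0, ref_idx.offsets[first_i], 0, alt_idx.offsets[first_j])
    for (i0, j0), (i1, j1) in zip(chain, chain[1:]):
        emit(
            ref_idx.offsets[i0] + ref_idx.lengths[i0],
            ref_idx.offsets[i1],
            alt_idx.offsets[j0] + alt_idx.lengths[j0],
            alt_idx.offsets[j1],
        )
    last_i, last_j = chain[-1]
    emit(
        ref_idx.offsets[last_i] + ref_idx.lengths[last_i],
        ref_idx.path_length,
        alt_idx.offsets[last_j] + alt_idx.lengths[last_j],
        alt_idx.path_length,
    )
    return records


def chain_ref_span(
    graph: PangenomeGraph, ref_path: HaplotypePath, alt_path: HaplotypePath
) -> tuple[int, int]:
    """Reference interval covered by the anchor chain (0-based, half-open)."""
    node_len = {nid: n.length for nid, n in graph.nodes.items()}
    chain = anchor_chain(ref_path, alt_path, node_len)
    ref_idx = build_path_index(graph, ref_path)
    first_i = chain[0][0]
    last_i = chain[-1][0]
    return ref_idx.offsets[first_i], ref_idx.offsets[last_i] + ref_idx.lengths[last_i]


def apply_variants(ref_seq: str, records: list[VariantRecord]) -> str:
    """Reconstruction oracle helper: apply records (non-overlapping) to REF."""
    records = sorted(records, key=lambda r: r.pos)
    out = []
    cursor = 0
    for r in records:
        start = r.pos - 1
        if start < cursor:
            raise ValueError(f"overlapping records at pos {r.pos}")
        if ref_seq[start : start + len(r.ref_allele)] != r.ref_allele:
            raise ValueError(f"REF mismatch at pos {r.pos}")
        out.append(ref_seq[cursor:start])
        out.append(r.alt_allele)
        cursor = start + len(r.ref_allele)
    out.append(ref_seq[cursor:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Multi-haplotype merge
# ---------------------------------------------------------------------------


def merge_and_normalize(
    per_hap: dict[str, list[VariantRecord]],
    spans: dict[str, tuple[int, int]] | None = None,
) -> list[VariantRecord]:
    """Merge per-haplotype records into one bi-allelic multi-sample site list.

    Sites are keyed by (pos, REF); distinct ALTs at a site stay separate
    bi-allelic records. A haplotype carrying the record gets genotype '1';
    one whose anchor chain spans the position gets '0'; one not covering the
    site is '.' (missing). Conflicting REF alleles of equal length at one
    position indicate graph inconsistency and raise.
    """
    by_key: dict[tuple[int, str, str], VariantRecord] = {}
    ref_at: dict[tuple[int, int], str] = {}
    haps = list(per_hap)
    for hap, records in per_hap.items():
        for r in records:
            probe = (r.pos, len(r.ref_allele))
            if probe in ref_at and ref_at[probe] != r.ref_allele:
                raise ValueError(
                    f"conflicting REF alleles at pos {r.pos}: "
                    f"{ref_at[probe]!r} vs {r.ref_allele!r}"
                )
            ref_at[probe] = r.ref_allele
            site = by_key.get(r.key)
            if site is None:
                site = VariantRecord(
                    r.chromosome, r.pos, r.ref_allele, r.alt_allele,
                    r.vtype, r.size, r.ref_span, r.alt_nodes,
                )
                by_key[r.key] = site
            site.genotypes[hap] = "1"
    for site in by_key.values():
        for hap in haps:
            if hap in site.genotypes:
                continue
            if spans is not None:
                s, e = spans.get(hap, (0, 0))
                covered = s <= site.pos - 1 and site.pos - 1 + len(site.ref_allele) <= e
            else:
                covered = True
            site.genotypes[hap] = "0" if covered else "."
    return sorted(by_key.values(), key=lambda r: (r.chromosome, r.pos, r.alt_allele))


def deconstruct_all(
    graph: PangenomeGraph,
    ref_path: HaplotypePath,
    alt_paths: list[HaplotypePath] | None = None,
) -> list[VariantRecord]:
    """Deconstruct every alternate path against one reference and merge."""
    if alt_paths is None:
        alt_paths = [
            p
            for p in graph.paths
            if p.name != ref_path.name and p.chromosome == ref_path.chromosome
        ]
    per_hap, spans = {}, {}
    for alt in alt_paths:
        per_hap[alt.name] = deconstruct_pair(graph, ref_path, alt)
        spans[alt.name] = chain_ref_span(graph, ref_path, alt)
    return merge_and_normalize(per_hap, spans)


def assign_site_class(
    record: VariantRecord,
    graph: PangenomeGraph,
    classes: pd.DataFrame,
    ref_index: PathIndex,
) -> str:
    """Pangenome class of the variant site.

    Majority-bp class of the reference nodes under the REF span; for pure
    insertions (1-bp anchored REF with inserted alt nodes) the class of the
    inserted nodes. Ties resolve in core > dispensable > private order.
    """
    class_by_node = dict(zip(classes["node_id"], classes["class"]))
    per_class = dict.fromkeys(CLASSES, 0)
    if record.vtype == "INS" and len(record.ref_allele) == 1 and record.alt_nodes:
        for nid in record.alt_nodes:
            cls = class_by_node.get(nid)
            if cls is not None:
                per_class[cls] += graph.nodes[nid].length
    else:
        start, end = record.ref_span
        for step_i, ov in ref_index.steps_overlapping(start, max(end, start + 1)):
            nid = ref_index.path.steps[step_i].node_id
            cls = class_by_node.get(nid)
            if cls is not None:
                per_class[cls] += ov
    best = max(CLASSES, key=lambda c: per_class[c])
    record.site_class = best
    return best


def genome_fraction_covered(
    records: list[VariantRecord], ref_length: int
) -> float:
    """Fraction of the reference covered by the union of variant REF spans."""
    ivals = sorted(
        (r.pos - 1, r.pos - 1 + len(r.ref_allele)) for r in records
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in ivals:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / ref_length


# ---------------------------------------------------------------------------
# Effect enrichment
# ---------------------------------------------------------------------------


def impact_enrichment(
    subset_counts: dict[str, int],
    background_counts: dict[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-effect enrichment of a variant subset against the background.

    For each effect label: 2x2 table (effect vs not, subset vs background),
    two-sided Fisher exact p, Bonferroni correction over the m labels,
    enrichment ratio = subset proportion / background proportion. An effect
    is significant when ratio > 1 and adjusted p < ``alpha``.
    """
    effects = sorted(set(subset_counts) | set(background_counts))
    sub_total = sum(subset_counts.values())
    bg_total = sum(background_counts.values())
    if bg_total == 0:
        raise ValueError("background has zero total counts")
    m = len(effects)
    rows = []
    for e in effects:
        a = subset_counts.get(e, 0)
        c = background_counts.get(e, 0)
        table = [[a, sub_total - a], [c, bg_total - c]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        ratio = (
            (a / sub_total) / (c / bg_total)
            if sub_total and c
            else float("inf") if a else 0.0
        )
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "effect": e,
                "subset_count": a,
                "background_count": c,
                "enrichment": ratio,
                "p_value": p,
                "p_adjusted": p_adj,
                "significant": bool(ratio > 1 and p_adj < alpha),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF output
# ---------------------------------------------------------------------------


def write_vcf(
    records: list[VariantRecord],
    contigs: dict[str, int],
    stream: TextIO,
    sample_order: list[str] | None = None,
) -> None:
    """Write merged records as VCF 4.2 with per-haplotype sample columns."""
    keys = [(r.chromosome, r.pos) for r in records]
    if keys != sorted(keys):
        raise ValueError("records must be sorted by (chromosome, pos)")
    if sample_order is None:
        sample_order = sorted({h for r in records for h in r.genotypes})
    stream.write("##fileformat=VCFv4.2\n")
    for name, length in contigs.items():
        stream.write(f"##contig=<ID={name},length={length}>\n")
    stream.write('##INFO=<ID=VTYPE,Number=1,Type=String,Description="Variant type">\n')
    stream.write('##INFO=<ID=SIZE,Number=1,Type=Integer,Description="Variant size (bp)">\n')
    stream.write(
        '##INFO=<ID=PCLASS,Number=1,Type=String,Description="Pangenome class of the site">\n'
    )
    stream.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    stream.write("\t".join(cols + sample_order) + "\n")
    for r in records:
        info = f"VTYPE={r.vtype};SIZE={r.size}"
        if r.site_class:
            info += f";PCLASS={r.site_class}"
        gts = [r.genotypes.get(h, ".") for h in sample_order]
        stream.write(
            f"{r.chromosome}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}"
            f"\t.\t.\t{info}\tGT\t" + "\t".join(gts) + "\n"
        )


def read_vcf(path: str) -> list[VariantRecord]:
    """Read a VCF (via pysam) back into VariantRecord form."""
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            gts = {}
            for s in samples:
                gt = rec.samples[s].get("GT", (None,))
                allele = gt[0] if gt else None
                gts[s] = "." if allele is None else str(allele)
            out.append(
                VariantRecord(
                    chromosome=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    vtype=rec.info.get("VTYPE", ""),
                    size=int(rec.info.get("SIZE", 0)),
                    site_class=rec.info.get("PCLASS"),
                    genotypes=gts,
                )
            )
    return out
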