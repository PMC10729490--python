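"""Gene-level pangenome: projection of gene models onto graph node classes.

A gene is assigned to the core/dispensable/private pangenome when more than
80% (strictly) of its body, in bp of traversed node space, falls into that
class; otherwise it is *ambiguous*. Gene bodies are the full gene-feature span
(introns included) by default; fractions are bp-weighted so that many short
nodes do not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import pandas as pd

from .classify import CLASSES, PresenceMatrix, _mask_groups, class_of_count
from .graph_io import HaplotypePath, PangenomeGraph, build_path_index


@dataclass
class GeneRecord:
    """A gene feature anchored on one haplotype assembly.

    start/end are 1-based inclusive (GFF3 convention) on the assembly, which
    is coordinate-identical to the matching graph path.
    """

    gene_id: str
    sample: str
    haplotype: int
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    @property
    def span0(self) -> tuple[int, int]:
        """0-based half-open interval on the path."""
        return self.start - 1, self.end


def load_genes(
    stream: TextIO | Iterable[str],
    graph: PangenomeGraph,
    seqid_map: dict[str, tuple[str, int, str]],
    feature_type: str = "gene",
) -> list[GeneRecord]:
    """Extract gene features from a GFF3 stream and validate coordinates.

    ``seqid_map`` maps each GFF3 seqid to (sample, haplotype, chromosome) of
    the corresponding graph path. Rows whose type differs from
    ``feature_type`` are skipped; an unmapped seqid or a gene extending past
    its path is an error.
    """
    path_len: dict[tuple[str, int, str], int] = {}
    for p in graph.paths:
        path_len[(p.sample, p.haplotype, p.chromosome)] = graph.path_length(p)

    genes: list[GeneRecord] = []
    unmatched: set[str] = set()
    for raw in stream:
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seqid, _, ftype, start, end, _, strand, _, attrs = fields[:9]
        if ftype != feature_type:
            continue
        if seqid not in seqid_map:
            unmatched.add(seqid)
            continue
        sample, hap, chrom = seqid_map[seqid]
        gene_id = None
        for item in attrs.split(";"):
            if item.startswith("ID="):
                gene_id = item[3:]
                break
        if gene_id is None:
            raise ValueError(f"gene feature without ID attribute: {line!r}")
        start_i, end_i = int(start), int(end)
        key = (sample, hap, chrom)
        if key not in path_len:
            raise ValueError(f"no graph path for seqid {seqid!r} -> {key}")
        if start_i < 1 or end_i > path_len[key] or start_i > end_i:
            raise ValueError(
                f"gene {gene_id}: range {start_i}..{end_i} outside path "
                f"length {path_len[key]} for {seqid}"
            )
        genes.append(GeneRecord(gene_id, sample, hap, chrom, start_i, end_i, strand))
    if unmatched:
        raise ValueError(
            "GFF3 seqids with no mapping to a graph path: "
            + ", ".join(sorted(unmatched))
        )
    return genes


def _gene_class_bp(
    gene: GeneRecord,
    graph: PangenomeGraph,
    path: HaplotypePath,
    class_by_node: dict[str, str],
    weight: str,
) -> tuple[dict[str, float], float]:
    """Per-class weight within the gene body and the traversed total."""
    index = build_path_index(graph, path)
    start, end = gene.span0
    per_class = dict.fromkeys(CLASSES, 0.0)
    for step_i, ov in index.steps_overlapping(start, end):
        nid = path.steps[step_i].node_id
        cls = class_by_node.get(nid)
        if cls is None:
            continue
        per_class[cls] += ov if weight == "bp" else 1.0
    return per_class, sum(per_class.values())


def classify_genes(
    genes: list[GeneRecord],
    graph: PangenomeGraph,
    classes: pd.DataFrame,
    threshold: float = 0.8,
    weight: str = "bp",
) -> pd.DataFrame:
    """Classify genes by node-class composition of their bodies.

    A gene is class c iff fraction(c) > threshold (strict: exactly 80% is
    ambiguous). Fractions are relative to the full gene span, so untraversed
    gaps shrink all three fractions. ``weight='count'`` switches to node-count
    weighting.
    """
    if weight not in ("bp", "count"):
        raise ValueError("weight must be 'bp' or 'count'")
    class_by_node = dict(zip(classes["node_id"], classes["class"]))
    paths = {(p.sample, p.haplotype, p.chromosome): p for p in graph.paths}
    rows = []
    for g in genes:
        path = paths[(g.sample, g.haplotype, g.chromosome)]
        per_class, traversed = _gene_class_bp(g, graph, path, class_by_node, weight)
        span = g.end - g.start + 1 if weight == "bp" else traversed
        denom = span if weight == "bp" else (traversed or 1.0)
        fracs = {c: per_class[c] / denom if denom else 0.0 for c in CLASSES}
        assigned = "ambiguous"
        for c in CLASSES:
            if fracs[c] > threshold:
                assigned = c
                break
        rows.append(
            {
                "gene_id": g.gene_id,
                "sample": g.sample,
                "haplotype": g.haplotype,
                "core_frac": fracs["core"],
                "dispensable_frac": fracs["dispensable"],
                "private_frac": fracs["private"],
                "traversed": traversed > 0,
                "class": assigned,
            }
        )
    return pd.DataFrame(rows)


def gene_growth_curves(
    genes: list[GeneRecord],
    graph: PangenomeGraph,
    presence: PresenceMatrix,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Gene-count growth curve over species subsets.

    For every non-empty subset S of species, genes of samples in S are
    re-classified against subset-relative node classes (core = all of S,
    private = exactly one when |S| >= 2) and counted per class. Exact
    enumeration; requires few species.
    """
    samples = presence.samples
    n = len(samples)
    if n > 20:
        raise ValueError("exact enumeration limited to N <= 20 species")
    sample_bit = {s: i for i, s in enumerate(samples)}
    paths = {(p.sample, p.haplotype, p.chromosome): p for p in graph.paths}

    # Per gene: bp of the body per species-presence bitmask (computed once).
    gene_mask_bp: list[tuple[str, str, dict[int, int], int]] = []
    for g in genes:
        path = paths[(g.sample, g.haplotype, g.chromosome)]
        index = build_path_index(graph, path)
        start, end = g.span0
        by_mask: dict[int, int] = {}
        for step_i, ov in index.steps_overlapping(start, end):
            m = presence.masks[path.steps[step_i].node_id]
            if m:
                by_mask[m] = by_mask.get(m, 0) + ov
        gene_mask_bp.append((g.gene_id, g.sample, by_mask, g.end - g.start + 1))

    rows = []
    for subset_mask in range(1, 1 << n):
        members = [samples[i] for i in range(n) if subset_mask >> i & 1]
        k = len(members)
        member_set = set(members)
        counts = {c: 0 for c in (*CLASSES, "ambiguous")}
        for gene_id, sample, by_mask, span in gene_mask_bp:
            if sample not in member_set:
                continue
            per_class = dict.fromkeys(CLASSES, 0)
            for m, bp in by_mask.items():
                cnt = (m & subset_mask).bit_count()
                if cnt == 0:
                    continue
                if cnt == k:
                    per_class["core"] += bp
                elif cnt == 1 and k >= 2:
                    per_class["private"] += bp
                else:
                    per_class["dispensable"] += bp
            assigned = "ambiguous"
            for c in CLASSES:
                if per_class[c] / span > threshold:
                    assigned = c
                    break
            counts[assigned] += 1
        label = ",".join(members)
        for c, cnt in counts.items():
            rows.append({"k": k, "subset": label, "class": c, "genes": cnt})
    return pd.DataFrame(rows)


def class_agreement(
    a: pd.DataFrame, b: pd.DataFrame, exclude_ambiguous: bool = True
) -> pd.DataFrame:
    """Agreement between two gene classifications on shared gene ids.

    Returns overall and per-class (of table ``a``) agreement percentages.
    Ambiguous genes are excluded by default, mirroring their exclusion from
    downstream analyses.
    """
    ta = a.set_index("gene_id")["class"]
    tb = b.set_index("gene_id")["class"]
    shared = ta.index.intersection(tb.index)
    if len(shared) == 0:
        raise ValueError("no shared gene ids between classifications")
    ta, tb = ta.loc[shared], tb.loc[shared]
    if exclude_ambiguous:
        keep = (ta != "ambiguous") & (tb != "ambiguous")
        ta, tb = ta[keep], tb[keep]
    match = ta == tb
    rows = [
        {
            "scope": "overall",
            "n_genes": len(ta),
            "agreement_pct": 100.0 * match.mean() if len(ta) else float("nan"),
        }
    ]
    for c in CLASSES:
        sel = ta == c
        rows.append(
            {
                "scope": c,
                "n_genes": int(sel.sum()),
                "agreement_pct": (
                    100.0 * match[sel].mean() if sel.any() else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
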