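"""Pangenome classes, composition, compression and growth curves.

Nodes are classified by the number of *species* whose haplotype paths traverse
them: the **core** genome (present in all species), the **dispensable** genome
(more than one species but not all) and the **private** genome (exactly one
species). Presence is boolean at the species level — either haplotype of a
diploid sample suffices — and ignores traversal orientation and multiplicity,
so all length-based summaries are over distinct ("unique") nodes.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_io import HaplotypePath, PangenomeGraph, build_path_index

CLASSES = ("core", "dispensable", "private")


@dataclass
class PresenceMatrix:
    """Boolean node x species presence, plus a compact bitmask grouping.

    ``masks[node_id]`` is an integer whose bit *s* is set iff any haplotype of
    sample ``samples[s]`` traverses the node; the matrix view is derived from
    it. Nodes declared in the GFA but traversed by no path keep all-false rows
    and are listed in ``untraversed``.
    """

    node_ids: list[str]
    samples: list[str]
    masks: dict[str, int]
    untraversed: list[str] = field(default_factory=list)

    @property
    def presence(self) -> np.ndarray:
        mat = np.zeros((len(self.node_ids), len(self.samples)), dtype=bool)
        for i, nid in enumerate(self.node_ids):
            m = self.masks[nid]
            for s in range(len(self.samples)):
                if m >> s & 1:
                    mat[i, s] = True
        return mat


def presence_matrix(graph: PangenomeGraph) -> PresenceMatrix:
    """Species-level presence of every node declared in the graph."""
    if not graph.paths:
        raise ValueError("graph has no paths; presence undefined")
    samples = graph.samples()
    sample_bit = {s: i for i, s in enumerate(samples)}
    masks = {nid: 0 for nid in graph.nodes}
    for p in graph.paths:
        bit = 1 << sample_bit[p.sample]
        for step in p.steps:
            masks[step.node_id] |= bit
    untraversed = [nid for nid, m in masks.items() if m == 0]
    return PresenceMatrix(list(graph.nodes), samples, masks, untraversed)


def class_of_count(species_count: int, n_species: int) -> str:
    if species_count == n_species:
        return "core"
    if species_count == 1:
        return "private"
    return "dispensable"


def classify_nodes(presence: PresenceMatrix, graph: PangenomeGraph) -> pd.DataFrame:
    """Per-node class table (node_id, species_count, class, length).

    Untraversed nodes are excluded; they remain listed on the presence matrix.
    Requires at least two species, otherwise the three classes collapse.
    """
    n = len(presence.samples)
    if n < 2:
        raise ValueError(f"need >=2 species to classify nodes, got {n}")
    rows = []
    for nid in presence.node_ids:
        m = presence.masks[nid]
        if m == 0:
            continue
        cnt = m.bit_count()
        rows.append((nid, cnt, class_of_count(cnt, n), graph.nodes[nid].length))
    return pd.DataFrame(rows, columns=["node_id", "species_count", "class", "length"])


def haplotype_composition(
    graph: PangenomeGraph, classes: pd.DataFrame
) -> pd.DataFrame:
    """Per-haplotype-path bp and percentage of each pangenome class.

    bp per class is the summed length of *distinct* nodes the path traverses,
    grouped by class; percentages are relative to the three-class total.
    """
    class_by_node = dict(zip(classes["node_id"], classes["class"]))
    len_by_node = dict(zip(classes["node_id"], classes["length"]))
    rows = []
    for p in graph.paths:
        bp = dict.fromkeys(CLASSES, 0)
        for nid in {s.node_id for s in p.steps}:
            cls = class_by_node.get(nid)
            if cls is not None:
                bp[cls] += len_by_node[nid]
        total = sum(bp.values())
        row = {"path": p.name, "sample": p.sample, "haplotype": p.haplotype}
        for c in CLASSES:
            row[f"{c}_bp"] = bp[c]
            row[f"{c}_pct"] = 100.0 * bp[c] / total if total else 0.0
        row["total_bp"] = total
        rows.append(row)
    return pd.DataFrame(rows)


def compression_ratio(graph: PangenomeGraph) -> pd.DataFrame:
    """Per-chromosome graph compression.

    For each chromosome group, ``ratio = 1 - distinct_bp / input_bp`` where
    ``distinct_bp`` is the summed length of distinct nodes traversed by the
    group's paths and ``input_bp`` the sum of the haplotype path lengths.
    The raw quotient is also emitted. High values mean high compression:
    eighteen identical haplotypes give 1 - 1/18.
    """
    groups: dict[str, list[HaplotypePath]] = {}
    for p in graph.paths:
        groups.setdefault(p.chromosome, []).append(p)
    rows = []
    for chrom, paths in groups.items():
        if not paths:
            raise ValueError(f"chromosome group {chrom!r} is empty")
        nodes: set[str] = set()
        input_bp = 0
        for p in paths:
            nodes.update(s.node_id for s in p.steps)
            input_bp += graph.path_length(p)
        distinct_bp = sum(graph.nodes[n].length for n in nodes)
        quotient = distinct_bp / input_bp
        rows.append(
            {
                "chromosome": chrom,
                "n_paths": len(paths),
                "input_bp": input_bp,
                "graph_bp": distinct_bp,
                "quotient": quotient,
                "ratio": 1.0 - quotient,
            }
        )
    return pd.DataFrame(rows)


def _mask_groups(presence: PresenceMatrix, graph: PangenomeGraph) -> dict[int, int]:
    """Total node bp per distinct species-presence bitmask (traversed only)."""
    groups: dict[int, int] = {}
    for nid, m in presence.masks.items():
        if m:
            groups[m] = groups.get(m, 0) + graph.nodes[nid].length
    return groups


def _subset_class_totals(
    mask_groups: dict[int, int], subset_mask: int, k: int
) -> dict[str, int]:
    """Per-class unique-node bp when only species in ``subset_mask`` are kept.

    Relative to a subset of size k: core = present in all k, private = exactly
    one (only when k >= 2; at k = 1 every traversed node is core), dispensable
    otherwise.
    """
    totals = dict.fromkeys(CLASSES, 0)
    for m, bp in mask_groups.items():
        cnt = (m & subset_mask).bit_count()
        if cnt == 0:
            continue
        if cnt == k:
            totals["core"] += bp
        elif cnt == 1 and k >= 2:
            totals["private"] += bp
        else:
            totals["dispensable"] += bp
    return totals


def growth_curves(
    graph: PangenomeGraph,
    presence: PresenceMatrix | None = None,
    enumeration: str = "exact",
    k_draws: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pangenome growth: per-class unique-node bp for species subsets.

    With ``enumeration='exact'`` every non-empty subset of the N species is
    evaluated (requires N <= 20); with ``'sampled'`` ``k_draws`` subsets are
    drawn uniformly per subset size k (seed mandatory). Output rows carry
    (k, subset label, class, bp).
    """
    presence = presence or presence_matrix(graph)
    samples = presence.samples
    n = len(samples)
    mg = _mask_groups(presence, graph)

    def subset_rows(mask: int, draw: int) -> list[dict]:
        members = [samples[i] for i in range(n) if mask >> i & 1]
        k = len(members)
        totals = _subset_class_totals(mg, mask, k)
        label = ",".join(members)
        return [
            {"k": k, "draw": draw, "subset": label, "class": c, "bp": totals[c]}
            for c in CLASSES
        ]

    rows: list[dict] = []
    if enumeration == "exact":
        if n > 20:
            raise ValueError("exact enumeration limited to N <= 20 species")
        for mask in range(1, 1 << n):
            rows.extend(subset_rows(mask, mask))
    elif enumeration == "sampled":
        if seed is None:
            raise ValueError("sampled enumeration requires a seed")
        rng = random.Random(seed)
        draw = 0
        for k in range(1, n + 1):
            for _ in range(k_draws):
                idx = rng.sample(range(n), k)
                mask = sum(1 << i for i in idx)
                rows.extend(subset_rows(mask, draw))
                draw += 1
    else:
        raise ValueError(f"unknown enumeration mode {enumeration!r}")
    return pd.DataFrame(rows)


def project_intervals_to_nodes(
    graph: PangenomeGraph,
    path: HaplotypePath,
    intervals: list[tuple[int, int, str]],
) -> pd.DataFrame:
    """Project labeled path intervals into node space.

    ``intervals`` are (start, end, label) with 0-based half-open coordinates on
    the path. Overlap bp is computed per node *occurrence* and aggregated per
    (node, label); a node traversed twice under one interval accumulates both
    occurrences.
    """
    index = build_path_index(graph, path)
    acc: dict[tuple[str, str], int] = {}
    for start, end, label in intervals:
        if start < 0 or end > index.path_length or start >= end:
            raise IndexError(
                f"interval [{start}, {end}) with label {label!r} outside "
                f"[0, {index.path_length}) on {path.name}"
            )
        for step_i, ov in index.steps_overlapping(start, end):
            nid = path.steps[step_i].node_id
            key = (nid, label)
            acc[key] = acc.get(key, 0) + ov
    rows = [
        {"node_id": nid, "label": label, "overlap_bp": bp}
        for (nid, label), bp in acc.items()
    ]
    return pd.DataFrame(rows, columns=["node_id", "label", "overlap_bp"])


def annotation_density_by_class(
    overlaps: pd.DataFrame,
    classes: pd.DataFrame,
    node_universe: set[str] | None = None,
) -> pd.DataFrame:
    """Annotated-bp density per pangenome class, plus per-label shares.

    Density for class c = (overlap bp on class-c nodes) / (total bp of class-c
    nodes in ``node_universe``, default: all classified nodes). Per-node
    overlap is capped at the node length so repeated traversals cannot push a
    density above 1 in distinct-node space.
    """
    cls = classes.set_index("node_id")
    if node_universe is not None:
        cls = cls.loc[cls.index.intersection(node_universe)]
    denom = cls.groupby("class")["length"].sum()

    rows = []
    if len(overlaps):
        ov = overlaps[overlaps["node_id"].isin(cls.index)].copy()
        per_node = ov.groupby(["node_id", "label"])["overlap_bp"].sum().reset_index()
        per_node["overlap_bp"] = np.minimum(
            per_node["overlap_bp"],
            cls.loc[per_node["node_id"], "length"].to_numpy(),
        )
        per_node["class"] = cls.loc[per_node["node_id"], "class"].to_numpy()
    else:
        per_node = pd.DataFrame(columns=["node_id", "label", "overlap_bp", "class"])
    for c in CLASSES:
        class_bp = int(denom.get(c, 0))
        sub = per_node[per_node["class"] == c]
        ann = int(sub["overlap_bp"].sum())
        rows.append(
            {
                "class": c,
                "class_bp": class_bp,
                "annotated_bp": ann,
                "density": ann / class_bp if class_bp else 0.0,
            }
        )
    density = pd.DataFrame(rows)

    if len(per_node):
        shares = (
            per_node.groupby(["class", "label"])["overlap_bp"].sum().reset_index()
        )
        shares["share"] = shares.groupby("class")["overlap_bp"].transform(
            lambda x: x / x.sum()
        )
    else:
        shares = pd.DataFrame(columns=["class", "label", "overlap_bp", "share"])
    density.attrs["label_shares"] = shares
    return density
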