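"""Relatedness between haplotype path sets via shared node space.

Two genomes that descend from (or hybridize between) related species traverse
many of the same graph nodes; the total length of the nodes they share is a
direct relatedness metric that needs no alignment. Percentages are reported
relative to each side's own distinct-node bp, so the matrix of percentages is
asymmetric even though the shared bp itself is symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .graph_io import HaplotypePath, PangenomeGraph, build_path_index


def _distinct_nodes(paths: list[HaplotypePath]) -> set[str]:
    out: set[str] = set()
    for p in paths:
        out.update(s.node_id for s in p.steps)
    return out


@dataclass
class SharedSpaceRecord:
    set_a: str
    set_b: str
    shared_bp: int
    shared_nodes: int
    pct_of_a: float
    pct_of_b: float


def shared_node_space(
    graph: PangenomeGraph,
    set_a: list[HaplotypePath],
    set_b: list[HaplotypePath],
    label_a: str = "A",
    label_b: str = "B",
) -> SharedSpaceRecord:
    """Shared node space between two path sets, in bp and node counts."""
    if not set_a or not set_b:
        raise ValueError("both path sets must be non-empty")
    nodes_a = _distinct_nodes(set_a)
    nodes_b = _distinct_nodes(set_b)
    shared = nodes_a & nodes_b
    bp = lambda ns: sum(graph.nodes[n].length for n in ns)  # noqa: E731
    shared_bp = bp(shared)
    return SharedSpaceRecord(
        set_a=label_a,
        set_b=label_b,
        shared_bp=shared_bp,
        shared_nodes=len(shared),
        pct_of_a=100.0 * shared_bp / bp(nodes_a) if nodes_a else 0.0,
        pct_of_b=100.0 * shared_bp / bp(nodes_b) if nodes_b else 0.0,
    )


def shared_space_matrix(
    graph: PangenomeGraph, sets: dict[str, list[HaplotypePath]]
) -> pd.DataFrame:
    """All pairwise shared-space records (chord-diagram input)."""
    labels = list(sets)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            r = shared_node_space(graph, sets[a], sets[b], a, b)
            rows.append(vars(r))
    return pd.DataFrame(rows)


@dataclass
class AlleleSpecificNodeSet:
    """Nodes present in every haplotype of one group, absent from the other."""

    group: str
    node_ids: set[str]
    total_bp: int


def allele_specific_nodes(
    graph: PangenomeGraph,
    group_a: list[HaplotypePath],
    group_b: list[HaplotypePath],
    label_a: str = "A",
    label_b: str = "B",
) -> tuple[AlleleSpecificNodeSet, AlleleSpecificNodeSet]:
    """Group-specific nodes under the strict intersection/exclusion rule.

    A node is A-specific iff it is traversed by *all* haplotypes of group A
    and by *none* of group B (and symmetrically for B). This is the criterion
    used to isolate the female/male alleles of a structurally divergent locus
    such as the grape sex-determining region.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    names_a = {p.name for p in group_a}
    if names_a & {p.name for p in group_b}:
        raise ValueError("groups share haplotype paths; they must be disjoint")

    def specific(ingroup: list[HaplotypePath], outgroup: list[HaplotypePath]) -> set[str]:
        inter = set(s.node_id for s in ingroup[0].steps)
        for p in ingroup[1:]:
            inter &= {s.node_id for s in p.steps}
        union_out = _distinct_nodes(outgroup)
        return inter - union_out

    a_nodes = specific(group_a, group_b)
    b_nodes = specific(group_b, group_a)
    bp = lambda ns: sum(graph.nodes[n].length for n in ns)  # noqa: E731
    return (
        AlleleSpecificNodeSet(label_a, a_nodes, bp(a_nodes)),
        AlleleSpecificNodeSet(label_b, b_nodes, bp(b_nodes)),
    )


def node_density_track(
    graph: PangenomeGraph,
    path: HaplotypePath,
    node_set: set[str],
    window_bp: int,
) -> pd.DataFrame:
    """Occurrence-bp density of a node set along a path, in tiling windows.

    Windows tile [0, path length) with the last window truncated; density is
    member-node occurrence bp in the window divided by the window's size, so a
    node traversed twice inside a window counts twice (the track is a
    positional signal, not a distinct-node summary).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be >= 1")
    index = build_path_index(graph, path)
    total = index.path_length
    covered = [0] * ((total + window_bp - 1) // window_bp)
    for i, step in enumerate(path.steps):
        if step.node_id not in node_set:
            continue
        start = index.offsets[i]
        end = start + index.lengths[i]
        w = start // window_bp
        pos = start
        while pos < end:
            w_end = min((w + 1) * window_bp, total)
            covered[w] += min(end, w_end) - pos
            pos = w_end
            w += 1
    rows = []
    for w, bp in enumerate(covered):
        w_start = w * window_bp
        w_end = min(w_start + window_bp, total)
        rows.append(
            {
                "start": w_start,
                "end": w_end,
                "density": bp / (w_end - w_start),
            }
        )
    return pd.DataFrame(rows)


def write_bedgraph(track: pd.DataFrame, chrom: str, stream) -> None:
    for row in track.itertuples():
        stream.write(f"{chrom}\t{row.start}\t{row.end}\t{row.density:.6g}\n")
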