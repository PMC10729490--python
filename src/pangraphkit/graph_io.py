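"""Read, index and write pangenome graphs in GFA v1.

A pangenome graph stores genomic sequence as *nodes* (segments, possibly a
single base pair) and each input haplotype chromosome as a *path*: an ordered,
oriented walk through the nodes. Everything downstream — pangenome classes,
relatedness, variant deconstruction — operates on the containers defined here.

Only blunt-ended GFA v1 graphs are accepted (S/L/P lines, overlap ``0M`` or
``*``), the dialect produced by seqwish/smoothxg. GFA v2 and W-lines are
rejected with a clear error.
"""

from __future__ import annotations

import io
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default PanSN-style path-name scheme: sample#haplotype#chromosome.
DEFAULT_PATH_SCHEME = re.compile(
    r"^(?P<sample>[^#]+)#(?P<haplotype>\d+)#(?P<chromosome>[^#]+)$"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N} (case kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GFAParseError(ValueError):
    """Malformed GFA input; carries the offending line number."""


@dataclass(frozen=True)
class SegmentNode:
    """A graph node: a DNA segment of at least one base."""

    node_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"node {self.node_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Link:
    """A GFA L-line: directed edge between oriented node ends."""

    from_node: str
    from_orient: str
    to_node: str
    to_orient: str
    overlap: str = "0M"


@dataclass(frozen=True)
class PathStep:
    """One oriented node traversal within a path."""

    node_id: str
    orient: str  # '+' or '-'


@dataclass
class HaplotypePath:
    """An ordered walk spelling one haplotype chromosome.

    ``sample`` is the species/accession label, ``haplotype`` the 1-based
    haplotype index within the (diploid) sample.
    """

    name: str
    sample: str
    haplotype: int
    chromosome: str
    steps: list[PathStep]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError(f"path {self.name}: no steps")


def parse_path_name(
    name: str, scheme: re.Pattern | str = DEFAULT_PATH_SCHEME
) -> tuple[str, int, str]:
    """Split a path name into (sample, haplotype, chromosome).

    The scheme is a regex with named groups ``sample``, ``haplotype`` and
    ``chromosome``; the default is the '#'-delimited PanSN convention,
    e.g. ``Vriparia#2#chr19`` -> ("Vriparia", 2, "chr19").
    """
    if isinstance(scheme, str):
        scheme = re.compile(scheme)
    m = scheme.match(name)
    if m is None:
        raise ValueError(
            f"path name {name!r} does not match scheme {scheme.pattern!r} "
            "(expected sample#haplotype#chromosome)"
        )
    return m.group("sample"), int(m.group("haplotype")), m.group("chromosome")


@dataclass
class PangenomeGraph:
    """Nodes, links and haplotype paths of one pangenome graph."""

    nodes: dict[str, SegmentNode] = field(default_factory=dict)
    links: list[Link] = field(default_factory=list)
    paths: list[HaplotypePath] = field(default_factory=list)

    # -- basic queries -------------------------------------------------
    def node_length(self, node_id: str) -> int:
        return self.nodes[node_id].length

    def path_length(self, path: HaplotypePath) -> int:
        return sum(self.nodes[s.node_id].length for s in path.steps)

    def path_by_name(self, name: str) -> HaplotypePath:
        for p in self.paths:
            if p.name == name:
                return p
        raise KeyError(f"no path named {name!r}")

    def samples(self) -> list[str]:
        """Distinct sample labels in path order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.paths:
            seen.setdefault(p.sample, None)
        return list(seen)

    def total_node_length(self) -> int:
        return sum(n.length for n in self.nodes.values())

    def traversed_nodes(self) -> set[str]:
        out: set[str] = set()
        for p in self.paths:
            out.update(s.node_id for s in p.steps)
        return out

    def validate(self) -> None:
        for link in self.links:
            for nid in (link.from_node, link.to_node):
                if nid not in self.nodes:
                    raise ValueError(f"link endpoint {nid!r} not a segment")
        for p in self.paths:
            for s in p.steps:
                if s.node_id not in self.nodes:
                    raise ValueError(
                        f"path {p.name}: step references unknown segment {s.node_id!r}"
                    )


def parse_gfa(
    stream: TextIO | str | Iterable[str],
    path_scheme: re.Pattern | str = DEFAULT_PATH_SCHEME,
) -> PangenomeGraph:
    """Parse a GFA v1 text stream into a :class:`PangenomeGraph`.

    S, L and P lines are kept; H lines and unknown record types are skipped
    with a logged warning. P-line names must parse under ``path_scheme``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = PangenomeGraph()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            for f in fields[1:]:
                if f.startswith("VN:Z:") and not f[5:].startswith("1"):
                    raise GFAParseError(
                        f"line {lineno}: GFA version {f[5:]} unsupported (v1 only)"
                    )
            continue
        if tag == "S":
            if len(fields) < 3 or not fields[1] or not fields[2] or fields[2] == "*":
                raise GFAParseError(f"line {lineno}: malformed S-line")
            nid, seq = fields[1], fields[2]
            if nid in graph.nodes:
                raise GFAParseError(f"line {lineno}: duplicate segment id {nid!r}")
            graph.nodes[nid] = SegmentNode(nid, seq)
        elif tag == "L":
            if len(fields) < 6:
                raise GFAParseError(f"line {lineno}: malformed L-line")
            overlap = fields[5]
            if overlap not in ("0M", "*"):
                raise GFAParseError(
                    f"line {lineno}: non-blunt overlap {overlap!r} unsupported"
                )
            graph.links.append(Link(fields[1], fields[2], fields[3], fields[4], "0M"))
        elif tag == "P":
            if len(fields) < 3:
                raise GFAParseError(f"line {lineno}: malformed P-line")
            name = fields[1]
            steps = []
            for item in fields[2].split(","):
                if len(item) < 2 or item[-1] not in "+-":
                    raise GFAParseError(
                        f"line {lineno}: malformed path step {item!r}"
                    )
                nid, orient = item[:-1], item[-1]
                if nid not in graph.nodes:
                    raise GFAParseError(
                        f"line {lineno}: path {name!r} references unknown "
                        f"segment {nid!r}"
                    )
                steps.append(PathStep(nid, orient))
            sample, hap, chrom = parse_path_name(name, path_scheme)
            graph.paths.append(HaplotypePath(name, sample, hap, chrom, steps))
        elif tag == "W":
            raise GFAParseError(f"line {lineno}: W-lines (GFA 1.1 walks) unsupported")
        else:
            logger.warning("skipping unknown GFA line type %r at line %d", tag, lineno)
    graph.validate()
    return graph


def write_gfa(graph: PangenomeGraph, stream: TextIO) -> None:
    """Write a graph as GFA v1, preserving segment and path order."""
    stream.write("H\tVN:Z:1.0\n")
    for node in graph.nodes.values():
        stream.write(f"S\t{node.node_id}\t{node.sequence}\n")
    for link in graph.links:
        stream.write(
            f"L\t{link.from_node}\t{link.from_orient}\t{link.to_node}"
            f"\t{link.to_orient}\t{link.overlap}\n"
        )
    for p in graph.paths:
        walk = ",".join(f"{s.node_id}{s.orient}" for s in p.steps)
        stream.write(f"P\t{p.name}\t{walk}\t*\n")


def gfa_to_string(graph: PangenomeGraph) -> str:
    buf = io.StringIO()
    write_gfa(graph, buf)
    return buf.getvalue()


def path_sequence(graph: PangenomeGraph, path: HaplotypePath) -> str:
    """Linear DNA sequence spelled by a path.

    '-' steps contribute the reverse complement of the node sequence.
    """
    parts = []
    for s in path.steps:
        seq = graph.nodes[s.node_id].sequence
        parts.append(seq if s.orient == "+" else reverse_complement(seq))
    return "".join(parts)


@dataclass
class PathIndex:
    """Cumulative-offset index mapping path positions to steps.

    ``offsets[i]`` is the 0-based start of step ``i`` on the path's linear
    coordinate; intervals are half-open ``[offsets[i], offsets[i]+len_i)``.
    """

    path: HaplotypePath
    offsets: list[int]
    lengths: list[int]

    @property
    def path_length(self) -> int:
        return self.offsets[-1] + self.lengths[-1]

    def step_at(self, pos: int) -> int:
        """Index of the step whose interval contains 0-based position ``pos``."""
        if pos < 0 or pos >= self.path_length:
            raise IndexError(
                f"position {pos} outside [0, {self.path_length}) on {self.path.name}"
            )
        return bisect_right(self.offsets, pos) - 1

    def steps_overlapping(self, start: int, end: int) -> list[tuple[int, int]]:
        """Steps overlapping [start, end), as (step index, overlap bp)."""
        if start < 0 or end > self.path_length or start >= end:
            raise IndexError(
                f"interval [{start}, {end}) outside [0, {self.path_length}) "
                f"on {self.path.name}"
            )
        first = self.step_at(start)
        out = []
        for i in range(first, len(self.offsets)):
            s0 = self.offsets[i]
            if s0 >= end:
                break
            s1 = s0 + self.lengths[i]
            ov = min(end, s1) - max(start, s0)
            if ov > 0:
                out.append((i, ov))
        return out


def build_path_index(graph: PangenomeGraph, path: HaplotypePath) -> PathIndex:
    offsets, lengths = [], []
    pos = 0
    for s in path.steps:
        ln = graph.nodes[s.node_id].length
        offsets.append(pos)
        lengths.append(ln)
        pos += ln
    return PathIndex(path, offsets, lengths)
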