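"""Synthetic multi-species diploid pangenomes with exact ground truth.

The generator builds the graph *directly* (no alignment step): an ancestral
chromosome is partitioned into segments, each assigned a carrier species
subset (all species -> core; exactly one -> private; otherwise dispensable).
Within a segment, anchor blocks shared by all carriers alternate with variant
sites where some haplotypes traverse an alternative node (SNP/MNP alleles) or
skip/insert a node (deletions/insertions). Because every node's carrier set
is known by construction, planted node classes, gene classes, repeat
densities and pairwise variant lists are exact, and every other module can be
tested against them without any external data.

Default parameters mimic the magnitudes reported for wild-grape genomes
scaled to a 100 kb chromosome: class shares near 48/36/16% of graph bp,
between-species SNP spacing of a few hundred bp, and a private genome
noticeably more repeat-dense than the core.

Consecutive variant sites are separated by at least one shared anchor node,
which makes pairwise deconstruction recall provably 1.0; ``dense=True``
drops the guarantee for stress testing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from random import Random

import numpy as np
import pandas as pd

from .classify import class_of_count
from .popgen import hill_weir_expected_r2
from .variants import classify_variant

_BASES = "ACGT"

Hap = tuple[int, int]  # (species index, haplotype index 1-based)


@dataclass
class SDRConfig:
    """A planted allele-divergent region (sex-determining-region style).

    Two adjacent segments carried by disjoint haplotype groups (default 11 vs
    4 haplotypes with at least one species straddling the groups, the design
    that makes collisions with species-level segments impossible), plus a few
    haplotypes carrying neither allele.
    """

    group_a_size: int = 11
    group_b_size: int = 4
    segment_bp: int = 3000


@dataclass
class SimulationConfig:
    n_species: int = 9
    haps_per_species: int = 2
    chrom_lengths: tuple[int, ...] = (100_000,)
    class_proportions: tuple[float, float, float] = (0.48, 0.36, 0.16)
    seg_len_range: tuple[int, int] = (1000, 3000)
    species_snp_rate: float = 1 / 300
    hap_snp_rate: float = 1 / 500
    species_indel_rate: float = 1 / 2000
    hap_indel_rate: float = 1 / 4000
    indel_geom_p: float = 0.15
    indel_max: int = 200
    n_genes: int = 40
    gene_len_range: tuple[int, int] = (800, 2400)
    gene_class_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    repeat_density: dict = field(
        default_factory=lambda: {"core": 0.40, "dispensable": 0.46, "private": 0.56}
    )
    sdr: SDRConfig | None = None
    dense: bool = False
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.class_proportions[1] > 0 and self.n_species < 3:
            raise ValueError("dispensable segments need >= 3 species")
        if self.n_species < 2:
            raise ValueError("need >= 2 species")


@dataclass
class Event:
    """One unit along the ancestral coordinate.

    ``alleles`` holds (node_id, sequence, carrier haplotype set) tuples; an
    anchor has one allele, a variant site two (a deleted or not-yet-inserted
    allele has node_id None and empty sequence).
    """

    kind: str  # anchor | snp | ins | del
    anc_start: int
    anc_end: int
    alleles: list[tuple[str | None, str, frozenset]]
    segment: int = -1

    def allele_of(self, hap: Hap) -> tuple[str | None, str]:
        for node_id, seq, carriers in self.alleles:
            if hap in carriers:
                return node_id, seq
        return None, ""


@dataclass
class SyntheticTruth:
    node_classes: pd.DataFrame
    gene_classes: pd.DataFrame
    repeat_density: pd.DataFrame
    repeat_nodes: set
    events: dict
    haps: list
    path_name: dict
    seqid_map: dict
    class_bp: dict
    sdr: dict | None = None


@dataclass
class SimResult:
    config: SimulationConfig
    gfa: str
    gff3: str
    bed: str
    truth: SyntheticTruth

    def write(self, outdir) -> None:
        import pathlib

        d = pathlib.Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        (d / "pangenome.gfa").write_text(self.gfa)
        (d / "genes.gff3").write_text(self.gff3)
        (d / "repeats.bed").write_text(self.bed)
        self.truth.node_classes.to_csv(d / "truth_nodes.tsv", sep="\t", index=False)
        self.truth.gene_classes.to_csv(d / "truth_genes.tsv", sep="\t", index=False)


def _rand_seq(rng: Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _sdr_groups(cfg: SimulationConfig) -> tuple[list[Hap], list[Hap]]:
    """11-vs-4 style haplotype groups with straddling species.

    Groups are filled species by species; because group A's size is odd, at
    least one species contributes one haplotype to A and (by construction
    here) its other haplotype to B, so no species-level carrier set can
    coincide with either group.
    """
    haps = [
        (s, h)
        for s in range(cfg.n_species)
        for h in range(1, cfg.haps_per_species + 1)
    ]
    na, nb = cfg.sdr.group_a_size, cfg.sdr.group_b_size
    if na + nb > len(haps):
        raise ValueError("SDR groups larger than the haplotype pool")
    group_a = haps[:na]
    group_b = haps[na : na + nb]
    return group_a, group_b


class _Builder:
    def __init__(self, cfg: SimulationConfig):
        cfg.validate()
        self.cfg = cfg
        self.rng = Random(cfg.seed)
        self.next_node = 1
        self.nodes: dict[str, tuple[str, frozenset]] = {}  # id -> (seq, carriers)
        self.haps: list[Hap] = [
            (s, h)
            for s in range(cfg.n_species)
            for h in range(1, cfg.haps_per_species + 1)
        ]
        self.all_haps = frozenset(self.haps)
        self.species_haps = {
            s: frozenset(h for h in self.haps if h[0] == s)
            for s in range(cfg.n_species)
        }
        self.events: dict[str, list[Event]] = {}
        self.sdr_groups = _sdr_groups(cfg) if cfg.sdr else None
        self.sdr_nodes: tuple[set, set] = (set(), set())

    # -- node registry -------------------------------------------------
    def new_node(self, seq: str, carriers: frozenset) -> str:
        nid = str(self.next_node)
        self.next_node += 1
        self.nodes[nid] = (seq, carriers)
        return nid

    def _collides_with_sdr(self, carriers: frozenset) -> bool:
        if self.sdr_groups is None:
            return False
        ga, gb = map(frozenset, self.sdr_groups)
        return carriers == ga or carriers == gb

    # -- segment layout ------------------------------------------------
    def _segment_plan(self, L: int) -> list[tuple[int, str, frozenset]]:
        """(length, category, carrier set) per segment; ends forced core.

        Categories are allocated greedily against bp targets so realized
        shares track the configured proportions within about one segment.
        """
        cfg, rng = self.cfg, self.rng
        lengths = []
        remaining = L
        while remaining > 0:
            ln = rng.randint(*cfg.seg_len_range)
            ln = min(ln, remaining)
            if remaining - ln < cfg.seg_len_range[0]:
                ln = remaining
            lengths.append(ln)
            remaining -= ln
        cats = ["core", "dispensable", "private"]
        targets = {c: L * p for c, p in zip(cats, cfg.class_proportions)}
        assigned = dict.fromkeys(cats, 0)
        plan = []
        for i, ln in enumerate(lengths):
            if i == 0 or i == len(lengths) - 1:
                cat = "core"
            else:
                cat = max(cats, key=lambda c: targets[c] - assigned[c])
                if cat == "dispensable" and cfg.n_species < 3:
                    cat = "core"
            assigned[cat] += ln
            if cat == "core":
                carriers = self.all_haps
            elif cat == "private":
                sp = rng.randrange(cfg.n_species)
                carriers = self.species_haps[sp]
            else:
                k = rng.randint(2, cfg.n_species - 1)
                subset = rng.sample(range(cfg.n_species), k)
                carriers = frozenset().union(
                    *(self.species_haps[s] for s in subset)
                )
            plan.append((ln, cat, carriers))
        return plan

    # -- variant sites -------------------------------------------------
    def _draw_alt_carriers(self, carriers: frozenset, species_scope: bool) -> frozenset:
        rng = self.rng
        species = sorted({h[0] for h in carriers})
        for _ in range(20):
            if species_scope and len(species) >= 2:
                k = rng.randint(1, len(species) - 1)
                subset = rng.sample(species, k)
                alt = frozenset().union(*(self.species_haps[s] for s in subset))
                alt &= carriers
            else:
                alt = frozenset([rng.choice(sorted(carriers))])
            ref = carriers - alt
            if not alt or not ref:
                continue
            if self._collides_with_sdr(alt) or self._collides_with_sdr(ref):
                continue
            return alt
        raise RuntimeError("could not draw collision-free allele carriers")

    def _indel_size(self) -> int:
        size = 1 + int(np.log(1 - self.rng.random()) / np.log(1 - self.cfg.indel_geom_p))
        return min(size, self.cfg.indel_max)

    def _build_segment(
        self, chrom: str, seg_idx: int, anc_pos: int, length: int, carriers: frozenset,
        allow_variants: bool = True,
    ) -> int:
        """Append the events of one segment; returns the new ancestral pos."""
        cfg, rng = self.cfg, self.rng
        events = self.events[chrom]
        end = anc_pos + length
        multi = len(carriers) >= 2 and allow_variants
        rates = (
            [
                ("snp_sp", cfg.species_snp_rate),
                ("snp_hap", cfg.hap_snp_rate),
                ("ind_sp", cfg.species_indel_rate),
                ("ind_hap", cfg.hap_indel_rate),
            ]
            if multi
            else []
        )
        total_rate = sum(r for _, r in rates)
        pos = anc_pos
        min_anchor = 1 if cfg.dense else 4
        while pos < end:
            if total_rate <= 0:
                gap = min(400, end - pos)
            else:
                gap = max(min_anchor, int(rng.expovariate(total_rate)))
            gap = min(gap, end - pos)
            nid = self.new_node(_rand_seq(rng, gap), carriers)
            events.append(Event("anchor", pos, pos + gap, [(nid, self.nodes[nid][0], carriers)], seg_idx))
            pos += gap
            if pos >= end:
                break
            if total_rate <= 0:
                continue
            # site kind
            u = rng.random() * total_rate
            kind = rates[-1][0]
            for name, r in rates:
                if u < r:
                    kind = name
                    break
                u -= r
            species_scope = kind.endswith("_sp") and len({h[0] for h in carriers}) >= 2
            alt_c = self._draw_alt_carriers(carriers, species_scope)
            ref_c = carriers - alt_c
            if kind.startswith("snp"):
                if end - pos < 1 + min_anchor:
                    continue
                ref_base = _rand_seq(rng, 1)
                alt_base = rng.choice([b for b in _BASES if b != ref_base])
                rn = self.new_node(ref_base, ref_c)
                an = self.new_node(alt_base, alt_c)
                events.append(
                    Event("snp", pos, pos + 1, [(rn, ref_base, ref_c), (an, alt_base, alt_c)], seg_idx)
                )
                pos += 1
            else:
                size = self._indel_size()
                if rng.random() < 0.5:  # deletion: alt carriers skip the node
                    if end - pos < size + min_anchor:
                        continue
                    seq = _rand_seq(rng, size)
                    rn = self.new_node(seq, ref_c)
                    events.append(
                        Event("del", pos, pos + size, [(rn, seq, ref_c), (None, "", alt_c)], seg_idx)
                    )
                    pos += size
                else:  # insertion: alt carriers traverse an extra node
                    seq = _rand_seq(rng, size)
                    an = self.new_node(seq, alt_c)
                    events.append(
                        Event("ins", pos, pos, [(None, "", ref_c), (an, seq, alt_c)], seg_idx)
                    )
        return end

    # -- whole chromosome ----------------------------------------------
    def build_chromosome(self, chrom: str, L: int) -> None:
        self.events[chrom] = []
        plan = self._segment_plan(L)
        if self.sdr_groups is not None:
            ga, gb = self.sdr_groups
            mid = len(plan) // 2
            plan = (
                plan[:mid]
                + [
                    (self.cfg.sdr.segment_bp, "sdr_a", frozenset(ga)),
                    (self.cfg.sdr.segment_bp, "sdr_b", frozenset(gb)),
                ]
                + plan[mid:]
            )
        anc = 0
        self.segment_cat: dict[int, tuple[str, frozenset]] = getattr(
            self, "segment_cat", {}
        )
        base = len(self.segment_cat)
        for i, (ln, cat, carriers) in enumerate(plan):
            seg_idx = base + i
            self.segment_cat[seg_idx] = (cat, carriers)
            before = len(self.nodes)
            anc = self._build_segment(
                chrom, seg_idx, anc, ln, carriers,
                allow_variants=not cat.startswith("sdr"),
            )
            if cat == "sdr_a":
                self.sdr_nodes[0].update(
                    str(n) for n in range(before + 1, len(self.nodes) + 1)
                )
            elif cat == "sdr_b":
                self.sdr_nodes[1].update(
                    str(n) for n in range(before + 1, len(self.nodes) + 1)
                )


def _hap_offsets(events: list[Event], hap: Hap) -> tuple[list[int], list[int]]:
    """Per-event haplotype start offset and carried allele length."""
    offs, lens = [], []
    pos = 0
    for ev in events:
        _, seq = ev.allele_of(hap)
        offs.append(pos)
        lens.append(len(seq))
        pos += len(seq)
    return offs, lens


def simulate_pangenome(config: SimulationConfig) -> SimResult:
    """Run the generator; returns GFA/GFF3/BED text plus the truth tables."""
    b = _Builder(config)
    cfg = config
    chrom_names = [f"chr{i + 1:02d}" for i in range(len(cfg.chrom_lengths))]
    for name, L in zip(chrom_names, cfg.chrom_lengths):
        b.build_chromosome(name, L)

    sample_label = lambda s: f"S{s + 1:02d}"  # noqa: E731
    path_name = {
        (hap, chrom): f"{sample_label(hap[0])}#{hap[1]}#{chrom}"
        for hap in b.haps
        for chrom in chrom_names
    }
    seqid = {
        (hap, chrom): f"{sample_label(hap[0])}.{hap[1]}.{chrom}"
        for hap in b.haps
        for chrom in chrom_names
    }

    # ---- node truth ---------------------------------------------------
    node_rows = []
    class_bp = dict.fromkeys(("core", "dispensable", "private"), 0)
    for nid, (seq, carriers) in b.nodes.items():
        n_sp = len({h[0] for h in carriers})
        cls = class_of_count(n_sp, cfg.n_species)
        class_bp[cls] += len(seq)
        node_rows.append(
            {"node_id": nid, "class": cls, "species_count": n_sp, "length": len(seq)}
        )
    node_truth = pd.DataFrame(node_rows)

    # ---- GFA ------------------------------------------------------------
    out = io.StringIO()
    out.write("H\tVN:Z:1.0\n")
    for nid, (seq, _) in b.nodes.items():
        out.write(f"S\t{nid}\t{seq}\n")
    links: dict[tuple, None] = {}
    path_steps: dict[tuple[Hap, str], list[str]] = {}
    for chrom in chrom_names:
        for hap in b.haps:
            steps = []
            for ev in b.events[chrom]:
                nid, seq = ev.allele_of(hap)
                if nid is not None:
                    steps.append(nid)
            path_steps[(hap, chrom)] = steps
            for a, c in zip(steps, steps[1:]):
                links.setdefault((a, c), None)
    for a, c in links:
        out.write(f"L\t{a}\t+\t{c}\t+\t0M\n")
    for (hap, chrom), steps in path_steps.items():
        walk = ",".join(f"{s}+" for s in steps)
        out.write(f"P\t{path_name[(hap, chrom)]}\t{walk}\t*\n")
    gfa_text = out.getvalue()

    # ---- genes ----------------------------------------------------------
    rng = b.rng
    offsets = {
        (hap, chrom): _hap_offsets(b.events[chrom], hap)
        for hap in b.haps
        for chrom in chrom_names
    }
    gene_rows, gff_lines = [], ["##gff-version 3"]
    cats = ("core", "dispensable", "private")
    gi = 0
    for chrom in chrom_names:
        events = b.events[chrom]
        seg_events: dict[int, list[int]] = {}
        for idx, ev in enumerate(events):
            seg_events.setdefault(ev.segment, []).append(idx)
        candidates = {
            c: [
                s
                for s, (cat, carriers) in b.segment_cat.items()
                if cat == c and s in seg_events
            ]
            for c in cats
        }
        placed = 0
        attempts = 0
        while placed < cfg.n_genes and attempts < cfg.n_genes * 50:
            attempts += 1
            cat = rng.choices(cats, weights=cfg.gene_class_weights)[0]
            if not candidates[cat]:
                continue
            seg = rng.choice(candidates[cat])
            idxs = seg_events[seg]
            seg_start = events[idxs[0]].anc_start
            seg_end = events[idxs[-1]].anc_end
            glen = rng.randint(*cfg.gene_len_range)
            if seg_end - seg_start < glen + 20:
                continue
            gs = rng.randint(seg_start + 2, seg_end - glen - 2)
            ge = gs + glen
            # snap both endpoints into anchor events
            anchor_at = {}
            ok = True
            for point, side in ((gs, "s"), (ge - 1, "e")):
                hit = None
                for idx in idxs:
                    ev = events[idx]
                    if ev.anc_start <= point < ev.anc_end and ev.kind == "anchor":
                        hit = idx
                        break
                if hit is None:
                    ok = False
                    break
                anchor_at[side] = hit
            if not ok:
                continue
            _, carriers = b.segment_cat[seg]
            # truth composition per carrier hap; require a safe margin
            ok = True
            for hap in sorted(carriers):
                per_class = dict.fromkeys(cats, 0)
                for idx in idxs:
                    ev = events[idx]
                    ov_anc = min(ge, ev.anc_end) - max(gs, ev.anc_start)
                    nid, seq = ev.allele_of(hap)
                    if nid is None:
                        continue
                    if ev.kind == "anchor":
                        if ov_anc > 0:
                            cls = class_of_count(
                                len({h[0] for h in b.nodes[nid][1]}), cfg.n_species
                            )
                            per_class[cls] += ov_anc
                    else:
                        inside = (
                            gs <= ev.anc_start and ev.anc_end <= ge
                            if ev.kind != "ins"
                            else gs < ev.anc_start < ge
                        )
                        if inside:
                            cls = class_of_count(
                                len({h[0] for h in b.nodes[nid][1]}), cfg.n_species
                            )
                            per_class[cls] += len(seq)
                total = sum(per_class.values())
                if total == 0 or per_class[cat] / max(total, glen) <= 0.85:
                    ok = False
                    break
            if not ok:
                continue
            gi += 1
            for hap in sorted(carriers):
                offs, _lens = offsets[(hap, chrom)]
                ev_s, ev_e = anchor_at["s"], anchor_at["e"]
                start0 = offs[ev_s] + (gs - events[ev_s].anc_start)
                end0 = offs[ev_e] + (ge - events[ev_e].anc_start)
                gid = f"g{gi:04d}_{sample_label(hap[0])}_{hap[1]}"
                gene_rows.append(
                    {
                        "gene_id": gid,
                        "sample": sample_label(hap[0]),
                        "haplotype": hap[1],
                        "chromosome": chrom,
                        "class": cat,
                    }
                )
                gff_lines.append(
                    f"{seqid[(hap, chrom)]}\t_synth\tgene\t{start0 + 1}\t{end0}"
                    f"\t.\t+\t.\tID={gid}"
                )
            placed += 1
    gene_truth = pd.DataFrame(
        gene_rows,
        columns=["gene_id", "sample", "haplotype", "chromosome", "class"],
    )
    gff3_text = "\n".join(gff_lines) + "\n"

    # ---- repeats --------------------------------------------------------
    repeat_nodes: dict[str, str] = {}
    label_weights = {
        "core": [0.25, 0.35, 0.25, 0.15],
        "dispensable": [0.35, 0.30, 0.20, 0.15],
        "private": [0.50, 0.25, 0.15, 0.10],
    }
    labels = ["LTR_Gypsy", "LTR_Copia", "DNA", "Other"]
    cls_by_node = dict(zip(node_truth["node_id"], node_truth["class"]))
    for nid in b.nodes:
        cls = cls_by_node[nid]
        if rng.random() < cfg.repeat_density[cls]:
            repeat_nodes[nid] = rng.choices(labels, weights=label_weights[cls])[0]
    bed_out = io.StringIO()
    for chrom in chrom_names:
        events = b.events[chrom]
        for hap in b.haps:
            offs, lens = offsets[(hap, chrom)]
            for idx, ev in enumerate(events):
                nid, _ = ev.allele_of(hap)
                if nid in repeat_nodes and lens[idx] > 0:
                    bed_out.write(
                        f"{seqid[(hap, chrom)]}\t{offs[idx]}\t{offs[idx] + lens[idx]}"
                        f"\t{repeat_nodes[nid]}\n"
                    )
    # truth densities over the first haplotype's distinct nodes
    first = b.haps[0]
    rows = []
    first_nodes = {
        n for chrom in chrom_names for n in path_steps[(first, chrom)]
    }
    for cls in cats:
        tot = sum(
            len(b.nodes[n][0]) for n in first_nodes if cls_by_node[n] == cls
        )
        cov = sum(
            len(b.nodes[n][0])
            for n in first_nodes
            if cls_by_node[n] == cls and n in repeat_nodes
        )
        rows.append(
            {
                "class": cls,
                "covered_bp": cov,
                "total_bp": tot,
                "density": cov / tot if tot else 0.0,
            }
        )
    repeat_truth = pd.DataFrame(rows)

    sdr_truth = None
    if b.sdr_groups is not None:
        ga, gb = b.sdr_groups
        sdr_truth = {
            "a_nodes": set(b.sdr_nodes[0]),
            "b_nodes": set(b.sdr_nodes[1]),
            "group_a": [path_name[(h, c)] for c in chrom_names for h in ga],
            "group_b": [path_name[(h, c)] for c in chrom_names for h in gb],
        }

    truth = SyntheticTruth(
        node_classes=node_truth,
        gene_classes=gene_truth,
        repeat_density=repeat_truth,
        repeat_nodes=set(repeat_nodes),
        events=b.events,
        haps=b.haps,
        path_name=path_name,
        seqid_map={v: (sample_label(k[0][0]), k[0][1], k[1]) for k, v in seqid.items()},
        class_bp=class_bp,
        sdr=sdr_truth,
    )
    return SimResult(config=cfg, gfa=gfa_text, gff3=gff3_text, bed=bed_out.getvalue(), truth=truth)


# ---------------------------------------------------------------------------
# Pairwise variant truth (independent event-walk, no graph machinery)
# ---------------------------------------------------------------------------


def truth_variants_for_pair(
    truth: SyntheticTruth, chrom: str, ref_hap: Hap, alt_hap: Hap
) -> list[tuple[int, str, str, str]]:
    """Expected (pos, REF, ALT, type) records for one haplotype pair.

    Walks the simulator's event list: runs of events where the two haplotypes
    do not traverse the same node accumulate into one pending difference,
    flushed at each co-traversed node (the shared anchor), then normalized
    with the VCF convention (common suffix/prefix trimmed, indels
    left-anchored with one preceding reference base).
    """
    ref_chars: list[str] = []
    pend_ref: list[str] = []
    pend_alt: list[str] = []
    records: list[tuple[int, str, str, str]] = []

    def flush(next_base: str | None) -> None:
        rg, ag = "".join(pend_ref), "".join(pend_alt)
        pend_ref.clear()
        pend_alt.clear()
        pos0 = len(ref_chars)
        ref_chars.extend(rg)
        if rg == ag:
            return
        ns = 0
        while ns < min(len(rg), len(ag)) and rg[len(rg) - 1 - ns] == ag[len(ag) - 1 - ns]:
            ns += 1
        rg, ag = rg[: len(rg) - ns], ag[: len(ag) - ns]
        npre = 0
        while npre < min(len(rg), len(ag)) and rg[npre] == ag[npre]:
            npre += 1
        rg, ag, pos0 = rg[npre:], ag[npre:], pos0 + npre
        if len(rg) == 0 or len(ag) == 0:
            if pos0 > 0:
                rg = ref_chars[pos0 - 1] + rg
                ag = ref_chars[pos0 - 1] + ag
                pos0 -= 1
            else:
                if next_base is None:
                    raise ValueError("difference at chromosome edge with no anchor")
                rg, ag = rg + next_base, ag + next_base
        vtype, _ = classify_variant(rg, ag)
        records.append((pos0 + 1, rg, ag, vtype))

    for ev in truth.events[chrom]:
        r_node, r_seq = ev.allele_of(ref_hap)
        a_node, a_seq = ev.allele_of(alt_hap)
        if r_node is not None and r_node == a_node:
            flush(r_seq[0] if r_seq else None)
            ref_chars.extend(r_seq)
        else:
            pend_ref.append(r_seq)
            pend_alt.append(a_seq)
    flush(None)
    return records


# ---------------------------------------------------------------------------
# LD-pair fixture
# ---------------------------------------------------------------------------


def sample_ld_pairs(
    rho: float,
    n: int,
    n_pairs: int,
    noise_sd: float,
    seed: int,
    d_range: tuple[float, float] = (1.0, 50_000.0),
) -> pd.DataFrame:
    """(distance, r2) records on the Hill–Weir curve plus truncated noise."""
    rng = np.random.default_rng(seed)
    d = rng.uniform(*d_range, size=n_pairs)
    r2 = hill_weir_expected_r2(rho * d, n)
    if noise_sd > 0:
        r2 = r2 + rng.normal(0.0, noise_sd, size=n_pairs)
    r2 = np.clip(r2, 0.0, 1.0)
    return pd.DataFrame({"distance": d, "r2": r2})
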