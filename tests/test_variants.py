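import io
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pangraphkit import parse_gfa, path_sequence
from pangraphkit.classify import classify_nodes, presence_matrix
from pangraphkit.graph_io import build_path_index
from pangraphkit.simulate import truth_variants_for_pair
from pangraphkit.variants import (
    VariantRecord,
    apply_variants,
    assign_site_class,
    classify_variant,
    deconstruct_all,
    deconstruct_pair,
    genome_fraction_covered,
    impact_enrichment,
    merge_and_normalize,
    read_vcf,
    size_bin,
    write_vcf,
)

from conftest import make_gfa


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref,alt,vtype,size",
        [
            ("C", "T", "SNP", 1),
            ("A", "ACCGGTTA", "INS", 7),
            ("ACCGGTTA", "A", "DEL", 7),
            ("AC", "GT", "MNP", 2),
        ],
    )
    def test_examples(self, ref, alt, vtype, size):
        assert classify_variant(ref, alt) == (vtype, size)

    def test_empty_allele_errors(self):
        with pytest.raises(ValueError):
            classify_variant("", "A")

    @settings(derandomize=True, max_examples=200)
    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=6),
        st.text(alphabet="ACGT", min_size=1, max_size=6),
    )
    def test_partition(self, ref, alt):
        """Every non-identical allele pair gets exactly one type."""
        if ref == alt:
            return
        vtype, size = classify_variant(ref, alt)
        assert vtype in {"SNP", "INS", "DEL", "MNP"}
        assert size >= 1

    @pytest.mark.parametrize(
        "size,label", [(1, "1"), (5, "2-10"), (11, "11-50"), (200, "51-1000"), (2000, ">1000")]
    )
    def test_size_bins(self, size, label):
        assert size_bin(size) == label


def pair_graph(extra_segments, ref_walk, alt_walk):
    segs = {"a": "AACCA", "z": "GGTTG"}
    segs.update(extra_segments)
    return parse_gfa(
        make_gfa(segs, {"R#1#chr1": ref_walk, "Q#1#chr1": alt_walk})
    )


class TestDeconstructPair:
    def test_identical_paths_no_variants(self):
        g = pair_graph({}, "a+,z+", "a+,z+")
        assert deconstruct_pair(g, g.paths[0], g.paths[1]) == []

    def test_single_snp(self):
        g = pair_graph({"c": "C", "t": "T"}, "a+,c+,z+", "a+,t+,z+")
        (rec,) = deconstruct_pair(g, g.paths[0], g.paths[1])
        assert (rec.pos, rec.ref_allele, rec.alt_allele, rec.vtype) == (6, "C", "T", "SNP")

    def test_eight_bp_insertion(self):
        g = pair_graph({"i": "ACGTACGT"}, "a+,z+", "a+,i+,z+")
        (rec,) = deconstruct_pair(g, g.paths[0], g.paths[1])
        assert rec.vtype == "INS" and rec.size == 8
        assert rec.pos == 5 and rec.ref_allele == "A"
        assert rec.alt_allele == "A" + "ACGTACGT"
        assert rec.alt_nodes == ("i",)

    def test_deletion(self):
        g = pair_graph({"d": "CCC"}, "a+,d+,z+", "a+,z+")
        (rec,) = deconstruct_pair(g, g.paths[0], g.paths[1])
        assert rec.vtype == "DEL" and rec.size == 3

    def test_reconstruction(self):
        g = pair_graph(
            {"c": "C", "t": "T", "i": "ACGTACGT", "m": "TTT"},
            "a+,c+,m+,z+",
            "a+,t+,m+,i+,z+",
        )
        recs = deconstruct_pair(g, g.paths[0], g.paths[1])
        assert apply_variants(path_sequence(g, g.paths[0]), recs) == path_sequence(
            g, g.paths[1]
        )

    def test_unalignable_error(self):
        g = parse_gfa(
            make_gfa({"1": "AC", "2": "GT"}, {"R#1#chr1": "1+", "Q#1#chr1": "2+"})
        )
        with pytest.raises(ValueError, match="unalignable"):
            deconstruct_pair(g, g.paths[0], g.paths[1])

    def test_inversion_flagged_other(self):
        # shared node traversed in reverse inside the gap never anchors
        g = pair_graph({"v": "ACGTT"}, "a+,v+,z+", "a+,v-,z+")
        (rec,) = deconstruct_pair(g, g.paths[0], g.paths[1])
        assert rec.vtype == "OTHER"

    def test_random_simulator_pairs_reconstruct(self, sim_small):
        res = sim_small
        g = parse_gfa(res.gfa)
        paths = {((int(p.sample[1:]) - 1, p.haplotype)): p for p in g.paths}
        rng = random.Random(1)
        haps = res.truth.haps
        for _ in range(40):
            rh, ah = rng.sample(haps, 2)
            recs = deconstruct_pair(g, paths[rh], paths[ah])
            assert apply_variants(
                path_sequence(g, paths[rh]), recs
            ) == path_sequence(g, paths[ah])
            truth = {
                (p, r, a)
                for p, r, a, _ in truth_variants_for_pair(res.truth, "chr01", rh, ah)
            }
            got = {(r.pos, r.ref_allele, r.alt_allele) for r in recs}
            assert got == truth  # recall and precision both exactly 1


class TestMerge:
    def three_path_graph(self):
        # ref a-c-z ; alt1 SNP c->t ; alt2 identical to ref
        return parse_gfa(
            make_gfa(
                {"a": "AACCA", "c": "C", "t": "T", "z": "GGTTG"},
                {
                    "R#1#chr1": "a+,c+,z+",
                    "Q#1#chr1": "a+,t+,z+",
                    "Q#2#chr1": "a+,c+,z+",
                },
            )
        )

    def test_shared_snp_both_alt(self):
        g = parse_gfa(
            make_gfa(
                {"a": "AACCA", "c": "C", "t": "T", "z": "GGTTG"},
                {
                    "R#1#chr1": "a+,c+,z+",
                    "Q#1#chr1": "a+,t+,z+",
                    "Q#2#chr1": "a+,t+,z+",
                },
            )
        )
        ref = g.path_by_name("R#1#chr1")
        sites = deconstruct_all(g, ref)
        assert len(sites) == 1
        assert sites[0].genotypes == {"Q#1#chr1": "1", "Q#2#chr1": "1"}

    def test_reference_genotype(self):
        g = self.three_path_graph()
        sites = deconstruct_all(g, g.path_by_name("R#1#chr1"))
        assert sites[0].genotypes == {"Q#1#chr1": "1", "Q#2#chr1": "0"}

    def test_multiallelic_split_biallelic(self):
        g = parse_gfa(
            make_gfa(
                {"a": "AACCA", "c": "C", "t": "T", "g": "G", "z": "GGTTG"},
                {
                    "R#1#chr1": "a+,c+,z+",
                    "Q#1#chr1": "a+,t+,z+",
                    "Q#2#chr1": "a+,g+,z+",
                },
            )
        )
        sites = deconstruct_all(g, g.path_by_name("R#1#chr1"))
        assert len(sites) == 2
        alts = {s.alt_allele for s in sites}
        assert alts == {"T", "G"}
        for s in sites:
            assert sorted(s.genotypes.values()) == ["0", "1"]

    def test_missing_genotype_outside_chain_span(self):
        g = parse_gfa(
            make_gfa(
                {"a": "AAAAA", "b": "CCCCC", "c": "G", "d": "T"},
                {
                    "R#1#chr1": "a+,b+,c+",
                    "Q#1#chr1": "a+,b+,d+",
                    "Q#2#chr1": "a+,b+",
                },
            )
        )
        sites = deconstruct_all(g, g.path_by_name("R#1#chr1"))
        # Q1 carries a terminal SNP; Q2's truncation is a terminal deletion
        snp = next(s for s in sites if s.vtype == "SNP")
        assert snp.genotypes["Q#1#chr1"] == "1"
        assert snp.genotypes["Q#2#chr1"] == "."  # outside Q2's anchor span

    def test_conflicting_ref_error(self):
        r1 = VariantRecord("chr1", 5, "AC", "A", "DEL", 1)
        r2 = VariantRecord("chr1", 5, "AG", "A", "DEL", 1)
        with pytest.raises(ValueError, match="conflicting"):
            merge_and_normalize({"h1": [r1], "h2": [r2]})


class TestSiteClass:
    def test_majority_and_insertion_rules(self, sim_small, ):
        res = sim_small
        g = parse_gfa(res.gfa)
        classes = classify_nodes(presence_matrix(g), g)
        ref = g.paths[0]
        idx = build_path_index(g, ref)
        sites = deconstruct_all(g, ref, [g.paths[1], g.paths[2]])
        truth_cls = dict(zip(res.truth.node_classes["node_id"], res.truth.node_classes["class"]))
        n_checked = 0
        for s in sites:
            got = assign_site_class(s, g, classes, idx)
            assert got in {"core", "dispensable", "private"}
            if s.vtype == "INS" and len(s.ref_allele) == 1 and len(s.alt_nodes) == 1:
                assert got == truth_cls[s.alt_nodes[0]]
                n_checked += 1
        assert n_checked > 0

    def test_snp_takes_underlying_node_class(self):
        g = parse_gfa(
            make_gfa(
                {"a": "AACCA", "c": "C", "t": "T", "z": "GGTTG"},
                {
                    "R#1#chr1": "a+,c+,z+",
                    "R#2#chr1": "a+,c+,z+",
                    "Q#1#chr1": "a+,t+,z+",
                    "S#1#chr1": "a+,z+",
                },
            )
        )
        classes = classify_nodes(presence_matrix(g), g)
        ref = g.path_by_name("R#1#chr1")
        (rec,) = deconstruct_pair(g, ref, g.path_by_name("Q#1#chr1"))
        got = assign_site_class(rec, g, classes, build_path_index(g, ref))
        assert got == "private"  # node "c" only in sample R


class TestGenomeFraction:
    def test_no_variants(self):
        assert genome_fraction_covered([], 100) == 0.0

    def test_overlapping_deletions(self):
        d1 = VariantRecord("c", 11, "A" * 10, "A", "DEL", 9)
        d2 = VariantRecord("c", 16, "A" * 15, "A", "DEL", 14)
        assert genome_fraction_covered([d1, d2], 100) == pytest.approx(0.20)

    def test_simulator_pair_coverage(self, sim_small):
        res = sim_small
        g = parse_gfa(res.gfa)
        paths = {((int(p.sample[1:]) - 1, p.haplotype)): p for p in g.paths}
        rh, ah = res.truth.haps[0], res.truth.haps[3]
        recs = deconstruct_pair(g, paths[rh], paths[ah])
        L = g.path_length(paths[rh])
        # per-base truth from the records themselves (interval union oracle)
        mask = [False] * L
        for r in recs:
            for p in range(r.pos - 1, r.pos - 1 + len(r.ref_allele)):
                mask[p] = True
        assert genome_fraction_covered(recs, L) == pytest.approx(sum(mask) / L)


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric tail sum with integer-exact probabilities."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    nums = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    thr = obs * (1 + 1e-7)  # relative slack for float ties, as in scipy
    return sum(n for n in nums if n <= thr) / math.comb(r1 + r2, c1)


class TestEnrichment:
    def test_flat_proportions_not_significant(self):
        out = impact_enrichment({"x": 10, "y": 10}, {"x": 100, "y": 100})
        assert (out["enrichment"] == 1.0).all()
        assert not out["significant"].any()

    def test_fisher_matches_enumeration(self):
        out = impact_enrichment({"hi": 8, "lo": 2}, {"hi": 20, "lo": 70})
        row = out.set_index("effect").loc["hi"]
        assert row["p_value"] == pytest.approx(fisher_oracle(8, 2, 20, 70), abs=1e-12)

    def test_exhaustive_small_tables(self):
        from scipy import stats

        for a in range(0, 12):
            for b in range(0, 12 - a):
                for c in range(0, 12 - a - b):
                    for d in range(0, 12 - a - b - c):
                        _, p = stats.fisher_exact([[a, b], [c, d]])
                        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)

    def test_bonferroni_arithmetic(self):
        counts_sub = {f"e{i}": 1 for i in range(10)}
        counts_bg = {f"e{i}": 1 for i in range(10)}
        out = impact_enrichment(counts_sub, counts_bg)
        assert (out["p_adjusted"] == (out["p_value"] * 10).clip(upper=1)).all()

    def test_zero_background_errors(self):
        with pytest.raises(ValueError, match="background"):
            impact_enrichment({"x": 1}, {})


class TestVCF:
    def test_round_trip(self, sim_small, tmp_path):
        res = sim_small
        g = parse_gfa(res.gfa)
        ref = g.paths[0]
        sites = deconstruct_all(g, ref, g.paths[1:4])
        contigs = {ref.chromosome: g.path_length(ref)}
        out = tmp_path / "x.vcf"
        with open(out, "w") as fh:
            write_vcf(sites, contigs, fh)
        back = read_vcf(str(out))
        assert len(back) == len(sites)
        for orig, rec in zip(sites, back):
            assert (rec.pos, rec.ref_allele, rec.alt_allele) == (
                orig.pos,
                orig.ref_allele,
                orig.alt_allele,
            )
            assert rec.vtype == orig.vtype and rec.size == orig.size
            assert rec.genotypes == orig.genotypes

    def test_insertion_left_anchored(self):
        g = pair_graph({"i": "ACGTACGT"}, "a+,z+", "a+,i+,z+")
        recs = deconstruct_pair(g, g.paths[0], g.paths[1])
        buf = io.StringIO()
        recs[0].genotypes["Q#1#chr1"] = "1"
        write_vcf(recs, {"chr1": 10}, buf)
        body = [l for l in buf.getvalue().splitlines() if not l.startswith("#")]
        assert body[0].split("\t")[3] == "A"  # REF starts with the anchor base

    def test_unsorted_errors(self):
        r1 = VariantRecord("c", 10, "A", "T", "SNP", 1)
        r2 = VariantRecord("c", 5, "A", "T", "SNP", 1)
        with pytest.raises(ValueError, match="sorted"):
            write_vcf([r1, r2], {"c": 20}, io.StringIO())
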