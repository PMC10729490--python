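import pytest

from pangraphkit import parse_gfa
from pangraphkit.classify import classify_nodes, presence_matrix
from pangraphkit.simulate import SimulationConfig, simulate_pangenome


def make_gfa(segments: dict[str, str], paths: dict[str, str]) -> str:
    """Tiny GFA builder: segments {id: seq}, paths {name: 'id+,id-'}.

    Path names must follow sample#hap#chrom.
    """
    lines = ["H\tVN:Z:1.0"]
    lines += [f"S\t{nid}\t{seq}" for nid, seq in segments.items()]
    lines += [f"P\t{name}\t{walk}\t*" for name, walk in paths.items()]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic pangenome: 9 species x 2 haplotypes, 100 kb, seed 42."""
    return simulate_pangenome(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def sim_graph(sim_default):
    return parse_gfa(sim_default.gfa)


@pytest.fixture(scope="session")
def sim_classes(sim_graph):
    pres = presence_matrix(sim_graph)
    return pres, classify_nodes(pres, sim_graph)


@pytest.fixture(scope="session")
def sim_small():
    """Smaller 30 kb chromosome for pairwise deconstruction tests."""
    return simulate_pangenome(SimulationConfig(seed=42, chrom_lengths=(30_000,)))


@pytest.fixture()
def toy_three_class():
    """One core (60 bp), one 2-species dispensable (30 bp), one private (10 bp)
    node over three species."""
    gfa = make_gfa(
        {"1": "A" * 60, "2": "C" * 30, "3": "G" * 10},
        {
            "A#1#chr1": "1+,2+,3+",
            "B#1#chr1": "1+,2+",
            "C#1#chr1": "1+",
        },
    )
    return parse_gfa(gfa)
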