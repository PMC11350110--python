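import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from bgcsurvey.simulate import SimulationConfig, simulate_panel  # noqa: E402

TWO_GENUS_TREE = ("(((GenA_s1:0.03,GenA_s2:0.03):0.03,"
                  "(GenA_s3:0.03,GenA_s4:0.03):0.03):0.15,"
                  "((GenB_s1:0.03,GenB_s2:0.03):0.03,"
                  "(GenB_s3:0.03,GenB_s4:0.03):0.03):0.15);")


def balanced_tree(genera: list[str], per_genus: int, intra: float = 0.02,
                  inter: float = 0.15) -> str:
    """Newick for a panel of genera, each a balanced clade of leaves.

    Root-to-leaf depth within a genus is ~intra * ceil(log2(per_genus)),
    so panels stay in a moderate-divergence regime even at 20 leaves.
    """
    def balanced(leaves: list[str]) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{intra}"
        mid = len(leaves) // 2
        return (f"({balanced(leaves[:mid])},{balanced(leaves[mid:])})"
                f":{intra}")

    clades = []
    for g in genera:
        names = [f"{g}_s{i + 1}" for i in range(per_genus)]
        clades.append(f"({balanced(names)}):{inter}")
    node = clades[0]
    for c in clades[1:]:
        node = f"({node},{c}):0.02"
    return node + ";"


@pytest.fixture(scope="session")
def small_panel():
    """8 strains, 2 genera, all carriers, moderate divergence."""
    cfg = SimulationConfig(species_tree=TWO_GENUS_TREE, n_lineages=8, seed=11)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def mixed_panel():
    """8 strains, half carriers, one MGE-flanked, one clonal pair."""
    cfg = SimulationConfig(
        species_tree=TWO_GENUS_TREE, n_lineages=8, seed=23,
        carrier_lineages=("GenA_s1", "GenA_s2", "GenA_s3", "GenB_s1"),
        mge_prob=1.0, clonal_lineages=("GenA_s1",), clonal_copies=2)
    return simulate_panel(cfg)
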