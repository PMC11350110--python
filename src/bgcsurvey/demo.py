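"""The shipped synthetic demo panel: one set of study conditions shared by
the analysis scripts so every stage runs on the same strains.

Two genera of eight lineages each; all of genus A carries the cluster
vertically, one genus-B lineage acquires it horizontally from GenA_s1,
flank ORFs are 80% conserved between sisters, one lineage pair is clonal,
some carriers have a transposase remnant by the cluster, and cluster genes
carry occasional single-base frameshifts. Host composition 54.6% GC,
cluster offset -15 points (the regime observed for most of the surveyed
clusters).
"""

from __future__ import annotations

from .simulate import PanelResult, SimulationConfig, simulate_panel


def demo_tree(intra: float = 0.02, inter: float = 0.12) -> str:
    def clade(g):
        leaves = [f"{g}_s{i}" for i in range(1, 9)]
        quads = []
        for q in range(0, 8, 4):
            a = f"({leaves[q]}:{intra},{leaves[q + 1]}:{intra}):{intra}"
            b = f"({leaves[q + 2]}:{intra},{leaves[q + 3]}:{intra}):{intra}"
            quads.append(f"({a},{b}):{intra}")
        return f"({quads[0]},{quads[1]}):{inter}"

    return f"({clade('GenA')},{clade('GenB')});"


def demo_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        species_tree=demo_tree(),
        n_lineages=16,
        genome_length=60_000,
        host_gc=54.6,
        cluster_gc_offset=-15.0,
        carrier_lineages=tuple(f"GenA_s{i}" for i in range(1, 9)),
        hgt_events=(("GenA_s1", "GenB_s2"),),
        frameshift_prob=0.1,
        clonal_lineages=("GenA_s3",),
        clonal_copies=1,
        flank_conservation=0.8,
        mge_prob=0.4,
        seed=seed,
    )


def demo_panel(seed: int = 0, out_dir=None) -> PanelResult:
    return simulate_panel(demo_config(seed), out_dir=out_dir)
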