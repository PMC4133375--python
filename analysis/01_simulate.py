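#!/usr/bin/env python
"""Simulate the three-forest-type metacommunity used by the downstream analyses.

Generates the atlantic-like scenario — a dated 105-species tree with a
small deeply diverging clade (conifer-like "D") plus two large subclades,
and 209 incidence plots in three groups of 63/50/96 — and writes the tree
(newick), the community matrix and the species-to-clade map under
results/data/.
"""

from pathlib import Path

from phylobeta_forest.community import write_community
from phylobeta_forest.synth import atlantic_like, clade_map, simulate_metacommunity, simulate_tree, spec_to_config
from phylobeta_forest.trees import write_tree

SEED = 2024
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = atlantic_like()
    tree = simulate_tree(spec, seed=SEED)
    community = simulate_metacommunity(tree, spec, seed=SEED + 1)

    write_tree(tree, OUT / "tree.nwk")
    write_community(community, OUT / "community.csv")
    clade_map(spec).to_csv(OUT / "clades.csv", header=True)
    (OUT / "scenario.toml").write_text(spec_to_config(spec))

    rich = community.richness()
    print(f"tree: {len(tree.leaf_nodes())} tips, root age {spec.deep_split_age}")
    print(f"plots: {community.n_sites} in groups "
          f"{community.groups.value_counts().to_dict()}")
    print(f"richness: median {rich.median():.0f} (range {rich.min()}-{rich.max()})")
    print(f"wrote tree, community, clade map and scenario config to {OUT}/")


if __name__ == "__main__":
    main()
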