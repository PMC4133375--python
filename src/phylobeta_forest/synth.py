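"""Synthetic dated trees and clade-structured metacommunities.

The generator emulates a three-forest-type floristic survey design: a
species pool split into a small, deeply diverging clade ``D`` (think
conifers against angiosperms) and a large clade with two subclades
``S1``/``S2``; plot groups of unequal size whose species are drawn with
group-specific per-clade occurrence probabilities; incidence-only data.
Within-clade topologies come from a pure-birth (Yule) process with node
ages rescaled to the clade's crown age, so the tree is ultrametric and
dated in the same arbitrary-but-consistent time units throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .trees import parse_newick


class ScenarioError(ValueError):
    pass


@dataclass
class GroupSpec:
    """Number of plots and per-clade occurrence probabilities for one group."""

    n_plots: int
    clade_probs: dict[str, float]


@dataclass
class ScenarioSpec:
    """Full description of a synthetic metacommunity scenario.

    Ages are in the same time units as the output tree's branch lengths
    (Myr-like).  ``deep_split_age`` dates the root (clade D against the
    large clade); ``large_split_age`` dates the S1/S2 split; ``crown_ages``
    date each clade's crown.  Per-plot richness follows a negative
    binomial shifted to a minimum of 2 and truncated at the number of
    species the group can actually sample.
    """

    clades: dict[str, int] = field(
        default_factory=lambda: {"D": 15, "S1": 80, "S2": 80}
    )
    deep_split_age: float = 300.0
    large_split_age: float = 150.0
    crown_ages: dict[str, float] = field(
        default_factory=lambda: {"D": 120.0, "S1": 100.0, "S2": 100.0}
    )
    groups: dict[str, GroupSpec] = field(default_factory=dict)
    richness_mean: float = 30.0
    richness_dispersion: float = 8.0

    def __post_init__(self) -> None:
        for clade, n in self.clades.items():
            if n < 1:
                raise ScenarioError(f"clade {clade!r} needs >= 1 species, got {n}")
        if not (self.deep_split_age > self.large_split_age > 0):
            raise ScenarioError("require deep_split_age > large_split_age > 0")
        for clade, age in self.crown_ages.items():
            stem_age = (
                self.deep_split_age if clade == "D" else self.large_split_age
            )
            if not (0 < age <= stem_age):
                raise ScenarioError(
                    f"crown age of {clade} must lie in (0, {stem_age}]"
                )
        for name, group in self.groups.items():
            if group.n_plots < 2:
                raise ScenarioError(f"group {name!r} needs >= 2 plots")
            for clade, p in group.clade_probs.items():
                if not 0 <= p <= 1:
                    raise ScenarioError(
                        f"occurrence probability of {clade} in {name} outside [0, 1]"
                    )
        if self.richness_mean <= 2:
            raise ScenarioError("richness_mean must exceed the minimum richness 2")

    @property
    def pool_size(self) -> int:
        return sum(self.clades.values())

    def species_names(self) -> dict[str, list[str]]:
        return {
            clade: [f"{clade}_{i + 1:03d}" for i in range(n)]
            for clade, n in self.clades.items()
        }


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def _yule_newick(names: list[str], crown_age: float, rng: np.random.Generator) -> str:
    """Newick for a Yule clade with node ages rescaled to the crown age."""
    n = len(names)
    if n == 1:
        return names[0]
    # forward pure-birth: event k (k lineages -> k+1) after Exp(k) waiting
    times = np.concatenate([[0.0], np.cumsum(rng.exponential(1.0 / np.arange(2, n)))]) if n > 2 else np.array([0.0])
    present = (times[-1] + rng.exponential(1.0 / n)) if n > 1 else 1.0
    ages = crown_age * (present - times) / present  # internal node ages, crown first

    def join(a, b, age):
        na, aa = a
        nb, ab = b
        return (f"({na}:{age - aa:.17g},{nb}:{age - ab:.17g})", age)

    # random-join (coalescent-view) topology, which matches the pure-birth
    # labelled-topology distribution; ages attach youngest-first
    active = [(names[i], 0.0) for i in range(n)]
    for age in sorted(ages):  # youngest internal node first
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        merged = join(active[i], active[j], age)
        active = [x for k, x in enumerate(active) if k not in (i, j)]
        active.append(merged)
    assert len(active) == 1
    return active[0][0]


def simulate_tree(spec: ScenarioSpec, seed: int | None = None) -> dendropy.Tree:
    """Simulate the dated scenario tree (ultrametric, tips at age 0)."""
    rng = np.random.default_rng(seed)
    names = spec.species_names()
    parts: dict[str, tuple[str, float]] = {}
    for clade in sorted(spec.clades):
        crown = spec.crown_ages[clade] if len(names[clade]) > 1 else 0.0
        parts[clade] = (_yule_newick(names[clade], crown, rng), crown)

    def with_stem(clade: str, parent_age: float) -> str:
        newick, crown = parts[clade]
        return f"{newick}:{parent_age - crown:.17g}"

    large = (
        f"({with_stem('S1', spec.large_split_age)},"
        f"{with_stem('S2', spec.large_split_age)})"
        f":{spec.deep_split_age - spec.large_split_age:.17g}"
    )
    newick = f"({with_stem('D', spec.deep_split_age)},{large});"
    return parse_newick(newick)


# ---------------------------------------------------------------------------
# metacommunity simulation
# ---------------------------------------------------------------------------

def _draw_richness(
    rng: np.random.Generator, mean: float, dispersion: float, upper: int
) -> int:
    # negative binomial on the excess over the minimum richness of 2
    mu = mean - 2.0
    p = dispersion / (dispersion + mu)
    r = 2 + int(rng.negative_binomial(dispersion, p))
    return int(np.clip(r, 2, upper))


def simulate_metacommunity(
    tree: dendropy.Tree, spec: ScenarioSpec, seed: int | None = None
) -> CommunityMatrix:
    """Sample plots for every group by weighted draws from the pool.

    Within a group every species carries the occurrence probability of
    its clade; each plot draws its richness, then samples that many
    species without replacement with those weights.  Species in
    zero-probability clades never occur.
    """
    rng = np.random.default_rng(seed)
    names = spec.species_names()
    pool = [s for clade in sorted(spec.clades) for s in names[clade]]
    clade_of = {s: clade for clade in spec.clades for s in names[clade]}
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [s for s in pool if s not in tips]
    if missing:
        raise ScenarioError(f"tree lacks scenario species: {missing[:5]}...")
    if not spec.groups:
        raise ScenarioError("scenario defines no groups")

    rows, site_ids, labels = [], [], []
    for group_name in sorted(spec.groups):
        group = spec.groups[group_name]
        weights = np.array(
            [group.clade_probs.get(clade_of[s], 0.0) for s in pool]
        )
        available = int((weights > 0).sum())
        if available < 2:
            raise ScenarioError(
                f"group {group_name!r} can sample only {available} species"
            )
        probs = weights / weights.sum()
        for j in range(group.n_plots):
            r = _draw_richness(
                rng, spec.richness_mean, spec.richness_dispersion, available
            )
            chosen = rng.choice(len(pool), size=r, replace=False, p=probs)
            row = np.zeros(len(pool), dtype=int)
            row[chosen] = 1
            rows.append(row)
            site_ids.append(f"{group_name}_{j + 1:03d}")
            labels.append(group_name)

    incidence = pd.DataFrame(np.array(rows), index=site_ids, columns=pool)
    groups = pd.Series(labels, index=site_ids, name="group")
    return CommunityMatrix(incidence, groups=groups)


def clade_map(spec: ScenarioSpec) -> pd.Series:
    """Species -> clade labels for PCPS clade-correlation summaries."""
    names = spec.species_names()
    return pd.Series(
        {s: clade for clade in spec.clades for s in names[clade]}, name="clade"
    )


# ---------------------------------------------------------------------------
# preset scenarios
# ---------------------------------------------------------------------------

def atlantic_like(
    n_plots: tuple[int, int, int] = (63, 50, 96),
    clades: tuple[int, int, int] = (25, 40, 40),
    richness_mean: float = 15.0,
) -> ScenarioSpec:
    """Three unequal groups mirroring a dense/mixed/seasonal survey design.

    The mixed-like group heavily samples the deep-diverging clade as well
    as the large clade, making its plots the most phylogenetically
    diverse and overdispersed and the deep split the dominant
    compositional gradient; the dense-like and seasonal-like groups avoid
    the deep clade and differ from each other only by opposite moderate
    subclade biases — so they are mutually more similar than either is to
    the mixed-like group.
    """
    n_dense, n_mixed, n_seasonal = n_plots
    d, s1, s2 = clades
    return ScenarioSpec(
        clades={"D": d, "S1": s1, "S2": s2},
        groups={
            "Dense": GroupSpec(n_dense, {"D": 0.05, "S1": 0.7, "S2": 0.45}),
            "Mixed": GroupSpec(n_mixed, {"D": 0.95, "S1": 0.45, "S2": 0.45}),
            "Seasonal": GroupSpec(n_seasonal, {"D": 0.0, "S1": 0.45, "S2": 0.7}),
        },
        richness_mean=richness_mean,
    )


def neutral(
    n_plots: tuple[int, int, int] = (63, 50, 96),
    clades: tuple[int, int, int] = (25, 40, 40),
    richness_mean: float = 15.0,
) -> ScenarioSpec:
    """All groups share one occurrence-probability vector (no structure)."""
    probs = {"D": 0.5, "S1": 0.5, "S2": 0.5}
    n_dense, n_mixed, n_seasonal = n_plots
    d, s1, s2 = clades
    return ScenarioSpec(
        clades={"D": d, "S1": s1, "S2": s2},
        groups={
            "Dense": GroupSpec(n_dense, dict(probs)),
            "Mixed": GroupSpec(n_mixed, dict(probs)),
            "Seasonal": GroupSpec(n_seasonal, dict(probs)),
        },
        richness_mean=richness_mean,
    )


def terminal_contrast(
    n_plots: tuple[int, int, int] = (63, 50, 96),
    clades: tuple[int, int, int] = (15, 80, 80),
    richness_mean: float = 24.0,
) -> ScenarioSpec:
    """Groups differing only in subclade membership within the large clade.

    The deep clade is sampled identically everywhere and the S1/S2 split
    is young (60 of the 300-unit root depth), so between-group structure
    lives at terminal nodes only — the regime where nearest-taxon and
    branch-sharing measures should outrun the basal mean-pairwise
    measure, which mostly sees the (group-invariant) deep clade.
    """
    n_dense, n_mixed, n_seasonal = n_plots
    d, s1, s2 = clades
    return ScenarioSpec(
        clades={"D": d, "S1": s1, "S2": s2},
        large_split_age=60.0,
        crown_ages={"D": 120.0, "S1": 50.0, "S2": 50.0},
        groups={
            "Dense": GroupSpec(n_dense, {"D": 0.1, "S1": 0.95, "S2": 0.25}),
            "Mixed": GroupSpec(n_mixed, {"D": 0.1, "S1": 0.6, "S2": 0.6}),
            "Seasonal": GroupSpec(n_seasonal, {"D": 0.1, "S1": 0.25, "S2": 0.95}),
        },
        richness_mean=richness_mean,
    )


def clade_driven(
    n_plots: tuple[int, int, int] = (63, 50, 96),
    clades: tuple[int, int, int] = (10, 45, 45),
    richness_mean: float = 15.0,
) -> ScenarioSpec:
    """Group differences driven by clade proportions, not species identity.

    The deep clade is species-poor but maximally divergent (conifer-like)
    and its occurrence probability differs strongly between groups, while
    the species-rich subclades are sampled with only moderate weight
    shifts.  Species-level composition then turns over heavily within
    groups, which is the regime where phylogeny-weighted composition
    discriminates groups better than raw compositional dissimilarity.
    """
    n_dense, n_mixed, n_seasonal = n_plots
    d, s1, s2 = clades
    return ScenarioSpec(
        clades={"D": d, "S1": s1, "S2": s2},
        groups={
            "Dense": GroupSpec(n_dense, {"D": 0.1, "S1": 0.75, "S2": 0.45}),
            "Mixed": GroupSpec(n_mixed, {"D": 0.8, "S1": 0.6, "S2": 0.6}),
            "Seasonal": GroupSpec(n_seasonal, {"D": 0.05, "S1": 0.45, "S2": 0.75}),
        },
        richness_mean=richness_mean,
    )


PRESETS = {
    "atlantic-like": atlantic_like,
    "neutral": neutral,
    "terminal-contrast": terminal_contrast,
    "clade-driven": clade_driven,
}


# ---------------------------------------------------------------------------
# plain-config serialization
# ---------------------------------------------------------------------------

def spec_to_config(spec: ScenarioSpec) -> str:
    """Serialize a scenario as a TOML document."""
    lines = [
        "[scenario]",
        f"deep_split_age = {spec.deep_split_age}",
        f"large_split_age = {spec.large_split_age}",
        f"richness_mean = {spec.richness_mean}",
        f"richness_dispersion = {spec.richness_dispersion}",
        "",
        "[clades]",
    ]
    for clade in sorted(spec.clades):
        lines.append(f"{clade} = {spec.clades[clade]}")
    lines += ["", "[crown_ages]"]
    for clade in sorted(spec.crown_ages):
        lines.append(f"{clade} = {spec.crown_ages[clade]}")
    for name in sorted(spec.groups):
        group = spec.groups[name]
        lines += ["", f"[groups.{name}]", f"n_plots = {group.n_plots}"]
        for clade in sorted(group.clade_probs):
            lines.append(f"prob_{clade} = {group.clade_probs[clade]}")
    return "\n".join(lines) + "\n"


def spec_from_config(text: str) -> ScenarioSpec:
    import tomllib

    doc = tomllib.loads(text)
    scenario = doc.get("scenario", {})
    groups = {
        name: GroupSpec(
            n_plots=int(sub["n_plots"]),
            clade_probs={
                key.removeprefix("prob_"): float(value)
                for key, value in sub.items()
                if key.startswith("prob_")
            },
        )
        for name, sub in doc.get("groups", {}).items()
    }
    return ScenarioSpec(
        clades={k: int(v) for k, v in doc.get("clades", {}).items()},
        deep_split_age=float(scenario.get("deep_split_age", 300.0)),
        large_split_age=float(scenario.get("large_split_age", 150.0)),
        crown_ages={k: float(v) for k, v in doc.get("crown_ages", {}).items()},
        groups=groups,
        richness_mean=float(scenario.get("richness_mean", 40.0)),
        richness_dispersion=float(scenario.get("richness_dispersion", 8.0)),
    )
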