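"""End-to-end orchestration: alpha, phylobetadiversity, PCPS and Mantel stages.

A :class:`RunConfig` points either at real inputs (newick tree, community
CSV, optional group CSV) or at a named synthetic scenario.  Each stage
writes tidy CSV tables; a JSON manifest records the configuration, seeds
and input hashes so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import ses
from .community import CommunityMatrix, read_community, read_groups, write_community
from .inference import mantel, perm_anova, permanova
from .pcps import pcps_ordination
from .phylobeta import (
    METHODS,
    PhyloBetaResult,
    fuzzy_composition,
    fuzzy_result,
    phylobeta_matrix,
)
from .synth import PRESETS, clade_map as scenario_clade_map, simulate_metacommunity, simulate_tree
from .trees import as_newick, patristic_distances, read_tree, write_tree

logger = logging.getLogger(__name__)

BETA_METHODS = ("jaccard", "fuzzy", "comdist", "comdistnt", "rao_h", "unifrac")


@dataclass
class RunConfig:
    """Inputs and parameters for one pipeline run."""

    tree_path: str | None = None
    community_path: str | None = None
    groups_path: str | None = None
    scenario: str | None = None  # preset name; mutually exclusive with paths
    scenario_plots: tuple[int, int, int] = (63, 50, 96)
    scenario_clades: tuple[int, int, int] = (25, 40, 40)
    scenario_richness_mean: float = 15.0
    n_null: int = 999
    n_perm: int = 999
    seed: int = 0
    methods: tuple[str, ...] = BETA_METHODS
    axis_threshold: float = 0.05
    output_dir: str = "results"

    def __post_init__(self) -> None:
        has_paths = self.tree_path is not None or self.community_path is not None
        if self.scenario is not None and has_paths:
            raise ValueError("give either input paths or a scenario, not both")
        if self.scenario is None and not has_paths:
            raise ValueError("either input paths or a scenario is required")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}")


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Independent sub-seeds derived from the master seed (all < 2^31)."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def load_inputs(cfg: RunConfig):
    """Resolve the config into (tree, community, clade_map or None)."""
    if cfg.scenario is not None:
        if cfg.scenario not in PRESETS:
            raise ValueError(
                f"unknown scenario {cfg.scenario!r}; presets: {sorted(PRESETS)}"
            )
        spec = PRESETS[cfg.scenario](
            n_plots=cfg.scenario_plots,
            clades=cfg.scenario_clades,
            richness_mean=cfg.scenario_richness_mean,
        )
        seeds = _stage_seeds(cfg.seed)
        tree = simulate_tree(spec, seed=seeds[0])
        community = simulate_metacommunity(tree, spec, seed=seeds[1])
        return tree, community, scenario_clade_map(spec)
    tree = read_tree(cfg.tree_path)
    community = read_community(cfg.community_path)
    if cfg.groups_path is not None:
        community = CommunityMatrix(
            community.incidence, groups=read_groups(cfg.groups_path)
        )
    return tree, community, None


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_alpha_stage(
    tree,
    community: CommunityMatrix,
    n_null: int = 999,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Per-site structure metrics plus group ANOVAs on log-richness,
    SES.PD, NRI and NTI (with pairwise contrasts)."""
    if community.groups is None:
        raise ValueError("alpha stage needs site group labels")
    seeds = _stage_seeds(seed)
    alpha = ses(tree, community, n_null=n_null, seed=seeds[2])
    table = alpha.table
    responses = {
        "log_richness": np.log(table["richness"].to_numpy(dtype=float)),
        "ses_pd": table["ses_pd"].to_numpy(),
        "nri": table["nri"].to_numpy(),
        "nti": table["nti"].to_numpy(),
    }
    groups = community.groups
    anova_rows = []
    for i, (name, y) in enumerate(responses.items()):
        finite = np.isfinite(y)
        res = perm_anova(
            y[finite], groups[finite], n_perm=n_perm, seed=seeds[3] + i, contrasts=True
        )
        row = {
            "response": name,
            "F": res.observed,
            "P": res.p_value,
            "df1": res.df[0],
            "df2": res.df[1],
        }
        for c in res.contrasts:
            row[f"F_{c.group1}_vs_{c.group2}"] = c.observed
            row[f"P_{c.group1}_vs_{c.group2}"] = c.p_value
        anova_rows.append(row)
    return {"alpha": alpha, "anova": pd.DataFrame(anova_rows)}


def run_beta_stage(
    tree,
    community: CommunityMatrix,
    methods: tuple[str, ...] = BETA_METHODS,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Dissimilarity matrices plus a PERMANOVA summary table (one row per
    method, with pairwise contrasts) — the group-comparison analogue of a
    multi-method phylobetadiversity table."""
    if community.groups is None:
        raise ValueError("beta stage needs site group labels")
    seeds = _stage_seeds(seed)
    dist = patristic_distances(tree).filter(community.species)
    results: dict[str, PhyloBetaResult] = {}
    P = None
    for method in methods:
        if method == "fuzzy":
            P = fuzzy_composition(community, tree, dist=dist)
            results[method] = fuzzy_result(P)
        else:
            results[method] = phylobeta_matrix(
                method, community, tree=tree, dist=dist
            )
    rows = []
    for i, (method, result) in enumerate(results.items()):
        if result.dm.data.max() == 0:
            raise ValueError(f"method {method!r} produced an all-zero matrix")
        res = permanova(
            result.dm, community.groups, n_perm=n_perm, seed=seeds[4] + i, contrasts=True
        )
        row = {
            "method": method,
            "R2": res.r_squared,
            "F": res.observed,
            "P": res.p_value,
        }
        for c in res.contrasts:
            row[f"F_{c.group1}_vs_{c.group2}"] = c.observed
            row[f"P_{c.group1}_vs_{c.group2}"] = c.p_value
        rows.append(row)
    return {"results": results, "permanova": pd.DataFrame(rows), "P": P}


def run_pcps_stage(
    P,
    fuzzy_dm,
    groups: pd.Series,
    clade_map: pd.Series | None = None,
    threshold: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """PCPS ordination of matrix P plus per-retained-axis permutation ANOVA."""
    seeds = _stage_seeds(seed)
    ordination = pcps_ordination(P, fuzzy_dm, clade_map=clade_map, threshold=threshold)
    eigen = pd.DataFrame(
        {
            "axis": ordination.axes,
            "eigenvalue": ordination.eigenvalues,
            "percent": ordination.percents,
            "retained": ordination.retained,
        }
    )
    rows = []
    if not ordination.retained.any():
        logger.warning("no axis holds more than %.1f%% of variation", threshold * 100)
    else:
        retained = ordination.retained_scores()
        for i, axis in enumerate(retained.columns):
            res = perm_anova(
                retained[axis].to_numpy(),
                groups.loc[retained.index],
                n_perm=n_perm,
                seed=seeds[5] + i,
                contrasts=True,
            )
            rows.append({"axis": axis, "F": res.observed, "P": res.p_value})
    return {
        "ordination": ordination,
        "eigen": eigen,
        "axis_anova": pd.DataFrame(rows, columns=["axis", "F", "P"]),
    }


def run_mantel_stage(
    results: dict[str, PhyloBetaResult],
    n_perm: int = 999,
    seed: int = 0,
    reference: str = "fuzzy",
) -> pd.DataFrame:
    """Mantel correlation of the reference method against every other."""
    if reference not in results:
        raise ValueError(f"reference method {reference!r} was not computed")
    seeds = _stage_seeds(seed)
    rows = []
    others = [m for m in results if m not in (reference, "jaccard")]
    for i, method in enumerate(others):
        res = mantel(
            results[reference].dm, results[method].dm, n_perm=n_perm, seed=seeds[6] + i
        )
        rows.append(
            {
                "method1": reference,
                "method2": method,
                "rho": res.rho,
                "P": res.p_value,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write CSV outputs plus a JSON manifest."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, community, cmap = load_inputs(cfg)

    write_tree(tree, outdir / "tree.nwk")
    write_community(community, outdir / "community.csv")

    alpha_out = run_alpha_stage(
        tree, community, n_null=cfg.n_null, n_perm=cfg.n_perm, seed=cfg.seed
    )
    alpha_out["alpha"].to_csv(outdir / "alpha_metrics.csv")
    alpha_out["anova"].to_csv(outdir / "alpha_anova.csv", index=False)

    beta_out = run_beta_stage(
        tree, community, methods=cfg.methods, n_perm=cfg.n_perm, seed=cfg.seed
    )
    for method, result in beta_out["results"].items():
        result.to_csv(outdir / f"beta_{method}.csv")
    beta_out["permanova"].to_csv(outdir / "beta_permanova.csv", index=False)

    pcps_out = None
    if "fuzzy" in beta_out["results"]:
        pcps_out = run_pcps_stage(
            beta_out["P"],
            beta_out["results"]["fuzzy"].dm,
            community.groups,
            clade_map=cmap,
            threshold=cfg.axis_threshold,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
        )
        pcps_out["ordination"].scores.to_csv(outdir / "pcps_scores.csv")
        pcps_out["eigen"].to_csv(outdir / "pcps_eigen.csv", index=False)
        pcps_out["axis_anova"].to_csv(outdir / "pcps_anova.csv", index=False)
        cc = pcps_out["ordination"].clade_correlations
        if cc is not None:
            cc.to_csv(outdir / "pcps_clade_correlations.csv")

    mantel_table = run_mantel_stage(
        beta_out["results"], n_perm=cfg.n_perm, seed=cfg.seed
    )
    mantel_table.to_csv(outdir / "mantel.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "stage_seeds": _stage_seeds(cfg.seed),
        "input_hashes": {
            "tree": _sha256(as_newick(tree)),
            "community": _sha256(community.incidence.to_csv()),
        },
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return {
        "alpha": alpha_out,
        "beta": beta_out,
        "pcps": pcps_out,
        "mantel": mantel_table,
        "manifest": manifest,
    }
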