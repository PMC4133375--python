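"""Intra-site phylogenetic structure: PD, MPD, MNTD and SES.PD / NRI / NTI.

Observed metrics per plot:

* Faith's PD — total branch length of the subtree spanning the plot's
  species and the tree root.
* MPD — mean patristic distance over unordered species pairs in the plot.
* MNTD — mean distance from each species to its nearest co-occurring
  relative.

Standardized effect sizes use the *taxa-shuffle* null: species identities
(tip labels) are permuted over the full regional pool while plot
composition counts stay fixed; SES = (obs − mean_null) / sd_null.  The
conventional sign flips NRI = −SES(MPD) and NTI = −SES(MNTD) make positive
values mean phylogenetic clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import CommunityMatrix
from .trees import edge_incidence, patristic_distances

logger = logging.getLogger(__name__)

METRICS = ("pd", "mpd", "mntd")


class AlphaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# observed metrics
# ---------------------------------------------------------------------------

def faith_pd(tree: dendropy.Tree, site: set[str] | list[str]) -> float:
    """Faith's PD of a species set, including the path to the root."""
    labels, A, lengths = edge_incidence(tree)
    index = {name: i for i, name in enumerate(labels)}
    species = list(site)
    if not species:
        raise AlphaError("PD of an empty species set is undefined")
    unknown = [s for s in species if s not in index]
    if unknown:
        raise AlphaError(f"species not on the tree: {unknown}")
    rows = [index[s] for s in species]
    covered = A[rows].any(axis=0)
    return float(lengths[covered].sum())


def _site_indices(dist: DistanceMatrix, site) -> np.ndarray:
    index = {name: i for i, name in enumerate(dist.ids)}
    unknown = [s for s in site if s not in index]
    if unknown:
        raise AlphaError(f"species not in the distance matrix: {unknown}")
    return np.array([index[s] for s in site], dtype=int)


def mpd(dist: DistanceMatrix, site) -> float:
    """Mean pairwise distance over unordered pairs of distinct species."""
    idx = _site_indices(dist, site)
    if len(idx) < 2:
        raise AlphaError("MPD needs at least two species")
    sub = dist.data[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub.sum() / (n * (n - 1)))


def mntd(dist: DistanceMatrix, site) -> float:
    """Mean distance to the nearest co-occurring species."""
    idx = _site_indices(dist, site)
    if len(idx) < 2:
        raise AlphaError("MNTD needs at least two species")
    sub = dist.data[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


# ---------------------------------------------------------------------------
# batch (vectorized) metric computation used by the null loop
# ---------------------------------------------------------------------------

def _pd_all(W: np.ndarray, A: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    covered = (W @ A) > 0
    return covered @ lengths


def _mpd_all(W: np.ndarray, D: np.ndarray, n: np.ndarray) -> np.ndarray:
    pair_sums = np.einsum("ks,st,kt->k", W, D, W)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, pair_sums / (n * (n - 1)), np.nan)


def _mntd_all(W: np.ndarray, D: np.ndarray, n: np.ndarray) -> np.ndarray:
    # mask distances to absent species and to self, take row minima
    masked = np.where(W[:, None, :] > 0, D[None, :, :], np.inf)
    masked[:, np.arange(D.shape[0]), np.arange(D.shape[0])] = np.inf
    minima = masked.min(axis=2)  # (sites, species)
    minima = np.where(W > 0, minima, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, minima.sum(axis=1) / n, np.nan)


# ---------------------------------------------------------------------------
# standardized effect sizes
# ---------------------------------------------------------------------------

@dataclass
class AlphaResult:
    """Per-site phylogenetic structure table plus null-model metadata."""

    table: pd.DataFrame  # index: site; columns: pd, mpd, mntd, ses_*, nri, nti, ...
    n_null: int
    seed: int | None

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def ses(
    tree: dendropy.Tree,
    community: CommunityMatrix,
    n_null: int = 999,
    seed: int | None = None,
    metrics: tuple[str, ...] = METRICS,
    dist: DistanceMatrix | None = None,
) -> AlphaResult:
    """Standardized effect sizes of PD/MPD/MNTD under the taxa-shuffle null.

    One tip-label permutation over the whole species pool is drawn per null
    iteration and shared across all sites, so null draws are comparable
    between sites.  ``sd`` uses the n−1 denominator; a zero null sd yields
    an undefined (NaN) SES, which is logged.
    """
    unknown = [m for m in metrics if m not in METRICS]
    if unknown:
        raise AlphaError(f"unknown metrics: {unknown}")
    if n_null < 1:
        raise AlphaError("n_null must be >= 1")

    labels, A, lengths = edge_incidence(tree)
    order = {name: i for i, name in enumerate(labels)}
    missing = [s for s in community.species if s not in order]
    if missing:
        raise AlphaError(f"community species not on the tree: {missing}")
    # the regional pool is the dataset's species; tree tips outside it do
    # not take part in the shuffle
    pool = community.species
    rows = [order[name] for name in pool]
    A = A[rows]
    W = community.to_array().astype(float)
    n = W.sum(axis=1)

    need_dist = "mpd" in metrics or "mntd" in metrics
    if need_dist:
        if dist is None:
            dist = patristic_distances(tree)
        dist = dist.filter(pool)  # align to pool order
        D = dist.data
    else:
        D = None

    observed: dict[str, np.ndarray] = {}
    if "pd" in metrics:
        observed["pd"] = _pd_all(W, A, lengths)
    if "mpd" in metrics:
        observed["mpd"] = _mpd_all(W, D, n)
    if "mntd" in metrics:
        observed["mntd"] = _mntd_all(W, D, n)

    rng = np.random.default_rng(seed)
    S = len(pool)
    nulls = {m: np.empty((n_null, community.n_sites)) for m in metrics}
    for b in range(n_null):
        perm = rng.permutation(S)
        Wp = W[:, perm]
        if "pd" in metrics:
            nulls["pd"][b] = _pd_all(Wp, A, lengths)
        if "mpd" in metrics:
            nulls["mpd"][b] = _mpd_all(Wp, D, n)
        if "mntd" in metrics:
            nulls["mntd"][b] = _mntd_all(Wp, D, n)

    table = pd.DataFrame(index=community.incidence.index)
    table["richness"] = n.astype(int)
    for m in metrics:
        null = nulls[m]
        null_mean = null.mean(axis=0)
        null_sd = null.std(axis=0, ddof=1) if n_null > 1 else np.zeros(community.n_sites)
        # all null draws identical -> sd is pure summation noise, force 0
        null_sd[null.max(axis=0) - null.min(axis=0) == 0] = 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(null_sd > 0, (observed[m] - null_mean) / null_sd, np.nan)
        degenerate = (null_sd == 0) & np.isfinite(observed[m])
        if degenerate.any():
            logger.warning(
                "SES undefined (zero null sd) for %d site(s) on metric %s",
                int(degenerate.sum()),
                m,
            )
        table[m] = observed[m]
        table[f"{m}_null_mean"] = null_mean
        table[f"{m}_null_sd"] = null_sd
        table[f"ses_{m}"] = z
    if "mpd" in metrics:
        table["nri"] = -table["ses_mpd"]
    if "mntd" in metrics:
        table["nti"] = -table["ses_mntd"]
    return AlphaResult(table=table, n_null=n_null, seed=seed)
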