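"""Between-plot phylobetadiversity on incidence data.

Six site-pair dissimilarity measures are provided, differing in their
sensitivity to basal versus terminal phylogenetic nodes:

* ``fuzzy`` — phylogenetic fuzzy weighting: species incidences are
  redistributed among phylogenetically similar co-occurring species
  (matrix **P**), then plots are compared by square-rooted Bray–Curtis
  dissimilarity.  Sensitive to both basal and terminal nodes.
* ``comdist`` — mean pairwise patristic distance between the species of
  the two plots (basal-node sensitive; equals between-plot Rao's D on
  incidence weights).
* ``comdistnt`` — mean nearest-taxon distance between plots, symmetrized
  by averaging both directions (terminal-node sensitive).
* ``rao_h`` — between-plot quadratic entropy standardized by the mean
  within-plot quadratic entropy (terminal-node sensitive).
* ``unifrac`` — fraction of the branch length of the two-plot spanning
  subtree that is exclusive to one plot (terminal-node sensitive; equal
  to the Jaccard distance on a star phylogeny).
* ``jaccard`` — plain compositional Jaccard distance, the phylogeny-free
  baseline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix

from .community import CommunityMatrix
from .trees import edge_incidence, patristic_distances

METHODS = ("fuzzy", "comdist", "comdistnt", "rao_h", "unifrac", "jaccard")


class PhyloBetaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# phylogenetic fuzzy weighting: similarities, belonging weights, matrix P
# ---------------------------------------------------------------------------

def phylo_similarities(dist: DistanceMatrix) -> pd.DataFrame:
    """Phylogenetic similarities s_ij = 1 − d_ij / max(d), with s_ii = 1."""
    d = dist.data
    dmax = d.max()
    if d.shape[0] < 2 or dmax <= 0:
        raise PhyloBetaError("degenerate distance matrix: no positive distances")
    s = 1.0 - d / dmax
    return pd.DataFrame(s, index=list(dist.ids), columns=list(dist.ids))


def phylo_weights(dist: DistanceMatrix) -> pd.DataFrame:
    """Fuzzy belonging weights q_ij = s_ij / Σ_k s_ik (rows sum to 1).

    The denominator runs over the whole species pool including the focal
    species itself (s_ii = 1), which keeps each row a probability vector.
    """
    s = phylo_similarities(dist)
    q = s.div(s.sum(axis=1), axis=0)
    return q


@dataclass
class PhyloWeightedComposition:
    """Matrix P: phylogeny-weighted species composition (species × sites).

    Each plot's incidences are redistributed among the plot's own species
    proportionally to fuzzy belonging, so each column sums to the plot's
    richness.
    """

    values: pd.DataFrame  # species × sites
    provenance: dict = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def sites(self) -> list[str]:
        return list(self.values.columns)


def matrix_p(
    community: CommunityMatrix, q: pd.DataFrame, provenance: dict | None = None
) -> PhyloWeightedComposition:
    """Phylogeny-weighted species composition from belonging weights.

    For plot *k* with species set S_k the belonging weights are
    renormalized within S_k and each member's incidence is spread over
    S_k:  p_jk = Σ_{i∈S_k} q_ij / Σ_{l∈S_k} q_il.  Column totals equal
    plot richness (incidence is conserved).
    """
    missing = [s for s in community.species if s not in q.index]
    if missing:
        raise PhyloBetaError(f"species without belonging weights: {missing}")
    qm = q.loc[community.species, community.species].to_numpy()
    W = community.to_array()
    n_sites, S = W.shape
    P = np.zeros((S, n_sites))
    for k in range(n_sites):
        members = np.flatnonzero(W[k])
        sub = qm[np.ix_(members, members)]
        rows = sub / sub.sum(axis=1, keepdims=True)
        P[members, k] = rows.sum(axis=0)
    values = pd.DataFrame(P, index=community.species, columns=community.sites)
    return PhyloWeightedComposition(values=values, provenance=provenance or {})


def fuzzy_dissimilarity(P: PhyloWeightedComposition) -> DistanceMatrix:
    """Square-rooted Bray–Curtis dissimilarity between plots on matrix P."""
    X = P.values.to_numpy().T  # sites × species
    bc = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(np.sqrt(bc), ids=P.sites)


# ---------------------------------------------------------------------------
# per-pair measures
# ---------------------------------------------------------------------------

def _pair_indices(dist: DistanceMatrix, site1, site2):
    index = {name: i for i, name in enumerate(dist.ids)}
    for site in (site1, site2):
        if not site:
            raise PhyloBetaError("empty species set")
        unknown = [s for s in site if s not in index]
        if unknown:
            raise PhyloBetaError(f"species not in distance matrix: {unknown}")
    return (
        np.array([index[s] for s in site1], dtype=int),
        np.array([index[s] for s in site2], dtype=int),
    )


def comdist(dist: DistanceMatrix, site1, site2) -> float:
    """Mean patristic distance over all cross pairs (shared species count
    as zero-distance pairs, which makes the measure the between-plot Rao's
    quadratic entropy on incidence weights)."""
    i1, i2 = _pair_indices(dist, site1, site2)
    return float(dist.data[np.ix_(i1, i2)].mean())


def comdistnt(dist: DistanceMatrix, site1, site2) -> float:
    """Symmetrized mean nearest-taxon distance between two plots."""
    i1, i2 = _pair_indices(dist, site1, site2)
    cross = dist.data[np.ix_(i1, i2)]
    return float(0.5 * (cross.min(axis=1).mean() + cross.min(axis=0).mean()))


def _rao_within(dist: DistanceMatrix, idx: np.ndarray) -> float:
    # quadratic entropy over ordered pairs including self (divisor n^2)
    sub = dist.data[np.ix_(idx, idx)]
    return float(sub.sum() / (len(idx) ** 2))


def rao_h(dist: DistanceMatrix, site1, site2) -> float:
    """Between-plot Rao's D standardized by mean within-plot Rao's D."""
    i1, i2 = _pair_indices(dist, site1, site2)
    between = float(dist.data[np.ix_(i1, i2)].mean())
    within = 0.5 * (_rao_within(dist, i1) + _rao_within(dist, i2))
    if within <= 0:
        raise PhyloBetaError(
            "within-plot quadratic entropy is zero; Rao's H undefined"
        )
    return between / within


def unifrac(tree: dendropy.Tree, site1, site2) -> float:
    """Unweighted UniFrac on the union spanning subtree (root included)."""
    labels, A, lengths = edge_incidence(tree)
    index = {name: i for i, name in enumerate(labels)}
    for site in (site1, site2):
        if not site:
            raise PhyloBetaError("empty species set")
        unknown = [s for s in site if s not in index]
        if unknown:
            raise PhyloBetaError(f"species not on the tree: {unknown}")
    cover1 = A[[index[s] for s in site1]].any(axis=0)
    cover2 = A[[index[s] for s in site2]].any(axis=0)
    union = float(lengths[cover1 | cover2].sum())
    exclusive = float(lengths[cover1 ^ cover2].sum())
    return exclusive / union if union > 0 else 0.0


def jaccard(site1, site2) -> float:
    """Jaccard dissimilarity 1 − |∩| / |∪| on species sets."""
    a, b = set(site1), set(site2)
    if not a or not b:
        raise PhyloBetaError("empty species set")
    return 1.0 - len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# batch drivers over all site pairs
# ---------------------------------------------------------------------------

@dataclass
class PhyloBetaResult:
    """A site × site dissimilarity matrix produced by one method."""

    method: str
    dm: DistanceMatrix
    params: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        frame = pd.DataFrame(self.dm.data, index=self.dm.ids, columns=self.dm.ids)
        frame.to_csv(path)

    def to_long(self) -> pd.DataFrame:
        ids = list(self.dm.ids)
        rows = [
            (ids[i], ids[j], self.dm.data[i, j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
        ]
        return pd.DataFrame(rows, columns=["site1", "site2", self.method])


def _aligned_distance(tree, community, dist):
    if dist is None:
        dist = patristic_distances(tree)
    return dist.filter(community.species)


def _comdist_matrix(D: np.ndarray, W: np.ndarray) -> np.ndarray:
    n = W.sum(axis=1)
    cross = W @ D @ W.T
    out = cross / np.outer(n, n)
    np.fill_diagonal(out, 0.0)
    return out


def _nearest_taxon(D: np.ndarray, W: np.ndarray) -> np.ndarray:
    """M[k, s] = distance from species s to its nearest member of plot k."""
    masked = np.where(W[:, None, :] > 0, D[None, :, :], np.inf)
    return masked.min(axis=2)


def _comdistnt_matrix(D: np.ndarray, W: np.ndarray) -> np.ndarray:
    n = W.sum(axis=1)
    M = _nearest_taxon(D, W)  # (sites, species)
    directed = (W @ M.T) / n[:, None]  # row i: mean over i's species of min to plot j
    out = 0.5 * (directed + directed.T)
    np.fill_diagonal(out, 0.0)
    return out


def _rao_h_matrix(D: np.ndarray, W: np.ndarray) -> np.ndarray:
    n = W.sum(axis=1)
    cross = W @ D @ W.T
    between = cross / np.outer(n, n)
    within = np.diag(cross) / n**2
    if np.any(within <= 0):
        bad = np.flatnonzero(within <= 0)
        raise PhyloBetaError(
            f"within-plot quadratic entropy is zero for site index(es) {bad.tolist()}"
        )
    out = between / (0.5 * (within[:, None] + within[None, :]))
    np.fill_diagonal(out, 0.0)  # H(site, site) = 1 by definition; stored as 0 self-dissimilarity
    return out


def _unifrac_matrix(tree, community) -> np.ndarray:
    labels, A, lengths = edge_incidence(tree)
    order = {name: i for i, name in enumerate(labels)}
    rows = [order[s] for s in community.species]
    cover = (community.to_array() @ A[rows]) > 0  # sites × edges
    weighted = cover * lengths
    shared = weighted @ cover.T
    totals = weighted.sum(axis=1)
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, 1.0 - shared / union, 0.0)
    np.fill_diagonal(out, 0.0)
    return out


def _jaccard_matrix(W: np.ndarray) -> np.ndarray:
    return squareform(pdist(W.astype(bool), metric="jaccard"))


def phylobeta_matrix(
    method: str,
    community: CommunityMatrix,
    tree: dendropy.Tree | None = None,
    dist: DistanceMatrix | None = None,
) -> PhyloBetaResult:
    """Full site × site dissimilarity matrix for one method.

    ``tree`` is required for every method except ``jaccard``; a
    precomputed patristic ``dist`` may be passed to avoid recomputation.
    """
    if method not in METHODS:
        raise PhyloBetaError(f"unknown method {method!r}; choose from {METHODS}")
    W = community.to_array().astype(float)
    params: dict = {}
    if method == "jaccard":
        data = _jaccard_matrix(W)
    elif method == "unifrac":
        if tree is None:
            raise PhyloBetaError("unifrac requires the tree")
        data = _unifrac_matrix(tree, community)
    elif method == "fuzzy":
        aligned = _aligned_distance(tree, community, dist)
        q = phylo_weights(aligned)
        P = matrix_p(community, q, provenance=_provenance(community, aligned))
        return fuzzy_result(P)
    else:
        aligned = _aligned_distance(tree, community, dist)
        D = aligned.data
        if method == "comdist":
            data = _comdist_matrix(D, W)
        elif method == "comdistnt":
            data = _comdistnt_matrix(D, W)
        else:
            data = _rao_h_matrix(D, W)
    data = 0.5 * (data + data.T)
    return PhyloBetaResult(method=method, dm=DistanceMatrix(data, ids=community.sites), params=params)


def fuzzy_result(P: PhyloWeightedComposition) -> PhyloBetaResult:
    return PhyloBetaResult(
        method="fuzzy", dm=fuzzy_dissimilarity(P), params=dict(P.provenance)
    )


def fuzzy_composition(
    community: CommunityMatrix,
    tree: dendropy.Tree | None = None,
    dist: DistanceMatrix | None = None,
) -> PhyloWeightedComposition:
    """Convenience: matrix P straight from a tree and a community matrix."""
    aligned = _aligned_distance(tree, community, dist)
    q = phylo_weights(aligned)
    return matrix_p(community, q, provenance=_provenance(community, aligned))


def _provenance(community: CommunityMatrix, dist: DistanceMatrix) -> dict:
    def digest(arr: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]

    return {
        "community_hash": digest(community.to_array()),
        "distance_hash": digest(dist.data),
    }


def all_methods(
    community: CommunityMatrix,
    tree: dendropy.Tree,
    methods: tuple[str, ...] = METHODS,
) -> dict[str, PhyloBetaResult]:
    """Compute several methods, sharing one patristic distance matrix."""
    dist = patristic_distances(tree)
    return {
        m: phylobeta_matrix(m, community, tree=tree, dist=dist) for m in methods
    }
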