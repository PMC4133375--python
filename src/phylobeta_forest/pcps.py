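"""Principal coordinates of phylogenetic structure (PCPS).

A PCoA of the square-rooted Bray–Curtis dissimilarities on matrix P
yields orthogonal site-score axes: the leading axis expresses gradients
at the deepest phylogenetic splits in the metacommunity, later axes
progressively shallower ones.  Correlating each species' row of matrix P
with the retained axes identifies which clades drive each gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .phylobeta import PhyloWeightedComposition

EIGEN_REL_TOL = 1e-10


class OrdinationError(ValueError):
    pass


@dataclass
class OrdinationResult:
    """PCoA axes over sites, with eigenvalues and axis bookkeeping.

    ``percents`` are shares of the sum of *positive* eigenvalues (small
    negative eigenvalues are expected for sqrt-Bray–Curtis input and are
    excluded from the denominator).
    """

    scores: pd.DataFrame  # sites × axes, columns "pcps1", "pcps2", ...
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    percents: np.ndarray  # % of total positive-eigenvalue variation
    retained: np.ndarray | None = None  # boolean mask over axes
    clade_correlations: pd.DataFrame | None = field(default=None)

    @property
    def axes(self) -> list[str]:
        return list(self.scores.columns)

    def retained_scores(self) -> pd.DataFrame:
        if self.retained is None:
            raise OrdinationError("no retention mask; call retain_axes first")
        return self.scores.loc[:, self.retained]


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Classical (Gower) principal coordinates analysis.

    Double-centers −½ d², takes the eigendecomposition, and keeps axes
    with eigenvalue above ``EIGEN_REL_TOL`` × the largest one.  Scores are
    eigenvectors scaled by √eigenvalue.  Each axis's sign is fixed so its
    largest-magnitude site score is positive, making runs comparable.
    """
    d = dist.data
    n = d.shape[0]
    B = -0.5 * d**2
    B = B - B.mean(axis=0) - B.mean(axis=1)[:, None] + B.mean()
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    keep = eigvals > max(EIGEN_REL_TOL * max(eigvals.max(), 0.0), 0.0)
    if not keep.any():
        raise OrdinationError("no positive eigenvalues; input is degenerate")
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    scores = eigvecs * np.sqrt(eigvals)
    # deterministic sign: largest |score| on each axis made positive
    flip = scores[np.abs(scores).argmax(axis=0), np.arange(scores.shape[1])] < 0
    scores[:, flip] *= -1.0
    percents = 100.0 * eigvals / eigvals.sum()
    frame = pd.DataFrame(
        scores,
        index=list(dist.ids),
        columns=[f"pcps{i + 1}" for i in range(scores.shape[1])],
    )
    return OrdinationResult(scores=frame, eigenvalues=eigvals, percents=percents)


def retain_axes(result: OrdinationResult, threshold: float = 0.05) -> OrdinationResult:
    """Mark axes holding more than ``threshold`` (fraction) of variation."""
    if not 0 < threshold <= 1:
        raise OrdinationError("threshold must be a fraction in (0, 1]")
    mask = result.percents > threshold * 100.0
    return replace(result, retained=mask)


def species_axis_correlations(
    P: PhyloWeightedComposition, result: OrdinationResult
) -> pd.DataFrame:
    """Pearson correlation of each species' matrix-P row with each retained axis.

    Species whose weighted incidence does not vary across sites get NaN.
    """
    scores = result.retained_scores()
    X = P.values.loc[:, scores.index].to_numpy()  # species × sites
    Y = scores.to_numpy()  # sites × axes
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=0, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Xc @ Yc) / np.outer(xs, ys)
    # a constant row/column has no defined correlation (range-based test
    # avoids calling centering round-off a signal)
    corr[np.ptp(X, axis=1) == 0, :] = np.nan
    corr[:, np.ptp(Y, axis=0) == 0] = np.nan
    return pd.DataFrame(corr, index=P.species, columns=scores.columns)


def orient_axes(
    result: OrdinationResult, P: PhyloWeightedComposition
) -> OrdinationResult:
    """Fix each retained axis's sign so the species with the largest-
    magnitude correlation correlates positively with it."""
    corr = species_axis_correlations(P, result)
    scores = result.scores.copy()
    for axis in corr.columns:
        col = corr[axis].dropna()
        if col.empty:
            continue
        if col.loc[col.abs().idxmax()] < 0:
            scores[axis] = -scores[axis]
    return replace(result, scores=scores)


def clade_correlations(
    P: PhyloWeightedComposition,
    result: OrdinationResult,
    clade_map: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Species-level axis correlations with clade labels and clade means.

    Returns a tidy table (species, clade, one column per retained axis);
    rows named ``<clade>//mean`` summarize each clade by the mean
    correlation of its member species.
    """
    clades = pd.Series(clade_map)
    corr = species_axis_correlations(P, result)
    table = corr.copy()
    table.insert(0, "clade", clades.reindex(corr.index))
    means = table.groupby("clade").mean(numeric_only=True)
    means.insert(0, "clade", means.index)
    means.index = [f"{c}//mean" for c in means.index]
    return pd.concat([table, means])


def pcps_ordination(
    P: PhyloWeightedComposition,
    dist: DistanceMatrix,
    clade_map: dict[str, str] | pd.Series | None = None,
    threshold: float = 0.05,
) -> OrdinationResult:
    """Full PCPS workflow: PCoA, axis retention, orientation, correlations."""
    result = retain_axes(pcoa(dist), threshold=threshold)
    if result.retained.any():
        result = orient_axes(result, P)
        if clade_map is not None:
            result = replace(
                result, clade_correlations=clade_correlations(P, result, clade_map)
            )
    return result


def scatter_plot(
    result: OrdinationResult,
    groups: pd.Series,
    path,
    axes: tuple[str, str] = ("pcps1", "pcps2"),
) -> None:
    """Scatter of sites on two PCPS axes, colored by group, with clade
    centroids overlaid when clade correlations are available."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    for name, members in groups.groupby(groups):
        sub = result.scores.loc[members.index]
        ax.scatter(sub[x], sub[y], label=name, alpha=0.7, s=25)
    cc = result.clade_correlations
    if cc is not None and {x, y} <= set(cc.columns):
        means = cc[cc.index.str.endswith("//mean")]
        scale = 0.9 * max(
            result.scores[x].abs().max(), result.scores[y].abs().max()
        )
        for _, row in means.iterrows():
            ax.annotate(
                row["clade"],
                (row[x] * scale, row[y] * scale),
                fontsize=10,
                fontweight="bold",
            )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
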