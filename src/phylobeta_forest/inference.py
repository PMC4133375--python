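"""Permutation-based group comparison: ANOVA, PERMANOVA, contrasts, Mantel.

All tests share the same machinery: an observed statistic, a null built
by permuting labels (or one distance matrix's rows+columns, for Mantel),
and the permutation P-value (b + 1) / (B + 1) where b counts null
statistics at least as large as the observed one (ties count as
exceedances).  Permutations are drawn from one seeded generator and are
evaluated in a single vectorized pass, which keeps large calibration
studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix


class InferenceError(ValueError):
    pass


@dataclass
class PermutationTestResult:
    statistic: str  # "F", "pseudo-F"
    observed: float
    p_value: float
    n_perm: int
    df: tuple[int, int]
    r_squared: float | None = None
    null_mean: float | None = None
    contrasts: list["ContrastResult"] = field(default_factory=list)


@dataclass
class ContrastResult:
    group1: str
    group2: str
    observed: float
    p_value: float


@dataclass
class MantelResult:
    rho: float
    p_value: float
    n_perm: int


def _p_value(null: np.ndarray, observed: float) -> float:
    exceed = int(np.sum(null >= observed - 1e-12))
    return (exceed + 1) / (len(null) + 1)


def _group_arrays(groups) -> tuple[np.ndarray, list[str], list[np.ndarray]]:
    labels = np.asarray(pd.Series(groups).astype(str))
    names = sorted(set(labels))
    idx = [np.flatnonzero(labels == g) for g in names]
    return labels, names, idx


# ---------------------------------------------------------------------------
# one-way permutation ANOVA
# ---------------------------------------------------------------------------

def _f_stats(Y: np.ndarray, idx: list[np.ndarray]) -> np.ndarray:
    """Classical one-way F for each row of Y (rows are permuted copies)."""
    n = Y.shape[1]
    g = len(idx)
    grand = Y.mean(axis=1)
    ss_total = ((Y - grand[:, None]) ** 2).sum(axis=1)
    ss_within = np.zeros(Y.shape[0])
    for members in idx:
        sub = Y[:, members]
        ss_within += ((sub - sub.mean(axis=1)[:, None]) ** 2).sum(axis=1)
    ss_between = ss_total - ss_within
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / (g - 1)) / (ss_within / (n - g))
    return np.where(ss_within > 0, F, np.inf)


def perm_anova(
    y,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    contrasts: bool = False,
) -> PermutationTestResult:
    """One-way ANOVA with a label-permutation null."""
    values = np.asarray(y, dtype=float)
    labels, names, idx = _group_arrays(groups)
    if len(values) != len(labels):
        raise InferenceError("response and group vectors differ in length")
    if len(names) < 2 or min(len(i) for i in idx) < 2:
        raise InferenceError("need >= 2 groups with >= 2 sites each")
    if not np.isfinite(values).all():
        raise InferenceError("response contains non-finite values")
    n, g = len(values), len(names)
    observed = float(_f_stats(values[None, :], idx)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    null = _f_stats(values[perms], idx)
    result = PermutationTestResult(
        statistic="F",
        observed=observed,
        p_value=_p_value(null, observed),
        n_perm=n_perm,
        df=(g - 1, n - g),
        null_mean=float(np.mean(null[np.isfinite(null)])) if np.isfinite(null).any() else None,
    )
    if contrasts:
        result.contrasts = pairwise_contrasts(
            values, labels, n_perm=n_perm, seed=seed, kind="anova"
        )
    return result


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(D2: np.ndarray, perms: np.ndarray, idx: list[np.ndarray]):
    """Pseudo-F (and R²) for each permutation row.

    SS_total = Σ_{i<j} d²/N;  SS_within = Σ_g Σ_{i<j∈g} d²/n_g;
    F = (SS_among/(g−1)) / (SS_within/(N−g)).
    """
    n = D2.shape[0]
    g = len(idx)
    ss_total = D2.sum() / (2 * n)
    ss_within = np.zeros(perms.shape[0])
    for members in idx:
        sub = perms[:, members]  # (B, n_g): permuted site indices per group
        ss_within += D2[sub[:, :, None], sub[:, None, :]].sum(axis=(1, 2)) / (
            2 * len(members)
        )
    ss_among = ss_total - ss_within
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_among / (g - 1)) / (ss_within / (n - g))
    F = np.where(ss_within > 0, F, np.inf)
    r2 = ss_among / ss_total
    return F, r2


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    contrasts: bool = False,
) -> PermutationTestResult:
    """One-factor PERMANOVA with unrestricted site-label permutations.

    ``groups`` may be a mapping/Series keyed by the distance matrix ids or
    a plain sequence aligned to them.
    """
    groups = _align_groups(dist, groups)
    labels, names, idx = _group_arrays(groups)
    if len(names) < 2 or min(len(i) for i in idx) < 2:
        raise InferenceError("need >= 2 groups with >= 2 sites each")
    D2 = dist.data**2
    n, g = D2.shape[0], len(names)
    identity = np.arange(n)[None, :]
    observed, r2 = _pseudo_f(D2, identity, idx)
    observed, r2 = float(observed[0]), float(r2[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    null, _ = _pseudo_f(D2, perms, idx)
    result = PermutationTestResult(
        statistic="pseudo-F",
        observed=observed,
        p_value=_p_value(null, observed),
        n_perm=n_perm,
        df=(g - 1, n - g),
        r_squared=r2,
        null_mean=float(np.mean(null[np.isfinite(null)])) if np.isfinite(null).any() else None,
    )
    if contrasts:
        result.contrasts = pairwise_contrasts(
            dist, labels, n_perm=n_perm, seed=seed, kind="permanova"
        )
    return result


def _align_groups(dist: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, (pd.Series, dict)):
        series = pd.Series(groups)
        missing = [i for i in dist.ids if i not in series.index]
        if missing:
            raise InferenceError(f"sites without group label: {missing}")
        return series.reindex(list(dist.ids)).to_numpy()
    groups = np.asarray(groups)
    if len(groups) != len(dist.ids):
        raise InferenceError("group vector length does not match distance matrix")
    return groups


# ---------------------------------------------------------------------------
# pairwise contrasts
# ---------------------------------------------------------------------------

def pairwise_contrasts(
    data,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    kind: str = "permanova",
    p_adjust: str | None = None,
) -> list[ContrastResult]:
    """Re-run the overall test on every two-group subset.

    P-values are raw by default; ``p_adjust='holm'`` applies Holm's
    step-down correction.
    """
    labels = np.asarray(pd.Series(groups).astype(str))
    names = sorted(set(labels))
    results: list[ContrastResult] = []
    for g1, g2 in combinations(names, 2):
        mask = (labels == g1) | (labels == g2)
        sub_groups = labels[mask]
        if kind == "anova":
            sub = np.asarray(data, dtype=float)[mask]
            res = perm_anova(sub, sub_groups, n_perm=n_perm, seed=seed)
        elif kind == "permanova":
            dist: DistanceMatrix = data
            keep = [i for i, m in zip(dist.ids, mask) if m]
            res = permanova(dist.filter(keep), sub_groups, n_perm=n_perm, seed=seed)
        else:
            raise InferenceError(f"unknown contrast kind {kind!r}")
        results.append(
            ContrastResult(group1=g1, group2=g2, observed=res.observed, p_value=res.p_value)
        )
    if p_adjust == "holm":
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adjusted = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * ps[i])
            adjusted[i] = min(1.0, running)
        for r, p in zip(results, adjusted):
            r.p_value = float(p)
    elif p_adjust is not None:
        raise InferenceError(f"unknown p_adjust {p_adjust!r}")
    return results


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test (Pearson correlation of lower triangles, one-sided for
    positive association); the null permutes rows+columns of ``d2``."""
    if set(d1.ids) != set(d2.ids):
        raise InferenceError("distance matrices have different site sets")
    d2 = d2.filter(list(d1.ids))
    n = d1.shape[0]
    tri = np.tril_indices(n, k=-1)
    x = d1.data[tri]
    if x.std() == 0:
        raise InferenceError("first distance matrix has zero variance")
    if d2.data[tri].std() == 0:
        raise InferenceError("second distance matrix has zero variance")

    def corr_with(ymat: np.ndarray) -> np.ndarray:
        y = ymat[..., tri[0], tri[1]]
        xc = x - x.mean()
        yc = y - y.mean(axis=-1, keepdims=True)
        denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum(axis=-1))
        return (yc @ xc) / denom

    observed = float(corr_with(d2.data[None])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    permuted = d2.data[perms[:, :, None], perms[:, None, :]]
    null = corr_with(permuted)
    return MantelResult(
        rho=observed, p_value=_p_value(null, observed), n_perm=n_perm
    )
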