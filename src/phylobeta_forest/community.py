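"""Sites-by-species incidence matrices with optional group labels.

The community matrix holds binary occurrences ``w_ik`` (species *i* in plot
*k*); all downstream metrics in this package are incidence-based.  Group
labels (e.g. forest types) attach one categorical label per site and travel
with the matrix through the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class CommunityError(ValueError):
    """Raised when a community matrix violates its invariants."""


def canonical_name(name: str) -> str:
    """Normalize a taxon label: trim whitespace, spaces -> underscores.

    Newick writers conventionally replace spaces with underscores in
    unquoted labels; treating the two as equivalent lets trees and CSV
    community tables round-trip without quoting games.
    """
    return str(name).strip().replace(" ", "_")


@dataclass
class CommunityMatrix:
    """Binary sites × species incidence matrix with optional site groups.

    Parameters
    ----------
    incidence
        DataFrame indexed by site id with species as columns; values 0/1.
    groups
        Optional Series mapping site id -> group label, aligned to
        ``incidence.index``.
    """

    incidence: pd.DataFrame
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        inc = self.incidence
        inc.index = inc.index.map(canonical_name)
        inc.columns = inc.columns.map(canonical_name)
        if inc.index.duplicated().any():
            dups = inc.index[inc.index.duplicated()].tolist()
            raise CommunityError(f"duplicate site ids: {dups}")
        if inc.columns.duplicated().any():
            dups = inc.columns[inc.columns.duplicated()].tolist()
            raise CommunityError(f"duplicate species names: {dups}")
        values = inc.to_numpy()
        if not np.isfinite(values).all():
            raise CommunityError("incidence matrix contains missing values")
        if (values < 0).any():
            raise CommunityError("incidence values must be nonnegative")
        nonbinary = (values > 0) & (values != 1)
        if nonbinary.any():
            warnings.warn(
                f"{int(nonbinary.sum())} abundance-like values coerced to "
                "presence (1); this package is incidence-only",
                stacklevel=2,
            )
            values = (values > 0).astype(int)
        self.incidence = pd.DataFrame(
            values.astype(int), index=inc.index, columns=inc.columns
        )
        empty = self.incidence.sum(axis=1) == 0
        if empty.any():
            raise CommunityError(
                f"sites with no species: {self.incidence.index[empty].tolist()}"
            )
        if self.groups is not None:
            groups = self.groups.copy()
            groups.index = groups.index.map(canonical_name)
            missing = self.incidence.index.difference(groups.index)
            if len(missing):
                raise CommunityError(f"sites without group label: {missing.tolist()}")
            self.groups = groups.reindex(self.incidence.index).astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def sites(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def n_sites(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_species(self) -> int:
        return self.incidence.shape[1]

    def richness(self) -> pd.Series:
        return self.incidence.sum(axis=1)

    def site_species(self, site: str) -> list[str]:
        row = self.incidence.loc[canonical_name(site)]
        return list(row.index[row > 0])

    def to_array(self) -> np.ndarray:
        return self.incidence.to_numpy()

    # -- alignment -------------------------------------------------------
    def restrict_to(self, species: list[str], prune_missing: bool = False) -> "CommunityMatrix":
        """Align the species set to an external list (e.g. tree tips).

        Species absent from ``species`` are a hard error unless
        ``prune_missing``; pruning that would empty a site is always an
        error.
        """
        keep = [canonical_name(s) for s in species]
        extra = [s for s in self.species if s not in set(keep)]
        if extra:
            if not prune_missing:
                raise CommunityError(
                    f"species not found in the phylogeny: {extra}; "
                    "pass prune_missing=True to drop them"
                )
            warnings.warn(f"pruning {len(extra)} species absent from the tree", stacklevel=2)
        cols = [s for s in self.species if s in set(keep)]
        return CommunityMatrix(self.incidence[cols].copy(), groups=self.groups)


def read_community(path, group_col: str = "group") -> CommunityMatrix:
    """Read a community CSV (first column site id, remaining columns species).

    A column named ``group_col`` (if present) supplies site group labels.
    """
    table = pd.read_csv(path, index_col=0)
    groups = None
    if group_col in table.columns:
        groups = table[group_col].astype(str)
        table = table.drop(columns=[group_col])
    return CommunityMatrix(table.astype(float), groups=groups)


def write_community(community: CommunityMatrix, path, group_col: str = "group") -> None:
    table = community.incidence.copy()
    if community.groups is not None:
        table.insert(0, group_col, community.groups)
    table.to_csv(path)


def read_groups(path, site_col: str | None = None, group_col: str | None = None) -> pd.Series:
    """Read a two-column site -> group CSV."""
    table = pd.read_csv(path)
    site_col = site_col or table.columns[0]
    group_col = group_col or table.columns[1]
    groups = pd.Series(
        table[group_col].astype(str).to_numpy(),
        index=table[site_col].map(canonical_name),
        name="group",
    )
    return groups
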