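import numpy as np
import pandas as pd
import pytest

from phylobeta_forest.community import CommunityMatrix
from phylobeta_forest.synth import _yule_newick
from phylobeta_forest.trees import parse_newick


@pytest.fixture
def small_tree():
    """Three tips, hand-checkable: d(A,B)=2, d(A,C)=d(B,C)=4, total length 5."""
    return parse_newick("((A:1,B:1):1,C:2);")


def random_tree(n_tips: int, rng: np.random.Generator, crown_age: float = 100.0):
    """Random ultrametric Yule tree with tips t1..tn."""
    names = [f"t{i + 1}" for i in range(n_tips)]
    return parse_newick(_yule_newick(names, crown_age, rng) + ";")


def random_community(
    n_sites: int,
    species: list[str],
    rng: np.random.Generator,
    min_rich: int = 2,
    max_rich: int | None = None,
    groups: list[str] | None = None,
) -> CommunityMatrix:
    """Sites assembled by uniform sampling without replacement."""
    max_rich = max_rich or len(species)
    rows = []
    for _ in range(n_sites):
        r = int(rng.integers(min_rich, max_rich + 1))
        chosen = rng.choice(len(species), size=r, replace=False)
        row = np.zeros(len(species), dtype=int)
        row[chosen] = 1
        rows.append(row)
    index = [f"site{i + 1}" for i in range(n_sites)]
    inc = pd.DataFrame(rows, index=index, columns=species)
    gser = pd.Series(groups, index=index) if groups is not None else None
    return CommunityMatrix(inc, groups=gser)


def star_tree(n_tips: int, length: float = 1.0):
    names = ",".join(f"t{i + 1}:{length}" for i in range(n_tips))
    return parse_newick(f"({names});")
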