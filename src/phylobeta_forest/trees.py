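"""Dated phylogenetic trees: newick I/O, patristic distances, node dating.

Trees are held as :class:`dendropy.Tree` objects.  Branch lengths are in
time units (age differences between parent and child nodes); "age" always
means time before present, with extant tips at age 0.  Undated interior
nodes can be filled in by even interpolation between dated nodes
(:func:`bladj_interpolate`), the branch-length-adjustment procedure used
with age-calibrated supertrees.
"""

from __future__ import annotations

from collections import deque
from collections.abc import Mapping

import dendropy
import numpy as np
from skbio import DistanceMatrix

from .community import canonical_name

ROOT_KEY = "root"


class TreeError(ValueError):
    """Raised for malformed or inconsistent phylogenetic trees."""


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string into a validated rooted tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"malformed newick: {exc}") from exc
    validate_tree(tree, require_lengths=False)
    return tree


def read_tree(path) -> dendropy.Tree:
    """Read a newick tree file into a validated rooted tree."""
    with open(path) as handle:
        return parse_newick(handle.read())


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as handle:
        handle.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True).strip() + "\n"


def validate_tree(tree: dendropy.Tree, require_lengths: bool = True) -> None:
    """Check tree invariants: unique tips, nonnegative branch lengths."""
    labels = tip_labels(tree)
    seen: set[str] = set()
    dups = {name for name in labels if name in seen or seen.add(name)}
    if dups:
        raise TreeError(f"duplicate tip names: {sorted(dups)}")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None:
            if require_lengths:
                raise TreeError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else edge.head_node.label}"
                )
        elif edge.length < 0:
            raise TreeError(f"negative branch length: {edge.length}")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [canonical_name(leaf.taxon.label) for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# edge incidence and patristic distances
# ---------------------------------------------------------------------------

def edge_incidence(tree: dendropy.Tree) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Tips × edges incidence of root-to-tip paths, with edge lengths.

    Returns ``(labels, A, lengths)`` where ``A[t, e]`` is True when edge
    *e* lies on the path from tip *t* to the root.  Every non-root edge of
    the tree appears exactly once.  This single structure drives Faith's
    PD, UniFrac and patristic distances.
    """
    validate_tree(tree, require_lengths=True)
    leaves = list(tree.leaf_node_iter())
    labels = [canonical_name(leaf.taxon.label) for leaf in leaves]
    edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
    lengths = np.array([e.length for e in edges], dtype=float)
    edge_index = {id(e): i for i, e in enumerate(edges)}
    A = np.zeros((len(leaves), len(edges)), dtype=bool)
    for t, leaf in enumerate(leaves):
        node = leaf
        while node.parent_node is not None:
            A[t, edge_index[id(node.edge)]] = True
            node = node.parent_node
    return labels, A, lengths


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs patristic distances (path-length sums between tips)."""
    labels, A, lengths = edge_incidence(tree)
    depth = A @ lengths  # root-to-tip path length per tip
    shared = (A * lengths) @ A.T  # shared path length of each tip pair
    d = depth[:, None] + depth[None, :] - 2.0 * shared
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # exact symmetry
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# node ages and BLADJ-style interpolation
# ---------------------------------------------------------------------------

def node_ages(tree: dendropy.Tree) -> dict[str, float]:
    """Ages (max distance to a descendant tip) of labelled interior nodes."""
    ages: dict[str, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._pf_age = 0.0
            continue
        node._pf_age = max(
            child._pf_age + (child.edge.length or 0.0) for child in node.child_nodes()
        )
        if node.label:
            ages[canonical_name(node.label)] = node._pf_age
    return ages


def bladj_interpolate(
    tree: dendropy.Tree, fixed_ages: Mapping[str, float]
) -> dendropy.Tree:
    """Date a tree by even interpolation between age-calibrated nodes.

    ``fixed_ages`` maps interior-node labels (or the key ``"root"``) to
    ages in time before present; tips are pinned at age 0.  Every undated
    interior node receives the age obtained by spacing nodes evenly along
    the path between its nearest dated ancestor and its nearest dated
    descendant (fewest intervening nodes; ties resolved toward the oldest
    candidate).  Branch lengths are then recomputed as parent-minus-child
    age differences.  Dated nodes are never moved, so the procedure is
    idempotent.
    """
    fixed = {canonical_name(k): float(v) for k, v in fixed_ages.items()}
    out = tree.clone(depth=1)
    nodes = list(out.preorder_node_iter())
    root = out.seed_node

    def fixed_age_of(node) -> float | None:
        if node.is_leaf():
            return 0.0
        label = canonical_name(node.label) if node.label else None
        if label and label in fixed:
            return fixed[label]
        if node is root and ROOT_KEY in fixed:
            return fixed[ROOT_KEY]
        return None

    anchors = {id(n): fixed_age_of(n) for n in nodes}
    if anchors[id(root)] is None:
        raise TreeError("the root must carry a fixed age")

    # consistency: nearest dated ancestor must be at least as old
    for node in nodes:
        age = anchors[id(node)]
        if age is None or node is root:
            continue
        parent = node.parent_node
        while anchors[id(parent)] is None:
            parent = parent.parent_node
        if anchors[id(parent)] < age - 1e-9:
            raise TreeError(
                f"fixed age {age} exceeds nearest dated ancestor age "
                f"{anchors[id(parent)]}"
            )

    def nearest_dated_below(node) -> tuple[int, float]:
        """(steps, age) of the closest dated descendant; oldest on ties."""
        queue = deque((child, 1) for child in node.child_nodes())
        best: tuple[int, float] | None = None
        while queue:
            current, steps = queue.popleft()
            if best is not None and steps > best[0]:
                break
            age = anchors[id(current)]
            if age is not None:
                if best is None or (steps == best[0] and age > best[1]):
                    best = (steps, age)
                continue
            queue.extend((child, steps + 1) for child in current.child_nodes())
        assert best is not None  # tips are always dated
        return best

    resolved: dict[int, float] = {}
    for node in nodes:
        if anchors[id(node)] is not None:
            resolved[id(node)] = anchors[id(node)]
            continue
        steps_up, parent = 1, node.parent_node
        while anchors[id(parent)] is None:
            parent = parent.parent_node
            steps_up += 1
        upper = anchors[id(parent)]
        steps_down, lower = nearest_dated_below(node)
        resolved[id(node)] = upper - (upper - lower) * steps_up / (steps_up + steps_down)

    for node in nodes:
        node.age = resolved[id(node)]
        if node.parent_node is not None:
            length = resolved[id(node.parent_node)] - resolved[id(node)]
            if length < -1e-9:
                raise TreeError("interpolated ages imply a negative branch length")
            node.edge.length = max(length, 0.0)
    return out
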