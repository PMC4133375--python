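"""Independent brute-force oracles used to check the library.

Everything here is written as plainly as possible — explicit loops over
species pairs and tree traversals via dendropy node walking — and shares
no code with the implementations under test.
"""

from __future__ import annotations

import numpy as np


def _tip_nodes(tree, names):
    by_label = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    return [by_label[n] for n in names]


def _path_edges(leaf):
    """Edges from a tip up to the root, as id()s paired with lengths."""
    edges = []
    node = leaf
    while node.parent_node is not None:
        edges.append((id(node.edge), node.edge.length))
        node = node.parent_node
    return edges


def pd_oracle(tree, site) -> float:
    """Faith's PD: mark tip-to-root path edges, sum unique edges."""
    seen = {}
    for leaf in _tip_nodes(tree, list(site)):
        for key, length in _path_edges(leaf):
            seen[key] = length
    return float(sum(seen.values()))


def patristic_oracle(tree):
    """All-pairs patristic distances via symmetric-difference of paths."""
    leaves = list(tree.leaf_node_iter())
    names = [leaf.taxon.label for leaf in leaves]
    paths = {leaf.taxon.label: dict(_path_edges(leaf)) for leaf in leaves}
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = paths[names[i]], paths[names[j]]
            total = 0.0
            for key, length in pi.items():
                if key not in pj:
                    total += length
            for key, length in pj.items():
                if key not in pi:
                    total += length
            D[i, j] = D[j, i] = total
    return names, D


def mpd_oracle(D: np.ndarray, idx) -> float:
    pairs = []
    for i in idx:
        for j in idx:
            if i < j:
                pairs.append(D[i, j])
    return float(np.mean(pairs))


def mntd_oracle(D: np.ndarray, idx) -> float:
    minima = []
    for i in idx:
        best = np.inf
        for j in idx:
            if j != i and D[i, j] < best:
                best = D[i, j]
        minima.append(best)
    return float(np.mean(minima))


def comdist_oracle(D: np.ndarray, idx1, idx2) -> float:
    values = [D[i, j] for i in idx1 for j in idx2]
    return float(np.mean(values))


def comdistnt_oracle(D: np.ndarray, idx1, idx2) -> float:
    a = [min(D[i, j] for j in idx2) for i in idx1]
    b = [min(D[i, j] for i in idx1) for j in idx2]
    return 0.5 * (float(np.mean(a)) + float(np.mean(b)))


def rao_between_oracle(D: np.ndarray, idx1, idx2) -> float:
    """Between-plot Rao's quadratic entropy with uniform incidence weights."""
    p1 = np.zeros(D.shape[0])
    p2 = np.zeros(D.shape[0])
    p1[list(idx1)] = 1.0 / len(idx1)
    p2[list(idx2)] = 1.0 / len(idx2)
    total = 0.0
    for i in range(D.shape[0]):
        for j in range(D.shape[0]):
            total += p1[i] * p2[j] * D[i, j]
    return float(total)


def rao_h_oracle(D: np.ndarray, idx1, idx2) -> float:
    between = rao_between_oracle(D, idx1, idx2)
    within1 = rao_between_oracle(D, idx1, idx1)
    within2 = rao_between_oracle(D, idx2, idx2)
    return between / (0.5 * (within1 + within2))


def unifrac_oracle(tree, site1, site2) -> float:
    """Classify every edge of the union spanning subtree by which sites'
    tips sit below it."""
    set1, set2 = set(site1), set(site2)
    shared = 0.0
    exclusive = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        in1 = bool(below & set1)
        in2 = bool(below & set2)
        if in1 and in2:
            shared += node.edge.length
        elif in1 or in2:
            exclusive += node.edge.length
    total = shared + exclusive
    return exclusive / total if total > 0 else 0.0


def jaccard_oracle(site1, site2) -> float:
    a, b = set(site1), set(site2)
    return 1.0 - len(a & b) / len(a | b)


def braycurtis_sqrt_oracle(x: np.ndarray, y: np.ndarray) -> float:
    num = float(np.abs(x - y).sum())
    den = float((x + y).sum())
    return float(np.sqrt(num / den))


def matrix_p_oracle(W: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Matrix P by the definition: per plot, renormalize similarities over
    the plot's species and spread each member's incidence."""
    n_sites, S = W.shape
    P = np.zeros((S, n_sites))
    for k in range(n_sites):
        members = [j for j in range(S) if W[k, j] > 0]
        for i in members:
            denom = sum(s[i, l] for l in members)
            for j in members:
                P[j, k] += W[k, i] * s[i, j] / denom
    return P
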