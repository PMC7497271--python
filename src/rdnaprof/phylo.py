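"""Jukes-Cantor distances, neighbour joining and tree-based assignment.

Distances use the Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3) on the
pairwise mismatch fraction p, with pairwise deletion of gap/N columns and
saturation (p >= 0.75) mapped to a configured maximum.  Trees are built
with Saitou-Nei neighbour joining under the Studier-Keppler Q criterion,
with deterministic label-order tie-breaks and negative branch lengths
clamped to zero.  Bootstrap support resamples alignment columns with
replacement and counts bipartition recovery over replicates.  Trees are
:class:`skbio.TreeNode` objects, so Newick round-trips come for free.
"""

from __future__ import annotations

import math

import numpy as np
from skbio import DistanceMatrix, TreeNode

#: Distance assigned when the mismatch fraction saturates the JC model.
MAX_JC_DISTANCE = 5.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def jc_distance(seq_a: str, seq_b: str, max_distance: float = MAX_JC_DISTANCE) -> float:
    """Jukes-Cantor distance between two equal-length sequences.

    Columns where either sequence has a gap or ambiguous base are excluded
    pairwise.  Raises if no comparable columns remain; returns
    ``max_distance`` when p >= 0.75 (the correction is undefined there).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    comparable = 0
    mismatches = 0
    for a, b in zip(seq_a, seq_b):
        if a not in _CODE or b not in _CODE:
            continue
        comparable += 1
        if a != b:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable columns between sequences")
    p = mismatches / comparable
    if p >= 0.75:
        return max_distance
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def jc_distance_matrix(
    sequences: list[str],
    labels: list[str],
    max_distance: float = MAX_JC_DISTANCE,
) -> DistanceMatrix:
    """Vectorised all-pairs JC distances with pairwise deletion."""
    if len(sequences) != len(labels):
        raise ValueError("labels/sequences length mismatch")
    n = len(sequences)
    length = len(sequences[0])
    arr = np.full((n, length), -1, dtype=np.int8)
    for i, seq in enumerate(sequences):
        if len(seq) != length:
            raise ValueError("sequences must have equal length")
        for j, base in enumerate(seq):
            arr[i, j] = _CODE.get(base, -1)
    valid = arr >= 0
    both = valid[:, None, :] & valid[None, :, :]
    comparable = both.sum(axis=2)
    mismatch = (both & (arr[:, None, :] != arr[None, :, :])).sum(axis=2)
    if np.any((comparable == 0) & ~np.eye(n, dtype=bool)):
        raise ValueError("a sequence pair has no comparable columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(comparable > 0, mismatch / np.maximum(comparable, 1), 0.0)
        d = np.where(p >= 0.75, max_distance, -0.75 * np.log1p(-4.0 * p / 3.0))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=labels)


def _tip(name: str) -> TreeNode:
    node = TreeNode(name=name)
    node.sort_key = name
    return node


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining with the Studier-Keppler Q criterion.

    Requires >= 3 taxa.  Ties in Q resolve to the lexicographically
    smallest (sorted) label pair; internal nodes inherit the smallest leaf
    label beneath them as their sort key.  Negative branch lengths are
    clamped to zero and flagged on the returned tree
    (``tree.negative_lengths_clamped``).
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes = [_tip(name) for name in dm.ids]
    clamped = False

    def clamp(value: float) -> float:
        nonlocal clamped
        if value < 0:
            clamped = True
            return 0.0
        return value

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        candidates = np.argwhere(np.isclose(Q, qmin))
        best = min(
            (tuple(sorted((nodes[i].sort_key, nodes[j].sort_key))), i, j)
            for i, j in candidates if i < j
        )
        _, i, j = best
        dij = D[i, j]
        vi = clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        vj = clamp(dij - (0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))))
        parent = TreeNode()
        parent.sort_key = min(nodes[i].sort_key, nodes[j].sort_key)
        nodes[i].length = vi
        nodes[j].length = vj
        parent.extend([nodes[i], nodes[j]])
        new_row = 0.5 * (D[i] + D[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = new_row[keep]
        D_new[:-1, -1] = new_row[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three nodes with the three-point formulas
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp(0.5 * (dab + dac - dbc))
    b.length = clamp(0.5 * (dab + dbc - dac))
    c.length = clamp(0.5 * (dac + dbc - dab))
    root = TreeNode()
    root.extend([a, b, c])
    root.negative_lengths_clamped = clamped
    return root


def _bipartitions(tree: TreeNode) -> dict:
    """Map canonical bipartition -> internal node (non-trivial edges only)."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            other = all_leaves - side
            key = min(tuple(sorted(side)), tuple(sorted(other)))
            out[key] = node
    return out


def bootstrap_support(
    alignment: list[tuple[str, str]],
    n_replicates: int = 100,
    seed: int = 0,
    builder=None,
) -> TreeNode:
    """NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_replicates`` times; each
    replicate tree is rebuilt with the same JC + NJ pipeline (or a custom
    ``builder(labels, sequences) -> TreeNode``), and each internal edge of
    the original tree is annotated with the percentage of replicates that
    recover its bipartition (``node.support``, in [0, 100]).
    """
    labels = [name for name, _ in alignment]
    sequences = [seq for _, seq in alignment]
    if builder is None:
        def builder(lbls, seqs):
            return nj_tree(jc_distance_matrix(seqs, lbls))

    tree = builder(labels, sequences)
    target = _bipartitions(tree)
    hits = {key: 0 for key in target}
    length = len(sequences[0])
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = ["".join(seq[c] for c in cols) for seq in sequences]
        replicate = builder(labels, resampled)
        for key in _bipartitions(replicate):
            if key in hits:
                hits[key] += 1
    for key, node in target.items():
        node.support = 100.0 * hits[key] / n_replicates
    return tree


def write_newick(tree: TreeNode, path) -> None:
    """Newick with bootstrap supports as internal node labels."""
    clone = tree.copy()
    for node in clone.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None:
            node.name = f"{support:g}"
            node.support = None  # avoid skbio folding it into the label too
    clone.write(str(path), format="newick")


def branch_assign(
    tree: TreeNode, reference_leaf_d: str, reference_leaf_s: str
) -> dict[str, str]:
    """Assign every leaf to the D or S side of the inter-family edge.

    The cut edge is chosen on the path between the two reference leaves as
    the edge with the greatest branch length (ties resolve towards the D
    reference); removing it splits the leaf set into the D-side and S-side
    subtrees.  Raises if a reference leaf is absent or the references are
    not separable.
    """
    try:
        node_d = tree.find(reference_leaf_d)
        node_s = tree.find(reference_leaf_s)
    except Exception as exc:  # skbio raises MissingNodeError
        raise ValueError(f"reference leaf not found: {exc}") from exc
    if node_d is node_s:
        raise ValueError("reference leaves are identical")

    lca = tree.lowest_common_ancestor([node_d, node_s])
    path = []
    for start in (node_d, node_s):
        node = start
        while node is not lca:
            path.append(node)  # edge (node, node.parent)
            node = node.parent
    if not path:
        raise ValueError("reference leaves are not separable")

    best = max(
        path,
        key=lambda nd: ((nd.length or 0.0),
                        1 if nd in (node_d, *node_d.ancestors()) else 0),
    )
    d_side = frozenset(leaf.name for leaf in best.tips(include_self=True))
    if reference_leaf_d not in d_side:
        d_side = frozenset(l.name for l in tree.tips()) - d_side
    return {
        leaf.name: ("D" if leaf.name in d_side else "S") for leaf in tree.tips()
    }
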