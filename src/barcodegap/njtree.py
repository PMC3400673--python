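"""Neighbour-joining trees, midpoint rooting and tree queries.

The tree container is scikit-bio's ``TreeNode`` (newick I/O, LCA and tip-tip
distances come from there).  The NJ agglomeration and midpoint rooting are
implemented here so their conventions are pinned and deterministic:

* Q-criterion ties are broken by the smallest (i, j) index pair;
* negative NJ branch lengths are clamped to zero with the deficit moved to
  the sister branch, preserving the joined pair's distance;
* ties for the tree diameter are broken by the lexicographically smallest
  leaf-name pair.

NJ is exact on additive matrices: leaf-to-leaf path lengths then reproduce
the input distances, which is the main correctness property the tests use.
"""

from __future__ import annotations

import io
import logging

import numpy as np

from skbio import TreeNode

from .k2p import DistanceMatrix

logger = logging.getLogger("barcodegap")


class PhyloTree:
    """A phylogenetic tree with branch lengths, unrooted (NJ output) or rooted."""

    def __init__(self, tree: TreeNode, rooted: bool = False):
        self.tree = tree
        self.rooted = rooted

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        tree = TreeNode.read(io.StringIO(newick), convert_underscores=False)
        if rooted is None:
            rooted = len(tree.children) == 2
        return cls(tree, rooted=rooted)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue().strip()

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.copy(), rooted=self.rooted)

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {len(list(self.tree.tips()))} tips>"


def _fmt(x: float) -> str:
    return f"{max(x, 0.0):.12g}"


def neighbor_joining(m: DistanceMatrix, impute: bool = False) -> PhyloTree:
    """Saitou–Nei neighbour joining on a K2P distance matrix.

    The matrix must be complete; with ``impute=True`` missing pairs are filled
    with the largest finite distance (a conservative placement), otherwise
    they are an error listing the offending pairs.  Returns an unrooted tree
    whose deepest node is the final trifurcation.
    """
    n = len(m.ids)
    if n < 3:
        raise ValueError(f"neighbour joining needs at least 3 taxa, got {n}")
    D = m.d.copy()
    if np.isnan(D).any():
        if not impute:
            pairs = [(m.ids[i], m.ids[j]) for (i, j) in sorted(m.flags)]
            raise ValueError(f"distance matrix has missing pairs: {pairs}")
        fill = np.nanmax(D)
        logger.warning("imputing %d missing pairs with max distance %.4f", m.n_missing, fill)
        D = np.where(np.isnan(D), fill, D)
        np.fill_diagonal(D, 0.0)

    # each active node is a newick fragment (no trailing length)
    nodes = [name for name in m.ids]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        Q[np.tril_indices(k)] = np.inf
        # row-major argmin picks the smallest (i, j) among ties
        i_loc, j_loc = np.unravel_index(np.argmin(Q), Q.shape)
        dij = sub[i_loc, j_loc]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (k - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0

        gi, gj = active[i_loc], active[j_loc]
        merged = f"({nodes[gi]}:{_fmt(li)},{nodes[gj]}:{_fmt(lj)})"
        # distances from the new node to the remaining ones
        new_row = np.full(D.shape[0] + 1, 0.0)
        for a_loc, g in enumerate(active):
            if g in (gi, gj):
                continue
            new_row[g] = 0.5 * (sub[i_loc, a_loc] + sub[j_loc, a_loc] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(merged)
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    # resolve the last three nodes around a central trifurcation
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    la = max(0.5 * (dab + dac - dbc), 0.0)
    lb = max(0.5 * (dab + dbc - dac), 0.0)
    lc = max(0.5 * (dac + dbc - dab), 0.0)
    newick = f"({nodes[a]}:{_fmt(la)},{nodes[b]}:{_fmt(lb)},{nodes[c]}:{_fmt(lc)});"
    return PhyloTree.from_newick(newick, rooted=False)


def midpoint_root(t: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    The two farthest leaves end up equidistant from the root; ties for the
    diameter pair are broken by the lexicographically smallest name pair.  A
    tree whose branch lengths are all zero is rooted on the first tip's branch
    with a warning.
    """
    tree = t.tree.copy()
    dm = tree.tip_tip_distances()
    names = list(dm.ids)
    data = dm.data
    dmax = float(data.max())
    if dmax <= 0.0:
        logger.warning("all-zero branch lengths; midpoint root placed arbitrarily")
        first = min(names)
        rooted = tree.root_at(tree.find(first), above=0.0)
        return PhyloTree(rooted, rooted=True)

    pairs = [
        tuple(sorted((names[i], names[j])))
        for i, j in zip(*np.nonzero(data == dmax))
        if i < j
    ]
    a_name, b_name = min(pairs)
    half = dmax / 2.0

    a, b = tree.find(a_name), tree.find(b_name)
    lca = tree.lca([a, b])

    def _walk(start) -> tuple[TreeNode, float] | None:
        cum = 0.0
        node = start
        while node is not lca:
            length = node.length or 0.0
            if cum + length >= half - 1e-12:
                return node, min(half - cum, length)
            cum += length
            node = node.parent
        return None

    placed = _walk(a)
    if placed is None:
        # midpoint lies on b's side of the LCA
        half = dmax - half
        placed = _walk(b)
        assert placed is not None, "midpoint not found on either side"
    node, above = placed
    rooted = tree.root_at(node, above=above)
    return PhyloTree(rooted, rooted=True)


def is_exclusive(t: PhyloTree, ids: set[str]) -> bool:
    """True iff the smallest clade containing *ids* contains no other leaf.

    Requires a rooted tree (clades are only defined with a root).
    """
    if not t.rooted:
        raise ValueError("exclusivity is defined on a rooted tree")
    leaves = set(t.tip_names())
    unknown = set(ids) - leaves
    if unknown:
        raise KeyError(f"unknown leaf ids: {sorted(unknown)}")
    if not ids:
        raise ValueError("empty id set")
    if len(ids) == 1:
        return True
    lca = t.tree.lca(sorted(ids))
    return {tip.name for tip in lca.tips()} == set(ids)


def patristic_matrix(
    t: PhyloTree, collapse: dict[str, str] | None = None
) -> DistanceMatrix:
    """Patristic (path-length) distances, optionally collapsed to lineages.

    *collapse* maps leaf id -> lineage label; the distance between two
    lineages is the mean path length over all cross-lineage leaf pairs.
    Without *collapse*, the leaf-level matrix is returned.  The ``sites``
    field carries the number of leaf pairs behind each entry.
    """
    dm = t.tree.tip_tip_distances()
    names = list(dm.ids)
    data = dm.data
    if collapse is None:
        sites = np.ones_like(data, dtype=np.int64)
        np.fill_diagonal(sites, 0)
        return DistanceMatrix(ids=names, d=data.copy(), sites=sites, flags={})

    unknown = set(collapse) - set(names)
    if unknown:
        raise KeyError(f"collapse refers to unknown leaves: {sorted(unknown)}")
    lineages = sorted(set(collapse.values()))
    members = {lin: [names.index(l) for l in sorted(collapse) if collapse[l] == lin]
               for lin in lineages}
    for lin, idx in members.items():
        if not idx:
            raise ValueError(f"lineage {lin!r} has no leaves")
    k = len(lineages)
    out = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            block = data[np.ix_(members[lineages[i]], members[lineages[j]])]
            out[i, j] = out[j, i] = float(block.mean())
            counts[i, j] = counts[j, i] = block.size
    return DistanceMatrix(ids=lineages, d=out, sites=counts, flags={})
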