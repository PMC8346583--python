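"""Neighbor-joining trees, outgroup rooting, and species-monophyly tests.

This is a distance-tree stand-in for full Bayesian phylogenetic inference:
topology and branch lengths come from the Saitou–Nei neighbor-joining
agglomeration on a complete K2P distance matrix, the tree is rooted on a
declared outgroup, and each species is tested for monophyly (does some node
of the rooted tree subtend exactly that species' specimens?).  No support
values are computed; reports label these trees as an NJ surrogate.

Trees are ``skbio.TreeNode`` objects, so newick round-tripping, rooting and
topology comparison come from scikit-bio.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from skbio import TreeNode
from skbio.tree import TreeError

from .exceptions import TopologyError, UsageError
from .k2p import DistanceMatrix
from .seqio import SpecimenRecord

logger = logging.getLogger("barcodegap")


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Build an unrooted NJ tree from a complete distance matrix.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - R_i - R_j is
    joined (ties broken by the smallest (row, column) index pair in the
    current label order, so runs are reproducible).  Negative branch lengths
    are clamped to zero with the deficit logged.  The returned tree's root
    is the usual degree-3 basal node of an unrooted NJ tree.
    """
    if not matrix.is_complete:
        raise UsageError(
            "distance matrix has undefined (NA) entries; raise min_sites "
            "coverage or exclude the affected specimens before tree building"
        )
    n = len(matrix)
    if n < 3:
        raise UsageError(f"neighbor joining needs >=3 taxa, got {n}")

    d = matrix.data.copy()
    nodes = [TreeNode(name=lab) for lab in matrix.labels]

    def clamp(x: float, context: str) -> float:
        if x < 0:
            logger.warning("negative NJ branch length %.3g at %s clamped to 0", x, context)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (row, col) among minima: argmin scans row-major, which is
        # exactly lexicographic (i, j) order
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length = clamp(li, f"join({i},{j})")
        b.length = clamp(lj, f"join({i},{j})")
        parent.extend([a, b])
        # distances from the new node to every remaining cluster
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]

    # connect the last three clusters to a single basal node
    root = TreeNode()
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    lens = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02), 0.5 * (d02 + d12 - d01)]
    for node, length in zip(nodes, lens):
        node.length = clamp(length, "final-join")
        root.append(node)
    return root


def root_with_outgroup(tree: TreeNode, outgroup: str | list[str] | set[str]) -> TreeNode:
    """Root the tree on the edge separating the outgroup from everything else.

    The branch carrying the outgroup is split equally to place the root.
    The outgroup must sit on one side of a single edge.
    """
    names = [outgroup] if isinstance(outgroup, str) else sorted(outgroup)
    tips = {t.name for t in tree.tips()}
    missing = [nm for nm in names if nm not in tips]
    if missing:
        raise UsageError(f"outgroup leaves not in tree: {missing}")
    if len(names) >= len(tips):
        raise UsageError("outgroup cannot contain every leaf")
    try:
        return tree.root_by_outgroup(names)
    except TreeError as exc:
        raise TopologyError(
            f"outgroup {names} is not separable by a single edge: {exc}"
        ) from exc


def is_rooted(tree: TreeNode) -> bool:
    return len(tree.children) == 2


def species_monophyly(
    tree: TreeNode,
    metadata: dict[str, SpecimenRecord],
) -> dict[str, bool]:
    """Test every (non-outgroup) species for monophyly on a rooted tree.

    A species is monophyletic when some node's descendant-leaf set equals
    exactly that species' leaf set; singleton species are trivially
    monophyletic.
    """
    if not is_rooted(tree):
        raise UsageError("species_monophyly requires a rooted (bifurcating-root) tree")
    leaf_species: dict[str, set[str]] = {}
    for tip in tree.tips():
        if tip.name not in metadata:
            raise UsageError(f"leaf {tip.name!r} has no metadata entry")
        rec = metadata[tip.name]
        if rec.status == "outgroup":
            continue
        leaf_species.setdefault(rec.species, set()).add(tip.name)

    clades: set[frozenset[str]] = set()
    for node in tree.postorder():
        clades.add(frozenset(t.name for t in node.tips(include_self=True)))

    return {sp: frozenset(leaves) in clades for sp, leaves in leaf_species.items()}


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_monophyly_report(
    monophyly: dict[str, bool],
    metadata: dict[str, SpecimenRecord],
    path: str | Path,
) -> None:
    """TSV report: species, number of leaves, monophyletic yes/no."""
    counts: dict[str, int] = {}
    for rec in metadata.values():
        if rec.status != "outgroup":
            counts[rec.species] = counts.get(rec.species, 0) + 1
    with open(path, "w") as fh:
        fh.write("species\tn_leaves\tmonophyletic\n")
        for sp in sorted(monophyly):
            fh.write(f"{sp}\t{counts.get(sp, 0)}\t{'yes' if monophyly[sp] else 'no'}\n")
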