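"""Phylogenetic utilities: Brownian-motion covariance and tree surgery.

Trees are :class:`dendropy.Tree` objects throughout.  Branch lengths are in
Ma; a time-calibrated (ultrametric) tree yields the usual Brownian-motion
covariance in which the shared variance of two tips equals the age of their
most recent common ancestor measured from the root.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "UnrootedTreeError",
    "bm_covariance",
    "expand_conspecific_tips",
    "is_ultrametric",
    "read_newick",
    "tip_depths",
    "write_newick",
]


class UnrootedTreeError(ValueError):
    """Raised when an operation requiring a rooted tree receives an unrooted one."""


def read_newick(path_or_string: str, *, from_string: bool = False) -> dendropy.Tree:
    """Read a rooted Newick tree (``[&R]`` hint honoured, default rooted)."""
    kwargs = dict(schema="newick", rooting="default-rooted")
    if from_string:
        return dendropy.Tree.get(data=path_or_string, **kwargs)
    return dendropy.Tree.get(path=path_or_string, **kwargs)


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick")


def _require_rooted(tree: dendropy.Tree) -> None:
    if tree.is_rooted is False:
        raise UnrootedTreeError("operation requires a rooted tree")


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every leaf, keyed by taxon label."""
    _require_rooted(tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-9) -> bool:
    depths = np.array(list(tip_depths(tree).values()))
    span = depths.max() - depths.min()
    return bool(span <= rel_tol * max(depths.max(), 1.0))


def bm_covariance(
    tree: dendropy.Tree, taxa: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance matrix implied by a rooted tree.

    ``C[i, j]`` is the root-to-MRCA path length of tips *i* and *j*; the
    diagonal holds root-to-tip depths.  Returns the matrix together with the
    tip-label order used.  If *taxa* is given the matrix rows/columns follow
    that order (all labels must be tips of the tree).
    """
    _require_rooted(tree)
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("tip labels are not unique")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    for lf in leaves:
        C[index[lf.taxon.label], index[lf.taxon.label]] = lf.root_distance

    # every internal node contributes its depth as the covariance of tip
    # pairs split across its children
    for node in tree.preorder_internal_node_iter():
        depth = node.root_distance
        child_leafsets = [
            [index[l.taxon.label] for l in ch.leaf_iter()] for ch in node.child_nodes()
        ]
        for a in range(len(child_leafsets)):
            for b in range(a + 1, len(child_leafsets)):
                for i in child_leafsets[a]:
                    for j in child_leafsets[b]:
                        C[i, j] = C[j, i] = depth

    if taxa is not None:
        missing = [t for t in taxa if t not in index]
        if missing:
            raise KeyError(f"labels not on tree: {missing}")
        order = [index[t] for t in taxa]
        C = C[np.ix_(order, order)]
        labels = list(taxa)
    return C, labels


def expand_conspecific_tips(
    tree: dendropy.Tree,
    specimens: Mapping[str, Sequence[str]],
    pendant_length: float = 1.0,
) -> dendropy.Tree:
    """Replace multi-specimen species tips by 1-Ma specimen polytomies.

    Each species in *specimens* with two or more specimen ids has its tip
    replaced by an internal node carrying one pendant branch of
    *pendant_length* (Ma) per specimen; the stem is shortened by the same
    amount so root-to-tip depths — and hence ultrametricity — are preserved.
    Species with a single listed specimen are renamed to that specimen id.
    """
    _require_rooted(tree)
    tree = tree.clone(depth=1)
    ns = tree.taxon_namespace
    for leaf in list(tree.leaf_node_iter()):
        label = leaf.taxon.label
        if label not in specimens:
            continue
        ids = list(specimens[label])
        if len(ids) == 1:
            leaf.taxon = ns.new_taxon(label=ids[0])
            continue
        if leaf.edge.length is None or leaf.edge.length <= pendant_length:
            raise ValueError(
                f"terminal branch of {label!r} ({leaf.edge.length}) must exceed "
                f"the pendant length {pendant_length}"
            )
        leaf.edge.length -= pendant_length
        leaf.taxon = None
        for sid in ids:
            child = dendropy.Node(edge_length=pendant_length)
            child.taxon = ns.new_taxon(label=sid)
            leaf.add_child(child)
    tree.update_taxon_namespace()
    return tree
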