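"""Phylogenetic variance-covariance matrices from Newick trees.

Under Brownian-motion evolution the expected trait covariance between two
species equals the total branch length they share on the path from the
root, so ``C[i, j]`` is the root-to-MRCA distance of tips *i* and *j* and
the diagonal holds root-to-tip distances. ``C_corr`` rescales ``C`` to
unit diagonal and is the correlation matrix used as the phylogenetic
random-effect structure in the structural equations.

A root edge length, when present, is shared by every tip and is included;
this makes pruning commute exactly with row/column subsetting of ``C``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloCovariance",
    "read_newick",
    "parse_newick",
    "vcv_from_tree",
    "prune_to_species",
    "tip_labels",
    "write_vcv_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class PhyloCovariance:
    """Species-level phylogenetic (co)variance and correlation matrices."""

    species: list[str]
    C: np.ndarray
    C_corr: np.ndarray

    def index_of(self, names: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.species)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise KeyError(f"species not in covariance matrix: {missing}")
        return np.array([pos[n] for n in names], dtype=int)

    def subset(self, names: list[str]) -> "PhyloCovariance":
        idx = self.index_of(names)
        return PhyloCovariance(
            species=list(names),
            C=self.C[np.ix_(idx, idx)].copy(),
            C_corr=self.C_corr[np.ix_(idx, idx)].copy(),
        )


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise ValueError("tree has unlabelled tip(s)")
    dupes = sorted({lbl for lbl in labels if labels.count(lbl) > 1})
    if dupes:
        raise ValueError(f"duplicate tip label(s): {dupes}")
    offenders = []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge may legitimately be None
        if edge.length is None:
            offenders.append(edge.head_node.taxon.label if edge.head_node.taxon else "<internal>")
        elif edge.length < 0:
            raise ValueError("negative branch length in tree")
    if offenders:
        raise ValueError(f"edges without branch lengths leading to: {offenders}")


def _normalize_labels(tree: dendropy.Tree, underscores_to_spaces: bool) -> None:
    for taxon in tree.taxon_namespace:
        if underscores_to_spaces:
            taxon.label = taxon.label.replace("_", " ")
        else:
            taxon.label = taxon.label.replace(" ", "_")


def parse_newick(newick: str, underscores_to_spaces: bool = False) -> dendropy.Tree:
    """Parse a Newick string into a validated rooted tree."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"could not parse Newick: {exc}") from exc
    _normalize_labels(tree, underscores_to_spaces)
    _validate_tree(tree)
    return tree


def read_newick(path, underscores_to_spaces: bool = False) -> dendropy.Tree:
    """Read a Newick file into a validated rooted tree."""
    with open(path) as fh:
        return parse_newick(fh.read(), underscores_to_spaces)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def vcv_from_tree(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion VCV: shared root-to-tip path length per tip pair.

    ``C_corr = D^{-1/2} C D^{-1/2}`` with ``D = diag(C)``. Non-ultrametric
    trees are accepted with a warning (the scaling is still defined).
    """
    _validate_tree(tree)
    root = tree.seed_node
    root_edge = root.edge.length or 0.0

    # depth of each node from the root (excluding the root edge)
    depth: dict[dendropy.Node, float] = {root: 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    pos = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    # C[i, j] = depth(MRCA(i, j)); fill via postorder leaf-set accumulation
    leafsets: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = pos[node]
            C[i, i] = depth[node]
            leafsets[node] = [i]
        else:
            children = [leafsets[ch] for ch in node.child_nodes()]
            d = depth[node]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = d
            merged = [i for ch in children for i in ch]
            leafsets[node] = merged

    C += root_edge
    diag = np.diag(C)
    if np.any(diag <= 0):
        bad = [labels[i] for i in np.where(diag <= 0)[0]]
        raise ValueError(f"zero root-to-tip distance for tip(s): {bad}")
    if not np.allclose(diag, diag[0], rtol=1e-6):
        warnings.warn("tree is not ultrametric; correlation scaling still applies", stacklevel=2)
    inv_sd = 1.0 / np.sqrt(diag)
    C_corr = C * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(C_corr, 1.0)
    return PhyloCovariance(species=labels, C=C, C_corr=C_corr)


def prune_to_species(tree: dendropy.Tree, species: list[str]) -> dendropy.Tree:
    """Induced subtree on *species*, collapsing degree-2 nodes.

    Branch lengths through collapsed nodes are summed; the path length
    from the (new) root down to each retained tip, including the root
    edge, is preserved exactly. Missing species are a hard error.
    """
    present = set(tip_labels(tree))
    missing = sorted(set(species) - present)
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    if len(set(species)) < len(species):
        raise ValueError("duplicate species in prune request")
    if len(species) == 1:
        logger.warning("pruning to a single tip yields a degenerate one-branch tree")

    pruned = tree.clone(depth=1)
    keep = set(species)
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    pruned.retain_taxa(taxa)
    # retain_taxa suppresses internal unifurcations but can leave a
    # unifurcate root; fold that edge into the root edge to preserve
    # root-to-tip path lengths.
    while pruned.seed_node.num_child_nodes() == 1:
        child = pruned.seed_node.child_nodes()[0]
        extra = (pruned.seed_node.edge.length or 0.0) + (child.edge.length or 0.0)
        child.parent_node = None
        pruned.seed_node = child
        pruned.seed_node.edge.length = extra
    _validate_tree(pruned)
    return pruned


def write_vcv_csv(cov: PhyloCovariance, path, correlation: bool = False) -> None:
    """Write C (or C_corr) as CSV with a species header row and column."""
    M = cov.C_corr if correlation else cov.C
    buf = io.StringIO()
    buf.write("species," + ",".join(cov.species) + "\n")
    for name, row in zip(cov.species, M):
        buf.write(name + "," + ",".join(repr(v) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
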