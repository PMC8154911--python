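"""Phylogenetic tree handling: newick I/O, grafting, patristic distances.

Trees are :class:`dendropy.Tree` objects throughout.  Pool species that are
missing from a backbone phylogeny are grafted into it by one of three
taxonomy-guided placement methods, mirroring the standard megatree workflow
(basal polytomy within the family, random placement within the family, or
placement constrained by the family -> order hierarchy when the family itself
has no tips in the tree).  Patristic distances are the substrate for the
community-phylogenetic statistics in :mod:`geothermflora.nri`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .exceptions import NewickParseError, UnplaceableSpeciesError

__all__ = [
    "GraftMethod",
    "PatristicMatrix",
    "read_newick",
    "write_newick",
    "tree_depth",
    "graft_species",
    "patristic_matrix",
    "sample_pairs",
]


class GraftMethod(str, enum.Enum):
    """How a species absent from the backbone tree is attached."""

    basal_polytomy = "basal_polytomy"
    random_within_family = "random_within_family"
    taxonomy_constrained = "taxonomy_constrained"


def read_newick(path) -> dendropy.Tree:
    """Read a rooted newick tree with branch lengths.

    Raises
    ------
    NewickParseError
        On malformed newick, duplicate tip labels, or missing branch lengths
        (patristic distances would be undefined).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickParseError(f"cannot parse newick file {path}: {exc}") from exc
    _validate_tree(tree)
    return tree


def read_newick_string(newick: str) -> dendropy.Tree:
    """Parse a newick string (same validation as :func:`read_newick`)."""
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"cannot parse newick string: {exc}") from exc
    _validate_tree(tree)
    return tree


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickParseError(f"duplicate tip labels: {', '.join(dupes)}")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length is None:
            raise NewickParseError(
                "branch length missing on an edge; patristic distances undefined"
            )
        if node.parent_node is not None and node.edge.length < 0:
            raise NewickParseError("negative branch length")


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as newick with branch lengths."""
    with open(path, "w") as fh:
        fh.write(as_newick(tree))


def as_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    return max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())


def graft_species(
    tree: dendropy.Tree,
    taxonomy,
    missing_species: Iterable[str],
    method: GraftMethod | str = GraftMethod.basal_polytomy,
    seed: int | np.random.Generator | None = None,
) -> dendropy.Tree:
    """Attach species absent from ``tree`` using family/order membership.

    Parameters
    ----------
    taxonomy : pandas.DataFrame
        Columns ``species``, ``family``, ``order`` (``class`` ignored here).
        Must cover every species to graft and should cover the existing tips
        so family clades can be located.
    missing_species : iterable of str
        Species to add; processed in sorted order for determinism.
    method : GraftMethod
        ``basal_polytomy`` attaches at the family crown node (MRCA);
        ``random_within_family`` at a uniformly chosen internal node of the
        family clade; ``taxonomy_constrained`` behaves like basal placement
        but falls back to the order MRCA when the family has no tips.
    seed : int or numpy Generator
        Randomness source for ``random_within_family``.

    The pendant branch length is (tree depth - depth of the attachment
    node): an ultrametric input stays ultrametric.  When a single-tip family
    must receive a graft, a new internal node is created at half that tip's
    pendant branch so the family remains monophyletic.

    Raises
    ------
    UnplaceableSpeciesError
        If, under ``taxonomy_constrained``, a species' family and order are
        both absent; under family-only methods, if the family is absent.
    """
    method = GraftMethod(method)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = tree.clone(depth=1)
    missing = sorted(set(missing_species))
    if not missing:
        return out

    fam_of = dict(zip(taxonomy["species"], taxonomy["family"]))
    order_of = dict(zip(taxonomy["species"], taxonomy["order"]))
    order_of_family = dict(zip(taxonomy["family"], taxonomy["order"]))

    depth = tree_depth(out)
    leaves = {leaf.taxon.label: leaf for leaf in out.leaf_node_iter()}
    fam_tips: dict[str, list] = {}
    for lab, leaf in leaves.items():
        if lab in fam_of:
            fam_tips.setdefault(fam_of[lab], []).append(leaf)

    unplaceable = []
    for sp in missing:
        if sp in leaves:
            continue
        fam = fam_of.get(sp)
        if fam is None:
            unplaceable.append(sp)
            continue
        tips = fam_tips.get(fam, [])
        if tips:
            attach = _family_attachment(out, tips, method, rng)
        elif method is GraftMethod.taxonomy_constrained:
            order = order_of.get(sp)
            order_tips = [
                leaf
                for lab, leaf in leaves.items()
                if order_of_family.get(fam_of.get(lab)) == order
            ]
            if not order_tips:
                unplaceable.append(sp)
                continue
            attach = _mrca_of(out, order_tips)
        else:
            unplaceable.append(sp)
            continue
        pendant = max(depth - attach.distance_from_root(), 0.0)
        taxon = out.taxon_namespace.require_taxon(label=sp)
        new_leaf = attach.new_child(taxon=taxon, edge_length=pendant)
        leaves[sp] = new_leaf
        fam_tips.setdefault(fam, []).append(new_leaf)

    if unplaceable:
        raise UnplaceableSpeciesError(unplaceable)
    return out


def _mrca_of(tree: dendropy.Tree, tips) -> dendropy.Node:
    """MRCA by parent-chain intersection (robust after grafting/pruning)."""
    if len(tips) == 1:
        return tips[0]
    first = []
    node = tips[0]
    while node is not None:
        first.append(node)
        node = node.parent_node
    common = set(first)
    for tip in tips[1:]:
        anc = set()
        node = tip
        while node is not None:
            anc.add(node)
            node = node.parent_node
        common &= anc
    for node in first:
        if node in common:
            return node
    raise ValueError("tips share no common ancestor (disconnected tree)")


def _family_attachment(tree, tips, method, rng):
    """Attachment node inside an existing family clade."""
    if len(tips) == 1:
        # split the lone tip's pendant edge at its midpoint
        return _split_pendant(tips[0])
    mrca = _mrca_of(tree, tips)
    if method is GraftMethod.random_within_family:
        internal = [nd for nd in mrca.preorder_iter() if not nd.is_leaf()]
        return internal[int(rng.integers(len(internal)))]
    return mrca


def _split_pendant(tip: dendropy.Node) -> dendropy.Node:
    parent = tip.parent_node
    half = tip.edge.length / 2.0
    parent.remove_child(tip)
    mid = parent.new_child(edge_length=half)
    mid.add_child(tip)
    tip.edge.length = half
    return mid


@dataclass
class PatristicMatrix:
    """Square patristic distance matrix with label bookkeeping."""

    labels: list[str]
    values: np.ndarray  # (n, n), symmetric, zero diagonal

    def __post_init__(self):
        self.index = {lab: i for i, lab in enumerate(self.labels)}

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.index[a], self.index[b]])

    def submatrix(self, labels: Sequence[str]) -> "PatristicMatrix":
        idx = [self.index[l] for l in labels]
        return PatristicMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def condensed(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Upper-triangle distances, ordered as ``np.triu_indices``."""
        vals = self.values if labels is None else self.submatrix(labels).values
        iu = np.triu_indices(vals.shape[0], 1)
        return vals[iu]


def patristic_matrix(
    tree: dendropy.Tree, species_subset: Sequence[str] | None = None
) -> PatristicMatrix:
    """All pairwise path-length (patristic) distances between tips.

    Raises ``KeyError`` if a requested species is not a tip of the tree.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    if species_subset is None:
        labels = sorted(taxa)
    else:
        labels = list(species_subset)
        missing = [l for l in labels if l not in taxa]
        if missing:
            raise KeyError(f"species not in tree: {', '.join(sorted(missing))}")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        ti = taxa[labels[i]]
        for j in range(i + 1, n):
            d = pdm.patristic_distance(ti, taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return PatristicMatrix(labels, mat)


def sample_pairs(
    species_list: Sequence[str],
    max_pairs: int = 100,
    seed: int | np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """All unordered pairs, or a uniform without-replacement subset.

    Returns every pair when the list yields at most ``max_pairs`` of them;
    otherwise ``max_pairs`` distinct pairs sampled uniformly.
    """
    species = list(species_list)
    n = len(species)
    if n < 2:
        raise ValueError("need at least 2 species to form pairs")
    iu, ju = np.triu_indices(n, 1)
    n_pairs = len(iu)
    if n_pairs <= max_pairs:
        chosen = np.arange(n_pairs)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        chosen = rng.choice(n_pairs, size=max_pairs, replace=False)
    return [(species[iu[c]], species[ju[c]]) for c in chosen]
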