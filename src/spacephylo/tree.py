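"""Ultrametric phylogeny: reading, validation, patristic distances, Faith's PD.

The tree is the study's fixed input: a rooted, dated phylogeny whose branch
lengths are in millions of years (Ma), one leaf per taxon (typically one
exemplar per genus). All downstream phylogenetic quantities — patristic
distances between taxa and Faith's phylogenetic diversity of taxon sets —
are path/edge sums on this tree.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeValidationError",
    "SpeciesLookupError",
    "UltrametricityWarning",
    "UltrametricTree",
    "SpeciesDistanceMatrix",
    "read_tree",
    "patristic_matrix",
    "faith_pd",
    "resolve_to_genus",
]

#: relative tolerance on root-to-leaf depth spread before a tree is flagged
ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Tree fails a structural requirement (labels, branch lengths)."""


class SpeciesLookupError(KeyError):
    """Requested taxa are not leaves of the tree."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(f"taxa not found in tree: {', '.join(self.missing)}")


class UltrametricityWarning(UserWarning):
    """Root-to-leaf depths differ beyond tolerance (dated trees may carry rounding)."""


@dataclass
class UltrametricTree:
    """A validated rooted ultrametric tree with branch lengths in Ma.

    Wraps a :class:`dendropy.Tree` and caches per-leaf depths and the root
    age (maximum leaf depth). Leaves carry unique non-empty labels.
    """

    tree: dendropy.Tree
    leaf_labels: tuple[str, ...]
    root_age: float
    _leaf_nodes: dict = field(repr=False, default_factory=dict)
    _depths: dict = field(repr=False, default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def total_branch_length(self) -> float:
        return sum(e.length for e in self.tree.edges() if e.length is not None)

    def leaf_depth(self, label: str) -> float:
        """Root-to-leaf path length (Ma); equals root_age if ultrametric."""
        if label not in self._leaf_nodes:
            raise SpeciesLookupError([label])
        return self._depths[self._leaf_nodes[label]]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class SpeciesDistanceMatrix:
    """Symmetric patristic-distance matrix (Ma) over an ordered taxon list."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def distance(self, a: str, b: str) -> float:
        missing = [s for s in (a, b) if s not in self._index]
        if missing:
            raise SpeciesLookupError(missing)
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels) -> "SpeciesDistanceMatrix":
        missing = [s for s in labels if s not in self._index]
        if missing:
            raise SpeciesLookupError(missing)
        idx = [self._index[s] for s in labels]
        return SpeciesDistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


def _node_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + node.edge.length
    return depths


def read_tree(newick_text: str, strict_ultrametric: bool = False) -> UltrametricTree:
    """Parse and validate a newick tree with branch lengths on all edges.

    Parameters
    ----------
    newick_text:
        A single rooted newick tree; every non-root edge must carry a
        branch length (Ma). A root edge length is optional and ignored.
    strict_ultrametric:
        If True, depth spread beyond ``ULTRAMETRIC_RTOL`` raises
        :class:`TreeValidationError` instead of warning.

    Raises
    ------
    TreeValidationError
        Malformed newick, missing branch length, duplicate or empty leaf
        label, negative branch length.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise TreeValidationError(f"malformed newick: {exc}") from exc

    tree.is_rooted = True

    labels = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon is not None else None
        if not label:
            raise TreeValidationError("leaf with empty label")
        labels.append(label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeValidationError(f"duplicate leaf labels: {', '.join(dupes)}")

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            if node.edge.length is None:
                node.edge.length = 0.0
            continue
        if node.edge.length is None:
            raise TreeValidationError(
                f"missing branch length on edge above {_describe_node(node)}"
            )
        if node.edge.length < 0:
            raise TreeValidationError(
                f"negative branch length above {_describe_node(node)}"
            )

    depths = _node_depths(tree)
    leaf_nodes = {}
    leaf_depths = []
    for leaf in tree.leaf_node_iter():
        leaf_nodes[leaf.taxon.label] = leaf
        leaf_depths.append(depths[leaf])
    root_age = float(max(leaf_depths))

    if root_age > 0:
        spread = (max(leaf_depths) - min(leaf_depths)) / root_age
        if spread > ULTRAMETRIC_RTOL:
            msg = (
                f"tree is not ultrametric: leaf depths span "
                f"[{min(leaf_depths):g}, {max(leaf_depths):g}] "
                f"(relative spread {spread:.3g})"
            )
            if strict_ultrametric:
                raise TreeValidationError(msg)
            warnings.warn(msg, UltrametricityWarning, stacklevel=2)

    return UltrametricTree(
        tree=tree,
        leaf_labels=tuple(sorted(labels)),
        root_age=root_age,
        _leaf_nodes=leaf_nodes,
        _depths=depths,
    )


def _describe_node(node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"leaf '{node.taxon.label}'"
    tips = [l.taxon.label for l in node.leaf_iter() if l.taxon is not None][:3]
    return f"internal node over ({', '.join(tips)}{'...' if len(tips) == 3 else ''})"


def patristic_matrix(utree: UltrametricTree, species) -> SpeciesDistanceMatrix:
    """Patristic (path-length) distances between the requested leaves, in Ma.

    Entry (i, j) is the sum of branch lengths on the tree path between
    leaves i and j, computed as depth(i) + depth(j) − 2·depth(MRCA(i, j)).
    """
    species = list(species)
    missing = [s for s in species if s not in utree._leaf_nodes]
    if missing:
        raise SpeciesLookupError(missing)

    depths = utree._depths
    n = len(species)
    # ancestor bitsets: for each internal node, which of the requested
    # leaves descend from it; MRCA depth found in one postorder sweep
    order = {s: i for i, s in enumerate(species)}
    vals = np.zeros((n, n), dtype=float)

    # per-leaf root paths; n is plot-scale (tens of species) so the
    # quadratic MRCA-by-path-intersection is plenty fast and transparent
    root_paths = {}
    for s in species:
        node = utree._leaf_nodes[s]
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        root_paths[s] = path

    path_sets = {s: set(id(n_) for n_ in p) for s, p in root_paths.items()}
    for i, a in enumerate(species):
        for j in range(i + 1, n):
            b = species[j]
            mrca = next(n_ for n_ in root_paths[a] if id(n_) in path_sets[b])
            d = depths[utree._leaf_nodes[a]] + depths[utree._leaf_nodes[b]] - 2 * depths[mrca]
            vals[i, j] = vals[j, i] = d
    return SpeciesDistanceMatrix(tuple(species), vals)


def faith_pd(utree: UltrametricTree, species_set, rooted: bool = True) -> float:
    """Faith's phylogenetic diversity of a taxon set, in Ma.

    Sum of branch lengths of the minimal subtree spanning the taxa. By
    default the root is included in the spanned subtree (the convention of
    the classic community-phylogenetics toolchain), so PD of a single taxon
    equals its root-to-tip depth. With ``rooted=False`` the subtree spans
    only down to the taxa's MRCA.
    """
    species_set = set(species_set)
    if not species_set:
        raise ValueError("faith_pd requires a non-empty species set")
    missing = [s for s in species_set if s not in utree._leaf_nodes]
    if missing:
        raise SpeciesLookupError(missing)

    edges = {}  # id(node) -> length of edge above node
    node_of = {}
    for s in species_set:
        node = utree._leaf_nodes[s]
        while node.parent_node is not None:
            edges[id(node)] = node.edge.length
            node_of[id(node)] = node
            node = node.parent_node
    total = float(sum(edges.values()))
    if not rooted:
        # subtract the shared root→MRCA stem: edges ancestral to every taxon
        counts = {}
        for s in species_set:
            node = utree._leaf_nodes[s]
            while node.parent_node is not None:
                counts[id(node)] = counts.get(id(node), 0) + 1
                node = node.parent_node
        k = len(species_set)
        total -= sum(edges[i] for i, c in counts.items() if c == k)
    return total


def resolve_to_genus(names, utree: UltrametricTree) -> dict:
    """Map species names to tree leaves, falling back to the genus leaf.

    For a genus-level tree (one exemplar per genus), a binomial such as
    ``"Genus epithet"`` that is not itself a leaf is mapped to the leaf
    ``"Genus"`` when present. Congeners therefore collapse onto one leaf and
    get patristic distance 0 from each other.

    Returns a dict name → leaf label; raises :class:`SpeciesLookupError`
    listing names resolvable neither way.
    """
    leaves = set(utree.leaf_labels)
    mapping, missing = {}, []
    for name in names:
        if name in leaves:
            mapping[name] = name
            continue
        genus = name.split()[0].split("_")[0]
        if genus in leaves:
            mapping[name] = genus
        else:
            missing.append(name)
    if missing:
        raise SpeciesLookupError(missing)
    return mapping
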