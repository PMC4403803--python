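"""Independent brute-force oracles used by the tests.

Each oracle recomputes a quantity through a different route than the
package (graph shortest paths, edge/leaf bipartitions, exhaustive
permutation or subset enumeration) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import itertools

import dendropy
import networkx as nx
import numpy as np


def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def patristic_brute(newick: str, species: list[str]) -> np.ndarray:
    """All-pairs patristic distances via Dijkstra on the tree graph."""
    tree = _parse(newick)
    g = nx.Graph()
    leaf_of = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node), weight=node.edge.length)
        if node.is_leaf():
            leaf_of[node.taxon.label] = id(node)
    n = len(species)
    out = np.zeros((n, n))
    for i, a in enumerate(species):
        lengths = nx.single_source_dijkstra_path_length(g, leaf_of[a], weight="weight")
        for j, b in enumerate(species):
            out[i, j] = lengths[leaf_of[b]]
    return out


def faith_pd_brute(newick: str, species_set, rooted: bool = True) -> float:
    """PD via edge bipartitions: an edge counts iff the leaf set below it
    meets the species set (rooted), minus edges ancestral to the whole set
    for the MRCA-spanning variant."""
    tree = _parse(newick)
    s = set(species_set)
    total = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {l.taxon.label for l in node.leaf_iter()}
        hit = below & s
        if not hit:
            continue
        if rooted or not (s <= below):
            total += node.edge.length
    return total


def pearson_brute(x, y) -> float:
    """Textbook Pearson formula, written out."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    num = n * np.sum(x * y) - np.sum(x) * np.sum(y)
    den = np.sqrt(n * np.sum(x**2) - np.sum(x) ** 2) * np.sqrt(
        n * np.sum(y**2) - np.sum(y) ** 2
    )
    return float(num / den)


def mantel_exact_p(physical: np.ndarray, phylogenetic: np.ndarray) -> tuple[float, float]:
    """Exact one-sided Mantel p over all n! label permutations (n small).

    Returns (r_observed, p_greater) with the add-one convention applied to
    the full permutation group (identity included), i.e. the proportion of
    permutations with r_perm >= r_obs.
    """
    n = physical.shape[0]
    iu = np.triu_indices(n, k=1)
    y = phylogenetic[iu]
    r_obs = pearson_brute(physical[iu], y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        r = pearson_brute(physical[np.ix_(p, p)][iu], y)
        count += r >= r_obs - 1e-12
        total += 1
    return r_obs, count / total


def pd_null_exact_p_low(newick: str, pool: list[str], observed: set) -> float:
    """Exact lower-tail probability of the richness-constrained PD null by
    enumerating every |observed|-subset of the pool."""
    obs_pd = faith_pd_brute(newick, observed)
    k = len(observed)
    vals = [faith_pd_brute(newick, c) for c in itertools.combinations(pool, k)]
    vals = np.asarray(vals)
    return float(np.mean(vals <= obs_pd + 1e-9))
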