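"""Richness-constrained randomization null for Faith's PD.

Each plot's observed PD is compared with the PD of random assemblages of
the same richness drawn uniformly without replacement from the study
species pool (by default, every species observed across all plots of both
vegetation types). Plots whose PD sits in the lower tail are
phylogenetically clustered; upper tail, overdispersed. Tail probabilities
are rank-based with ties counted inclusively and add-one smoothing, so a
degenerate null (e.g. on a star tree, where PD depends only on richness)
classifies as "neither" rather than as both extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plots import EmptyPlotError, PlotData, filter_plot
from .tree import SpeciesLookupError, UltrametricTree, faith_pd

__all__ = ["PDNullResult", "pd_null_test", "run_pd_suite", "leaf_edge_incidence"]

CLASSIFICATIONS = ("clustered", "overdispersed", "neither")


@dataclass
class PDNullResult:
    plot_id: str
    observed_pd: float
    richness: int
    null_mean: float
    null_sd: float
    ses: float
    p_low: float
    p_high: float
    n_rep: int
    classification: str


def leaf_edge_incidence(utree: UltrametricTree, pool: list[str]):
    """Boolean leaf × edge incidence over root paths, plus edge lengths.

    Row s marks the edges on the root path of pool species s; the rooted PD
    of any subset is then the length-sum over the union of its rows. This
    is what makes 10^4 null replicates cheap.
    """
    edge_index: dict[int, int] = {}
    lengths: list[float] = []
    rows = []
    for s in pool:
        node = utree._leaf_nodes[s]
        row: list[int] = []
        while node.parent_node is not None:
            key = id(node)
            if key not in edge_index:
                edge_index[key] = len(lengths)
                lengths.append(node.edge.length)
            row.append(edge_index[key])
            node = node.parent_node
        rows.append(row)
    n_edges = len(lengths)
    inc = np.zeros((len(pool), n_edges), dtype=bool)
    for i, row in enumerate(rows):
        inc[i, row] = True
    return inc, np.asarray(lengths)


def pd_null_test(
    utree: UltrametricTree,
    pool,
    observed,
    n_rep: int = 10000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    plot_id: str = "",
) -> PDNullResult:
    """Classify one assemblage against the richness-constrained PD null.

    Null replicate: Faith's PD (rooted) of |observed| species drawn
    uniformly without replacement from the pool. Two-sided decision at
    overall alpha: clustered if p_low <= alpha/2, overdispersed if
    p_high <= alpha/2.
    """
    pool = sorted(set(pool))
    observed = set(observed)
    if not observed:
        raise ValueError("observed species set is empty")
    if not observed <= set(pool):
        raise ValueError("observed species must be a subset of the pool")
    missing = [s for s in pool if s not in utree._leaf_nodes]
    if missing:
        raise SpeciesLookupError(missing)
    k = len(observed)
    if len(pool) <= k:
        raise ValueError(
            f"pool ({len(pool)}) must exceed observed richness ({k}): null undefined"
        )
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")

    obs_pd = faith_pd(utree, observed)
    inc, lengths = leaf_edge_incidence(utree, pool)
    rng = np.random.default_rng(seed)

    null = np.empty(n_rep)
    chunk = max(1, int(2e7 // max(1, k * inc.shape[1])))
    done = 0
    while done < n_rep:
        m = min(chunk, n_rep - done)
        draws = np.array([rng.choice(len(pool), size=k, replace=False) for _ in range(m)])
        union = inc[draws].any(axis=1)  # (m, k, E) -> (m, E)
        null[done : done + m] = union @ lengths
        done += m

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_rep > 1 else 0.0
    ses = (obs_pd - null_mean) / null_sd if null_sd > 0 else 0.0

    tol = 1e-9 * max(1.0, abs(obs_pd))  # rank ties at floating-point resolution
    p_low = (1 + np.sum(null <= obs_pd + tol)) / (1 + n_rep)
    p_high = (1 + np.sum(null >= obs_pd - tol)) / (1 + n_rep)

    if p_low <= alpha / 2:
        classification = "clustered"
    elif p_high <= alpha / 2:
        classification = "overdispersed"
    else:
        classification = "neither"

    return PDNullResult(
        plot_id=plot_id,
        observed_pd=float(obs_pd),
        richness=k,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=float(ses),
        p_low=float(p_low),
        p_high=float(p_high),
        n_rep=n_rep,
        classification=classification,
    )


#: the three sensitivity configurations reported for the randomization
SUITE_CONFIGS = {
    "full": {},
    "no_aliens": {"exclude_status": {"alien"}},
    "no_graminoids": {"exclude_families": {"Poaceae"}},
}


def run_pd_suite(
    plots: list[PlotData],
    utree: UltrametricTree,
    n_rep: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    configs: dict | None = None,
    species_resolver: dict | None = None,
) -> dict[str, dict[str, PDNullResult | None]]:
    """Run the PD null over every plot under each sensitivity configuration.

    Configurations (default): full data; aliens removed; graminoids
    (Poaceae) removed. The species pool is recomputed per configuration
    from the filtered plots. A plot a filter empties is marked unevaluable
    (None); the rest proceed. ``species_resolver`` optionally maps stem-map
    species names to tree leaf labels (genus-level trees).
    """
    configs = SUITE_CONFIGS if configs is None else configs
    resolve = (lambda s: species_resolver.get(s, s)) if species_resolver else (lambda s: s)
    ss = np.random.SeedSequence(seed)
    results: dict[str, dict[str, PDNullResult | None]] = {}
    for (name, filt), cfg_seed in zip(configs.items(), ss.spawn(len(configs))):
        filtered: dict[str, PlotData | None] = {}
        for plot in plots:
            try:
                filtered[plot.plot_id] = filter_plot(plot, **filt) if filt else plot
            except EmptyPlotError:
                filtered[plot.plot_id] = None
        pool = sorted(
            {resolve(s) for p in filtered.values() if p is not None for s in p.species}
        )
        per_plot: dict[str, PDNullResult | None] = {}
        plot_seeds = cfg_seed.spawn(len(plots))
        for plot, pseed in zip(plots, plot_seeds):
            fp = filtered[plot.plot_id]
            if fp is None:
                per_plot[plot.plot_id] = None
                continue
            observed = {resolve(s) for s in fp.species}
            if len(pool) <= len(observed):
                per_plot[plot.plot_id] = None  # richness equals pool: degenerate
                continue
            per_plot[plot.plot_id] = pd_null_test(
                utree,
                pool,
                observed,
                n_rep=n_rep,
                alpha=alpha,
                seed=np.random.default_rng(pseed),
                plot_id=plot.plot_id,
            )
        results[name] = per_plot
    return results
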