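"""Synthetic stem-mapped studies with known spatial-phylogenetic coupling.

Generates what the field study measured — an ultrametric genus-level tree
and fully stem-mapped 5 × 5 m plots in two vegetation types — from a known
generative model, so every stage of the pipeline can be verified against
ground truth:

* tree: pure-birth (Yule) topology, branch lengths rescaled to an exact
  root age;
* species niche centres: two independent Brownian-motion traits evolved
  along the tree and rescaled to the plot square, so close relatives get
  close centres in expectation;
* individuals: per plot, richness and total abundance drawn from
  vegetation-specific ranges (grassland denser), abundances following a
  geometric rank series; each individual sits at its species' centre plus
  isotropic Gaussian noise with probability κ (the coupling knob) and
  uniformly at random otherwise. κ = 0 gives no spatial-phylogenetic
  signal (the Mantel null); κ = 1 with small noise makes related species
  spatially aggregated.

A fixed fraction of pool species is flagged alien (phylogenetically
unconstrained by default, mirroring aliens that blend into the local
phylogenetic landscape; optionally confined to one clade); grassland plots
can optionally draw their species from a designated shallow clade, which
depresses grassland PD the way graminoid dominance does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plots import PlantRecord, PlotData, write_stem_maps
from .tree import UltrametricTree, read_tree

__all__ = [
    "SimParams",
    "SimulatedStudy",
    "yule_event_times",
    "simulate_tree",
    "simulate_niches",
    "simulate_plot",
    "simulate_study",
    "write_study",
]


@dataclass
class SimParams:
    """Generator settings; defaults emulate the study design.

    Twenty 5 × 5 m plots (ten per vegetation type), a pool of ~200 species
    on a deep angiosperm-scale tree, per-plot richness of a few tens of
    species, 100–400 individuals per plot with grassland denser, and
    roughly 9% of pool species alien (≈ the study's 18 of 194).
    """

    n_species_pool: int = 200
    root_age: float = 150.0  # Ma; angiosperm-crown scale
    n_plots_forest: int = 10
    n_plots_grassland: int = 10
    richness_forest: tuple[int, int] = (10, 35)
    richness_grassland: tuple[int, int] = (10, 35)
    individuals_forest: tuple[int, int] = (100, 250)
    individuals_grassland: tuple[int, int] = (200, 400)
    kappa: float = 0.5  # coupling: P(individual placed at its species centre)
    sigma: float = 0.75  # m; placement noise around the centre
    p_alien_species: float = 0.09
    p_graminoid_species: float = 0.15
    geometric_ratio: float = 0.8  # abundance rank series
    plot_size: float = 5.0  # m; plots are squares
    grassland_shallow_clade: bool = False
    alien_clade: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.plot_size <= 0:
            raise ValueError("plot_size must be > 0")
        if self.n_species_pool < 2:
            raise ValueError("need at least 2 pool species")
        if min(self.n_plots_forest, self.n_plots_grassland) < 0:
            raise ValueError("plot counts must be >= 0")
        if self.n_plots_forest + self.n_plots_grassland < 1:
            raise ValueError("need at least one plot")
        for name in ("richness_forest", "richness_grassland"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi <= self.n_species_pool):
                raise ValueError(f"{name} range ({lo}, {hi}) infeasible for pool")
        for veg in ("forest", "grassland"):
            r_hi = getattr(self, f"richness_{veg}")[1]
            n_lo = getattr(self, f"individuals_{veg}")[0]
            if n_lo < r_hi:
                raise ValueError(
                    f"{veg}: min individuals ({n_lo}) below max richness ({r_hi})"
                )


@dataclass
class SimulatedStudy:
    tree: UltrametricTree
    plots: list[PlotData]
    niche_centres: dict[str, tuple[float, float]]
    alien_species: frozenset[str]
    graminoid_species: frozenset[str]
    params: SimParams = field(repr=False, default=None)


def yule_event_times(n: int, rng: np.random.Generator) -> tuple[list[float], float]:
    """Speciation event times of a rate-1 pure-birth process from 2 lineages.

    Returns the times at which the lineage count steps 2→3, …, (n−1)→n,
    plus the present ``t_end`` (one further exponential wait at rate n).
    E[t_end] is the harmonic tail sum_{k=2..n} 1/k.
    """
    times: list[float] = []
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / k)
        times.append(t)
    t_end = t + rng.exponential(1.0 / n)
    return times, t_end


def simulate_tree(
    n: int, root_age: float, seed: int | np.random.Generator | None = None
) -> UltrametricTree:
    """Yule (pure-birth) ultrametric tree with an exact root age.

    Exponential waiting times between speciation events (rate = number of
    extant lineages), uniform choice of the splitting lineage; all node
    times are finally rescaled so the root-to-tip depth equals ``root_age``
    exactly. Leaves are labelled sp001..spNNN in a seeded random order.
    """
    if n < 2:
        raise ValueError("need at least 2 species")
    if root_age <= 0:
        raise ValueError("root_age must be > 0")
    rng = np.random.default_rng(seed)

    event_times, t_end = yule_event_times(n, rng)

    # node = [split_time or None, child_a, child_b]; leaves have no children
    root = [0.0, None, None]
    active = [[None, None, None], [None, None, None]]
    root[1], root[2] = active
    birth = {id(active[0]): 0.0, id(active[1]): 0.0}
    for t in event_times:
        i = rng.integers(len(active))
        node = active.pop(i)
        node[0] = t
        kids = [[None, None, None], [None, None, None]]
        node[1], node[2] = kids
        birth[id(kids[0])] = birth[id(kids[1])] = t
        active.extend(kids)
    scale = root_age / t_end

    labels = [f"sp{i + 1:03d}" for i in range(n)]
    rng.shuffle(labels)
    label_iter = iter(labels)

    def newick(node, parent_time):
        if node[1] is None:
            return f"{next(label_iter)}:{(t_end - birth[id(node)]) * scale:.10f}"
        left = newick(node[1], node[0])
        right = newick(node[2], node[0])
        return f"({left},{right}):{(node[0] - parent_time) * scale:.10f}"

    nwk = f"({newick(root[1], 0.0)},{newick(root[2], 0.0)});"
    return read_tree(nwk)


def simulate_niches(
    utree: UltrametricTree,
    plot_size: float = 5.0,
    seed: int | np.random.Generator | None = None,
) -> dict[str, tuple[float, float]]:
    """Brownian-motion niche centres: species → (x*, y*) within the plot.

    Two independent traits evolve along the tree with per-edge variance
    proportional to branch length; each trait is affinely rescaled to span
    [0, plot_size]. Sister species separated by little evolutionary time
    therefore receive nearby centres.
    """
    rng = np.random.default_rng(seed)
    traits: dict[int, np.ndarray] = {}
    leaf_vals: dict[str, np.ndarray] = {}
    for node in utree.tree.preorder_node_iter():
        if node.parent_node is None:
            traits[id(node)] = np.zeros(2)
        else:
            step = rng.normal(size=2) * math.sqrt(max(node.edge.length, 0.0))
            traits[id(node)] = traits[id(node.parent_node)] + step
        if node.is_leaf():
            leaf_vals[node.taxon.label] = traits[id(node)]

    vals = np.array([leaf_vals[l] for l in utree.leaf_labels])
    lo, hi = vals.min(axis=0), vals.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (vals - lo) / span * plot_size
    scaled[:, hi == lo] = plot_size / 2.0  # degenerate axis: centre of plot
    return {l: (float(x), float(y)) for l, (x, y) in zip(utree.leaf_labels, scaled)}


def _geometric_abundances(k: int, total: int, ratio: float, rng) -> np.ndarray:
    """k abundances summing to total: 1 each + multinomial over a geometric
    rank series assigned in random species order."""
    w = ratio ** np.arange(k)
    rng.shuffle(w)
    counts = np.ones(k, dtype=int)
    counts += rng.multinomial(total - k, w / w.sum())
    return counts


def simulate_plot(
    utree: UltrametricTree,
    centres: dict[str, tuple[float, float]],
    vegetation: str,
    params: SimParams,
    seed: int | np.random.Generator | None = None,
    plot_id: str = "plot",
    species_pool: list[str] | None = None,
    alien_species: frozenset[str] = frozenset(),
    graminoid_species: frozenset[str] = frozenset(),
) -> PlotData:
    """One stem-mapped plot under the generative model (see module docs)."""
    params.validate()
    rng = np.random.default_rng(seed)
    pool = sorted(species_pool) if species_pool is not None else list(utree.leaf_labels)
    lo_k, hi_k = getattr(params, f"richness_{vegetation}")
    lo_n, hi_n = getattr(params, f"individuals_{vegetation}")
    k = int(rng.integers(min(lo_k, len(pool)), min(hi_k, len(pool)) + 1))
    n_total = int(rng.integers(lo_n, hi_n + 1))

    chosen = list(rng.choice(pool, size=k, replace=False))
    counts = _geometric_abundances(k, n_total, params.geometric_ratio, rng)

    size = params.plot_size
    plants = []
    i = 0
    for sp, cnt in zip(chosen, counts):
        cx, cy = centres[sp]
        status = "alien" if sp in alien_species else "indigenous"
        family = "Poaceae" if sp in graminoid_species else f"F{sp[2:4]}"
        for _ in range(cnt):
            i += 1
            if rng.random() < params.kappa:
                while True:  # resample, not clip: keeps density smooth at edges
                    x, y = rng.normal((cx, cy), params.sigma)
                    if 0 <= x <= size and 0 <= y <= size:
                        break
            else:
                x, y = rng.uniform(0, size, 2)
            plants.append(
                PlantRecord(
                    individual_id=f"{plot_id}.{i}",
                    species=sp,
                    status=status,
                    family=family,
                    x=float(x),
                    y=float(y),
                )
            )
    return PlotData(
        plot_id=plot_id,
        vegetation=vegetation,
        width=size,
        height=size,
        plants=tuple(plants),
    )


def _shallow_clade(utree: UltrametricTree, min_frac=0.15, max_frac=0.45) -> list[str]:
    """Leaves of the lowest-crown-age clade holding 15–45% of the pool."""
    n = utree.n_leaves
    depths = utree._depths
    best, best_age = None, None
    for node in utree.tree.preorder_internal_node_iter():
        leaves = [l.taxon.label for l in node.leaf_iter()]
        if min_frac * n <= len(leaves) <= max_frac * n:
            crown = utree.root_age - depths[node]
            if best_age is None or crown < best_age:
                best, best_age = leaves, crown
    if best is None:  # fall back: smallest clade above the minimum size
        cands = [
            [l.taxon.label for l in node.leaf_iter()]
            for node in utree.tree.preorder_internal_node_iter()
        ]
        best = min((c for c in cands if len(c) >= 2), key=len)
    return sorted(best)


def simulate_study(params: SimParams) -> SimulatedStudy:
    """Full study: one tree plus all forest and grassland plots, one seed."""
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    s_tree, s_niche, s_flags, s_plots = ss.spawn(4)

    utree = simulate_tree(params.n_species_pool, params.root_age, np.random.default_rng(s_tree))
    centres = simulate_niches(utree, params.plot_size, np.random.default_rng(s_niche))

    rng = np.random.default_rng(s_flags)
    pool = list(utree.leaf_labels)
    n_alien = int(round(params.p_alien_species * len(pool)))
    if params.alien_clade and n_alien:
        clade = _shallow_clade(utree)
        aliens = frozenset(rng.choice(clade, size=min(n_alien, len(clade)), replace=False))
    else:
        aliens = frozenset(rng.choice(pool, size=n_alien, replace=False))

    shallow = _shallow_clade(utree) if params.grassland_shallow_clade else None
    if shallow is not None:
        graminoids = frozenset(shallow)
    else:
        n_gram = int(round(params.p_graminoid_species * len(pool)))
        graminoids = frozenset(rng.choice(pool, size=n_gram, replace=False))

    plots = []
    veg_seq = ["forest"] * params.n_plots_forest + ["grassland"] * params.n_plots_grassland
    for i, (veg, pseed) in enumerate(zip(veg_seq, s_plots.spawn(len(veg_seq))), start=1):
        plot_pool = shallow if (veg == "grassland" and shallow is not None) else None
        plots.append(
            simulate_plot(
                utree,
                centres,
                veg,
                params,
                seed=np.random.default_rng(pseed),
                plot_id=f"{veg[0].upper()}{i:02d}",
                species_pool=plot_pool,
                alien_species=aliens,
                graminoid_species=graminoids,
            )
        )
    return SimulatedStudy(
        tree=utree,
        plots=plots,
        niche_centres=centres,
        alien_species=aliens,
        graminoid_species=graminoids,
        params=params,
    )


def write_study(study: SimulatedStudy, tree_path, table_path, metadata_path) -> None:
    """Write the simulated study via the standard writers (newick + CSVs)."""
    with open(tree_path, "w") as fh:
        fh.write(study.tree.as_newick() + "\n")
    write_stem_maps(study.plots, table_path, metadata_path)
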