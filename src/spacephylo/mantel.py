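"""Per-plot Mantel permutation test between physical and phylogenetic distances.

The statistic is Pearson's r over the vectorised upper triangles of the two
matched matrices. The null distribution is built by jointly permuting the
rows and columns of one matrix with a random permutation of the individual
labels — the permutation unit is the individual plant, which is what the
individual-level matrix construction dictates. The p-value uses the add-one
rule, so it is never zero and never below 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairs import DegenerateMatrixError, PairDistanceSet

__all__ = ["MantelResult", "pairwise_pearson", "mantel_test"]

ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass
class MantelResult:
    plot_id: str
    r: float
    p_value: float
    n_perm: int
    n_individuals: int
    pair_count: int
    alternative: str = "greater"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def _pearson(x: np.ndarray, y: np.ndarray, context: str = "") -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise DegenerateMatrixError(
            f"{context}zero variance in a distance vector; correlation undefined"
        )
    return float((xc @ yc) / (sx * sy))


def pairwise_pearson(pds: PairDistanceSet) -> float:
    """Pearson r between the matched pair-distance vectors of one plot."""
    phys, phylo = pds.pair_vectors()
    if len(phys) < 3:
        raise DegenerateMatrixError(
            f"plot {pds.plot_id}: need >= 3 unmasked pairs, have {len(phys)}"
        )
    return _pearson(phys, phylo, context=f"plot {pds.plot_id}: ")


def mantel_test(
    pds: PairDistanceSet,
    n_perm: int = 999,
    alternative: str = "greater",
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> MantelResult:
    """Mantel permutation test for one plot's pair-distance set.

    Permutes the physical matrix's individual labels (rows and columns
    together); any conspecific mask stays attached to the phylogenetic
    side, so the set of evaluated pairs is fixed by species identity. The
    default one-sided "greater" alternative asks whether physically close
    plants are more closely related than expected; "two-sided" covers the
    repulsion hypothesis as well.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")

    r_obs = pairwise_pearson(pds)
    rng = np.random.default_rng(seed)
    n = pds.n
    iu0, iu1 = np.triu_indices(n, k=1)
    phylo_vec = pds.phylogenetic[iu0, iu1]
    keep = None
    if pds.mask is not None:
        keep = ~pds.mask[iu0, iu1]
        phylo_vec = phylo_vec[keep]

    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n)
        phys_vec = pds.physical[perm[iu0], perm[iu1]]
        if keep is not None:
            phys_vec = phys_vec[keep]
        r_perm[k] = _pearson(phys_vec, phylo_vec)

    if alternative == "greater":
        extreme = np.sum(r_perm >= r_obs)
    elif alternative == "less":
        extreme = np.sum(r_perm <= r_obs)
    else:
        extreme = np.sum(np.abs(r_perm) >= abs(r_obs))
    p = (1 + extreme) / (1 + n_perm)

    return MantelResult(
        plot_id=pds.plot_id,
        r=r_obs,
        p_value=float(p),
        n_perm=n_perm,
        n_individuals=n,
        pair_count=pds.pair_count,
        alternative=alternative,
        alpha=alpha,
    )
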