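"""Matched physical- and phylogenetic-distance matrices over individual plants.

The central data structure of the analysis: for each plot, every unordered
pair of individual plants contributes one physical distance (Euclidean,
metres) and one phylogenetic distance (the patristic distance between the
two species, Ma). Conspecific pairs have phylogenetic distance 0; because a
plot holds many individuals of few species, many physical values map onto
one phylogenetic value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .plots import PlotData
from .tree import SpeciesDistanceMatrix, SpeciesLookupError

__all__ = [
    "InsufficientIndividualsError",
    "DegenerateMatrixError",
    "PairDistanceSet",
    "physical_distances",
    "build_pair_distances",
]


class InsufficientIndividualsError(ValueError):
    """Fewer than two individuals: no pairs to form."""


class DegenerateMatrixError(ValueError):
    """All pairs masked or a distance vector is constant."""


@dataclass
class PairDistanceSet:
    """Matched n×n physical (m) and phylogenetic (Ma) distance matrices."""

    plot_id: str
    individual_ids: tuple[str, ...]
    physical: np.ndarray
    phylogenetic: np.ndarray
    mask: np.ndarray | None = None  # True = pair excluded (conspecific variant)

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def pair_count(self) -> int:
        """Number of unordered pairs, n(n−1)/2 (before masking)."""
        return self.n * (self.n - 1) // 2

    def pair_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle vectors of (physical, phylogenetic), mask applied."""
        iu = np.triu_indices(self.n, k=1)
        phys = self.physical[iu]
        phylo = self.phylogenetic[iu]
        if self.mask is not None:
            keep = ~self.mask[iu]
            phys, phylo = phys[keep], phylo[keep]
        return phys, phylo


def physical_distances(plot: PlotData) -> np.ndarray:
    """Pairwise Euclidean distances (m) between all individuals of a plot."""
    if plot.n_plants < 2:
        raise InsufficientIndividualsError(
            f"plot {plot.plot_id}: need >= 2 individuals, have {plot.n_plants}"
        )
    return squareform(pdist(plot.coordinates(), metric="euclidean"))


def build_pair_distances(
    plot: PlotData,
    sdm: SpeciesDistanceMatrix,
    include_conspecific: bool = True,
) -> PairDistanceSet:
    """Assemble the matched pair-distance matrices for one plot.

    The phylogenetic entry for individuals i and j is the patristic distance
    between species(i) and species(j); conspecific pairs get 0. By default
    conspecific pairs are retained (zero phylogenetic distance is the signal
    that spatial aggregation of conspecifics feeds into the correlation);
    with ``include_conspecific=False`` they are masked out and downstream
    statistics use heterospecific pairs only.
    """
    phys = physical_distances(plot)
    species = [p.species for p in plot.plants]
    missing = sorted(set(species) - set(sdm.labels))
    if missing:
        raise SpeciesLookupError(missing)

    idx = {lab: i for i, lab in enumerate(sdm.labels)}
    sp_idx = np.array([idx[s] for s in species])
    phylo = sdm.values[np.ix_(sp_idx, sp_idx)].copy()
    np.fill_diagonal(phylo, 0.0)

    mask = None
    if not include_conspecific:
        same = sp_idx[:, None] == sp_idx[None, :]
        np.fill_diagonal(same, False)
        mask = same
        iu = np.triu_indices(len(species), k=1)
        if mask[iu].all():
            raise DegenerateMatrixError(
                f"plot {plot.plot_id}: all pairs conspecific; nothing left unmasked"
            )

    return PairDistanceSet(
        plot_id=plot.plot_id,
        individual_ids=tuple(p.individual_id for p in plot.plants),
        physical=phys,
        phylogenetic=phylo,
        mask=mask,
    )
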