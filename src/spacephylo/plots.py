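"""Stem-map tables: reading, writing, per-plot descriptors, sensitivity filters.

A stem map is a full census of a vegetation plot: one row per individual
plant with its species, regional status (indigenous or alien), optional
family, and x/y coordinates in metres from one plot corner. Plot metadata
supplies the vegetation type (forest or grassland) and plot dimensions
(default 5 × 5 m).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "PlotValidationError",
    "EmptyPlotError",
    "PlantRecord",
    "PlotData",
    "read_stem_maps",
    "write_stem_maps",
    "plant_density",
    "percent_alien",
    "filter_plot",
    "study_summary",
    "read_species_by_plot",
    "summary_from_representation",
]

STATUSES = ("indigenous", "alien")
VEGETATION_TYPES = ("forest", "grassland")

#: families treated as graminoids for the "remove grasses" sensitivity rerun;
#: the default rerun excludes Poaceae only, the broader set is documented
GRAMINOID_FAMILIES = frozenset({"Poaceae", "Cyperaceae"})


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class PlotValidationError(ValueError):
    """A row or plot violates its invariants."""


class EmptyPlotError(ValueError):
    """A filter removed every plant; downstream statistics are undefined."""


@dataclass(frozen=True)
class PlantRecord:
    individual_id: str
    species: str
    status: str
    x: float
    y: float
    family: str | None = None


@dataclass(frozen=True)
class PlotData:
    plot_id: str
    vegetation: str
    plants: tuple[PlantRecord, ...]
    width: float = 5.0
    height: float = 5.0

    def __post_init__(self):
        if self.vegetation not in VEGETATION_TYPES:
            raise PlotValidationError(
                f"plot {self.plot_id}: unknown vegetation {self.vegetation!r}"
            )
        if self.width <= 0 or self.height <= 0:
            raise PlotValidationError(f"plot {self.plot_id}: non-positive dimensions")
        if len(self.plants) == 0:
            raise EmptyPlotError(f"plot {self.plot_id}: no plants")
        ids = [p.individual_id for p in self.plants]
        if len(set(ids)) != len(ids):
            raise PlotValidationError(f"plot {self.plot_id}: duplicate individual ids")
        for p in self.plants:
            if p.status not in STATUSES:
                raise PlotValidationError(
                    f"plot {self.plot_id}, {p.individual_id}: bad status {p.status!r}"
                )
            if not (0 <= p.x <= self.width) or not (0 <= p.y <= self.height):
                raise PlotValidationError(
                    f"plot {self.plot_id}, {p.individual_id}: coordinates "
                    f"({p.x}, {p.y}) outside [0,{self.width}]x[0,{self.height}]"
                )

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def species(self) -> set[str]:
        return {p.species for p in self.plants}

    @property
    def richness(self) -> int:
        return len(self.species)

    def coordinates(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in row order."""
        return np.array([(p.x, p.y) for p in self.plants], dtype=float)


_STEM_COLS = ("plot_id", "species", "status", "x", "y")
_META_COLS = ("plot_id", "vegetation")


def _normalise_header(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def read_stem_maps(table_path, metadata_path) -> list[PlotData]:
    """Read a stem-map CSV plus plot-metadata CSV into validated plots.

    The stem map needs columns plot_id, species, status, x, y (plus
    optional individual_id and family); metadata needs plot_id, vegetation
    (plus optional width, height). Header matching is case-insensitive.
    Rows with out-of-bounds coordinates are rejected with their row numbers.
    """
    stems = _normalise_header(pd.read_csv(table_path))
    meta = _normalise_header(pd.read_csv(metadata_path))

    missing = [c for c in _STEM_COLS if c not in stems.columns]
    if missing:
        raise SchemaError(f"stem map missing columns: {', '.join(missing)}")
    missing = [c for c in _META_COLS if c not in meta.columns]
    if missing:
        raise SchemaError(f"metadata missing columns: {', '.join(missing)}")

    meta = meta.set_index(meta["plot_id"].astype(str))
    stems["plot_id"] = stems["plot_id"].astype(str)
    absent = sorted(set(stems["plot_id"]) - set(meta.index))
    if absent:
        raise PlotValidationError(
            f"plots in stem map absent from metadata: {', '.join(absent)}"
        )

    bad_veg = sorted(set(meta["vegetation"]) - set(VEGETATION_TYPES))
    if bad_veg:
        raise PlotValidationError(f"unknown vegetation labels: {', '.join(map(str, bad_veg))}")

    has_family = "family" in stems.columns
    has_ind = "individual_id" in stems.columns

    # a genus-level label carrying both statuses would be ambiguous
    status_per_species = stems.groupby("species")["status"].nunique()
    ambiguous = sorted(status_per_species[status_per_species > 1].index)
    if ambiguous:
        raise PlotValidationError(
            f"species with conflicting status across rows: {', '.join(ambiguous)}"
        )

    plots = []
    for plot_id, rows in stems.groupby("plot_id", sort=True):
        mrow = meta.loc[plot_id]
        width = float(mrow.get("width", 5.0)) if "width" in meta.columns else 5.0
        height = float(mrow.get("height", 5.0)) if "height" in meta.columns else 5.0

        oob = rows[
            (rows["x"] < 0) | (rows["x"] > width) | (rows["y"] < 0) | (rows["y"] > height)
        ]
        if len(oob):
            rownums = ", ".join(str(i + 2) for i in oob.index[:10])  # +2: header + 0-base
            raise PlotValidationError(
                f"plot {plot_id}: coordinates outside plot bounds at file rows {rownums}"
            )

        plants = tuple(
            PlantRecord(
                individual_id=str(r["individual_id"]) if has_ind else f"{plot_id}.{i}",
                species=str(r["species"]),
                status=str(r["status"]).strip().lower(),
                family=(str(r["family"]) if has_family and pd.notna(r["family"]) else None),
                x=float(r["x"]),
                y=float(r["y"]),
            )
            for i, (_, r) in enumerate(rows.iterrows(), start=1)
        )
        plots.append(
            PlotData(
                plot_id=str(plot_id),
                vegetation=str(mrow["vegetation"]).strip().lower(),
                width=width,
                height=height,
                plants=plants,
            )
        )
    return plots


def write_stem_maps(plots, table_path, metadata_path) -> None:
    """Write plots back to the stem-map + metadata CSV pair (round-trips)."""
    rows = []
    for plot in plots:
        for p in plot.plants:
            rows.append(
                {
                    "plot_id": plot.plot_id,
                    "individual_id": p.individual_id,
                    "species": p.species,
                    "family": p.family if p.family is not None else "",
                    "status": p.status,
                    "x": p.x,
                    "y": p.y,
                }
            )
    pd.DataFrame(rows).to_csv(table_path, index=False)
    pd.DataFrame(
        [
            {
                "plot_id": plot.plot_id,
                "vegetation": plot.vegetation,
                "width": plot.width,
                "height": plot.height,
            }
            for plot in plots
        ]
    ).to_csv(metadata_path, index=False)


def plant_density(plot: PlotData) -> float:
    """Plants per square metre."""
    return plot.n_plants / plot.area


def percent_alien(plot: PlotData) -> float:
    """Percentage of individuals whose species is alien, in [0, 100]."""
    n_alien = sum(1 for p in plot.plants if p.status == "alien")
    return 100.0 * n_alien / plot.n_plants


def filter_plot(
    plot: PlotData,
    exclude_status: set | None = None,
    exclude_families: set | None = None,
) -> PlotData:
    """Drop plants by status and/or family; metadata is unchanged.

    Used for the sensitivity reruns: ``exclude_status={"alien"}`` removes
    alien individuals, ``exclude_families={"Poaceae"}`` (or the full
    graminoid set) removes grasses. Raises :class:`EmptyPlotError` if the
    filter removes every plant.
    """
    exclude_status = exclude_status or set()
    exclude_families = exclude_families or set()
    kept = tuple(
        p
        for p in plot.plants
        if p.status not in exclude_status
        and (p.family is None or p.family not in exclude_families)
    )
    if not kept:
        raise EmptyPlotError(f"plot {plot.plot_id}: filter removed all plants")
    return replace(plot, plants=kept)


def study_summary(plots) -> dict:
    """Study-wide counts and the species representation table.

    Returns a dict with totals (individuals, alien individuals, distinct
    species / alien species, and genera / families where derivable) plus a
    ``species_table`` DataFrame with per-species total abundance and the
    number of forest and grassland plots each species occurs in.
    """
    recs = []
    for plot in plots:
        for p in plot.plants:
            recs.append(
                {
                    "plot_id": plot.plot_id,
                    "vegetation": plot.vegetation,
                    "species": p.species,
                    "status": p.status,
                    "family": p.family,
                }
            )
    df = pd.DataFrame(recs)
    alien = df[df["status"] == "alien"]

    def genus(s):
        return s.split()[0].split("_")[0]

    species_status = df.drop_duplicates("species").set_index("species")["status"]
    abundance = df.groupby("species").size().rename("total_abundance")
    presence = (
        df.drop_duplicates(["species", "plot_id"])
        .groupby(["species", "vegetation"])
        .size()
        .unstack(fill_value=0)
    )
    for veg in VEGETATION_TYPES:
        if veg not in presence.columns:
            presence[veg] = 0
    table = pd.concat([abundance, presence], axis=1).reset_index()
    table["status"] = table["species"].map(species_status)
    table = table.rename(
        columns={"forest": "forest_plots_present", "grassland": "grassland_plots_present"}
    ).sort_values("total_abundance", ascending=False, ignore_index=True)

    summary = {
        "n_individuals": int(len(df)),
        "n_alien_individuals": int(len(alien)),
        "n_species": int(df["species"].nunique()),
        "n_alien_species": int(alien["species"].nunique()),
        "n_genera": int(df["species"].map(genus).nunique()),
        "n_alien_genera": int(alien["species"].map(genus).nunique()),
        "species_table": table,
    }
    if df["family"].notna().any():
        summary["n_families"] = int(df["family"].dropna().nunique())
        summary["n_alien_families"] = int(alien["family"].dropna().nunique())
    return summary


def read_species_by_plot(path, shape: str = "auto") -> pd.DataFrame:
    """Read a species-by-plot representation table (long or wide).

    Long shape: columns species, plot_id, abundance (one row per
    species-plot pair). Wide shape: a species column followed by one column
    per plot holding abundances. Returns the long form with columns
    species, plot_id, abundance (zero rows dropped).
    """
    df = _normalise_header(pd.read_csv(path))
    if shape == "auto":
        shape = "long" if {"species", "plot_id", "abundance"} <= set(df.columns) else "wide"
    if shape == "long":
        missing = [c for c in ("species", "plot_id", "abundance") if c not in df.columns]
        if missing:
            raise SchemaError(f"long table missing columns: {', '.join(missing)}")
        out = df[["species", "plot_id", "abundance"]].copy()
    elif shape == "wide":
        if "species" not in df.columns:
            raise SchemaError("wide table needs a 'species' column")
        id_cols = [c for c in ("species", "status", "family") if c in df.columns]
        out = df.melt(id_vars=id_cols, var_name="plot_id", value_name="abundance")
        out = out[["species", "plot_id", "abundance"]]
    else:
        raise ValueError(f"unknown shape {shape!r}")
    out["abundance"] = pd.to_numeric(out["abundance"]).fillna(0).astype(int)
    out["plot_id"] = out["plot_id"].astype(str)
    return out[out["abundance"] > 0].reset_index(drop=True)


def summary_from_representation(
    long_df: pd.DataFrame,
    status: dict | None = None,
    family: dict | None = None,
) -> dict:
    """Study totals from a species-by-plot abundance table (no coordinates).

    ``long_df`` is the long form returned by :func:`read_species_by_plot`;
    ``status`` and ``family`` are optional species → value maps. Computes the
    same totals as :func:`study_summary` where derivable from abundances
    alone (individuals, species, genera, and the alien breakdown when a
    status map is given).
    """
    df = long_df.copy()

    def genus(s):
        return s.split()[0].split("_")[0]

    out = {
        "n_individuals": int(df["abundance"].sum()),
        "n_species": int(df["species"].nunique()),
        "n_genera": int(df["species"].map(genus).nunique()),
    }
    if status is not None:
        df["status"] = df["species"].map(status)
        alien = df[df["status"] == "alien"]
        out["n_alien_individuals"] = int(alien["abundance"].sum())
        out["n_alien_species"] = int(alien["species"].nunique())
        out["n_alien_genera"] = int(alien["species"].map(genus).nunique())
    if family is not None:
        fam = df["species"].map(family).dropna()
        out["n_families"] = int(fam.nunique())
        if status is not None:
            out["n_alien_families"] = int(
                df.loc[df["status"] == "alien", "species"].map(family).dropna().nunique()
            )
    return out
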