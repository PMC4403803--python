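"""End-to-end orchestration: plots + tree → Mantel, PD nulls, comparisons.

Runs the full analysis in the order of the field study: build each plot's
matched pair-distance matrices, Mantel-test each plot, run the Faith's-PD
randomization suite (full / aliens removed / graminoids removed), assemble
the per-plot summary table, and fit the between-vegetation ANOVA and the
Mantel-r GLMs. Per-plot failures (too few individuals, degenerate
matrices) are recorded and the run continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparative, mantel, nullmodels, pairs, plots as plot_io, tree as tree_mod

__all__ = ["StudyResult", "run_study"]


@dataclass
class StudyResult:
    mantel_results: dict[str, mantel.MantelResult | None]
    pd_suite: dict[str, dict[str, nullmodels.PDNullResult | None]]
    summaries: list[comparative.PlotSummary]
    anova: dict[str, tuple[float, float] | None]
    glm_fits: list[comparative.ModelFit] | None
    errors: dict[str, str] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return comparative.summaries_to_frame(self.summaries)

    def report(self) -> dict:
        """JSON-serialisable run report (all F, t and p values)."""
        out = {
            "plots": [
                {
                    **{k: v for k, v in vars(s).items()},
                }
                for s in self.summaries
            ],
            "anova": {
                name: None if fp is None else {"F": fp[0], "p": fp[1]}
                for name, fp in self.anova.items()
            },
            "glm": None
            if self.glm_fits is None
            else [
                {
                    "model": f.model_id,
                    "terms": [
                        {"term": n, "estimate": e, "se": se, "t": t, "p": p}
                        for n, e, se, t, p in f.terms
                    ],
                }
                for f in self.glm_fits
            ],
            "pd_classifications": {
                cfg: {
                    pid: None if r is None else r.classification
                    for pid, r in per_plot.items()
                }
                for cfg, per_plot in self.pd_suite.items()
            },
            "errors": self.errors,
        }
        return out


def run_study(
    plots: list[plot_io.PlotData],
    utree: tree_mod.UltrametricTree,
    n_perm: int = 999,
    n_rep: int = 10000,
    alpha: float = 0.05,
    seed: int | None = None,
    include_conspecific: bool = True,
    exclude_status: set | None = None,
    exclude_families: set | None = None,
    genus_fallback: bool = True,
) -> StudyResult:
    """Run the whole pipeline on a set of plots and an ultrametric tree.

    ``exclude_status`` / ``exclude_families`` apply a global sensitivity
    filter before everything else (the PD suite additionally runs its own
    three configurations). With ``genus_fallback`` species names missing
    from the tree are resolved to their genus leaf where possible.
    """
    ss = np.random.SeedSequence(seed)
    s_mantel, s_pd = ss.spawn(2)

    errors: dict[str, str] = {}
    if exclude_status or exclude_families:
        kept = []
        for p in plots:
            try:
                kept.append(
                    plot_io.filter_plot(
                        p, exclude_status=exclude_status, exclude_families=exclude_families
                    )
                )
            except plot_io.EmptyPlotError as exc:
                errors[p.plot_id] = str(exc)
        plots = kept
    if not plots:
        raise ValueError("no plots left to analyse")

    all_species = sorted({s for p in plots for s in p.species})
    resolver = (
        tree_mod.resolve_to_genus(all_species, utree)
        if genus_fallback
        else {s: s for s in all_species}
    )
    sdm = tree_mod.patristic_matrix(utree, sorted(set(resolver.values())))

    mantel_results: dict[str, mantel.MantelResult | None] = {}
    plot_seeds = s_mantel.spawn(len(plots))
    for plot, pseed in zip(plots, plot_seeds):
        try:
            renamed = plot_io.PlotData(
                plot_id=plot.plot_id,
                vegetation=plot.vegetation,
                width=plot.width,
                height=plot.height,
                plants=tuple(
                    plot_io.PlantRecord(
                        individual_id=pl.individual_id,
                        species=resolver[pl.species],
                        status=pl.status,
                        family=pl.family,
                        x=pl.x,
                        y=pl.y,
                    )
                    for pl in plot.plants
                ),
            )
            pds = pairs.build_pair_distances(
                renamed, sdm, include_conspecific=include_conspecific
            )
            mantel_results[plot.plot_id] = mantel.mantel_test(
                pds, n_perm=n_perm, seed=np.random.default_rng(pseed), alpha=alpha
            )
        except (pairs.InsufficientIndividualsError, pairs.DegenerateMatrixError) as exc:
            mantel_results[plot.plot_id] = None
            errors[plot.plot_id] = str(exc)

    pd_suite = nullmodels.run_pd_suite(
        plots,
        utree,
        n_rep=n_rep,
        alpha=alpha,
        seed=int(s_pd.generate_state(1)[0] % (2**31)),
        species_resolver=resolver,
    )

    summaries = []
    for plot in plots:
        mres = mantel_results.get(plot.plot_id)
        pdres = pd_suite["full"].get(plot.plot_id)
        pct = plot_io.percent_alien(plot)
        summaries.append(
            comparative.PlotSummary(
                plot_id=plot.plot_id,
                vegetation=plot.vegetation,
                richness=plot.richness,
                pd=pdres.observed_pd
                if pdres is not None
                else tree_mod.faith_pd(utree, {resolver[s] for s in plot.species}),
                density=plot_io.plant_density(plot),
                pct_alien=pct,
                log_pct_alien=comparative.log_pct_alien(pct),
                mantel_r=None if mres is None else mres.r,
                mantel_p=None if mres is None else mres.p_value,
                pd_classification=None if pdres is None else pdres.classification,
            )
        )

    df = comparative.summaries_to_frame(summaries)
    anova: dict[str, tuple[float, float] | None] = {}
    groups = df["vegetation"].to_numpy()
    for var in ("richness", "pd", "density", "pct_alien", "mantel_r"):
        vals = df[var].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        try:
            anova[var] = comparative.anova_oneway(vals[ok], groups[ok])
        except ValueError as exc:
            anova[var] = None
            errors[f"anova:{var}"] = str(exc)

    try:
        glm_fits = comparative.fit_mantel_glms(summaries)
    except (ValueError, np.linalg.LinAlgError) as exc:
        glm_fits = None
        errors["glm"] = str(exc)

    return StudyResult(
        mantel_results=mantel_results,
        pd_suite=pd_suite,
        summaries=summaries,
        anova=anova,
        glm_fits=glm_fits,
        errors=errors,
    )
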