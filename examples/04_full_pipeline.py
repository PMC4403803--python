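"""The whole analysis in one call: Mantel + PD nulls + ANOVA + GLMs.

Simulates a default-size study (20 plots of 5 × 5 m, ten per vegetation
type, ~200-species pool) and runs the complete pipeline, printing the
between-vegetation ANOVA table and the GLM term tests for Mantel r.
"""

import spacephylo as sp

study = sp.simulate_study(sp.SimParams(seed=2026))
counts = sp.study_summary(study.plots)
print(f"{counts['n_individuals']} individuals, {counts['n_species']} species, "
      f"{counts['n_alien_individuals']} alien individuals "
      f"({100 * counts['n_alien_individuals'] / counts['n_individuals']:.1f}%)")

res = sp.run_study(study.plots, study.tree, n_perm=999, n_rep=10000, seed=1)

print("\none-way ANOVA forest vs grassland:")
for var, fp in res.anova.items():
    if fp is not None:
        print(f"  {var:>10}: F = {fp[0]:7.3f}, p = {fp[1]:.4f}")

n_sig = sum(1 for m in res.mantel_results.values() if m and m.significant)
print(f"\nsignificant Mantel plots: {n_sig} of {len(res.mantel_results)}")

print("\nGLM term tests for Mantel r (vegetation x covariate):")
for fit in res.glm_fits:
    for name, est, se, t, p in fit.terms:
        if name != "Intercept":
            print(f"  [{fit.model_id:>13}] {name:<40} t = {t:6.2f}, p = {p:.4f}")
# Twelve non-intercept P values across the four models; the density ANOVA
# reflects the generator's denser grassland, and the Mantel counts reflect
# the default coupling κ = 0.5.
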