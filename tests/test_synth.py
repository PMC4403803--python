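"""Synthetic study generator: tree, niches, plots, determinism."""

import numpy as np
import pytest

import spacephylo as sp
from spacephylo.synth import yule_event_times


class TestSimulateTree:
    def test_two_species_is_cherry_with_root_age_branches(self):
        t = sp.simulate_tree(2, 120.0, seed=0)
        assert t.n_leaves == 2
        assert t.root_age == pytest.approx(120.0)
        m = sp.patristic_matrix(t, list(t.leaf_labels))
        assert m.values.max() == pytest.approx(240.0)

    def test_output_is_valid_ultrametric_tree(self):
        for seed in range(5):
            t = sp.simulate_tree(25, 150.0, seed=seed)
            assert t.n_leaves == 25
            assert t.root_age == pytest.approx(150.0)
            depths = [t.leaf_depth(l) for l in t.leaf_labels]
            assert max(depths) - min(depths) <= 1e-6 * 150.0

    def test_waiting_times_match_yule_expectation(self):
        """Mean time-to-present of the rate-1 pure-birth process equals the
        harmonic tail sum_{k=2..n} 1/k (analytic Yule oracle)."""
        n, reps = 12, 400
        rng = np.random.default_rng(42)
        ends = [yule_event_times(n, rng)[1] for _ in range(reps)]
        expected = sum(1.0 / k for k in range(2, n + 1))
        sd = np.sqrt(sum(1.0 / k**2 for k in range(2, n + 1)) / reps)
        assert np.mean(ends) == pytest.approx(expected, abs=4 * sd)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            sp.simulate_tree(1, 100.0, seed=0)


class TestSimulateNiches:
    def test_centres_inside_plot_square(self):
        t = sp.simulate_tree(30, 100.0, seed=1)
        centres = sp.simulate_niches(t, plot_size=5.0, seed=2)
        assert set(centres) == set(t.leaf_labels)
        arr = np.array(list(centres.values()))
        assert arr.min() >= 0 and arr.max() <= 5.0

    def test_zero_length_cherry_gets_identical_centres(self):
        t = sp.read_tree("((A:0,B:0):10,C:10);")
        centres = sp.simulate_niches(t, seed=3)
        assert centres["A"] == pytest.approx(centres["B"])

    def test_patristic_distance_correlates_with_centre_distance(self):
        """Brownian centres: closer relatives sit closer, on average."""
        rng = np.random.default_rng(4)
        cors = []
        for _ in range(40):
            t = sp.simulate_tree(20, 100.0, rng)
            centres = sp.simulate_niches(t, seed=rng)
            labels = list(t.leaf_labels)
            pm = sp.patristic_matrix(t, labels).values
            pts = np.array([centres[l] for l in labels])
            sd = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            iu = np.triu_indices(len(labels), k=1)
            cors.append(np.corrcoef(pm[iu], sd[iu])[0, 1])
        assert np.mean(cors) > 0.1


class TestSimulatePlot:
    def _setup(self, **over):
        params = sp.SimParams(
            n_species_pool=30, richness_forest=(5, 10), richness_grassland=(5, 10),
            individuals_forest=(30, 60), individuals_grassland=(40, 80), seed=5, **over,
        )
        t = sp.simulate_tree(30, 100.0, seed=6)
        centres = sp.simulate_niches(t, seed=7)
        return params, t, centres

    def test_abundances_sum_to_drawn_total_and_plot_validates(self):
        params, t, centres = self._setup()
        plot = sp.simulate_plot(t, centres, "forest", params, seed=8)
        assert 30 <= plot.n_plants <= 60
        assert 5 <= plot.richness <= 10
        # PlotData invariants (bounds, uniqueness) checked in its constructor

    def test_kappa_one_small_sigma_aggregates_conspecifics(self):
        params, t, centres = self._setup(kappa=1.0, sigma=0.05)
        plot = sp.simulate_plot(t, centres, "forest", params, seed=9)
        coords = plot.coordinates()
        species = [p.species for p in plot.plants]
        for s in set(species):
            idx = [i for i, x in enumerate(species) if x == s]
            if len(idx) > 1:
                spread = coords[idx].std(axis=0).max()
                assert spread < 0.2  # all near the species centre

    def test_kappa_one_mantel_r_reproducibly_positive(self):
        params, t, centres = self._setup(kappa=1.0)
        sdm = sp.patristic_matrix(t, list(t.leaf_labels))
        rs = []
        for seed in range(12):
            plot = sp.simulate_plot(t, centres, "grassland", params, seed=seed)
            rs.append(sp.pairwise_pearson(sp.build_pair_distances(plot, sdm)))
        assert np.mean(rs) > 0.05

    def test_infeasible_ranges_rejected(self):
        with pytest.raises(ValueError, match="below max richness"):
            sp.SimParams(richness_forest=(10, 50), individuals_forest=(20, 60)).validate()
        with pytest.raises(ValueError, match="kappa"):
            sp.SimParams(kappa=1.5).validate()


class TestSimulateStudy:
    def test_default_parameters_give_twenty_plots_ten_per_vegetation(self):
        study = sp.simulate_study(sp.SimParams(seed=10))
        assert len(study.plots) == 20
        veg = [p.vegetation for p in study.plots]
        assert veg.count("forest") == 10 and veg.count("grassland") == 10
        assert study.tree.n_leaves == 200

    def test_same_seed_gives_byte_identical_files(self, tmp_path, small_params):
        paths = []
        for run in ("a", "b"):
            study = sp.simulate_study(small_params)
            base = tmp_path / run
            base.mkdir()
            sp.write_study(study, base / "t.nwk", base / "s.csv", base / "m.csv")
            paths.append(base)
        for name in ("t.nwk", "s.csv", "m.csv"):
            assert (paths[0] / name).read_bytes() == (paths[1] / name).read_bytes()

    def test_written_study_round_trips_through_readers(self, tmp_path, small_study):
        sp.write_study(small_study, tmp_path / "t.nwk", tmp_path / "s.csv",
                       tmp_path / "m.csv")
        tree = sp.read_tree((tmp_path / "t.nwk").read_text())
        plots = sp.read_stem_maps(tmp_path / "s.csv", tmp_path / "m.csv")
        assert tree.n_leaves == small_study.tree.n_leaves
        assert sum(p.n_plants for p in plots) == sum(
            p.n_plants for p in small_study.plots
        )

    def test_grassland_shallow_clade_depresses_grassland_pd(self):
        """With grassland confined to a shallow clade, mean grassland PD is
        below mean forest PD across replicate studies."""
        diffs = []
        for seed in range(10):
            study = sp.simulate_study(
                sp.SimParams(
                    n_species_pool=60, n_plots_forest=3, n_plots_grassland=3,
                    richness_forest=(6, 12), richness_grassland=(6, 12),
                    individuals_forest=(30, 50), individuals_grassland=(40, 60),
                    grassland_shallow_clade=True, seed=seed,
                )
            )
            pd_by_veg = {"forest": [], "grassland": []}
            for p in study.plots:
                pd_by_veg[p.vegetation].append(sp.faith_pd(study.tree, p.species))
            diffs.append(np.mean(pd_by_veg["forest"]) - np.mean(pd_by_veg["grassland"]))
        assert np.mean(diffs) > 0
        assert sum(d > 0 for d in diffs) >= 8

    def test_alien_species_fraction_close_to_parameter(self):
        study = sp.simulate_study(sp.SimParams(seed=12))
        assert len(study.alien_species) == round(0.09 * 200)
        statuses = {
            p.species: p.status for plot in study.plots for p in plot.plants
        }
        for s, st in statuses.items():
            assert st == ("alien" if s in study.alien_species else "indigenous")
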