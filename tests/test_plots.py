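"""Stem-map IO, per-plot descriptors, filters, study summaries."""

import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import spacephylo as sp
from spacephylo.plots import EmptyPlotError, PlotValidationError, SchemaError

from conftest import make_plot

STEMS_CSV = textwrap.dedent(
    """\
    plot_id,individual_id,species,family,status,x,y
    P1,a1,Acacia karroo,Fabaceae,indigenous,0.5,0.5
    P1,a2,Acacia karroo,Fabaceae,indigenous,1.0,4.0
    P1,a3,Lantana camara,Verbenaceae,alien,2.5,2.5
    P2,b1,Themeda triandra,Poaceae,indigenous,0.1,0.2
    P2,b2,Acacia karroo,Fabaceae,indigenous,3.3,4.4
    """
)
META_CSV = "plot_id,vegetation\nP1,forest\nP2,grassland\n"


@pytest.fixture
def csv_pair(tmp_path):
    stems = tmp_path / "stems.csv"
    meta = tmp_path / "meta.csv"
    stems.write_text(STEMS_CSV)
    meta.write_text(META_CSV)
    return stems, meta


class TestReadStemMaps:
    def test_small_table_partitions_into_plots(self, csv_pair):
        plots = sp.read_stem_maps(*csv_pair)
        assert [p.plot_id for p in plots] == ["P1", "P2"]
        assert [p.n_plants for p in plots] == [3, 2]
        assert plots[0].vegetation == "forest"
        assert sum(p.n_plants for p in plots) == 5  # row conservation

    def test_out_of_bounds_row_rejected_with_row_number(self, tmp_path):
        stems = tmp_path / "stems.csv"
        stems.write_text(STEMS_CSV.replace("3.3,4.4", "5.3,4.4"))
        meta = tmp_path / "meta.csv"
        meta.write_text(META_CSV)
        with pytest.raises(PlotValidationError, match="rows 6"):
            sp.read_stem_maps(stems, meta)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        stems = tmp_path / "stems.csv"
        stems.write_text("plot_id,species,x,y\nP1,A,1,1\n")
        meta = tmp_path / "meta.csv"
        meta.write_text(META_CSV)
        with pytest.raises(SchemaError, match="status"):
            sp.read_stem_maps(stems, meta)

    def test_unknown_vegetation_and_missing_plot_rejected(self, tmp_path):
        stems = tmp_path / "s.csv"
        stems.write_text(STEMS_CSV)
        meta = tmp_path / "m.csv"
        meta.write_text("plot_id,vegetation\nP1,forest\nP2,savanna\n")
        with pytest.raises(PlotValidationError, match="savanna"):
            sp.read_stem_maps(stems, meta)
        meta.write_text("plot_id,vegetation\nP1,forest\n")
        with pytest.raises(PlotValidationError, match="P2"):
            sp.read_stem_maps(stems, meta)

    def test_species_with_conflicting_status_rejected(self, tmp_path):
        stems = tmp_path / "s.csv"
        stems.write_text(STEMS_CSV.replace("P2,b2,Acacia karroo,Fabaceae,indigenous",
                                           "P2,b2,Acacia karroo,Fabaceae,alien"))
        meta = tmp_path / "m.csv"
        meta.write_text(META_CSV)
        with pytest.raises(PlotValidationError, match="Acacia karroo"):
            sp.read_stem_maps(stems, meta)

    def test_write_read_round_trip(self, csv_pair, tmp_path):
        plots = sp.read_stem_maps(*csv_pair)
        out_s, out_m = tmp_path / "o_s.csv", tmp_path / "o_m.csv"
        sp.write_stem_maps(plots, out_s, out_m)
        again = sp.read_stem_maps(out_s, out_m)
        assert again == plots


class TestDescriptors:
    def test_density_is_count_over_area(self):
        plot = make_plot([(i % 5 + 0.1, i // 5 + 0.1) for i in range(25)], ["A"] * 25)
        assert sp.plant_density(plot) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "statuses,expected",
        [(["alien"] + ["indigenous"] * 9, 10.0),
         (["indigenous"] * 10, 0.0),
         (["alien"] * 10, 100.0)],
    )
    def test_percent_alien(self, statuses, expected):
        plot = make_plot([(0.1 * i, 0.1 * i) for i in range(10)], ["A"] * 10,
                         statuses=statuses)
        assert sp.percent_alien(plot) == pytest.approx(expected)


class TestFilterPlot:
    def _plot(self):
        return make_plot(
            [(i * 0.3, i * 0.3) for i in range(10)],
            ["A"] * 5 + ["B"] * 5,
            statuses=["alien"] + ["indigenous"] * 9,
            families=["Poaceae"] * 5 + ["Fabaceae"] * 5,
        )

    def test_exclude_status_removes_exactly_aliens(self):
        assert sp.filter_plot(self._plot(), exclude_status={"alien"}).n_plants == 9

    def test_exclude_family_removes_exactly_that_family(self):
        out = sp.filter_plot(self._plot(), exclude_families={"Poaceae"})
        assert out.n_plants == 5
        assert all(p.family != "Poaceae" for p in out.plants)

    def test_no_exclusions_is_identity(self):
        p = self._plot()
        assert sp.filter_plot(p) == p

    def test_filter_removing_everything_raises(self):
        with pytest.raises(EmptyPlotError):
            sp.filter_plot(self._plot(), exclude_families={"Poaceae", "Fabaceae"})

    def test_filter_composition_is_order_independent(self):
        p = self._plot()
        ab = sp.filter_plot(sp.filter_plot(p, exclude_status={"alien"}),
                            exclude_families={"Poaceae"})
        ba = sp.filter_plot(sp.filter_plot(p, exclude_families={"Poaceae"}),
                            exclude_status={"alien"})
        assert ab == ba

    @given(st.sets(st.sampled_from(["Poaceae", "Fabaceae"])))
    def test_filter_never_increases_plant_count(self, families):
        p = self._plot()
        try:
            assert sp.filter_plot(p, exclude_families=families).n_plants <= p.n_plants
        except EmptyPlotError:
            pass


class TestStudySummary:
    def test_species_shared_between_plots_counted_once(self, csv_pair):
        s = sp.study_summary(sp.read_stem_maps(*csv_pair))
        assert s["n_individuals"] == 5
        assert s["n_species"] == 3  # Acacia karroo appears in both plots
        assert s["n_alien_individuals"] == 1
        assert s["n_alien_species"] == 1
        assert s["n_families"] == 3

    def test_species_table_mirrors_abundance_and_presence(self, csv_pair):
        table = sp.study_summary(sp.read_stem_maps(*csv_pair))["species_table"]
        row = table.set_index("species").loc["Acacia karroo"]
        assert row["total_abundance"] == 3
        assert row["forest_plots_present"] == 1
        assert row["grassland_plots_present"] == 1

    def test_single_plot_single_species(self):
        plot = make_plot([(0.5, 0.5), (1, 1)], ["A", "A"])
        s = sp.study_summary([plot])
        assert s["n_species"] == 1 and s["n_individuals"] == 2

    def test_counts_preserved_on_simulated_study(self, small_study):
        s = sp.study_summary(small_study.plots)
        assert s["n_individuals"] == sum(p.n_plants for p in small_study.plots)
        assert s["n_species"] == len({sp_ for p in small_study.plots for sp_ in p.species})
        assert s["species_table"]["total_abundance"].sum() == s["n_individuals"]


class TestSpeciesByPlotReaders:
    LONG = "species,plot_id,abundance\nA,P1,3\nA,P2,2\nB,P1,1\nC,P2,0\n"
    WIDE = "species,P1,P2\nA,3,2\nB,1,0\nC,0,0\n"

    @pytest.mark.parametrize("text,shape", [(LONG, "long"), (WIDE, "wide")])
    def test_long_and_wide_shapes_agree(self, tmp_path, text, shape):
        f = tmp_path / "rep.csv"
        f.write_text(text)
        df = sp.read_species_by_plot(f, shape="auto")
        assert sorted(df["species"]) == ["A", "A", "B"]
        assert df["abundance"].sum() == 6

    def test_summary_from_representation_totals(self, tmp_path):
        f = tmp_path / "rep.csv"
        f.write_text(self.LONG)
        df = sp.read_species_by_plot(f)
        s = sp.summary_from_representation(df, status={"A": "indigenous", "B": "alien"})
        assert s["n_individuals"] == 6
        assert s["n_species"] == 2
        assert s["n_alien_individuals"] == 1
        assert s["n_alien_species"] == 1
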