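"""Plot-metric oracles: every formula checked against hand computation or
brute force on tiny, fully enumerable inputs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mopane_es.config import AllometryCoeffs, RunConfig
from mopane_es import inventory
from mopane_es.inventory import (
    CwdPiece,
    Quadrat,
    StemRecord,
    correct_dbh,
    cwd_biomass,
    grass_biomass,
    mean_se,
    plot_structure,
    plots_from_frames,
    reconstruct_stump_dbh,
    stem_agb,
)

IDENT = AllometryCoeffs(a=1.0, b=1.0)


class TestCorrectDbh:
    @pytest.mark.parametrize("d, pom, taper, expected", [
        (10.0, 1.3, 0.05, 10.0),          # identity at breast height
        (10.0, 0.3, 0.02, 9.8),           # 10 * (1 - 0.02*1.0)
        (12.0, 0.8, 0.02, 12.0 * 0.99),
    ])
    def test_linear_taper(self, d, pom, taper, expected):
        assert correct_dbh(d, pom, taper) == pytest.approx(expected)

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_diameter(self, d1, d2):
        if d1 == d2:
            return
        lo, hi = sorted((d1, d2))
        assert correct_dbh(lo, 0.5) < correct_dbh(hi, 0.5)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            correct_dbh(0.0, 1.3)
        with pytest.raises(ValueError):
            correct_dbh(10.0, -1.0)


class TestStemAgb:
    def test_identity_coefficients(self):
        assert stem_agb(7.0, IDENT) == pytest.approx(7.0)

    def test_power_evaluation(self):
        # 0.03 * 10**2.5
        assert stem_agb(10.0, AllometryCoeffs(a=0.03, b=2.5)) == pytest.approx(9.4868, abs=1e-4)

    def test_doubling_scales_by_2_to_b(self):
        c = AllometryCoeffs(a=0.03, b=2.5)
        assert stem_agb(14.0, c) / stem_agb(7.0, c) == pytest.approx(2**2.5)

    def test_rejects_nonpositive_dbh(self):
        with pytest.raises(ValueError):
            stem_agb(0.0, IDENT)


class TestPlotStructure:
    def test_empty_plot(self, plot_factory):
        s = plot_structure(plot_factory(), IDENT)
        assert s["stem_density"] == 0 and s["agb"] == 0 and s["richness"] == 0
        assert s["evenness"] == 1.0

    def test_density_of_100_stems(self, plot_factory):
        p = plot_factory([("A", 10.0)] * 100)
        s = plot_structure(p, IDENT)
        assert s["stem_density"] == pytest.approx(100e4 / (math.pi * 400), abs=0.1)
        assert s["stem_density"] == pytest.approx(795.77, abs=0.01)

    def test_equal_shares_maximal_evenness(self, plot_factory):
        p = plot_factory([("A", 10.0), ("B", 10.0), ("C", 10.0), ("D", 10.0)])
        assert plot_structure(p, IDENT)["evenness"] == pytest.approx(1.0)

    def test_matches_brute_force(self, plot_factory):
        coeffs = AllometryCoeffs(a=0.02, b=2.2)
        taper = 0.03
        stems = [("A", 7.2), ("A", 11.0), ("B", 5.5),
                 dict(species="C", diameter=9.0, pom=0.7),
                 dict(species="B", diameter=30.0),
                 dict(species="D", diameter=14.0, alive=False),          # standing dead
                 dict(species="A", diameter=8.0, pom=0.3, alive=False,
                      cut=True, stump_height=0.4)]                        # stump
        p = plot_factory(stems)
        s = plot_structure(p, coeffs, taper)
        # brute force over the five live intact stems
        area = math.pi * 400 / 1e4
        dbhs = [7.2, 11.0, 5.5, 9.0 * (1 - taper * (1.3 - 0.7)), 30.0]
        agb = sum(0.02 * d**2.2 for d in dbhs)
        assert s["n_live"] == 5
        assert s["stem_density"] == pytest.approx(5 / area)
        assert s["agb"] == pytest.approx(agb / area)
        assert s["richness"] == 3  # live species {A, B, C}

    def test_richness_counts_live_species_only(self, plot_factory):
        p = plot_factory([("A", 7.0), ("B", 8.0),
                          dict(species="Z", diameter=9.0, alive=False)])
        assert plot_structure(p, IDENT)["richness"] == 2


class TestGrass:
    def test_zero_quadrats_mass(self, plot_factory):
        p = plot_factory()
        p.quadrats = [Quadrat(0.0, 0.5)] * 4
        assert grass_biomass(p) == 0.0

    def test_unit_conversion(self, plot_factory):
        # 100 g fresh * 0.5 dry = 50 g m^-2 = 0.5 Mg ha^-1
        p = plot_factory()
        p.quadrats = [Quadrat(100.0, 0.5)] * 4
        assert grass_biomass(p) == pytest.approx(0.5)

    def test_burnt_plot_is_excluded_not_crashed(self, plot_factory):
        p = plot_factory(burnt=True)
        p.quadrats = [Quadrat(100.0, 0.5)] * 4
        assert np.isnan(grass_biomass(p))


class TestCwd:
    DENS = {1: 0.9, 2: 0.9, 3: 0.9, 4: 0.9, 5: 0.9}

    def test_no_pieces(self, plot_factory):
        assert cwd_biomass(plot_factory(), self.DENS) == 0.0

    def test_line_intersect_hand_value(self, plot_factory):
        # one 10 cm piece over 80 m of transect, density 0.9, C fraction 0.47
        p = plot_factory()
        p.cwd_pieces = [CwdPiece(10.0, 2.0, 1)]
        vol = math.pi**2 / (8 * 80) * 0.1**2 * 1e4
        assert vol == pytest.approx(1.5421, abs=1e-4)
        assert cwd_biomass(p, self.DENS, 0.47) == pytest.approx(vol * 0.9 * 0.47)
        assert cwd_biomass(p, self.DENS, 0.47) == pytest.approx(0.652, abs=1e-3)

    def test_quadratic_in_diameter(self, plot_factory):
        p1, p2 = plot_factory(), plot_factory()
        p1.cwd_pieces = [CwdPiece(5.0, 1.0, 2), CwdPiece(8.0, 1.0, 2)]
        p2.cwd_pieces = [CwdPiece(10.0, 1.0, 2), CwdPiece(16.0, 1.0, 2)]
        assert cwd_biomass(p2, self.DENS) == pytest.approx(4 * cwd_biomass(p1, self.DENS))

    def test_small_pieces_rejected_at_ingest(self):
        plots_df = pd.DataFrame([{"plot_id": "P", "village": "V", "radius_m": 20.0,
                                  "burnt": False}])
        stems_df = pd.DataFrame(columns=["plot_id", "species", "diameter_cm",
                                         "pom_m", "alive", "cut"])
        quad_df = pd.DataFrame(columns=["plot_id", "fresh_g", "dry_fraction"])
        cwd_df = pd.DataFrame([
            {"plot_id": "P", "diameter_cm": 2.9, "length_m": 2.0, "decay_class": 1},
            {"plot_id": "P", "diameter_cm": 10.0, "length_m": 0.4, "decay_class": 1},
            {"plot_id": "P", "diameter_cm": 10.0, "length_m": 2.0, "decay_class": 1},
        ])
        (plot,) = plots_from_frames(plots_df, stems_df, quad_df, cwd_df)
        assert len(plot.cwd_pieces) == 1


class TestStumpReconstruction:
    def test_identity_at_breast_height(self):
        s = StemRecord("P", "A", 12.0, pom=1.3, alive=False, cut=True, stump_height=1.4)
        assert reconstruct_stump_dbh(s, 0.02) == pytest.approx(12.0)

    def test_taper_projection(self):
        s = StemRecord("P", "A", 12.0, pom=0.3, alive=False, cut=True, stump_height=0.4)
        assert reconstruct_stump_dbh(s, 0.02) == pytest.approx(11.76)

    def test_missing_height_skipped(self):
        s = StemRecord("P", "A", 12.0, pom=float("nan"), alive=False, cut=True,
                       stump_height=0.4)
        assert reconstruct_stump_dbh(s, 0.02) is None

    def test_generator_round_trip(self, type_params, run_config, links):
        """A generated stump projects back to the DBH the tree was drawn with."""
        rng = np.random.default_rng(5)
        tp = type_params["Mopane woodland"]
        stumps = []
        for _ in range(20):
            from mopane_es.synth import gen_plot
            p = gen_plot(tp, 1.0, rng, config=run_config,
                         charcoal_species=links.species_for("charcoal"))
            stumps += [s for s in p.stems if s.cut]
        assert stumps
        for s in stumps:
            dbh = reconstruct_stump_dbh(s, run_config.taper)
            # suitability threshold was applied to the original DBH (>= 10 cm)
            assert dbh >= 10.0 - 1e-9


class TestMeanSe:
    def test_matches_sd_over_sqrt_n(self):
        vals = [2.0, 4.0, 6.0, 8.0]
        m, se = mean_se(vals)
        assert m == 5.0
        assert se == pytest.approx(np.std(vals, ddof=1) / 2.0)

    def test_suppressed_below_min_n(self):
        m, se = mean_se([2.0, 4.0])
        assert m == 3.0 and np.isnan(se)

    def test_nan_values_do_not_count(self):
        m, se = mean_se([1.0, 1.0, 1.0, float("nan")])
        assert m == 1.0 and np.isnan(se)

    def test_identical_values_zero_se(self):
        _, se = mean_se([3.0] * 5)
        assert se == 0.0
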