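"""Rho factors, resistance surrogates, calibration and AIS/soma adaptation."""

import math

import numpy as np
import pytest

from empop import morph, rho, sim
from empop.rho import RhoTargets


@pytest.fixture(scope="module")
def passive_params():
    return {"all.pas.g": 1e-4, "all.pas.e": -75.0}


@pytest.fixture(scope="module")
def fixture_morph(ball_and_stick):
    return ball_and_stick


class TestComponentResistances:
    def test_isolated_soma_closed_form(self, fixture_morph, passive_params):
        comp = rho.component_resistances(fixture_morph, passive_params)
        area = fixture_morph.soma_area * 1e-8  # cm^2
        expected = 1.0 / (1e-4 * area) / 1e6  # MOhm
        assert comp.rin_soma == pytest.approx(expected, rel=0.01)

    def test_rho_arithmetic(self):
        c = rho.ComponentResistances(
            rin_soma=1000.0, rin_ais=500.0, rin_nosoma=250.0, rin_noais=125.0
        )
        rf = c.rho_factors()
        assert rf.rho == 4.0
        assert rf.rho_ais == 4.0

    def test_all_four_match_nodal_oracle(self, fixture_morph, passive_params):
        """Passive three-component cell: every component resistance agrees
        with an independent dense nodal-analysis solve."""
        comp = rho.component_resistances(fixture_morph, passive_params)

        def oracle(include, junction):
            cell = sim.build_cell(
                fixture_morph, passive_params,
                include_regions=include, junction_root=junction,
            )
            n = cell.n
            g_m = cell.g_pas * cell.area * cell.memb_scale * 1e6
            G = np.diag(g_m)
            for i in range(1, n):
                p = cell.parent[i]
                G[i, i] += cell.g_axial[i]
                G[p, p] += cell.g_axial[i]
                G[i, p] -= cell.g_axial[i]
                G[p, i] -= cell.g_axial[i]
            b0 = g_m * cell.e_pas
            v0 = np.linalg.solve(G, b0)
            b1 = b0.copy()
            b1[0] += -0.02
            v1 = np.linalg.solve(G, b1)
            return (v1[0] - v0[0]) / -0.02

        assert comp.rin_soma == pytest.approx(oracle({"somatic"}, False), rel=0.005)
        assert comp.rin_ais == pytest.approx(oracle({"axonal"}, True), rel=0.005)
        assert comp.rin_nosoma == pytest.approx(
            oracle({"axonal", "myelin", "basal", "apical"}, True), rel=0.005
        )
        assert comp.rin_noais == pytest.approx(
            oracle({"somatic", "basal", "apical"}, False), rel=0.005
        )

    def test_missing_ais_errors(self, passive_params):
        s = morph.Section(0, "basal", np.array([[0, 0, 0, 1.0], [0, 100, 0, 1.0]]))
        m = morph.Morphology(8.0, 8.0, {0: s})
        with pytest.raises(rho.RhoError, match="AIS"):
            rho.component_resistances(m, passive_params)


class TestResistanceSurrogate:
    def test_soma_power_law_slope(self, fixture_morph, passive_params):
        """Isolated soma: every membrane conductance scales with area, so
        Rin is exactly proportional to scale^-2 -> log-log slope -2."""
        sur = rho.fit_resistance_surrogate(fixture_morph, passive_params, "soma")
        c3, c2, c1, c0 = sur.coefficients
        assert c1 == pytest.approx(-2.0, abs=1e-6)
        assert abs(c3) < 1e-6 and abs(c2) < 1e-6
        assert not sur.poor_fit

    def test_inversion_closed_form(self, fixture_morph, passive_params):
        sur = rho.fit_resistance_surrogate(fixture_morph, passive_params, "soma")
        r1 = float(sur.predict(1.0))
        scale, clamped = sur.invert(r1 / 4.0)
        assert not clamped
        assert scale == pytest.approx(2.0, abs=1e-3)

    def test_constant_resistance_degenerate(self):
        sur = rho.ResistanceSurrogate("soma", np.array([0.0, 0.0, 0.0, 2.0]), rms=0.0)
        assert float(sur.predict(0.5)) == pytest.approx(100.0)

    def test_out_of_range_target_clamps(self, fixture_morph, passive_params):
        sur = rho.fit_resistance_surrogate(fixture_morph, passive_params, "soma")
        huge = float(sur.predict(0.1)) * 100
        scale, clamped = sur.invert(huge)
        assert clamped
        assert scale == pytest.approx(0.1)

    def test_cross_validated_prediction_error(self, fixture_morph, passive_params):
        """Held-out scales predicted within 2% across the fitted range."""
        sur = rho.fit_resistance_surrogate(fixture_morph, passive_params, "AIS")
        for s in np.geomspace(0.15, 8.0, 7):  # off-grid scales
            cell = sim.build_cell(
                fixture_morph, passive_params, ais_scale=s,
                include_regions={"axonal"}, junction_root=True,
            )
            actual = sim.input_resistance(cell, site=0, probe_amp=-0.02, method="steady").rin
            assert float(sur.predict(s)) == pytest.approx(actual, rel=0.02)


class TestCalibration:
    def test_planted_minimum_recovered(self, fixture_morph, fixture_problem_small):
        prob = fixture_problem_small
        grid = rho.SCALE_GRID

        def planted(ais_s, soma_s):
            return 10 * ((ais_s - grid[6]) ** 2 + (soma_s - grid[2]) ** 2)

        rt = rho.calibrate_rho_targets(
            prob.p_true, prob.exemplar, prob.targets, prob.suite,
            base_params=prob.base_params, evaluator=planted,
        )
        assert rt.grid_point == (pytest.approx(grid[6]), pytest.approx(grid[2]))
        # rho factors computed at the planted grid point
        comp = rho.component_resistances(
            prob.exemplar, {**prob.base_params, **prob.p_true},
            soma_scale=grid[2], ais_scale=grid[6],
        )
        rf = comp.rho_factors()
        assert rt.rho == pytest.approx(rf.rho, rel=1e-9)
        assert rt.rho_ais == pytest.approx(rf.rho_ais, rel=1e-9)

    def test_symmetric_bowl_center(self, fixture_problem_small):
        prob = fixture_problem_small
        grid = rho.SCALE_GRID
        center = grid[len(grid) // 2]

        def bowl(a, s):
            return (a - center) ** 2 + (s - center) ** 2

        rt = rho.calibrate_rho_targets(
            prob.p_true, prob.exemplar, prob.targets, prob.suite,
            base_params=prob.base_params, evaluator=bowl,
        )
        assert rt.grid_point == (pytest.approx(center), pytest.approx(center))

    def test_tie_breaks_toward_lowest_scales(self, fixture_problem_small):
        prob = fixture_problem_small
        rt = rho.calibrate_rho_targets(
            prob.p_true, prob.exemplar, prob.targets, prob.suite,
            base_params=prob.base_params, evaluator=lambda a, s: 1.0,
        )
        grid = rho.SCALE_GRID
        assert rt.grid_point == (pytest.approx(grid[0]), pytest.approx(grid[0]))

    def test_argmin_invariant_to_constant_shift(self, fixture_problem_small):
        prob = fixture_problem_small
        grid = rho.SCALE_GRID

        def base(a, s):
            return (a - grid[3]) ** 2 + (s - grid[7]) ** 2

        r1 = rho.calibrate_rho_targets(
            prob.p_true, prob.exemplar, prob.targets, prob.suite,
            base_params=prob.base_params, evaluator=base,
        )
        r2 = rho.calibrate_rho_targets(
            prob.p_true, prob.exemplar, prob.targets, prob.suite,
            base_params=prob.base_params, evaluator=lambda a, s: base(a, s) + 2.0,
        )
        assert r1.grid_point == r2.grid_point

    def test_all_non_spiking_grid_fails(self, fixture_problem_small):
        prob = fixture_problem_small
        from empop.cost import MAX_COST

        with pytest.raises(rho.RhoError, match="all grid points"):
            rho.calibrate_rho_targets(
                prob.p_true, prob.exemplar, prob.targets, prob.suite,
                base_params=prob.base_params, evaluator=lambda a, s: MAX_COST,
            )


@pytest.fixture(scope="module")
def surrogates(fixture_problem_small):
    prob = fixture_problem_small
    full = {**prob.base_params, **prob.p_true}
    soma = rho.fit_resistance_surrogate(prob.exemplar, full, "soma")
    ais = rho.fit_resistance_surrogate(prob.exemplar, full, "AIS")
    return soma, ais


class TestAdaptation:
    def test_fixed_point_leaves_cell_unchanged(self, fixture_problem_small, surrogates):
        prob = fixture_problem_small
        full = {**prob.base_params, **prob.p_true}
        comp = rho.component_resistances(prob.exemplar, full)
        rf = comp.rho_factors()
        targets = RhoTargets(rho=rf.rho, rho_ais=rf.rho_ais)
        res = rho.adapt_ais_soma(prob.exemplar, full, targets, *surrogates)
        assert res.soma_scale == pytest.approx(1.0, abs=0.01)
        assert res.ais_scale == pytest.approx(1.0, abs=0.01)

    def test_planted_target_reached_within_5_percent(self, fixture_problem_small, surrogates):
        """Forward-simulate AIS scale 1.3, use its rho factors as targets."""
        prob = fixture_problem_small
        full = {**prob.base_params, **prob.p_true}
        comp = rho.component_resistances(prob.exemplar, full, ais_scale=1.3, soma_scale=1.1)
        rf = comp.rho_factors()
        targets = RhoTargets(rho=rf.rho, rho_ais=rf.rho_ais)
        res = rho.adapt_ais_soma(prob.exemplar, full, targets, *surrogates, n_rounds=2)
        assert res.achieved.rho == pytest.approx(rf.rho, rel=0.05)
        assert res.achieved.rho_ais == pytest.approx(rf.rho_ais, rel=0.05)
        assert res.ais_scale == pytest.approx(1.3, rel=0.05)

    def test_transfer_to_other_morphologies(self, fixture_problem_small, surrogates):
        """Exemplar-calibrated targets are achieved on different cells."""
        prob = fixture_problem_small
        full = {**prob.base_params, **prob.p_true}
        comp = rho.component_resistances(prob.exemplar, full)
        rf = comp.rho_factors()
        targets = RhoTargets(rho=rf.rho, rho_ais=rf.rho_ais)
        for m in prob.population[:3]:
            res = rho.adapt_ais_soma(m, full, targets, *surrogates)
            assert res.achieved.rho == pytest.approx(rf.rho, rel=0.05)
            assert res.achieved.rho_ais == pytest.approx(rf.rho_ais, rel=0.05)

    def test_rounds_do_not_diverge(self, fixture_problem_small, surrogates):
        prob = fixture_problem_small
        full = {**prob.base_params, **prob.p_true}
        comp = rho.component_resistances(prob.exemplar, full, ais_scale=1.2)
        rf = comp.rho_factors()
        targets = RhoTargets(rho=rf.rho, rho_ais=rf.rho_ais)
        m = prob.population[0]
        errs = []
        for rounds in (1, 2):
            res = rho.adapt_ais_soma(m, full, targets, *surrogates, n_rounds=rounds)
            errs.append(
                abs(res.achieved.rho - rf.rho) / rf.rho
                + abs(res.achieved.rho_ais - rf.rho_ais) / rf.rho_ais
            )
        assert errs[1] <= errs[0] + 1e-6

    def test_poor_fit_blocks_adaptation(self, fixture_problem_small, surrogates):
        prob = fixture_problem_small
        bad = rho.ResistanceSurrogate("soma", surrogates[0].coefficients, rms=0.2, poor_fit=True)
        with pytest.raises(rho.RhoError, match="poor"):
            rho.adapt_ais_soma(
                prob.exemplar, {**prob.base_params, **prob.p_true},
                RhoTargets(rho=5.0, rho_ais=30.0), bad, surrogates[1],
            )

    def test_rho_identity_holds(self, fixture_problem_small):
        """rho * Rin_nosoma = Rin_soma by construction."""
        prob = fixture_problem_small
        full = {**prob.base_params, **prob.p_true}
        comp = rho.component_resistances(prob.exemplar, full)
        rf = comp.rho_factors()
        assert rf.rho * comp.rin_nosoma == pytest.approx(comp.rin_soma, rel=1e-12)
        assert rf.rho_ais * comp.rin_noais == pytest.approx(comp.rin_ais, rel=1e-12)
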