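"""Morphology I/O, morphometrics, diametrization and exemplar selection."""

import math

import numpy as np
import pytest

from empop import morph
from empop.fixtures import FixtureConfig, gen_morph_population


def write(tmp_path, text, name="cell.swc"):
    p = tmp_path / name
    p.write_text(text)
    return p


SIMPLE_SWC = """# comment line
1 1 0 0 0 5.0 -1
2 3 0 0 0 1.0 1
3 3 0 30 40 1.0 2
"""


class TestReadSWC:
    def test_single_neurite_length_is_point_distance(self, tmp_path):
        m = morph.read_swc(write(tmp_path, SIMPLE_SWC))
        secs = list(m.iter_sections())
        assert len(secs) == 1
        assert secs[0].stype == "basal"
        assert secs[0].length == pytest.approx(50.0)  # 3-4-5 triangle
        # radii doubled to diameters
        assert np.allclose(secs[0].points[:, 3], 2.0)

    def test_spherical_soma_becomes_equal_area_cylinder(self, tmp_path):
        m = morph.read_swc(write(tmp_path, SIMPLE_SWC))
        assert m.soma_area == pytest.approx(4 * math.pi * 5.0**2)

    def test_round_trip_identity(self, tmp_path):
        cfg = FixtureConfig(n_morphs=3, seed=7)
        for i, m in enumerate(gen_morph_population(cfg)):
            p = tmp_path / f"c{i}.swc"
            morph.write_swc(m, p)
            m2 = morph.read_swc(p)
            p2 = tmp_path / f"c{i}_again.swc"
            morph.write_swc(m2, p2)
            assert p.read_text() == p2.read_text()  # bit-equal after one cycle
            # unbranched runs are normalized on read; a second cycle is exact
            m3 = morph.read_swc(p2)
            assert len(m3.sections) == len(m2.sections)
            for sid in m2.sections:
                assert np.array_equal(m3.sections[sid].points, m2.sections[sid].points)
            assert m2.soma_area == pytest.approx(m.soma_area, rel=1e-12)

    def test_orphan_parent_is_parse_error(self, tmp_path):
        bad = "1 1 0 0 0 5.0 -1\n5 3 0 10 0 1.0 99\n"
        with pytest.raises(morph.MorphologyError, match="99"):
            morph.read_swc(write(tmp_path, bad))

    def test_non_positive_radius_rejected(self, tmp_path):
        bad = "1 1 0 0 0 5.0 -1\n2 3 0 10 0 0.0 1\n"
        with pytest.raises(morph.MorphologyError, match="radius"):
            morph.read_swc(write(tmp_path, bad))


class TestResidualPathDistances:
    def test_two_section_chain(self):
        s0 = morph.Section(0, "basal", np.array([[0, 0, 0, 1.0], [0, 50, 0, 1.0]]))
        s1 = morph.Section(1, "basal", np.array([[0, 50, 0, 1.0], [0, 100, 0, 1.0]]), parent=0)
        m = morph.Morphology(8.0, 8.0, {0: s0, 1: s1})
        r = morph.residual_path_distances(m, "basal")
        assert r[0] == pytest.approx(0.5)  # root end -> 50/100
        assert r[1] == 0.0  # terminal

    def test_y_tree_against_brute_force(self, y_tree):
        r = morph.residual_path_distances(y_tree, "basal")
        # brute force: enumerate root-to-tip paths
        paths = [100 + 30, 100 + 70]
        lmax = max(paths)
        assert r[0] == pytest.approx(70 / lmax)
        assert r[1] == 0.0 and r[2] == 0.0
        assert all(0.0 <= v <= 1.0 for v in r.values())

    def test_single_section_maps_to_zero(self):
        s0 = morph.Section(0, "apical", np.array([[0, 0, 0, 1.0], [0, 80, 0, 1.0]]))
        m = morph.Morphology(8.0, 8.0, {0: s0})
        assert morph.residual_path_distances(m, "apical") == {0: 0.0}

    def test_empty_type_gives_empty_map(self, y_tree):
        assert morph.residual_path_distances(y_tree, "apical") == {}


class TestDiameterModel:
    def _linear_pop(self):
        """Population whose section mean diameter is exactly 2.0 - 1.5 x."""
        pop = []
        s0 = morph.Section(0, "basal", np.array([[0, 0, 0, 1.0], [0, 60, 0, 1.0]]))
        s1 = morph.Section(1, "basal", np.array([[0, 60, 0, 1.0], [0, 100, 0, 1.0]]), parent=0)
        m = morph.Morphology(8.0, 8.0, {0: s0, 1: s1})
        coords = morph._section_coordinates(m, "basal")
        for sid, x in coords.items():
            m.sections[sid].points[:, 3] = 2.0 - 1.5 * x
        pop.append(m)
        return pop

    def test_exact_linear_recovery(self):
        model = morph.fit_diameter_model(self._linear_pop(), "basal", degree=1)
        assert np.allclose(model.coefficients, [-1.5, 2.0], atol=1e-9)

    def test_constant_population(self, y_tree):
        m = y_tree.copy()
        for s in m.sections.values():
            s.points[:, 3] = 1.0
        model = morph.fit_diameter_model([m], "basal", degree=0)
        assert model(0.3) == pytest.approx(1.0)

    def test_underdetermined_fit_errors(self):
        s0 = morph.Section(0, "basal", np.array([[0, 0, 0, 1.0], [0, 60, 0, 1.0]]))
        m = morph.Morphology(8.0, 8.0, {0: s0})
        with pytest.raises(morph.MorphologyError, match="polynomial"):
            morph.fit_diameter_model([m], "basal", degree=3)


class TestApplyDiametrization:
    def test_last_diameter_rule(self, y_tree):
        model = morph.DiameterModel("basal", 1, np.array([-1.0, 2.0]))  # 2 - x
        out = morph.apply_diametrization(y_tree, model)
        coords = morph._section_coordinates(y_tree, "basal")
        d_first = {sid: 2.0 - x for sid, x in coords.items()}
        expected_last = 0.5 * (d_first[0] + max(d_first[1], d_first[2]))
        assert out.sections[0].points[-1, 3] == pytest.approx(expected_last)
        # stated arithmetic example: first 2.0 and children {1.0, 1.4} -> 1.7
        assert 0.5 * (2.0 + max(1.0, 1.4)) == pytest.approx(1.7)

    def test_idempotent(self, y_tree):
        model = morph.DiameterModel("basal", 1, np.array([-1.0, 2.0]))
        once = morph.apply_diametrization(y_tree, model)
        twice = morph.apply_diametrization(once, model)
        for sid in once.sections:
            assert np.array_equal(once.sections[sid].points, twice.sections[sid].points)

    def test_constant_model(self, y_tree):
        model = morph.DiameterModel("basal", 0, np.array([1.0]))
        out = morph.apply_diametrization(y_tree, model)
        for s in out.iter_sections("basal"):
            assert np.allclose(s.points[:, 3], 1.0)

    def test_geometry_unchanged(self, y_tree):
        model = morph.DiameterModel("basal", 1, np.array([-1.0, 2.0]))
        out = morph.apply_diametrization(y_tree, model)
        for sid in y_tree.sections:
            assert np.array_equal(
                out.sections[sid].points[:, :3], y_tree.sections[sid].points[:, :3]
            )


class TestSurfaceAreas:
    def _cylinder(self, d=2.0, length=100.0):
        s = morph.Section(0, "basal", np.array([[0, 0, 0, d], [0, length, 0, d]]))
        return morph.Morphology(8.0, 8.0, {0: s})

    def test_cylinder_total(self):
        m = self._cylinder()
        assert morph.total_dendrite_area(m) == pytest.approx(2 * math.pi * 1 * 100, rel=1e-12)

    def test_cylinder_proximal_cutoff(self):
        m = self._cylinder()
        assert morph.proximal_surface_area(m, 50.0) == pytest.approx(math.pi * 2 * 50, rel=1e-12)

    def test_tapered_frustum_vs_fine_integration(self):
        s = morph.Section(0, "basal", np.array([[0, 0, 0, 2.0], [0, 10, 0, 1.0]]))
        m = morph.Morphology(8.0, 8.0, {0: s})
        # oracle: fine-grained numerical integration of 2 pi r(l) sqrt(1+r'^2) dl
        ls = np.linspace(0, 10, 200001)
        rs = 1.0 - 0.05 * ls
        slant = math.sqrt(1 + 0.05**2)
        oracle = np.trapezoid(2 * math.pi * rs * slant, ls)
        assert morph.total_dendrite_area(m) == pytest.approx(oracle, rel=1e-3)

    def test_profile_total_matches_segment_oracle(self, y_tree):
        prof = morph.surface_area_profile(y_tree, bin_width=20.0)
        oracle = 0.0
        for sec in y_tree.iter_sections():
            pts = sec.points
            for i in range(len(pts) - 1):
                r0, r1 = pts[i, 3] / 2, pts[i + 1, 3] / 2
                seg = np.linalg.norm(pts[i + 1, :3] - pts[i, :3])
                oracle += math.pi * (r0 + r1) * math.sqrt(seg**2 + (r1 - r0) ** 2)
        assert prof.total == pytest.approx(oracle, rel=1e-9)
        assert np.all(np.diff(prof.cumulative_area) >= 0)


class TestBuildExemplar:
    def test_identical_population(self, y_tree):
        pop = [y_tree.copy() for _ in range(3)]
        ex = morph.build_exemplar(pop)
        assert ex.soma_area == pytest.approx(y_tree.soma_area, rel=1e-9)
        dend = [s for s in ex.iter_sections() if s.stype == "basal"]
        assert len(dend) == len([s for s in y_tree.iter_sections("basal")])

    def test_mean_soma_area(self):
        pop = []
        for target in (400.0, 500.0, 600.0):
            m = morph.Morphology(8.0, target / (2 * math.pi * 8.0) - 8.0, {})
            s = morph.Section(0, "basal", np.array([[0, 0, 0, 1.0], [0, 50, 0, 1.0]]))
            m.sections[0] = s
            assert m.soma_area == pytest.approx(target)
            pop.append(m)
        with pytest.warns(UserWarning, match="no axons"):
            ex = morph.build_exemplar(pop)
        assert ex.soma_area == pytest.approx(500.0, rel=1e-9)

    def test_selects_planted_median_profile(self):
        cfg = FixtureConfig(n_morphs=5, seed=3)
        pop = gen_morph_population(cfg)
        ex = morph.build_exemplar(pop)
        # brute-force oracle over all profiles
        mat = morph._profile_matrix(pop, 20.0)
        med = np.median(mat, axis=0)
        expected = int(np.argmin(np.linalg.norm(mat - med, axis=1)))
        assert ex.metadata["exemplar"]["chosen_index"] == expected

    def test_exemplar_has_ais_and_myelin(self):
        pop = gen_morph_population(FixtureConfig(n_morphs=4, seed=5))
        ex = morph.build_exemplar(pop)
        ais = [s for s in ex.iter_sections("AIS")]
        myelin = [s for s in ex.iter_sections("myelin")]
        assert len(ais) == 2 and sum(s.length for s in ais) == pytest.approx(60.0)
        assert len(myelin) == 1 and myelin[0].length == pytest.approx(1000.0)


class TestPopulationGenerator:
    def test_spread_controls_area_ratio(self):
        pop = gen_morph_population(FixtureConfig(n_morphs=50, spread=4.0, seed=1))
        areas = [morph.total_dendrite_area(m) for m in pop]
        assert 3.0 <= max(areas) / min(areas) <= 5.0

    def test_spread_one_identical_up_to_rotation(self):
        pop = gen_morph_population(FixtureConfig(n_morphs=5, spread=1.0, seed=2))
        areas = [morph.total_dendrite_area(m) for m in pop]
        assert np.allclose(areas, areas[0], rtol=1e-9)
        lengths = [sum(s.length for s in m.iter_sections()) for m in pop]
        assert np.allclose(lengths, lengths[0], rtol=1e-9)

    def test_deterministic_per_seed(self, tmp_path):
        cfg = FixtureConfig(n_morphs=3, seed=11)
        gen_morph_population(cfg, out_dir=tmp_path / "a")
        gen_morph_population(cfg, out_dir=tmp_path / "b")
        for i in range(3):
            assert (tmp_path / "a" / f"cell_{i}.swc").read_text() == (
                tmp_path / "b" / f"cell_{i}.swc"
            ).read_text()

    def test_generated_morphologies_validate(self):
        for m in gen_morph_population(FixtureConfig(n_morphs=4, seed=9)):
            m.validate()
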