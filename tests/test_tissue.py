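import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ringmc import (FingerGeometry, LayerComposition, PhysiologicalState,
                    build_tissue_map, classify_point, default_compositions,
                    mix_absorption)
from ringmc.properties import LAYER_INDEX
from ringmc.spectra import SpectrumRangeError
from ringmc.tissue import OUTSIDE, CompositionError, GeometryError


def _comp(fractions, layer="reticular_dermis"):
    return LayerComposition(layer=layer, fractions=fractions,
                            mu_s_per_cm={660.0: 100.0}, g=0.8, n=1.4)


class TestMixAbsorption:
    def test_empty_mixture_is_transparent(self, spectra):
        comp = _comp({"water": 0.0, "blood": 0.0})
        assert mix_absorption(comp, spectra, 660, 1.0) == 0.0

    def test_pure_water_identity_lookup(self, spectra):
        comp = _comp({"water": 1.0})
        assert mix_absorption(comp, spectra, 940, 1.0) == \
            spectra.absorption("water", 940)

    @pytest.mark.parametrize("spo2_pair", [(0.70, 1.00)])
    def test_red_absorption_rises_with_desaturation(self, spectra,
                                                    spo2_pair):
        """At 660 nm deoxy-Hb absorbs more, so lower SpO2 -> higher mu_a;
        cross-checked against a direct evaluation of the two-term blood
        mixing formula."""
        comp = _comp({"blood": 1.0}, layer="artery_blood")
        lo, hi = spo2_pair
        mu_lo = mix_absorption(comp, spectra, 660, lo)
        mu_hi = mix_absorption(comp, spectra, 660, hi)
        assert mu_lo > mu_hi
        for s, mu in ((lo, mu_lo), (hi, mu_hi)):
            direct = (s * spectra.absorption("oxy_hb", 660)
                      + (1 - s) * spectra.absorption("deoxy_hb", 660))
            assert mu == pytest.approx(direct, rel=1e-12)

    @given(m1=st.floats(0.1, 2.0), m2=st.floats(0.1, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_in_blood_multiplier(self, spectra, m1, m2):
        comp = _comp({"blood": 0.3, "water": 0.3})
        if m1 == m2:
            return
        lo, hi = sorted((m1, m2))
        assert mix_absorption(comp, spectra, 660, 0.9, lo) < \
            mix_absorption(comp, spectra, 660, 0.9, hi)

    def test_multiplier_overflow_rejected(self, spectra):
        comp = _comp({"blood": 0.5, "water": 0.5})
        with pytest.raises(CompositionError):
            mix_absorption(comp, spectra, 660, 1.0, phase_multiplier=1.5)

    def test_wavelength_out_of_table_rejected(self, spectra):
        comp = _comp({"water": 1.0})
        with pytest.raises(SpectrumRangeError):
            mix_absorption(comp, spectra, 1500, 1.0)


class TestCompositionValidation:
    def test_fraction_sum_above_one_rejected(self):
        with pytest.raises(CompositionError):
            _comp({"water": 0.7, "collagen": 0.4})

    def test_anisotropy_bounds(self):
        with pytest.raises(CompositionError):
            LayerComposition(layer="bone", fractions={"water": 1.0},
                             mu_s_per_cm={660.0: 10.0}, g=1.0, n=1.4)


@pytest.fixture(scope="module")
def dia_map(model):
    return build_tissue_map(model.geometry, list(model.compositions),
                            model.spectra,
                            PhysiologicalState.diastolic(1.0), 660)


@pytest.fixture(scope="module")
def sys_map(model):
    return build_tissue_map(model.geometry, list(model.compositions),
                            model.spectra,
                            PhysiologicalState.systolic(1.0), 660)


class TestClassification:
    def test_bone_center(self, dia_map):
        assert classify_point(dia_map, (0.0, 0.3, 0.0)) == "bone"

    def test_artery_centers(self, dia_map):
        assert classify_point(dia_map, (-0.4, 0.45, 0.0)) == "artery_blood"
        assert classify_point(dia_map, (0.4, 0.45, 0.0)) == "artery_blood"

    def test_point_just_outside_surface(self, dia_map):
        r = dia_map.geometry.radius_cm
        assert classify_point(dia_map, (0.0, r + 1e-9, 0.0)) == "outside"

    def test_led_contact_point_is_epidermis(self, dia_map):
        r = dia_map.geometry.radius_cm
        assert classify_point(dia_map, (0.0, r - 1e-6, 0.0)) == "epidermis"

    def test_beyond_end_caps_is_outside(self, dia_map):
        assert classify_point(dia_map, (0.0, 0.0, 2.5)) == "outside"

    def test_against_brute_force_containment(self, dia_map):
        """Classification of random points must agree with direct
        circle/ellipse membership tests evaluated independently."""
        geo = dia_map.geometry
        rng = np.random.default_rng(42)
        n = 1_000_000
        x = rng.uniform(-0.9, 0.9, n)
        y = rng.uniform(-0.9, 0.9, n)
        got = dia_map.classify_xy(x, y)

        r = np.hypot(x, y)
        ra = dia_map.state.artery_radius_cm
        expected = np.full(n, OUTSIDE)
        inside = r < geo.radius_cm
        shell = np.full(n, LAYER_INDEX["subcutaneous_fat"])
        bounds = np.concatenate(([geo.radius_cm], geo.shell_inner_radii_cm))
        for i in range(5):
            shell[(r >= bounds[i + 1]) & (r < bounds[i])] = i
        expected[inside] = shell[inside]
        bx, by = geo.bone_center_cm
        a, b = geo.bone_semi_axes_cm
        in_bone = ((x - bx) / a) ** 2 + ((y - by) / b) ** 2 <= 1
        expected[inside & in_bone] = LAYER_INDEX["bone"]
        for cx, cy in geo.artery_centers_cm():
            in_art = (x - cx) ** 2 + (y - cy) ** 2 <= ra ** 2
            expected[inside & in_art] = LAYER_INDEX["artery_blood"]
        assert np.array_equal(got, expected)

    def test_monte_carlo_areas_match_analytic(self, dia_map):
        """Layer areas estimated by point counting converge to the
        circle/ellipse formulas."""
        geo = dia_map.geometry
        rng = np.random.default_rng(7)
        n = 2_000_000
        x = rng.uniform(-0.85, 0.85, n)
        y = rng.uniform(-0.85, 0.85, n)
        cell = (1.7 * 1.7) / n
        got = dia_map.classify_xy(x, y)
        area_art = np.sum(got == LAYER_INDEX["artery_blood"]) * cell
        area_bone = np.sum(got == LAYER_INDEX["bone"]) * cell
        exact_art = 2 * math.pi * dia_map.state.artery_radius_cm ** 2
        exact_bone = math.pi * geo.bone_semi_axes_cm[0] * \
            geo.bone_semi_axes_cm[1]
        assert area_art == pytest.approx(exact_art, rel=0.02)
        assert area_bone == pytest.approx(exact_bone, rel=0.02)

    def test_diastolic_artery_area_ratio(self, dia_map, sys_map):
        """Diastolic/systolic artery cross-section = (0.092/0.08)^2."""
        g = np.linspace(-0.85, 0.85, 1400)
        xx, yy = np.meshgrid(g, g)
        n_dia = np.sum(dia_map.classify_xy(xx, yy)
                       == LAYER_INDEX["artery_blood"])
        n_sys = np.sum(sys_map.classify_xy(xx, yy)
                       == LAYER_INDEX["artery_blood"])
        assert n_dia / n_sys == pytest.approx((0.092 / 0.08) ** 2, rel=0.02)

    def test_state_swap_identical_outside_artery_annulus(self, dia_map,
                                                         sys_map):
        rng = np.random.default_rng(3)
        n = 200_000
        x = rng.uniform(-0.85, 0.85, n)
        y = rng.uniform(-0.85, 0.85, n)
        d = dia_map.classify_xy(x, y)
        s = sys_map.classify_xy(x, y)
        in_annulus = np.zeros(n, dtype=bool)
        for cx, cy in dia_map.geometry.artery_centers_cm():
            rr = np.hypot(x - cx, y - cy)
            in_annulus |= (rr >= 0.08) & (rr <= 0.092)
        assert np.array_equal(d[~in_annulus], s[~in_annulus])


class TestMapBuilding:
    def test_partition_every_interior_point_has_one_layer(self, dia_map):
        rng = np.random.default_rng(11)
        x = rng.uniform(-0.849, 0.849, 50_000)
        y = rng.uniform(-0.849, 0.849, 50_000)
        got = dia_map.classify_xy(x, y)
        inside = np.hypot(x, y) < dia_map.geometry.radius_cm
        assert np.all(got[inside] >= 0)
        assert np.all(got[~inside] == OUTSIDE)

    def test_capillary_multiplier_raises_tissue_absorption(self, model):
        dia = build_tissue_map(model.geometry, list(model.compositions),
                               model.spectra,
                               PhysiologicalState.diastolic(1.0), 660)
        sys_ = build_tissue_map(model.geometry, list(model.compositions),
                                model.spectra,
                                PhysiologicalState.systolic(1.0), 660)
        i_dermis = LAYER_INDEX["reticular_dermis"]
        i_artery = LAYER_INDEX["artery_blood"]
        assert dia.mu_a[i_dermis] > sys_.mu_a[i_dermis]
        # arteries pulse geometrically, not in concentration
        assert dia.mu_a[i_artery] == sys_.mu_a[i_artery]

    def test_missing_layer_composition_rejected(self, model):
        comps = [c for c in model.compositions if c.layer != "bone"]
        with pytest.raises(ValueError, match="bone"):
            build_tissue_map(model.geometry, comps, model.spectra,
                             PhysiologicalState.diastolic(1.0), 660)

    def test_bad_geometry_rejected(self, model):
        geo = FingerGeometry(artery_y_cm=0.8)   # artery outside the core
        with pytest.raises(GeometryError):
            build_tissue_map(geo, list(model.compositions), model.spectra,
                             PhysiologicalState.diastolic(1.0), 660)

    def test_artery_overlapping_bone_rejected(self, model):
        geo = FingerGeometry(artery_abs_x_cm=0.1, artery_y_cm=0.35)
        with pytest.raises(GeometryError):
            build_tissue_map(geo, list(model.compositions), model.spectra,
                             PhysiologicalState.diastolic(1.0), 660)
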