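"""Stereological estimator: shrinkage, mean profile area, adequacy rules,
volume fraction and the end-to-end nephron-number chain."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nephrokit.stereology import (
    BiopsySection,
    BiopsySpecimen,
    GlomerularGeometry,
    ShrinkageModel,
    assess_adequacy,
    cohort_mean_radius,
    correct_to_in_vivo,
    cortex_section_area,
    estimate_nephrons,
    linear_shrinkage_factor,
    mean_profile_area,
    needle_internal_diameter,
    total_glomerular_number,
    volume_fraction,
)
from nephrokit.units import Volume


def mc_mean_profile_area(r, r_o, n_draws, rng):
    """Independent Monte-Carlo oracle: cut a sphere of radius r by planes
    uniform within the countable band |x| <= h and average the circle areas."""
    h = math.sqrt(r**2 - r_o**2)
    x = rng.uniform(-h, h, n_draws)
    areas = math.pi * (r**2 - x**2)
    return areas.mean(), areas.std(ddof=1) / math.sqrt(n_draws)


class TestShrinkage:
    @pytest.mark.parametrize(
        "fraction,expected",
        [(0.31, 0.883), (0.43, 0.829), (0.0, 1.0)],
    )
    def test_linear_factor_matches_conventional_values(self, fraction, expected):
        # 0.883 truncates the exact cube root 0.88366
        assert linear_shrinkage_factor(fraction) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_linear_factor_domain(self, bad):
        with pytest.raises(ValueError):
            linear_shrinkage_factor(bad)

    @pytest.mark.parametrize(
        "measured,factor,expected",
        [(10.0, 0.883, 11.325028), (7.0, 1.0, 7.0), (8.29, 0.829, 10.0)],
    )
    def test_correct_to_in_vivo(self, measured, factor, expected):
        assert correct_to_in_vivo(measured, factor) == pytest.approx(expected, rel=1e-6)

    @given(st.floats(0.0, 1000.0), st.floats(0.01, 0.99))
    def test_round_trip(self, x, volume_shrinkage):
        f = linear_shrinkage_factor(volume_shrinkage)
        assert correct_to_in_vivo(x * f, f) == pytest.approx(x, rel=1e-12, abs=1e-12)

    def test_model_defaults(self, shrinkage):
        assert shrinkage.linear_tissue == pytest.approx(0.8837, abs=1e-4)
        assert shrinkage.linear_glomerulus == pytest.approx(0.8291, abs=1e-4)


class TestMeanProfileArea:
    def test_no_cutoff_is_classic_two_thirds(self):
        g = GlomerularGeometry(r=100.0, r_o=0.0)
        assert mean_profile_area(g) == pytest.approx(2.0 / 3.0 * math.pi * 100**2)

    def test_near_cutoff_limit_is_equatorial_circle(self):
        g = GlomerularGeometry(r=10.0, r_o=10.0 - 1e-9)
        assert mean_profile_area(g) == pytest.approx(math.pi * 10.0**2, rel=1e-6)

    def test_default_geometry_value(self, geometry):
        # pi * (2/3 * 100^2 + 1/3 * 2.5^2)
        assert mean_profile_area(geometry) == pytest.approx(20950.496, abs=1e-2)

    def test_against_monte_carlo_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(10):
            r = rng.uniform(30.0, 200.0)
            r_o = rng.uniform(0.0, 0.3) * r
            mc, se = mc_mean_profile_area(r, r_o, 10**5, rng)
            analytic = mean_profile_area(GlomerularGeometry(r=r, r_o=r_o))
            assert abs(analytic - mc) < 3.0 * se

    def test_monotone_in_r_and_cutoff(self):
        rs = np.linspace(50.0, 150.0, 11)
        areas = [mean_profile_area(GlomerularGeometry(r, 2.5)) for r in rs]
        assert np.all(np.diff(areas) > 0)
        cutoffs = np.linspace(0.0, 10.0, 11)
        areas = [mean_profile_area(GlomerularGeometry(100.0, ro)) for ro in cutoffs]
        assert np.all(np.diff(areas) > 0)

    def test_pythagorean_truncation_height(self, geometry):
        assert geometry.h**2 + geometry.r_o**2 == pytest.approx(geometry.r**2)

    def test_r_not_above_cutoff_rejected(self):
        with pytest.raises(ValueError):
            GlomerularGeometry(r=2.0, r_o=2.5)


class TestNeedleTable:
    def test_known_gauge(self):
        assert needle_internal_diameter(16) == pytest.approx(1.19)

    def test_single_entry_table(self):
        assert needle_internal_diameter(99, {99: 1.0}) == 1.0

    def test_unknown_gauge_lists_known(self):
        with pytest.raises(KeyError, match="known gauges"):
            needle_internal_diameter(99)


class TestAdequacy:
    def test_single_glomerulus_section_is_ignored(self):
        spec = BiopsySpecimen(
            [BiopsySection([2.0], 1), BiopsySection([3.0], 5), BiopsySection([1.0], 4)],
            needle_gauge=16,
        )
        res = assess_adequacy(spec)
        assert res.n_profiles == 9
        assert res.sections_ignored == 1
        assert res.adequate  # total over all sections is 10 >= 8

    def test_total_under_eight_is_insufficient(self):
        spec = BiopsySpecimen(
            [BiopsySection([2.0], 3), BiopsySection([2.0], 4)], needle_gauge=16
        )
        assert not assess_adequacy(spec).adequate

    def test_exactly_eight_is_adequate(self):
        spec = BiopsySpecimen([BiopsySection([2.0], 8)], needle_gauge=16)
        assert assess_adequacy(spec).adequate

    def test_zero_glomeruli_section_keeps_length(self, shrinkage):
        spec = BiopsySpecimen(
            [BiopsySection([5.0], 0), BiopsySection([5.0], 9)], needle_gauge=16
        )
        area = cortex_section_area(spec, shrinkage, {16: 1.0})
        expected = (10.0 / shrinkage.linear_tissue) * 1.0 * 1e6
        assert area == pytest.approx(expected)


class TestCortexArea:
    def test_worked_example(self, shrinkage):
        spec = BiopsySpecimen([BiopsySection([10.0], 10)], needle_gauge=16)
        area = cortex_section_area(spec, shrinkage, {16: 1.0})
        # (10 mm / 0.883) * 1 mm = 11.325 mm^2 = 1.1325e7 um^2
        assert area == pytest.approx(1.1325e7, rel=1e-3)

    def test_no_shrinkage(self):
        spec = BiopsySpecimen([BiopsySection([5.0], 10)], needle_gauge=16)
        area = cortex_section_area(spec, ShrinkageModel(0.0, 0.0), {16: 2.0})
        assert area == pytest.approx(10.0 * 1e6)

    def test_two_segment_cortex_sums(self, shrinkage):
        # medulla sandwiched between cortices: lengths a and b simply add
        split = BiopsySpecimen([BiopsySection([3.0, 4.0], 10)], needle_gauge=16)
        joint = BiopsySpecimen([BiopsySection([7.0], 10)], needle_gauge=16)
        table = {16: 1.0}
        assert cortex_section_area(split, shrinkage, table) == pytest.approx(
            cortex_section_area(joint, shrinkage, table)
        )

    def test_zero_length_rejected(self, shrinkage):
        spec = BiopsySpecimen([BiopsySection([0.0], 10)], needle_gauge=16)
        with pytest.raises(ValueError, match="zero usable cortex length"):
            cortex_section_area(spec, shrinkage, {16: 1.0})


class TestVolumeFractionAndTotal:
    def test_direct_arithmetic(self):
        vf, clipped = volume_fraction(10, 2.0e4, 1.0e7)
        assert vf == pytest.approx(0.02)
        assert not clipped

    def test_zero_profiles(self):
        assert volume_fraction(0, 2.0e4, 1.0e7) == (0.0, False)

    def test_clipping_flag(self):
        vf, clipped = volume_fraction(1000, 2.0e4, 1.0e7)
        assert vf == 1.0 and clipped

    def test_total_number_worked_example(self, geometry):
        n = total_glomerular_number(0.03, Volume(100.0, "cm3"), geometry)
        assert n == pytest.approx(0.03 * 1e14 / (4.0 / 3.0 * math.pi * 100**3), rel=1e-12)
        assert n == pytest.approx(716197, rel=1e-4)

    def test_linearity_in_cortex_volume(self, geometry):
        n1 = total_glomerular_number(0.02, Volume(50.0, "cm3"), geometry)
        n2 = total_glomerular_number(0.02, Volume(100.0, "cm3"), geometry)
        assert n2 == pytest.approx(2.0 * n1)

    def test_untagged_volume_rejected(self, geometry):
        with pytest.raises(TypeError):
            total_glomerular_number(0.02, 100.0, geometry)

    def test_mm3_and_cm3_tags_agree(self, geometry):
        a = total_glomerular_number(0.02, Volume(100.0, "cm3"), geometry)
        b = total_glomerular_number(0.02, Volume(100.0e3, "mm3"), geometry)
        assert a == pytest.approx(b)


class TestCohortMeanRadius:
    def test_small_cohort_samples_one(self):
        radii = list(range(1, 21))
        r = cohort_mean_radius(radii, 0.05, seed=7)
        assert r in radii

    def test_full_fraction_is_mean(self):
        radii = [80.0, 90.0, 100.0, 110.0]
        assert cohort_mean_radius(radii, 1.0, seed=0) == pytest.approx(95.0)

    def test_deterministic_given_seed(self):
        radii = np.linspace(80, 120, 200)
        assert cohort_mean_radius(radii, 0.05, seed=42) == cohort_mean_radius(
            radii, 0.05, seed=42
        )

    def test_on_slide_correction(self, shrinkage):
        r = cohort_mean_radius(
            [82.91344341849698], 1.0, shrinkage=shrinkage, radii_scale="on_slide"
        )
        assert r == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_mean_radius([], 0.05)


class TestEstimateNephrons:
    def test_composition_equals_step_products(self, geometry, shrinkage):
        spec = BiopsySpecimen([BiopsySection([10.0], 10)], needle_gauge=16)
        table = {16: 1.0}
        est = estimate_nephrons(
            spec, Volume(100.0, "cm3"), geometry, shrinkage, table
        )
        a_h = mean_profile_area(geometry)
        a_cortex = cortex_section_area(spec, shrinkage, table)
        vf = 10 * a_h / a_cortex
        expected = vf * 1e14 / geometry.sphere_volume_um3
        assert est.total_number == pytest.approx(expected, rel=1e-12)
        assert est.volume_fraction == pytest.approx(vf)
        assert est.n_profiles_used == 10
        assert est.adequacy == "adequate"

    def test_all_single_glomerulus_sections(self, geometry, shrinkage):
        spec = BiopsySpecimen(
            [BiopsySection([3.0], 1), BiopsySection([4.0], 1)], needle_gauge=16
        )
        est = estimate_nephrons(spec, Volume(100.0, "cm3"), geometry, shrinkage)
        assert est.adequacy == "insufficient"
        assert est.n_profiles_used == 0
        assert est.total_number == 0.0

    def test_insufficient_still_reports_estimate(self, geometry, shrinkage):
        spec = BiopsySpecimen([BiopsySection([10.0], 5)], needle_gauge=16)
        est = estimate_nephrons(spec, Volume(100.0, "cm3"), geometry, shrinkage)
        assert est.adequacy == "insufficient"
        assert est.total_number > 0

    def test_nonsclerotic_estimate(self, geometry, shrinkage):
        spec = BiopsySpecimen([BiopsySection([10.0], 10, 3)], needle_gauge=16)
        est = estimate_nephrons(spec, Volume(100.0, "cm3"), geometry, shrinkage)
        assert est.n_profiles_nonsclerotic == 7
        assert est.total_number_nonsclerotic == pytest.approx(
            est.total_number * 0.7
        )

    def test_on_slide_cutoff_space_raises_cutoff(self, shrinkage):
        spec = BiopsySpecimen([BiopsySection([10.0], 10)], needle_gauge=16)
        g = GlomerularGeometry(r=100.0, r_o=2.5)
        vivo = estimate_nephrons(
            spec, Volume(100.0, "cm3"), g, shrinkage, cutoff_space="in_vivo"
        )
        slide = estimate_nephrons(
            spec, Volume(100.0, "cm3"), g, shrinkage, cutoff_space="on_slide"
        )
        assert slide.r_o_um == pytest.approx(2.5 / shrinkage.linear_glomerulus)
        assert slide.mean_profile_area_um2 > vivo.mean_profile_area_um2

    @given(st.sampled_from([("mm3", 1.0), ("cm3", 1e-3)]))
    def test_unit_invariance_of_total(self, tag):
        # the same physical volume under different tags gives the same count
        unit, scale = tag
        g = GlomerularGeometry(r=100.0, r_o=2.5)
        spec = BiopsySpecimen([BiopsySection([10.0], 10)], needle_gauge=16)
        base = estimate_nephrons(spec, Volume(9.0e4, "mm3"), g)
        other = estimate_nephrons(spec, Volume(9.0e4 * scale, unit), g)
        assert other.total_number == pytest.approx(base.total_number, rel=1e-12)
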