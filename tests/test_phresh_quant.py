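"""PHRESH quantification: references, profiles, classification, maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phresh.errors import InvalidParameterError, NoReferenceError
from phresh.image_synthesis import ImageStack
from phresh.phresh_quant import (PROFILE_GRID, above_half_max_extent,
                                 average_over_somites, build_map,
                                 class_composition, classify_map,
                                 classify_response, dv_profile, ml_profile,
                                 stack_profiles, unconverted_reference)
from phresh.pipeline import simulate_phresh_stack


def make_stack(green, converted=(20.0, 60.0)):
    green = np.asarray(green, float)
    data = np.stack([green, np.zeros_like(green)])
    return ImageStack(data=data, converted_ap_window=converted)


class TestUnconvertedReference:
    def test_planted_maximum_recovered(self):
        green = np.zeros((4, 8, 100))
        green[2, 3, 5] = 1000.0  # ap index 5 lies outside (20, 60)
        stack = make_stack(green)
        assert unconverted_reference(stack, mode="max", background=0.0) \
            == 1000.0

    def test_fully_converted_stack_has_no_reference(self):
        green = np.ones((2, 4, 50))
        stack = make_stack(green, converted=(-1.0, 51.0))
        with pytest.raises(NoReferenceError):
            unconverted_reference(stack)

    def test_percentile_mode_resists_hot_pixel(self, rng):
        green = rng.uniform(90, 110, size=(4, 8, 100))
        green[1, 1, 2] = 50000.0  # single hot pixel in the reference region
        stack = make_stack(green)
        robust = unconverted_reference(stack, mode="percentile",
                                       background=0.0)
        assert robust < 50000.0
        assert robust == pytest.approx(110, rel=0.05)


class TestProfiles:
    def test_uniform_section_flat_profile(self):
        section = np.full((40, 20), 55.0)
        prof = dv_profile(section, canal_px=(12, 10), reference=110.0)
        np.testing.assert_allclose(prof.values, 50.0)
        assert prof.axis == "DV"
        assert prof.n_lines_averaged == 3

    def test_three_lines_averaged_before_normalisation(self):
        section = np.zeros((10, 30))
        canal = (5, 15)
        spacing = 4
        section[:, 15] = 30.0   # a
        section[:, 11] = 60.0   # b
        section[:, 19] = 90.0   # c
        prof = dv_profile(section, canal, reference=100.0,
                          line_spacing=spacing)
        np.testing.assert_allclose(prof.values, 100.0 * 60.0 / 100.0)

    def test_planted_ventral_band_extent(self):
        section = np.zeros((100, 20))
        section[:40] = 200.0  # ventral 40% (row 0 = ventral)
        prof = dv_profile(section, canal_px=(30, 10), reference=200.0)
        assert above_half_max_extent(prof) == pytest.approx(0.40, abs=0.02)

    def test_canal_outside_section_rejected(self):
        with pytest.raises(InvalidParameterError):
            dv_profile(np.zeros((10, 10)), canal_px=(20, 5), reference=1.0)

    def test_ml_profile_flat_and_peak_location(self):
        section = np.full((40, 21), 10.0)
        prof = ml_profile(section, canal_px=(10, 10), reference=20.0,
                          dorsal_offset=5)
        np.testing.assert_allclose(prof.values, 50.0)
        cols = np.arange(21)
        band = 100.0 * np.exp(-0.5 * ((cols - 10.5) / 2.0) ** 2)
        section2 = np.tile(band, (40, 1))
        prof2 = ml_profile(section2, canal_px=(10, 10), reference=100.0,
                           dorsal_offset=5)
        peak = prof2.positions[np.argmax(prof2.values)]
        assert peak == pytest.approx(0.5, abs=1.5 / 21)

    def test_dorsal_offset_outside_cord_rejected(self):
        with pytest.raises(InvalidParameterError):
            ml_profile(np.zeros((20, 20)), canal_px=(18, 10), reference=1.0,
                       dorsal_offset=5)


class TestAverageOverSomites:
    def _profile(self, values):
        return dv_profile(np.tile(np.asarray(values, float)[:, None],
                                  (1, 10)), canal_px=(1, 5), reference=100.0)

    def test_mean_is_idempotent_on_identical_profiles(self):
        p = self._profile([10, 20, 30, 40])
        avg = average_over_somites([p] * 5)
        np.testing.assert_allclose(avg.values, p.values)
        assert avg.n_somites_averaged == 5

    def test_pointwise_mean(self):
        profiles = [self._profile([0, 0]) for _ in range(4)] \
            + [self._profile([5, 5])]
        avg = average_over_somites(profiles)
        np.testing.assert_allclose(avg.values, 100.0 * 1.0 / 100.0)

    def test_unexpected_count_warns_but_averages(self):
        with pytest.warns(UserWarning):
            avg = average_over_somites([self._profile([1, 2])] * 3)
        assert avg.n_somites_averaged == 3

    def test_mismatched_grids_rejected(self):
        a = self._profile([1, 2, 3])
        b = a.__class__(axis="ML", positions=a.positions, values=a.values,
                        canal_frac=0.5)
        with pytest.raises(InvalidParameterError):
            average_over_somites([a, b], expected_n=2)


class TestClassification:
    @pytest.mark.parametrize("green,red,expected", [
        (50.0, 1.0, "new"),
        (1.0, 50.0, "past"),
        (40.0, 40.0, "continued"),
        (1.0, 1.0, "none"),
        (10.0, 10.0, "none"),  # threshold is exclusive
    ])
    def test_scheme(self, green, red, expected):
        assert classify_response(green, red, threshold=10.0) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(g=st.floats(0, 200), r=st.floats(0, 200),
           thr=st.floats(0.1, 50))
    def test_partition_exhaustive_and_exclusive(self, g, r, thr):
        cls = classify_response(g, r, thr)
        assert cls in ("new", "continued", "past", "none")
        matches = [(g > thr and r <= thr, "new"),
                   (g > thr and r > thr, "continued"),
                   (g <= thr and r > thr, "past"),
                   (g <= thr and r <= thr, "none")]
        assert sum(cond for cond, _ in matches) == 1
        assert next(name for cond, name in matches if cond) == cls

    def test_vectorised_matches_scalar(self, rng):
        g = rng.uniform(0, 50, 100)
        r = rng.uniform(0, 50, 100)
        labels = classify_map(g, r, 10.0)
        for gi, ri, li in zip(g, r, labels):
            assert classify_response(gi, ri, 10.0) == li
        comp = class_composition(labels)
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_response(-1.0, 0.0)


class TestPipelineProfiles:
    @pytest.fixture(scope="class")
    def hh_stack(self):
        return simulate_phresh_stack("hh", t0=24.0, seed=11)

    def test_normalisation_scale_invariance(self, hh_stack):
        """Scaling the green channel (and hence the reference) by c leaves
        the normalised profiles unchanged."""
        dv1, ml1, _ = stack_profiles(hh_stack)
        scaled = ImageStack(data=hh_stack.data * 3.0,
                            voxel_size=hh_stack.voxel_size,
                            origin=hh_stack.origin,
                            channels=hh_stack.channels,
                            converted_ap_window=hh_stack.converted_ap_window,
                            meta=hh_stack.meta)
        dv3, ml3, _ = stack_profiles(scaled)
        np.testing.assert_allclose(dv3.values, dv1.values, atol=0.35)
        np.testing.assert_allclose(ml3.values, ml1.values, atol=0.35)

    def test_build_map_single_embryo_equals_that_embryo(self, hh_stack):
        m = build_map({24.0: [hh_stack]})
        dv, ml, comp = stack_profiles(hh_stack)
        np.testing.assert_allclose(m[24.0].dv.values, dv.values)
        assert m[24.0].composition == comp

    def test_map_reproduces_consolidation_and_termination(self):
        m = build_map({t0: [simulate_phresh_stack("hh", t0, seed=4)]
                       for t0 in (24.0, 54.0, 72.0)})
        assert above_half_max_extent(m[24.0].dv) > \
            above_half_max_extent(m[54.0].dv)
        comp72 = m[72.0].composition
        assert comp72["past"] + comp72["none"] > 0.75
        assert comp72["new"] < 0.05

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_map({})
        with pytest.raises(InvalidParameterError):
            build_map({24.0: []})

    def test_profile_grid_is_common(self, hh_stack):
        dv, ml, _ = stack_profiles(hh_stack)
        np.testing.assert_array_equal(dv.positions, PROFILE_GRID)
        np.testing.assert_array_equal(ml.positions, PROFILE_GRID)
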