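"""Constraint-based airway cropping and fossil placement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nasallom.allometry import AllometricFit
from nasallom.morphometry import label_volume
from nasallom.phantom import PhantomSpec, generate_skull_phantom
from nasallom.reconstruct import (
    ConstraintLandmarks,
    LandmarkOutOfBoundsError,
    Plane,
    UndefinedIndexError,
    add_mirrored_component,
    crop_main_airway,
    place_fossil,
    soft_tissue_corrected_range,
)


def _fit(slope, intercept):
    return AllometricFit(
        method="pgls", slope=slope, intercept=intercept, n=20, r2=0.95, resid_var=0.01
    )


class TestPlane:
    def test_zero_normal_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            Plane(point=(0, 0, 0), normal=(0, 0, 0))

    def test_normal_is_normalized(self):
        p = Plane(point=(0, 0, 0), normal=(0, 0, 5))
        assert p.normal == (0.0, 0.0, 1.0)

    def test_plane_fit_to_surface_oriented_toward_seed(self, rng):
        # noisy z=2 plane; seed above -> normal points up
        pts = np.column_stack(
            [rng.uniform(0, 10, 50), rng.uniform(0, 10, 50), 2 + 0.01 * rng.standard_normal(50)]
        )
        plane = Plane.from_surface(pts, toward_point=(5, 5, 10))
        assert plane.normal[2] > 0.99


class TestCropMainAirway:
    def test_nonbinding_landmarks_keep_entire_cavity(self, default_phantom):
        vol, _, truths = default_phantom
        lm = ConstraintLandmarks(
            nostril_plane=Plane(point=(1.0, 16, 16), normal=(1, 0, 0)),
            antrum_boundary=Plane(point=(24.0, 16, 1.0), normal=(0, 0, 1)),
            choana_plane=Plane(point=(47.0, 16, 16), normal=(-1, 0, 0)),
            mesethmoid_point=(47.0, 16, 16),
        )
        out = crop_main_airway(vol, lm)
        assert label_volume(out, "main_airway") == pytest.approx(
            truths["cavity_vol_mm3"], rel=0.01
        )
        assert label_volume(out, "olfactory") == 0.0

    def test_center_choana_plane_yields_half_ellipsoid(self, default_phantom):
        vol, _, truths = default_phantom
        lm = ConstraintLandmarks(
            nostril_plane=Plane(point=(1.0, 16, 16), normal=(1, 0, 0)),
            antrum_boundary=Plane(point=(24.0, 16, 1.0), normal=(0, 0, 1)),
            choana_plane=Plane(point=(24.0, 16, 16), normal=(-1, 0, 0)),
            mesethmoid_point=(47.0, 16, 16),
        )
        out = crop_main_airway(vol, lm)
        assert label_volume(out, "main_airway") == pytest.approx(
            truths["cavity_vol_mm3"] / 2, rel=0.005
        )

    def test_degenerate_plane_ordering_warns_and_empties(self, default_phantom):
        vol, _, _ = default_phantom
        lm = ConstraintLandmarks(
            nostril_plane=Plane(point=(40.0, 16, 16), normal=(1, 0, 0)),
            antrum_boundary=Plane(point=(24.0, 16, 1.0), normal=(0, 0, 1)),
            choana_plane=Plane(point=(10.0, 16, 16), normal=(-1, 0, 0)),
            mesethmoid_point=(47.0, 16, 16),
        )
        with pytest.warns(UserWarning, match="no main-airway"):
            out = crop_main_airway(vol, lm)
        assert label_volume(out, "main_airway") == 0.0

    def test_output_partitions_input_cavity_exactly(self, default_phantom):
        vol, lm, _ = default_phantom
        cavity_before = vol.mask("main_airway", "olfactory")
        out = crop_main_airway(vol, lm)
        after = out.mask("main_airway", "olfactory", "excluded_cavity")
        assert np.array_equal(cavity_before, after)
        # no overlap between partitions by construction (single label grid)
        assert np.array_equal(out.mask("bone"), vol.mask("bone"))

    def test_adding_constraint_is_monotone(self, default_phantom):
        vol, _, _ = default_phantom
        loose = ConstraintLandmarks(
            nostril_plane=Plane(point=(1.0, 16, 16), normal=(1, 0, 0)),
            antrum_boundary=Plane(point=(24.0, 16, 1.0), normal=(0, 0, 1)),
            choana_plane=Plane(point=(47.0, 16, 16), normal=(-1, 0, 0)),
            mesethmoid_point=(47.0, 16, 16),
        )
        tight = ConstraintLandmarks(
            nostril_plane=Plane(point=(18.0, 16, 16), normal=(1, 0, 0)),
            antrum_boundary=Plane(point=(24.0, 16, 14.0), normal=(0, 0, 1)),
            choana_plane=Plane(point=(30.0, 16, 16), normal=(-1, 0, 0)),
            mesethmoid_point=(47.0, 16, 16),
        )
        v_loose = label_volume(crop_main_airway(vol, loose), "main_airway")
        v_tight = label_volume(crop_main_airway(vol, tight), "main_airway")
        assert v_tight <= v_loose

    def test_landmark_outside_volume_rejected(self, default_phantom):
        vol, lm, _ = default_phantom
        bad = ConstraintLandmarks(
            nostril_plane=Plane(point=(-5.0, 0, 0), normal=(1, 0, 0)),
            antrum_boundary=lm.antrum_boundary,
            choana_plane=lm.choana_plane,
            mesethmoid_point=lm.mesethmoid_point,
        )
        with pytest.raises(LandmarkOutOfBoundsError):
            crop_main_airway(vol, bad)


class TestSoftTissueCorrection:
    def test_canonical_fractions(self):
        assert soft_tissue_corrected_range(1000.0) == (400.0, 600.0)

    def test_zero_volume(self):
        assert soft_tissue_corrected_range(0.0) == (0.0, 0.0)

    def test_inverted_fractions_rejected(self):
        with pytest.raises(ValueError):
            soft_tissue_corrected_range(100.0, 0.7, 0.4)

    @settings(derandomize=True, max_examples=25)
    @given(v=st.floats(0, 1e6), k=st.floats(0.1, 10))
    def test_endpoints_scale_linearly(self, v, k):
        lo1, hi1 = soft_tissue_corrected_range(v)
        lo2, hi2 = soft_tissue_corrected_range(k * v)
        assert lo2 == pytest.approx(k * lo1)
        assert hi2 == pytest.approx(k * hi1)


def test_add_mirrored_component():
    assert add_mirrored_component(100.0, 0.0) == 100.0
    assert add_mirrored_component(100.0, 7.0) == 107.0
    with pytest.raises(ValueError):
        add_mirrored_component(100.0, -1.0)


class TestPlaceFossil:
    ENDO = _fit(slope=0.9, intercept=1.0)
    ECTO = _fit(slope=0.9, intercept=0.4)

    def test_midpoint_gives_half(self):
        x = 4.0
        y_mid = (self.ENDO.predict(x) + self.ECTO.predict(x)) / 2
        pl = place_fossil(x, y_mid, self.ENDO, self.ECTO)
        assert pl.relative_index_bony == pytest.approx(0.5)

    def test_on_endotherm_line_gives_one(self):
        x = 3.0
        pl = place_fossil(x, float(self.ENDO.predict(x)), self.ENDO, self.ECTO)
        assert pl.relative_index_bony == pytest.approx(1.0)

    def test_corrected_upper_endpoint_hand_computed(self):
        # fossil on the ectotherm line shifted by log10(0.5); corrected by
        # the default 40-60% bracket
        x = 4.2
        y = float(self.ECTO.predict(x)) + np.log10(0.5)
        pl = place_fossil(x, y, self.ENDO, self.ECTO)
        expected_hi = (y + np.log10(0.6) - float(self.ECTO.predict(x))) / (
            float(self.ENDO.predict(x)) - float(self.ECTO.predict(x))
        )
        assert pl.relative_index_corrected[1] == pytest.approx(expected_hi, abs=1e-10)
        assert pl.y_corrected_range[0] < pl.y_corrected_range[1] <= pl.y_bony

    def test_coincident_lines_rejected(self):
        with pytest.raises(UndefinedIndexError):
            place_fossil(2.0, 1.0, self.ENDO, self.ENDO)

    @settings(derandomize=True, max_examples=25)
    @given(y=st.floats(-2, 4))
    def test_swapping_lines_flips_index(self, y):
        x = 3.5
        a = place_fossil(x, y, self.ENDO, self.ECTO).relative_index_bony
        b = place_fossil(x, y, self.ECTO, self.ENDO).relative_index_bony
        assert a == pytest.approx(1.0 - b, abs=1e-9)
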