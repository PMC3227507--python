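"""Geometry layer: default model, electrode pairs, bag model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from esofield.geometry import (
    BAG_MAX_DIAMETER_MM,
    PATCH_SIDE_MM,
    ContactPatch,
    LayerSpec,
    bag_radius,
    build_default_model,
    make_patch_pair,
    make_ring_pair,
)


class TestDefaultModel:
    def test_wall_composition(self):
        model = build_default_model()
        assert [l.name for l in model.layers] == ["mucosa", "muscle"]
        assert model.wall_thickness == pytest.approx(3.57, abs=1e-12)
        assert [l.conductivity for l in model.layers] == [0.05, 0.53]
        assert model.surround_conductivity == 0.27
        assert model.inner_radius == 1.5

    @pytest.mark.parametrize("thickness,conductivity", [(0.0, 0.05), (0.85, 0.0), (-1.0, 0.05)])
    def test_nonpositive_layer_parameters_rejected(self, thickness, conductivity):
        with pytest.raises(ValueError):
            LayerSpec("mucosa", thickness, conductivity)

    def test_distension_conserves_layer_cross_sections(self):
        model = build_default_model()
        d = model.distended(8.0)
        radii_0 = model.layer_radii()[:-1]
        radii_1 = d.layer_radii()[:-1]
        areas_0 = np.diff(radii_0**2)
        areas_1 = np.diff(radii_1**2)
        assert areas_1 == pytest.approx(areas_0, rel=1e-12)
        assert all(a.thickness < b.thickness for a, b in zip(d.layers, model.layers))
        assert d.resting_layers == model.layers


class TestRingPair:
    def test_circular_pair_geometry(self):
        pair = make_ring_pair(10, "circle", 20.0)
        assert pair.kind == "ring"
        zs = sorted(c.center_axial_position for c in pair.contacts)
        assert zs == [-5.0, 5.0]
        assert all(c.dimensions == (1.5,) for c in pair.contacts)
        assert all(c.center_angle == 0.0 for c in pair.contacts)
        assert pair.source.area == pytest.approx(math.pi * 1.5**2)

    def test_elliptical_pair_at_2mm_accepted(self):
        # axial gap 2 - 2*0.7 = 0.6 mm > 0
        pair = make_ring_pair(2, "ellipse", 20.0)
        assert pair.contacts[0].dimensions == (0.7, 7.5)
        gap = pair.interelectrode_distance - 2 * pair.contacts[0].axial_half_extent
        assert gap == pytest.approx(0.6)

    def test_circular_pair_at_2mm_overlaps(self):
        with pytest.raises(ValueError, match="overlap"):
            make_ring_pair(2, "circle", 20.0)

    def test_equal_and_opposite_contacts(self):
        pair = make_ring_pair(20, "circle", 20.0)
        assert {c.polarity for c in pair.contacts} == {"source", "sink"}
        assert pair.contacts[0].area == pair.contacts[1].area


class TestBagAndPatchPair:
    def test_patch_pair_defaults(self):
        pair = make_patch_pair(2, 20.0)
        assert pair.kind == "patch"
        assert pair.interelectrode_distance == 10.0
        assert pair.bag_volume == 2
        # patch area equals the circular ring-contact area
        assert pair.source.area == pytest.approx(math.pi * 1.5**2)
        assert pair.source.dimensions == (PATCH_SIDE_MM, PATCH_SIDE_MM)

    def test_overfilled_bag_rejected(self):
        with pytest.raises(ValueError, match="6"):
            make_patch_pair(7, 20.0)

    def test_partial_filling_radius_below_maximum(self):
        assert bag_radius(5) < BAG_MAX_DIAMETER_MM / 2
        assert bag_radius(6) == pytest.approx(BAG_MAX_DIAMETER_MM / 2)

    @given(st.floats(min_value=0.01, max_value=6.0))
    def test_bag_radius_monotone_and_bounded(self, v):
        r = bag_radius(v)
        assert 0 < r <= BAG_MAX_DIAMETER_MM / 2
        assert bag_radius(min(6.0, v * 1.5)) >= r


class TestContactMembership:
    def test_circle_footprint_on_cylinder(self):
        c = ContactPatch("circle", (1.5,), center_axial_position=5.0)
        assert c.contains(np.array([5.0]), np.array([0.0]), 1.5)[0]
        assert not c.contains(np.array([7.0]), np.array([0.0]), 1.5)[0]
        # arc distance: 1 rad on r=1.5 is 1.5 mm, exactly the radius
        assert c.contains(np.array([5.0]), np.array([0.999]), 1.5)[0]
        assert not c.contains(np.array([5.0]), np.array([1.01]), 1.5)[0]

    def test_wide_ellipse_wraps_into_closed_band(self):
        # 7.5 mm circumferential semi-axis exceeds the half-circumference of
        # the 1.5 mm catheter, so the footprint closes into a ring band
        c = ContactPatch("ellipse", (0.7, 7.5), center_axial_position=0.0)
        theta = np.linspace(-math.pi, math.pi, 64)
        assert c.contains(np.zeros_like(theta), theta, 1.5).all()
        assert not c.contains(np.full_like(theta, 0.71), theta, 1.5).any()

    @given(st.floats(-math.pi, math.pi), st.floats(-1.0, 1.0))
    def test_membership_symmetric_under_mirror(self, theta, dz):
        c = ContactPatch("ellipse", (0.7, 2.0), center_axial_position=0.0)
        a = c.contains(np.array([dz]), np.array([theta]), 1.5)[0]
        b = c.contains(np.array([-dz]), np.array([-theta]), 1.5)[0]
        assert a == b
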