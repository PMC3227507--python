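"""Mesher: region tagging, resolution rule, analytic volumes, boundary."""

import math

import numpy as np
import pytest

from esofield.geometry import build_default_model, make_patch_pair, make_ring_pair
from esofield.mesh import box_mesh, coaxial_cylinder_mesh, generate_mesh, spherical_shell_mesh


def annulus_volume(r1, r2, L):
    return math.pi * (r2**2 - r1**2) * L


def wrapped_ellipse_band_area(a_ax, b_circ, half_circ):
    """Developed area of an elliptical footprint truncated (wrapped) at the
    half-circumference: 2 * integral of a*sqrt(1-(s/b)^2) over [-L, L]."""
    L = min(b_circ, half_circ)
    return 2 * a_ax * (L * math.sqrt(max(0.0, 1 - (L / b_circ) ** 2)) + b_circ * math.asin(L / b_circ))


@pytest.fixture(scope="module")
def ring2_mesh():
    return generate_mesh(build_default_model(), make_ring_pair(2, "ellipse", 26.0), 0.17)


class TestResolutionRule:
    def test_too_coarse_h_rejected_citing_rule(self):
        with pytest.raises(ValueError, match="five"):
            generate_mesh(build_default_model(), make_ring_pair(10, "circle", 20.0), h=0.3)

    def test_five_radial_layers_in_mucosa(self, ring2_mesh):
        model = build_default_model()
        nodes_r = np.hypot(ring2_mesh.nodes[:, 0], ring2_mesh.nodes[:, 1])
        in_mucosa = (nodes_r >= model.inner_radius - 1e-9) & (
            nodes_r <= model.inner_radius + model.layers[0].thickness + 1e-9
        )
        n_shells = len(np.unique(np.round(nodes_r[in_mucosa], 9)))
        assert n_shells >= 6  # >= 5 element layers

    def test_distended_thin_layers_keep_five_divisions(self):
        model = build_default_model().distended(8.083)
        pair = make_patch_pair(2, 29.0)
        mesh = generate_mesh(model, pair, 0.17)  # gate vs resting wall
        r = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        t_muc = model.layers[0].thickness
        assert t_muc < 0.25  # strongly thinned
        in_muc = (r >= model.inner_radius - 1e-9) & (r <= model.inner_radius + t_muc + 1e-9)
        assert len(np.unique(np.round(r[in_muc], 9))) >= 6


class TestRegionVolumes:
    def test_layer_volumes_match_analytic_annuli(self, ring2_mesh):
        model = build_default_model()
        L = model.axial_length
        radii = model.layer_radii()
        for i, layer in enumerate(model.layers):
            exact = annulus_volume(radii[i], radii[i + 1], L)
            assert ring2_mesh.region_volume(layer.name) == pytest.approx(exact, rel=0.02)
        exact_surround = annulus_volume(radii[-2], radii[-1], L)
        assert ring2_mesh.region_volume("surround") == pytest.approx(exact_surround, rel=0.02)

    def test_volume_error_shrinks_under_refinement(self):
        model = build_default_model()
        pair = make_ring_pair(2, "ellipse", 26.0)
        radii = model.layer_radii()
        exact = annulus_volume(radii[0], radii[1], model.axial_length)
        errs = []
        for h in (0.17, 0.085):
            m = generate_mesh(model, pair, h)
            errs.append(abs(m.region_volume("mucosa") - exact) / exact)
        # halving h at least halves the polygonal volume deficit
        assert errs[1] <= 0.5 * errs[0] + 1e-12

    def test_mirrored_polarity_gives_identical_region_volumes(self):
        model = build_default_model()
        a = generate_mesh(model, make_ring_pair(10, "circle", 20.0), 0.17)
        flipped = make_ring_pair(10, "circle", 20.0)
        from dataclasses import replace

        contacts = tuple(
            replace(c, polarity=("sink" if c.polarity == "source" else "source"))
            for c in flipped.contacts
        )
        b = generate_mesh(model, replace(flipped, contacts=contacts), 0.17)
        for name in a.region_names:
            assert a.region_volume(name) == pytest.approx(b.region_volume(name), rel=1e-12)
        assert a.electrode_facet_area("electrode_source") == pytest.approx(
            b.electrode_facet_area("electrode_sink"), rel=1e-12
        )


class TestElectrodeFacets:
    def test_circular_contact_area_within_5pct(self):
        m = generate_mesh(build_default_model(), make_ring_pair(10, "circle", 20.0), 0.17)
        nominal = math.pi * 1.5**2
        for tag in ("electrode_source", "electrode_sink"):
            assert m.electrode_facet_area(tag) == pytest.approx(nominal, rel=0.05)

    def test_wrapped_ellipse_band_area_within_5pct(self, ring2_mesh):
        nominal = wrapped_ellipse_band_area(0.7, 7.5, math.pi * 1.5)
        assert ring2_mesh.electrode_facet_area("electrode_source") == pytest.approx(
            nominal, rel=0.05
        )

    def test_square_patch_area_within_5pct(self):
        model = build_default_model().distended(8.083)
        m = generate_mesh(model, make_patch_pair(2, 29.0), 0.17)
        nominal = math.pi * 1.5**2
        assert m.electrode_facet_area("electrode_source") == pytest.approx(nominal, rel=0.05)


class TestTopology:
    @pytest.mark.parametrize(
        "mesh_fn",
        [
            lambda: coaxial_cylinder_mesh(1.0, 2.0, 2.0, 1.0, nr=4, ntheta=12, nz=3),
            lambda: box_mesh(1, 1, 1, 1.0, nx=3, ny=3, nz=3),
            lambda: spherical_shell_mesh([1.0, 2.0], [1.0], n_per_shell=4, npolar=5, nphi=12),
        ],
    )
    def test_stored_boundary_equals_once_counted_faces(self, mesh_fn):
        """The structured boundary extraction must agree with the generic
        rule: a facet is on the boundary iff it belongs to exactly one tet."""
        m = mesh_fn()
        faces = m.tets[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
        faces_sorted = np.sort(faces, axis=1)
        uniq, counts = np.unique(faces_sorted, axis=0, return_counts=True)
        assert set(counts) <= {1, 2}  # conforming: no face shared by 3+ tets
        boundary = uniq[counts == 1]
        stored = np.unique(np.sort(m.tris, axis=1), axis=0)
        assert boundary.shape == stored.shape
        assert (boundary == stored).all()

    def test_single_region_homogeneous_fixture(self):
        m = spherical_shell_mesh([1.0, 2.0], [1.0], n_per_shell=4, npolar=5, nphi=12)
        assert m.region_names == ("shell0",)
        assert set(np.unique(m.region)) == {0}

    def test_all_tets_positive_volume(self, ring2_mesh):
        assert (ring2_mesh.tet_volumes > 0).all()

    def test_boundary_facet_owners_touch_their_facets(self, ring2_mesh):
        m = ring2_mesh
        idx = np.linspace(0, len(m.tris) - 1, 200).astype(int)
        for f in idx:
            tet = set(m.tets[m.tri_owner[f]])
            assert set(m.tris[f]) <= tet
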