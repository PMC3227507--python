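"""Solver contracts: exactness on linear fields, linearity, reciprocity,
equipotential contacts, conservation, far-field insensitivity."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial import cKDTree

from esofield.geometry import build_default_model, make_ring_pair
from esofield.mesh import coaxial_cylinder_mesh, generate_mesh
from esofield.postprocess import impedance
from esofield.solver import (
    assemble_and_solve,
    check_current_conservation,
    solve_current,
)

from conftest import mesh_pair


class TestSlabExactness:
    def test_linear_potential_and_exact_resistance(self, slab):
        mesh, sol = slab
        # V must be an affine function of z (exact for first-order elements)
        z = mesh.nodes[:, 2]
        coeff = np.polyfit(z, sol.potential, 1)
        assert np.abs(sol.potential - np.polyval(coeff, z)).max() < 1e-9 * abs(sol.voltage)
        # R = L / (sigma A): 8 mm / (0.5 * 16 mm^2) in SI -> 1 kOhm
        exact_kohm = 8e-3 / (0.5 * 16e-6) / 1e3
        assert impedance(sol) == pytest.approx(exact_kohm, rel=1e-8)

    def test_contacts_are_equipotential(self, slab):
        mesh, sol = slab
        span = abs(sol.voltage)
        for tag in ("electrode_source", "electrode_sink"):
            v = sol.potential[mesh.nodes_with_tag(tag)]
            assert np.ptp(v) <= 1e-6 * span

    def test_extrema_on_electrodes(self, slab):
        mesh, sol = slab
        v_src = sol.potential[mesh.nodes_with_tag("electrode_source")][0]
        v_snk = sol.potential[mesh.nodes_with_tag("electrode_sink")][0]
        assert sol.potential.max() <= v_src + 1e-12
        assert sol.potential.min() >= v_snk - 1e-12


class TestLinearity:
    def test_zero_current_gives_zero_field(self, coax):
        mesh, _ = coax
        sol0 = solve_current(mesh, 0.0)
        assert np.all(sol0.potential == 0.0)
        assert check_current_conservation(sol0) == 0.0

    def test_doubling_current_doubles_potential(self, coax):
        mesh, sol = coax
        sol2 = solve_current(mesh, 2 * sol.current)
        assert np.allclose(sol2.potential, 2 * sol.potential, rtol=1e-8, atol=1e-12)

    def test_superposition(self, coax):
        mesh, _ = coax
        s1, s2 = solve_current(mesh, 3.0), solve_current(mesh, 7.0)
        s12 = solve_current(mesh, 10.0)
        scale = np.abs(s12.potential).max()
        assert np.abs(s12.potential - (s1.potential + s2.potential)).max() <= 1e-8 * scale

    def test_reciprocity_swapped_polarity_negates_field(self, coax):
        mesh, sol = coax
        swapped = dataclasses.replace(mesh)  # shallow copy, retag boundary
        src, snk = mesh.tag_id("electrode_source"), mesh.tag_id("electrode_sink")
        tag = mesh.tri_tag.copy()
        tag[mesh.tri_tag == src] = snk
        tag[mesh.tri_tag == snk] = src
        swapped.tri_tag = tag
        sol_sw = solve_current(swapped, sol.current)
        scale = np.abs(sol.potential).max()
        assert np.abs(sol_sw.potential + sol.potential).max() <= 1e-8 * scale


class TestConservationAndErrors:
    def test_consistent_flux_matches_injected_current(self, coax, ring2_case):
        _, sol_coax = coax
        assert check_current_conservation(sol_coax) < 1e-8
        *_, sol_ring = ring2_case
        assert check_current_conservation(sol_ring) < 1e-8

    def test_missing_sink_raises_ungrounded_error(self):
        mesh = coaxial_cylinder_mesh(1.0, 2.0, 2.0, 1.0, nr=4, ntheta=12, nz=3)
        tag = mesh.tri_tag.copy()
        tag[tag == mesh.tag_id("electrode_sink")] = mesh.tag_id("insulated")
        mesh.tri_tag = tag
        with pytest.raises(ValueError, match="ungrounded|sink"):
            solve_current(mesh, 1.0)

    def test_solver_residual_within_tolerance(self, ring2_case):
        *_, sol = ring2_case
        assert sol.residual <= 1e-8

    def test_repeated_solves_bitwise_identical(self, coax):
        """No randomness anywhere: identical inputs give identical bits."""
        mesh, _ = coax
        a = solve_current(mesh, 5.0)
        b = solve_current(mesh, 5.0)
        assert (a.potential == b.potential).all()
        assert a.electrode_potentials == b.electrode_potentials


class TestEsophagusFieldStructure:
    def test_potential_antisymmetric_about_midplane(self, ring2_case):
        _, _, mesh, sol = ring2_case
        mirrored = mesh.nodes * np.array([1.0, 1.0, -1.0])
        tree = cKDTree(mesh.nodes)
        d, j = tree.query(mirrored, k=1)
        assert d.max() < 1e-9  # the axial grid is symmetric by construction
        span = sol.potential.max() - sol.potential.min()
        assert np.abs(sol.potential + sol.potential[j]).max() <= 0.01 * span

    def test_electrode_potentials_antisymmetric_gauge(self, ring2_case):
        *_, sol = ring2_case
        v_src, v_snk = sol.electrode_potentials
        assert v_src == pytest.approx(-v_snk, rel=1e-12)
        assert v_src > 0

    def test_near_maximum_principle_on_contacts(self, ring2_case):
        """Interior nodal extrema must not exceed the electrode potentials
        (tiny overshoot tolerance for the non-Delaunay structured split)."""
        *_, sol = ring2_case
        v_el = abs(sol.electrode_potentials[0])
        assert np.abs(sol.potential).max() <= v_el * (1 + 1e-9)

    def test_far_field_truncation_insensitive(self):
        """Doubling the truncation radius moves the impedance by < 2%,
        quantifying the 'infinite surround' idealization."""
        pair = make_ring_pair(2, "ellipse", 26.0)
        z = {}
        for far, L in ((50.0, 120.0), (100.0, 220.0)):
            model = dataclasses.replace(build_default_model(), far_radius=far, axial_length=L)
            sol = assemble_and_solve(generate_mesh(model, pair, 0.17), pair)
            z[far] = impedance(sol)
        assert abs(z[100.0] - z[50.0]) / z[50.0] < 0.02
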