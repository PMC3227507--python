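"""Shared fixtures.

The six bundled scenarios are solved once per session at the default
resolution and summarized; several test modules (acceptance, scenarios)
consume the summaries.  Small analytic fixtures (slab, coaxial cylinder)
are module-scoped and cheap.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from esofield.geometry import build_default_model, make_ring_pair
from esofield.mesh import box_mesh, coaxial_cylinder_mesh, generate_mesh
from esofield.postprocess import field_magnitude, impedance
from esofield.scenarios import SCENARIO_IDS, run_scenario
from esofield.solver import assemble_and_solve, check_current_conservation

settings.register_profile(
    "ci", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DEFAULT_H = 0.17


@pytest.fixture(scope="session")
def scenario_summaries():
    """Solve every bundled scenario once; keep compact summaries only.

    Per scenario: the ScenarioResult (threshold 20 V/m at ST and PDT),
    muscle activation volumes for the 3/20/100 V/m sweep at PDT current,
    the current-conservation error, and a discrete maximum-principle check."""
    from esofield.scenarios import build_scenario
    from esofield.postprocess import threshold_sweep

    out = {}
    for sid in SCENARIO_IDS:
        model, pair = build_scenario(sid)
        mesh = generate_mesh(model, pair, DEFAULT_H)
        sol = assemble_and_solve(mesh, pair)
        result = run_scenario(sid, DEFAULT_H, solution=sol)
        sweep = threshold_sweep(sol, [3.0, 20.0, 100.0], sid)
        v_abs = np.abs(sol.potential)
        v_el = abs(sol.electrode_potentials[0])
        out[sid] = {
            "result": result,
            "sweep_muscle": {r.threshold: r.volumes["muscle"] for r in sweep},
            "sweep_all": {r.threshold: r.volumes for r in sweep},
            "conservation": check_current_conservation(sol),
            "max_overshoot": float(v_abs.max() / v_el - 1.0),
            "n_nodes": mesh.n_nodes,
        }
        del sol, mesh
    return out


@pytest.fixture(scope="session")
def ring2_case():
    """Full solution of the smallest scenario (2 mm ring, elliptical
    contacts) at the default resolution, for field-level checks."""
    model = build_default_model()
    pair = make_ring_pair(2, "ellipse", current=26.0)
    mesh = generate_mesh(model, pair, DEFAULT_H)
    sol = assemble_and_solve(mesh, pair)
    return model, pair, mesh, sol


@pytest.fixture(scope="module")
def slab():
    """Homogeneous 4x4x8 mm slab, plate electrodes on the z faces: the exact
    solution is linear in z, hence exactly representable by the elements."""
    mesh = box_mesh(4.0, 4.0, 8.0, sigma=0.5, nx=4, ny=4, nz=8)
    sol = assemble_and_solve(mesh, mesh_pair(mesh, 10.0))
    return mesh, sol


class mesh_pair:
    """Minimal current-drive stand-in for fixtures without a geometric pair."""

    def __init__(self, mesh, current):
        self.mesh = mesh
        self.current = current


@pytest.fixture(scope="module")
def coax():
    """Coaxial-cylinder fixture: exact resistance ln(b/a)/(2 pi sigma L)."""
    mesh = coaxial_cylinder_mesh(1.5, 5.07, 10.0, sigma=0.27, nr=16, ntheta=28, nz=6)
    sol = assemble_and_solve(mesh, mesh_pair(mesh, 5.0))
    return mesh, sol
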