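"""Closed-form resistances on degenerate geometries, used to validate the
finite-element pipeline end to end (mesher included).

Two exactly solvable cases:

* concentric spherical shells between full spherical electrodes:
      R = sum_i 1/(4 pi sigma_i) (1/r_i - 1/r_{i+1})
  The FEM fixture truncates the sphere with insulated polar caps (the exact
  radial solution also solves the truncated sector), so the FEM value is
  compared against the closed form scaled by 4*pi / sector solid angle.

* coaxial cylinder between full inner/outer electrodes with insulated ends:
      R = ln(b/a) / (2 pi sigma L)

Both closed forms are evaluated directly from the formulas, independent of
the FEM code path.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass

import numpy as np

from . import mesh as _mesh
from .postprocess import impedance
from .solver import solve_current

__all__ = [
    "OracleCase",
    "OracleResult",
    "concentric_shell_resistance",
    "coaxial_cylinder_resistance",
    "run_oracle_suite",
    "default_cases",
]


def concentric_shell_resistance(radii: list[float], conductivities: list[float]) -> float:
    """Series resistance (kOhm) of concentric spherical shells, radii in mm
    (strictly increasing), conductivities in S/m, full spherical electrodes
    at the innermost and outermost radii."""
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) < 2 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing with at least two entries")
    if len(conductivities) != len(radii) - 1:
        raise ValueError("need exactly one conductivity per shell")
    if any(s <= 0 for s in conductivities):
        raise ValueError("conductivities must be > 0")
    r_m = radii * 1e-3
    R = sum(
        (1.0 / (4 * math.pi * s)) * (1.0 / r_m[i] - 1.0 / r_m[i + 1])
        for i, s in enumerate(conductivities)
    )
    return R / 1e3  # Ohm -> kOhm


def coaxial_cylinder_resistance(a: float, b: float, length: float, sigma: float) -> float:
    """Resistance (kOhm) between full coaxial cylindrical electrodes,
    a < b and length in mm, sigma in S/m."""
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    if length <= 0 or sigma <= 0:
        raise ValueError("length and sigma must be > 0")
    return math.log(b / a) / (2 * math.pi * sigma * length * 1e-3) / 1e3


@dataclass(frozen=True)
class OracleCase:
    name: str
    kind: str  # "shell" | "coax"
    params: dict
    closed_form_kohm: float
    tolerance: float = 0.02


@dataclass(frozen=True)
class OracleResult:
    case: OracleCase
    fem_kohm: float
    rel_error: float
    passed: bool
    n_tets: int
    seconds: float


def _shell_case(name: str, radii, sigmas, cap_angle=math.pi / 3) -> OracleCase:
    base = concentric_shell_resistance(radii, sigmas)
    scale = 4 * math.pi / _mesh.sector_solid_angle(cap_angle)
    return OracleCase(
        name=name,
        kind="shell",
        params={"radii": list(radii), "sigmas": list(sigmas), "cap_angle": cap_angle},
        closed_form_kohm=base * scale,
    )


def default_cases() -> list[OracleCase]:
    return [
        _shell_case("single-shell 1-2 mm", [1.0, 2.0], [1.0]),
        _shell_case("two-shell 1-1.5-2 mm", [1.0, 1.5, 2.0], [1.0, 0.5]),
        OracleCase(
            name="coaxial cylinder 1.5-5.07 mm",
            kind="coax",
            params={"a": 1.5, "b": 5.07, "length": 10.0, "sigma": 0.27},
            closed_form_kohm=coaxial_cylinder_resistance(1.5, 5.07, 10.0, 0.27),
        ),
    ]


def _fem_resistance(case: OracleCase, level: float) -> tuple[float, int]:
    """Solve a case with all mesh densities scaled by `level` (1 = default)."""
    p = case.params
    if case.kind == "shell":
        m = _mesh.spherical_shell_mesh(
            p["radii"],
            p["sigmas"],
            cap_angle=p["cap_angle"],
            n_per_shell=max(2, round(6 * level)),
            npolar=max(4, round(10 * level)),
            nphi=max(8, round(28 * level)),
        )
    elif case.kind == "coax":
        m = _mesh.coaxial_cylinder_mesh(
            p["a"],
            p["b"],
            p["length"],
            p["sigma"],
            nr=max(4, round(20 * level)),
            ntheta=max(8, round(32 * level)),
            nz=max(2, round(6 * level)),
        )
    else:
        raise ValueError(f"unknown oracle kind {case.kind!r}")
    sol = solve_current(m, current_mA=1.0)
    return impedance(sol), m.n_tets


def run_oracle_suite(
    cases: list[OracleCase] | None = None, level: float = 1.0
) -> list[OracleResult]:
    """FEM-vs-closed-form comparison for every case at the given resolution."""
    results = []
    for case in cases or default_cases():
        t0 = time.perf_counter()
        fem, n_tets = _fem_resistance(case, level)
        err = abs(fem - case.closed_form_kohm) / case.closed_form_kohm
        results.append(
            OracleResult(
                case=case,
                fem_kohm=fem,
                rel_error=err,
                passed=err <= case.tolerance,
                n_tets=n_tets,
                seconds=time.perf_counter() - t0,
            )
        )
    return results
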