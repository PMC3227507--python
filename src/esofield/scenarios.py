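"""The six bundled stimulation scenarios and their sensory calibration.

Three ring-electrode spacings (2, 10, 20 mm) on the 1.5 mm catheter and
three patch-on-bag fillings (2, 4, 5 mL, patches 10 mm apart) are coupled
with the sensation-threshold (ST, VAS 1) and pain-detection-threshold
(PDT, VAS 5) currents measured in the in-vivo esophageal stimulation
experiment the model accompanies.  One FEM solve per scenario suffices:
the problem is linear in the injected current, so fields at any current
follow by scaling, and the activation volume at threshold t and current
k*I equals the volume at threshold t/k and current I.

The 2 mm ring scenario uses the elliptical mucosal contact (axial semi-axis
0.7 mm): two 1.5 mm-radius circular footprints cannot sit 2 mm apart
centre-to-centre without overlapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .geometry import (
    ElectrodePair,
    EsophagusModel,
    bag_radius,
    build_default_model,
    make_patch_pair,
    make_ring_pair,
)
from .mesh import Mesh, generate_mesh
from .postprocess import (
    DEFAULT_THRESHOLD_V_PER_M,
    ActivationReport,
    activation_volumes_by_region,
    field_magnitude,
    impedance,
)
from .solver import FieldSolution, assemble_and_solve

__all__ = [
    "StimulusTrain",
    "SensoryCalibration",
    "ScenarioResult",
    "SCENARIO_IDS",
    "CALIBRATIONS",
    "REFERENCE_COMPUTED",
    "build_scenario",
    "run_scenario",
    "stimulation_current_range",
    "table1_report",
]


@dataclass(frozen=True)
class StimulusTrain:
    """Constant-current pulse train descriptor (the stimulus delivered at
    each calibrated current)."""

    pulse_width: float = 1.0  # ms
    frequency: float = 200.0  # Hz
    n_pulses: int = 5

    def __post_init__(self) -> None:
        if self.pulse_width <= 0 or self.frequency <= 0 or self.n_pulses < 1:
            raise ValueError("invalid stimulus train")
        if self.pulse_width * self.frequency > 1000.0:
            raise ValueError("pulses overlap: pulse_width * frequency exceeds 1000 ms*Hz")


DEFAULT_STIMULUS = StimulusTrain()


@dataclass(frozen=True)
class SensoryCalibration:
    """ST/PDT currents (mA) anchoring VAS 1 and VAS 5 for one scenario."""

    scenario_id: str
    ST_current: float
    PDT_current: float

    def __post_init__(self) -> None:
        if not 0 < self.ST_current < self.PDT_current:
            raise ValueError("need 0 < ST_current < PDT_current")


SCENARIO_IDS = ("ring2", "ring10", "ring20", "patch2ml", "patch4ml", "patch5ml")

# Bundled in-vivo calibration (two healthy volunteers, averaged): sensation
# and pain-detection currents per electrode configuration.
CALIBRATIONS: dict[str, SensoryCalibration] = {
    "ring2": SensoryCalibration("ring2", 13.0, 26.0),
    "ring10": SensoryCalibration("ring10", 8.0, 22.0),
    "ring20": SensoryCalibration("ring20", 4.0, 14.0),
    "patch2ml": SensoryCalibration("patch2ml", 14.0, 29.0),
    "patch4ml": SensoryCalibration("patch4ml", 12.0, 22.0),
    "patch5ml": SensoryCalibration("patch5ml", 12.0, 21.0),
}

# Published model outputs for the same six scenarios, kept for side-by-side
# comparison in table1_report; never overwritten by computed values.
REFERENCE_COMPUTED: dict[str, dict[str, float]] = {
    "impedance_kohm": {
        "ring2": 0.94, "ring10": 1.05, "ring20": 1.08,
        "patch2ml": 0.86, "patch4ml": 0.81, "patch5ml": 0.79,
    },
    "mucosa_ST_mm3": {
        "ring2": 276, "ring10": 626, "ring20": 419,
        "patch2ml": 697, "patch4ml": 557, "patch5ml": 647,
    },
    "mucosa_PDT_mm3": {
        "ring2": 388, "ring10": 793, "ring20": 971,
        "patch2ml": 1102, "patch4ml": 880, "patch5ml": 1104,
    },
    "muscle_ST_mm3": {
        "ring2": 898, "ring10": 2759, "ring20": 1249,
        "patch2ml": 2739, "patch4ml": 2318, "patch5ml": 2631,
    },
    "muscle_PDT_mm3": {
        "ring2": 1551, "ring10": 3681, "ring20": 4504,
        "patch2ml": 4437, "patch4ml": 3701, "patch5ml": 4536,
    },
}


@dataclass(frozen=True)
class ScenarioResult:
    scenario_id: str
    impedance: float  # kOhm
    report_ST: ActivationReport
    report_PDT: ActivationReport
    current_range: float  # mA
    n_nodes: int

    def __post_init__(self) -> None:
        cal = CALIBRATIONS[self.scenario_id]
        expected = cal.PDT_current - cal.ST_current
        if abs(self.current_range - expected) > 1e-12:
            raise ValueError("current_range must equal PDT_current - ST_current")


def stimulation_current_range(cal: SensoryCalibration) -> float:
    """Usable dynamic window PDT - ST in mA."""
    if cal.ST_current >= cal.PDT_current:
        raise ValueError("empty stimulation window: ST >= PDT")
    return cal.PDT_current - cal.ST_current


def build_scenario(scenario_id: str) -> tuple[EsophagusModel, ElectrodePair]:
    """Model + electrode pair for a bundled scenario, at its PDT current."""
    if scenario_id not in SCENARIO_IDS:
        raise KeyError(f"unknown scenario {scenario_id!r}; choose from {SCENARIO_IDS}")
    cal = CALIBRATIONS[scenario_id]
    model = build_default_model()
    if scenario_id.startswith("ring"):
        distance = float(scenario_id.removeprefix("ring"))
        shape = "ellipse" if distance < 3.0 else "circle"
        pair = make_ring_pair(distance, shape, current=cal.PDT_current)
    else:
        volume = float(scenario_id.removeprefix("patch").removesuffix("ml"))
        pair = make_patch_pair(volume, current=cal.PDT_current)
        # inflation presses the wall out to the bag radius; the incompressible
        # wall thins as it stretches circumferentially
        model = model.distended(bag_radius(volume))
    return model, pair


def run_scenario(
    scenario_id: str,
    h: float = 0.17,
    threshold: float = DEFAULT_THRESHOLD_V_PER_M,
    *,
    mesh: Mesh | None = None,
    solution: FieldSolution | None = None,
) -> ScenarioResult:
    """Solve a bundled scenario once (at PDT current) and report activation
    volumes at both calibrated currents.

    The ST-current report is obtained from the PDT solve through the exact
    scaling identity vol(t, ST) = vol(t * PDT/ST, PDT).  A pre-computed mesh
    or solution may be passed to avoid re-solving.
    """
    cal = CALIBRATIONS[scenario_id]
    model, pair = build_scenario(scenario_id)
    if solution is None:
        if mesh is None:
            mesh = generate_mesh(model, pair, h)
        solution = assemble_and_solve(mesh, pair)
    z = impedance(solution)
    emag = field_magnitude(solution)  # at PDT current

    def report(current: float) -> ActivationReport:
        scale = cal.PDT_current / current
        vols = {
            name: float(
                solution.mesh.tet_volumes[
                    (emag >= threshold * scale) & solution.mesh.region_mask(name)
                ].sum()
            )
            for name in solution.mesh.region_names
        }
        return ActivationReport(
            scenario_id=scenario_id,
            impedance=z,
            threshold=threshold,
            volumes=vols,
            current=current,
        )

    return ScenarioResult(
        scenario_id=scenario_id,
        impedance=z,
        report_ST=report(cal.ST_current),
        report_PDT=report(cal.PDT_current),
        current_range=stimulation_current_range(cal),
        n_nodes=solution.mesh.n_nodes,
    )


def table1_report(
    h: float = 0.17,
    scenario_ids: tuple[str, ...] = SCENARIO_IDS,
    results: dict[str, ScenarioResult] | None = None,
) -> pd.DataFrame:
    """Computed impedances and ST/PDT activation volumes for the bundled
    scenarios, side by side with the published model values and relative
    deviations.  Pass precomputed ScenarioResults to skip the solves."""
    rows = []
    for sid in scenario_ids:
        res = results[sid] if results else run_scenario(sid, h)
        row = {
            "scenario": sid,
            "impedance_kohm": res.impedance,
            "mucosa_ST_mm3": res.report_ST.volumes["mucosa"],
            "mucosa_PDT_mm3": res.report_PDT.volumes["mucosa"],
            "muscle_ST_mm3": res.report_ST.volumes["muscle"],
            "muscle_PDT_mm3": res.report_PDT.volumes["muscle"],
        }
        for key in REFERENCE_COMPUTED:
            ref = REFERENCE_COMPUTED[key][sid]
            row[f"{key}_ref"] = ref
            row[f"{key}_dev"] = (row[key] - ref) / ref
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario")
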