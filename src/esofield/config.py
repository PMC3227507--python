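"""YAML run configuration: scenario selection or fully custom geometry.

A config names either a bundled scenario (defaults are then filled in from
its presets) or a custom layered model plus electrode pair.  Unknown keys are
rejected at every level; loading then dumping then loading reproduces the
same configuration exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import (
    ContactPatch,
    ElectrodePair,
    EsophagusModel,
    LayerSpec,
    bag_radius,
    build_default_model,
    make_patch_pair,
    make_ring_pair,
)
from .postprocess import DEFAULT_THRESHOLD_V_PER_M

__all__ = ["RunConfig", "load_config", "dump_config"]

_TOP_KEYS = {
    "scenario",
    "current_mA",
    "electrode",
    "layers",
    "surround_S_per_m",
    "inner_radius_mm",
    "far_radius_mm",
    "axial_length_mm",
    "mesh",
    "thresholds_Vpm",
    "out_dir",
    "export",
}
_ELECTRODE_KEYS = {"kind", "distance_mm", "shape", "bag_volume_ml"}
_LAYER_KEYS = {"name", "thickness_mm", "conductivity_S_per_m"}
_MESH_KEYS = {"h_mm", "refine"}
_EXPORT_KEYS = {"vtu", "mesh"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass(frozen=True)
class RunConfig:
    scenario: str | None
    current_mA: float
    electrode: dict
    layers: tuple[dict, ...]
    surround_S_per_m: float
    inner_radius_mm: float
    far_radius_mm: float
    axial_length_mm: float
    h_mm: float
    refine: int
    thresholds_Vpm: tuple[float, ...]
    out_dir: str
    export_vtu: bool
    export_mesh: bool

    def to_model(self) -> EsophagusModel:
        layers = tuple(
            LayerSpec(l["name"], l["thickness_mm"], l["conductivity_S_per_m"])
            for l in self.layers
        )
        return EsophagusModel(
            inner_radius=self.inner_radius_mm,
            layers=layers,
            surround_conductivity=self.surround_S_per_m,
            far_radius=self.far_radius_mm,
            axial_length=self.axial_length_mm,
        )

    def to_pair(self) -> ElectrodePair:
        e = self.electrode
        if e["kind"] == "ring":
            return make_ring_pair(e["distance_mm"], e["shape"], self.current_mA)
        return make_patch_pair(
            e["bag_volume_ml"], self.current_mA, distance=e["distance_mm"]
        )

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "current_mA": self.current_mA,
            "electrode": dict(self.electrode),
            "layers": [dict(l) for l in self.layers],
            "surround_S_per_m": self.surround_S_per_m,
            "inner_radius_mm": self.inner_radius_mm,
            "far_radius_mm": self.far_radius_mm,
            "axial_length_mm": self.axial_length_mm,
            "mesh": {"h_mm": self.h_mm, "refine": self.refine},
            "thresholds_Vpm": list(self.thresholds_Vpm),
            "out_dir": self.out_dir,
            "export": {"vtu": self.export_vtu, "mesh": self.export_mesh},
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        _check_keys(raw, _TOP_KEYS, "config")
        scenario = raw.get("scenario")

        # defaults, optionally specialized by the named scenario
        from .scenarios import CALIBRATIONS, SCENARIO_IDS, build_scenario

        model = build_default_model()
        electrode = {"kind": "ring", "distance_mm": 10.0, "shape": "circle", "bag_volume_ml": None}
        current = 20.0
        if scenario is not None:
            if scenario not in SCENARIO_IDS:
                raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIO_IDS}")
            model, pair = build_scenario(scenario)
            current = CALIBRATIONS[scenario].PDT_current
            electrode = {
                "kind": pair.kind,
                "distance_mm": pair.interelectrode_distance,
                "shape": pair.contacts[0].shape if pair.kind == "ring" else "rect",
                "bag_volume_ml": pair.bag_volume,
            }

        if "electrode" in raw:
            _check_keys(raw["electrode"], _ELECTRODE_KEYS, "electrode")
            electrode.update(raw["electrode"])
        layers_raw = raw.get(
            "layers",
            [
                {"name": l.name, "thickness_mm": l.thickness, "conductivity_S_per_m": l.conductivity}
                for l in model.layers
            ],
        )
        for l in layers_raw:
            _check_keys(l, _LAYER_KEYS, f"layer {l.get('name', '?')!r}")
        mesh_raw = raw.get("mesh", {})
        _check_keys(mesh_raw, _MESH_KEYS, "mesh")
        export_raw = raw.get("export", {})
        _check_keys(export_raw, _EXPORT_KEYS, "export")

        cfg = cls(
            scenario=scenario,
            current_mA=float(raw.get("current_mA", current)),
            electrode=electrode,
            layers=tuple(dict(l) for l in layers_raw),
            surround_S_per_m=float(raw.get("surround_S_per_m", model.surround_conductivity)),
            inner_radius_mm=float(raw.get("inner_radius_mm", model.inner_radius)),
            far_radius_mm=float(raw.get("far_radius_mm", model.far_radius)),
            axial_length_mm=float(raw.get("axial_length_mm", model.axial_length)),
            h_mm=float(mesh_raw.get("h_mm", 0.17)),
            refine=int(mesh_raw.get("refine", 2)),
            thresholds_Vpm=tuple(
                float(t) for t in raw.get("thresholds_Vpm", [DEFAULT_THRESHOLD_V_PER_M])
            ),
            out_dir=str(raw.get("out_dir", "out")),
            export_vtu=bool(export_raw.get("vtu", False)),
            export_mesh=bool(export_raw.get("mesh", False)),
        )
        cfg.to_model()  # validates geometry values with field-level messages
        cfg.to_pair()
        if any(t <= 0 for t in cfg.thresholds_Vpm):
            raise ValueError("thresholds_Vpm must be > 0")
        return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw or {})


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
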