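"""Layered esophageal volume-conductor geometry and bipolar electrode pairs.

The esophagus is modelled as a straight tube of two concentric tissue shells
(mucosa, muscle) around a non-conducting catheter/bag lumen, embedded in an
effectively infinite surrounding medium (serosa plus lung, one equivalent
conductivity).  All lengths are millimetres, conductivities S/m, currents mA.

Coordinates: z runs along the esophageal axis with the origin midway between
the two electrode contacts; angles are measured around the axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "LayerSpec",
    "EsophagusModel",
    "ContactPatch",
    "ElectrodePair",
    "build_default_model",
    "make_ring_pair",
    "make_patch_pair",
    "bag_radius",
    "DEFAULT_CIRCLE_RADIUS_MM",
    "DEFAULT_ELLIPSE_SEMI_AXES_MM",
    "PATCH_SIDE_MM",
    "BAG_MAX_VOLUME_ML",
    "BAG_MAX_DIAMETER_MM",
    "BAG_LENGTH_MM",
]

#: Mucosal contact footprint of a ring electrode with full circular apposition.
DEFAULT_CIRCLE_RADIUS_MM = 1.5
#: (axial, circumferential) semi-axes of the elliptical footprint seen when the
#: catheter lies in a collapsed, slit-like lumen.
DEFAULT_ELLIPSE_SEMI_AXES_MM = (0.7, 7.5)
#: Square patch electrode with the same surface area as the circular ring
#: contact (area equality between the two electrode designs is a property of
#: the physical catheter).
PATCH_SIDE_MM = math.sqrt(math.pi) * DEFAULT_CIRCLE_RADIUS_MM  # sqrt(pi*r^2)

BAG_MAX_VOLUME_ML = 6.0
BAG_MAX_DIAMETER_MM = 28.0
#: Bag modelled as a cylinder of fixed length whose full 6 mL filling yields
#: the 28 mm maximum diameter: L = V_max / (pi * R_max^2).
BAG_LENGTH_MM = BAG_MAX_VOLUME_ML * 1000.0 / (math.pi * (BAG_MAX_DIAMETER_MM / 2) ** 2)


@dataclass(frozen=True)
class LayerSpec:
    """One isotropic tissue shell of the esophageal wall."""

    name: str
    thickness: float  # mm
    conductivity: float  # S/m

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0, got {self.thickness}")
        if self.conductivity <= 0:
            raise ValueError(
                f"layer {self.name!r}: conductivity must be > 0, got {self.conductivity}"
            )


MUCOSA = LayerSpec("mucosa", thickness=0.85, conductivity=0.05)
MUSCLE = LayerSpec("muscle", thickness=2.72, conductivity=0.53)
SURROUND_CONDUCTIVITY = 0.27  # serosa + lung equivalent


@dataclass(frozen=True)
class EsophagusModel:
    """Layered tubular volume conductor around a non-conducting lumen.

    ``inner_radius`` is the surface where electrodes touch the mucosa (the
    catheter radius for ring electrodes, the inflated bag radius for patch
    electrodes).  ``far_radius`` and ``axial_length`` truncate the infinite
    surround; the far boundary is held at zero potential by the solver.
    """

    inner_radius: float = DEFAULT_CIRCLE_RADIUS_MM
    layers: tuple[LayerSpec, ...] = (MUCOSA, MUSCLE)
    surround_conductivity: float = SURROUND_CONDUCTIVITY
    far_radius: float = 50.0
    axial_length: float = 120.0
    #: resting-state layers when this model is a distended variant (the mesh
    #: coarseness gate is anchored to the resting anatomy)
    resting_layers: tuple[LayerSpec, ...] | None = None

    def __post_init__(self) -> None:
        if self.inner_radius <= 0:
            raise ValueError("inner_radius must be > 0")
        if not self.layers:
            raise ValueError("at least one tissue layer is required")
        if self.surround_conductivity <= 0:
            raise ValueError("surround_conductivity must be > 0")
        if self.far_radius <= self.outer_wall_radius:
            raise ValueError(
                f"far_radius {self.far_radius} mm must exceed the outer wall radius "
                f"{self.outer_wall_radius:.2f} mm"
            )
        if self.axial_length <= 0:
            raise ValueError("axial_length must be > 0")

    @property
    def wall_thickness(self) -> float:
        return sum(l.thickness for l in self.layers)

    @property
    def outer_wall_radius(self) -> float:
        return self.inner_radius + self.wall_thickness

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.layers) + ("surround",)

    def conductivity_of(self, region: str) -> float:
        for l in self.layers:
            if l.name == region:
                return l.conductivity
        if region == "surround":
            return self.surround_conductivity
        raise KeyError(f"unknown region {region!r}")

    def layer_radii(self) -> np.ndarray:
        """Interface radii, innermost surface first, ending at far_radius."""
        r = [self.inner_radius]
        for l in self.layers:
            r.append(r[-1] + l.thickness)
        r.append(self.far_radius)
        return np.asarray(r)

    def with_inner_radius(self, inner_radius: float) -> "EsophagusModel":
        return replace(self, inner_radius=inner_radius)

    def distended(self, inner_radius: float) -> "EsophagusModel":
        """Model with the lumen distended to a new inner radius.

        The wall is treated as incompressible under circumferential stretch
        (plane strain): each layer keeps its annular cross-sectional area, so
        distension thins the layers.  Conductivities are unchanged.  Used for
        the patch-on-bag scenarios, where inflation presses the wall outward.
        """
        if inner_radius < self.inner_radius:
            raise ValueError("distension cannot reduce the inner radius")
        r_old = self.inner_radius
        r_new = inner_radius
        new_layers = []
        for l in self.layers:
            r_old_out = r_old + l.thickness
            r_new_out = math.sqrt(r_new**2 + r_old_out**2 - r_old**2)
            new_layers.append(replace(l, thickness=r_new_out - r_new))
            r_old, r_new = r_old_out, r_new_out
        return replace(
            self,
            inner_radius=inner_radius,
            layers=tuple(new_layers),
            resting_layers=self.resting_layers or self.layers,
        )


def build_default_model() -> EsophagusModel:
    """Default two-layer model: mucosa 0.85 mm / 0.05 S/m, muscle 2.72 mm /
    0.53 S/m, surround 0.27 S/m, catheter radius 1.5 mm."""
    return EsophagusModel()


Shape = Literal["circle", "ellipse", "rect"]
Polarity = Literal["source", "sink"]


@dataclass(frozen=True)
class ContactPatch:
    """Electrode contact footprint on the inner (mucosal) surface.

    The footprint is defined in the developed coordinates of the contact
    cylinder: axial offset dz and arc length ds = R * dtheta.  Because the
    cylinder is a developable surface, planar shape areas are preserved.
    A footprint whose circumferential extent exceeds the half-circumference
    wraps into a closed band (the limiting case of a ring electrode in a
    collapsed lumen).
    """

    shape: Shape
    dimensions: tuple[float, ...]  # circle: (r,); ellipse: (a_axial, b_circ); rect: (w_axial, l_circ)
    center_axial_position: float = 0.0  # mm
    center_angle: float = 0.0  # rad
    polarity: Polarity = "source"

    def __post_init__(self) -> None:
        n_expected = {"circle": 1, "ellipse": 2, "rect": 2}
        if self.shape not in n_expected:
            raise ValueError(f"unknown contact shape {self.shape!r}")
        if len(self.dimensions) != n_expected[self.shape]:
            raise ValueError(f"{self.shape} contact needs {n_expected[self.shape]} dimension(s)")
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("contact dimensions must be > 0")
        if self.polarity not in ("source", "sink"):
            raise ValueError(f"polarity must be 'source' or 'sink', got {self.polarity!r}")

    @property
    def axial_half_extent(self) -> float:
        if self.shape == "circle":
            return self.dimensions[0]
        if self.shape == "ellipse":
            return self.dimensions[0]
        return self.dimensions[0] / 2  # rect

    @property
    def circumferential_half_extent(self) -> float:
        if self.shape == "circle":
            return self.dimensions[0]
        if self.shape == "ellipse":
            return self.dimensions[1]
        return self.dimensions[1] / 2

    @property
    def area(self) -> float:
        """Nominal (developed-plane) footprint area in mm^2."""
        if self.shape == "circle":
            return math.pi * self.dimensions[0] ** 2
        if self.shape == "ellipse":
            return math.pi * self.dimensions[0] * self.dimensions[1]
        return self.dimensions[0] * self.dimensions[1]

    def contains(self, z: np.ndarray, theta: np.ndarray, surface_radius: float) -> np.ndarray:
        """Membership of surface points (z, theta) on a cylinder of the given
        radius, with circumferential wrap-around."""
        dz = np.asarray(z) - self.center_axial_position
        dtheta = np.mod(np.asarray(theta) - self.center_angle + math.pi, 2 * math.pi) - math.pi
        ds = surface_radius * dtheta
        if self.shape == "circle":
            r = self.dimensions[0]
            return dz**2 + ds**2 <= r**2
        if self.shape == "ellipse":
            a, b = self.dimensions
            return (dz / a) ** 2 + (ds / b) ** 2 <= 1.0
        w, l = self.dimensions
        return (np.abs(dz) <= w / 2) & (np.abs(ds) <= l / 2)


@dataclass(frozen=True)
class ElectrodePair:
    """Bipolar pair: two equal-area contacts of opposite polarity, separated
    axially by ``interelectrode_distance`` (centre to centre)."""

    kind: Literal["ring", "patch"]
    contacts: tuple[ContactPatch, ContactPatch]
    interelectrode_distance: float  # mm
    current: float  # mA
    bag_volume: float | None = None  # mL, patch kind only

    def __post_init__(self) -> None:
        if self.kind not in ("ring", "patch"):
            raise ValueError(f"kind must be 'ring' or 'patch', got {self.kind!r}")
        if self.interelectrode_distance <= 0:
            raise ValueError("interelectrode_distance must be > 0")
        if self.current < 0:
            raise ValueError("current must be >= 0")
        pols = sorted(c.polarity for c in self.contacts)
        if pols != ["sink", "source"]:
            raise ValueError("pair needs exactly one source and one sink contact")
        a0, a1 = (c.area for c in self.contacts)
        if not math.isclose(a0, a1, rel_tol=1e-9):
            raise ValueError("the two contacts must have equal area")
        gap = self.interelectrode_distance - sum(c.axial_half_extent for c in self.contacts)
        if gap <= 0:
            raise ValueError(
                f"contacts overlap axially: centre distance {self.interelectrode_distance} mm "
                f"<= combined axial extent {sum(c.axial_half_extent for c in self.contacts)} mm"
            )
        if self.kind == "patch" and self.bag_volume is None:
            raise ValueError("patch pair requires bag_volume")

    @property
    def source(self) -> ContactPatch:
        return next(c for c in self.contacts if c.polarity == "source")

    @property
    def sink(self) -> ContactPatch:
        return next(c for c in self.contacts if c.polarity == "sink")

    def with_current(self, current: float) -> "ElectrodePair":
        return replace(self, current=current)


def _symmetric_contacts(
    shape: Shape, dims: tuple[float, ...], distance: float
) -> tuple[ContactPatch, ContactPatch]:
    half = distance / 2
    return (
        ContactPatch(shape, dims, center_axial_position=+half, polarity="source"),
        ContactPatch(shape, dims, center_axial_position=-half, polarity="sink"),
    )


def make_ring_pair(
    distance: float,
    contact_shape: Literal["circle", "ellipse"] = "circle",
    current: float = 20.0,
    *,
    circle_radius: float = DEFAULT_CIRCLE_RADIUS_MM,
    ellipse_semi_axes: tuple[float, float] = DEFAULT_ELLIPSE_SEMI_AXES_MM,
) -> ElectrodePair:
    """Bipolar ring-electrode pair on the catheter.

    ``contact_shape`` selects the mucosal apposition: ``circle`` (radius
    1.5 mm by default) for a round lumen cross-section, ``ellipse``
    (semi-axes 0.7 mm axial x 7.5 mm circumferential) for a collapsed one.
    Rejects spacings at which the two footprints would overlap.
    """
    if distance <= 0:
        raise ValueError("interelectrode distance must be > 0")
    if contact_shape == "circle":
        contacts = _symmetric_contacts("circle", (circle_radius,), distance)
    elif contact_shape == "ellipse":
        contacts = _symmetric_contacts("ellipse", tuple(ellipse_semi_axes), distance)
    else:
        raise ValueError(f"ring contact shape must be 'circle' or 'ellipse', got {contact_shape!r}")
    return ElectrodePair(
        kind="ring",
        contacts=contacts,
        interelectrode_distance=distance,
        current=current,
    )


def bag_radius(volume_ml: float) -> float:
    """Radius (mm) of the inflation bag at a given filling volume.

    Cylinder of fixed length ``BAG_LENGTH_MM``; radius grows as sqrt(volume)
    up to the 14 mm maximum at 6 mL.
    """
    if not 0 < volume_ml <= BAG_MAX_VOLUME_ML:
        raise ValueError(
            f"bag volume must be in (0, {BAG_MAX_VOLUME_ML}] mL (fully inflated bag holds "
            f"{BAG_MAX_VOLUME_ML} mL), got {volume_ml}"
        )
    return (BAG_MAX_DIAMETER_MM / 2) * math.sqrt(volume_ml / BAG_MAX_VOLUME_ML)


def make_patch_pair(
    bag_volume: float,
    current: float = 20.0,
    *,
    distance: float = 10.0,
    side: float = PATCH_SIDE_MM,
) -> ElectrodePair:
    """Bipolar patch pair glued to the non-conducting inflation bag.

    Square patches (side chosen so the area equals the circular ring contact)
    sit at the bag surface, 10 mm apart axially at the same angular position.
    The bag interior is non-conducting; its wall is insulating except at the
    two patches.
    """
    bag_radius(bag_volume)  # validates the volume
    contacts = _symmetric_contacts("rect", (side, side), distance)
    return ElectrodePair(
        kind="patch",
        contacts=contacts,
        interelectrode_distance=distance,
        current=current,
        bag_volume=bag_volume,
    )
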