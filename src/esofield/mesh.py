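"""Deterministic structured meshing of layered tubular (and fixture) domains.

A curvilinear structured grid (three 1-D parameter arrays plus a coordinate
mapping, optionally periodic in the second parameter) is subdivided into
tetrahedra with the Kuhn 6-tet split.  Because every hexahedron is split
identically in index space, shared faces — including the periodic seam —
carry matching diagonals, so the mesh is conforming by construction.

Grids are graded: fine near the electrode contacts, geometrically coarsening
towards the truncated far field.  Radial node lines coincide exactly with the
tissue interfaces, so every element lies in exactly one region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .geometry import ContactPatch, ElectrodePair, EsophagusModel

__all__ = [
    "Mesh",
    "generate_mesh",
    "coaxial_cylinder_mesh",
    "spherical_shell_mesh",
    "box_mesh",
    "BOUNDARY_TAGS",
]

BOUNDARY_TAGS = ("electrode_source", "electrode_sink", "far_field", "insulated")

# Kuhn subdivision: 6 tets per hex, one per permutation of the three local
# axes.  Corner index = 4*di + 2*dj + dk.
_TETS6 = np.array(
    [
        (0, 4, 6, 7),
        (0, 4, 5, 7),
        (0, 2, 6, 7),
        (0, 2, 3, 7),
        (0, 1, 5, 7),
        (0, 1, 3, 7),
    ],
    dtype=np.int64,
)

# Boundary-face triangulation induced by the Kuhn split: for each structured
# face (axis, side) the two triangles (as hex-corner triples) and the local
# index (0..5) of the tet owning each triangle.
_FACE_TRIS = {
    (0, 0): (((0, 1, 3), 5), ((0, 2, 3), 3)),
    (0, 1): (((4, 6, 7), 0), ((4, 5, 7), 1)),
    (1, 0): (((0, 4, 5), 1), ((0, 1, 5), 4)),
    (1, 1): (((2, 6, 7), 2), ((2, 3, 7), 3)),
    (2, 0): (((0, 4, 6), 0), ((0, 2, 6), 2)),
    (2, 1): (((1, 5, 7), 4), ((1, 3, 7), 5)),
}

# the four hex corners spanning each structured boundary face
_FACE_QUADS = {
    (0, 0): (0, 1, 2, 3),
    (0, 1): (4, 5, 6, 7),
    (1, 0): (0, 1, 4, 5),
    (1, 1): (2, 3, 6, 7),
    (2, 0): (0, 2, 4, 6),
    (2, 1): (1, 3, 5, 7),
}


@dataclass
class Mesh:
    """Labelled tetrahedral mesh.

    nodes are in mm.  ``region`` holds one region id per tet (index into
    ``region_names``); boundary triangles carry a tag (index into
    ``tag_names``) and the id of the owning tet for flux evaluation.
    """

    nodes: np.ndarray  # (N, 3) float64, mm
    tets: np.ndarray  # (M, 4) int
    region: np.ndarray  # (M,) int
    region_names: tuple[str, ...]
    tris: np.ndarray  # (F, 3) int
    tri_tag: np.ndarray  # (F,) int
    tag_names: tuple[str, ...]
    tri_owner: np.ndarray  # (F,) int
    conductivity: dict[str, float]
    h: float

    @cached_property
    def tet_volumes(self) -> np.ndarray:
        p = self.nodes[self.tets]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0

    def region_id(self, name: str) -> int:
        return self.region_names.index(name)

    def tag_id(self, name: str) -> int:
        return self.tag_names.index(name)

    def region_volume(self, name: str) -> float:
        return float(self.tet_volumes[self.region == self.region_id(name)].sum())

    def region_mask(self, name: str) -> np.ndarray:
        return self.region == self.region_id(name)

    def sigma_by_element(self) -> np.ndarray:
        table = np.array([self.conductivity[n] for n in self.region_names])
        return table[self.region]

    def facets_with_tag(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.tri_tag == self.tag_id(name))

    def nodes_with_tag(self, name: str) -> np.ndarray:
        return np.unique(self.tris[self.facets_with_tag(name)])

    def facet_areas(self, facets: np.ndarray | None = None) -> np.ndarray:
        tris = self.tris if facets is None else self.tris[facets]
        p = self.nodes[tris]
        return 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    def facet_outward_normals(self, facets: np.ndarray) -> np.ndarray:
        """Unit normals pointing out of the domain (away from the owner tet)."""
        tris = self.tris[facets]
        p = self.nodes[tris]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        n /= np.linalg.norm(n, axis=1, keepdims=True)
        tet_centroid = self.nodes[self.tets[self.tri_owner[facets]]].mean(axis=1)
        tri_centroid = p.mean(axis=1)
        flip = np.einsum("ij,ij->i", n, tri_centroid - tet_centroid) < 0
        n[flip] *= -1
        return n

    def electrode_facet_area(self, which: str) -> float:
        return float(self.facet_areas(self.facets_with_tag(which)).sum())

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_tets(self) -> int:
        return self.tets.shape[0]


# ---------------------------------------------------------------------------
# structured block machinery
# ---------------------------------------------------------------------------


class _Block:
    """Structured (n1+1) x n2(+1) x (n3+1) node grid, optionally periodic in
    axis 2, with Kuhn tetrahedralization and structured boundary faces."""

    def __init__(self, g1: np.ndarray, g2: np.ndarray, g3: np.ndarray, periodic2: bool):
        self.g1, self.g2, self.g3 = g1, g2, g3
        self.periodic2 = periodic2
        self.n1 = len(g1) - 1
        self.n2 = len(g2) - 1 if not periodic2 else len(g2)
        self.n3 = len(g3) - 1
        self.N2 = self.n2 if periodic2 else self.n2 + 1
        self.N3 = self.n3 + 1

    def node_id(self, i, j, k):
        jj = np.mod(j, self.N2) if self.periodic2 else j
        return (np.asarray(i) * self.N2 + jj) * self.N3 + np.asarray(k)

    def param_nodes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        p2 = self.g2[: self.N2] if self.periodic2 else self.g2
        P1, P2, P3 = np.meshgrid(self.g1, p2, self.g3, indexing="ij")
        return P1.ravel(), P2.ravel(), P3.ravel()

    def hex_corner_ids(self) -> np.ndarray:
        """(n_hex, 8) node ids, corner order 4*di + 2*dj + dk."""
        i = np.arange(self.n1)
        j = np.arange(self.n2)
        k = np.arange(self.n3)
        I, J, K = np.meshgrid(i, j, k, indexing="ij")
        I, J, K = I.ravel(), J.ravel(), K.ravel()
        corners = [
            self.node_id(I + di, J + dj, K + dk)
            for di in (0, 1)
            for dj in (0, 1)
            for dk in (0, 1)
        ]
        # reorder into 4*di+2*dj+dk
        return np.stack(corners, axis=1)

    def tets(self, hexes: np.ndarray) -> np.ndarray:
        t = hexes[:, _TETS6]  # (n_hex, 6, 4)
        return t.reshape(-1, 4)

    def hex_grid_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        i = np.arange(self.n1)
        j = np.arange(self.n2)
        k = np.arange(self.n3)
        I, J, K = np.meshgrid(i, j, k, indexing="ij")
        return I.ravel(), J.ravel(), K.ravel()

    def boundary_faces(self):
        """Yield (axis, side, tris, owner_tets, quads) per structured boundary.

        `tris` holds both triangles of every quad face (first all first
        triangles, then all second ones); `quads` holds the four face corners
        once per face, so tags computed on quad centroids — which respect the
        grid's mirror symmetries — can be tiled onto the triangles."""
        sides = [(0, 0), (0, 1), (2, 0), (2, 1)]
        if not self.periodic2:
            sides += [(1, 0), (1, 1)]
        hexes = self.hex_corner_ids()
        n2, n3 = self.n2, self.n3
        for axis, side in sides:
            if axis == 0:
                ii = 0 if side == 0 else self.n1 - 1
                hex_ids = (ii * n2 + np.arange(n2)[:, None]) * n3 + np.arange(n3)[None, :]
            elif axis == 1:
                jj = 0 if side == 0 else self.n2 - 1
                hex_ids = (np.arange(self.n1)[:, None] * n2 + jj) * n3 + np.arange(n3)[None, :]
            else:
                kk = 0 if side == 0 else self.n3 - 1
                hex_ids = (np.arange(self.n1)[:, None] * n2 + np.arange(n2)[None, :]) * n3 + kk
            hex_ids = hex_ids.ravel()
            corners = hexes[hex_ids]
            tris, owners = [], []
            for (tri_corners, local_tet) in _FACE_TRIS[(axis, side)]:
                tris.append(corners[:, list(tri_corners)])
                owners.append(hex_ids * 6 + local_tet)
            quads = corners[:, list(_FACE_QUADS[(axis, side)])]
            yield axis, side, np.concatenate(tris), np.concatenate(owners), quads


def _orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = nodes[tets]
    det = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    flip = det < 0
    tets[flip, 0], tets[flip, 1] = tets[flip, 1].copy(), tets[flip, 0].copy()
    return tets


def _build_mesh(
    block: _Block,
    mapping,
    region_of_i1,
    tag_fn,
    region_names: tuple[str, ...],
    conductivity: dict[str, float],
    h: float,
) -> Mesh:
    p1, p2, p3 = block.param_nodes()
    nodes = mapping(p1, p2, p3)
    hexes = block.hex_corner_ids()
    tets = _orient_positive(nodes, block.tets(hexes).astype(np.int32))
    I, _, _ = block.hex_grid_index()
    region = np.repeat(region_of_i1[I].astype(np.int16), 6)

    all_tris, all_tags, all_owners = [], [], []
    for axis, side, tris, owners, quads in block.boundary_faces():
        centroids = nodes[quads].mean(axis=1)
        tags = np.tile(tag_fn(axis, side, centroids), 2)
        all_tris.append(tris)
        all_tags.append(tags)
        all_owners.append(owners)
    mesh = Mesh(
        nodes=nodes,
        tets=tets,
        region=region,
        region_names=region_names,
        tris=np.concatenate(all_tris).astype(np.int32),
        tri_tag=np.concatenate(all_tags).astype(np.int16),
        tag_names=BOUNDARY_TAGS,
        tri_owner=np.concatenate(all_owners).astype(np.int64),
        conductivity=conductivity,
        h=h,
    )
    if np.any(mesh.tet_volumes <= 0):
        raise RuntimeError("degenerate tetrahedra in structured mesh")
    return mesh


# ---------------------------------------------------------------------------
# grid grading helpers
# ---------------------------------------------------------------------------


def _graded_march(start: float, stop: float, d0: float, ratio: float, cap: float) -> np.ndarray:
    """Points from start to stop with spacing d0 growing by `ratio`, capped.

    The last interval is snapped onto `stop` (merged with its neighbour if it
    would be shorter than 40% of the previous spacing)."""
    pts = [start]
    d = d0
    while pts[-1] + d < stop:
        pts.append(pts[-1] + d)
        d = min(d * ratio, cap)
    if len(pts) > 1 and stop - pts[-1] < 0.4 * (pts[-1] - pts[-2]):
        pts.pop()
    pts.append(stop)
    return np.asarray(pts)


def _uniform(start: float, stop: float, target: float, n_min: int = 1) -> np.ndarray:
    n = max(n_min, int(math.ceil((stop - start) / target - 1e-9)))
    return np.linspace(start, stop, n + 1)


def _radial_grid(model: EsophagusModel, h: float) -> tuple[np.ndarray, np.ndarray]:
    """Radial node positions plus region id per radial interval."""
    radii = model.layer_radii()
    pts = [np.array([radii[0]])]
    region_of = []
    last_d = h
    for li in range(len(model.layers)):
        t = radii[li + 1] - radii[li]
        n = max(5, int(math.ceil(t / (2 * h) - 1e-9)))
        seg = np.linspace(radii[li], radii[li + 1], n + 1)[1:]
        pts.append(seg)
        region_of += [li] * n
        last_d = t / n
    surround = _graded_march(radii[-2], radii[-1], d0=1.4 * last_d, ratio=1.4, cap=10.0)[1:]
    pts.append(surround)
    region_of += [len(model.layers)] * len(surround)
    return np.concatenate(pts), np.asarray(region_of)


def _theta_grid(a: float, contact: ContactPatch, h: float) -> np.ndarray:
    """Angular nodes (radians), symmetric about the contact angle 0; fine over
    the contact arc plus one patch-diameter, coarsening towards the far side.
    Returns the full periodic grid in [-pi, pi) (end point excluded)."""
    half_circ = math.pi * a
    c_half = contact.circumferential_half_extent
    s_fine = min(half_circ, c_half + 2 * c_half)
    if s_fine >= 0.95 * half_circ:
        n = max(16, int(math.ceil(2 * half_circ / h)))
        n += n % 2
        return np.linspace(-math.pi, math.pi, n + 1)[:-1]
    fine = _uniform(0.0, s_fine, h)
    coarse = _graded_march(s_fine, half_circ, d0=1.4 * h, ratio=1.4, cap=half_circ / 4)[1:]
    s_half = np.concatenate([fine, coarse])
    s = np.concatenate([-s_half[::-1][:-1], s_half[:-1]])  # drop duplicate 0 and +pi
    return s / a


def _z_grid(pair: ElectrodePair, model: EsophagusModel, h: float, refine: int) -> np.ndarray:
    e = pair.contacts[0].axial_half_extent
    d = pair.interelectrode_distance
    band_lo = max(0.0, d / 2 - e - 2 * e)
    band_hi = d / 2 + e + 2 * e
    hf = h / refine
    segs = []
    if band_lo > 0:
        segs.append(_uniform(0.0, band_lo, h)[:-1])
    segs.append(_uniform(band_lo, band_hi, hf)[:-1])
    coarse = _graded_march(band_hi, model.axial_length / 2, d0=1.4 * h, ratio=1.4, cap=8.0)
    segs.append(coarse)
    half = np.concatenate(segs)
    return np.concatenate([-half[::-1][:-1], half])


# ---------------------------------------------------------------------------
# public mesh constructors
# ---------------------------------------------------------------------------


def generate_mesh(
    model: EsophagusModel,
    pair: ElectrodePair,
    h: float = 0.17,
    refine: int = 2,
) -> Mesh:
    """Mesh the layered tube with the bipolar contact pair on its inner surface.

    ``h`` is the target edge length (mm) and must not exceed one fifth of the
    thinnest tissue layer, so each layer receives at least five element layers
    radially.  Axial spacing is ``h/refine`` over each contact and one
    patch-diameter beyond its edges; the grid coarsens geometrically towards
    the far-field truncation.  The inner surface is insulated except at the
    contacts; the outer radius and both axial ends are far-field.
    """
    # The coarseness gate is anchored to the resting anatomy; the radial grid
    # itself always places >= 5 element layers across every (possibly
    # distension-thinned) tissue layer regardless of h.
    gate_layers = model.resting_layers or model.layers
    t_min = min(l.thickness for l in gate_layers)
    if h > t_min / 5 + 1e-12:
        raise ValueError(
            f"h = {h} mm too coarse: at least five mesh points are required across each "
            f"uniform tissue domain (thinnest layer {t_min} mm needs h <= {t_min / 5:.4g} mm)"
        )
    for c in pair.contacts:
        if abs(c.center_axial_position) + c.axial_half_extent >= model.axial_length / 2:
            raise ValueError("contact extends beyond the modelled axial length")
    e = pair.contacts[0].axial_half_extent
    z_outer = pair.interelectrode_distance / 2 + 3 * e
    if model.axial_length < 2 * z_outer + model.far_radius:
        raise ValueError(
            "axial_length too short for this pair: need > 2*(d/2 + 3*contact extent) "
            "plus a far-field margin of one far_radius"
        )

    a = model.inner_radius
    g_r, region_of = _radial_grid(model, h)
    g_theta = _theta_grid(a, pair.contacts[0], h)
    g_z = _z_grid(pair, model, h, refine)
    block = _Block(g_r, g_theta, g_z, periodic2=True)

    def mapping(r, theta, z):
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    src, snk = pair.source, pair.sink
    far = model.far_radius

    def tag_fn(axis, side, centroids):
        tags = np.full(len(centroids), BOUNDARY_TAGS.index("insulated"), dtype=np.int16)
        if axis == 0 and side == 1:
            tags[:] = BOUNDARY_TAGS.index("far_field")
        elif axis == 2:
            tags[:] = BOUNDARY_TAGS.index("far_field")
        elif axis == 0 and side == 0:
            z = centroids[:, 2]
            theta = np.arctan2(centroids[:, 1], centroids[:, 0])
            tags[src.contains(z, theta, a)] = BOUNDARY_TAGS.index("electrode_source")
            tags[snk.contains(z, theta, a)] = BOUNDARY_TAGS.index("electrode_sink")
        return tags

    conductivity = {l.name: l.conductivity for l in model.layers}
    conductivity["surround"] = model.surround_conductivity
    return _build_mesh(block, mapping, region_of, tag_fn, model.region_names, conductivity, h)


def coaxial_cylinder_mesh(
    a: float,
    b: float,
    length: float,
    sigma: float,
    nr: int = 20,
    ntheta: int = 32,
    nz: int = 8,
) -> Mesh:
    """Homogeneous annular cylinder; full inner electrode (source), full outer
    electrode (sink), insulated ends.  Exact solution V ~ ln(r)."""
    if not 0 < a < b:
        raise ValueError("need 0 < a < b")
    g_r = np.linspace(a, b, nr + 1)
    g_theta = np.linspace(-math.pi, math.pi, ntheta + 1)[:-1]
    g_z = np.linspace(0, length, nz + 1)
    block = _Block(g_r, g_theta, g_z, periodic2=True)

    def mapping(r, theta, z):
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    def tag_fn(axis, side, centroids):
        tags = np.full(len(centroids), BOUNDARY_TAGS.index("insulated"), dtype=np.int16)
        if axis == 0:
            tags[:] = BOUNDARY_TAGS.index(
                "electrode_source" if side == 0 else "electrode_sink"
            )
        return tags

    return _build_mesh(
        block,
        mapping,
        np.zeros(nr, dtype=int),
        tag_fn,
        ("domain",),
        {"domain": sigma},
        h=(b - a) / nr,
    )


def spherical_shell_mesh(
    radii: list[float],
    conductivities: list[float],
    cap_angle: float = math.pi / 3,
    n_per_shell: int = 6,
    npolar: int = 12,
    nphi: int = 32,
) -> Mesh:
    """Concentric spherical shells truncated by insulated polar caps.

    The exact solution of the full-sphere concentric-electrode problem is
    purely radial, so it also solves this sector with its insulated lateral
    boundaries; the sector resistance is the full-sphere value scaled by
    4*pi over the sector solid angle.  Innermost sphere is the source,
    outermost the sink.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    if len(conductivities) != len(radii) - 1:
        raise ValueError("need one conductivity per shell")
    g_r = np.concatenate(
        [
            np.linspace(radii[i], radii[i + 1], n_per_shell + 1)[(1 if i else 0) :]
            for i in range(len(radii) - 1)
        ]
    )
    region_of = np.repeat(np.arange(len(radii) - 1), n_per_shell)
    g_polar = np.linspace(cap_angle, math.pi - cap_angle, npolar + 1)
    g_phi = np.linspace(-math.pi, math.pi, nphi + 1)[:-1]
    # axes: (polar, phi periodic, r) so the electrode surfaces are axis-2 faces
    block = _Block(g_polar, g_phi, g_r, periodic2=True)

    def mapping(polar, phi, r):
        return np.column_stack(
            [r * np.sin(polar) * np.cos(phi), r * np.sin(polar) * np.sin(phi), r * np.cos(polar)]
        )

    def tag_fn(axis, side, centroids):
        tags = np.full(len(centroids), BOUNDARY_TAGS.index("insulated"), dtype=np.int16)
        if axis == 2:
            tags[:] = BOUNDARY_TAGS.index(
                "electrode_source" if side == 0 else "electrode_sink"
            )
        return tags

    names = tuple(f"shell{i}" for i in range(len(radii) - 1))
    cond = {f"shell{i}": s for i, s in enumerate(conductivities)}
    # region is indexed by the first block axis (polar here): all polar rows
    # share the radial layering, so regions must come from the third axis.
    block_region = np.zeros(block.n1, dtype=int)
    mesh = _build_mesh(block, mapping, block_region, tag_fn, names, cond, h=(radii[-1] - radii[0]) / len(region_of))
    # reassign per-tet regions from radial position of tet centroids
    centroids = mesh.nodes[mesh.tets].mean(axis=1)
    r_c = np.linalg.norm(centroids, axis=1)
    mesh.region = np.searchsorted(radii[1:-1], r_c).astype(np.int16)
    return mesh


def sector_solid_angle(cap_angle: float) -> float:
    """Solid angle of the polar-cap-truncated spherical sector."""
    return 4 * math.pi * math.cos(cap_angle)


def box_mesh(
    lx: float, ly: float, lz: float, sigma: float, nx: int = 4, ny: int = 4, nz: int = 8
) -> Mesh:
    """Homogeneous slab with full plate electrodes on the two z faces.

    The exact solution is linear in z and lies in the first-order element
    space, so computed fields and resistance are exact to solver tolerance.
    """
    block = _Block(
        np.linspace(0, lx, nx + 1), np.linspace(0, ly, ny + 1), np.linspace(0, lz, nz + 1),
        periodic2=False,
    )

    def mapping(x, y, z):
        return np.column_stack([x, y, z])

    def tag_fn(axis, side, centroids):
        tags = np.full(len(centroids), BOUNDARY_TAGS.index("insulated"), dtype=np.int16)
        if axis == 2:
            tags[:] = BOUNDARY_TAGS.index(
                "electrode_source" if side == 0 else "electrode_sink"
            )
        return tags

    return _build_mesh(
        block, mapping, np.zeros(nx, dtype=int), tag_fn, ("domain",), {"domain": sigma},
        h=lz / nz,
    )
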