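"""Tagged computational domains: idealized intracranial geometry and fixtures.

The idealized domain is a desk-scale twin of a segmented intracranial
geometry: a rigid outer spherical shell (skull), a thin CSF gap (cranial
SAS), a thick poroelastic spherical shell (parenchyma), an inner CSF cavity
(ventricle analog), a channel through the shell at the north pole (aqueduct
analog) and a caudal outlet tube at the south pole whose end face splits
into a clamped spinal-cord disc and an open spinal-SAS annulus.

Conventions: coordinates in meters, z is cranio-caudal with the outlet at
low z; the stored interface orientation points from the CSF into the
parenchyma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from icpulse.fem.mesh import SimplexMesh

__all__ = [
    "CellTag",
    "FacetTag",
    "Probe",
    "DomainModel",
    "IdealizedSpec",
    "build_idealized",
    "build_two_box_2d",
    "build_two_box_3d",
    "build_unit_cube",
    "build_tube",
    "load_mesh",
    "write_mesh",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised for infeasible geometric specifications or invalid meshes."""


class CellTag:
    PARENCHYMA = 1
    CSF = 2

    names = {1: "PARENCHYMA", 2: "CSF"}
    ids = {"PARENCHYMA": 1, "CSF": 2}


class FacetTag:
    SKULL = 1
    SPINAL_CORD = 2
    SPINAL_SAS = 3
    INTERFACE = 4

    names = {1: "SKULL", 2: "SPINAL_CORD", 3: "SPINAL_SAS", 4: "INTERFACE"}
    ids = {"SKULL": 1, "SPINAL_CORD": 2, "SPINAL_SAS": 3, "INTERFACE": 4}


@dataclass(frozen=True)
class Probe:
    name: str
    point: tuple
    subdomain: str  # "CSF" or "PARENCHYMA"


@dataclass
class DomainModel:
    """A tagged mesh with subdomains, interface, boundaries and probes."""

    mesh: SimplexMesh
    probes: dict = field(default_factory=dict)
    named_surfaces: dict = field(default_factory=dict)  # name -> (facet_ids, orient_cells)
    cell_regions: dict = field(default_factory=dict)    # name -> cell id array
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------ subdomains
    @property
    def parenchyma_cells(self) -> np.ndarray:
        return np.nonzero(self.mesh.cell_tags == CellTag.PARENCHYMA)[0]

    @property
    def csf_cells(self) -> np.ndarray:
        return np.nonzero(self.mesh.cell_tags == CellTag.CSF)[0]

    @property
    def interface_facets(self) -> np.ndarray:
        return self.mesh.facets_with_tag(FacetTag.INTERFACE)

    def interface_orient_cells(self) -> np.ndarray:
        """Adjacent CSF cell per interface facet (normal points CSF->parenchyma)."""
        fc = self.mesh.facet_cells[self.interface_facets]
        t0 = self.mesh.cell_tags[fc[:, 0]]
        return np.where(t0 == CellTag.CSF, fc[:, 0], fc[:, 1])

    # --------------------------------------------------------------- measure
    def measure(self, region_name: str) -> float:
        """Volume (m^3) of a cell region or area (m^2) of a facet region."""
        mesh = self.mesh
        if region_name in CellTag.ids:
            cells = np.nonzero(mesh.cell_tags == CellTag.ids[region_name])[0]
            return float(mesh.cell_volumes()[cells].sum())
        if region_name in self.cell_regions:
            return float(mesh.cell_volumes()[self.cell_regions[region_name]].sum())
        if region_name in FacetTag.ids:
            fids = mesh.facets_with_tag(FacetTag.ids[region_name])
            return float(mesh.facet_areas(fids).sum()) if len(fids) else 0.0
        if region_name in self.named_surfaces:
            fids, _ = self.named_surfaces[region_name]
            return float(mesh.facet_areas(fids).sum()) if len(fids) else 0.0
        raise KeyError(f"unknown region {region_name!r}")

    # -------------------------------------------------------------- validate
    def validate(self) -> None:
        mesh = self.mesh
        tags = set(np.unique(mesh.cell_tags))
        if not tags <= {CellTag.PARENCHYMA, CellTag.CSF}:
            raise GeometryError(f"unknown cell tags {tags}")
        vols = mesh.cell_volumes()
        if np.any(vols <= 0):
            raise GeometryError("mesh contains degenerate cells")
        # exterior facets must all be tagged with a boundary tag
        ext = mesh.boundary_facets
        ext_tags = mesh.facet_tags[ext]
        if np.any(ext_tags == 0):
            raise GeometryError(
                f"{int((ext_tags == 0).sum())} exterior facet(s) are untagged"
            )
        bad = set(np.unique(ext_tags)) - {
            FacetTag.SKULL, FacetTag.SPINAL_CORD, FacetTag.SPINAL_SAS
        }
        if bad:
            raise GeometryError(f"exterior facets carry non-boundary tags {bad}")
        # interface facets are exactly the parenchyma/CSF adjacencies
        detected = set(
            mesh.interface_facets(CellTag.PARENCHYMA, CellTag.CSF).tolist()
        )
        tagged = set(mesh.facets_with_tag(FacetTag.INTERFACE).tolist())
        if detected != tagged:
            raise GeometryError(
                "INTERFACE tags inconsistent with subdomain adjacency "
                f"({len(detected)} detected vs {len(tagged)} tagged)"
            )
        # probes must lie strictly inside their subdomain
        for p in self.probes.values():
            cells = (
                self.parenchyma_cells if p.subdomain == "PARENCHYMA" else self.csf_cells
            )
            hit, _ = mesh.locate_points(np.asarray(p.point), candidate_cells=cells)
            if hit[0] < 0:
                raise GeometryError(f"probe {p.name} lies outside subdomain {p.subdomain}")


def tag_interface(mesh: SimplexMesh) -> None:
    mesh.tag_facets(
        mesh.interface_facets(CellTag.PARENCHYMA, CellTag.CSF), FacetTag.INTERFACE
    )


# ======================================================================
# structured generators
# ======================================================================
def _square_triangulation(nx: int, ny: int, x0=0.0, x1=1.0, y0=0.0, y1=1.0):
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)

    def vid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            tris.append((a, b, c))
            tris.append((a, c, d))
    return pts, np.asarray(tris, dtype=np.int64)


def build_two_box_2d(n: int, height: float = 1.0) -> DomainModel:
    """Two stacked unit boxes with a flat interface at y=0.

    Parenchyma occupies y<0, CSF y>0.  The outer solid boundary is tagged
    SPINAL_CORD and the outer fluid boundary SKULL (Dirichlet segments of
    the verification fixture); the y=0 facets are the interface.
    """
    pts, tris = _square_triangulation(n, 2 * n, 0.0, 1.0, -height, height)
    mid = pts[tris].mean(axis=1)
    tags = np.where(mid[:, 1] < 0, CellTag.PARENCHYMA, CellTag.CSF)
    mesh = SimplexMesh(pts, tris, tags)
    tag_interface(mesh)
    ext = mesh.boundary_facets
    cent = pts[mesh.facets[ext]].mean(axis=1)
    solid = cent[:, 1] < 0
    mesh.tag_facets(ext[solid], FacetTag.SPINAL_CORD)
    mesh.tag_facets(ext[~solid], FacetTag.SKULL)
    return DomainModel(mesh=mesh, meta={"fixture": "two_box_2d", "n": n})


def _extrude_layers(base_tris: np.ndarray, layer_points: np.ndarray):
    """Extrude a triangulated surface through a stack of layer positions.

    layer_points: (n_layers+1, ns, 3) vertex positions per layer.
    Returns points (n_layers+1 * ns, 3) and tets using the sorted-column
    splitting rule (conforming across neighboring prisms).
    """
    nl1, ns, _ = layer_points.shape
    pts = layer_points.reshape(-1, 3)
    tets = []
    for k in range(nl1 - 1):
        lo = k * ns
        hi = (k + 1) * ns
        for tri in base_tris:
            a, b, c = sorted(tri)
            tets.append((lo + a, lo + b, lo + c, hi + a))
            tets.append((lo + b, lo + c, hi + a, hi + b))
            tets.append((lo + c, hi + a, hi + b, hi + c))
    return pts, np.asarray(tets, dtype=np.int64)


def _extrude_layers_indexed(base_tris, n_layers):
    """Tet connectivity (in layer-local vertex ids) for an extrusion.

    Returns a list over layers of (ntri*3, 4) arrays with entries
    (layer k vertex -> k*ns + s)."""
    tets_per_layer = []
    for tri in base_tris:
        a, b, c = sorted(tri)
        tets_per_layer.append([(a, 0), (b, 0), (c, 0), (a, 1)])
        tets_per_layer.append([(b, 0), (c, 0), (a, 1), (b, 1)])
        tets_per_layer.append([(c, 0), (a, 1), (b, 1), (c, 1)])
    return np.asarray(tets_per_layer)


def build_two_box_3d(n: int, height: float = 1.0) -> DomainModel:
    """3D analog of the two-box fixture: [0,1]^2 x [-h, h], interface z=0."""
    pts2, tris = _square_triangulation(n, n)
    zs = np.linspace(-height, height, 2 * n + 1)
    layers = np.zeros((len(zs), len(pts2), 3))
    layers[:, :, :2] = pts2[None, :, :]
    layers[:, :, 2] = zs[:, None]
    pts, tets = _extrude_layers(tris, layers)
    mid = pts[tets].mean(axis=1)
    tags = np.where(mid[:, 2] < 0, CellTag.PARENCHYMA, CellTag.CSF)
    mesh = SimplexMesh(pts, tets, tags)
    tag_interface(mesh)
    ext = mesh.boundary_facets
    cent = pts[mesh.facets[ext]].mean(axis=1)
    solid = cent[:, 2] < 0
    mesh.tag_facets(ext[solid], FacetTag.SPINAL_CORD)
    mesh.tag_facets(ext[~solid], FacetTag.SKULL)
    return DomainModel(mesh=mesh, meta={"fixture": "two_box_3d", "n": n})


def build_unit_cube(n: int = 2, cell_tag: int = CellTag.PARENCHYMA,
                    facet_tag: int = FacetTag.SKULL) -> DomainModel:
    """Unit cube fixture with uniform tags (mesh-I/O round-trip tests)."""
    pts2, tris = _square_triangulation(n, n)
    zs = np.linspace(0.0, 1.0, n + 1)
    layers = np.zeros((len(zs), len(pts2), 3))
    layers[:, :, :2] = pts2[None, :, :]
    layers[:, :, 2] = zs[:, None]
    pts, tets = _extrude_layers(tris, layers)
    mesh = SimplexMesh(pts, tets, np.full(len(tets), cell_tag))
    mesh.tag_facets(mesh.boundary_facets, facet_tag)
    return DomainModel(mesh=mesh, meta={"fixture": "unit_cube", "n": n})


def _disc_triangulation(n: int, radius: float):
    """Triangulated disc via the max-norm square-to-disc map."""
    pts, tris = _square_triangulation(n, n, -1.0, 1.0, -1.0, 1.0)
    r = np.linalg.norm(pts, axis=1)
    m = np.maximum(np.abs(pts[:, 0]), np.abs(pts[:, 1]))
    scale = np.where(r > 0, m / np.maximum(r, 1e-300), 0.0)
    return pts * scale[:, None] * radius, tris


def build_tube(radius: float, length: float, n_cross: int = 6,
               n_axial: int = 8) -> DomainModel:
    """Straight CSF-filled tube along z (Poiseuille fixture).

    Side walls are SKULL (no slip); the end faces are SPINAL_SAS (z=0,
    outlet) and SPINAL_CORD (z=length, inlet) so pressure-drop traction
    conditions can be attached to the end tags.
    """
    pts2, tris = _disc_triangulation(n_cross, radius)
    zs = np.linspace(0.0, length, n_axial + 1)
    layers = np.zeros((len(zs), len(pts2), 3))
    layers[:, :, :2] = pts2[None, :, :]
    layers[:, :, 2] = zs[:, None]
    pts, tets = _extrude_layers(tris, layers)
    mesh = SimplexMesh(pts, tets, np.full(len(tets), CellTag.CSF))
    ext = mesh.boundary_facets
    cent = pts[mesh.facets[ext]].mean(axis=1)
    bot = np.abs(cent[:, 2]) < 1e-12
    top = np.abs(cent[:, 2] - length) < 1e-12
    mesh.tag_facets(ext[bot], FacetTag.SPINAL_SAS)
    mesh.tag_facets(ext[top], FacetTag.SPINAL_CORD)
    mesh.tag_facets(ext[~(bot | top)], FacetTag.SKULL)
    return DomainModel(mesh=mesh, meta={"fixture": "tube", "radius": radius,
                                        "length": length})


# ======================================================================
# icosphere
# ======================================================================
def _icosahedron():
    """Icosahedron with vertices at the +-z poles."""
    phi = np.linspace(0, 2 * np.pi, 6)[:-1]
    zc = 1.0 / np.sqrt(5.0)
    rc = 2.0 / np.sqrt(5.0)
    top = np.stack([rc * np.cos(phi), rc * np.sin(phi), np.full(5, zc)], axis=1)
    bot = np.stack(
        [rc * np.cos(phi + np.pi / 5), rc * np.sin(phi + np.pi / 5), np.full(5, -zc)],
        axis=1,
    )
    verts = np.vstack([[[0, 0, 1.0]], top, bot, [[0, 0, -1.0]]])
    faces = []
    for i in range(5):
        j = (i + 1) % 5
        faces.append((0, 1 + i, 1 + j))                 # north cap
        faces.append((1 + i, 6 + i, 1 + j))
        faces.append((1 + j, 6 + i, 6 + j))
        faces.append((11, 6 + j, 6 + i))                # south cap
    return verts, np.asarray(faces, dtype=np.int64)


def _icosphere(level: int):
    verts, faces = _icosahedron()
    for _ in range(level):
        edge_mid: dict = {}
        new_faces = []
        verts = list(map(tuple, verts))

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                p = (np.asarray(verts[a]) + np.asarray(verts[b])) / 2.0
                p /= np.linalg.norm(p)
                edge_mid[key] = len(verts)
                verts.append(tuple(p))
            return edge_mid[key]

        for (a, b, c) in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = np.asarray(new_faces, dtype=np.int64)
        verts = np.asarray(verts)
    return np.asarray(verts), faces


# ======================================================================
# idealized intracranial domain
# ======================================================================
@dataclass
class IdealizedSpec:
    """Geometric parameters of the idealized intracranial domain.

    Volume targets are matched by calibrating the three radii against the
    discrete (polyhedral) mesh volumes.  The channel and outlet diameters
    are requests; at coarse resolution the effective diameters are larger
    (clamped by mesh quality) and are recorded in the domain metadata.
    """

    parenchyma_volume_ml: float = 1369.54
    sas_volume_ml: float = 292.08
    ventricle_volume_ml: float = 30.3
    channel_diameter: float = 2.88e-3   # aqueduct analog [m]
    canal_diameter: float = 12e-3       # spinal canal [m]
    cord_diameter: float = 7e-3         # spinal cord [m]
    outlet_length: float = 0.02         # [m]
    subdivisions: int = 2               # icosphere refinement level
    n_vent_layers: int = 2
    n_shell_layers: int = 3
    n_gap_layers: int = 1
    n_outlet_layers: int = 2
    min_pinch: float = 0.30             # quality floor for pole pinching
    calibration_iters: int = 3
    volume_tol: float = 0.02

    def __post_init__(self):
        if min(self.parenchyma_volume_ml, self.sas_volume_ml,
               self.ventricle_volume_ml) <= 0:
            raise GeometryError("volume targets must be positive")
        if self.channel_diameter <= 0 or self.canal_diameter <= 0:
            raise GeometryError("diameters must be positive")
        if self.cord_diameter >= self.canal_diameter:
            raise GeometryError("spinal cord must be narrower than the canal")
        if self.n_vent_layers < 1 or self.n_shell_layers < 1 or self.n_gap_layers < 1:
            raise GeometryError("need at least one layer per region")


def _initial_radii(spec: IdealizedSpec):
    v1 = spec.ventricle_volume_ml * 1e-6
    vp = spec.parenchyma_volume_ml * 1e-6
    vs = spec.sas_volume_ml * 1e-6
    R1 = (3 * v1 / (4 * np.pi)) ** (1 / 3)
    R2 = (3 * (v1 + vp) / (4 * np.pi)) ** (1 / 3)
    R3 = (3 * (v1 + vp + vs) / (4 * np.pi)) ** (1 / 3)
    # infeasibility guard: the channel must fit within the shell
    if spec.channel_diameter / 2 >= R1:
        raise GeometryError(
            f"channel radius {spec.channel_diameter/2:.4g} m must be smaller "
            f"than the ventricular cavity radius {R1:.4g} m"
        )
    return R1, R2, R3


def _pinch_surface(verts, faces, pole_idx, target_angle, min_pinch):
    """Pull the vertices adjacent to a pole toward it on the unit sphere."""
    pole = verts[pole_idx]
    ring = np.unique(faces[np.any(faces == pole_idx, axis=1)])
    ring = ring[ring != pole_idx]
    out = verts.copy()
    for v in ring:
        p = verts[v]
        ang = np.arccos(np.clip(p @ pole, -1, 1))
        f = np.clip(target_angle / ang, min_pinch, 1.0)
        # slerp toward the pole
        newp = (np.sin(f * ang) * p + np.sin((1 - f) * ang) * pole) / np.sin(ang)
        out[v] = newp / np.linalg.norm(newp)
    return out, ring


def _build_idealized_once(spec: IdealizedSpec, R1, R2, R3):
    verts, faces = _icosphere(spec.subdivisions)
    north = int(np.argmax(verts[:, 2]))
    south = int(np.argmin(verts[:, 2]))
    # pinch pole neighborhoods toward requested channel/canal radii
    aq_angle = (spec.channel_diameter / 2) / ((R1 + R2) / 2)
    verts, _ = _pinch_surface(verts, faces, north, aq_angle, spec.min_pinch)
    canal_angle = (spec.canal_diameter / 2) / R3
    verts, s_ring = _pinch_surface(verts, faces, south, canal_angle, spec.min_pinch)

    ns = len(verts)
    channel_faces = np.nonzero(np.any(faces == north, axis=1))[0]
    ring1_faces = np.nonzero(np.any(faces == south, axis=1))[0]
    ring1_verts = np.unique(faces[ring1_faces])
    ring2_faces = np.nonzero(
        np.any(np.isin(faces, ring1_verts), axis=1)
        & ~np.any(faces == south, axis=1)
    )[0]
    outlet_faces = np.concatenate([ring1_faces, ring2_faces])
    outlet_verts = np.unique(faces[outlet_faces])

    # ---------------- radial layering of the ball
    radii = np.concatenate([
        np.linspace(0.0, R1, spec.n_vent_layers + 1)[1:],
        np.linspace(R1, R2, spec.n_shell_layers + 1)[1:],
        np.linspace(R2, R3, spec.n_gap_layers + 1)[1:],
    ])
    n_radii = len(radii)
    pts = [np.zeros((1, 3))]
    for r in radii:
        pts.append(verts * r)
    points = np.vstack(pts)

    def lv(layer, s):                          # layer vertex id (layer 0.. on sphere)
        return 1 + layer * ns + s

    tets = []
    tags = []
    region = []
    layer_of_cell = []
    face_of_cell = []
    # innermost cap: center -> first sphere layer
    for fi, tri in enumerate(faces):
        a, b, c = sorted(tri)
        tets.append((0, lv(0, a), lv(0, b), lv(0, c)))
        tags.append(CellTag.CSF)
        region.append("VENTRICLE")
        layer_of_cell.append(0)
        face_of_cell.append(fi)
    shell_lo = spec.n_vent_layers - 1          # layer index where shell starts
    shell_hi = shell_lo + spec.n_shell_layers
    channel_set = set(channel_faces.tolist())
    ring1_set = set(ring1_faces.tolist())
    ring2_set = set(ring2_faces.tolist())
    for k in range(n_radii - 1):
        for fi, tri in enumerate(faces):
            a, b, c = sorted(tri)
            prism_tets = [
                (lv(k, a), lv(k, b), lv(k, c), lv(k + 1, a)),
                (lv(k, b), lv(k, c), lv(k + 1, a), lv(k + 1, b)),
                (lv(k, c), lv(k + 1, a), lv(k + 1, b), lv(k + 1, c)),
            ]
            if k < shell_lo:
                tag, reg = CellTag.CSF, "VENTRICLE"
            elif k < shell_hi:
                if fi in channel_set:
                    tag, reg = CellTag.CSF, "CHANNEL"
                else:
                    tag, reg = CellTag.PARENCHYMA, "BRAIN"
            else:
                if fi in ring1_set:
                    tag, reg = CellTag.PARENCHYMA, "CORD"
                else:
                    tag, reg = CellTag.CSF, "SAS"
            for t in prism_tets:
                tets.append(t)
                tags.append(tag)
                region.append(reg)
                layer_of_cell.append(k + 1)
                face_of_cell.append(fi)

    # ---------------- outlet tube below the south pole
    z_bottom = -(R3 + spec.outlet_length)
    col_index = {int(s): i for i, s in enumerate(outlet_verts)}
    n_out = spec.n_outlet_layers
    start = points[[lv(n_radii - 1, s) for s in outlet_verts]]
    extra = []
    for k in range(1, n_out + 1):
        frac = k / n_out
        layer = start.copy()
        layer[:, 2] = start[:, 2] * (1 - frac) + z_bottom * frac
        extra.append(layer)
    base_offset = len(points)
    points = np.vstack([points] + extra)

    def ov(layer, s):                          # outlet layer vertex (layer >= 1)
        if layer == 0:
            return lv(n_radii - 1, s)
        return base_offset + (layer - 1) * len(outlet_verts) + col_index[int(s)]

    for k in range(n_out):
        for fi in outlet_faces:
            tri = faces[fi]
            a, b, c = sorted(tri)
            prism_tets = [
                (ov(k, a), ov(k, b), ov(k, c), ov(k + 1, a)),
                (ov(k, b), ov(k, c), ov(k + 1, a), ov(k + 1, b)),
                (ov(k, c), ov(k + 1, a), ov(k + 1, b), ov(k + 1, c)),
            ]
            if fi in ring1_set:
                tag, reg = CellTag.PARENCHYMA, "CORD"
            else:
                tag, reg = CellTag.CSF, "OUTLET"
            for t in prism_tets:
                tets.append(t)
                tags.append(tag)
                region.append(reg)
                layer_of_cell.append(n_radii + k)
                face_of_cell.append(fi)

    tets = np.asarray(tets, dtype=np.int64)
    tags = np.asarray(tags, dtype=np.int64)
    region = np.asarray(region)
    mesh = SimplexMesh(points, tets, tags)
    tag_interface(mesh)

    # boundary tags
    ext = mesh.boundary_facets
    cent = points[mesh.facets[ext]].mean(axis=1)
    tol = 1e-9
    bottom = np.abs(cent[:, 2] - z_bottom) < max(1e-9, 1e-6 * abs(z_bottom))
    bott_ids = ext[bottom]
    # classify bottom facets by the adjacent cell's tag
    adj = mesh.facet_cells[bott_ids, 0]
    is_cord = mesh.cell_tags[adj] == CellTag.PARENCHYMA
    mesh.tag_facets(bott_ids[is_cord], FacetTag.SPINAL_CORD)
    mesh.tag_facets(bott_ids[~is_cord], FacetTag.SPINAL_SAS)
    mesh.tag_facets(ext[~bottom], FacetTag.SKULL)

    info = {
        "faces": faces,
        "region": region,
        "layer_of_cell": np.asarray(layer_of_cell),
        "face_of_cell": np.asarray(face_of_cell),
        "channel_faces": channel_faces,
        "n_radii": n_radii,
        "shell_lo": shell_lo,
        "shell_hi": shell_hi,
        "radii": radii,
        "z_bottom": z_bottom,
    }
    return mesh, info


def build_idealized(spec: IdealizedSpec | None = None) -> DomainModel:
    """Build the idealized tagged intracranial domain.

    Radii are calibrated so that the discrete parenchyma, cranial-SAS and
    ventricle volumes match the requested targets.
    """
    if spec is None:
        spec = IdealizedSpec()
    R1, R2, R3 = _initial_radii(spec)
    mesh = info = None
    for _ in range(spec.calibration_iters):
        mesh, info = _build_idealized_once(spec, R1, R2, R3)
        vols = mesh.cell_volumes()
        reg = info["region"]
        v_vent = vols[reg == "VENTRICLE"].sum()
        v_par = vols[mesh.cell_tags == CellTag.PARENCHYMA].sum()
        v_sas = vols[reg == "SAS"].sum()
        t_vent = spec.ventricle_volume_ml * 1e-6
        t_par = spec.parenchyma_volume_ml * 1e-6
        t_sas = spec.sas_volume_ml * 1e-6
        if (abs(v_vent - t_vent) < 0.5 * spec.volume_tol * t_vent
                and abs(v_par - t_par) < 0.5 * spec.volume_tol * t_par
                and abs(v_sas - t_sas) < 0.5 * spec.volume_tol * t_sas):
            break
        R1n = R1 * (t_vent / v_vent) ** (1 / 3)
        R2n = (R1n ** 3 + (R2 ** 3 - R1 ** 3) * t_par / v_par) ** (1 / 3)
        R3n = (R2n ** 3 + (R3 ** 3 - R2 ** 3) * t_sas / v_sas) ** (1 / 3)
        R1, R2, R3 = R1n, R2n, R3n

    reg = info["region"]
    vols = mesh.cell_volumes()
    cell_regions = {name: np.nonzero(reg == name)[0]
                    for name in np.unique(reg)}

    # ---------------- probes (cell centroids: strictly interior)
    cents = mesh.cell_centroids()

    def nearest_centroid(cells, target):
        d = np.linalg.norm(cents[cells] - np.asarray(target), axis=1)
        return cents[cells[np.argmin(d)]]

    vent_cells = cell_regions["VENTRICLE"]
    chan_cells = cell_regions["CHANNEL"]
    sas_cells = cell_regions["SAS"]
    lv_pt = nearest_centroid(vent_cells, (0.0, 0.0, 0.0))
    mid_sas = 0.5 * (R2 + R3)
    sas_pt = nearest_centroid(
        sas_cells, (mid_sas / np.sqrt(2), 0.0, mid_sas / np.sqrt(2))
    )
    v4_pt = nearest_centroid(chan_cells, (0.0, 0.0, 0.5 * (R1 + R2)))
    probes = {
        "LV": Probe("LV", tuple(lv_pt), "CSF"),
        "SAS": Probe("SAS", tuple(sas_pt), "CSF"),
        "V4": Probe("V4", tuple(v4_pt), "CSF"),
    }

    # ---------------- named internal surfaces
    # aqueduct cross-section: facets between channel cells of the two middle
    # shell layers, oriented ventricle -> SAS (outward radial)
    layer = info["layer_of_cell"]
    mid_layer = (info["shell_lo"] + info["shell_hi"] + 1) // 2
    inner = chan_cells[layer[chan_cells] == mid_layer]
    outer = chan_cells[layer[chan_cells] == mid_layer + 1]
    fc = mesh.facet_cells
    in_inner = np.isin(fc, inner)
    in_outer = np.isin(fc, outer)
    aq_facets = np.nonzero(in_inner.any(axis=1) & in_outer.any(axis=1))[0]
    aq_orient = np.where(in_inner[aq_facets, 0], fc[aq_facets, 0], fc[aq_facets, 1])
    sp_facets = mesh.facets_with_tag(FacetTag.SPINAL_SAS)
    named_surfaces = {
        "AQUEDUCT": (aq_facets, aq_orient),
        "SPINAL_OUTLET": (sp_facets, fc[sp_facets, 0]),
    }

    # effective (resolution-limited) channel / outlet dimensions
    aq_area = mesh.facet_areas(aq_facets).sum()
    eff_channel_d = 2 * np.sqrt(aq_area / np.pi)
    sas_area = mesh.facet_areas(sp_facets).sum()
    cord_facets = mesh.facets_with_tag(FacetTag.SPINAL_CORD)
    cord_area = mesh.facet_areas(cord_facets).sum()
    eff_cord_d = 2 * np.sqrt(cord_area / np.pi)
    eff_canal_d = 2 * np.sqrt((cord_area + sas_area) / np.pi)

    meta = {
        "spec": asdict(spec),
        "radii": {"ventricle": R1, "brain": R2, "skull": R3},
        "effective_channel_diameter": float(eff_channel_d),
        "effective_cord_diameter": float(eff_cord_d),
        "effective_canal_diameter": float(eff_canal_d),
        "volumes_ml": {
            "parenchyma": float(vols[mesh.cell_tags == CellTag.PARENCHYMA].sum() * 1e6),
            "csf_total": float(vols[mesh.cell_tags == CellTag.CSF].sum() * 1e6),
            "ventricle": float(vols[cell_regions["VENTRICLE"]].sum() * 1e6),
            "sas": float(vols[cell_regions["SAS"]].sum() * 1e6),
        },
    }
    dom = DomainModel(mesh=mesh, probes=probes, named_surfaces=named_surfaces,
                      cell_regions=cell_regions, meta=meta)
    # final volume check against targets
    v_par = dom.meta["volumes_ml"]["parenchyma"]
    if abs(v_par - spec.parenchyma_volume_ml) > spec.volume_tol * spec.parenchyma_volume_ml:
        raise GeometryError(
            f"calibration failed: parenchyma volume {v_par:.1f} ml vs target "
            f"{spec.parenchyma_volume_ml} ml"
        )
    return dom


# ======================================================================
# mesh exchange (Gmsh MSH 2.2 ASCII + JSON sidecar)
# ======================================================================
_MSH_TET = 4
_MSH_TRI = 2
_MSH_LINE = 1


def write_mesh(dom: DomainModel, path) -> None:
    """Write the domain as Gmsh MSH 2.2 ASCII plus a JSON sidecar.

    The sidecar (same path with suffix .json) records tag-name maps, probe
    points, named surfaces and metadata.
    """
    path = Path(path)
    mesh = dom.mesh
    dim = mesh.dim
    facet_type = _MSH_TRI if dim == 3 else _MSH_LINE
    cell_type = _MSH_TET if dim == 3 else _MSH_TRI
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(mesh.num_points)]
    for i, p in enumerate(mesh.points):
        coords = list(p) + [0.0] * (3 - dim)
        lines.append(f"{i + 1} {coords[0]:.17g} {coords[1]:.17g} {coords[2]:.17g}")
    lines.append("$EndNodes")
    tagged = np.nonzero(mesh.facet_tags != 0)[0]
    lines += ["$Elements", str(len(tagged) + mesh.num_cells)]
    eid = 1
    for f in tagged:
        verts = " ".join(str(v + 1) for v in mesh.facets[f])
        t = mesh.facet_tags[f]
        lines.append(f"{eid} {facet_type} 2 {t} {t} {verts}")
        eid += 1
    for c in range(mesh.num_cells):
        verts = " ".join(str(v + 1) for v in mesh.cells[c])
        t = mesh.cell_tags[c] + 100           # offset cell physical ids
        lines.append(f"{eid} {cell_type} 2 {t} {t} {verts}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")

    sidecar = {
        "cell_tags": {str(v + 100): k for k, v in CellTag.ids.items()},
        "facet_tags": {str(v): k for k, v in FacetTag.ids.items()},
        "probes": {k: {"point": list(map(float, p.point)), "subdomain": p.subdomain}
                   for k, p in dom.probes.items()},
        "named_surfaces": {
            name: {"facet_vertices": mesh.facets[fids].tolist(),
                   "orient_cells_first_vertex": mesh.cells[oc, 0].tolist()}
            for name, (fids, oc) in dom.named_surfaces.items()
        },
        "cell_regions": {k: v.tolist() for k, v in dom.cell_regions.items()},
        "meta": _jsonable(dom.meta),
        "dim": dim,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_mesh(path) -> DomainModel:
    """Read a domain written by :func:`write_mesh` (MSH 2.2 + sidecar)."""
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise GeometryError(f"missing sidecar naming map {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    dim = sidecar.get("dim", 3)
    text = path.read_text().splitlines()
    it = iter(text)
    nodes = []
    facet_elems = []
    cell_elems = []
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(x) for x in parts[1:4]])
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype = int(parts[1])
                ntags = int(parts[2])
                phys = int(parts[3])
                verts = [int(v) - 1 for v in parts[3 + ntags:]]
                if etype in (_MSH_TRI, _MSH_LINE) and (
                    (dim == 3 and etype == _MSH_TRI) or (dim == 2 and etype == _MSH_LINE)
                ):
                    facet_elems.append((phys, verts))
                elif (dim == 3 and etype == _MSH_TET) or (dim == 2 and etype == _MSH_TRI):
                    cell_elems.append((phys, verts))
    points = np.asarray(nodes)[:, :dim]
    cells = np.asarray([v for _, v in cell_elems], dtype=np.int64)
    cell_phys = np.asarray([p for p, _ in cell_elems], dtype=np.int64)
    ct_map = {int(k): CellTag.ids[v] for k, v in sidecar["cell_tags"].items()}
    for p in np.unique(cell_phys):
        if int(p) not in ct_map:
            raise GeometryError(f"cell physical id {p} has no name in the sidecar")
    cell_tags = np.asarray([ct_map[int(p)] for p in cell_phys])
    mesh = SimplexMesh(points, cells, cell_tags)
    ft_map = {int(k): FacetTag.ids[v] for k, v in sidecar["facet_tags"].items()}
    for phys, verts in facet_elems:
        if phys not in ft_map:
            raise GeometryError(f"facet physical id {phys} has no name in the sidecar")
        fid = mesh.find_facets([verts])
        mesh.tag_facets(fid, ft_map[phys])
    probes = {k: Probe(k, tuple(v["point"]), v["subdomain"])
              for k, v in sidecar.get("probes", {}).items()}
    named_surfaces = {}
    for name, d in sidecar.get("named_surfaces", {}).items():
        fids = mesh.find_facets(d["facet_vertices"])
        first_verts = d["orient_cells_first_vertex"]
        # recover orientation cells: adjacent cell whose first vertex matches
        fc = mesh.facet_cells[fids]
        oc = []
        for (c0, c1), fv in zip(fc, first_verts):
            if mesh.cells[c0, 0] == fv or c1 < 0:
                oc.append(c0)
            else:
                oc.append(c1)
        named_surfaces[name] = (fids, np.asarray(oc))
    cell_regions = {k: np.asarray(v, dtype=np.int64)
                    for k, v in sidecar.get("cell_regions", {}).items()}
    return DomainModel(mesh=mesh, probes=probes, named_surfaces=named_surfaces,
                       cell_regions=cell_regions, meta=sidecar.get("meta", {}))
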