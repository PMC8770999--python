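"""Synthetic mandible-like geometry with fracture cut and fixation hardware.

The mandible is idealized as a rectangular cross-section swept along a
U-shaped centerline: two straight corpus legs joined anteriorly by a
semicircular dental arch, with vertical rami rising at the posterior ends.
The solid is meshed as a structured hex lattice (Freudenthal-split into six
tetrahedra per hex, which keeps all region interfaces conforming), carries a
cortical shell / trabecular core / tooth-block material partition, and is
mirror-symmetric about the midsagittal plane before any fracture is cut.

Coordinate frame (used throughout the package):

* ``X`` mediolateral, positive toward the anatomical right (the left side of
  the jaw sits at ``x < 0``),
* ``Y`` anteroposterior, positive anterior,
* ``Z`` superoinferior, positive superior.

An angle fracture is realized by duplicating the nodes on a planar cut at
the corpus-ramus junction and rigidly offsetting the two faces by the gap
width, which yields an exact node-pair registry for interfragmentary
displacement analysis.  Miniplate hardware is meshed as thin tetrahedral
strips on the lateral surface; screws carry no geometry and are represented
as node-set pairings that the solver ties together.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

MUSCLE_NAMES = (
    "anterior_temporalis",
    "posterior_temporalis",
    "deep_masseter",
    "superficial_masseter",
    "medial_pterygoid",
)

_DEFAULT_TEETH = (0.21, 0.25, 0.29, 0.33, 0.37, 0.63, 0.67, 0.71, 0.75, 0.79)


class GeometryError(ValueError):
    """Raised when a geometry specification cannot be realized."""


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MandibleSpec:
    """Parameters of the idealized swept-arch mandible (all lengths in mm)."""

    arch_radius: float = 22.0
    corpus_length: float = 60.0
    ramus_height: float = 45.0
    corpus_section_width: float = 8.0
    corpus_section_height: float = 14.0
    cortical_thickness: float = 2.0
    n_arch_segments: int = 14
    elements_per_section: int = 6
    tooth_positions: tuple = _DEFAULT_TEETH
    seed: int = 0

    def validate(self) -> None:
        for name in ("arch_radius", "corpus_length", "ramus_height",
                     "corpus_section_width", "corpus_section_height",
                     "cortical_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        sect = min(self.corpus_section_width, self.corpus_section_height)
        if self.cortical_thickness >= sect / 2:
            raise GeometryError(
                "cortical_thickness must be below half the smallest section "
                f"dimension ({sect / 2:g} mm)")
        if self.n_arch_segments < 4:
            raise GeometryError("n_arch_segments must be at least 4")
        if self.elements_per_section < 3:
            raise GeometryError("elements_per_section must be at least 3")
        if self.ramus_height <= self.corpus_section_height:
            raise GeometryError("ramus_height must exceed corpus_section_height")
        pos = np.asarray(self.tooth_positions, float)
        if pos.size and (pos.min() <= 0 or pos.max() >= 1):
            raise GeometryError("tooth_positions must lie strictly in (0, 1)")


@dataclass(frozen=True)
class FractureSpec:
    """A planar cut of the stated side's angle region.

    ``plane_normal`` points toward the anterior fragment; the duplicated
    faces are separated by ``gap_width`` along it.
    """

    side: str = "left"
    plane_point: tuple = (0.0, 0.0, 0.0)
    plane_normal: tuple = (0.0, 1.0, 0.0)
    gap_width: float = 0.2

    def validate(self) -> None:
        if self.side not in ("left", "right"):
            raise GeometryError("side must be 'left' or 'right'")
        if self.gap_width <= 0:
            raise GeometryError("gap_width must be positive")
        n = np.asarray(self.plane_normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise GeometryError("plane_normal must be a unit vector")


@dataclass(frozen=True)
class FixationSpec:
    """Miniplate hardware: locking plates whose screws are node-set ties."""

    technique: str = "champy"  # none | champy | biplanar
    plate_length: float = 26.1
    plate_width: float = 2.5
    plate_thickness: float = 1.0
    screw_diameter: float = 4.2
    screws_per_plate: int = 4

    def validate(self) -> None:
        if self.technique not in ("none", "champy", "biplanar"):
            raise GeometryError("technique must be none, champy or biplanar")
        if min(self.plate_length, self.plate_width, self.plate_thickness,
               self.screw_diameter) <= 0:
            raise GeometryError("plate/screw dimensions must be positive")
        if self.screws_per_plate < 2 or self.screws_per_plate % 2:
            raise GeometryError("screws_per_plate must be an even count >= 2")


@dataclass
class FracturePairs:
    """Registry of matched node pairs across the fracture gap."""

    anterior: np.ndarray   # (P,) node ids on the anterior face
    posterior: np.ndarray  # (P,) node ids on the posterior face
    distance: np.ndarray   # (P,) undeformed pair distance, mm
    normal: np.ndarray     # (P, 3) unit pair normals (== plane normal)

    def __len__(self) -> int:
        return len(self.anterior)


@dataclass
class Mesh:
    """Tetrahedral mesh with named node/element sets.

    ``element_sets`` partition the tets into material regions; ``node_sets``
    carry boundary-condition and muscle-insertion surfaces.  ``tie_pairs``
    lists (slave, master) node pairs constrained to equal displacement
    (screw sites).  ``meta`` holds sweep-path information used for sectional
    moment profiles and hardware placement.
    """

    nodes: np.ndarray
    tets: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_sets: dict = field(default_factory=dict)
    fracture_pairs: FracturePairs | None = None
    tie_pairs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def copy(self) -> "Mesh":
        return Mesh(
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_sets={k: v.copy() for k, v in self.element_sets.items()},
            fracture_pairs=None if self.fracture_pairs is None else
            FracturePairs(self.fracture_pairs.anterior.copy(),
                          self.fracture_pairs.posterior.copy(),
                          self.fracture_pairs.distance.copy(),
                          self.fracture_pairs.normal.copy()),
            tie_pairs=None if self.tie_pairs is None else self.tie_pairs.copy(),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Mesh utilities
# ---------------------------------------------------------------------------

def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of the tetrahedra (positive for right-handed ordering)."""
    p = nodes[tets]
    return np.einsum(
        "ij,ij->i",
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
        p[:, 3] - p[:, 0]) / 6.0


def mesh_volume(mesh: Mesh) -> float:
    return float(tet_volumes(mesh.nodes, mesh.tets).sum())


# Freudenthal subdivision of a hex (corner order: bottom 0-3 CCW, top 4-7).
# All six tets share the 0-6 diagonal; translated copies are face-conforming.
_HEX_TETS = ((0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
             (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6))


def box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int,
             origin=(0.0, 0.0, 0.0), region: str = "solid") -> Mesh:
    """Structured tetrahedral box mesh (used for plates and verification)."""
    xs = np.linspace(0.0, lx, nx + 1) + origin[0]
    ys = np.linspace(0.0, ly, ny + 1) + origin[1]
    zs = np.linspace(0.0, lz, nz + 1) + origin[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = (nid(i, j, k), nid(i + 1, j, k),
                     nid(i + 1, j + 1, k), nid(i, j + 1, k),
                     nid(i, j, k + 1), nid(i + 1, j, k + 1),
                     nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1))
                for t in _HEX_TETS:
                    tets.append([c[t[0]], c[t[1]], c[t[2]], c[t[3]]])
    tets = np.asarray(tets, dtype=np.int64)
    mesh = Mesh(nodes=nodes, tets=tets,
                element_sets={region: np.arange(len(tets))})
    return mesh


# ---------------------------------------------------------------------------
# Sweep-path construction
# ---------------------------------------------------------------------------

def _stations(spec: MandibleSpec):
    """Centerline stations of the U-arch, exactly mirror-symmetric in x.

    Returns (points, tangents, medials, arc) where ``arc`` is the arc-length
    coordinate of each station, and segment/station counts.
    """
    R, L = spec.arch_radius, spec.corpus_length
    n_a = spec.n_arch_segments + (spec.n_arch_segments % 2)  # even
    seg_arch = np.pi * R / n_a
    n_c = max(4, int(round(L / seg_arch)))
    n_s = 2 * n_c + n_a          # total sweep segments
    half = n_c + n_a // 2

    pts = np.zeros((n_s + 1, 3))
    tan = np.zeros((n_s + 1, 3))
    arc = np.zeros(n_s + 1)
    for i in range(half + 1):
        if i <= n_c:  # left corpus, posterior -> anterior
            pts[i] = (-R, -L + i * L / n_c, 0.0)
            tan[i] = (0.0, 1.0, 0.0)
            arc[i] = i * L / n_c
        else:         # left half of the anterior arch
            k = i - n_c
            th = np.pi - k * np.pi / n_a
            pts[i] = (R * np.cos(th), R * np.sin(th), 0.0)
            tan[i] = (np.sin(th), -np.cos(th), 0.0)
            arc[i] = L + k * seg_arch
    total = 2 * L + np.pi * R
    for i in range(half + 1, n_s + 1):  # mirror the left half
        j = n_s - i
        pts[i] = pts[j] * (-1, 1, 1)
        tan[i] = tan[j] * (1, -1, 1)
        arc[i] = total - arc[j]
    med = np.column_stack([tan[:, 1], -tan[:, 0], np.zeros(n_s + 1)])
    return pts, tan, med, arc, n_c, n_a, n_s


# ---------------------------------------------------------------------------
# build_mandible
# ---------------------------------------------------------------------------

def build_mandible(spec: MandibleSpec | None = None) -> Mesh:
    """Generate the intact (healthy-control) mandible mesh.

    Deterministic for a fixed spec; the mesh is mirror-symmetric about the
    midsagittal plane and carries condyle, bite, muscle-insertion and
    material sets on both sides.
    """
    spec = spec or MandibleSpec()
    spec.validate()

    w = spec.corpus_section_width
    h = spec.corpus_section_height
    ct = spec.cortical_thickness
    pts, tan, med, arc, n_c, n_a, n_s = _stations(spec)
    total_arc = arc[-1]
    seg_c = spec.corpus_length / n_c

    n_w = spec.elements_per_section
    n_h = max(3, int(round(spec.elements_per_section * h / w)))
    dz = h / n_h
    n_zr = max(1, int(round((spec.ramus_height - h) / dz)))
    ramus_top = h + n_zr * dz
    n_ram = max(2, int(round(2.0 * h / seg_c)))  # ramus footprint, in segments
    if n_ram >= n_c:
        raise GeometryError("corpus_length too short for the ramus footprint "
                            "(increase corpus_length or n_arch_segments)")

    def is_ramus_station(i):
        return i <= n_ram or i >= n_s - n_ram

    n_z_at = [n_h + (n_zr if is_ramus_station(i) else 0) for i in range(n_s + 1)]

    # -- nodes ------------------------------------------------------------
    ids = {}
    coords = []
    for i in range(n_s + 1):
        for j in range(n_w + 1):
            off = w * (j / n_w - 0.5)          # along the lateral direction
            base = pts[i] - off * med[i]
            for k in range(n_z_at[i] + 1):
                ids[(i, j, k)] = len(coords)
                coords.append(base + (0.0, 0.0, k * dz))
    nodes = np.asarray(coords)

    # -- hexes -> tets, with material regions ------------------------------
    tooth_pos = np.asarray(spec.tooth_positions, float)
    seg_mid = 0.5 * (arc[:-1] + arc[1:]) / total_arc
    tooth_seg = set()
    corpus_lo = arc[n_ram] / total_arc
    corpus_hi = arc[n_s - n_ram] / total_arc
    for p in tooth_pos:
        if not (corpus_lo < p < corpus_hi):
            raise GeometryError(
                f"tooth_positions: {p:g} falls outside the corpus span "
                f"({corpus_lo:.3f}..{corpus_hi:.3f})")
        tooth_seg.add(int(np.argmin(np.abs(seg_mid - p))))

    # The right half uses the mirrored hex decomposition so the tet mesh
    # (not just the node lattice) is mirror-symmetric; the two patterns meet
    # conformingly because their shared faces lie on the midsagittal plane.
    half = n_c + n_a // 2
    tets = []
    regions = []  # 0 cortical, 1 trabecular, 2 teeth
    for i in range(n_s):
        ram = is_ramus_station(i) and is_ramus_station(i + 1)
        n_z_seg = n_h + (n_zr if ram else 0)
        top = ramus_top if ram else h
        mirrored = i >= half
        for j in range(n_w):
            d_side = w / 2 - abs(w * ((j + 0.5) / n_w - 0.5))
            for k in range(n_z_seg):
                zc = (k + 0.5) * dz
                if i in tooth_seg and k == n_h - 1:
                    reg = 2
                elif min(d_side, zc, top - zc) < ct:
                    reg = 0
                else:
                    reg = 1
                c = (ids[(i, j, k)], ids[(i + 1, j, k)],
                     ids[(i + 1, j + 1, k)], ids[(i, j + 1, k)],
                     ids[(i, j, k + 1)], ids[(i + 1, j, k + 1)],
                     ids[(i + 1, j + 1, k + 1)], ids[(i, j + 1, k + 1)])
                if mirrored:
                    c = (c[1], c[0], c[3], c[2], c[5], c[4], c[7], c[6])
                for t in _HEX_TETS:
                    tet = [c[t[0]], c[t[1]], c[t[2]], c[t[3]]]
                    if mirrored:
                        tet[2], tet[3] = tet[3], tet[2]
                    tets.append(tet)
                    regions.append(reg)
    tets = np.asarray(tets, dtype=np.int64)
    regions = np.asarray(regions)
    if not np.any(regions == 1):
        raise GeometryError("cortical_thickness leaves no trabecular core at "
                            "this discretization; refine elements_per_section")

    vols = tet_volumes(nodes, tets)
    if vols.min() <= 0:
        raise GeometryError("degenerate spec produced inverted elements")

    element_sets = {
        "cortical": np.flatnonzero(regions == 0),
        "trabecular": np.flatnonzero(regions == 1),
    }
    if np.any(regions == 2):
        element_sets["teeth"] = np.flatnonzero(regions == 2)

    # -- node sets ----------------------------------------------------------
    node_sets: dict[str, np.ndarray] = {}

    def add_set(name, members):
        members = np.unique(np.asarray(sorted(members), dtype=np.int64))
        if members.size == 0:
            raise GeometryError(f"node set '{name}' came out empty; the "
                                "discretization is too coarse to host it")
        node_sets[name] = members

    def mirror_station(i):
        return n_s - i

    kmax = n_h + n_zr
    # condylar surfaces: top face of the posterior-most ramus segment
    for side, s0 in (("left", 0), ("right", n_s)):
        st = [0, 1] if side == "left" else [n_s, n_s - 1]
        add_set(f"condyle_{side}",
                [ids[(i, j, kmax)] for i in st for j in range(n_w + 1)])

    # occlusal (bite) surfaces above the premolar/M1 teeth of each side
    left_teeth = sorted(s for s in tooth_seg if s < n_s // 2)
    for side in ("left", "right"):
        segs = left_teeth[1:4] if len(left_teeth) > 3 else left_teeth
        if side == "right":
            segs = [n_s - 1 - s for s in segs]
        members = [ids[(i, j, n_h)]
                   for s in segs for i in (s, s + 1) for j in range(n_w + 1)]
        add_set(f"bite_{side}", members)

    # muscle insertion patches (strictly posterior of the angle cut plane)
    ram_st = {"left": range(0, n_ram), "right": range(n_s - n_ram + 1, n_s + 1)}
    for side in ("left", "right"):
        lat_j, medl_j = n_w, 0
        lo, hi = 0.10 * ramus_top, 0.55 * ramus_top
        sup, deep, pter, post = [], [], [], []
        for i in ram_st[side]:
            for k in range(n_z_at[i] + 1):
                z = k * dz
                if lo <= z <= hi:
                    sup.append(ids[(i, lat_j, k)])
                    pter.append(ids[(i, medl_j, k)])
                elif hi < z <= 0.90 * ramus_top:
                    deep.append(ids[(i, lat_j, k)])
        add_set(f"superficial_masseter_{side}", sup)
        add_set(f"deep_masseter_{side}", deep)
        add_set(f"medial_pterygoid_{side}", pter)
        # posterior temporalis: superior ramus surface behind the coronoid
        st = (range(2, max(3, n_ram - 1)) if side == "left" else
              range(n_s - max(3, n_ram - 1) + 1, n_s - 1))
        post = [ids[(i, j, kmax)] for i in st for j in range(n_w + 1)]
        add_set(f"posterior_temporalis_{side}", post)
        # anterior temporalis: coronoid surrogate, anterior ramus face, top
        i = n_ram if side == "left" else n_s - n_ram
        ant = [ids[(i, j, k)] for j in range(n_w + 1)
               for k in range(n_z_at[i] + 1) if k * dz >= 0.75 * ramus_top]
        add_set(f"anterior_temporalis_{side}", ant)

    meta = {
        "spec": dataclasses.asdict(spec),
        "path_points": pts,
        "path_tangents": tan,
        "path_medials": med,
        "path_arc": arc,
        "n_ram": n_ram,
        "n_segments": n_s,
        "section_width": w,
        "section_height": h,
        "ramus_top": ramus_top,
        "corpus_span": (corpus_lo, corpus_hi),
        "angle_y": {"left": float(pts[n_ram][1]), "right": float(pts[n_ram][1])},
        "lateral_x": {"left": float(-(spec.arch_radius + w / 2)),
                      "right": float(spec.arch_radius + w / 2)},
    }
    return Mesh(nodes=nodes, tets=tets, node_sets=node_sets,
                element_sets=element_sets, meta=meta)


def analytic_volume(spec: MandibleSpec) -> float:
    """Closed-form volume of the swept solid (Pappus) plus the ramus blocks."""
    spec.validate()
    pts, tan, med, arc, n_c, n_a, n_s = _stations(spec)
    w, h = spec.corpus_section_width, spec.corpus_section_height
    n_h = max(3, int(round(spec.elements_per_section * h / w)))
    dz = h / n_h
    n_zr = max(1, int(round((spec.ramus_height - h) / dz)))
    ramus_top = h + n_zr * dz
    seg_c = spec.corpus_length / n_c
    n_ram = max(2, int(round(2.0 * h / seg_c)))
    sweep = w * h * (2 * spec.corpus_length + np.pi * spec.arch_radius)
    rami = 2 * (n_ram * seg_c) * w * (ramus_top - h)
    return sweep + rami


# ---------------------------------------------------------------------------
# cut_fracture
# ---------------------------------------------------------------------------

def default_fracture(mesh: Mesh, side: str = "left", gap_width: float = 0.2,
                     obliquity_deg: float = 0.0) -> FractureSpec:
    """Fracture plane through the angle (corpus-ramus junction) of a side.

    The default plane is transverse to the sweep path; ``obliquity_deg``
    rotates it about the vertical axis.
    """
    meta = mesh.meta
    if "path_points" not in meta:
        raise GeometryError("default_fracture needs a mandible mesh with "
                            "sweep-path metadata")
    n_ram, n_s = meta["n_ram"], meta["n_segments"]
    i = n_ram if side == "left" else n_s - n_ram
    point = np.asarray(meta["path_points"][i], float)
    normal = np.asarray(meta["path_tangents"][i], float)
    if obliquity_deg:
        a = np.radians(obliquity_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        normal = rot @ normal
    return FractureSpec(side=side, plane_point=tuple(point),
                        plane_normal=tuple(normal / np.linalg.norm(normal)),
                        gap_width=gap_width)


def cut_fracture(mesh: Mesh, frac: FractureSpec) -> Mesh:
    """Insert a planar fracture gap by node duplication and rigid offset.

    Nodes shared between elements on the two sides of the plane (restricted
    to the stated side of the jaw) are duplicated; the anterior face keeps
    the original ids and both faces are offset by half the gap width along
    the plane normal, so every pair's undeformed distance equals
    ``gap_width`` exactly.
    """
    frac.validate()
    if mesh.fracture_pairs is not None:
        raise GeometryError("mesh already contains a fracture")
    out = mesh.copy()
    n = np.asarray(frac.plane_normal, float)
    n = n / np.linalg.norm(n)
    p = np.asarray(frac.plane_point, float)

    cent = out.nodes[out.tets].mean(axis=1)
    d_el = (cent - p) @ n
    if "path_points" in out.meta:
        sgn = -1.0 if frac.side == "left" else 1.0
        side_mask = sgn * cent[:, 0] > 0
        # the plane must actually pass through the angle region of that side
        meta = out.meta
        i = meta["n_ram"] if frac.side == "left" else meta["n_segments"] - meta["n_ram"]
        junction = np.asarray(meta["path_points"][i], float)
        if abs((junction - p) @ n) > 2.0 * meta["section_height"]:
            raise GeometryError("fracture plane does not intersect the angle "
                                "region of the stated side")
    else:
        side_mask = np.ones(len(cent), bool)

    edges = out.nodes[out.tets]
    h_el = float(np.max(np.linalg.norm(
        edges[:, 1:] - edges[:, :1], axis=2)))
    anterior_el = side_mask & (d_el > 0)
    posterior_near = side_mask & ~anterior_el & (np.abs(d_el) < 3.0 * h_el)
    nodes_a = np.unique(out.tets[anterior_el])
    nodes_p = np.unique(out.tets[posterior_near])
    d_node = (out.nodes - p) @ n
    iface = np.intersect1d(nodes_a, nodes_p)
    iface = iface[np.abs(d_node[iface]) <= 1.5 * h_el]
    if iface.size == 0:
        raise GeometryError("fracture plane misses the solid")

    n0 = out.n_nodes
    new_ids = np.arange(n0, n0 + iface.size)
    remap = np.arange(n0)
    remap[iface] = new_ids
    out.nodes = np.vstack([out.nodes, out.nodes[iface]])
    # elements on the posterior side adopt the duplicated (posterior) copies
    post_el = ~anterior_el
    touches = np.isin(out.tets, iface).any(axis=1)
    sel = post_el & touches
    out.tets[sel] = remap[out.tets[sel]]
    # rigid offset: half the gap to each side of the plane
    out.nodes[iface] += 0.5 * frac.gap_width * n
    out.nodes[new_ids] -= 0.5 * frac.gap_width * n

    if tet_volumes(out.nodes, out.tets).min() <= 0:
        raise GeometryError("gap_width is too wide for the local element "
                            "size (elements would invert)")

    out.node_sets["fracture_face_anterior"] = iface.copy()
    out.node_sets["fracture_face_posterior"] = new_ids.copy()
    out.fracture_pairs = FracturePairs(
        anterior=iface.copy(),
        posterior=new_ids.copy(),
        distance=np.linalg.norm(out.nodes[iface] - out.nodes[new_ids], axis=1),
        normal=np.tile(n, (iface.size, 1)),
    )
    out.meta["fracture"] = {"side": frac.side, "gap_width": frac.gap_width,
                            "plane_point": tuple(p), "plane_normal": tuple(n)}
    return out


# ---------------------------------------------------------------------------
# attach_fixation
# ---------------------------------------------------------------------------

def attach_fixation(mesh: Mesh, fix: FixationSpec) -> Mesh:
    """Attach miniplate hardware across the fracture.

    Champy: a single plate at the superior border (external oblique ridge
    surrogate on the superolateral surface).  Biplanar: the Champy plate
    plus a second plate on the inferolateral surface.  Plates are flat
    tetrahedral strips on the lateral surface; each screw site pairs the
    plate nodes within a screw radius of the hole with their nearest
    cortical surface nodes, to be tied by the solver.
    """
    fix.validate()
    if fix.technique == "none":
        raise GeometryError("technique 'none' attaches no hardware")
    if mesh.fracture_pairs is None:
        raise GeometryError("attach_fixation requires a fractured mesh")
    meta = mesh.meta
    if "fracture" not in meta:
        raise GeometryError("mesh lacks fracture placement metadata")
    side = meta["fracture"]["side"]
    y_f = float(np.asarray(meta["fracture"]["plane_point"])[1])
    x_lat = meta["lateral_x"][side]
    h = meta["section_height"]
    sgn = -1.0 if side == "left" else 1.0

    out = mesh.copy()
    out.tie_pairs = (np.empty((0, 2), dtype=np.int64)
                     if out.tie_pairs is None else out.tie_pairs)

    # candidate bone anchor nodes: cortical nodes on the lateral face
    lat_nodes = np.flatnonzero(np.abs(out.nodes[:, 0] - x_lat) < 1e-8)
    if lat_nodes.size == 0:
        raise GeometryError("no lateral-surface nodes found for plating")
    tree = cKDTree(out.nodes[lat_nodes])

    n_plates = 1 if fix.technique == "champy" else 2
    z_centers = [h - 0.5 * fix.plate_width - 0.75, 0.5 * fix.plate_width + 0.75]
    interface: list[int] = []
    n_half = fix.screws_per_plate // 2
    hole_off = np.linspace(0.35, 0.80, n_half) * (fix.plate_length / 2)

    for ip in range(n_plates):
        zc = z_centers[ip]
        nlen = max(8, int(round(fix.plate_length / 2.0)))
        nwid = max(2, int(round(fix.plate_width / 1.25)))
        plate = box_mesh(fix.plate_thickness, fix.plate_length, fix.plate_width,
                         1, nlen, nwid)
        x0 = x_lat - fix.plate_thickness if side == "left" else x_lat
        plate.nodes += (x0, y_f - fix.plate_length / 2, zc - fix.plate_width / 2)

        base_n, base_e = out.n_nodes, out.n_tets
        out.nodes = np.vstack([out.nodes, plate.nodes])
        out.tets = np.vstack([out.tets, plate.tets + base_n])
        out.element_sets[f"plate_{ip + 1}"] = base_e + np.arange(plate.n_tets)

        inner = np.flatnonzero(np.abs(plate.nodes[:, 0] - x_lat) < 1e-9)
        anchored_y = []
        for ih, off in enumerate(np.concatenate([-hole_off[::-1], hole_off])):
            y_h = y_f + off
            dy = plate.nodes[inner, 1] - y_h
            dzp = plate.nodes[inner, 2] - zc
            sel = inner[np.hypot(dy, dzp) <= fix.screw_diameter / 2]
            if sel.size == 0:
                raise GeometryError("screw hole hosts no plate nodes; refine "
                                    "the plate discretization")
            dist, idx = tree.query(out.nodes[base_n + sel])
            if np.any(dist > fix.screw_diameter):
                raise GeometryError("plate does not sit on the bone surface "
                                    "at a screw site")
            bone = lat_nodes[idx]
            pairs = np.column_stack([base_n + sel, bone])
            out.tie_pairs = np.vstack([out.tie_pairs, pairs])
            out.node_sets[f"screw_p{ip + 1}_{ih + 1}_plate"] = np.unique(base_n + sel)
            out.node_sets[f"screw_p{ip + 1}_{ih + 1}_bone"] = np.unique(bone)
            interface.extend(bone.tolist())
            anchored_y.extend(out.nodes[bone, 1].tolist())
        anchored_y = np.asarray(anchored_y)
        if not (np.any(anchored_y < y_f) and np.any(anchored_y > y_f)):
            raise GeometryError("plate does not span the fracture plane "
                                "(no screw anchorage on each fragment)")

    # bone-implant interface: anchored nodes plus lateral-face nodes under
    # the plate footprints
    span = fix.plate_length / 2
    for ip in range(n_plates):
        zc = z_centers[ip]
        m = (np.abs(out.nodes[lat_nodes, 1] - y_f) <= span) & \
            (np.abs(out.nodes[lat_nodes, 2] - zc) <= fix.plate_width)
        interface.extend(lat_nodes[m].tolist())
    out.node_sets["implant_interface"] = np.unique(np.asarray(interface))
    out.meta["fixation"] = {"technique": fix.technique, "n_plates": n_plates}
    return out
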