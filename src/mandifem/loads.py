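"""Masticatory load cases: materials, muscle forces, boundary conditions.

Muscle force magnitudes follow the physiological recipe

    |F| = EMG x PCSA x specific tension,

with normalized EMG in [0, 1], PCSA in cm^2 and a specific tension of
30 N/cm^2.  Each muscle pulls from the centroid of its mandibular insertion
patch toward a cranium-side origin anchor point; the total force is split
equally across the insertion nodes.

Boundary conditions encode unilateral chewing: the working-side condyle is
fixed in all directions, the balancing-side condyle is fixed
anteroposteriorly and superoinferiorly but free to translate mediolaterally
(allowing lateral "wishboning" of the corpus), and the working-side
premolar/first-molar occlusal nodes are fixed in all directions so that
bite force emerges as a constraint reaction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Mesh, MandibleSpec, MUSCLE_NAMES

logger = logging.getLogger("mandifem")

SPECIFIC_TENSION = 30.0  # N/cm^2

#: physiological cross-sectional areas, cm^2 per side, at the scale reported
#: for adult macaque jaw adductors (temporalis largest, then masseter)
DEFAULT_PCSA = {
    "anterior_temporalis": 5.5,
    "posterior_temporalis": 3.5,
    "deep_masseter": 2.5,
    "superficial_masseter": 5.0,
    "medial_pterygoid": 3.5,
}

#: normalized EMG drive of the working / balancing side (all muscles)
DEFAULT_EMG_WORKING = 1.0
DEFAULT_EMG_BALANCING = 0.6


class LoadError(ValueError):
    pass


@dataclass(frozen=True)
class Material:
    region: str
    E: float      # Young's modulus, MPa
    nu: float     # Poisson ratio

    def __post_init__(self):
        if self.E <= 0:
            raise LoadError(f"material '{self.region}': E must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise LoadError(f"material '{self.region}': nu must be in [0, 0.5)")


def default_materials(cortical_E: float = 17000.0) -> dict:
    """Material table: isotropic cortical/trabecular bone, teeth, titanium."""
    mats = {
        "cortical": Material("cortical", cortical_E, 0.3),
        "trabecular": Material("trabecular", 10000.0, 0.3),
        "teeth": Material("teeth", 24500.0, 0.3),
        "plate_1": Material("plate_1", 105000.0, 0.36),
        "plate_2": Material("plate_2", 105000.0, 0.36),
        "solid": Material("solid", 17000.0, 0.3),  # generic test meshes
    }
    return mats


@dataclass
class MuscleDef:
    name: str
    side: str
    insertion_set: str
    origin_anchor: np.ndarray   # mm, cranium-side centroid surrogate
    emg: float = 1.0            # mean normalized EMG amplitude, [0, 1]
    pcsa: float = 2.0           # cm^2
    specific_tension: float = SPECIFIC_TENSION  # N/cm^2

    def validate(self):
        if not 0.0 <= self.emg <= 1.0:
            raise LoadError(f"{self.name} ({self.side}): emg must be in [0,1]")
        if self.pcsa <= 0:
            raise LoadError(f"{self.name} ({self.side}): pcsa must be positive")

    @property
    def total_force(self) -> float:
        """Total muscle force magnitude, N."""
        return self.emg * self.pcsa * self.specific_tension


def default_anchors(spec: MandibleSpec) -> dict:
    """Cranium-side origin anchor points derived from the mandible dimensions.

    There is no cranium mesh; only the origin centroid enters the force
    direction, so abstract points above the ramus suffice.  The masseter
    origins sit on the laterally flared zygomatic arch (lateral pull), the
    medial pterygoid origin near the midline pterygoid plates (medial
    pull) -- their opposition drives the lateral-transverse "wishboning"
    load on the balancing corpus -- and the temporalis origins sit above
    (anterior part) and posterosuperior to (posterior part) the coronoid.
    """
    R, L = spec.arch_radius, spec.corpus_length
    w, h = spec.corpus_section_width, spec.corpus_section_height
    x_lat = R + w / 2
    y_ang = -L + 2.0 * h  # approximate angle location along the corpus
    top = spec.ramus_height
    left = {
        "superficial_masseter": (-(x_lat + 6.0), y_ang + 25.0, top + 25.0),
        "deep_masseter": (-(x_lat + 8.0), y_ang + 8.0, top + 20.0),
        "medial_pterygoid": (-6.0, y_ang + 12.0, top + 18.0),
        "anterior_temporalis": (-(R + 2.0), y_ang + 8.0, top + 35.0),
        "posterior_temporalis": (-(R + 2.0), y_ang - 25.0, top + 25.0),
    }
    anchors = {}
    for name, p in left.items():
        anchors[(name, "left")] = np.asarray(p, float)
        anchors[(name, "right")] = np.asarray(p, float) * (-1, 1, 1)
    return anchors


def default_muscles(spec: MandibleSpec | None = None, pcsa: dict | None = None,
                    anchors: dict | None = None) -> list:
    """The ten masticatory muscles (five per side) with default parameters."""
    spec = spec or MandibleSpec()
    pcsa = {**DEFAULT_PCSA, **(pcsa or {})}
    anchors = anchors or default_anchors(spec)
    muscles = []
    for side in ("left", "right"):
        for name in MUSCLE_NAMES:
            muscles.append(MuscleDef(
                name=name, side=side,
                insertion_set=f"{name}_{side}",
                origin_anchor=np.asarray(anchors[(name, side)], float),
                pcsa=float(pcsa[name])))
    return muscles


@dataclass
class ChewConfig:
    """Which side chews, which side is fractured, and the EMG drive table."""

    chew_side: str = "left"
    fracture_side: str = "left"
    emg_table: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.chew_side not in ("left", "right") or \
                self.fracture_side not in ("left", "right"):
            raise LoadError("chew_side and fracture_side must be left/right")
        if not self.emg_table:
            self.emg_table = {
                (name, side): (DEFAULT_EMG_WORKING if side == self.chew_side
                               else DEFAULT_EMG_BALANCING)
                for name in MUSCLE_NAMES for side in ("left", "right")}
        missing = [(n, s) for n in MUSCLE_NAMES for s in ("left", "right")
                   if (n, s) not in self.emg_table]
        if missing:
            raise LoadError(f"emg_table is missing entries: {missing}")

    @property
    def laterality(self) -> str:
        return ("ipsilateral" if self.chew_side == self.fracture_side
                else "contralateral")


@dataclass
class LoadCase:
    """Solver-ready nodal forces and homogeneous displacement constraints."""

    forces: np.ndarray          # (N, 3) nodal forces, N
    constraints: list           # [(node, dof, value), ...] dof: 0=x 1=y 2=z
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def muscle_force(m: MuscleDef, mesh: Mesh):
    """Nodal force vectors for one muscle.

    Returns ``(node_ids, vectors)`` whose vectors sum to the muscle's total
    force along the unit direction from the insertion centroid to the origin
    anchor, split equally across insertion nodes.
    """
    m.validate()
    if m.insertion_set not in mesh.node_sets:
        raise LoadError(f"mesh lacks insertion set '{m.insertion_set}'")
    ids = mesh.node_sets[m.insertion_set]
    if ids.size == 0:
        raise LoadError(f"insertion set '{m.insertion_set}' is empty")
    centroid = mesh.nodes[ids].mean(axis=0)
    d = np.asarray(m.origin_anchor, float) - centroid
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise LoadError(f"{m.name} ({m.side}): origin anchor coincides with "
                        "the insertion centroid")
    vec = (m.total_force / norm / ids.size) * d
    return ids, np.tile(vec, (ids.size, 1))


def build_constraints(cfg: ChewConfig, mesh: Mesh) -> list:
    """Condyle and occlusal constraints for the chosen chewing side.

    Working condyle: fixed x, y, z.  Balancing condyle: fixed y (AP) and z
    (SI); mediolateral x free.  Working-side bite nodes: fixed x, y, z.
    All prescribed values are zero.
    """
    working = cfg.chew_side
    balancing = "right" if working == "left" else "left"
    for name in (f"condyle_{working}", f"condyle_{balancing}",
                 f"bite_{working}"):
        if name not in mesh.node_sets or mesh.node_sets[name].size == 0:
            raise LoadError(f"mesh lacks required node set '{name}'")
    constraints = []
    for n in mesh.node_sets[f"condyle_{working}"]:
        constraints += [(int(n), d, 0.0) for d in (0, 1, 2)]
    for n in mesh.node_sets[f"condyle_{balancing}"]:
        constraints += [(int(n), d, 0.0) for d in (1, 2)]
    for n in mesh.node_sets[f"bite_{working}"]:
        constraints += [(int(n), d, 0.0) for d in (0, 1, 2)]
    return constraints


def assemble_loadcase(cfg: ChewConfig, muscles: list, mesh: Mesh) -> LoadCase:
    """Superpose all muscle force fields and attach the chewing constraints.

    Forces landing on constrained degrees of freedom are zeroed with a
    logged warning (a prescribed displacement overrides an applied force).
    """
    forces = np.zeros((mesh.n_nodes, 3))
    applied = []
    for m in muscles:
        key = (m.name, m.side)
        emg = cfg.emg_table.get(key, m.emg)
        m = replace(m, emg=float(emg))
        if m.emg == 0.0:
            applied.append((key, 0.0))
            continue
        ids, vecs = muscle_force(m, mesh)
        forces[ids] += vecs
        applied.append((key, m.total_force))
    constraints = build_constraints(cfg, mesh)
    fixed = {(n, d) for n, d, _ in constraints}
    clobbered = 0
    for n, d in fixed:
        if forces[n, d] != 0.0:
            forces[n, d] = 0.0
            clobbered += 1
    if clobbered:
        logger.warning("zeroed muscle forces on %d constrained DOFs", clobbered)
    return LoadCase(forces=forces, constraints=constraints,
                    provenance={"chew_side": cfg.chew_side,
                                "fracture_side": cfg.fracture_side,
                                "laterality": cfg.laterality,
                                "muscle_totals": applied})
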