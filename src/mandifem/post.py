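"""Outcome statistics: strain fields, trimmed extremes, interfragmentary
displacement, sectional moment profiles, and strain-difference maps.

Conventions follow the biomechanics literature: maximum/minimum principal
strains e1/e3 are the extreme eigenvalues of the small-strain tensor,
reported in microstrain (tension positive); interfragmentary displacement
(IFD) is the percentage change of each fracture node-pair distance between
the unloaded and loaded states (negative = compression, positive = gap
opening); sectional moments are free-body resultants about the centroid of
each cross-section, expressed in local axes where Mx is sagittal bending
(about the mediolateral axis), My is anteroposterior twisting and Mz is
transverse bending.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Mesh, tet_volumes
from .fem import (FEMError, SolutionField, shape_gradients,
                  material_of_elements)


@dataclass
class StrainField:
    element_tensors: np.ndarray   # (M, 3, 3) dimensionless
    nodal_tensors: np.ndarray     # (N, 3, 3) volume-weighted averages
    eps1: np.ndarray              # (N,) max principal strain, microstrain
    eps3: np.ndarray              # (N,) min principal strain, microstrain


@dataclass
class StressField:
    element_tensors: np.ndarray   # (M, 3, 3) MPa
    nodal_tensors: np.ndarray     # (N, 3, 3) MPa
    von_mises_nodal: np.ndarray   # (N,) MPa


@dataclass
class IFDReport:
    """Percentage change in interfragmentary distance per fracture pair."""

    per_pair_pct: np.ndarray
    mode_pct: float               # center of the tallest 1%-wide bin
    mean_pct: float
    n_pairs: int


@dataclass
class MomentProfile:
    stations: np.ndarray          # normalized arc positions along the corpus
    moments: np.ndarray           # (S, 3) N*m, local (Mx, My, Mz)
    forces: np.ndarray            # (S, 3) N, local axes


@dataclass
class DifferenceMap:
    """Treatment-minus-control principal strain differences, microstrain."""

    control_nodes: np.ndarray     # control bone node ids
    mapping: np.ndarray           # matched treatment node per control node
    delta_eps1: np.ndarray
    delta_eps3: np.ndarray


@dataclass
class TrimmedSummary:
    region: str
    largest_eps1: float
    largest_eps3: float           # most negative remaining value
    trim_fraction: float = 0.05
    n_nodes: int = 0


# ---------------------------------------------------------------------------
# Strain and stress recovery
# ---------------------------------------------------------------------------

def _nodal_average(mesh: Mesh, element_tensors: np.ndarray) -> np.ndarray:
    vol = tet_volumes(mesh.nodes, mesh.tets)
    acc = np.zeros((mesh.n_nodes, 3, 3))
    wsum = np.zeros(mesh.n_nodes)
    flat = mesh.tets.ravel()
    rep = np.repeat(vol[:, None, None] * element_tensors, 4, axis=0)
    np.add.at(acc, flat, rep)
    np.add.at(wsum, flat, np.repeat(vol, 4))
    wsum[wsum == 0] = 1.0
    return acc / wsum[:, None, None]


def element_strain(solution: SolutionField, mesh: Mesh) -> StrainField:
    """Constant per-element strain tensors and nodal principal strains.

    Nodal tensors are the volume-weighted average of the adjacent element
    tensors; principal values come from the averaged tensor (averaging
    before eigen-decomposition).
    """
    if not solution.converged:
        raise FEMError("strain recovery requires a converged solution")
    grads, _vol = shape_gradients(mesh.nodes, mesh.tets)
    u = solution.displacements[mesh.tets]           # (M, 4, 3)
    grad_u = np.einsum("mak,mai->mki", grads, u)    # du_i/dx_k
    eps = 0.5 * (grad_u + np.transpose(grad_u, (0, 2, 1)))
    nodal = _nodal_average(mesh, eps)
    vals = np.linalg.eigvalsh(nodal)
    return StrainField(element_tensors=eps, nodal_tensors=nodal,
                       eps1=vals[:, 2] * 1e6, eps3=vals[:, 0] * 1e6)


def stress_from_strain(strain: StrainField, mesh: Mesh, materials) -> StressField:
    """Element stresses via each region's isotropic elasticity tensor."""
    E, nu = material_of_elements(mesh, materials)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    eps = strain.element_tensors
    tr = np.trace(eps, axis1=1, axis2=2)
    sig = 2 * mu[:, None, None] * eps
    sig[:, np.arange(3), np.arange(3)] += (lam * tr)[:, None]
    nodal = _nodal_average(mesh, sig)
    return StressField(element_tensors=sig, nodal_tensors=nodal,
                       von_mises_nodal=von_mises(nodal))


def von_mises(tensors: np.ndarray) -> np.ndarray:
    """sqrt(3/2 dev(s):dev(s)) for an array of symmetric 3x3 tensors."""
    t = np.asarray(tensors)
    tr = np.trace(t, axis1=-2, axis2=-1)
    dev = t - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


# ---------------------------------------------------------------------------
# Trimmed extremes
# ---------------------------------------------------------------------------

def trimmed_range(values, trim_fraction: float = 0.05,
                  method: str = "percentile"):
    """(smallest, largest) after symmetric tail exclusion.

    ``percentile`` drops the top and bottom ``trim_fraction`` of the sorted
    values; ``sd`` drops values outside two standard deviations of the mean.
    """
    v = np.sort(np.asarray(values, float).ravel())
    if v.size == 0:
        raise ValueError("cannot trim an empty value list")
    if method == "percentile":
        k = int(np.floor(v.size * trim_fraction))
        kept = v[k:v.size - k] if v.size > 2 * k else v[v.size // 2:v.size // 2 + 1]
    elif method == "sd":
        m, s = v.mean(), v.std()
        kept = v[(v >= m - 2 * s) & (v <= m + 2 * s)]
        if kept.size == 0:
            kept = v
    else:
        raise ValueError(f"unknown trim method '{method}'")
    return float(kept[0]), float(kept[-1])


def trimmed_extreme(values, trim_fraction: float = 0.05,
                    method: str = "percentile") -> float:
    """Largest remaining value after symmetric tail exclusion."""
    return trimmed_range(values, trim_fraction, method)[1]


def region_summary(strain: StrainField, mesh: Mesh, region: str,
                   trim_fraction: float = 0.05,
                   method: str = "percentile") -> TrimmedSummary:
    """Trimmed strain extremes of a node set (element-set names resolve to
    the nodes of their elements)."""
    if region in mesh.node_sets:
        ids = mesh.node_sets[region]
    elif region in mesh.element_sets:
        ids = np.unique(mesh.tets[mesh.element_sets[region]])
    else:
        raise ValueError(f"unknown region '{region}'")
    _lo1, hi1 = trimmed_range(strain.eps1[ids], trim_fraction, method)
    lo3, _hi3 = trimmed_range(strain.eps3[ids], trim_fraction, method)
    return TrimmedSummary(region=region, largest_eps1=hi1, largest_eps3=lo3,
                          trim_fraction=trim_fraction, n_nodes=int(ids.size))


# ---------------------------------------------------------------------------
# Interfragmentary displacement
# ---------------------------------------------------------------------------

def ifd_report(solution: SolutionField, mesh: Mesh,
               bin_width: float = 1.0) -> IFDReport:
    """Percentage change of every fracture pair distance under load.

    The modal value is the center of the tallest ``bin_width``-percent-wide
    histogram bin (ties resolve to the lowest bin); the mean is reported
    alongside.
    """
    pairs = mesh.fracture_pairs
    if pairs is None or len(pairs) == 0:
        raise ValueError("mesh has no fracture pairs")
    if not solution.converged:
        raise FEMError("IFD requires a converged solution")
    u = solution.displacements
    xa = mesh.nodes[pairs.anterior] + u[pairs.anterior]
    xb = mesh.nodes[pairs.posterior] + u[pairs.posterior]
    deformed = np.linalg.norm(xa - xb, axis=1)
    pct = 100.0 * (deformed - pairs.distance) / pairs.distance
    lo = np.floor(pct.min() / bin_width) * bin_width - bin_width / 2
    hi = np.ceil(pct.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(pct, bins=edges)
    mode = float(0.5 * (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]))
    return IFDReport(per_pair_pct=pct, mode_pct=mode,
                     mean_pct=float(pct.mean()), n_pairs=len(pairs))


# ---------------------------------------------------------------------------
# Sectional moments (free-body cuts)
# ---------------------------------------------------------------------------

def _applied_nodal_forces(solution: SolutionField, mesh: Mesh) -> np.ndarray:
    """External + reaction + contact force at every node.

    Because element internal nodal forces are self-equilibrated, summing
    this vector over the nodes of the elements on one side of a cut gives
    the force (and, with moment arms, the moment) transmitted across the
    cut by the other side.
    """
    lc = solution.loadcase
    if lc is None:
        raise FEMError("solution carries no load case")
    q = np.array(lc.forces, float)
    for (nid, dof, _v), r in zip(lc.constraints, solution.reactions):
        q[nid, dof] += r
    q += solution.contact_nodal
    return q


def free_body_cut(solution: SolutionField, mesh: Mesh, point, normal,
                  about=None):
    """Transmitted force and moment across the plane (point, normal).

    The free body is the element set on the positive side of the plane;
    the returned (force, moment) is what the negative side exerts on it,
    with the moment taken about ``about`` (default: the plane point).
    Units: N and N*mm.
    """
    point = np.asarray(point, float)
    normal = np.asarray(normal, float)
    about = point if about is None else np.asarray(about, float)
    cent = mesh.nodes[mesh.tets].mean(axis=1)
    side = (cent - point) @ normal > 0
    ids = np.unique(mesh.tets[side])
    q = _applied_nodal_forces(solution, mesh)[ids]
    force = q.sum(axis=0)
    moment = np.cross(mesh.nodes[ids] - about, q).sum(axis=0)
    return force, moment


def section_moments(solution: SolutionField, mesh: Mesh, stations,
                    side_of_plane: str = "forward") -> MomentProfile:
    """Moment profile at normalized arc stations along the corpus.

    Each station defines a coronal cut perpendicular to the sweep path; the
    free body is the part of the model ahead of the station along the path
    (``side_of_plane='forward'``) or behind it (``'backward'``).  Moments
    are taken about the section centroid and expressed in local axes
    (X mediolateral: sagittal bending; Y path tangent: AP twist;
    Z vertical: transverse bending), in N*m.
    """
    meta = mesh.meta
    if "path_arc" not in meta:
        raise ValueError("section_moments requires a mandible mesh with "
                         "sweep-path metadata")
    arc = meta["path_arc"]
    s_norm = arc / arc[-1]
    lo, hi = meta["corpus_span"]
    stations = np.atleast_1d(np.asarray(stations, float))
    moments = np.zeros((stations.size, 3))
    forces = np.zeros((stations.size, 3))
    h = meta["section_height"]
    for k, s in enumerate(stations):
        if not (lo <= s <= hi):
            raise ValueError(f"station {s:g} lies outside the corpus span "
                             f"({lo:.3f}..{hi:.3f})")
        pt = np.array([np.interp(s, s_norm, meta["path_points"][:, i])
                       for i in range(3)])
        tn = np.array([np.interp(s, s_norm, meta["path_tangents"][:, i])
                       for i in range(3)])
        tn /= np.linalg.norm(tn)
        sign = 1.0 if side_of_plane == "forward" else -1.0
        centroid = pt + np.array([0.0, 0.0, h / 2])
        F, M = free_body_cut(solution, mesh, pt, sign * tn, about=centroid)
        e_y = tn
        e_z = np.array([0.0, 0.0, 1.0])
        e_x = np.cross(e_y, e_z)
        R = np.vstack([e_x, e_y, e_z])
        moments[k] = R @ M / 1000.0   # N*mm -> N*m
        forces[k] = R @ F
    return MomentProfile(stations=stations, moments=moments, forces=forces)


# ---------------------------------------------------------------------------
# Strain difference maps
# ---------------------------------------------------------------------------

def _bone_nodes(mesh: Mesh) -> np.ndarray:
    """Nodes of non-hardware elements, minus plate-side screw sets."""
    hw = [els for name, els in mesh.element_sets.items()
          if name.startswith("plate")]
    excluded = (np.unique(mesh.tets[np.concatenate(hw)])
                if hw else np.zeros(0, dtype=np.int64))
    for name, ids in mesh.node_sets.items():
        if name.startswith("screw") and name.endswith("plate"):
            excluded = np.union1d(excluded, ids)
    bone_els = np.setdiff1d(np.arange(mesh.n_tets),
                            np.concatenate(hw) if hw else [])
    return np.setdiff1d(np.unique(mesh.tets[bone_els]), excluded)


def strain_difference_map(treatment: StrainField, control: StrainField,
                          treatment_mesh: Mesh, control_mesh: Mesh,
                          max_distance: float = 2.0) -> DifferenceMap:
    """Per-node treatment-minus-control principal strain differences.

    Every bone node of the control is matched to its nearest treatment bone
    node in undeformed coordinates (hardware and screw sites excluded), so
    the map is purely geometric and insensitive to node numbering.
    """
    c_ids = _bone_nodes(control_mesh)
    t_ids = _bone_nodes(treatment_mesh)
    tree = cKDTree(treatment_mesh.nodes[t_ids])
    dist, idx = tree.query(control_mesh.nodes[c_ids])
    if np.any(dist > max_distance):
        raise ValueError(
            f"nearest-neighbor distance up to {dist.max():.3g} mm exceeds "
            f"max_distance={max_distance:g}; meshes appear incompatible")
    t_match = t_ids[idx]
    return DifferenceMap(
        control_nodes=c_ids,
        mapping=t_match,
        delta_eps1=treatment.eps1[t_match] - control.eps1[c_ids],
        delta_eps3=treatment.eps3[t_match] - control.eps3[c_ids],
    )
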