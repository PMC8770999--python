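"""Static linear-elastic FEM on linear tetrahedra with ties and contact.

The solver assembles constant-strain-tetrahedron stiffness, condenses
equal-displacement tie constraints (screw sites) by union-find elimination,
applies Dirichlet conditions by row/column elimination (so reactions are
exact), and resolves the fracture interface with a small-sliding node-pair
penalty contact model: compression-only normal springs on pairs whose gap
has closed, plus tangential springs capped by the Coulomb bound
``|f_t| <= mu * f_n``.  A single static load step is solved by an outer
active-set / stick-slip fixed-point iteration with a direct sparse
factorization inside.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh, FracturePairs, tet_volumes
from .loads import LoadCase, Material

logger = logging.getLogger("mandifem")


class FEMError(RuntimeError):
    pass


@dataclass
class ContactParams:
    """Penalty-contact parameters for the fracture node pairs.

    ``normal_penalty`` (N/mm per pair) defaults to 100x the mean diagonal
    stiffness of the elements adjacent to the fracture faces, which keeps
    residual penetration far below the mesh scale without wrecking the
    conditioning.  ``mu`` is the static friction coefficient.
    """

    normal_penalty: float | None = None
    tangential_penalty: float | None = None
    mu: float = 0.3
    penetration_tol: float = 1e-3   # mm
    max_outer_iters: int = 40
    convergence_tol: float = 1e-8

    def __post_init__(self):
        if self.mu < 0:
            raise FEMError("mu must be non-negative")
        if self.normal_penalty is not None and self.normal_penalty <= 0:
            raise FEMError("normal_penalty must be positive")
        if self.max_outer_iters < 1:
            raise FEMError("max_outer_iters must be at least 1")


@dataclass
class SolutionField:
    """Displacements, reactions and contact state of one solved load step."""

    displacements: np.ndarray           # (N, 3) mm
    reactions: np.ndarray               # per constraint, N (aligned w/ loadcase)
    contact_normal: np.ndarray          # (P,) compressive normal force, N
    contact_tangential: np.ndarray      # (P, 3) tangential force on anterior node
    contact_nodal: np.ndarray           # (N, 3) total contact force per node
    converged: bool
    iterations: int
    loadcase: LoadCase | None = None
    trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Element stiffness and assembly
# ---------------------------------------------------------------------------

def isotropic_elasticity(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix, Voigt order (xx,yy,zz,xy,yz,zx)."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def shape_gradients(nodes: np.ndarray, tets: np.ndarray):
    """Per-element shape-function gradients and volumes (vectorized)."""
    p = nodes[tets]                       # (M, 4, 3)
    J = p[:, 1:] - p[:, :1]               # (M, 3, 3)
    vol = np.linalg.det(J) / 6.0
    if np.any(vol <= 0):
        raise FEMError("mesh contains non-positive element volumes")
    Jinv = np.linalg.inv(J)               # rows: d(local)/d(global)
    g = np.empty((len(tets), 4, 3))
    g[:, 1:] = np.transpose(Jinv, (0, 2, 1))
    g[:, 0] = -g[:, 1:].sum(axis=1)
    return g, vol


def element_b_matrices(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices B (M, 6, 12), engineering shear rows."""
    M = len(grads)
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B


def material_of_elements(mesh: Mesh, materials) -> tuple[np.ndarray, np.ndarray]:
    """Per-element (E, nu) arrays from the region material table."""
    if isinstance(materials, (list, tuple)):
        materials = {m.region: m for m in materials}
    E = np.full(mesh.n_tets, -1.0)
    nu = np.zeros(mesh.n_tets)
    matched = set()
    for region, els in mesh.element_sets.items():
        if region in materials:
            m = materials[region]
            E[els] = m.E
            nu[els] = m.nu
            matched.add(region)
    if np.any(E < 0):
        missing = [r for r in mesh.element_sets if r not in matched]
        raise FEMError("no material assigned for element region(s): "
                       f"{missing or 'elements outside any set'}")
    return E, nu


@dataclass
class FESystem:
    """Assembled stiffness plus tie-condensation bookkeeping."""

    mesh: Mesh
    K: sp.csr_matrix                  # full 3N x 3N stiffness
    E: np.ndarray
    nu: np.ndarray
    node_rep: np.ndarray | None = None   # node -> representative node
    T: sp.csr_matrix | None = None       # full dof -> reduced dof projection

    @property
    def ndof(self) -> int:
        return self.K.shape[0]

    @property
    def K_reduced(self) -> sp.csr_matrix:
        if self.T is None:
            return self.K
        return (self.T.T @ self.K @ self.T).tocsr()


def assemble_stiffness(mesh: Mesh, materials) -> FESystem:
    """Assemble the global stiffness matrix (symmetric, CST elements)."""
    E, nu = material_of_elements(mesh, materials)
    grads, vol = shape_gradients(mesh.nodes, mesh.tets)
    B = element_b_matrices(grads)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    # D @ B without forming per-element D: split volumetric/deviatoric rows
    DB = np.empty_like(B)
    trace = B[:, 0] + B[:, 1] + B[:, 2]
    for r in range(3):
        DB[:, r] = lam[:, None] * trace + 2 * mu[:, None] * B[:, r]
    for r in range(3, 6):
        DB[:, r] = mu[:, None] * B[:, r]
    Ke = np.einsum("mki,mkj,m->mij", B, DB, vol)

    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
    rows = np.repeat(dofs, 12, axis=1).ravel()
    cols = np.tile(dofs, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * mesh.n_nodes, 3 * mesh.n_nodes)).tocsr()
    return FESystem(mesh=mesh, K=K, E=E, nu=nu)


def count_rigid_body_modes(K, tol: float = 1e-6) -> int:
    """Number of near-zero eigenvalues (dense; for verification meshes)."""
    Kd = K.toarray() if sp.issparse(K) else np.asarray(K)
    w = np.linalg.eigvalsh(Kd)
    scale = abs(w).max() or 1.0
    return int(np.sum(np.abs(w) < tol * scale))


# ---------------------------------------------------------------------------
# Tie constraints
# ---------------------------------------------------------------------------

def apply_ties(system: FESystem, mesh: Mesh | None = None) -> FESystem:
    """Condense equal-displacement tie pairs (screw sites) out of the system.

    Pairs are merged with union-find, so chained and shared anchors resolve
    to a single representative node; conforming material interfaces already
    share nodes and need no explicit ties.
    """
    mesh = mesh or system.mesh
    n = mesh.n_nodes
    parent = np.arange(n)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    if mesh.tie_pairs is not None:
        for a, b in np.asarray(mesh.tie_pairs, dtype=np.int64):
            ra, rb = find(int(a)), find(int(b))
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    rep = np.array([find(i) for i in range(n)])
    system.node_rep = rep
    if np.all(rep == np.arange(n)):
        system.T = None
        return system
    uniq, red_of_rep = np.unique(rep, return_inverse=True)
    rows = (3 * np.arange(n)[:, None] + np.arange(3)).ravel()
    cols = (3 * red_of_rep[:, None] + np.arange(3)).ravel()
    T = sp.coo_matrix((np.ones(3 * n), (rows, cols)),
                      shape=(3 * n, 3 * len(uniq))).tocsr()
    system.T = T
    system._red_node_of = red_of_rep  # node -> reduced node index
    return system


# ---------------------------------------------------------------------------
# Contact solve
# ---------------------------------------------------------------------------

def _auto_penalty(system: FESystem, pairs: FracturePairs) -> float:
    touched = np.isin(system.mesh.tets,
                      np.concatenate([pairs.anterior, pairs.posterior])).any(axis=1)
    dofs = np.unique((3 * system.mesh.tets[touched][:, :, None]
                      + np.arange(3)).ravel())
    diag = system.K.diagonal()[dofs]
    return 100.0 * float(diag.mean())


def _reduced_dofs(system: FESystem, nodes: np.ndarray) -> np.ndarray:
    """Reduced-space dof triples for the given nodes."""
    if system.T is None:
        base = nodes
    else:
        base = system._red_node_of[system.node_rep[nodes]]
    return (3 * base[:, None] + np.arange(3))


def solve_contact(system: FESystem, loadcase: LoadCase,
                  contact: ContactParams | None = None,
                  pairs: FracturePairs | None = None) -> SolutionField:
    """Solve the constrained static problem with fracture contact.

    Without pairs this is a single direct linear solve.  With pairs, an
    outer loop updates the active (closed-gap) set and the stick/slip state
    until both are stable and the displacement increment is below the
    convergence tolerance.
    """
    mesh = system.mesh
    contact = contact or ContactParams()
    if pairs is None:
        pairs = mesh.fracture_pairs
    npairs = 0 if pairs is None else len(pairs)

    K_red = system.K_reduced
    nred = K_red.shape[0]
    f_full = np.asarray(loadcase.forces, float).ravel()
    if system.T is not None:
        f_red0 = system.T.T @ f_full
    else:
        f_red0 = f_full.copy()

    # Dirichlet bookkeeping in reduced space
    cons = loadcase.constraints
    fixed_vals: dict[int, float] = {}
    for nid, dof, val in cons:
        rd = int(_reduced_dofs(system, np.array([nid]))[0, dof])
        if rd in fixed_vals and fixed_vals[rd] != val:
            raise FEMError(f"conflicting prescribed values on dof {rd}")
        fixed_vals[rd] = float(val)
    fixed = np.array(sorted(fixed_vals), dtype=np.int64)
    if fixed.size == 0:
        raise FEMError("load case has no displacement constraints")
    ufix = np.array([fixed_vals[d] for d in fixed])
    free = np.setdiff1d(np.arange(nred), fixed)

    if npairs:
        kn = contact.normal_penalty or _auto_penalty(system, pairs)
        kt = contact.tangential_penalty or kn
        a_dofs = _reduced_dofs(system, pairs.anterior)    # (P, 3)
        b_dofs = _reduced_dofs(system, pairs.posterior)
        nrm = pairs.normal
        g0 = pairs.distance

    active = np.zeros(npairs, bool)
    slip = np.zeros(npairs, bool)
    kt_pair = np.full(npairs, kt) if npairs else np.zeros(0)
    u_red = np.zeros(nred)
    u_prev = None
    converged = False
    trace = []
    it = 0

    for it in range(1, contact.max_outer_iters + 1):
        K_it = K_red
        f_it = f_red0.copy()
        if npairs and active.any():
            rows, cols, vals = [], [], []
            for i in np.flatnonzero(active):
                ni = nrm[i]
                # compression-only normal spring plus a tangential spring
                # whose secant stiffness enforces the Coulomb cap
                blocks = (kn * np.outer(ni, ni)
                          + kt_pair[i] * (np.eye(3) - np.outer(ni, ni)))
                for (da, db, s) in ((a_dofs[i], a_dofs[i], 1.0),
                                    (b_dofs[i], b_dofs[i], 1.0),
                                    (a_dofs[i], b_dofs[i], -1.0),
                                    (b_dofs[i], a_dofs[i], -1.0)):
                    rows.append(np.repeat(da, 3))
                    cols.append(np.tile(db, 3))
                    vals.append((s * blocks).ravel())
                # rest-gap offset load: springs are unstretched at gap g0
                f_it[a_dofs[i]] -= kn * g0[i] * ni
                f_it[b_dofs[i]] += kn * g0[i] * ni
            Kc = sp.coo_matrix((np.concatenate(vals),
                                (np.concatenate(rows), np.concatenate(cols))),
                               shape=(nred, nred)).tocsr()
            K_it = (K_red + Kc).tocsr()

        # Dirichlet elimination (exact reactions)
        Kff = K_it[free][:, free]
        rhs = f_it[free] - K_it[free][:, fixed] @ ufix
        try:
            lu = spla.splu(Kff.tocsc())
        except RuntimeError as exc:
            raise FEMError(f"singular constrained system: {exc}") from exc
        u_new = np.zeros(nred)
        u_new[fixed] = ufix
        u_new[free] = lu.solve(rhs)
        resid = np.linalg.norm(Kff @ u_new[free] - rhs)
        if resid > 1e-9 * max(1.0, np.linalg.norm(rhs)):
            logger.warning("linear solve residual %.3e", resid)

        if not npairs:
            u_red, u_prev = u_new, u_new
            converged = True
            K_final, f_final = K_it, f_it
            break

        du = (u_new[a_dofs] - u_new[b_dofs])
        gap = g0 + np.einsum("ij,ij->i", du, nrm)
        new_active = gap < 1e-12
        f_n = np.maximum(0.0, -kn * gap)
        s_t = du - np.einsum("ij,ij->i", du, nrm)[:, None] * nrm
        st_norm = np.linalg.norm(s_t, axis=1)
        cap = contact.mu * f_n
        # classify with the full stick stiffness; report with the secant one
        trial = kt * st_norm
        actual = kt_pair * st_norm
        new_slip = new_active & (trial > cap * (1 + 1e-9) + 1e-12)
        # secant update: a slipping pair's spring is softened so its force
        # sits exactly on the Coulomb cone; sticking pairs revert to kt
        kt_new = np.where(new_slip & (st_norm > 1e-30),
                          np.divide(cap, np.maximum(st_norm, 1e-30)),
                          kt)

        du_step = 0.0 if u_prev is None else float(
            np.max(np.abs(u_new - u_red)) / max(np.max(np.abs(u_new)), 1e-30))
        kt_step = float(np.max(np.abs(kt_new - kt_pair)) / kt) if npairs else 0.0
        sets_stable = np.array_equal(new_active, active)
        trace.append({"iter": it, "n_active": int(new_active.sum()),
                      "n_slip": int(new_slip.sum()), "du": du_step,
                      "dkt": kt_step})
        u_prev, u_red = u_red, u_new
        K_final, f_final = K_it, f_it
        cap_ok = np.all(actual[new_active] <= cap[new_active] * (1 + 1e-6)
                        + 1e-9) if new_active.any() else True
        if (sets_stable and it > 1 and du_step <= contact.convergence_tol
                and cap_ok):
            converged = True
            break
        active, slip = new_active, new_slip
        kt_pair = kt_new

    # reactions at constrained dofs (reduced space, exact)
    r_red = K_final @ u_red - f_final
    reactions = np.empty(len(cons))
    for k, (nid, dof, _val) in enumerate(cons):
        rd = int(_reduced_dofs(system, np.array([nid]))[0, dof])
        reactions[k] = r_red[rd]

    # contact forces from the final displacement field
    contact_nodal = np.zeros((mesh.n_nodes, 3))
    if npairs:
        du = (u_red[a_dofs] - u_red[b_dofs])
        gap = g0 + np.einsum("ij,ij->i", du, nrm)
        f_n = np.where(active, np.maximum(0.0, -kn * gap), 0.0)
        s_t = du - np.einsum("ij,ij->i", du, nrm)[:, None] * nrm
        f_t = np.where(active[:, None], -kt_pair[:, None] * s_t, 0.0)
        ft_norm = np.linalg.norm(f_t, axis=1)
        cap = contact.mu * f_n
        over = ft_norm > cap
        f_t[over] *= np.divide(cap[over], ft_norm[over],
                               out=np.zeros_like(cap[over]),
                               where=ft_norm[over] > 0)[:, None]
        # normal force pushes the faces apart: anterior along +n
        f_a = f_n[:, None] * nrm + f_t
        np.add.at(contact_nodal, pairs.anterior, f_a)
        np.add.at(contact_nodal, pairs.posterior, -f_a)
        pen = np.maximum(0.0, -gap).max() if len(gap) else 0.0
        if pen > contact.penetration_tol:
            logger.warning("residual penetration %.3e exceeds tolerance", pen)
            converged = False
        contact_normal, contact_tangential = f_n, f_t
    else:
        contact_normal = np.zeros(0)
        contact_tangential = np.zeros((0, 3))

    if npairs and not converged and it >= contact.max_outer_iters:
        logger.warning("contact loop did not converge in %d iterations", it)

    # expand to full dof space
    if system.T is not None:
        u_full = (system.T @ u_red).reshape(-1, 3)
    else:
        u_full = u_red.reshape(-1, 3)
    return SolutionField(
        displacements=u_full,
        reactions=reactions,
        contact_normal=contact_normal,
        contact_tangential=contact_tangential,
        contact_nodal=contact_nodal,
        converged=converged,
        iterations=it,
        loadcase=loadcase,
        trace=trace,
    )


def solve_linear(system: FESystem, loadcase: LoadCase) -> SolutionField:
    """Contact-free solve (healthy control, verification models)."""
    return solve_contact(system, loadcase, ContactParams(), pairs=None)


def compute_reactions(solution: SolutionField, system: FESystem,
                      loadcase: LoadCase | None = None):
    """Reactions per constraint plus the global equilibrium residual.

    Returns ``(reactions, residual)`` where residual is the norm of the sum
    of external forces and reactions relative to the total applied force.
    """
    loadcase = loadcase or solution.loadcase
    if not solution.converged:
        raise FEMError("reactions require a converged solution")
    total_ext = np.asarray(loadcase.forces).sum(axis=0)
    total_r = np.zeros(3)
    for (nid, dof, _v), r in zip(loadcase.constraints, solution.reactions):
        total_r[dof] += r
    scale = np.abs(loadcase.forces).sum() or 1.0
    residual = float(np.linalg.norm(total_ext + total_r) / scale)
    return solution.reactions, residual
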