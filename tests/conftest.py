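import numpy as np
import pytest

import mandifem as mf


@pytest.fixture(scope="session")
def small_spec():
    """Coarse mandible used for fast unit tests (~3k tets)."""
    return mf.MandibleSpec(n_arch_segments=8, elements_per_section=3)


@pytest.fixture(scope="session")
def small_mandible(small_spec):
    return mf.build_mandible(small_spec)


@pytest.fixture(scope="session")
def small_fractured(small_mandible):
    return mf.cut_fracture(small_mandible, mf.default_fracture(small_mandible))


@pytest.fixture(scope="session")
def small_champy(small_fractured):
    return mf.attach_fixation(small_fractured, mf.FixationSpec("champy"))


@pytest.fixture(scope="session")
def small_biplanar(small_fractured):
    return mf.attach_fixation(small_fractured, mf.FixationSpec("biplanar"))


@pytest.fixture(scope="session")
def materials():
    return mf.default_materials()


def merge_meshes(m1, m2):
    """Concatenate two meshes into one (no node merging)."""
    n = m1.n_nodes
    sets = {f"a_{k}": v for k, v in m1.element_sets.items()}
    sets.update({f"b_{k}": v + m1.n_tets for k, v in m2.element_sets.items()})
    return mf.Mesh(nodes=np.vstack([m1.nodes, m2.nodes]),
                   tets=np.vstack([m1.tets, m2.tets + n]),
                   element_sets=sets)


def solve_cantilever(n, load=10.0, E=10000.0):
    """Tip-loaded cantilever 100x10x10 mm; returns (mesh, solution, tip ids)."""
    nx, ny, nz = n
    mesh = mf.box_mesh(100.0, 10.0, 10.0, nx, ny, nz)
    mats = {"solid": mf.Material("solid", E, 0.3)}
    system = mf.apply_ties(mf.assemble_stiffness(mesh, mats))
    support = np.flatnonzero(np.abs(mesh.nodes[:, 0]) < 1e-9)
    tip = np.flatnonzero(np.abs(mesh.nodes[:, 0] - 100.0) < 1e-9)
    f = np.zeros((mesh.n_nodes, 3))
    f[tip, 2] = -load / len(tip)
    cons = [(int(nn), d, 0.0) for nn in support for d in range(3)]
    lc = mf.LoadCase(forces=f, constraints=cons)
    sol = mf.solve_contact(system, lc)
    return mesh, system, sol, tip


def contact_blocks(gap=0.2, n=(2, 2, 2), size=10.0):
    """Two blocks separated by ``gap`` along x, with a fracture-pair registry
    matching the opposing face nodes."""
    a = mf.box_mesh(size, size, size, *n)
    b = mf.box_mesh(size, size, size, *n, origin=(size + gap, 0.0, 0.0))
    mesh = merge_meshes(a, b)
    face_a = np.flatnonzero(np.abs(mesh.nodes[:, 0] - size) < 1e-9)
    face_b = np.flatnonzero(np.abs(mesh.nodes[:, 0] - size - gap) < 1e-9)
    # match by (y, z)
    order_a = np.lexsort((mesh.nodes[face_a, 2], mesh.nodes[face_a, 1]))
    order_b = np.lexsort((mesh.nodes[face_b, 2], mesh.nodes[face_b, 1]))
    fa, fb = face_a[order_a], face_b[order_b]
    normal = np.tile([-1.0, 0.0, 0.0], (len(fa), 1))  # x_a - x_b = gap * n
    mesh.fracture_pairs = mf.FracturePairs(
        anterior=fa, posterior=fb,
        distance=np.full(len(fa), gap), normal=normal)
    return mesh


@pytest.fixture(scope="session")
def default_bundle():
    """Full default study (all six arms) used by the acceptance checks."""
    cfg = mf.RunConfig(outdir="scratch/acceptance_run")
    return mf.run_pipeline(cfg, write_outputs=False)
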