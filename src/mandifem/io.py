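"""File formats and run configuration.

Meshes interchange through a small Abaqus ``.inp`` subset (``*NODE``,
``*ELEMENT, TYPE=C3D4``, ``*NSET``, ``*ELSET``) because that is the format
the study's models are distributed in; unknown keywords are skipped with a
logged warning and unsupported element types are rejected by name.  A JSON
sidecar carries what the .inp cannot: the fracture pair registry, screw tie
pairs and sweep-path metadata.  Fields export to legacy-ASCII VTK
unstructured grids for visualization.  ``RunConfig`` serializes the whole
study definition to YAML with round-trip identity and a content hash that
stamps every output.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import (Mesh, FracturePairs, MandibleSpec, FixationSpec)
from .fem import ContactParams

logger = logging.getLogger("mandifem")


def setup_logging(logfile=None, level=logging.INFO):
    """Log to stderr, and to ``logfile`` when given."""
    root = logging.getLogger("mandifem")
    root.setLevel(level)
    root.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    root.addHandler(h)
    if logfile:
        fh = logging.FileHandler(logfile, mode="a")
        fh.setFormatter(fmt)
        root.addHandler(fh)
    return root


# ---------------------------------------------------------------------------
# Abaqus .inp subset
# ---------------------------------------------------------------------------

class InpError(ValueError):
    pass


def _parse_keyword(line: str) -> tuple[str, dict]:
    parts = [p.strip() for p in line.lstrip("*").split(",")]
    kw = parts[0].upper()
    params = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            params[k.strip().upper()] = v.strip()
        elif p:
            params[p.upper()] = True
    return kw, params


def read_inp(path) -> Mesh:
    """Read a mesh from the supported .inp subset (permissive, logged skips)."""
    path = Path(path)
    node_ids: list[int] = []
    coords: list[list[float]] = []
    elems: list[list[int]] = []
    elem_sets: dict[str, list[int]] = {}
    node_sets_raw: dict[str, list[int]] = {}
    bad_types: list[str] = []
    mode, cur_params = None, {}
    skipped: set[str] = set()

    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                kw, params = _parse_keyword(line)
                cur_params = params
                if kw == "NODE":
                    mode = "node"
                elif kw == "ELEMENT":
                    etype = params.get("TYPE", "").upper()
                    if etype != "C3D4":
                        bad_types.append(etype or "<missing>")
                        mode = "skip"
                    else:
                        mode = "element"
                        elem_sets.setdefault(params.get("ELSET", "all"), [])
                elif kw == "NSET":
                    mode = "nset"
                    node_sets_raw.setdefault(params.get("NSET", "unnamed"), [])
                elif kw == "ELSET":
                    mode = "elset"
                    elem_sets.setdefault(params.get("ELSET", "unnamed"), [])
                else:
                    mode = "skip"
                    skipped.add(kw)
                continue
            try:
                if mode == "node":
                    f = line.rstrip(",").split(",")
                    node_ids.append(int(f[0]))
                    coords.append([float(x) for x in f[1:4]])
                elif mode == "element":
                    f = [int(x) for x in line.rstrip(",").split(",")]
                    elems.append(f[1:5])
                    elem_sets[cur_params.get("ELSET", "all")].append(len(elems) - 1)
                elif mode == "nset":
                    name = cur_params.get("NSET", "unnamed")
                    vals = [int(x) for x in line.rstrip(",").split(",") if x.strip()]
                    if cur_params.get("GENERATE"):
                        first, last = vals[0], vals[1]
                        step = vals[2] if len(vals) > 2 else 1
                        vals = list(range(first, last + 1, step))
                    node_sets_raw[name].extend(vals)
                elif mode == "elset":
                    name = cur_params.get("ELSET", "unnamed")
                    vals = [int(x) for x in line.rstrip(",").split(",") if x.strip()]
                    if cur_params.get("GENERATE"):
                        first, last = vals[0], vals[1]
                        step = vals[2] if len(vals) > 2 else 1
                        vals = list(range(first, last + 1, step))
                    elem_sets[name].extend(v - 1 for v in vals)
            except (ValueError, IndexError) as exc:
                raise InpError(f"{path}:{ln}: malformed line: {line!r}") from exc

    if bad_types:
        raise InpError(f"{path}: unsupported element type(s): "
                       f"{sorted(set(bad_types))}; only C3D4 is supported")
    if not coords:
        raise InpError(f"{path}: no *NODE block found")
    if skipped:
        logger.warning("%s: skipped unsupported keywords: %s",
                       path.name, sorted(skipped))
    id_map = {nid: i for i, nid in enumerate(node_ids)}
    tets = np.array([[id_map[n] for n in e] for e in elems], dtype=np.int64)
    node_sets = {name: np.unique([id_map[n] for n in vals])
                 for name, vals in node_sets_raw.items() if vals}
    element_sets = {name: np.asarray(sorted(set(vals)), dtype=np.int64)
                    for name, vals in elem_sets.items() if vals}
    return Mesh(nodes=np.asarray(coords), tets=tets,
                node_sets=node_sets, element_sets=element_sets)


def write_inp(mesh: Mesh, path) -> None:
    """Write the mesh as the .inp subset (1-based ids, C3D4 elements)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("*HEADING\nmandifem mesh export\n")
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, 1):
            fh.write(f"{i}, {x:.10g}, {y:.10g}, {z:.10g}\n")
        fh.write("*ELEMENT, TYPE=C3D4, ELSET=all\n")
        for e, (a, b, c, d) in enumerate(mesh.tets + 1, 1):
            fh.write(f"{e}, {a}, {b}, {c}, {d}\n")
        for name, els in mesh.element_sets.items():
            if name == "all":
                continue
            fh.write(f"*ELSET, ELSET={name}\n")
            ids1 = (np.asarray(els) + 1).tolist()
            for k in range(0, len(ids1), 10):
                fh.write(", ".join(str(v) for v in ids1[k:k + 10]) + "\n")
        for name, ids in mesh.node_sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            ids1 = (np.asarray(ids) + 1).tolist()
            for k in range(0, len(ids1), 10):
                fh.write(", ".join(str(v) for v in ids1[k:k + 10]) + "\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_mesh_bundle(mesh: Mesh, base) -> None:
    """Write ``<base>.inp`` plus ``<base>.meta.json`` (pairs, ties, path)."""
    base = Path(base)
    write_inp(mesh, base.with_suffix(".inp"))
    meta = {"meta": _jsonable(mesh.meta)}
    if mesh.fracture_pairs is not None:
        fp = mesh.fracture_pairs
        meta["fracture_pairs"] = {
            "anterior": fp.anterior.tolist(),
            "posterior": fp.posterior.tolist(),
            "distance": fp.distance.tolist(),
            "normal": fp.normal.tolist(),
        }
    if mesh.tie_pairs is not None:
        meta["tie_pairs"] = np.asarray(mesh.tie_pairs).tolist()
    with open(base.with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh)


def read_mesh_bundle(base) -> Mesh:
    base = Path(base)
    mesh = read_inp(base.with_suffix(".inp"))
    side = base.with_suffix(".meta.json")
    if side.exists():
        with open(side) as fh:
            meta = json.load(fh)
        m = meta.get("meta", {})
        for key in ("path_points", "path_tangents", "path_medials", "path_arc"):
            if key in m:
                m[key] = np.asarray(m[key])
        if "corpus_span" in m:
            m["corpus_span"] = tuple(m["corpus_span"])
        mesh.meta = m
        if "fracture_pairs" in meta:
            fp = meta["fracture_pairs"]
            mesh.fracture_pairs = FracturePairs(
                anterior=np.asarray(fp["anterior"], dtype=np.int64),
                posterior=np.asarray(fp["posterior"], dtype=np.int64),
                distance=np.asarray(fp["distance"], float),
                normal=np.asarray(fp["normal"], float))
        if "tie_pairs" in meta:
            mesh.tie_pairs = np.asarray(meta["tie_pairs"], dtype=np.int64)
    return mesh


# ---------------------------------------------------------------------------
# VTK (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------

def write_vtk(mesh: Mesh, path, point_data: dict | None = None,
              cell_data: dict | None = None,
              displacement_scale: float = 0.0,
              displacements: np.ndarray | None = None) -> None:
    """Write the mesh and optional nodal/element fields to a legacy VTK file.

    With ``displacement_scale`` > 0 and a displacement field, the written
    coordinates are the deformed shape magnified by that factor.
    """
    nodes = mesh.nodes
    if displacement_scale and displacements is not None:
        nodes = nodes + displacement_scale * displacements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmandifem fields\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        for x, y, z in nodes:
            fh.write(f"{x:.9g} {y:.9g} {z:.9g}\n")
        fh.write(f"\nCELLS {mesh.n_tets} {5 * mesh.n_tets}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"\nCELL_TYPES {mesh.n_tets}\n")
        fh.write("\n".join(["10"] * mesh.n_tets) + "\n")
        if point_data:
            fh.write(f"\nPOINT_DATA {len(nodes)}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for v in arr:
                        fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        if cell_data:
            fh.write(f"\nCELL_DATA {mesh.n_tets}\n")
            for name, arr in cell_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.9g}" for v in np.asarray(arr)) + "\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete definition of one in-silico fixation comparison study."""

    mandible: MandibleSpec = field(default_factory=MandibleSpec)
    fixation: FixationSpec = field(default_factory=lambda: FixationSpec("champy"))
    contact: ContactParams = field(default_factory=ContactParams)
    fracture_side: str = "left"
    gap_width: float = 0.2
    obliquity_deg: float = 0.0
    techniques: tuple = ("champy", "biplanar")
    chew_sides: tuple = ("left", "right")
    cortical_E: float = 17000.0
    pcsa: dict = field(default_factory=dict)
    emg_working: float = 1.0
    emg_balancing: float = 0.6
    stations: tuple | None = None     # normalized arc positions; None = auto
    trim_fraction: float = 0.05
    trim_method: str = "percentile"
    ifd_bin_width: float = 1.0
    display_scale: float = 20.0       # deformed-shape magnification in VTK
    seed: int = 0
    outdir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mandible"]["tooth_positions"] = list(self.mandible.tooth_positions)
        d["techniques"] = list(self.techniques)
        d["chew_sides"] = list(self.chew_sides)
        d["stations"] = None if self.stations is None else list(self.stations)
        return _jsonable(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mandible" in d:
            md = dict(d["mandible"])
            md["tooth_positions"] = tuple(md.get("tooth_positions", ()))
            d["mandible"] = MandibleSpec(**md)
        if "fixation" in d:
            d["fixation"] = FixationSpec(**d["fixation"])
        if "contact" in d:
            d["contact"] = ContactParams(**d["contact"])
        for key in ("techniques", "chew_sides"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("stations") is not None:
            d["stations"] = tuple(d["stations"])
        return cls(**d)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
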