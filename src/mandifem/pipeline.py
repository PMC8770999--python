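"""End-to-end study pipeline: build, solve and compare all study arms.

One run solves, for each requested chewing side, the healthy control plus
one model per fixation technique (all sharing the same bone mesh and load
definitions, differing only in fracture and hardware), then emits the
study's outcome tables: trimmed principal-strain extremes by region, mode
interfragmentary displacement, sectional moment profiles, and
strain-difference maps against the healthy control.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry, loads, fem, post
from .io import RunConfig, save_config, write_mesh_bundle, write_vtk

logger = logging.getLogger("mandifem")


@dataclass
class ArmResult:
    name: str                 # e.g. "champy_contralateral"
    model: str                # healthy | champy | biplanar
    chew_side: str
    laterality: str | None
    converged: bool
    solution: object = None
    strain: object = None
    ifd: object = None
    moments: object = None
    summaries: dict = field(default_factory=dict)
    diffmap: object = None
    timings: dict = field(default_factory=dict)


@dataclass
class ReportBundle:
    config: RunConfig
    config_hash: str
    arms: dict                # name -> ArmResult
    meshes: dict              # model -> Mesh
    tables: dict = field(default_factory=dict)   # name -> DataFrame


def build_study_meshes(config: RunConfig) -> dict:
    """Healthy control plus one fractured+fixed mesh per technique.

    All models derive from the same intact bone mesh, so they differ only
    in the fracture cut and hardware.
    """
    spec = config.mandible
    healthy = geometry.build_mandible(spec)
    frac = geometry.default_fracture(healthy, side=config.fracture_side,
                                     gap_width=config.gap_width,
                                     obliquity_deg=config.obliquity_deg)
    fractured = geometry.cut_fracture(healthy, frac)
    meshes = {"healthy": healthy}
    for tech in config.techniques:
        fix = geometry.FixationSpec(
            technique=tech,
            plate_length=config.fixation.plate_length,
            plate_width=config.fixation.plate_width,
            plate_thickness=config.fixation.plate_thickness,
            screw_diameter=config.fixation.screw_diameter,
            screws_per_plate=config.fixation.screws_per_plate)
        meshes[tech] = geometry.attach_fixation(fractured, fix)
    return meshes


def _default_stations(mesh, n: int = 17):
    lo, hi = mesh.meta["corpus_span"]
    pad = 0.02 * (hi - lo)
    return np.linspace(lo + pad, hi - pad, n)


def _arm_name(model: str, chew: str, fracture_side: str) -> str:
    if model == "healthy":
        return f"healthy_{chew}"
    lat = "ipsilateral" if chew == fracture_side else "contralateral"
    return f"{model}_{lat}"


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> ReportBundle:
    """Run every study arm and assemble the comparison reports.

    Arms that fail to converge are marked failed and skipped in the
    comparison tables; the pipeline continues.
    """
    np.random.seed(config.seed % (2 ** 31))
    t_start = time.time()
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        save_config(config, outdir / "config.yaml")
    chash = config.hash()
    logger.info("pipeline start (config %s)", chash)

    meshes = build_study_meshes(config)
    materials = loads.default_materials(cortical_E=config.cortical_E)
    muscles = loads.default_muscles(config.mandible, pcsa=config.pcsa or None)
    stations = (np.asarray(config.stations) if config.stations is not None
                else _default_stations(meshes["healthy"]))

    systems = {}
    for model, mesh in meshes.items():
        t0 = time.time()
        systems[model] = fem.apply_ties(fem.assemble_stiffness(mesh, materials))
        logger.info("assembled %s: %d tets, %.2fs", model, mesh.n_tets,
                    time.time() - t0)

    arms: dict[str, ArmResult] = {}
    for chew in config.chew_sides:
        cfg = loads.ChewConfig(chew_side=chew,
                               fracture_side=config.fracture_side)
        emg = {(n, s): (config.emg_working if s == chew
                        else config.emg_balancing)
               for n in geometry.MUSCLE_NAMES for s in ("left", "right")}
        cfg.emg_table = emg
        for model in ["healthy", *config.techniques]:
            mesh = meshes[model]
            name = _arm_name(model, chew, config.fracture_side)
            t0 = time.time()
            lc = loads.assemble_loadcase(cfg, muscles, mesh)
            sol = fem.solve_contact(systems[model], lc, config.contact)
            arm = ArmResult(name=name, model=model, chew_side=chew,
                            laterality=None if model == "healthy"
                            else cfg.laterality,
                            converged=sol.converged, solution=sol)
            arm.timings["solve"] = time.time() - t0
            if not sol.converged:
                logger.warning("arm %s failed to converge; skipping "
                               "post-processing", name)
                arms[name] = arm
                continue
            arm.strain = post.element_strain(sol, mesh)
            regions = ["cortical"]
            if model != "healthy":
                regions += ["implant_interface", "plate_1"]
                if "plate_2" in mesh.element_sets:
                    regions += ["plate_2"]
                arm.ifd = post.ifd_report(sol, mesh,
                                          bin_width=config.ifd_bin_width)
            for region in regions:
                arm.summaries[region] = post.region_summary(
                    arm.strain, mesh, region,
                    trim_fraction=config.trim_fraction,
                    method=config.trim_method)
            arm.moments = post.section_moments(sol, mesh, stations)
            arm.timings["post"] = time.time() - t0 - arm.timings["solve"]
            arms[name] = arm
            logger.info("arm %-22s solved in %d contact iteration(s), "
                        "%.2fs", name, sol.iterations, arm.timings["solve"])

    # difference maps against the same-chew healthy control
    for name, arm in arms.items():
        if arm.model == "healthy" or not arm.converged:
            continue
        control = arms.get(f"healthy_{arm.chew_side}")
        if control is None or not control.converged:
            continue
        arm.diffmap = post.strain_difference_map(
            arm.strain, control.strain, meshes[arm.model], meshes["healthy"])

    bundle = ReportBundle(config=config, config_hash=chash, arms=arms,
                          meshes=meshes)
    bundle.tables = _build_tables(bundle)
    if write_outputs:
        _write_outputs(bundle, outdir)
    logger.info("pipeline done in %.1fs", time.time() - t_start)
    return bundle


def _build_tables(bundle: ReportBundle) -> dict:
    rows_t1, rows_t2, rows_mom, rows_dm = [], [], [], []
    for name, arm in bundle.arms.items():
        if not arm.converged:
            continue
        for region, s in arm.summaries.items():
            rows_t1.append({"arm": name, "model": arm.model,
                            "chew_side": arm.chew_side,
                            "laterality": arm.laterality or "control",
                            "region": region,
                            "largest_eps1_microstrain": s.largest_eps1,
                            "largest_eps3_microstrain": s.largest_eps3,
                            "n_nodes": s.n_nodes})
        if arm.ifd is not None:
            peak = float(np.percentile(np.abs(arm.ifd.per_pair_pct), 95))
            rows_t2.append({"arm": name, "model": arm.model,
                            "laterality": arm.laterality,
                            "n_pairs": arm.ifd.n_pairs,
                            "mode_ifd_pct": arm.ifd.mode_pct,
                            "mean_ifd_pct": arm.ifd.mean_pct,
                            "peak_abs_ifd_pct": peak})
        if arm.moments is not None:
            for s_, M in zip(arm.moments.stations, arm.moments.moments):
                rows_mom.append({"arm": name, "station": s_,
                                 "Mx_sagittal_Nm": M[0],
                                 "My_twist_Nm": M[1],
                                 "Mz_transverse_Nm": M[2]})
        if arm.diffmap is not None:
            rows_dm.append({"arm": name, "model": arm.model,
                            "laterality": arm.laterality,
                            "mean_abs_deps1_microstrain":
                                float(np.abs(arm.diffmap.delta_eps1).mean()),
                            "mean_abs_deps3_microstrain":
                                float(np.abs(arm.diffmap.delta_eps3).mean()),
                            "n_nodes": len(arm.diffmap.control_nodes)})
    return {"trimmed_extremes": pd.DataFrame(rows_t1),
            "ifd": pd.DataFrame(rows_t2),
            "moments": pd.DataFrame(rows_mom),
            "diffmap_summary": pd.DataFrame(rows_dm)}


def _write_outputs(bundle: ReportBundle, outdir: Path) -> None:
    for name, df in bundle.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    for model, mesh in bundle.meshes.items():
        write_mesh_bundle(mesh, outdir / f"mesh_{model}")
    for name, arm in bundle.arms.items():
        if not arm.converged or arm.strain is None:
            continue
        mesh = bundle.meshes[arm.model]
        point_data = {"displacement": arm.solution.displacements,
                      "eps1_microstrain": arm.strain.eps1,
                      "eps3_microstrain": arm.strain.eps3}
        if arm.diffmap is not None:
            d1 = np.full(mesh.n_nodes, np.nan)
            d1[arm.diffmap.mapping] = arm.diffmap.delta_eps1
            point_data["delta_eps1_microstrain"] = np.nan_to_num(d1)
        write_vtk(mesh, outdir / f"fields_{name}.vtk", point_data=point_data,
                  displacement_scale=bundle.config.display_scale,
                  displacements=arm.solution.displacements)
    summary = {
        "config_hash": bundle.config_hash,
        "arms": {name: {"model": a.model, "chew_side": a.chew_side,
                        "laterality": a.laterality, "converged": a.converged,
                        "iterations": getattr(a.solution, "iterations", None),
                        "timings": a.timings}
                 for name, a in bundle.arms.items()},
    }
    with open(outdir / "bundle.json", "w") as fh:
        json.dump(summary, fh, indent=2)


def friction_sweep(config: RunConfig, mus=(0.1, 0.2, 0.3, 0.4, 0.5),
                   technique: str = "champy") -> pd.DataFrame:
    """Mode IFD of one technique across static friction coefficients."""
    rows = []
    for mu in mus:
        cfg = RunConfig.from_dict(config.to_dict())
        cfg.techniques = (technique,)
        cfg.contact.mu = float(mu)
        bundle = run_pipeline(cfg, write_outputs=False)
        for name, arm in bundle.arms.items():
            if arm.ifd is None:
                continue
            rows.append({"mu": mu, "arm": name,
                         "mode_ifd_pct": arm.ifd.mode_pct,
                         "mean_ifd_pct": arm.ifd.mean_pct})
    return pd.DataFrame(rows)
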