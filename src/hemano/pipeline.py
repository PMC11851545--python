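"""Pipeline stages over a study directory.

A study directory is created by the generator (``config.yaml``,
``waveform.csv``, ``ilt.csv``) and populated by the stages:

    flow     -> outputs/flow.npz, wss_<side>.csv, mesh.vtk, flow_*.vtk
    no       -> outputs/no.npz, no_field.csv, tacno_<side>.csv, no_*.vtk
    indices  -> outputs/indices_<side>.csv, fields.vtk
    analyze  -> outputs/sections.csv, directional.csv, scatter.png,
                report.json

Each stage reads its predecessors' outputs from disk, so stages can be
re-run independently; re-running with unchanged inputs reproduces identical
outputs (all numerics are deterministic).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, from_yaml, to_yaml
from .exceptions import DataError
from .flow import FlowSolution, solve_pulsatile
from .geometry import build_mesh
from .ilt import (
    ILTMap,
    compare_ilt_groups,
    correlate_area_no,
    directional_analysis,
    section_table,
)
from .indices import compute_index_field
from .no_transport import NOSolution, solve_no
from .vtkio import write_mesh, write_quad_mesh
from .waveform import fit_waveform, read_waveform_csv

log = logging.getLogger("hemano")


def _outputs(study: Path) -> Path:
    out = Path(study) / "outputs"
    out.mkdir(exist_ok=True)
    return out


def _load_config(study) -> RunConfig:
    path = Path(study) / "config.yaml"
    if not path.exists():
        raise DataError(
            f"no config.yaml in {study}; run the generate stage first"
        )
    return from_yaml(path)


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise DataError(
            f"missing input {path.name} in {path.parent}; run the "
            f"'{produced_by}' stage first"
        )
    return path


def _mesh_and_waveform(cfg: RunConfig, study: Path):
    mesh = build_mesh(cfg.geometry, cfg.resolution, cfg.mode)
    samples = read_waveform_csv(_require(Path(study) / "waveform.csv", "generate"))
    wf = fit_waveform(samples, K=cfg.n_harmonics, period=cfg.period_s)
    return mesh, wf


def stage_flow(study) -> FlowSolution:
    """Pulsatile flow stage: waveform fit + 5-cycle transient solve."""
    t0 = time.perf_counter()
    study = Path(study)
    cfg = _load_config(study)
    mesh, wf = _mesh_and_waveform(cfg, study)
    log.info("flow: waveform fit residual RMS %.3e m/s", wf.residual_rms)
    flow = solve_pulsatile(
        mesh,
        cfg.fluid,
        wf,
        cycles=cfg.cycles,
        steps_per_cycle=cfg.steps_per_cycle,
        flow_grading=cfg.flow_grading,
    )
    out = _outputs(study)
    flow.save(out / "flow.npz")
    for side in flow.sides:
        tcyc, tau = flow.wss_final_cycle(side)
        s = mesh.interface_arclength(side)
        df = pd.DataFrame(tau.T, columns=[f"t_{t:.6f}" for t in tcyc])
        df.insert(0, "s_mm", s * 1e3)
        df.to_csv(out / f"wss_{side}.csv", index=False)
    write_mesh(out / "mesh.vtk", mesh)
    # velocity snapshots at quarter-cycle intervals of the final cycle
    idx = flow.final_cycle_indices()
    sysf = flow._system
    Zf = np.repeat(mesh.zs[:, None], sysf.Y.shape[1], axis=1)
    for q, k in enumerate(idx[:: max(1, len(idx) // 4)]):
        uz, ur = flow.velocity(int(k))
        write_quad_mesh(
            out / f"flow_{q:02d}.vtk",
            Zf,
            sysf.Y,
            point_data={"u_axial": uz, "u_transverse": ur,
                        "psi": flow.psi[int(k)]},
        )
    to_yaml(cfg, out / "config_resolved.yaml")
    log.info("flow: stage done in %.1f s", time.perf_counter() - t0)
    return flow


def stage_no(study) -> NOSolution:
    """NO transport stage driven by the stored flow solution."""
    t0 = time.perf_counter()
    study = Path(study)
    cfg = _load_config(study)
    mesh, wf = _mesh_and_waveform(cfg, study)
    out = _outputs(study)
    flow = FlowSolution.load(
        _require(out / "flow.npz", "flow"), mesh, cfg.fluid, waveform=wf
    )
    no = solve_no(mesh, flow, cfg.transport, cycles=cfg.cycles)
    no.save(out / "no.npz")
    # cell-centre concentration table (final snapshot and cycle average)
    sysn = no._system
    pd.DataFrame(
        {
            "z_mm": sysn.Cz.ravel() * 1e3,
            "y_mm": sysn.Cy.ravel() * 1e3,
            "domain": mesh.cell_domain().ravel(),
            "c_final_nM": no.c[-1].ravel(),
            "c_cycle_avg_nM": no.time_averaged_field().ravel(),
        }
    ).to_csv(out / "no_field.csv", index=False)
    Zn, Yn = mesh.node_coords()
    for q in range(0, no.c.shape[0], max(1, no.c.shape[0] // 4)):
        write_quad_mesh(
            out / f"no_{q:03d}.vtk", Zn, Yn, cell_data={"c_nM": no.c[q]}
        )
    for side in no.sides:
        pd.DataFrame(
            {
                "z_mm": no.face_positions() * 1e3,
                "tacno_nM": no.interface_tacno(side),
            }
        ).to_csv(out / f"tacno_{side}.csv", index=False)
    log.info("no: stage done in %.1f s", time.perf_counter() - t0)
    return no


def stage_indices(study) -> dict:
    """Hemodynamic index fields per wall side."""
    t0 = time.perf_counter()
    study = Path(study)
    cfg = _load_config(study)
    mesh, wf = _mesh_and_waveform(cfg, study)
    out = _outputs(study)
    flow = FlowSolution.load(
        _require(out / "flow.npz", "flow"), mesh, cfg.fluid, waveform=wf
    )
    no = NOSolution.load(_require(out / "no.npz", "no"), mesh, cfg.transport)
    fields = {}
    for side in flow.sides:
        df = compute_index_field(flow, no, side)
        df.to_csv(out / f"indices_{side}.csv", index=False)
        fields[side] = df
    Zn, Yn = mesh.node_coords()
    write_quad_mesh(
        out / "fields.vtk",
        Zn,
        Yn,
        cell_data={"tacno_time_avg": no.time_averaged_field(),
                   "domain": mesh.cell_domain()},
    )
    log.info("indices: stage done in %.1f s", time.perf_counter() - t0)
    return fields


def stage_analyze(study) -> dict:
    """Sectioning, correlation, group and directional analysis."""
    t0 = time.perf_counter()
    study = Path(study)
    cfg = _load_config(study)
    mesh, _wf = _mesh_and_waveform(cfg, study)
    out = _outputs(study)
    no = NOSolution.load(_require(out / "no.npz", "no"), mesh, cfg.transport)
    ilt = ILTMap.from_csv(_require(study / "ilt.csv", "generate"))
    table = section_table(
        cfg.geometry,
        ilt,
        no,
        spacing=cfg.section_spacing_mm * 1e-3,
        average=cfg.average,
    )
    table.to_csv(out / "sections.csv", index=False)
    results: dict = {"n_sections": int(len(table))}
    n_ilt = int((table["group"] == "ILT").sum())
    if n_ilt >= 3:
        fit = correlate_area_no(table, ilt_only=True)
        results["fit"] = fit.to_dict()
        _scatter_plot(table, fit, out / "scatter.png")
    else:
        results["fit"] = {"status": "not-applicable", "n_ilt_sections": n_ilt}
    results["groups"] = compare_ilt_groups(table)
    if n_ilt > 0:
        try:
            d = directional_analysis(
                no,
                cfg.geometry,
                ilt,
                spacing=cfg.representative_spacing_mm * 1e-3,
            )
            d["per_section"].to_csv(out / "directional.csv", index=False)
            results["directional"] = {
                "mean_tacno_thickest": d["mean_tacno_thickest"],
                "mean_tacno_thinnest": d["mean_tacno_thinnest"],
            }
        except Exception as e:  # representative sections may fall outside
            results["directional"] = {"status": f"skipped: {e}"}
    with open(out / "report.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    log.info("analyze: stage done in %.1f s", time.perf_counter() - t0)
    return results


def _scatter_plot(table: pd.DataFrame, fit, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = table[table["group"] == "ILT"]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(sub["tacno_nM"], sub["thrombus_area_mm2"], c="tab:red", s=25)
    for _, row in sub.iterrows():
        ax.annotate(
            f"{row['z_mm']:.0f}",
            (row["tacno_nM"], row["thrombus_area_mm2"]),
            fontsize=6,
            xytext=(2, 2),
            textcoords="offset points",
        )
    xs = np.linspace(sub["tacno_nM"].min(), sub["tacno_nM"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k--", lw=1)
    ax.set_xlabel("section TAcNO (nM)")
    ax.set_ylabel("thrombus area (mm$^2$)")
    ax.set_title(
        f"$R^2$={fit.r_squared:.3f}, p={fit.p_value:.2e} (labels: z mm)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_all(study) -> dict:
    """Chain flow -> no -> indices -> analyze on an existing study."""
    stage_flow(study)
    stage_no(study)
    stage_indices(study)
    return stage_analyze(study)
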