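"""Synthetic study generation.

Everything patient data would otherwise supply is generated here: an
idealized fusiform aneurysm geometry, a triphasic aortic inlet waveform, and
an ILT thickness map whose per-section thrombus area is statistically tied
(negatively, in the physiological regime) to the computed per-section TAcNO,
so that the downstream correlation analysis has a known ground truth to
recover.

The generator is deterministic given the seed; the only randomness is the
per-section noise on the area-TAcNO relation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, to_yaml
from .exceptions import ConfigError, ContractError
from .flow import FlowSolution, solve_pulsatile
from .geometry import build_mesh
from .ilt import (
    ILTMap,
    line_averaged_tacno,
    section_positions,
    section_tacno,
    thickness_for_area,
)
from .no_transport import NOSolution, solve_no
from .waveform import fit_waveform, write_waveform_csv
from .geometry import radius_profile


def make_waveform(
    preset: str, period: float = 1.0, peak_velocity: float = 0.6, n_samples: int = 64
) -> np.ndarray:
    """(t, v) samples of one period of an inlet mean-velocity waveform.

    ``triphasic`` mimics the infrarenal aortic pattern: a strong forward
    systolic peak, a single early-diastolic reversal interval, and weak
    late-diastolic forward flow.
    """
    t = period * np.arange(n_samples) / n_samples
    if preset == "constant":
        v = np.full_like(t, peak_velocity)
    elif preset == "sinusoidal":
        v = peak_velocity * np.sin(2.0 * np.pi * t / period)
    elif preset == "triphasic":
        f1, f2 = 0.36, 0.58  # phase fractions: end systole, end reversal
        v = np.zeros_like(t)
        ph = t / period
        m = ph < f1
        v[m] = peak_velocity * np.sin(np.pi * ph[m] / f1) ** 2
        m = (ph >= f1) & (ph < f2)
        v[m] = -0.25 * peak_velocity * np.sin(np.pi * (ph[m] - f1) / (f2 - f1)) ** 2
        m = ph >= f2
        v[m] = 0.08 * peak_velocity * np.sin(np.pi * (ph[m] - f2) / (1.0 - f2)) ** 2
    else:
        raise ContractError(f"unsupported waveform preset {preset!r}")
    return np.column_stack([t, v])


def ilt_window_length(cfg: RunConfig) -> int:
    """Number of contiguous sections in the thrombus-bearing window."""
    spacing = cfg.section_spacing_mm * 1e-3
    n = int(round(2 * cfg.ilt.halfspan_mm * 1e-3 / spacing)) + 1
    total = len(section_positions(cfg.geometry, spacing))
    return min(n, total)


def ilt_zone_sections(cfg: RunConfig, x_all: np.ndarray | None = None) -> np.ndarray:
    """Section positions (m) of the thrombus-bearing window.

    ``low-no`` placement (default): the contiguous window of sections whose
    mean coupling variable (section TAcNO, given as ``x_all``) is lowest --
    the generator's statistical emulation of thrombus accumulating where NO
    is depressed.  ``bulge`` placement: the window centred on the bulge.
    """
    zs = section_positions(cfg.geometry, cfg.section_spacing_mm * 1e-3)
    n_win = ilt_window_length(cfg)
    if cfg.ilt.placement == "bulge" or x_all is None:
        half = cfg.ilt.halfspan_mm * 1e-3
        zone = zs[np.abs(zs - cfg.geometry.bulge_center) <= half + 1e-9]
        return zone[:n_win]
    means = np.array(
        [x_all[i : i + n_win].mean() for i in range(len(zs) - n_win + 1)]
    )
    start = int(np.argmin(means))
    return zs[start : start + n_win]


def derive_sigma(x: np.ndarray, beta: float, target_r2: float) -> float:
    """Noise sd (mm^2) giving the requested expected R^2 for area = a+b*x+eps.

    Uses the population identity R^2 = var(beta x)/(var(beta x) + sigma^2).
    """
    var_sig = float(np.var(beta * np.asarray(x)))
    if var_sig == 0:
        warnings.warn("TAcNO has no variance across sections; sigma set to 0")
        return 0.0
    return float(np.sqrt(var_sig * (1.0 - target_r2) / target_r2))


def draw_section_areas(
    x: np.ndarray, cfg: RunConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Draw per-section thrombus areas (mm^2) tied to section TAcNO ``x``.

    Returns (areas, noiseless areas, alpha, sigma).  ``alpha`` anchors the
    smallest noiseless area at ``base_area_mm2`` so the zero-truncation
    max(0, .) rarely binds.
    """
    beta = cfg.ilt.beta_mm2_per_nM
    if beta >= 0:
        warnings.warn(
            "beta >= 0: the physiological regime has thrombus area decreasing "
            "with TAcNO (beta < 0)"
        )
    sigma = (
        cfg.ilt.sigma_mm2
        if cfg.ilt.sigma_mm2 is not None
        else derive_sigma(x, beta, cfg.ilt.target_r2)
    )
    alpha = cfg.ilt.base_area_mm2 - beta * float(np.max(x)) if beta < 0 else cfg.ilt.base_area_mm2
    noiseless = alpha + beta * x
    eps = rng.normal(0.0, sigma, size=len(x)) if sigma > 0 else np.zeros(len(x))
    areas = np.maximum(0.0, noiseless + eps)
    return areas, noiseless, float(alpha), float(sigma)


def make_ilt_from_no(
    no: NOSolution,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
    flow: FlowSolution | None = None,
) -> tuple[ILTMap, pd.DataFrame]:
    """Generate an ILT thickness map tied to the computed NO field.

    Per section inside the ILT zone the thrombus area is drawn as
    max(0, alpha + beta*TAcNO + eps); thickness is distributed over wall
    directions according to the configured model (``annular``: uniform;
    ``one-sided``: entirely on the lower-TAcNO side).  Returns the map and
    the noiseless ground-truth table for recovery tests.

    With ``couple_to = "tawss"`` the coupling variable is the section TAWSS
    instead (discriminability mode; requires ``flow``).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    geom = cfg.geometry
    zs_all = section_positions(geom, cfg.section_spacing_mm * 1e-3)
    if cfg.ilt.model == "none":
        ilt = ILTMap.zero(geom, directions=tuple(no.sides), n_z=len(zs_all))
        truth = pd.DataFrame(
            {"z_mm": zs_all * 1e3, "tacno_nM": section_tacno(no, zs_all, cfg.average)}
        )
        truth["area_true_mm2"] = 0.0
        truth["area_mm2"] = 0.0
        return ilt, truth

    if cfg.ilt.couple_to == "tawss":
        if flow is None:
            raise ConfigError("couple_to='tawss' requires the flow solution")
        from .indices import tawss

        vals = []
        for side in flow.sides:
            tcyc, tau = flow.wss_final_cycle(side)
            vals.append(
                np.interp(zs_all, flow.mesh.zs, np.atleast_1d(tawss(tcyc, tau)))
            )
        x_all = np.mean(vals, axis=0)
    else:
        x_all = section_tacno(no, zs_all, cfg.average)
    zone = ilt_zone_sections(cfg, x_all)
    in_zone = np.isin(np.round(zs_all, 9), np.round(zone, 9))
    x = x_all[in_zone]
    areas, noiseless, alpha, sigma = draw_section_areas(x, cfg, rng)

    dirs = tuple(no.sides)
    h = np.zeros((len(zs_all), len(dirs)))
    zone_idx = {round(z, 9): k for k, z in enumerate(zs_all)}
    # one-sided allocation uses the same per-direction line-averaged TAcNO
    # the directional analysis compares, so the thickest direction carries
    # the lower NO by construction
    side_line = {
        d: np.array([line_averaged_tacno(no, z, d) for z in zone]) for d in dirs
    }
    for m, z in enumerate(zone):
        k = zone_idx[round(z, 9)]
        area_m2 = areas[m] * 1e-6
        if area_m2 <= 0:
            continue
        radii = np.array([radius_profile(geom, z, d) for d in dirs])
        if cfg.ilt.model == "annular" or len(dirs) == 1:
            h[k, :] = thickness_for_area(area_m2, radii)
        else:  # one-sided: concentrate on the lowest-NO direction
            low = int(np.argmin([side_line[d][m] for d in dirs]))
            r = radii[low]
            n = len(dirs)
            hk = np.sqrt(r**2 + n * area_m2 / np.pi) - r
            if hk > 0.9 * r:  # thrombus cannot (nearly) fill the lumen
                warnings.warn(
                    "one-sided thrombus capped at 90% of the lumen radius; "
                    "the drawn area-TAcNO coupling is distorted at this "
                    "section (reduce |beta| or base_area)"
                )
                hk = 0.9 * r
            h[k, low] = hk
    ilt = ILTMap(z=zs_all, directions=dirs, thickness=h)
    truth = pd.DataFrame(
        {
            "z_mm": zone * 1e3,
            "tacno_nM": x,
            "area_true_mm2": noiseless,
            "area_mm2": areas,
        }
    )
    truth.attrs.update(alpha_mm2=alpha, sigma_mm2=sigma, beta=cfg.ilt.beta_mm2_per_nM)
    return ilt, truth


def run_simulation(cfg: RunConfig):
    """Geometry -> mesh -> pulsatile flow -> NO transport for one config."""
    cfg.validate()
    mesh = build_mesh(cfg.geometry, cfg.resolution, cfg.mode)
    samples = make_waveform(
        cfg.waveform_preset, cfg.period_s, cfg.peak_velocity
    )
    wf = fit_waveform(samples, K=cfg.n_harmonics, period=cfg.period_s)
    flow = solve_pulsatile(
        mesh,
        cfg.fluid,
        wf,
        cycles=cfg.cycles,
        steps_per_cycle=cfg.steps_per_cycle,
        flow_grading=cfg.flow_grading,
    )
    no = solve_no(mesh, flow, cfg.transport, cycles=cfg.cycles)
    return mesh, wf, flow, no


def make_study(cfg: RunConfig, outdir) -> dict:
    """Write a self-contained study directory runnable end-to-end.

    Contents: ``config.yaml``, ``waveform.csv``, ``ilt.csv`` and a README
    manifest.  Producing the ILT map requires the NO field, so the full
    simulation is run once here with the configured resolution.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = make_waveform(cfg.waveform_preset, cfg.period_s, cfg.peak_velocity)
    mesh, wf, flow, no = run_simulation(cfg)
    ilt, truth = make_ilt_from_no(no, cfg, flow=flow)
    to_yaml(cfg, outdir / "config.yaml")
    write_waveform_csv(outdir / "waveform.csv", samples)
    ilt.to_csv(outdir / "ilt.csv")
    truth.to_csv(outdir / "ground_truth.csv", index=False)
    (outdir / "README.md").write_text(
        "# Synthetic study bundle\n\n"
        f"- generator: hemano {__version__}\n"
        f"- seed: {cfg.seed}\n"
        f"- ilt model: {cfg.ilt.model} (coupled to {cfg.ilt.couple_to})\n"
        "- files: config.yaml, waveform.csv, ilt.csv, ground_truth.csv\n"
    )
    return {
        "dir": outdir,
        "config": cfg,
        "mesh": mesh,
        "waveform": wf,
        "flow": flow,
        "no": no,
        "ilt": ilt,
        "ground_truth": truth,
    }
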