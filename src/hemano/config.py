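"""Run configuration: schema, validation, YAML round-trip.

A study is fully described by one YAML file.  Lengths in the geometry and
analysis blocks carry an explicit ``_mm`` unit tag; fluid and transport
constants are SI (with nM-based reaction rates), matching the package-wide
units policy (SI internally, mm/nM at I/O boundaries).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from .exceptions import ConfigError
from .flow import FluidProperties
from .geometry import MODES, PLANAR, MeshResolution, VesselGeometry
from .no_transport import TransportParameters

ILT_MODELS = ("none", "annular", "one-sided")
WAVEFORM_PRESETS = ("constant", "sinusoidal", "triphasic")


@dataclass(frozen=True)
class ILTGenerationConfig:
    """How the synthetic ILT map is tied to the computed NO field.

    Per ILT-zone section the thrombus area (mm^2) is drawn as
    max(0, alpha + beta * TAcNO + eps), eps ~ N(0, sigma^2); ``sigma`` is
    either given directly or derived from ``target_r2`` via the linear-model
    identity R^2 = var(beta x) / (var(beta x) + sigma^2).
    """

    model: str = "one-sided"
    beta_mm2_per_nM: float = -30.0
    target_r2: float = 0.8
    sigma_mm2: float | None = None
    base_area_mm2: float = 30.0
    halfspan_mm: float = 30.0
    placement: str = "low-no"  # or "bulge": window centred on the bulge
    couple_to: str = "tacno"  # or "tawss": WSS-coupled discriminability mode


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one study (generation + simulation + analysis)."""

    seed: int = 0
    mode: str = PLANAR
    geometry: VesselGeometry = field(
        default_factory=lambda: VesselGeometry(
            axial_length=0.100,
            inlet_radius=0.010,
            bulge_amplitude=0.008,
            bulge_center=0.050,
            bulge_width=0.012,
            asymmetry=0.6,
            wall_thickness=0.002,
        )
    )
    resolution: MeshResolution = field(
        default_factory=lambda: MeshResolution(
            n_axial=90, n_lumen=28, n_wall=10, grading=1.15
        )
    )
    fluid: FluidProperties = field(default_factory=FluidProperties)
    transport: TransportParameters = field(default_factory=TransportParameters)
    waveform_preset: str = "triphasic"
    period_s: float = 1.0
    peak_velocity: float = 0.6
    n_harmonics: int = 8
    cycles: int = 5
    steps_per_cycle: int = 100
    flow_grading: float = 1.05
    section_spacing_mm: float = 5.0
    representative_spacing_mm: float = 20.0
    average: str = "perimeter"
    ilt: ILTGenerationConfig = field(default_factory=ILTGenerationConfig)

    def validate(self) -> "RunConfig":
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.waveform_preset not in WAVEFORM_PRESETS:
            raise ConfigError(
                f"waveform preset must be one of {WAVEFORM_PRESETS}, "
                f"got {self.waveform_preset!r}"
            )
        if self.ilt.model not in ILT_MODELS:
            raise ConfigError(
                f"ilt model must be one of {ILT_MODELS}, got {self.ilt.model!r}"
            )
        if self.period_s <= 0 or self.cycles < 1 or self.steps_per_cycle < 8:
            raise ConfigError("invalid solver block: period, cycles or steps")
        if self.section_spacing_mm <= 0:
            raise ConfigError("section spacing must be positive")
        if self.ilt.sigma_mm2 is not None and self.ilt.sigma_mm2 < 0:
            raise ConfigError("ilt sigma must be >= 0")
        if not 0 < self.ilt.target_r2 < 1:
            raise ConfigError("ilt target_r2 must lie in (0, 1)")
        if self.ilt.placement not in ("low-no", "bulge"):
            raise ConfigError("ilt placement must be 'low-no' or 'bulge'")
        return self


def _geometry_to_dict(g: VesselGeometry) -> dict:
    return {
        "axial_length_mm": g.axial_length * 1e3,
        "inlet_radius_mm": g.inlet_radius * 1e3,
        "bulge_amplitude_mm": g.bulge_amplitude * 1e3,
        "bulge_center_mm": g.bulge_center * 1e3,
        "bulge_width_mm": g.bulge_width * 1e3,
        "asymmetry": g.asymmetry,
        "wall_thickness_mm": g.wall_thickness * 1e3,
    }


def _geometry_from_dict(d: dict) -> VesselGeometry:
    try:
        return VesselGeometry(
            axial_length=float(d["axial_length_mm"]) * 1e-3,
            inlet_radius=float(d["inlet_radius_mm"]) * 1e-3,
            bulge_amplitude=float(d.get("bulge_amplitude_mm", 0.0)) * 1e-3,
            bulge_center=float(d["bulge_center_mm"]) * 1e-3
            if d.get("bulge_center_mm") is not None
            else None,
            bulge_width=float(d.get("bulge_width_mm", 10.0)) * 1e-3,
            asymmetry=float(d.get("asymmetry", 0.0)),
            wall_thickness=float(d.get("wall_thickness_mm", 2.0)) * 1e-3,
        )
    except (KeyError, TypeError, ValueError) as e:
        raise ConfigError(f"invalid geometry block: {e}") from e


def to_yaml(cfg: RunConfig, path) -> None:
    cfg.validate()
    doc = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "geometry": _geometry_to_dict(cfg.geometry),
        "mesh": asdict(cfg.resolution),
        "fluid": asdict(cfg.fluid),
        "transport": asdict(cfg.transport),
        "waveform": {
            "preset": cfg.waveform_preset,
            "period_s": cfg.period_s,
            "peak_velocity_m_per_s": cfg.peak_velocity,
            "n_harmonics": cfg.n_harmonics,
        },
        "solver": {
            "cycles": cfg.cycles,
            "steps_per_cycle": cfg.steps_per_cycle,
            "flow_grading": cfg.flow_grading,
        },
        "analysis": {
            "section_spacing_mm": cfg.section_spacing_mm,
            "representative_spacing_mm": cfg.representative_spacing_mm,
            "average": cfg.average,
        },
        "ilt": {
            "model": cfg.ilt.model,
            "beta_mm2_per_nM": cfg.ilt.beta_mm2_per_nM,
            "target_r2": cfg.ilt.target_r2,
            "sigma_mm2": cfg.ilt.sigma_mm2,
            "base_area_mm2": cfg.ilt.base_area_mm2,
            "halfspan_mm": cfg.ilt.halfspan_mm,
            "placement": cfg.ilt.placement,
            "couple_to": cfg.ilt.couple_to,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def from_yaml(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config {path} is not a YAML mapping")
    try:
        wf = doc.get("waveform", {})
        solver = doc.get("solver", {})
        analysis = doc.get("analysis", {})
        ilt = doc.get("ilt", {})
        cfg = RunConfig(
            seed=int(doc.get("seed", 0)),
            mode=doc.get("mode", PLANAR),
            geometry=_geometry_from_dict(doc.get("geometry", {})),
            resolution=MeshResolution(**doc.get("mesh", {})),
            fluid=FluidProperties(**doc.get("fluid", {})),
            transport=TransportParameters(**doc.get("transport", {})),
            waveform_preset=wf.get("preset", "triphasic"),
            period_s=float(wf.get("period_s", 1.0)),
            peak_velocity=float(wf.get("peak_velocity_m_per_s", 0.6)),
            n_harmonics=int(wf.get("n_harmonics", 8)),
            cycles=int(solver.get("cycles", 5)),
            steps_per_cycle=int(solver.get("steps_per_cycle", 100)),
            flow_grading=float(solver.get("flow_grading", 1.05)),
            section_spacing_mm=float(analysis.get("section_spacing_mm", 5.0)),
            representative_spacing_mm=float(
                analysis.get("representative_spacing_mm", 20.0)
            ),
            average=analysis.get("average", "perimeter"),
            ilt=ILTGenerationConfig(
                model=ilt.get("model", "one-sided"),
                beta_mm2_per_nM=float(ilt.get("beta_mm2_per_nM", -30.0)),
                target_r2=float(ilt.get("target_r2", 0.8)),
                sigma_mm2=None
                if ilt.get("sigma_mm2") is None
                else float(ilt.get("sigma_mm2")),
                base_area_mm2=float(ilt.get("base_area_mm2", 30.0)),
                halfspan_mm=float(ilt.get("halfspan_mm", 30.0)),
                placement=ilt.get("placement", "low-no"),
                couple_to=ilt.get("couple_to", "tacno"),
            ),
        )
    except ConfigError:
        raise
    except Exception as e:
        raise ConfigError(f"schema-invalid config {path}: {e}") from e
    return cfg.validate()


def with_seed(cfg: RunConfig, seed: int) -> RunConfig:
    return replace(cfg, seed=seed)
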