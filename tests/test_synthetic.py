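"""Synthetic study generation: presets, coupling, determinism, recovery."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

from hemano import correlate_area_no
from hemano.config import ILTGenerationConfig, RunConfig
from hemano.exceptions import ContractError
from hemano.geometry import MeshResolution
from hemano.synthetic import (
    derive_sigma,
    draw_section_areas,
    ilt_zone_sections,
    make_ilt_from_no,
    make_study,
    make_waveform,
)
from hemano.waveform import fit_waveform


class TestWaveformPresets:
    def test_constant(self):
        s = make_waveform("constant", peak_velocity=0.2)
        assert np.allclose(s[:, 1], 0.2)

    def test_sinusoidal_zero_mean_single_harmonic(self):
        s = make_waveform("sinusoidal", peak_velocity=0.5)
        assert abs(s[:, 1].mean()) < 1e-12
        wf = fit_waveform(s, K=4, period=1.0)
        assert abs(wf.b[0]) == pytest.approx(0.5, abs=1e-10)
        assert np.abs(wf.b[1:]).max() < 1e-10

    def test_triphasic_has_one_reversal_interval(self):
        s = make_waveform("triphasic")
        neg = (s[:, 1] < -1e-12).astype(int)
        onsets = np.sum(np.diff(neg) == 1)
        assert onsets == 1
        assert s[:, 1].max() == pytest.approx(0.6, rel=0.02)  # sampled peak
        assert s[:, 1].min() < -0.1  # early-diastolic reversal
        assert s[:, 1].mean() > 0  # net forward flow

    def test_unknown_preset_rejected(self):
        with pytest.raises(ContractError):
            make_waveform("biphasic")


class TestAreaDraw:
    X = np.linspace(8.0, 12.0, 13)

    def test_sigma_from_target_r2(self):
        sigma = derive_sigma(self.X, -120.0, 0.8)
        var_sig = np.var(-120.0 * self.X)
        assert var_sig / (var_sig + sigma**2) == pytest.approx(0.8)

    def test_noiseless_draw_hits_base_area_at_max_tacno(self):
        cfg = RunConfig(ilt=ILTGenerationConfig(sigma_mm2=0.0))
        rng = np.random.default_rng(0)
        areas, noiseless, alpha, sigma = draw_section_areas(self.X, cfg, rng)
        assert sigma == 0.0
        assert areas.min() == pytest.approx(cfg.ilt.base_area_mm2)
        assert np.allclose(areas, noiseless)

    def test_positive_beta_warns(self):
        cfg = RunConfig(ilt=ILTGenerationConfig(beta_mm2_per_nM=10.0, sigma_mm2=1.0))
        with pytest.warns(UserWarning, match="beta"):
            draw_section_areas(self.X, cfg, np.random.default_rng(0))

    @pytest.mark.filterwarnings("ignore:beta")
    def test_beta_zero_slope_estimates_center_on_zero(self):
        """With no true coupling the fitted slope is centred on zero."""
        cfg = RunConfig(ilt=ILTGenerationConfig(beta_mm2_per_nM=1e-12, sigma_mm2=30.0))
        rng = np.random.default_rng(42)
        slopes = []
        for _ in range(200):
            areas, *_ = draw_section_areas(self.X, cfg, rng)
            fit = correlate_area_no(
                pd.DataFrame(
                    {"group": "ILT", "tacno_nM": self.X, "thrombus_area_mm2": areas}
                )
            )
            slopes.append(fit.slope)
        # standard error of the mean slope: sigma / (sd(x) sqrt(n_rep * n))
        sem = 30.0 / (np.std(self.X) * np.sqrt(200 * len(self.X)))
        assert abs(np.mean(slopes)) < 4 * sem


class TestStudyBundle:
    def test_zone_has_13_sections(self, study_config):
        assert len(ilt_zone_sections(study_config)) == 13

    def test_bundle_files_written(self, study):
        d = study["dir"]
        for name in ("config.yaml", "waveform.csv", "ilt.csv", "ground_truth.csv", "README.md"):
            assert (d / name).exists(), name

    def test_noiseless_coupling_gives_perfect_fit(self, study):
        """sigma = 0: correlate on the generated areas returns the exact
        generator slope with R^2 = 1."""
        cfg = dataclasses.replace(
            study["config"], ilt=ILTGenerationConfig(sigma_mm2=0.0)
        )
        ilt, truth = make_ilt_from_no(study["no"], cfg, flow=study["flow"])
        fit = correlate_area_no(
            pd.DataFrame(
                {
                    "group": "ILT",
                    "tacno_nM": truth["tacno_nM"],
                    "thrombus_area_mm2": truth["area_mm2"],
                }
            )
        )
        assert fit.slope == pytest.approx(cfg.ilt.beta_mm2_per_nM, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_one_sided_mode_places_thrombus_on_low_no_side(self, study):
        from hemano.ilt import line_averaged_tacno

        ilt = study["ilt"]
        no = study["no"]
        for k, z in enumerate(ilt.z):
            h = ilt.thickness[k]
            if h.max() <= 0:
                continue
            assert (h > 0).sum() == 1  # one-sided by construction
            side_vals = {
                s: line_averaged_tacno(no, z, s) for s in ilt.directions
            }
            occupied = ilt.directions[int(np.argmax(h))]
            assert occupied == min(side_vals, key=side_vals.get)

    def test_ilt_model_none_disables_correlation(self, study, tmp_path):
        import shutil

        from hemano import pipeline

        src = study["dir"]
        dst = tmp_path / "none_study"
        shutil.copytree(src, dst)
        cfg = dataclasses.replace(
            study["config"], ilt=ILTGenerationConfig(model="none")
        )
        ilt, _ = make_ilt_from_no(study["no"], cfg)
        ilt.to_csv(dst / "ilt.csv")
        results = pipeline.stage_analyze(dst)
        assert results["fit"].get("status") == "not-applicable"
        assert results["groups"]["ILT"]["n"] == 0

    def test_wss_coupled_mode_runs(self, study):
        cfg = dataclasses.replace(
            study["config"],
            ilt=ILTGenerationConfig(couple_to="tawss", sigma_mm2=0.0),
        )
        ilt, truth = make_ilt_from_no(study["no"], cfg, flow=study["flow"])
        assert (truth["area_mm2"] >= 0).all()
        assert ilt.thickness.max() > 0


class TestDeterminism:
    TINY = RunConfig(
        seed=3,
        resolution=MeshResolution(n_axial=36, n_lumen=14, n_wall=6),
        steps_per_cycle=24,
        cycles=2,
    )

    def test_same_seed_byte_identical_bundle(self, tmp_path):
        a = make_study(self.TINY, tmp_path / "a")
        b = make_study(self.TINY, tmp_path / "b")
        for name in ("config.yaml", "waveform.csv", "ilt.csv", "ground_truth.csv"):
            assert filecmp.cmp(a["dir"] / name, b["dir"] / name, shallow=False), name

    def test_different_seed_changes_ilt_only_in_noise(self, tmp_path):
        a = make_study(self.TINY, tmp_path / "s3")
        b = make_study(dataclasses.replace(self.TINY, seed=4), tmp_path / "s4")
        assert filecmp.cmp(a["dir"] / "waveform.csv", b["dir"] / "waveform.csv", shallow=False)
        ta = pd.read_csv(a["dir"] / "ground_truth.csv")
        tb = pd.read_csv(b["dir"] / "ground_truth.csv")
        assert np.allclose(ta["tacno_nM"], tb["tacno_nM"])  # same physics
        assert not np.allclose(ta["area_mm2"], tb["area_mm2"])  # new noise
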