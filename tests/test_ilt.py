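"""ILT sectioning, thrombus areas, correlation and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hemano import (
    ILTMap,
    VesselGeometry,
    compare_ilt_groups,
    correlate_area_no,
    section_geometry,
    thrombus_area,
)
from hemano.exceptions import ContractError, DataError
from hemano.ilt import (
    directional_analysis,
    line_averaged_tacno,
    section_positions,
    section_table,
    thickness_for_area,
)


GEOM60 = VesselGeometry(axial_length=0.060, inlet_radius=0.010)


def flat_map(geom, h_by_z, directions=("upper",)):
    z = np.linspace(0, geom.axial_length, 61)
    h = np.array([[h_by_z(zi)] * len(directions) for zi in z])
    return ILTMap(z=z, directions=directions, thickness=h)


class TestSectioning:
    def test_sixty_mm_at_five_mm_gives_13_sections(self):
        assert len(section_positions(GEOM60, 5e-3)) == 13

    def test_all_non_ilt_for_zero_map(self):
        table = section_geometry(GEOM60, flat_map(GEOM60, lambda z: 0.0))
        assert (table["group"] == "non-ILT").all()
        assert len(table) == 13

    def test_support_of_h_defines_ilt_group(self):
        ilt = flat_map(GEOM60, lambda z: 2e-3 if 0.020 <= z <= 0.040 else 0.0)
        table = section_geometry(GEOM60, ilt)
        ilt_z = table[table["group"] == "ILT"]["z_mm"].to_numpy()
        assert np.array_equal(ilt_z, [20, 25, 30, 35, 40])

    def test_sub_threshold_thickness_ignored(self):
        ilt = flat_map(GEOM60, lambda z: 0.05e-3)  # 0.05 mm < 0.1 mm threshold
        table = section_geometry(GEOM60, ilt)
        assert (table["group"] == "non-ILT").all()

    def test_spacing_larger_than_segment_rejected(self):
        with pytest.raises(ContractError):
            section_positions(GEOM60, 0.1)

    def test_every_section_in_exactly_one_group(self):
        ilt = flat_map(GEOM60, lambda z: 3e-3 if z > 0.03 else 0.0)
        table = section_geometry(GEOM60, ilt)
        assert set(table["group"]).issubset({"ILT", "non-ILT"})
        assert len(table) == int(np.floor(0.060 / 0.005)) + 1


class TestThrombusArea:
    def test_zero_thickness_zero_area(self):
        assert thrombus_area(0.03, GEOM60, flat_map(GEOM60, lambda z: 0.0)) == 0.0

    def test_uniform_annulus_closed_form(self):
        # lumen 10 mm, thrombus-free radius 15 mm: pi (15^2 - 10^2) = 392.70 mm^2
        ilt = flat_map(GEOM60, lambda z: 5e-3)
        a = thrombus_area(0.03, GEOM60, ilt) * 1e6
        assert a == pytest.approx(np.pi * (15**2 - 10**2), rel=1e-9)
        assert a == pytest.approx(392.70, abs=0.01)

    def test_two_direction_piecewise_sum(self):
        # upper h=3 mm, lower h=1 mm on a 10 mm lumen: half-annuli sum
        z = np.linspace(0, GEOM60.axial_length, 5)
        h = np.column_stack([np.full(5, 1e-3), np.full(5, 3e-3)])
        ilt = ILTMap(z=z, directions=("lower", "upper"), thickness=h)
        a = thrombus_area(0.03, GEOM60, ilt)
        hand = (np.pi / 2) * ((11e-3) ** 2 - (10e-3) ** 2) + (np.pi / 2) * (
            (13e-3) ** 2 - (10e-3) ** 2
        )
        assert a == pytest.approx(hand, rel=1e-3)

    def test_area_monotone_in_thickness(self):
        areas = [
            thrombus_area(0.03, GEOM60, flat_map(GEOM60, lambda z, h=h: h))
            for h in (1e-3, 2e-3, 4e-3)
        ]
        assert areas[0] < areas[1] < areas[2]

    def test_thickness_area_roundtrip(self):
        r = np.array([0.010, 0.012])
        h = thickness_for_area(3e-4, r)
        area = (np.pi / 2) * (((r + h) ** 2 - r**2)).sum()
        assert area == pytest.approx(3e-4, rel=1e-12)

    def test_excessive_thickness_rejected(self):
        ilt = flat_map(GEOM60, lambda z: 20e-3)  # thicker than the lumen radius
        with pytest.raises(DataError):
            thrombus_area(0.03, GEOM60, ilt)


class TestCorrelation:
    @staticmethod
    def table(x, y, group="ILT"):
        return pd.DataFrame(
            {"group": group, "tacno_nM": x, "thrombus_area_mm2": y}
        )

    def test_exact_line_recovered(self):
        fit = correlate_area_no(self.table([1, 2, 3], [5, 3, 1]))
        assert fit.slope == pytest.approx(-2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n == 3

    def test_constant_response_r2_zero(self):
        fit = correlate_area_no(self.table([1, 2, 3, 4], [7, 7, 7, 7]))
        assert fit.r_squared == 0.0
        assert fit.p_value == 1.0

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 5, 20)
        y = 100 - 12 * x + rng.normal(0, 3, 20)
        fit = correlate_area_no(self.table(x, y))
        ref = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope)
        assert fit.r_squared == pytest.approx(ref.rvalue**2)
        assert fit.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert fit.f_stat == pytest.approx(ref.rvalue**2 / (1 - ref.rvalue**2) * 18)

    def test_too_few_sections_rejected(self):
        with pytest.raises(ContractError):
            correlate_area_no(self.table([1, 2], [3, 4]))

    def test_degenerate_x_rejected(self):
        with pytest.raises(ContractError):
            correlate_area_no(self.table([2, 2, 2], [1, 2, 3]))

    def test_non_ilt_sections_excluded_by_default(self):
        t = pd.concat(
            [
                self.table([1, 2, 3], [5, 3, 1]),
                self.table([9], [999], group="non-ILT"),
            ]
        )
        fit = correlate_area_no(t)
        assert fit.n == 3 and fit.r_squared == pytest.approx(1.0)


class TestGroupComparison:
    def test_identical_no_gives_zero_difference(self):
        t = pd.DataFrame(
            {
                "group": ["ILT", "ILT", "non-ILT"],
                "tacno_nM": [4.0, 4.0, 4.0],
                "thrombus_area_mm2": [10, 20, 0],
            }
        )
        out = compare_ilt_groups(t)
        assert out["difference_nM"] == 0.0 and out["complete"]

    def test_single_section_groups(self):
        t = pd.DataFrame(
            {"group": ["ILT", "non-ILT"], "tacno_nM": [2.0, 5.0],
             "thrombus_area_mm2": [10, 0]}
        )
        out = compare_ilt_groups(t)
        assert out["ILT"]["mean_tacno_nM"] == 2.0
        assert out["non-ILT"]["mean_tacno_nM"] == 5.0

    def test_empty_group_flagged_partial(self):
        t = pd.DataFrame(
            {"group": ["ILT", "ILT"], "tacno_nM": [2.0, 3.0],
             "thrombus_area_mm2": [10, 12]}
        )
        out = compare_ilt_groups(t)
        assert not out["complete"]
        assert np.isnan(out["difference_nM"])


class TestDirectional:
    def test_sections_outside_support_rejected(self, analyzed_study):
        no = analyzed_study["no"]
        cfg = analyzed_study["config"]
        ilt = analyzed_study["ilt"]
        with pytest.raises(ContractError):
            directional_analysis(
                no, cfg.geometry, ilt, sections=np.array([0.095, 0.100])
            )

    def test_unknown_direction_rejected(self, analyzed_study):
        with pytest.raises(ContractError):
            line_averaged_tacno(analyzed_study["no"], 0.05, "sideways")

    def test_one_sided_map_ranks_directions(self, analyzed_study):
        """One-sided generated thrombus sits on the low-NO side, so the
        thickest direction must show the lower line-averaged TAcNO."""
        out = directional_analysis(
            analyzed_study["no"],
            analyzed_study["config"].geometry,
            analyzed_study["ilt"],
        )
        assert out["mean_tacno_thickest"] < out["mean_tacno_thinnest"]
        assert len(out["per_section"]) == 3


class TestEndToEndTable:
    def test_section_table_bookkeeping(self, analyzed_study):
        cfg = analyzed_study["config"]
        table = section_table(
            cfg.geometry, analyzed_study["ilt"], analyzed_study["no"]
        )
        assert len(table) == int(np.floor(cfg.geometry.axial_length / 5e-3)) + 1
        ilt_rows = table[table["group"] == "ILT"]
        assert (ilt_rows["thrombus_area_mm2"] > 0).all()
        non_rows = table[table["group"] == "non-ILT"]
        assert (non_rows["thrombus_area_mm2"] == 0).all()
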