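import numpy as np
import pytest
from shapely.geometry import box

from benthosdm.grids import GridSurface, Zone, ZoneSet
from benthosdm.zoning import (
    PRECISION_LEVELS,
    PROBABILITY_LEVELS,
    ComboMap,
    combo_maps,
    precision_terciles,
    sensitivity_report,
    zonal_area,
)


def grid(vals):
    return GridSurface(np.asarray(vals, dtype=float), cell_size=2.0)


def full_footprint(template):
    return template.like(np.where(template.mask, 1.0, np.nan))


class TestPrecisionTerciles:
    def test_interpolated_order_statistic_oracle(self):
        cov = grid(np.arange(0.1, 1.0, 0.1).reshape(3, 3))
        cls = precision_terciles(cov, full_footprint(cov))
        # positions 1+(n-1)p with n=9: 11/3 and 19/3 -> 0.3667 / 0.6333
        assert cls.q33 == pytest.approx(0.3667, abs=5e-5)
        assert cls.q67 == pytest.approx(0.6333, abs=5e-5)
        assert cls.max == pytest.approx(0.9)

    def test_constant_cov_collapses_breakpoints(self):
        cov = grid(np.full((4, 4), 0.42))
        cls = precision_terciles(cov, full_footprint(cov))
        assert cls.q33 == cls.q67 == cls.max == pytest.approx(0.42)

    def test_normal_cov_quantiles_match_theory(self, rng):
        # CoV ~ N(0.47, 0.12): 33rd/67th percentiles at 0.47 -+ 0.4399*0.12
        n = 110 * 110
        vals = rng.normal(0.47, 0.12, size=n).reshape(110, 110)
        cov = GridSurface(vals, cell_size=2.0)
        cls = precision_terciles(cov, full_footprint(cov))
        from scipy.stats import norm

        z = norm.ppf(2 / 3)
        assert cls.q33 == pytest.approx(0.47 - z * 0.12, abs=0.02)
        assert cls.q67 == pytest.approx(0.47 + z * 0.12, abs=0.02)

    def test_empty_footprint_rejected(self):
        cov = grid(np.full((3, 3), 0.5))
        empty = cov.like(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="empty"):
            precision_terciles(cov, empty)


class TestComboMaps:
    def hand_setup(self):
        prob = grid(
            [[0.01, 0.05, 0.10, 0.20, 0.30, 0.40],
             [0.02, 0.06, 0.12, 0.22, 0.32, 0.42],
             [0.03, 0.07, 0.14, 0.24, 0.34, 0.44],
             [0.01, 0.08, 0.16, 0.26, 0.36, 0.46],
             [0.02, 0.09, 0.18, 0.28, 0.38, 0.48],
             [0.03, 0.04, 0.19, 0.29, 0.39, 0.50]]
        )
        cov = grid(np.linspace(0.1, 1.8, 36).reshape(6, 6))
        return prob, cov

    def test_nine_maps_with_cumulative_cutoffs(self):
        prob, cov = self.hand_setup()
        combos = combo_maps(prob, cov, (0.04, 0.17, 0.29))
        assert len(combos) == 9
        assert [c.probability_level for c in combos[:3]] == ["low"] * 3
        for level in PROBABILITY_LEVELS:
            cs = {c.precision_level: c for c in combos if c.probability_level == level}
            assert cs["high"].cov_cutoff <= cs["moderate"].cov_cutoff <= cs["low"].cov_cutoff

    def test_masks_match_manual_set_intersection(self):
        prob, cov = self.hand_setup()
        combos = combo_maps(prob, cov, (0.04, 0.17, 0.29))
        for c in combos:
            expected = ((prob.values >= c.probability_threshold)
                        & (cov.values <= c.cov_cutoff)).astype(float)
            np.testing.assert_allclose(c.mask.values, expected)
            assert c.area_m2 == pytest.approx(expected.sum() * 4.0)

    def test_nesting_within_probability_level(self):
        prob, cov = self.hand_setup()
        combos = combo_maps(prob, cov, (0.04, 0.17, 0.29))
        for level in PROBABILITY_LEVELS:
            cs = {c.precision_level: c.mask.values for c in combos
                  if c.probability_level == level}
            assert np.all(cs["moderate"][cs["high"] == 1] == 1)
            assert np.all(cs["low"][cs["moderate"] == 1] == 1)

    def test_low_precision_mask_equals_footprint(self):
        prob, cov = self.hand_setup()
        combos = combo_maps(prob, cov, (0.04, 0.17, 0.29))
        for c in combos:
            if c.precision_level == "low":
                footprint = (prob.values >= c.probability_threshold).astype(float)
                np.testing.assert_allclose(c.mask.values, footprint)

    def test_uniform_cov_makes_all_precisions_equal_footprint(self):
        prob, _ = self.hand_setup()
        cov = grid(np.full((6, 6), 0.5))
        combos = combo_maps(prob, cov, (0.04, 0.17, 0.29))
        for level in PROBABILITY_LEVELS:
            masks = [c.mask.values for c in combos if c.probability_level == level]
            np.testing.assert_allclose(masks[0], masks[1])
            np.testing.assert_allclose(masks[1], masks[2])

    def test_footprints_nest_across_probability_levels(self):
        prob, cov = self.hand_setup()
        combos = {(c.probability_level, c.precision_level): c
                  for c in combo_maps(prob, cov, (0.04, 0.17, 0.29))}
        hi = combos[("high", "low")].mask.values
        mod = combos[("moderate", "low")].mask.values
        lo = combos[("low", "low")].mask.values
        assert np.all(mod[hi == 1] == 1)
        assert np.all(lo[mod == 1] == 1)

    def test_empty_footprint_warns_and_yields_zero_area(self, caplog):
        prob, cov = self.hand_setup()
        with caplog.at_level("WARNING"):
            combos = combo_maps(prob, cov, (0.04, 0.17, 0.99))
        high = [c for c in combos if c.probability_level == "high"]
        assert all(c.area_m2 == 0 for c in high)
        assert any("empty footprint" in r.message for r in caplog.records)

    def test_unordered_thresholds_rejected(self):
        prob, cov = self.hand_setup()
        with pytest.raises(ValueError, match="ordered"):
            combo_maps(prob, cov, (0.29, 0.17, 0.04))


class TestZonalArea:
    def all_ones_combo(self, shape=(10, 10)):
        mask = grid(np.ones(shape))
        return ComboMap("low", "low", 0.04, 1.0, mask, float(np.prod(shape)) * 4.0)

    def test_counting_oracle(self):
        combo = self.all_ones_combo()
        # one 5x5-cell zone: cells are 2 m, so the zone box spans 10 m
        zones = ZoneSet([Zone("z1", "exclusion", box(0, 0, 10, 10))])
        rep = zonal_area(combo, zones)
        inside = rep[rep.zone_id == "z1"].area_m2.iloc[0]
        outside = rep[rep.zone_id == "outside"].area_m2.iloc[0]
        assert inside == pytest.approx(25 * 4.0)
        assert outside == pytest.approx(100 * 4.0 - 100.0)

    def test_zone_tiling_grid_leaves_no_outside(self):
        combo = self.all_ones_combo()
        zones = ZoneSet([Zone("all", "exclusion", box(0, 0, 20, 20))])
        rep = zonal_area(combo, zones)
        assert rep[rep.zone_id == "outside"].area_m2.iloc[0] == 0.0

    def test_empty_mask_gives_zero_everywhere(self):
        mask = grid(np.zeros((6, 6)))
        combo = ComboMap("high", "high", 0.29, 0.4, mask, 0.0)
        zones = ZoneSet([Zone("z", "operation", box(0, 0, 4, 4))])
        rep = zonal_area(combo, zones)
        assert (rep.area_m2 == 0).all()

    def test_area_conservation(self, rng):
        mask = grid(rng.binomial(1, 0.4, size=(12, 12)))
        combo = ComboMap("low", "moderate", 0.04, 0.9, mask,
                         float(np.nansum(mask.values)) * 4.0)
        zones = ZoneSet([Zone("a", "exclusion", box(0, 0, 8, 8)),
                         Zone("b", "operation", box(10, 10, 20, 18))])
        rep = zonal_area(combo, zones)
        assert rep.area_m2.sum() == pytest.approx(combo.area_m2)

    def test_overlapping_zones_rejected(self):
        combo = self.all_ones_combo()
        zones = ZoneSet([Zone("a", "exclusion", box(0, 0, 8, 8)),
                         Zone("b", "operation", box(4, 4, 12, 12))])
        with pytest.raises(ValueError, match="overlap"):
            zonal_area(combo, zones)


class TestSensitivityReport:
    def make_reports(self, rng):
        prob = grid(rng.random((8, 8)))
        cov = grid(rng.random((8, 8)) + 0.05)
        combos = combo_maps(prob, cov, (0.2, 0.4, 0.6))
        zones = ZoneSet([Zone("z1", "exclusion", box(0, 0, 8, 8)),
                         Zone("z2", "operation", box(10, 0, 16, 8))])
        reports = [zonal_area(c, zones) for c in combos]
        return combos, reports

    def test_identical_combos_have_unit_ratios(self):
        mask = grid(np.ones((4, 4)))
        combos = [ComboMap("low", p, 0.1, 1.0, mask, 64.0) for p in PRECISION_LEVELS]
        zones = ZoneSet([Zone("z", "exclusion", box(0, 0, 4, 4))])
        reports = [zonal_area(c, zones) for c in combos]
        rep = sensitivity_report(reports, combos)
        assert all(r == pytest.approx(1.0) for r in rep["area_ratios"].values())

    def test_area_monotone_in_both_threshold_axes(self, rng):
        combos, reports = self.make_reports(rng)
        rep = sensitivity_report(reports, combos)
        per = rep["per_combo"]
        for prec in PRECISION_LEVELS:
            assert (per[f"p_low_prec_{prec}"]["total_area_m2"]
                    >= per[f"p_moderate_prec_{prec}"]["total_area_m2"]
                    >= per[f"p_high_prec_{prec}"]["total_area_m2"])
        for plevel in PROBABILITY_LEVELS:
            assert (per[f"p_{plevel}_prec_low"]["total_area_m2"]
                    >= per[f"p_{plevel}_prec_moderate"]["total_area_m2"]
                    >= per[f"p_{plevel}_prec_high"]["total_area_m2"])

    def test_zone_presence_count_matches_recount(self, rng):
        combos, reports = self.make_reports(rng)
        rep = sensitivity_report(reports, combos)
        for combo, frame in zip(combos, reports):
            inside = frame[frame.zone_id != "outside"]
            assert (rep["per_combo"][combo.name]["zones_with_presence"]
                    == int((inside.area_m2 > 0).sum()))

    def test_conservation_inside_plus_outside(self, rng):
        combos, reports = self.make_reports(rng)
        rep = sensitivity_report(reports, combos)
        for c in combos:
            d = rep["per_combo"][c.name]
            assert d["inside_area_m2"] + d["outside_area_m2"] == pytest.approx(
                d["total_area_m2"]
            )
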