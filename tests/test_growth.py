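"""The growth statistic: frequencies, truncated OLS fits, escaper
correction, normalization, timecourse and uncorrected comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from titracrispr import (
    CountTensor,
    GrowthFit,
    compute_frequency,
    escaper_correct,
    fit_relative_growth,
    normalize_growth,
    pick_reference_negc,
    timecourse_growth,
    uncorrected_growth,
)
from titracrispr.growth import FrequencySeries

from conftest import planted_tensor


def series(f, depths, gens=None, nc=None):
    f = np.asarray(f, float)
    depths = np.asarray(depths)
    gens = np.arange(len(f), dtype=float) if gens is None else np.asarray(gens, float)
    nc = np.full(len(f), 1000) if nc is None else np.asarray(nc)
    return FrequencySeries("g", "bc", gens, f, depths, nc)


class TestReference:
    def test_median_slope_wins(self):
        ct = planted_tensor({"negC_a": -0.1, "negC_b": 0.0, "negC_c": 0.1})
        ref = pick_reference_negc(ct, ["negC_a", "negC_b", "negC_c"])
        assert ref == "negC_b"

    def test_tie_breaks_to_first_id(self):
        ct = planted_tensor({"negC_a": 0.0, "negC_b": 0.0, "negC_c": 0.0})
        assert pick_reference_negc(ct, ["negC_c", "negC_a", "negC_b"]) == "negC_a"

    def test_no_coverage_is_an_error(self):
        ct = planted_tensor({"negC_a": -3.0, "negC_b": -3.0, "negC_c": -3.0},
                            base=5.0)
        # all three decay to zero counts at late timepoints
        with pytest.raises(ValueError):
            pick_reference_negc(ct, ["negC_a", "negC_b", "negC_c"])


class TestFrequency:
    def test_worked_log_ratio(self):
        # guide 100 -> 400, reference 100 -> 200 over one step: f = 1
        hours = np.array([0.0, 2.0])
        counts = np.array([[[100, 400]], [[100, 200]]], dtype=np.int64)
        ct = CountTensor(["g", "ref"], ["b1"], hours, counts)
        fs = compute_frequency(ct, "ref", 1.0)
        g = next(s for s in fs if s.guide_id == "g")
        assert g.f[1] == pytest.approx(1.0)

    def test_reference_frequency_is_zero(self):
        ct = planted_tensor({"g1": -0.4, "g2": 0.1})
        fs = compute_frequency(ct, "negC_ref", 1.0)
        ref = next(s for s in fs if s.guide_id == "negC_ref")
        assert np.allclose(ref.f, 0.0)

    def test_matches_direct_log_ratio_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 10_000, size=(6, 3, 5)).astype(np.int64)
        hours = np.array([0.0, 2, 4, 6, 8])
        guides = [f"g{i}" for i in range(5)] + ["ref"]
        ct = CountTensor(guides, ["b1", "b2", "b3"], hours, counts)
        dph = 0.94
        for fs in compute_frequency(ct, "ref", dph):
            gi = guides.index(fs.guide_id)
            bi = ["b1", "b2", "b3"].index(fs.barcode)
            for t in range(5):
                expected = np.log2(counts[gi, bi, t] / counts[5, bi, t]) - np.log2(
                    counts[gi, bi, 0] / counts[5, bi, 0]
                )
                assert fs.f[t] == pytest.approx(expected, abs=1e-12)
                assert fs.generations[t] == hours[t] * dph

    def test_zero_t0_lineage_dropped_with_warning(self):
        counts = np.array([[[0, 50, 60]], [[100, 100, 100]]], dtype=np.int64)
        ct = CountTensor(["g", "ref"], ["b1"], np.array([0.0, 2, 4]), counts)
        with pytest.warns(UserWarning, match="zero count at t=0"):
            fs = compute_frequency(ct, "ref", 1.0)
        assert all(s.guide_id != "g" for s in fs)


class TestFitRelativeGrowth:
    def test_perfect_line(self):
        gens = np.arange(7, dtype=float)
        fit = fit_relative_growth(series(-0.5 * gens, [100] * 7, gens))
        assert fit.slope == pytest.approx(-0.5)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.n_points_used == 7

    def test_depth_truncation_includes_first_low_point(self):
        depths = [100, 80, 60, 9, 50, 40, 30]
        fit = fit_relative_growth(series(np.zeros(7), depths))
        assert fit.n_points_used == 4

    def test_zero_count_point_excluded_and_truncates(self):
        depths = [100, 80, 0, 50, 40, 30, 20]
        f = np.array([0, -1, np.nan, -3, -4, -5, -6], float)
        fit = fit_relative_growth(series(f, depths))
        assert fit.n_points_used == 2

    def test_too_few_points_is_none(self):
        assert fit_relative_growth(series([0.0, np.nan], [100, 0])) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gens = np.arange(7, dtype=float)
        f = -0.3 * gens + rng.normal(0, 0.2, 7)
        f[0] = 0.0
        fit = fit_relative_growth(series(f, [100] * 7, gens))
        # closed-form OLS via the normal equations
        x, y = gens, f
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)


def _fit(slope, r2=0.95):
    return GrowthFit(slope, 0.0, r2, 7)


class TestEscaperCorrect:
    def test_escaper_removed_by_q_test(self):
        fits = {
            "b1": _fit(-0.50), "b2": _fit(-0.52), "b3": _fit(-0.48),
            "b4": _fit(-0.51), "b5": _fit(-0.49), "b6": _fit(0.02),
        }
        res = escaper_correct("g", fits)
        assert not res.rejected
        assert ("b6", "q_test") in res.removed
        assert res.estimate.n_replicates == 5
        assert res.estimate.mean_raw == pytest.approx(-0.50)
        assert res.estimate.sem == pytest.approx(res.estimate.sd / np.sqrt(5))

    def test_low_r2_filtered_unless_near_zero(self):
        fits = {
            "b1": _fit(-0.50, r2=0.30),  # removed: bad fit, big effect
            "b2": _fit(0.02, r2=0.10),  # kept: inside the exemption band
            "b3": _fit(-0.49), "b4": _fit(-0.51), "b5": _fit(-0.50),
        }
        res = escaper_correct("g", fits)
        removed = dict(res.removed)
        assert removed.get("b1") == "low_R2"
        assert "b2" not in removed or removed["b2"] != "low_R2"

    def test_fewer_than_three_survivors_rejects(self):
        fits = {"b1": _fit(-0.5), "b2": _fit(-0.5, r2=0.2), "b3": _fit(-0.6, r2=0.1)}
        res = escaper_correct("g", fits)
        assert res.rejected
        assert ("*", "too_few_replicates") in res.removed

    def test_identical_slopes_keep_all(self):
        fits = {f"b{i}": _fit(-0.3) for i in range(6)}
        res = escaper_correct("g", fits)
        assert res.estimate.n_replicates == 6
        assert res.estimate.sd == 0.0

    def test_at_most_one_q_removal(self):
        # two symmetric extremes: single-pass Q removes at most one
        fits = {
            "b1": _fit(-0.9), "b2": _fit(0.9), "b3": _fit(0.0),
            "b4": _fit(0.01), "b5": _fit(-0.01), "b6": _fit(0.0),
        }
        res = escaper_correct("g", fits)
        n_q = sum(1 for _, r in res.removed if r == "q_test")
        assert n_q <= 1


class TestNormalize:
    @pytest.mark.parametrize(
        "raw,expected", [(-1.23, 0.0), (0.0, 1.0), (-0.615, 0.5)]
    )
    def test_worked_examples(self, raw, expected):
        assert normalize_growth(raw, -1.23) == pytest.approx(expected)

    def test_positive_floor_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_growth(0.0, 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-2, 1), min_size=2, max_size=10), st.floats(-3, -0.1))
    def test_affine_map_preserves_ranking(self, raws, floor):
        normalized = [normalize_growth(r, floor) for r in raws]
        for i in range(len(raws)):
            for j in range(len(raws)):
                if raws[i] < raws[j]:
                    assert normalized[i] <= normalized[j]


class TestTimecourse:
    def test_exact_line_all_endpoints_agree(self):
        gens = np.arange(7, dtype=float)
        hours = gens.copy()
        fs = series(-0.4 * gens, [100] * 7, gens)
        res = timecourse_growth(fs, hours)
        for s in res.endpoint_slopes.values():
            assert s == pytest.approx(-0.4)
        assert res.all_points.slope == pytest.approx(-0.4)

    def test_flat_then_declining_sign_pattern(self):
        gens = np.arange(7, dtype=float)
        f = np.array([0, 0, 0, 0, -1, -2, -3], float)
        res = timecourse_growth(series(f, [100] * 7, gens), gens)
        slopes = [res.endpoint_slopes[h] for h in sorted(res.endpoint_slopes)]
        assert all(s == 0 for s in slopes[:3])
        assert all(s < 0 for s in slopes[3:])


class TestUncorrected:
    def test_reference_slope_zero(self):
        ct = planted_tensor({"g1": -0.4})
        out = uncorrected_growth(ct, "negC_ref", 1.0)
        assert out["negC_ref"] == pytest.approx(0.0)

    def test_matches_planted_rho_without_escapers(self):
        ct = planted_tensor({"g1": -0.4, "g2": 0.05})
        out = uncorrected_growth(ct, "negC_ref", 1.0)
        assert out["g1"] == pytest.approx(-0.4, abs=1e-3)
        assert out["g2"] == pytest.approx(0.05, abs=1e-3)

    def test_escaper_inflates_uncorrected_estimate(self):
        """A lineage that reverts to wild-type growth mid-run drags the
        pooled two-point estimate up, while the all-points corrected fit
        on clean barcodes stays at the true (deleterious) rate."""
        hours = np.array([0.0, 2, 4, 6, 10, 12, 14])
        rho = -0.8
        base = 100_000.0
        clean = np.rint(base * np.exp2(rho * hours)).astype(np.int64)
        esc = np.rint(
            base * np.exp2(rho * np.minimum(hours, 4.0))
        ).astype(np.int64)  # escapes at hour 4
        ref = np.full(7, int(base))
        counts = np.stack(
            [np.stack([clean, clean, esc]), np.stack([ref, ref, ref])]
        )
        ct = CountTensor(["g", "negC_ref"], ["b1", "b2", "b3"], hours, counts)
        unc = uncorrected_growth(ct, "negC_ref", 1.0)["g"]
        assert unc > rho + 0.1  # strictly higher than the true rate
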