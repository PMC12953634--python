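"""Dose-response fitting, screen hit rules and synergy surfaces."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistkit.pharm import (
    DoseResponseCurve,
    bliss_excess,
    call_hits,
    compute_auc,
    ddcq_fold_change,
    fit_4pl,
    loewe_excess,
    msa_score,
    normalize_poc,
    score_synergy,
    tumour_volume,
    zip_delta,
)
from resistkit.simulate import (
    FourPLParams,
    dilution_series,
    four_pl_poc,
    simulate_combination,
    simulate_drug_screen,
)

DOSES7 = dilution_series(100.0, 5.0, 7)


def curve_from_params(params, doses=DOSES7, n_rep=3):
    poc = four_pl_poc(doses, params)
    return DoseResponseCurve(doses, np.tile(poc[:, None], (1, n_rep)))


class TestNormalizePoc:
    def test_vehicle_raw_and_scaled_values(self):
        curve = normalize_poc(
            np.array([[8.0], [0.0], [9.6]]), np.array([8.0, 8.0]), [1.0, 2.0, 4.0]
        )
        np.testing.assert_allclose(sorted(curve.poc.ravel()), [0.0, 100.0, 120.0])

    def test_nonpositive_vehicle_rejected(self):
        with pytest.raises(ValueError):
            normalize_poc(np.ones((2, 1)), np.zeros(3), [1.0, 2.0])

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    def test_common_scaling_cancels(self, scale):
        raw = np.array([[4.0, 4.4], [2.0, 2.2]])
        vehicle = np.array([4.0, 4.0])
        a = normalize_poc(raw, vehicle, [1.0, 5.0])
        b = normalize_poc(raw * scale, vehicle * scale, [1.0, 5.0])
        np.testing.assert_allclose(a.poc, b.poc)


class TestFourPL:
    def test_noise_free_parameters_recovered(self):
        fit = fit_4pl(curve_from_params(FourPLParams(100, 0, 1.0, 1.0)))
        assert fit.top == pytest.approx(100.0, abs=1e-5)
        assert fit.bottom == pytest.approx(0.0, abs=1e-5)
        assert fit.ic50_uM == pytest.approx(1.0, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_flat_curve_flags_extrapolated_ic50(self):
        curve = DoseResponseCurve(DOSES7, np.full((7, 3), 100.0))
        fit = fit_4pl(curve)
        assert fit.ic50_extrapolated
        assert fit.auc == pytest.approx(100.0)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_4pl(DoseResponseCurve(np.array([1.0, 2.0, 4.0]), np.ones((3, 2))))

    def test_absolute_ic50_recovered_under_noise(self):
        hits = 0
        for seed in range(20):
            tab = simulate_drug_screen({"L": 1.0}, noise_cv=0.05, seed=seed)["L"]
            fit = fit_4pl(DoseResponseCurve(tab.index.to_numpy(), tab.to_numpy()))
            hits += abs(fit.absolute_ic50_uM - 1.0) <= 0.10
        assert hits >= 18


class TestAuc:
    def test_flat_hundred_and_zero(self):
        assert compute_auc(DoseResponseCurve(DOSES7, np.full((7, 2), 100.0)))[
            0
        ] == pytest.approx(100.0)
        assert compute_auc(DoseResponseCurve(DOSES7, np.zeros((7, 2))))[
            0
        ] == pytest.approx(0.0)

    def test_linear_decline_gives_half(self):
        doses = np.sort(DOSES7)
        x = np.log10(doses)
        poc = 100.0 - 100.0 * (x - x[0]) / (x[-1] - x[0])
        auc, sd = compute_auc(DoseResponseCurve(doses, poc[:, None]))
        assert auc == pytest.approx(50.0)
        assert sd == 0.0

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            compute_auc(DoseResponseCurve(np.array([1.0]), np.array([[100.0]])))


class TestHitCalls:
    def test_worked_pass(self):
        hit = call_hits({"line": (300.0, 30.0)}, (400.0, 20.0), min_lines=1)
        row = hit.per_line.loc["line"]
        assert row["eq1_pass"] and row["auc_diff_pass"]
        assert hit.hit

    def test_sd_overlap_blocks_pass(self):
        hit = call_hits({"line": (370.0, 20.0)}, (400.0, 20.0), min_lines=1)
        assert not hit.per_line.loc["line", "eq1_pass"]
        assert not hit.hit

    def test_two_of_three_lines_make_a_hit(self):
        hit = call_hits(
            {"l1": (300.0, 10.0), "l2": (310.0, 10.0), "l3": (390.0, 5.0)},
            (400.0, 20.0),
        )
        assert hit.n_lines_passing == 2
        assert hit.hit

    def test_missing_sd_rejected(self):
        with pytest.raises(ValueError):
            call_hits({"l": (300.0, np.nan)}, (400.0, 20.0))

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.2, max_value=5.0))
    def test_decision_invariant_under_uniform_rescaling(self, scale):
        lines = {"l1": (300.0, 30.0), "l2": (380.0, 15.0)}
        base = call_hits(lines, (400.0, 20.0), auc_diff_threshold=50.0, min_lines=1)
        scaled = call_hits(
            {k: (a * scale, s * scale) for k, (a, s) in lines.items()},
            (400.0 * scale, 20.0 * scale),
            auc_diff_threshold=50.0 * scale,
            min_lines=1,
        )
        assert base.hit == scaled.hit
        assert base.n_lines_passing == scaled.n_lines_passing


def _grid(synergy_delta=0.0, ic50_a=100.0, ic50_b=100.0):
    doses = np.concatenate([[0.0], dilution_series(100, 5, 7)[::-1]])
    return simulate_combination(
        FourPLParams(ic50_uM=ic50_a),
        FourPLParams(ic50_uM=ic50_b),
        doses,
        doses,
        synergy_delta,
        0.0,
        0,
    )


class TestBliss:
    def test_independence_null_is_exactly_zero(self):
        assert np.abs(bliss_excess(_grid(0.0))).max() < 1e-9

    def test_hand_computed_excess(self):
        doses = np.array([0.0, 1.0])
        grid = pd.DataFrame(
            [[100.0, 50.0], [50.0, 10.0]],
            index=pd.Index(doses),
            columns=pd.Index(doses),
        )
        excess = bliss_excess(grid)
        # yA=0.5, yB=0.5, observed 0.9 -> expected 0.75 -> +15 points
        assert excess[1, 1] == pytest.approx(15.0)

    def test_planted_delta_recovered_on_unsaturated_grid(self):
        excess = bliss_excess(_grid(10.0))
        assert np.allclose(excess[1:, 1:], 10.0)

    def test_monotherapy_rows_are_zero(self):
        excess = bliss_excess(_grid(10.0))
        assert np.allclose(excess[0, :], 0.0)
        assert np.allclose(excess[:, 0], 0.0)


class TestLoewe:
    def test_sham_combination_excess_below_one_point(self):
        doses = np.concatenate([[0.0], dilution_series(100, 5, 7)[::-1]])
        params = FourPLParams(100, 0, 1.0, 1.0)
        poc = np.empty((doses.size, doses.size))
        for i, a in enumerate(doses):
            for j, b in enumerate(doses):
                total = a + b
                poc[i, j] = (
                    100.0 if total == 0 else float(four_pl_poc(np.array([total]), params)[0])
                )
        grid = pd.DataFrame(poc, index=pd.Index(doses), columns=pd.Index(doses))
        fit = fit_4pl(
            DoseResponseCurve(doses[1:], four_pl_poc(doses[1:], params)[:, None])
        )
        excess = loewe_excess(grid, fit, fit)
        assert np.abs(excess).max() < 1.0

    def test_zero_partner_dose_returns_monotherapy_expectation(self):
        grid = _grid(0.0)
        doses = grid.index.to_numpy()
        params = FourPLParams(ic50_uM=100.0)
        fit = fit_4pl(
            DoseResponseCurve(doses[1:], four_pl_poc(doses[1:], params)[:, None])
        )
        excess = loewe_excess(grid, fit, fit)
        np.testing.assert_allclose(excess[1:, 0], 0.0, atol=0.5)


class TestZip:
    def test_flat_zero_inhibition_gives_zero_delta(self):
        doses = np.concatenate([[0.0], dilution_series(100, 5, 7)[::-1]])
        grid = pd.DataFrame(
            np.full((8, 8), 100.0), index=pd.Index(doses), columns=pd.Index(doses)
        )
        delta = zip_delta(grid)
        # numerically zero: bounded only by the flat-curve fit tolerance
        assert np.nanmax(np.abs(delta)) < 1e-2

    def test_independence_null_below_one_point(self):
        delta = zip_delta(_grid(0.0))
        assert np.nanmax(np.abs(delta)) < 1.0

    def test_planted_delta_recovered_within_band(self):
        delta = zip_delta(_grid(10.0))
        assert np.nanmean(delta[1:, 1:]) == pytest.approx(10.0, abs=3.0)


class TestMsa:
    def test_constant_surface(self):
        assert msa_score(np.full((5, 5), 10.0)) == 10.0

    def test_embedded_block_is_found(self):
        surface = np.zeros((6, 6))
        surface[2:5, 2:5] = 12.0
        assert msa_score(surface) == 12.0

    def test_msa_at_least_global_mean(self, rng):
        surface = rng.normal(size=(7, 7))
        assert msa_score(surface) >= surface.mean() - 1e-12

    def test_invariant_under_transposition(self, rng):
        surface = rng.normal(size=(6, 8))
        assert msa_score(surface) == pytest.approx(msa_score(surface.T))

    def test_smaller_than_window_uses_largest_square(self):
        # a 1x2 surface admits only 1x1 squares: the best cell wins
        assert msa_score(np.array([[4.0, 6.0]]), window=3) == pytest.approx(6.0)


class TestScoreSynergy:
    def test_all_models_agree_on_planted_synergy_direction(self):
        result = score_synergy(_grid(10.0))
        assert set(result.surfaces) == {"bliss", "loewe", "zip"}
        assert all(v > 5.0 for v in result.msa.values())

    def test_null_grid_produces_no_synergy_calls(self):
        result = score_synergy(_grid(0.0), models=("bliss", "zip"))
        assert all(abs(v) < 1.0 for v in result.msa.values())


class TestSmallAssayUtilities:
    def test_tumour_volume_printed_formula(self):
        assert tumour_volume(10.0, 5.0) == 125.0
        assert tumour_volume(2.0, 2.0) == 4.0

    def test_tumour_volume_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tumour_volume(10.0, 0.0)

    def test_tumour_volume_warns_on_swapped_axes(self):
        with pytest.warns(UserWarning):
            tumour_volume(5.0, 10.0)

    def test_fold_change_identity_and_doubling(self):
        assert ddcq_fold_change(20, 20, 20, 20) == 1.0
        assert ddcq_fold_change(19, 20, 20, 20) == pytest.approx(2.0)

    def test_fold_change_ten_fold_down(self):
        assert ddcq_fold_change(20 + 3.3219, 20, 20, 20) == pytest.approx(0.1, rel=1e-4)
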