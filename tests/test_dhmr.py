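"""Negative-binomial differential testing: normalization, calibration,
dispersion, the Wald test against a Poisson GLM oracle, and calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from hmcdiff.dhmr import (
    DhmrParams,
    DispersionModel,
    apply_calibration,
    call_dhmrs,
    estimate_dispersion,
    nb_wald_test,
    run_dhmr,
    size_factors,
    tpm,
)
from hmcdiff.simulate import SimConfig, simulate_dataset


def _groups(counts):
    return {c: ("tumor" if c.startswith("t") else "normal") for c in counts.columns}


class TestSizeFactors:
    def test_identical_samples(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(size_factors(counts), [1, 1])

    def test_doubled_sample_median_of_ratios(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        assert np.allclose(size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_sample(self):
        assert size_factors(pd.DataFrame({"a": [5, 0, 3]})).tolist() == [1.0]

    def test_fallback_when_no_all_positive_bin(self):
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        sf = size_factors(counts)
        assert np.allclose(sf, [1, 1])


class TestCalibration:
    def test_unit_folds_noop(self):
        sf = pd.Series([1.0, 2.0], index=["a", "b"])
        out = apply_calibration(sf, {"a": 1.0, "b": 1.0})
        assert np.allclose(out, sf)

    def test_normalized_count_scaling(self):
        # raw 100 at size factor 1 with fold 0.4367 -> normalized 43.67
        sf = apply_calibration(pd.Series([1.0], index=["a"]), {"a": 0.4367})
        assert 100 / sf["a"] == pytest.approx(43.67)

    def test_missing_fold_error(self):
        with pytest.raises(ValueError):
            apply_calibration(pd.Series([1.0], index=["a"]), {})

    def test_pure_global_shift_gives_constant_lfc(self):
        """Identical raw counts in both groups with tumor fold 0.5 ->
        fitted log2FC = -1 at every testable bin."""
        rng = np.random.default_rng(0)
        base = rng.integers(50, 500, 50)
        counts = pd.DataFrame({f"t{i}": base for i in range(4)} | {f"n{i}": base for i in range(4)})
        sheet = pd.DataFrame(
            {
                "sample": counts.columns,
                "group": ["tumor"] * 4 + ["normal"] * 4,
                "calibration_fold": [0.5] * 4 + [1.0] * 4,
            }
        )
        res = run_dhmr(counts, sheet, DhmrParams())
        assert np.allclose(res.log2FC, -1.0, atol=1e-6)

    def test_calibration_identity_when_folds_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.poisson(100, (80, 8)),
                              columns=[f"t{i}" for i in range(4)] + [f"n{i}" for i in range(4)])
        sheet = pd.DataFrame({"sample": counts.columns,
                              "group": ["tumor"] * 4 + ["normal"] * 4,
                              "calibration_fold": 1.0})
        a = run_dhmr(counts, sheet, DhmrParams(calibration="offset"))
        b = run_dhmr(counts, sheet, DhmrParams(calibration="off"))
        pd.testing.assert_frame_equal(a, b)

    def test_scaled_counts_mode_runs_and_agrees_in_sign(self):
        b = simulate_dataset(SimConfig(seed=31, n_tumor=6, n_normal=6,
                                       global_level_tumor=0.2, n_gain=0, n_loss=0,
                                       intensity_sigma=0.0, zero_inflation=0.0))
        sheet = b.samples.assign(
            calibration_fold=np.where(b.samples.group == "tumor", 0.2, 1.0)
        )
        res = run_dhmr(b.counts, sheet, DhmrParams(calibration="scaled-counts"))
        assert res.log2FC.median() == pytest.approx(np.log2(0.2), abs=0.15)


class TestDispersion:
    def test_constant_counts_zero_raw_dispersion(self):
        counts = pd.DataFrame({"t1": [10, 5], "t2": [10, 5], "n1": [10, 5], "n2": [10, 5]})
        disp = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), _groups(counts))
        assert np.allclose(disp.alpha_raw, 0.0)

    def test_poisson_counts_small_final_alpha(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(80, (300, 12)),
            columns=[f"t{i}" for i in range(6)] + [f"n{i}" for i in range(6)],
        )
        disp = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), _groups(counts))
        assert np.median(disp.alpha) < 0.01

    def test_nb_alpha_recovered(self):
        rng = np.random.default_rng(3)
        alpha = 0.1
        mu = 200.0
        lam = rng.gamma(1 / alpha, alpha * mu, (500, 40))
        counts = pd.DataFrame(
            rng.poisson(lam),
            columns=[f"t{i}" for i in range(20)] + [f"n{i}" for i in range(20)],
        )
        disp = estimate_dispersion(counts, pd.Series(1.0, index=counts.columns), _groups(counts))
        assert 0.05 <= np.median(disp.alpha) <= 0.2

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            estimate_dispersion(
                pd.DataFrame({"t1": [1]}), pd.Series([1.0], index=["t1"]), {"t1": "tumor"}
            )


class TestWaldTest:
    def test_poisson_glm_oracle_at_zero_dispersion(self):
        """With alpha -> 0 the NB IRLS fit must match statsmodels' Poisson GLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        B, n = 100, 10
        mu = rng.lognormal(3, 1, B)
        y = rng.poisson(mu, (n, B)).T
        counts = pd.DataFrame(y, columns=[f"t{i}" for i in range(5)] + [f"n{i}" for i in range(5)])
        sf = pd.Series(1.0, index=counts.columns)
        disp = DispersionModel(np.zeros(B), (0, 0), np.full(B, 1e-12))
        res = nb_wald_test(counts, _groups(counts), sf, disp)
        X = np.column_stack([np.ones(n), [1] * 5 + [0] * 5])
        for i in range(B):
            if y[i].sum() == 0 or y[i, :5].sum() == 0 or y[i, 5:].sum() == 0:
                continue
            fit = sm.GLM(y[i], X, family=sm.families.Poisson()).fit()
            assert abs(fit.params[1] / np.log(2) - res.log2FC.iloc[i]) < 1e-4

    def test_null_pvalues_uniform(self):
        """Equal group means: Wald p-values are ~Uniform(0,1).  The Wald z is
        asymptotic, so this is checked in a well-powered regime (depth
        ~300/bin, 10v10)."""
        b = simulate_dataset(SimConfig(seed=32, n_tumor=10, n_normal=10,
                                       depth=1_500_000,
                                       global_level_tumor=1.0, n_gain=0, n_loss=0,
                                       zero_inflation=0.0))
        res = run_dhmr(b.counts, b.samples.assign(calibration_fold=1.0), DhmrParams())
        p = res.p.dropna()
        assert np.isclose(res.log2FC.median(), 0.0, atol=0.05)
        assert ss.kstest(p, "uniform").pvalue > 0.01

    def test_planted_fold_recovered(self):
        """A 4-fold regional increase at depth ~100/bin, 8v8, is estimated
        near log2FC = 2."""
        b = simulate_dataset(SimConfig(seed=33, n_tumor=8, n_normal=8,
                                       global_level_tumor=1.0, n_gain=150, n_loss=0,
                                       dhmr_log2fc=2.0, zero_inflation=0.0))
        res = run_dhmr(b.counts, b.samples.assign(calibration_fold=1.0),
                       DhmrParams(lfc_threshold=1.0))
        planted = b.truth.planted_gain.bin_id
        assert res.loc[planted, "log2FC"].mean() == pytest.approx(2.0, abs=0.1)

    def test_all_zero_bins_na(self):
        counts = pd.DataFrame({"t1": [0, 5], "t2": [0, 7], "n1": [0, 6], "n2": [0, 4]})
        sf = pd.Series(1.0, index=counts.columns)
        disp = DispersionModel(np.zeros(2), (0, 0), np.full(2, 0.01))
        res = nb_wald_test(counts, _groups(counts), sf, disp)
        assert np.isnan(res.p.iloc[0]) and not np.isnan(res.p.iloc[1])

    def test_one_group_zero_pseudo_mean_reporting(self):
        counts = pd.DataFrame({"t1": [8], "t2": [8], "n1": [0], "n2": [0]})
        sf = pd.Series(1.0, index=counts.columns)
        disp = DispersionModel(np.zeros(1), (0, 0), np.full(1, 0.01))
        res = nb_wald_test(counts, _groups(counts), sf, disp)
        assert res.log2FC.iloc[0] == pytest.approx(np.log2(8 / 0.5))


class TestCalling:
    def test_threshold_logic(self):
        res = pd.DataFrame(
            {"baseMean": [1, 1, 1, 1], "log2FC": [2.5, -2.5, 2.5, 0.1],
             "SE": 0.1, "stat": 1.0,
             "p": [1e-6, 1e-6, 0.02, 0.5]}
        )
        out = call_dhmrs(res, DhmrParams())
        # BH over 4 p-values: q = [2e-6, 2e-6, 0.0267, 0.5]
        assert out.call.tolist() == ["gain", "loss", "ns", "ns"]

    def test_empty_input(self):
        res = pd.DataFrame({"baseMean": [], "log2FC": [], "SE": [], "stat": [], "p": []})
        assert len(call_dhmrs(res)) == 0

    def test_monotone_recall_in_effect_size(self):
        """Raising the planted |log2FC| never lowers recall."""
        recalls = []
        for lfc in (2.2, 3.0, 4.0):
            b = simulate_dataset(SimConfig(seed=34, n_tumor=6, n_normal=6,
                                           global_level_tumor=1.0, n_gain=100, n_loss=100,
                                           dhmr_log2fc=lfc))
            res = run_dhmr(b.counts, b.samples.assign(calibration_fold=1.0), DhmrParams())
            truth = set(b.truth.planted_gain.bin_id) | set(b.truth.planted_loss.bin_id)
            called = set(res.index[res.call != "ns"])
            recalls.append(len(called & truth) / len(truth))
        assert recalls == sorted(recalls)


class TestTpm:
    def test_single_gene(self):
        t = tpm(pd.DataFrame({"s": [7]}, index=["g"]), pd.Series([500], index=["g"]))
        assert t["s"].tolist() == [1e6]

    def test_equal_counts_equal_lengths(self):
        t = tpm(pd.DataFrame({"s": [10, 10]}, index=["a", "b"]),
                pd.Series([1000, 1000], index=["a", "b"]))
        assert np.allclose(t["s"], [5e5, 5e5])

    def test_length_normalization_hand_arithmetic(self):
        t = tpm(pd.DataFrame({"s": [10, 10]}, index=["a", "b"]),
                pd.Series([1000, 2000], index=["a", "b"]))
        assert np.allclose(t["s"], [2e6 / 3, 1e6 / 3])
        assert t["s"].sum() == pytest.approx(1e6)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm(pd.DataFrame({"s": [0]}, index=["g"]), pd.Series([100], index=["g"]))
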