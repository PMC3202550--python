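"""Screening and goodness-of-fit: VIF, delta-DIC tables, AUC, calibration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import beechmort as bm
from beechmort.evaluate import period_death_probability


class TestVIF:
    def test_orthogonal_covariates_have_unit_vif(self):
        n = 8
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        vif = bm.compute_vif(np.column_stack([x1, x2]))
        assert np.allclose(vif.values, 1.0)

    def test_bivariate_closed_form_at_correlation_0_8(self):
        # exact sample correlation 0.8 built from orthonormal vectors
        u = np.tile([1.0, -1.0], 50)
        v = np.repeat([1.0, -1.0], 50)
        x2 = 0.8 * u + 0.6 * v
        vif = bm.compute_vif(np.column_stack([u, x2]), names=["u", "x2"])
        assert vif["u"] == pytest.approx(1.0 / (1.0 - 0.64), rel=1e-9)

    def test_duplicated_covariate_reported_infinite(self):
        x = np.random.default_rng(0).normal(size=(30, 1))
        vif = bm.compute_vif(np.column_stack([x, x]))
        assert np.isinf(vif.values).all()

    def test_matches_statsmodels_on_random_matrix(self):
        from statsmodels.stats.outliers_influence import variance_inflation_factor

        rng = np.random.default_rng(3)
        base = rng.normal(size=(200, 1))
        x = np.column_stack(
            [base + rng.normal(scale=0.5, size=(200, 1)) for _ in range(3)]
        )
        mine = bm.compute_vif(x).values
        design = np.column_stack([np.ones(200), x])
        theirs = [variance_inflation_factor(design, i + 1) for i in range(3)]
        assert np.allclose(mine, theirs, rtol=1e-8)

    def test_vif_at_least_one(self, fitted_small_model):
        data, _ = fitted_small_model
        vif = bm.compute_vif(data.design.matrix, names=data.design.names)
        assert (vif.values >= 1.0 - 1e-12).all()

    def test_needs_two_covariates(self):
        with pytest.raises(ValueError):
            bm.compute_vif(np.ones((10, 1)))


class TestCompareModels:
    def test_threshold_labels(self):
        table = bm.compare_models([("A", 106.0), ("B", 111.0)])
        assert list(table["delta_dic"]) == [0.0, 5.0]
        assert list(table["evidence"]) == ["none", "substantial"]
        assert table["is_best"].tolist() == [True, False]

    def test_very_strong_evidence(self):
        table = bm.compare_models([("A", 90.0), ("B", 104.0)])
        assert table.loc[1, "evidence"] == "very strong"

    def test_tie_broken_by_listed_order_and_noted(self):
        table = bm.compare_models([("A", 100.0), ("B", 100.0)])
        assert table["is_best"].sum() == 1
        assert table.loc[0, "is_best"]
        assert "tie" in table.attrs["note"]

    def test_different_tree_sets_rejected(self):
        with pytest.raises(ValueError):
            bm.compare_models([("A", 10.0), ("B", 12.0)], n_obs=[100, 101])


class TestAUC:
    def test_perfect_separation(self):
        assert bm.compute_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_four_tree_worked_example(self):
        assert bm.compute_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            bm.compute_auc([0.2, 0.4], [1, 1])

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(7)
        p = np.round(rng.random(500), 1)  # coarse grid forces ties
        d = rng.random(500) < p
        if d.all() or not d.any():
            d[0] = ~d[0]
        pos = p[d][:, None]
        neg = p[~d][None, :]
        oracle = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (pos.size * neg.size)
        assert bm.compute_auc(p, d) == pytest.approx(oracle, rel=1e-12)

    @given(st.floats(min_value=0.1, max_value=5.0))
    def test_invariant_under_strictly_increasing_transforms(self, power):
        rng = np.random.default_rng(11)
        p = rng.random(200)
        d = rng.random(200) < p
        if d.all() or not d.any():
            d[0] = ~d[0]
        assert bm.compute_auc(p**power, d) == pytest.approx(bm.compute_auc(p, d))


class TestCalibration:
    def test_homogeneous_predictions_land_in_one_bin(self):
        rng = np.random.default_rng(5)
        d = rng.random(1000) < 0.3
        table = bm.calibration_bins(np.full(1000, 0.3), d)
        occupied = table[table["n"] > 0]
        assert len(occupied) == 1
        row = occupied.iloc[0]
        assert row["bin_low"] == pytest.approx(0.3)  # edge value goes up
        assert row["observed_fraction"] == pytest.approx(0.3, abs=0.05)

    def test_edge_conventions(self):
        table = bm.calibration_bins([0.0, 0.5, 1.0], [0, 1, 1])
        assert table.loc[0, "n"] == 1       # 0.0 in [0, 0.1)
        assert table.loc[5, "n"] == 1       # 0.5 in [0.5, 0.6)
        assert table.loc[9, "n"] == 1       # 1.0 belongs to the last bin

    def test_empty_bins_reported_with_nan_fraction(self):
        table = bm.calibration_bins([0.05], [0])
        assert (table["n"] == 0).sum() == 9
        assert table.loc[9, "n"] == 0 and np.isnan(table.loc[9, "observed_fraction"])

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            bm.calibration_bins([1.2], [1])

    def test_well_specified_model_is_calibrated(self, fitted_small_model):
        data, result = fitted_small_model
        predicted = period_death_probability(result, data)
        table = bm.calibration_bins(predicted, data.y)
        checked = ok = 0
        for _, row in table.iterrows():
            if row["n"] < 30:
                continue
            checked += 1
            se = np.sqrt(row["midpoint"] * (1 - row["midpoint"]) / row["n"])
            ok += abs(row["observed_fraction"] - row["midpoint"]) <= 2 * se + 0.02
        assert checked >= 3
        assert ok / checked >= 0.8


def test_report_bundle_serializes(fitted_small_model):
    data, result = fitted_small_model
    predicted = period_death_probability(result, data)
    report = bm.EvaluationReport(
        vif=bm.compute_vif(data.design.matrix[:, :2], names=["D", "BAL"]),
        dic_table=bm.compare_models([("BAL", result.dic.dic), ("BA", result.dic.dic + 7)]),
        auc=bm.compute_auc(predicted, data.y),
        calibration=bm.calibration_bins(predicted, data.y),
    )
    payload = report.to_dict()
    assert 0.5 < payload["auc"] <= 1.0
    assert payload["dic_table"][0]["is_best"]
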