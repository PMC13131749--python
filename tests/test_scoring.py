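"""PRS arithmetic, composite-model fitting, ROC/threshold/calibration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dqrisk.cohort import call_dq_frame
from dqrisk.scoring import (
    COMPOSITE_FEATURES,
    CompositeScoreModel,
    PlattCalibrator,
    PrsWeightTable,
    ScoreModel,
    SeparationError,
    brier,
    build_feature_frame,
    compute_prs,
    compute_prs_frame,
    fit_composite,
    platt_calibrate,
    roc,
    score,
    score_frame,
    select_threshold,
)
from dqrisk.simulate import (
    DiseaseModelSpec,
    build_default_pools,
    default_snp_panel,
    sample_cohort,
)


def auc_pair_counting(scores, labels):
    """Independent AUC oracle: exhaustive case/control pair comparison."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0)
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestComputePrs:
    def weights(self, entries, hla=None):
        return PrsWeightTable(
            tuple(entries),
            hla or {"high": 0.0, "moderate": 0.0, "low": 0.0, "none": 0.0},
        )

    def test_zero_weights_give_zero(self):
        w = self.weights([("v1", "A", 0.0)])
        assert compute_prs({"risk_category": "none", "dos_v1": 2}, w) == 0.0

    def test_additive_in_dosage_and_hla_term(self):
        w = self.weights([("v1", "A", 0.7)], {"high": 2.0, "none": 0.0})
        assert compute_prs(
            {"risk_category": "high", "dos_v1": 2}, w
        ) == pytest.approx(2.0 + 1.4)

    def test_missing_dosage_counts_as_zero_with_warning(self):
        w = self.weights([("v1", "A", 0.7), ("v2", "A", 0.3)])
        with pytest.warns(UserWarning, match="missing dosage"):
            value = compute_prs({"risk_category": "none", "dos_v1": 1}, w)
        assert value == pytest.approx(0.7)

    @given(
        weights=st.lists(st.floats(-2, 2), min_size=1, max_size=8),
        dosages=st.lists(st.integers(0, 2), min_size=8, max_size=8),
        hla=st.floats(-1, 3),
    )
    def test_equals_independent_dot_product(self, weights, dosages, hla):
        entries = [(f"v{i}", "A", w) for i, w in enumerate(weights)]
        table = PrsWeightTable(tuple(entries), {"high": hla})
        record = {"risk_category": "high"}
        record.update({f"dos_v{i}": d for i, d in enumerate(dosages)})
        expected = hla + sum(w * d for w, d in zip(weights, dosages))
        assert compute_prs(record, table) == pytest.approx(expected)

    def test_frame_version_matches_scalar(self, small_mixed_cohort):
        ann = call_dq_frame(small_mixed_cohort.head(50))
        entries = [(f"snp{i + 1:03d}", "A", 0.1 * (i + 1)) for i in range(3)]
        w = PrsWeightTable(
            tuple(entries), {"high": 2.0, "moderate": 1.0, "low": 0.5, "none": 0.0}
        )
        series = compute_prs_frame(ann, w)
        for idx in ann.index[:10]:
            assert series[idx] == pytest.approx(compute_prs(ann.loc[idx], w))

    def test_duplicate_variant_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PrsWeightTable((("v1", "A", 0.1), ("v1", "C", 0.2)))

    def test_weight_table_round_trips_via_frame(self):
        w = PrsWeightTable(
            (("v1", "A", 0.25), ("v2", "G", -0.5)),
            {"high": 2.0, "moderate": 1.0, "low": 0.5, "none": 0.0},
        )
        again = PrsWeightTable.from_frame(w.to_frame())
        assert again == w


class TestScoreModel:
    MODEL = ScoreModel(-1.5, {"prs": 0.8, "family_history": 1.2})

    def test_all_zero_features_give_intercept(self):
        assert score({"prs": 0.0, "family_history": 0}, self.MODEL) == -1.5

    def test_flag_flip_changes_score_by_weight(self):
        base = score({"prs": 1.0, "family_history": 0}, self.MODEL)
        flipped = score({"prs": 1.0, "family_history": 1}, self.MODEL)
        assert flipped - base == pytest.approx(1.2)

    def test_hand_computed_sum(self):
        assert score(
            {"prs": 2.5, "family_history": 1}, self.MODEL
        ) == pytest.approx(-1.5 + 0.8 * 2.5 + 1.2)

    def test_frame_version_matches(self):
        X = pd.DataFrame({"prs": [0.0, 2.5], "family_history": [0, 1]})
        out = score_frame(X, self.MODEL)
        assert out.tolist() == pytest.approx([-1.5, -1.5 + 2.0 + 1.2])

    def test_nonfinite_weight_rejected(self):
        with pytest.raises(ValueError):
            ScoreModel(0.0, {"x": float("nan")})


class TestFitComposite:
    def test_null_feature_coefficient_near_zero(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.integers(0, 2, 4000)})
        y = rng.integers(0, 2, 4000)
        model = fit_composite(X, y)
        assert abs(model.feature_weights["f"]) < 0.15

    def test_parameter_recovery_at_n10k(self):
        # generate from a known additive logistic model; family history
        # log-OR = 1.0 must be recovered within +-0.15
        rng = np.random.default_rng(7)
        n = 10_000
        X = pd.DataFrame({
            "family_history": rng.integers(0, 2, n),
            "diarrhea": rng.integers(0, 2, n),
            "prs": rng.normal(0, 1, n),
        })
        logit = -2.0 + 1.0 * X.family_history + 0.5 * X.diarrhea + 0.8 * X.prs
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        model = fit_composite(X, y)
        assert model.feature_weights["family_history"] == pytest.approx(1.0, abs=0.15)
        assert model.feature_weights["prs"] == pytest.approx(0.8, abs=0.15)
        assert model.intercept == pytest.approx(-2.0, abs=0.2)

    def test_separation_raises_with_remedy(self):
        X = pd.DataFrame({"f": [0, 0, 0, 1, 1, 1]})
        y = [0, 0, 0, 1, 1, 1]
        with pytest.raises(SeparationError, match="penalize"):
            fit_composite(X, y)
        model = fit_composite(X, y, penalize=True)
        assert math.isfinite(model.feature_weights["f"])

    def test_duplicate_columns_split_under_penalty(self):
        rng = np.random.default_rng(1)
        f = rng.integers(0, 2, 2000)
        noise = rng.random(2000)
        y = ((0.8 * f + noise) > 0.9).astype(int)
        X = pd.DataFrame({"f1": f, "f2": f})
        model = fit_composite(X, y, penalize=True)
        assert model.feature_weights["f1"] == pytest.approx(
            model.feature_weights["f2"], rel=1e-3
        )

    def test_degenerate_labels_rejected(self):
        X = pd.DataFrame({"f": [0, 1]})
        with pytest.raises(ValueError):
            fit_composite(X, [1, 1])

    def test_estimator_interface(self):
        est = CompositeScoreModel(penalize=True).set_params(max_iter=50)
        assert est.get_params()["max_iter"] == 50
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"f": rng.normal(size=500)})
        y = (rng.random(500) < 1 / (1 + np.exp(-X.f))).astype(int)
        est.fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (500, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        res = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    @pytest.mark.parametrize(
        "scores,labels,expected",
        [((1, 2, 3, 4), (0, 0, 1, 1), 1.0), ((1, 3, 2, 4), (0, 0, 1, 1), 0.75)],
    )
    def test_exhaustive_pair_counting_examples(self, scores, labels, expected):
        assert roc(scores, labels).auc == pytest.approx(expected)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        if y.sum() in (0, 40):
            y[0] = 1 - y[0]
        assert roc(s, y).auc == pytest.approx(1 - roc(s, 1 - y).auc)

    @settings(deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 1)),
            min_size=4, max_size=20,
        ).filter(lambda xs: 0 < sum(l for _, l in xs) < len(xs))
    )
    def test_auc_equals_pair_counting_oracle_with_ties(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [l for _, l in pairs]
        assert roc(scores, labels).auc == pytest.approx(
            auc_pair_counting(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2], [1, 1])

    def test_matches_sklearn_on_synthetic_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.integers(0, 2, 500)
        s = rng.normal(size=500) + y
        assert roc(s, y).auc == pytest.approx(roc_auc_score(y, s))


def accuracy_at(scores, labels, t):
    s = np.asarray(scores)
    y = np.asarray(labels)
    pred = s >= t
    return float((pred == (y == 1)).mean())


class TestSelectThreshold:
    def test_perfect_separation_returns_gap_midpoint(self):
        res = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert select_threshold(res, "max_accuracy") == pytest.approx(6.5)

    def test_max_accuracy_matches_bruteforce_sweep(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=10)
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        res = roc(scores, labels)
        t = select_threshold(res, "max_accuracy")
        brute_best = max(
            accuracy_at(scores, labels, c)
            for c in np.r_[scores, scores.min() - 1, scores.max() + 1]
        )
        assert accuracy_at(scores, labels, t) == pytest.approx(brute_best)

    def test_sensitivity_90_boundary(self):
        # 10 cases: exactly 9 score >= 5.0 -> largest threshold with
        # sensitivity >= 0.9 is 5.0
        case_scores = [5.0, 5.5, 6, 6.5, 7, 7.5, 8, 8.5, 9, 1.0]
        ctrl_scores = [0.0, 0.5, 2.0]
        scores = np.r_[case_scores, ctrl_scores]
        labels = np.r_[np.ones(10), np.zeros(3)]
        res = roc(scores, labels)
        t = select_threshold(res, "sensitivity_90")
        assert t == pytest.approx(5.0)
        sens = (np.asarray(case_scores) >= t).mean()
        assert sens >= 0.9

    def test_unknown_criterion_rejected(self):
        res = roc([1, 2], [0, 1])
        with pytest.raises(ValueError, match="criterion"):
            select_threshold(res, "youden")


class TestPlattAndBrier:
    def test_constant_scores_calibrate_to_prevalence(self):
        (slope, intercept), probs = platt_calibrate(
            [3.0] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        )
        assert slope == 0.0
        assert probs[0] == pytest.approx(0.3)

    def test_true_logit_scores_nearly_identity(self):
        rng = np.random.default_rng(9)
        logits = rng.normal(0, 2, 5000)
        y = (rng.random(5000) < 1 / (1 + np.exp(-logits))).astype(int)
        (slope, intercept), probs = platt_calibrate(logits, y)
        raw = 1 / (1 + np.exp(-logits))
        assert brier(probs, y) <= brier(raw, y) + 1e-6

    def test_balanced_symmetric_scores_zero_intercept(self):
        # perfectly separated by sign, so the ridge fallback is required;
        # symmetry forces the intercept to zero either way
        scores = np.r_[-np.arange(1, 50), np.arange(1, 50)]
        labels = np.r_[np.zeros(49), np.ones(49)]
        with pytest.raises(SeparationError):
            PlattCalibrator().fit(scores, labels)
        cal = PlattCalibrator(penalize=True).fit(scores, labels)
        assert abs(cal.intercept_) < 1e-3

    def test_brier_arithmetic(self):
        assert brier([1.0, 0.0], [1, 0]) == 0.0
        assert brier([0.5, 0.5], [1, 0]) == 0.25
        assert brier([0.8, 0.3], [1, 0]) == pytest.approx(0.065)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            brier([1.2], [1])


class TestCompositeVsPrsOnSyntheticCohort:
    def test_composite_not_materially_worse_than_prs(self):
        """With real HLA + SNP + clinical effects the combined model's AUC
        must not fall below the PRS AUC by more than 0.005."""
        panel = default_snp_panel(10, seed=1)
        snp_betas = {s.variant_id: 0.25 for s in panel}
        disease = DiseaseModelSpec(snp_log_odds=snp_betas)
        pools = [p for p in build_default_pools() if p.ancestry_label == "EUR"]
        cohort = call_dq_frame(sample_cohort(
            pools, disease_model=disease, n_per_ancestry=12_000, seed=31,
            snp_panel=panel,
        ))
        weights = PrsWeightTable(
            tuple((s.variant_id, "A", snp_betas[s.variant_id]) for s in panel),
            {"high": 2 * math.log(3.6), "moderate": math.log(3.6),
             "low": 0.3, "none": 0.0},
        )
        cohort["prs"] = compute_prs_frame(cohort, weights)
        y = (cohort.ced_ehr | cohort.ced_survey).astype(int)
        auc_prs = roc(cohort["prs"].to_numpy(), y.to_numpy()).auc
        X = build_feature_frame(cohort, weights, COMPOSITE_FEATURES)
        model = fit_composite(X, y)
        composite = score_frame(X, model)
        auc_combined = roc(composite.to_numpy(), y.to_numpy()).auc
        assert auc_combined >= auc_prs - 0.005
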