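"""Cluster features, rule classification, logistic scoring and model fitting."""

import numpy as np
import pandas as pd
import pytest

import idlink as il
from idlink.detection import (
    DEFAULT_CUTOFF,
    PUBLISHED_COEFFICIENTS,
    PUBLISHED_INTERCEPT,
    ClusterFeatures,
)
from idlink.linkage import Cluster

COLS = ["record_id", "nhs_number", "hospital_number", "surname", "forename", "sex",
        "birthdate", "composite_id"]


def make_cluster(rows, cid=1):
    frame = pd.DataFrame(rows, columns=COLS)
    return Cluster(cid, frame)


R1 = (1, "N1", "H1", "WILSON", "DAVID", "M", "1969-01-20", "WILSON|DAV|1969-01-20")
R1B = (2, "N1", "H1", "WILSON", "DAVID", "M", "1969-01-20", "WILSON|DAV|1969-01-20")


class TestIsComplex:
    def test_singleton(self):
        assert not il.is_complex(make_cluster([R1]))

    def test_same_nhs_different_hospital(self):
        rows = [R1, (2, "N1", "H2", "WILSON", "DAVID", "M", "1969-01-20", "WILSON|DAV|1969-01-20")]
        assert il.is_complex(make_cluster(rows))

    def test_null_does_not_count_as_variation(self):
        rows = [R1, (2, None, "H1", "WILSON", "DAVID", "M", "1969-01-20", "WILSON|DAV|1969-01-20")]
        assert not il.is_complex(make_cluster(rows))


class TestRuleClassify:
    def test_one_nhs_one_hospital_wins_despite_two_surnames(self):
        rows = [R1, (2, "N1", "H1", "JONES", "DAVID", "M", "1969-01-20", "JONES|DAV|1969-01-20")]
        verdict = il.rule_classify(make_cluster(rows))
        assert verdict.label == "good" and verdict.matched_rule == "one_nhs_one_hospital"

    def test_hospital_and_composite_rule(self):
        rows = [R1, (2, "N2", "H1", "WILSON", "DAVID", "M", "1969-01-20", "WILSON|DAV|1969-01-20")]
        verdict = il.rule_classify(make_cluster(rows))
        assert verdict.label == "good" and verdict.matched_rule == "one_hospital_one_composite"

    def test_all_identifiers_varying_is_uncertain(self):
        rows = [R1, (2, "N2", "H2", "SMITH", "JOHN", "M", "2007-02-24", "SMITH|JOH|2007-02-24")]
        assert il.rule_classify(make_cluster(rows)).label == "uncertain"

    def test_absent_identifier_cannot_satisfy_a_rule(self):
        rows = [(1, None, None, "WILSON", "DAVID", "M", "1969-01-20", "WILSON|DAV|1969-01-20")]
        # composite invariant but no second invariant identifier present
        assert il.rule_classify(make_cluster(rows)).label == "uncertain"


class TestExtractFeatures:
    def test_identical_records_all_zero(self):
        feats = il.extract_features(make_cluster([R1, R1B]))
        assert all(v == 0.0 for v in feats.as_dict().values())
        assert not feats.any_female and not feats.is_complex

    def test_dob_components_compared_separately(self):
        rows = [R1, (2, "N1", "H1", "WILSON", "DAVID", "M", "2007-01-20", "WILSON|DAV|2007-01-20")]
        feats = il.extract_features(make_cluster(rows))
        assert feats.dob_year == 4.0  # Levenshtein("1969", "2007")
        assert feats.dob_day == 0.0 and feats.dob_month == 0.0

    def test_max_over_all_pairs(self):
        rows = [
            (1, "N1", "H1", "WILSON", "DAVID", "M", "1969-01-20", "x"),
            (2, "N1", "H1", "WILSON", "DAVIE", "M", "1969-01-20", "x"),
            (3, "N1", "H1", "WILSON", "JOHN", "M", "1969-01-20", "x"),
        ]
        feats = il.extract_features(make_cluster(rows))
        pairwise = [
            il.jaro_winkler_distance("DAVID", "DAVIE"),
            il.jaro_winkler_distance("DAVID", "JOHN"),
            il.jaro_winkler_distance("DAVIE", "JOHN"),
        ]
        assert feats.forename == pytest.approx(max(pairwise))

    def test_nulls_are_skipped_not_conflicting(self):
        rows = [R1, (2, "N1", "H1", "WILSON", "DAVID", "M", None, "x")]
        feats = il.extract_features(make_cluster(rows))
        assert feats.dob_year == 0.0  # only one non-null birthdate

    def test_any_female_and_sex_distance(self):
        rows = [R1, (2, "N1", "H1", "WILSON", "DAVINA", "F", "1969-01-20", "x")]
        feats = il.extract_features(make_cluster(rows))
        assert feats.any_female and feats.sex == 1.0

    def test_permutation_invariant(self):
        rows = [
            (1, "N1", "H1", "WILSON", "DAVID", "M", "1969-01-20", "x"),
            (2, "N2", "H2", "SMITH", "JOHN", "F", "2007-02-24", "y"),
            (3, "N1", "H3", "JONES", "CHRIS", "M", "1969-11-02", "z"),
        ]
        a = il.extract_features(make_cluster(rows))
        b = il.extract_features(make_cluster(rows[::-1]))
        assert a.as_dict() == b.as_dict()


class TestScoreCluster:
    def test_all_zero_features_score_at_intercept(self):
        score, label = il.score_cluster(ClusterFeatures())
        assert score == pytest.approx(PUBLISHED_INTERCEPT)
        assert label == "good"

    def test_birth_year_conflict_dominates(self):
        score, label = il.score_cluster(ClusterFeatures(dob_year=4.0))
        assert score == pytest.approx(-3.33 + 4 * 5.12)  # 17.15
        assert label == "bad"

    def test_cutoff_is_strict(self):
        # engineer a feature vector landing exactly on the cutoff
        gap = (DEFAULT_CUTOFF - PUBLISHED_INTERCEPT) / PUBLISHED_COEFFICIENTS["dob_day"]
        score, label = il.score_cluster(ClusterFeatures(dob_day=gap))
        assert score == pytest.approx(DEFAULT_CUTOFF)
        assert label == "good"  # bad requires score strictly above the cutoff

    def test_any_female_model_ignores_surname(self):
        s_m, _ = il.score_cluster(ClusterFeatures(surname=1.0, any_female=False))
        s_f, _ = il.score_cluster(ClusterFeatures(surname=1.0, any_female=True))
        # published set carries no surname term in either model
        assert s_m == s_f == pytest.approx(PUBLISHED_INTERCEPT)

    def test_missing_feature_for_coefficient_is_an_error(self):
        model = il.LogisticModel(0.0, {"postcode": 1.0})
        with pytest.raises(KeyError):
            model.score(ClusterFeatures())

    def test_score_monotone_in_positive_coefficients(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            base = ClusterFeatures(
                dob_day=rng.uniform(0, 2), dob_month=rng.uniform(0, 2),
                dob_year=rng.uniform(0, 4), forename=rng.uniform(), sex=float(rng.integers(2)),
            )
            s0, _ = il.score_cluster(base)
            bumped = ClusterFeatures(**{**base.__dict__, "dob_year": base.dob_year + 0.5})
            s1, _ = il.score_cluster(bumped)
            assert s1 > s0


class TestSimulateBad:
    def test_pairing_count_and_determinism(self, good_clusters):
        bad = il.simulate_bad_by_combination(good_clusters, rng_seed=4)
        assert len(bad) == len(good_clusters) // 2
        again = il.simulate_bad_by_combination(good_clusters, rng_seed=4)
        assert [b.members for b in bad] == [c.members for c in again]
        # disjoint pairing: every record used at most once
        used = [m for b in bad for m in b.members]
        assert len(used) == len(set(used))

    def test_combined_clusters_are_complex(self, good_clusters):
        for bad in il.simulate_bad_by_combination(good_clusters, rng_seed=4):
            assert il.is_complex(bad)

    def test_fewer_than_two_inputs(self, good_clusters):
        assert il.simulate_bad_by_combination(good_clusters[:1], rng_seed=0) == []


class TestFitLogistic:
    @staticmethod
    def _simulate(n, rng, coefs, intercept):
        X = pd.DataFrame({k: rng.uniform(0, 1, n) for k in coefs})
        eta = intercept + sum(c * X[k] for k, c in coefs.items())
        y = rng.uniform(size=n) < 1 / (1 + np.exp(-eta))
        return X, y.astype(int)

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(2024)
        true = {"dob_year": 3.0, "forename": 1.5, "hospital_number": -1.0}
        X, y = self._simulate(5000, rng, true, intercept=-1.0)
        fit = il.fit_logistic_backward_aic(X, y, included_fields=list(true))
        for name, target in true.items():
            est, se = fit.model.coefficients[name], fit.stderr[name]
            assert abs(est - target) < 3 * se, name
        assert abs(fit.model.intercept - (-1.0)) < 3 * fit.stderr["const"]

    def test_backward_aic_drops_pure_noise(self):
        dropped = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            true = {"dob_year": 3.0}
            X, y = self._simulate(1500, rng, true, intercept=-1.0)
            X["noise"] = rng.uniform(0, 1, len(X))
            fit = il.fit_logistic_backward_aic(X, y, included_fields=["dob_year", "noise"])
            dropped += "noise" in fit.eliminated
            assert "dob_year" not in fit.eliminated  # the real signal survives
        assert dropped >= 8  # well above the ~50% of chance elimination

    def test_independent_labels_reduce_to_intercept_only(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame({"a": rng.uniform(size=800), "b": rng.uniform(size=800)})
        y = rng.integers(0, 2, 800)
        fit = il.fit_logistic_backward_aic(X, y, included_fields=["a", "b"])
        assert fit.model.coefficients == {}
        assert set(fit.eliminated) == {"a", "b"}

    def test_single_label_rejected(self):
        X = pd.DataFrame({"a": [0.1, 0.2, 0.3, 0.4]})
        with pytest.raises(ValueError):
            il.fit_logistic_backward_aic(X, [1, 1, 1, 1])

    def test_separation_warns_and_clips(self):
        X = pd.DataFrame({"a": np.r_[np.zeros(30), np.ones(30)]})
        y = np.r_[np.zeros(30), np.ones(30)]
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = il.fit_logistic_backward_aic(X, y, included_fields=["a"], clip=20.0)
        assert abs(fit.model.coefficients.get("a", 0.0)) <= 20.0


def test_features_frame_shape(good_clusters):
    bad = il.simulate_bad_by_combination(good_clusters, rng_seed=1)
    table = il.features_frame(good_clusters + bad)
    assert {"cluster_id", "dob_year", "score", "label", "any_female"} <= set(table.columns)
    assert len(table) == len(good_clusters) + len(bad)
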