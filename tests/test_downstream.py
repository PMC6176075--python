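"""Subnetwork strength, Spearman correlations, LOO classification, confusion math."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from megconn.downstream import (
    DownstreamError,
    accuracy_interval,
    confusion_from_rates,
    loo_logistic_classify,
    spearman_correlations,
    subnetwork_strength,
)
from megconn.experiments import spearman_oracle
from megconn.nbs import SubjectTable


class TestSubnetworkStrength:
    def test_single_link_equals_that_plv(self, rng):
        fc = rng.uniform(0, 1, size=(6, 5, 5))
        fc = 0.5 * (fc + fc.transpose(0, 2, 1))
        strength = subnetwork_strength(fc, [(1, 3)])
        assert np.array_equal(strength.values, fc[:, 1, 3])

    def test_uniform_links_give_that_constant(self):
        fc = np.full((4, 6, 6), 0.37)
        strength = subnetwork_strength(fc, [(0, 1), (2, 3), (4, 5)])
        assert np.allclose(strength.values, 0.37)

    def test_matches_bruteforce_loop(self, rng):
        fc = rng.uniform(0, 1, size=(8, 10, 10))
        fc = 0.5 * (fc + fc.transpose(0, 2, 1))
        links = [(0, 4), (1, 7), (2, 9), (3, 5), (0, 8), (6, 7), (2, 4), (1, 9), (5, 8)]
        strength = subnetwork_strength(fc, links)
        for s in range(8):
            total = 0.0
            for i, j in links:
                total += fc[s, i, j]
            assert strength.values[s] == pytest.approx(total / len(links), abs=1e-12)

    def test_missing_link_rejected(self, rng):
        fc = rng.uniform(0, 1, size=(3, 4, 4))
        with pytest.raises(DownstreamError, match="not present"):
            subnetwork_strength(fc, [(0, 9)])


class TestSpearman:
    def test_monotone_pair_gives_one(self, toy_table):
        x = np.arange(8, dtype=float)
        result = spearman_correlations(
            {"feat": np.exp(x)},
            _with_score(toy_table, x * 2 + 1),
            scores=["score_lin"],
            per_group=False,
        )
        assert result["rho"].iloc[0] == pytest.approx(1.0)

    def test_antitone_pair_gives_minus_one(self, toy_table):
        x = np.arange(8, dtype=float)
        result = spearman_correlations(
            {"feat": x}, _with_score(toy_table, -x), scores=["score_lin"],
            per_group=False,
        )
        assert result["rho"].iloc[0] == pytest.approx(-1.0)

    def test_tied_toy_matches_midrank_oracle(self, toy_table):
        # six usable points with one tie in each variable would be enough;
        # use the full 8 with ties
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 3.0, 6.0, 5.0, 7.0])
        result = spearman_correlations(
            {"feat": x}, _with_score(toy_table, y), scores=["score_lin"],
            per_group=False,
        )
        assert result["rho"].iloc[0] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_subgroup_rows_present(self, toy_table, rng):
        result = spearman_correlations(
            {"feat": rng.uniform(size=8)}, toy_table, scores=["score_fds"]
        )
        assert set(result["subgroup"]) == {"all", "Val/Val", "Val/Met"}

    def test_zero_variance_flagged_nan(self, toy_table):
        result = spearman_correlations(
            {"feat": np.ones(8)}, toy_table, scores=["score_fds"], per_group=False
        )
        assert np.isnan(result["rho"].iloc[0])


def _with_score(table: SubjectTable, values) -> SubjectTable:
    frame = table.frame.copy()
    frame["score_lin"] = values
    return SubjectTable(frame=frame)


class TestLOOClassification:
    def test_separable_classes_classified_perfectly(self, rng):
        labels = np.array([0] * 20 + [1] * 16)
        feature = np.concatenate([
            rng.uniform(0.14, 0.18, 20), rng.uniform(0.10, 0.13, 16)
        ])
        report = loo_logistic_classify(feature, labels)
        assert report.accuracy == 1.0
        assert report.ppv == 1.0 and report.npv == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0

    def test_constant_feature_predicts_majority(self):
        labels = np.array([0] * 12 + [1] * 8)
        report = loo_logistic_classify(np.full(20, 0.5), labels)
        assert report.sensitivity == 0.0
        assert report.specificity == 1.0
        assert report.accuracy == pytest.approx(12 / 20)

    def test_matches_sklearn_unpenalized_fit(self, rng):
        from sklearn.linear_model import LogisticRegression

        labels = np.array([0] * 11 + [1] * 9)
        feature = rng.normal(0, 1, size=20) + 0.8 * labels
        mine = loo_logistic_classify(feature, labels)
        tp = fp = tn = fn = 0
        for held in range(20):
            mask = np.ones(20, dtype=bool)
            mask[held] = False
            clf = LogisticRegression(C=1e12, tol=1e-12, max_iter=10000)
            clf.fit(feature[mask, None], labels[mask])
            pred = int(clf.predict_proba(feature[held, None][None])[0, 1] > 0.5)
            if labels[held] == 1:
                tp, fn = (tp + 1, fn) if pred else (tp, fn + 1)
            else:
                fp, tn = (fp + 1, tn) if pred else (fp, tn + 1)
        assert (mine.tp, mine.fp, mine.tn, mine.fn) == (tp, fp, tn, fn)

    def test_report_identities_hold(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, size=24)
            if labels.min() == labels.max():
                continue
            feature = rng.normal(size=24)
            r = loo_logistic_classify(feature, labels)
            n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
            assert r.tp + r.fn == n_pos and r.tn + r.fp == n_neg
            assert r.accuracy == pytest.approx((r.tp + r.tn) / r.n)
            if r.tp + r.fp:
                assert r.ppv == pytest.approx(r.tp / (r.tp + r.fp))
            if r.tn + r.fn:
                assert r.npv == pytest.approx(r.tn / (r.tn + r.fn))
            assert r.ci_lower <= r.accuracy <= r.ci_upper

    def test_confusion_roundtrip_idempotent(self, rng):
        labels = np.array([0] * 20 + [1] * 16)
        feature = rng.normal(size=36) + 0.9 * labels
        report = loo_logistic_classify(feature, labels)
        rebuilt = confusion_from_rates(
            report.sensitivity, report.specificity, 16, 20
        )
        assert rebuilt.accuracy == report.accuracy
        assert rebuilt.ppv == report.ppv and rebuilt.npv == report.npv


TABLE2_ROWS = [
    # (feature, sens, spec, acc, ppv, npv, upper, lower) as printed
    ("subnetwork_strength", 0.875, 0.850, 0.861, 0.824, 0.895, 0.953, 0.705),
    ("lLSOcc-rSFG", 0.750, 0.700, 0.722, 0.667, 0.778, 0.858, 0.548),
    ("lLSOcc-lSFo", 0.625, 0.600, 0.611, 0.556, 0.667, 0.769, 0.435),
    ("lLSOcc-rMotor", 0.813, 0.600, 0.694, 0.619, 0.800, 0.837, 0.519),
    ("lLSOcc-lRectus", 0.688, 0.650, 0.667, 0.611, 0.722, 0.814, 0.490),
    ("lLSOcc-lACC", 0.813, 0.600, 0.694, 0.619, 0.800, 0.837, 0.519),
    ("rLSOcc-rSFo", 0.813, 0.650, 0.722, 0.650, 0.813, 0.858, 0.548),
    ("rLSOcc-rIFGo", 0.875, 0.650, 0.750, 0.667, 0.867, 0.879, 0.578),
    ("rLSOcc-lRectus", 0.875, 0.750, 0.806, 0.737, 0.882, 0.918, 0.640),
    ("rLSOcc-rRectus", 0.750, 0.600, 0.667, 0.600, 0.750, 0.814, 0.490),
]


class TestConfusionFromRates:
    @pytest.mark.parametrize("row", TABLE2_ROWS, ids=lambda r: r[0])
    def test_reconstructs_published_study_rows(self, row):
        """16 vs 20 group sizes; all derived metrics recoverable to 3 decimals."""
        _, sens, spec, acc, ppv, npv, upper, lower = row
        report = confusion_from_rates(sens, spec, n_pos=16, n_neg=20)
        assert report.accuracy == pytest.approx(acc, abs=5.1e-4)
        assert report.ppv == pytest.approx(ppv, abs=5.1e-4)
        assert report.npv == pytest.approx(npv, abs=5.1e-4)
        assert report.ci_upper == pytest.approx(upper, abs=5.1e-4)
        assert report.ci_lower == pytest.approx(lower, abs=5.1e-4)

    def test_perfect_rates(self):
        report = confusion_from_rates(1.0, 1.0, 16, 20)
        assert report.accuracy == 1.0 and report.ppv == 1.0 and report.npv == 1.0

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(DownstreamError, match="outside"):
            confusion_from_rates(1.2, 0.5, 16, 20)

    def test_wilson_interval_differs_from_clopper_pearson(self):
        cp = accuracy_interval(31, 36, method="clopper-pearson")
        wilson = accuracy_interval(31, 36, method="wilson")
        assert cp != wilson
        assert wilson[0] > cp[0] and wilson[1] < cp[1]  # Wilson is narrower


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    tp=st.integers(0, 16), tn=st.integers(0, 20),
)
def test_confusion_identities_exhaustive(tp, tn):
    """All metric identities hold for any confusion matrix of the study size."""
    from megconn.downstream import ClassificationReport

    r = ClassificationReport(tp=tp, fp=20 - tn, tn=tn, fn=16 - tp)
    assert r.n == 36
    assert r.accuracy == pytest.approx((tp + tn) / 36)
    sens = r.sensitivity
    assert sens == pytest.approx(tp / 16)
    rebuilt = confusion_from_rates(r.sensitivity, r.specificity, 16, 20)
    assert (rebuilt.tp, rebuilt.tn) == (tp, tn)


class TestNullAndComparativeBehaviour:
    def test_null_loo_accuracy_shows_pessimistic_bias(self):
        """On label-shuffled features the exact-MLE LOO logistic scores below
        the majority-class rate (the LOO slope anti-correlates with the
        held-out subject), but stays well above chance-flip levels."""
        from megconn.experiments import null_classifier_accuracy

        result = null_classifier_accuracy(n_sims=300, seed=99)
        assert result["mean_accuracy"] < result["majority_rate"]
        assert result["mean_accuracy"] > 0.40

    def test_strength_outperforms_median_single_link(self):
        """Subnetwork strength classifies at least as well as the median
        individual link, as a tendency over 50 planted cohorts."""
        from dataclasses import replace

        from megconn.experiments import study_config
        from megconn.synth import cohort_plv_stack, generate_metadata

        base = study_config(sampling_rate=125.0)
        links = base.planted_links
        rows = np.array([i for i, _ in links])
        cols = np.array([j for _, j in links])
        g = np.random.default_rng(314)
        strength_acc, median_link_acc = [], []
        for _ in range(50):
            cfg = replace(base, seed=int(g.integers(0, 2**31 - 1)))
            fc = cohort_plv_stack(cfg)
            table = generate_metadata(cfg)
            labels = table.group_indicator.astype(int)
            link_values = fc[:, rows, cols]
            strength_acc.append(
                loo_logistic_classify(link_values.mean(axis=1), labels).accuracy
            )
            per_link = [
                loo_logistic_classify(link_values[:, k], labels).accuracy
                for k in range(len(links))
            ]
            median_link_acc.append(np.median(per_link))
        assert np.mean(strength_acc) >= np.mean(median_link_acc)
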