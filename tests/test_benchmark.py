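"""Labeling rules, AUPRC, fold construction, strata, and correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from deltapwm import (
    SnvContext,
    SnvMeasurement,
    allelic_ratio_correlation,
    auprc,
    correlation_with_pbs,
    label_records,
    obs_quantile_strata,
    stratified_kfold,
)
from deltapwm.benchmark import EXCLUDED, NEGATIVE, POSITIVE, LabeledRecord, ranking_scores
from deltapwm.scoring import AllelicPrediction


def meas(pbs_p=0.5, obs_p=0.5, batch=1, tf="TF1", snv_id="s1", pbs=0.0, obs=0.0):
    ctx = SnvContext(snv_id, "A" * 19 + "C" + "A" * 20, 19, "C", "G")
    return SnvMeasurement(tf, ctx, pbs, pbs_p, obs, obs_p, batch)


class TestLabeling:
    @pytest.mark.parametrize("pbs_p,obs_p,expected", [
        (0.005, 0.01, POSITIVE),
        (0.6, 0.01, NEGATIVE),
        (0.1, 0.01, EXCLUDED),
        (0.005, 0.9, EXCLUDED),   # OBS not significant
        (0.6, 0.9, EXCLUDED),
    ])
    def test_batch1_rules(self, pbs_p, obs_p, expected):
        [lr] = label_records([meas(pbs_p, obs_p, batch=1)], batch=1)
        assert lr.label == expected

    @pytest.mark.parametrize("pbs_p,expected", [
        (0.005, POSITIVE),  # no OBS condition in batch 2
        (0.6, NEGATIVE),
        (0.1, EXCLUDED),
    ])
    def test_batch2_rules(self, pbs_p, expected):
        [lr] = label_records([meas(pbs_p, 0.9, batch=2)], batch=2)
        assert lr.label == expected

    def test_labeling_is_a_partition(self, rng):
        records = [meas(p, o, batch=1, snv_id=f"s{i}")
                   for i, (p, o) in enumerate(rng.uniform(0, 1, size=(200, 2)))]
        for batch in (1, 2):
            labels = [lr.label for lr in label_records(records, batch)]
            assert all(l in (POSITIVE, NEGATIVE, EXCLUDED) for l in labels)
            assert len(labels) == len(records)


def brute_force_auprc(scores, labels):
    """All-thresholds PR curve computed by direct counting (independent oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    pts = [(0.0, 1.0)]
    for t in sorted(set(scores), reverse=True):
        called = scores >= t
        tp = int((labels[called] == 1).sum())
        pts.append((tp / n_pos, tp / int(called.sum())))
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2
    return area


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([5, 4, 3, 1, 0], [1, 1, 1, 0, 0]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert auprc([4, 3, 2, 1], [1, 0, 1, 0]) == pytest.approx(0.5 + 0.5 * (0.5 + 2 / 3) / 2)

    def test_single_class_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(auprc([1, 2], [1, 1]))

    def test_matches_brute_force_on_all_small_labelings(self, rng):
        for n in range(2, 9):
            scores = rng.normal(size=n)
            scores[rng.integers(0, n)] = scores[0]  # inject a tie
            for labels in itertools.product([0, 1], repeat=n):
                if 0 < sum(labels) < n:
                    assert auprc(scores, labels) == pytest.approx(
                        brute_force_auprc(scores, labels), abs=1e-12)

    def test_matches_sklearn_pr_curve_area(self, rng):
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import precision_recall_curve

        scores = rng.normal(size=300)
        labels = (rng.uniform(size=300) < 0.3).astype(int)
        prec, rec, _ = precision_recall_curve(labels, scores)
        assert auprc(scores, labels) == pytest.approx(sk_auc(rec, prec), abs=1e-12)

    def test_random_scores_approach_prevalence(self, rng):
        scores = rng.normal(size=4000)
        labels = (rng.uniform(size=4000) < 0.5).astype(int)
        assert auprc(scores, labels) == pytest.approx(labels.mean(), abs=0.05)


def labeled_set(n_pos, n_neg):
    recs = [meas(0.001, 0.01, snv_id=f"p{i}") for i in range(n_pos)]
    recs += [meas(0.9, 0.01, snv_id=f"n{i}") for i in range(n_neg)]
    return label_records(recs, 1)


class TestStratifiedKfold:
    def test_divisible_case_balanced_exactly(self):
        folds = stratified_kfold(labeled_set(10, 90), k=5, seed=3)
        for fold in folds:
            assert sum(1 for lr in fold if lr.label == POSITIVE) == 2
            assert sum(1 for lr in fold if lr.label == NEGATIVE) == 18

    def test_partition_and_determinism(self):
        labeled = labeled_set(11, 52)
        folds_a = stratified_kfold(labeled, k=5, seed=9)
        folds_b = stratified_kfold(labeled, k=5, seed=9)
        ids = lambda folds: [[lr.measurement.snv.snv_id for lr in f] for f in folds]
        assert ids(folds_a) == ids(folds_b)
        flat = [i for f in ids(folds_a) for i in f]
        assert sorted(flat) == sorted(lr.measurement.snv.snv_id for lr in labeled)
        assert len(flat) == len(set(flat))
        counts = [sum(1 for lr in f if lr.label == POSITIVE) for f in folds_a]
        assert max(counts) - min(counts) <= 1

    def test_too_few_of_a_class(self):
        with pytest.raises(ValueError, match="each class"):
            stratified_kfold(labeled_set(3, 50), k=5)


class TestObsQuantiles:
    def _labeled_with_obs(self, n=100, rng=None):
        rng = rng or np.random.default_rng(5)
        recs = []
        for i in range(n):
            pbs_p = 0.001 if i % 3 == 0 else 0.9
            recs.append(meas(pbs_p, 0.01, snv_id=f"s{i}", obs=float(rng.normal())))
        labeled = label_records(recs, 1)
        preds = [AllelicPrediction(f"s{i}", "m", 0.5, 0.5, 0.0, False,
                                   float(rng.uniform()))
                 for i in range(n)]
        return labeled, preds

    def test_equal_count_strata(self):
        labeled, preds = self._labeled_with_obs(100)
        idx, table = obs_quantile_strata(labeled, preds, n_quantiles=5)
        assert list(table["n"]) == [20] * 5

    def test_indices_monotone_in_obs(self):
        labeled, preds = self._labeled_with_obs(100)
        idx, _ = obs_quantile_strata(labeled, preds, n_quantiles=5)
        obs = np.array([lr.measurement.obs_score for lr in labeled])
        order = np.argsort(obs, kind="stable")
        assert (np.diff(idx[order]) >= 0).all()

    def test_stratum_without_both_classes_is_nan(self):
        labeled, preds = self._labeled_with_obs(20)
        # force one stratum all-negative by relabeling
        labeled = [LabeledRecord(lr.measurement, NEGATIVE) for lr in labeled[:20]]
        with pytest.warns(UserWarning):
            _, table = obs_quantile_strata(labeled, preds, n_quantiles=4)
        assert table["auprc"].isna().all()


def pred_frame(tfs, snvs, delta, p_ref=None, p_alt=None):
    n = len(delta)
    return pd.DataFrame({
        "tf_name": tfs, "snv_id": snvs, "delta": delta,
        "p_ref": p_ref if p_ref is not None else np.full(n, 0.5),
        "p_alt": p_alt if p_alt is not None else np.full(n, 0.5),
    })


class TestCorrelations:
    def test_exact_linear_relation(self, rng):
        delta = rng.normal(size=50)
        preds = pred_frame(["T"] * 50, [f"s{i}" for i in range(50)], delta)
        meas_df = pd.DataFrame({"tf_name": ["T"] * 50, "snv_id": [f"s{i}" for i in range(50)],
                                "pbs_score": 2 * delta})
        r, p, sign, n = correlation_with_pbs(preds, meas_df, subset="all")
        assert r == pytest.approx(1.0) and sign == 1 and n == 50

    def test_negated_relation_flips_sign(self, rng):
        delta = rng.normal(size=30)
        preds = pred_frame(["T"] * 30, [f"s{i}" for i in range(30)], delta)
        meas_df = pd.DataFrame({"tf_name": ["T"] * 30, "snv_id": [f"s{i}" for i in range(30)],
                                "pbs_score": -delta})
        r, p, sign, n = correlation_with_pbs(preds, meas_df, subset="all")
        assert r == pytest.approx(-1.0) and sign == -1

    def test_strong_hits_subset_filters_on_best_allele_pvalue(self, rng):
        n = 40
        snvs = [f"s{i}" for i in range(n)]
        p_ref = np.where(np.arange(n) < 10, 1e-6, 0.5)
        preds = pred_frame(["T"] * n, snvs, rng.normal(size=n), p_ref=p_ref)
        meas_df = pd.DataFrame({"tf_name": ["T"] * n, "snv_id": snvs,
                                "pbs_score": rng.normal(size=n)})
        *_, n_used = correlation_with_pbs(preds, meas_df, subset="strong_hits",
                                          strong_hit_alpha=1e-4)
        assert n_used == 10

    def test_best_tf_per_snp_keeps_highest_pbs(self, rng):
        preds = pred_frame(["A", "B"], ["s1", "s1"], [0.1, 0.9])
        preds = pd.concat([preds, pred_frame(["A"], ["s2"], [0.5]),
                           pred_frame(["B"], ["s3"], [0.2])], ignore_index=True)
        meas_df = pd.DataFrame({
            "tf_name": ["A", "B", "A", "B"], "snv_id": ["s1", "s1", "s2", "s3"],
            "pbs_score": [1.0, 3.0, 0.5, 0.2]})
        r, p, sign, n = correlation_with_pbs(preds, meas_df, subset="best_tf_per_snp")
        assert n == 3  # one row per SNV

    def test_attenuation_matches_closed_form(self):
        rng = np.random.default_rng(123)
        n = 1000
        delta = rng.normal(size=n)
        sigma = 0.25 * delta.std()
        meas_df = pd.DataFrame({"tf_name": ["T"] * n, "snv_id": [f"s{i}" for i in range(n)],
                                "pbs_score": delta + rng.normal(0, sigma, n)})
        preds = pred_frame(["T"] * n, [f"s{i}" for i in range(n)], delta)
        r, *_ = correlation_with_pbs(preds, meas_df, subset="all")
        expected = 1.0 / np.sqrt(1.0 + sigma ** 2 / delta.var())
        assert r == pytest.approx(expected, abs=0.03)

    def test_too_few_pairs(self):
        preds = pred_frame(["T"], ["s1"], [0.1])
        meas_df = pd.DataFrame({"tf_name": ["T"], "snv_id": ["s1"], "pbs_score": [0.1]})
        with pytest.raises(ValueError, match="fewer than 3"):
            correlation_with_pbs(preds, meas_df)


class TestAllelicRatioCorrelation:
    def _data(self, rng, n=60):
        delta = rng.normal(size=n)
        snvs = [f"s{i}" for i in range(n)]
        p_ref = rng.uniform(0, 0.02, size=n)
        preds = pred_frame(["T"] * n, snvs, delta, p_ref=p_ref)
        asb = pd.DataFrame({"tf_name": ["T"] * n, "snv_id": snvs,
                            "allelic_ratio": 1 / (1 + np.exp(-delta))})
        return preds, asb

    def test_no_filter_equals_permissive_filter(self, rng):
        preds, asb = self._data(rng)
        assert allelic_ratio_correlation(asb, preds, None) == \
            allelic_ratio_correlation(asb, preds, 1.1)

    def test_tightening_filter_never_increases_n(self, rng):
        preds, asb = self._data(rng)
        ns = [allelic_ratio_correlation(asb, preds, f)[2] for f in (1.0, 0.01, 0.005)]
        assert ns == sorted(ns, reverse=True)

    def test_monotone_ratios_correlate_positively(self, rng):
        preds, asb = self._data(rng)
        r, p, n = allelic_ratio_correlation(asb, preds, None)
        assert r > 0.9 and p < 1e-6


def test_ranking_scores_order_negatives_by_best_pvalue():
    preds = [
        AllelicPrediction("a", "m", 0.5, 0.5, 0.3, False, 0.3),
        AllelicPrediction("b", "m", 0.02, 0.9, 0.0, True, 0.0),
        AllelicPrediction("c", "m", 0.4, 0.9, 0.0, True, 0.0),
    ]
    s = ranking_scores(preds)
    assert s[0] > s[1] > s[2]  # scored first, then negatives by smaller min p
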