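"""Classification experiments, ROC aggregation, tSNE, Wasserstein distances."""

import numpy as np
import pandas as pd
import pytest

from dwiharm.classify import (
    collect_roi_samples,
    loso_cv,
    roc_auc,
    roc_from_report,
    tsne_embed,
    wasserstein_matrix,
)
from dwiharm.classify import test_retest_cv as run_test_retest
from dwiharm.errors import FoldError, PairingError

ORGANS = ["kidney", "kidney", "liver", "liver", "liver", "spleen", "spleen",
          "muscle", "muscle", "vertebra", "vertebra"]


def separable_table(n_sites=7, noise=0.01, seed=0, timepoint="t1"):
    """One-hot organ features: linearly separable by construction."""
    rng = np.random.default_rng(seed)
    organs = sorted(set(ORGANS))
    rows = []
    for s in range(n_sites):
        for label, organ in enumerate(ORGANS, start=1):
            feats = {f"f_{o}": float(o == organ) + noise * rng.normal()
                     for o in organs}
            rows.append({"site": chr(65 + s), "timepoint": timepoint,
                         "roi_label": label, "roi_name": f"roi{label}",
                         "organ_class": organ, **feats})
    return pd.DataFrame(rows)


def wasserstein_oracle(a, b):
    """L1 distance between empirical quantile functions (CDF integral)."""
    a, b = np.sort(a), np.sort(b)
    grid = np.sort(np.concatenate([a, b]))
    cdf_a = np.searchsorted(a, grid[:-1], side="right") / a.size
    cdf_b = np.searchsorted(b, grid[:-1], side="right") / b.size
    return float(np.sum(np.abs(cdf_a - cdf_b) * np.diff(grid)))


class TestLoso:
    def test_separable_features_perfect_accuracy(self):
        report = loso_cv(separable_table(), n_runs=2, seed=0, n_estimators=50)
        assert report.overall_accuracy == 1.0
        assert (report.per_site["accuracy_sd"] == 0.0).all()

    def test_run_and_site_structure(self):
        report = loso_cv(separable_table(n_sites=3), n_runs=4, seed=1,
                         n_estimators=20)
        assert report.run_accuracies.shape == (4, 3)
        assert report.config["n_runs"] == 4
        assert list(report.per_site["site"]) == ["A", "B", "C"]

    def test_shared_seed_mode_has_zero_run_variance(self):
        table = separable_table(noise=0.8, seed=3)
        report = loso_cv(table, n_runs=3, seed=5, n_estimators=30,
                         shared_seed=True)
        # run-to-run variance is numerically zero (up to float rounding,
        # the familiar ~1e-16 SDs of shared-seed forests)
        assert np.all(report.run_accuracies.std(axis=0) < 1e-12)

    def test_missing_class_in_fold_raises(self):
        table = separable_table(n_sites=3)
        table = table[~((table["site"] != "C") & (table["organ_class"] == "liver"))]
        with pytest.raises(FoldError, match="liver"):
            loso_cv(table, n_runs=1, n_estimators=10)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            loso_cv(separable_table(n_sites=2), n_runs=1, n_estimators=10)


class TestTestRetest:
    def test_identical_timepoints_perfect(self):
        t1 = separable_table()
        t2 = t1.assign(timepoint="t2")
        report = run_test_retest(t1, t2, n_runs=2, seed=0, n_estimators=50)
        assert report.overall_accuracy == 1.0
        assert report.config["n_runs"] == 2

    def test_noise_timepoint2_near_chance(self):
        rng = np.random.default_rng(8)
        t1 = separable_table()
        t2 = t1.copy()
        feats = [c for c in t1.columns if c.startswith("f_")]
        t2[feats] = rng.normal(size=t2[feats].shape)
        report = run_test_retest(t1, t2, n_runs=3, seed=0, n_estimators=100)
        assert abs(report.overall_accuracy - 0.2) < 0.15

    def test_key_mismatch_raises(self):
        t1 = separable_table()
        t2 = t1[t1["roi_label"] != 5]
        with pytest.raises(PairingError):
            run_test_retest(t1, t2, n_runs=1, n_estimators=10)


class TestRocAuc:
    def test_three_of_four_concordant_pairs(self):
        scores = np.array([0.9, 0.4, 0.8, 0.3])
        labels = np.array([1, 1, 0, 0])
        roc = roc_auc(scores, labels)
        assert roc["mean_auc"] == pytest.approx(0.75)

    def test_perfect_ordering(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        roc = roc_auc(scores, np.array([1, 1, 0, 0]))
        assert roc["mean_auc"] == pytest.approx(1.0)
        assert roc["mean_tpr"][1:].min() == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        roc = roc_auc(rng.uniform(size=n), rng.integers(0, 2, n))
        assert abs(roc["mean_auc"] - 0.5) < 3.0 / np.sqrt(n)

    def test_single_class_group_skipped(self, caplog):
        scores = np.array([0.9, 0.4, 0.8, 0.3])
        labels = np.array([1, 1, 1, 0])
        grouping = np.array([0, 0, 1, 1])
        roc = roc_auc(scores, labels, grouping=grouping)
        # group 0 (positives only) is skipped; group 1 contributes the
        # two mirrored one-vs-rest curves of a binary problem
        assert roc["n_curves"] == 2

    def test_report_aggregation_axes(self):
        report = loso_cv(separable_table(n_sites=3), n_runs=2, n_estimators=20)
        roc = roc_from_report(report)
        # 2 runs × 3 sites × 5 organ curves
        assert roc["n_curves"] == 30
        assert roc["mean_auc"] > 0.9
        assert roc["fpr_grid"].shape == (101,)


class TestTsne:
    def test_shape_finite_and_deterministic(self):
        table = separable_table(n_sites=3)
        e1 = tsne_embed(table, seed=4)
        e2 = tsne_embed(table, seed=4)
        assert e1.shape == (33, 2)
        assert np.all(np.isfinite(e1))
        np.testing.assert_array_equal(e1, e2)

    def test_two_cluster_structure_preserved(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(2)
        X = np.r_[rng.normal(0, 0.3, (20, 5)), rng.normal(4, 0.3, (20, 5))]
        labels = np.r_[np.zeros(20), np.ones(20)]
        emb = tsne_embed(X, seed=0)
        assert silhouette_score(emb, labels) > 0

    def test_min_rows_and_perplexity_shrink(self):
        with pytest.raises(ValueError):
            tsne_embed(np.zeros((4, 3)), seed=0)
        with pytest.warns(UserWarning, match="perplexity"):
            tsne_embed(np.random.default_rng(0).normal(size=(8, 3)), seed=0)


class TestWasserstein:
    def test_identical_distributions_zero(self):
        dm = wasserstein_matrix({"a": np.array([1.0, 2.0, 3.0]),
                                 "b": np.array([1.0, 2.0, 3.0])})
        assert dm.raw[0, 1] == 0.0

    def test_point_mass_transport(self):
        dm = wasserstein_matrix({"a": np.array([0.0, 0.0]),
                                 "b": np.array([1.0, 1.0])})
        assert dm.raw[0, 1] == pytest.approx(1.0)

    def test_matches_quantile_integral_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 30))
            b = rng.gamma(2.0, 1.0, size=rng.integers(2, 30))
            dm = wasserstein_matrix({"a": a, "b": b})
            assert dm.raw[0, 1] == pytest.approx(wasserstein_oracle(a, b),
                                                 rel=1e-10)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            samples = {k: rng.normal(rng.uniform(-2, 2), 1.0, 25)
                       for k in "abc"}
            dm = wasserstein_matrix(samples)
            assert np.allclose(dm.raw, dm.raw.T)
            assert np.all(np.diag(dm.raw) == 0)
            for i, j, k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
                assert dm.raw[i, j] <= dm.raw[i, k] + dm.raw[k, j] + 1e-12

    def test_normalization_bounds_and_extremes(self):
        rng = np.random.default_rng(11)
        dm = wasserstein_matrix({k: rng.normal(i, 1.0, 30)
                                 for i, k in enumerate("abcd")})
        off = dm.normalized[~np.eye(4, dtype=bool)]
        assert off.min() == 0.0 and off.max() == 1.0
        assert np.all((dm.normalized >= 0) & (dm.normalized <= 1))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_matrix({"a": np.array([]), "b": np.array([1.0])})

    def test_binned_input_supported(self):
        # histogram form of {0,0} vs {1,1}
        dm = wasserstein_matrix({
            "a": (np.array([0.0]), np.array([2.0])),
            "b": (np.array([1.0]), np.array([2.0])),
        })
        assert dm.raw[0, 1] == pytest.approx(1.0)

    def test_within_organ_closer_than_between(self, test_retest_study):
        """The organ-block structure of the distance heatmap."""
        from dwiharm.adcfit import compute_adc_map

        samples = {}
        for sid, rec in test_retest_study.sites.items():
            for tp, series, rois in (("t1", rec.dwi, rec.rois),
                                     ("t2", rec.dwi_retest, rec.rois_retest)):
                adc = compute_adc_map(series)
                samples.update(collect_roi_samples(
                    adc.values, rois, adc.valid_mask, site=sid, timepoint=tp))
        dm = wasserstein_matrix(samples)
        organs = np.array([k[0] for k in dm.labels])
        same = organs[:, None] == organs[None, :]
        off = ~np.eye(len(organs), dtype=bool)
        within = dm.normalized[same & off].mean()
        between = dm.normalized[~same].mean()
        assert within < between
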