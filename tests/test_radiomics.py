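"""Preprocessing, feature extraction and two-stage selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dwiharm.core import ROISet
from dwiharm.errors import DegenerateInputError
from dwiharm.pipeline import select_features, study_feature_table
from dwiharm.radiomics import (
    AnovaFSelector,
    StabilityFilter,
    anova_select,
    extract_features,
    feature_columns,
    histogram_match,
    resample_isotropic,
    stability_filter,
)
from dwiharm.reproducibility import roi_stats
from dwiharm.synthdata import make_roi_masks


def anova_f_oracle(values, groups):
    """Brute-force one-way ANOVA F via explicit SSB/SSW."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    grand = values.mean()
    ssb = ssw = 0.0
    classes = np.unique(groups)
    for c in classes:
        sel = values[groups == c]
        ssb += sel.size * (sel.mean() - grand) ** 2
        ssw += ((sel - sel.mean()) ** 2).sum()
    df_b = classes.size - 1
    df_w = values.size - classes.size
    return (ssb / df_b) / (ssw / df_w)


class TestResample:
    def test_identity_on_isotropic_input(self):
        rng = np.random.default_rng(0)
        vol = rng.uniform(0, 100, (12, 10, 8))
        out, spacing = resample_isotropic(vol, (1.0, 1.0, 1.0))
        assert spacing == (1.0, 1.0, 1.0)
        np.testing.assert_allclose(out, vol, atol=1e-10)

    def test_constant_volume_dimensions_scale(self):
        vol = np.full((10, 10, 6), 5.0)
        out, _ = resample_isotropic(vol, (2.0, 2.0, 2.0))
        assert out.shape == (20, 20, 12)
        np.testing.assert_allclose(out, 5.0)

    def test_mask_stays_binary(self):
        mask = np.zeros((10, 10, 6), dtype=np.int16)
        mask[3:7, 3:7, 2:4] = 1
        out, _ = resample_isotropic(mask, (2.6, 2.6, 5.0), is_mask=True)
        assert set(np.unique(out)) <= {0, 1}
        assert out.dtype == mask.dtype


class TestHistogramMatch:
    @staticmethod
    def _foreground_landmarks(vol, q=np.linspace(0.05, 0.95, 10)):
        fg = vol[vol > vol.mean()]
        return np.quantile(fg, q)

    def test_self_match_preserves_landmarks(self):
        rng = np.random.default_rng(1)
        vol = rng.gamma(4.0, 50.0, (24, 24, 8))
        out = histogram_match(vol, vol)
        width = (vol.max() - vol.min()) / 128
        assert np.all(np.abs(self._foreground_landmarks(out)
                             - self._foreground_landmarks(vol)) <= width + 1e-9)

    def test_doubling_gain_is_removed(self):
        rng = np.random.default_rng(2)
        ref = rng.gamma(4.0, 50.0, (24, 24, 8))
        out = histogram_match(2.0 * ref, ref)
        width = (ref.max() - ref.min()) / 128
        assert np.all(np.abs(self._foreground_landmarks(out)
                             - self._foreground_landmarks(ref)) <= 2 * width)

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateInputError):
            histogram_match(np.ones((5, 5, 5)), np.zeros((5, 5, 5)) + 2.0)

    def test_matching_shrinks_cross_site_gain_spread(self, traveling_study):
        """Cross-site SD of liver T2w ROI means drops after matching."""
        ref = traveling_study.sites["F"].t2w
        before, after = [], []
        for sid, rec in traveling_study.sites.items():
            rois = rec.rois
            raw = roi_stats(rec.t2w, rois)
            matched = roi_stats(histogram_match(rec.t2w, ref) if sid != "F"
                                else rec.t2w, rois)
            before.append(raw[raw.organ_class == "liver"]["mean"].mean())
            after.append(matched[matched.organ_class == "liver"]["mean"].mean())
        assert np.std(after) < np.std(before)


def tiny_roiset(coords, shape=(6, 6, 2), organ="liver"):
    masks = np.zeros(shape, dtype=np.int16)
    for c in coords:
        masks[c] = 1
    return ROISet(masks=masks, label_names={1: "roi"},
                  organ_of_label={1: organ}, spacing=(1.0, 1.0, 1.0))


class TestExtractFeatures:
    def test_feature_count_is_26(self, traveling_study):
        rec = traveling_study.sites["A"]
        table = extract_features(rec.t2w, rec.rois, site="A")
        assert len(feature_columns(table)) == 26
        assert len(table) == 11
        assert not table[feature_columns(table)].isna().any().any()

    def test_constant_roi_degenerate_conventions(self):
        rois = tiny_roiset([(i, j, 0) for i in range(4) for j in range(4)])
        vol = np.full(rois.masks.shape, 3.0)
        row = extract_features(vol, rois, min_voxels=1).iloc[0]
        assert row["fo_sd"] == 0.0
        assert row["fo_skewness"] == 0.0
        assert row["fo_uniformity"] == 1.0
        assert row["glcm_contrast"] == 0.0
        assert row["fo_entropy"] == 0.0

    def test_two_voxel_roi_hand_computed(self):
        rois = tiny_roiset([(0, 0, 0), (0, 1, 0)])
        vol = np.zeros(rois.masks.shape)
        vol[0, 1, 0] = 2.0
        row = extract_features(vol, rois, min_voxels=1).iloc[0]
        assert row["fo_mean"] == 1.0
        assert row["fo_range"] == 2.0
        assert row["fo_variance"] == 1.0  # population convention
        assert row["fo_energy"] == 4.0
        assert row["fo_rms"] == pytest.approx(np.sqrt(2.0))

    def test_small_roi_skipped(self, caplog):
        rois = tiny_roiset([(0, 0, 0), (0, 1, 0)])
        table = extract_features(np.ones(rois.masks.shape), rois, min_voxels=10)
        assert len(table) == 0


def site_tables(values_by_site):
    """Feature tables with one feature over 11 ROI labels per site."""
    out = {}
    for site, vals in values_by_site.items():
        out[site] = pd.DataFrame({
            "site": site,
            "roi_label": range(1, len(vals) + 1),
            "organ_class": "liver",
            "feat": vals,
        })
    return out


class TestStabilityFilter:
    def test_identical_feature_scores_one(self):
        v = list(np.linspace(1, 11, 11))
        scores, survivors = stability_filter(site_tables({"A": v, "B": v, "C": v}))
        assert scores["feat"] == pytest.approx(1.0)
        assert survivors == ["feat"]

    def test_sign_flip_still_scores_one(self):
        v = np.linspace(1, 11, 11)
        scores, _ = stability_filter(site_tables({"A": list(v), "B": list(-v)}))
        assert scores["feat"] == pytest.approx(1.0)

    def test_independent_noise_removed(self):
        rng = np.random.default_rng(3)
        tabs = site_tables({s: list(rng.normal(size=11)) for s in "ABCDEFG"})
        scores, survivors = stability_filter(tabs)
        assert scores["feat"] < 0.75
        assert survivors == []

    def test_zero_variance_pair_scores_zero(self, caplog):
        scores, _ = stability_filter(
            site_tables({"A": [1.0] * 11, "B": list(range(11))}))
        assert scores["feat"] == 0.0

    @given(a=st.floats(min_value=0.1, max_value=10.0),
           b=st.floats(min_value=-100.0, max_value=100.0))
    def test_invariant_under_per_site_affine_rescaling(self, a, b):
        rng = np.random.default_rng(5)
        base = {s: list(rng.normal(size=11)) for s in "ABC"}
        s0, _ = stability_filter(site_tables(base))
        scaled = dict(base)
        scaled["B"] = [a * v + b for v in base["B"]]
        s1, _ = stability_filter(site_tables(scaled))
        assert s1["feat"] == pytest.approx(s0["feat"], rel=1e-9)

    def test_mismatched_roi_labels_rejected(self):
        tabs = site_tables({"A": list(range(11)), "B": list(range(11))})
        tabs["B"] = tabs["B"].iloc[:-1]
        with pytest.raises(ValueError):
            stability_filter(tabs)


class TestAnovaSelect:
    def _table(self, feat_values, classes):
        return pd.DataFrame({"organ_class": classes, "f1": feat_values})

    def test_worked_example_f_equals_8(self):
        table = self._table([1.0, 2.0, 3.0, 4.0], ["A", "A", "B", "B"])
        res = anova_select(table, ["f1"], n_select=1)
        assert res.f_score["f1"] == pytest.approx(8.0, rel=1e-12)

    def test_matches_ssb_ssw_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            classes = rng.choice(list("ABCDE"), size=40)
            while np.unique(classes).size < 2 or min(
                    np.bincount(pd.factorize(classes)[0])) < 2:
                classes = rng.choice(list("ABCDE"), size=40)
            vals = rng.normal(size=40)
            res = anova_select(self._table(vals, classes), ["f1"], n_select=1)
            oracle = anova_f_oracle(vals, classes)
            assert res.f_score["f1"] == pytest.approx(oracle, rel=1e-10)

    def test_constant_feature_never_beats_varying(self):
        rng = np.random.default_rng(4)
        classes = ["A"] * 10 + ["B"] * 10
        table = pd.DataFrame({
            "organ_class": classes,
            "const": 5.0,
            "vary": np.r_[rng.normal(0, 1, 10), rng.normal(3, 1, 10)],
        })
        res = anova_select(table, ["const", "vary"], n_select=1)
        assert res.f_score["const"] == 0.0
        assert res.selected == ["vary"]

    def test_selects_exactly_15_when_enough_survive(self, traveling_study):
        table = study_feature_table(traveling_study, "adc", resample=False)
        res = select_features(table)
        assert len(res.selected) == 15
        assert set(res.selected) <= {f for f, s in res.stability_score.items()
                                     if s >= 0.75}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            anova_select(self._table([1.0, 2.0], ["A", "A"]), ["f1"])


class TestTransformers:
    def test_pipeline_composition(self, traveling_study):
        from sklearn.pipeline import Pipeline

        table = study_feature_table(traveling_study, "adc", resample=False)
        pipe = Pipeline([
            ("stability", StabilityFilter(threshold=0.75)),
            ("anova", AnovaFSelector(n_select=15)),
        ])
        out = pipe.fit_transform(table)
        assert len(feature_columns(out)) == 15
        assert pipe.named_steps["stability"].stability_scores_.shape[0] == 26
        # facade agrees with the functional path
        res = select_features(table)
        assert sorted(pipe.named_steps["anova"].selected_) == sorted(res.selected)

    def test_get_params_round_trip(self):
        f = StabilityFilter(threshold=0.8)
        assert f.get_params() == {"threshold": 0.8}
        f.set_params(threshold=0.6)
        assert f.threshold == 0.6


class TestPipelineRecovery:
    def _planted_tables(self, study, seed):
        """Feature table with a stable-discriminative and a confounded plant."""
        table = study_feature_table(study, "adc", resample=False)
        rng = np.random.default_rng(seed)
        organ_code = {o: i for i, o in enumerate(sorted(set(table["organ_class"])))}
        roi_offset = table["roi_label"].to_numpy() * 0.37
        table["planted_stable"] = (
            100.0 * table["organ_class"].map(organ_code).to_numpy() + roi_offset
        )
        gains = {p.site_id: p.gain for p in study.manifest}
        table["planted_confounded"] = (
            table["site"].map(gains).to_numpy()
            + 0.02 * rng.normal(size=len(table))
        )
        return table

    @pytest.mark.parametrize("seed", [0, 1])
    def test_planted_features_resolved(self, traveling_study, seed):
        table = self._planted_tables(traveling_study, seed)
        res = select_features(table)
        assert "planted_stable" in res.selected
        assert res.stability_score["planted_confounded"] < 0.75
        assert "planted_confounded" not in res.selected
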