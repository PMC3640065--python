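"""Regional summaries, 112-element QA vector, cohort PCA and outlier flags."""

import numpy as np
import pandas as pd
import pytest

from dtiqa import dti_core
from dtiqa.noise_and_sampling import subsample_voxels
from dtiqa.qa_features import (
    QaFeatureVector,
    build_feature_vector,
    default_pooling_map,
    embed_cohort,
    flag_outliers,
    summarize_regions,
    vectors_to_frame,
)


@pytest.fixture(scope="module")
def summary_inputs(noisy_phantom):
    study, _ = noisy_phantom
    fit = dti_core.fit_study(study)
    vs = subsample_voxels(study.labels, fit.mask, target_fraction=0.05, seed=0)
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "region": vs.regions,
            "sigma_fa": rng.uniform(0.01, 0.05, vs.regions.size),
            "bias_fa": rng.uniform(0.0, 0.05, vs.regions.size),
        }
    )
    return study, fit, table


class TestSummaries:
    def test_both_region_sets_and_four_metrics(self, summary_inputs):
        study, fit, table = summary_inputs
        summary = summarize_regions(fit, study.labels, table)
        t = summary.table
        assert set(t["metric"]) == {"md", "fa", "sigma_fa", "bias_fa"}
        full = t[t["region_set"] == "full"]
        pooled = t[t["region_set"] == "pooled"]
        assert full["region"].nunique() == 25
        assert pooled["region"].nunique() == 14

    def test_pooled_mean_is_count_weighted_combination(self, summary_inputs):
        """Pooled mean recomputes from the union of left+right voxels."""
        study, fit, table = summary_inputs
        summary = summarize_regions(fit, study.labels, table)
        t = summary.table
        row = t[(t["region_set"] == "pooled") & (t["region"] == "pair_01")
                & (t["metric"] == "fa")].iloc[0]
        raw = fit.fa[np.isin(study.labels, [1, 2]) & fit.mask]
        assert row["mean"] == pytest.approx(raw.mean(), rel=1e-12)
        assert row["n"] == raw.size

    def test_constant_region_collapses_boxplot(self, scheme32):
        table = pd.DataFrame(
            {"region": np.ones(60, int), "sigma_fa": np.full(60, 0.03),
             "bias_fa": np.full(60, 0.01)}
        )
        labels = np.ones((4, 4, 4), int)
        fa = np.full((4, 4, 4), 0.5)
        fit = dti_core.TensorFit(
            tensors=None, eigenvalues=None, e1=None, fa=fa, md=fa * 1e-3,
            squared_error=None, mask=np.ones((4, 4, 4), bool),
            s_measured=None, s_fitted=None, scheme=scheme32,
        )
        t = summarize_regions(fit, labels, table,
                              pooling={"only": [1]}).table
        row = t[(t["region_set"] == "full") & (t["metric"] == "fa")].iloc[0]
        assert row["sd"] == 0.0
        assert row["q1"] == row["q3"] == row["median"]


class TestFeatureVector:
    def test_length_112_and_canonical_names(self, summary_inputs):
        study, fit, table = summary_inputs
        summary = summarize_regions(fit, study.labels, table)
        vec = build_feature_vector(summary)
        assert vec.values.size == 112
        assert vec.names[0] == "mid_01_md_mean"
        assert len(set(vec.names)) == 112

    def test_deterministic_for_identical_inputs(self, summary_inputs):
        study, fit, table = summary_inputs
        v1 = build_feature_vector(summarize_regions(fit, study.labels, table))
        v2 = build_feature_vector(summarize_regions(fit, study.labels, table))
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_voxel_order_invariance(self, summary_inputs):
        study, fit, table = summary_inputs
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        v1 = build_feature_vector(summarize_regions(fit, study.labels, table))
        v2 = build_feature_vector(summarize_regions(fit, study.labels, shuffled))
        np.testing.assert_allclose(v1.values, v2.values, rtol=1e-12)

    def test_wrong_region_count_rejected(self, summary_inputs):
        study, fit, table = summary_inputs
        summary = summarize_regions(fit, study.labels, table,
                                    pooling={"a": [1], "b": [2]})
        with pytest.raises(ValueError, match="112"):
            build_feature_vector(summary)
        vec = build_feature_vector(summary, expected_length=None)
        assert vec.values.size == 16


def _cohort(rng, n, shift=0.0, scale=1.0, ids=None):
    base = rng.normal(0, 1, size=(n, 112)) * scale + shift
    return [
        QaFeatureVector(values=base[i], names=[f"f{k}" for k in range(112)],
                        dataset_id=(ids[i] if ids else str(i)))
        for i in range(n)
    ]


class TestEmbedding:
    def test_duplicated_datasets_coincide(self):
        rng = np.random.default_rng(0)
        vecs = _cohort(rng, 4)
        vecs.append(QaFeatureVector(values=vecs[0].values.copy(),
                                    names=vecs[0].names, dataset_id="dup"))
        emb = embed_cohort(vecs)
        np.testing.assert_allclose(emb.scores[0], emb.scores[-1], atol=1e-10)

    def test_explained_variance_properties(self):
        rng = np.random.default_rng(1)
        emb = embed_cohort(_cohort(rng, 10), n_components=3)
        evr = emb.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-12

    def test_constant_shift_of_one_metric_invariant(self):
        """Adding a constant to a feature across the cohort changes nothing
        (z-scoring removes location)."""
        rng = np.random.default_rng(2)
        vecs = _cohort(rng, 8)
        shifted = [
            QaFeatureVector(values=v.values + np.r_[np.full(10, 5.0),
                                                    np.zeros(102)],
                            names=v.names, dataset_id=v.dataset_id)
            for v in vecs
        ]
        e1 = embed_cohort(vecs)
        e2 = embed_cohort(shifted)
        np.testing.assert_allclose(e1.scores, e2.scores, atol=1e-8)

    def test_constant_columns_dropped(self):
        rng = np.random.default_rng(3)
        vecs = _cohort(rng, 6)
        for v in vecs:
            v.values[7] = 3.3
        emb = embed_cohort(vecs)
        assert 7 in emb.dropped_columns
        assert emb.zscored.shape[1] == 111

    def test_z_scored_columns(self):
        rng = np.random.default_rng(4)
        emb = embed_cohort(_cohort(rng, 9))
        np.testing.assert_allclose(emb.zscored.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(emb.zscored.std(axis=0), 1.0, atol=1e-10)

    def test_too_few_datasets_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="3"):
            embed_cohort(_cohort(rng, 2))

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(6)
        vecs = _cohort(rng, 10)
        e1 = embed_cohort(vecs)
        e2 = embed_cohort(vecs)
        np.testing.assert_array_equal(e1.scores, e2.scores)
        for c in range(e1.loadings.shape[0]):
            assert e1.loadings[c, np.abs(e1.loadings[c]).argmax()] > 0


class TestOutlierFlags:
    def test_homogeneous_group_unflagged(self):
        rng = np.random.default_rng(7)
        emb = embed_cohort(_cohort(rng, 10))
        flags = flag_outliers(emb, ["g"] * 10)
        assert not flags["flagged"].any()

    def test_threshold_infinity_never_flags(self):
        rng = np.random.default_rng(8)
        vecs = _cohort(rng, 8) + _cohort(rng, 1, shift=30.0)
        emb = embed_cohort(vecs)
        flags = flag_outliers(emb, ["g"] * 9, threshold=np.inf)
        assert not flags["flagged"].any()

    def test_small_group_skipped(self):
        rng = np.random.default_rng(9)
        emb = embed_cohort(_cohort(rng, 6))
        flags = flag_outliers(emb, ["a"] * 3 + ["b"] * 3, min_group_size=4)
        assert flags["skipped"].all()

    def test_planted_outlier_flagged(self):
        rng = np.random.default_rng(10)
        vecs = _cohort(rng, 9)
        vecs.append(QaFeatureVector(values=vecs[0].values + 40.0,
                                    names=vecs[0].names, dataset_id="bad"))
        emb = embed_cohort(vecs)
        flags = flag_outliers(emb, ["g"] * 10)
        assert flags.loc[flags["dataset"] == 9, "flagged"].item()

    def test_frame_export(self):
        rng = np.random.default_rng(11)
        vecs = _cohort(rng, 3, ids=["a", "b", "c"])
        frame = vectors_to_frame(vecs)
        assert frame.shape == (3, 114)
        assert frame["dataset_id"].tolist() == ["a", "b", "c"]
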