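import numpy as np
import pandas as pd
import pytest

from litterlab.metabolomics import (
    FeatureMatrix, FilterReport, autocorr_filter, blank_sn_filter,
    log_autoscale, pca_scores, permanova, plsda_vip, qc_cv_filter, top_vips,
)


def tiny_matrix(rows, rts=None):
    """Build a FeatureMatrix from {feature_id: [4 samples, 2 blanks, 3 pools]}."""
    ids = list(rows)
    data = pd.DataFrame([rows[i] for i in ids], index=ids, columns=[
        "sample_ND_1", "sample_ND_2", "sample_AD_1", "sample_AD_2",
        "blank_B_1", "blank_B_2", "pool_QC_1", "pool_QC_2", "pool_QC_3"])
    rts = rts or {i: 1.0 + j for j, i in enumerate(ids)}
    features = pd.DataFrame(
        {"mz": np.linspace(100, 200, len(ids)),
         "rt_min": [rts[i] for i in ids]}, index=pd.Index(ids))
    roles = pd.Series({c: c.split("_")[0] for c in data.columns})
    groups = pd.Series({c: c.split("_")[1] for c in data.columns})
    return FeatureMatrix(features=features, intensities=data,
                         roles=roles, groups=groups)


def test_blank_filter_ratio_arithmetic():
    m = tiny_matrix({
        "A": [1000, 1000, 1000, 1000, 50, 50, 900, 900, 900],   # S/N 20
        "B": [90, 90, 90, 90, 10, 10, 80, 80, 80],              # S/N 9
        "C": [40, 40, 40, 40, 0, 0, 40, 40, 40],                # blank-free
    })
    filtered, report = blank_sn_filter(m, sn_threshold=10)
    assert set(filtered.features.index) == {"A", "C"}
    assert report.removed == ("B",)
    assert report.n_before - len(report.removed) == report.n_after


def test_blank_filter_requires_blanks():
    m = tiny_matrix({"A": [1, 1, 1, 1, 0, 0, 1, 1, 1]})
    m.roles[:] = "sample"
    with pytest.raises(ValueError, match="blank"):
        blank_sn_filter(m)


def test_cv_filter_sample_sd_convention():
    m = tiny_matrix({
        "A": [10, 10, 10, 10, 0, 0, 100, 100, 100],  # CV 0
        "B": [10, 10, 10, 10, 0, 0, 100, 200, 300],  # CV 0.5
        "C": [10, 10, 10, 10, 0, 0, 95, 100, 105],   # CV 0.05
        "D": [10, 10, 10, 10, 0, 0, 0, 0, 0],        # zero pools -> removed
    })
    filtered, report = qc_cv_filter(m, cv_threshold=0.3)
    assert set(filtered.features.index) == {"A", "C"}
    assert set(report.removed) == {"B", "D"}


def test_autocorr_filter_keeps_most_intense_coeluter():
    x = [100.0, 120.0, 90.0, 110.0]
    m = tiny_matrix({
        "A": x + [0, 0, 100, 100, 100],
        "B": [2 * v for v in x] + [0, 0, 200, 200, 200],
        "C": x + [0, 0, 100, 100, 100],
    }, rts={"A": 1.00, "B": 1.02, "C": 5.0})
    filtered, report = autocorr_filter(m, r_threshold=0.9, rt_tol_min=0.05)
    # A and B co-elute and are proportional: the weaker one (A) goes;
    # C is identical to A but elutes far away, so the RT gate protects it
    assert report.removed == ("A",)
    assert set(filtered.features.index) == {"B", "C"}


def test_autocorr_transitive_grouping():
    x = np.array([100.0, 120.0, 90.0, 110.0])
    m = tiny_matrix({
        "A": list(x) + [0, 0, 1, 1, 1],
        "B": list(2 * x) + [0, 0, 1, 1, 1],
        "C": list(3 * x) + [0, 0, 1, 1, 1],
    }, rts={"A": 1.00, "B": 1.04, "C": 1.08})
    # A-B and B-C are within the RT gate, A-C is not: one group via closure
    filtered, report = autocorr_filter(m, rt_tol_min=0.05)
    assert set(report.removed) == {"A", "B"}


def test_filter_chain_removes_planted_artifacts_exactly(metabo_fixture):
    matrix, truth = metabo_fixture
    f1, r1 = blank_sn_filter(matrix)
    f2, r2 = qc_cv_filter(f1)
    f3, r3 = autocorr_filter(f2)
    assert len(set(r1.removed) & set(truth.blank_contaminated)) >= \
        0.9 * len(truth.blank_contaminated)
    assert len(set(r2.removed) & set(truth.high_cv)) >= \
        0.9 * len(truth.high_cv)
    assert set(r3.removed) == set(truth.redundant)
    # provenance telescopes
    for rep in f3.provenance:
        assert rep.n_before - len(rep.removed) == rep.n_after
    assert f3.provenance[0].n_before == matrix.n_features
    assert f3.provenance[-1].n_after == f3.n_features


def test_filter_report_validates_accounting():
    with pytest.raises(ValueError, match="accounting"):
        FilterReport(step="x", params={}, n_before=10, n_after=8,
                     removed=("a",))


def test_log_autoscale_identities(metabo_fixture):
    matrix, _ = metabo_fixture
    transformed = log_autoscale(matrix)
    assert transformed.shape[0] == 10
    assert np.allclose(transformed.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(transformed.var(axis=0, ddof=1), 1.0, atol=1e-9)


def test_log_autoscale_drops_constant_features():
    m = tiny_matrix({
        "A": [5, 5, 5, 5, 0, 0, 5, 5, 5],
        "B": [1, 2, 3, 4, 0, 0, 2, 2, 2],
    })
    transformed = log_autoscale(m)
    assert list(transformed.columns) == ["B"]


def test_pca_explained_variance_properties(metabo_fixture):
    matrix, _ = metabo_fixture
    transformed = log_autoscale(matrix)
    _, _, frac = pca_scores(transformed)
    assert frac.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(frac) <= 1e-12)


def test_pca_rank_one_toy():
    base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    X = pd.DataFrame(np.outer(base - base.mean(), [1.0, 2.0, 0.5]))
    _, _, frac = pca_scores(X)
    assert frac[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_separates_groups(metabo_fixture):
    matrix, truth = metabo_fixture
    transformed = log_autoscale(matrix)
    scores, _, _ = pca_scores(transformed, n_components=2)
    labels = matrix.sample_groups().loc[scores.index]
    centroids = scores.groupby(labels.to_numpy()).mean()
    spread = scores["PC1"].std()
    assert abs(centroids["PC1"].iloc[0] - centroids["PC1"].iloc[1]) > \
        0.5 * spread


def test_permanova_coordinate_distance_identity():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 6))
    labels = np.repeat(["a", "b", "c"], 4)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    f_coord, _ = permanova(X, labels, n_perm=10, seed=1)
    f_dist, _ = permanova(d, labels, n_perm=10, seed=1)
    assert f_coord == pytest.approx(f_dist, abs=1e-9)


def test_permanova_detects_strong_separation():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(10, 5))
    X[5:] += 50.0  # 10+ within-group SDs apart
    labels = np.repeat(["nd", "ad"], 5)
    f, p = permanova(X, labels, n_perm=999, seed=2)
    # only permutations reproducing the observed partition (or its mirror,
    # ~0.8% of label shuffles at n=10) can tie the observed F
    assert p < 0.02
    assert f > 10


def test_permanova_statistic_matches_scikit_bio():
    """Independent oracle: pseudo-F agrees with skbio's PERMANOVA."""
    import skbio

    rng = np.random.default_rng(7)
    X = rng.normal(size=(14, 5))
    X[7:, 0] += 1.5
    labels = np.repeat(["nd", "ad"], 7)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    f_ours, _ = permanova(X, labels, n_perm=10, seed=0)
    dm = skbio.DistanceMatrix(d, ids=[str(i) for i in range(14)])
    ref = skbio.stats.distance.permanova(dm, grouping=labels, permutations=10)
    assert f_ours == pytest.approx(ref["test statistic"], rel=1e-9)


def test_permanova_input_validation():
    X = np.random.default_rng(0).normal(size=(6, 3))
    with pytest.raises(ValueError, match="2 groups"):
        permanova(X, ["a"] * 6)
    with pytest.raises(ValueError, match="at least 2 samples"):
        permanova(X, ["a", "a", "a", "a", "a", "b"])


def test_vip_normalisation_and_injected_biomarker():
    rng = np.random.default_rng(8)
    n, p = 12, 40
    X = rng.normal(size=(n, p))
    labels = np.repeat([0, 1], n // 2)
    X[:, 17] = labels * 6.0 + rng.normal(0, 0.1, n)
    df = pd.DataFrame(X, columns=[f"F{i:03d}" for i in range(p)])
    df = (df - df.mean()) / df.std(ddof=1)
    vip = plsda_vip(df, labels)
    assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-9)
    assert vip.idxmax() == "F017"
    assert top_vips(vip, 5).index[0] == "F017"


def test_vip_requires_two_groups():
    df = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 4)))
    with pytest.raises(ValueError):
        plsda_vip(df, [1, 1, 1, 1, 1, 1])


def test_top_vips_ranking_and_ties():
    vip = pd.Series({"b": 2.0, "a": 2.0, "c": 1.0})
    top = top_vips(vip, 2)
    assert list(top.index) == ["a", "b"]  # tie broken by feature_id
    assert list(top_vips(vip, 3).index) == ["a", "b", "c"]
    with pytest.raises(ValueError):
        top_vips(vip, 4)


def test_feature_matrix_csv_round_trip(tmp_path, metabo_fixture):
    matrix, _ = metabo_fixture
    path = tmp_path / "features.csv"
    matrix.to_csv(path)
    back = FeatureMatrix.from_csv(path)
    assert back.n_features == matrix.n_features
    assert list(back.intensities.columns) == list(matrix.intensities.columns)
    assert np.allclose(back.intensities.to_numpy(),
                       matrix.intensities.to_numpy(), rtol=1e-12)
    assert (back.roles == matrix.roles).all()
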