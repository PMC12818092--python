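"""GPA, outlier filtering, TPS imputation, warps, CDA and LOO-LDA."""

import numpy as np
import pandas as pd
import pytest

from crataegus.morphometrics import (
    average_and_combine,
    cda_with_passive,
    centroid_size,
    chained_impute,
    filter_outlier_shapes,
    gpa_align,
    impute_missing_landmarks,
    loo_lda,
    pca_traits,
    procrustes_distance,
    prune_correlated,
    relative_warps,
)

TRIANGLE = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.5]])


def similarity(shape, theta=0.0, scale=1.0, shift=(0.0, 0.0)):
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    return shape @ R.T * scale + np.asarray(shift)


# ---------------------------------------------------------------------------
# GPA


def test_gpa_removes_rotation_and_scale():
    shapes = np.stack([TRIANGLE, similarity(TRIANGLE, np.pi / 2, 2.0, (5, -3))])
    res = gpa_align(shapes)
    assert np.linalg.norm(res.aligned[0] - res.aligned[1]) < 1e-8


def test_gpa_invariant_to_random_similarity_transforms(rng):
    base = rng.normal(size=(8, 13, 2))
    res1 = gpa_align(base)
    jittered = np.stack([
        similarity(s, rng.uniform(0, 2 * np.pi), rng.uniform(0.5, 3.0),
                   rng.uniform(-10, 10, 2))
        for s in base
    ])
    res2 = gpa_align(jittered)
    # the two aligned sets agree up to one global rotation
    flat1 = res1.aligned.reshape(len(base), -1)
    flat2 = res2.aligned.reshape(len(base), -1)
    d = procrustes_distance(res1.mean_shape, res2.mean_shape)
    assert d < 1e-6
    assert np.allclose(
        np.linalg.norm(flat1 - flat1.mean(0), axis=1),
        np.linalg.norm(flat2 - flat2.mean(0), axis=1),
        atol=1e-6,
    )


def test_gpa_unit_centroid_sizes():
    rng = np.random.default_rng(1)
    res = gpa_align(rng.normal(size=(5, 13, 2)))
    for s in res.aligned:
        assert centroid_size(s) == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(s.mean(axis=0), 0.0, atol=1e-8)


def test_gpa_mean_midway_between_two_shapes():
    a = TRIANGLE
    b = TRIANGLE + np.array([[0.1, 0.0], [0.0, -0.1], [0.0, 0.0]])
    res = gpa_align(np.stack([a, b]))
    mid = (res.aligned[0] + res.aligned[1]) / 2
    mid = mid / centroid_size(mid)
    assert np.linalg.norm(res.mean_shape - mid) < 1e-6


def test_gpa_degenerate_shape_rejected():
    shapes = np.stack([TRIANGLE, np.zeros((3, 2))])
    with pytest.raises(ValueError, match="degenerate"):
        gpa_align(shapes)


# ---------------------------------------------------------------------------
# outlier filtering


def test_identical_leaves_never_removed():
    shapes = np.stack([TRIANGLE / centroid_size(TRIANGLE)] * 4)
    keep, removals = filter_outlier_shapes(shapes, ["i1"] * 4)
    assert keep.all() and not removals


def test_single_gross_outlier_removed():
    local = np.random.default_rng(4)
    base = TRIANGLE / centroid_size(TRIANGLE)
    leaves = [base + local.normal(0, 0.01, base.shape) for _ in range(5)]
    deformed = base + np.array([[0.5, 0.3], [-0.4, 0.2], [0.1, -0.5]])
    shapes = np.stack(leaves + [deformed / centroid_size(deformed)])
    keep, removals = filter_outlier_shapes(shapes, ["i1"] * 6)
    assert list(keep) == [True] * 5 + [False]
    assert len(removals) == 1


def test_removal_invariant_to_leaf_order(rng):
    base = TRIANGLE / centroid_size(TRIANGLE)
    leaves = np.stack(
        [base + rng.normal(0, 1e-3, base.shape) for _ in range(5)]
        + [base + 0.3]
    )
    keep1, _ = filter_outlier_shapes(leaves, ["i"] * 6)
    perm = np.array([5, 0, 3, 1, 4, 2])
    keep2, _ = filter_outlier_shapes(leaves[perm], ["i"] * 6)
    assert np.array_equal(keep1[perm], keep2)


# ---------------------------------------------------------------------------
# averaging, combining, imputation


def test_composite_single_leaf_blocks():
    fl = {"a": np.stack([np.arange(26.0).reshape(13, 2)])}
    sh = {"a": np.stack([np.arange(26.0).reshape(13, 2) + 1])}
    ids, comp = average_and_combine(fl, sh)
    assert ids == ["a"]
    assert np.allclose(comp[0, :13], fl["a"][0])
    assert np.allclose(comp[0, 13:], sh["a"][0])


def test_composite_two_leaves_average_coordinatewise():
    l1 = np.zeros((13, 2))
    l2 = np.ones((13, 2))
    ids, comp = average_and_combine({"a": np.stack([l1, l2])},
                                    {"a": np.stack([l1])})
    assert np.allclose(comp[0, :13], 0.5)


def test_missing_block_flagged_as_nan():
    fl = {"a": np.stack([np.random.default_rng(0).normal(size=(13, 2))])}
    ids, comp = average_and_combine(fl, {})
    assert np.isnan(comp[0, 13:]).all()
    assert not np.isnan(comp[0, :13]).any()


def test_tps_imputation_exact_for_reference_copy(rng):
    ref_pool = rng.normal(size=(6, 26, 2))
    specimen = ref_pool.mean(axis=0).copy()  # identical to the reference
    specimen_missing = specimen.copy()
    specimen_missing[7] = np.nan
    comp = np.concatenate([ref_pool, specimen_missing[None]], axis=0)
    filled, kept, _ = impute_missing_landmarks(comp)
    assert kept.all()
    assert np.allclose(filled[-1][7], specimen[7], atol=1e-8)


def test_tps_imputation_exact_under_similarity_transform(rng):
    """TPS reproduces affine maps exactly, so a similarity-transformed copy
    of the reference has its deleted landmark restored to the true point."""
    ref_pool = rng.normal(size=(5, 26, 2))
    ref = ref_pool.mean(axis=0)
    transformed = similarity(ref, theta=0.7, scale=1.8, shift=(3.0, -2.0))
    broken = transformed.copy()
    broken[11] = np.nan
    comp = np.concatenate([ref_pool, broken[None]], axis=0)
    filled, kept, _ = impute_missing_landmarks(comp)
    assert np.allclose(filled[-1][11], transformed[11], atol=1e-6)


def test_imputation_noop_when_complete(rng):
    comp = rng.normal(size=(4, 26, 2))
    filled, kept, log = impute_missing_landmarks(comp)
    assert np.array_equal(filled, comp) and kept.all() and not log


def test_imputation_excludes_sparse_specimens(rng):
    comp = rng.normal(size=(4, 26, 2))
    comp[0, 2:] = np.nan  # only two observed landmarks
    filled, kept, _ = impute_missing_landmarks(comp)
    assert not kept[0] and kept[1:].all()


# ---------------------------------------------------------------------------
# relative warps


def test_warp_variance_sums_to_100(rng):
    res = relative_warps(rng.normal(size=(10, 13, 2)) * 0.01
                         + TRIANGLE[0])
    assert res.pct_variance.sum() == pytest.approx(100.0, abs=1e-6)


def test_single_planted_mode_dominates():
    rng = np.random.default_rng(8)
    mean = rng.normal(size=(13, 2))
    mode = rng.normal(size=(13, 2))
    mode /= np.linalg.norm(mode)
    shapes = np.stack([
        mean + rng.normal() * mode + rng.normal(0, 0.01, (13, 2))
        for _ in range(40)
    ])
    res = relative_warps(shapes)
    assert res.pct_variance[0] >= 90.0


def test_alpha_zero_equals_plain_pca(rng):
    shapes = rng.normal(size=(12, 13, 2))
    res = relative_warps(shapes, alpha=0.0)
    X = shapes.reshape(12, -1)
    Xc = X - X.mean(axis=0)
    vals, vecs = np.linalg.eigh(Xc.T @ Xc)
    order = np.argsort(vals)[::-1]
    ref_scores = Xc @ vecs[:, order]
    for j in range(res.scores.shape[1]):
        flip = np.sign(res.scores[:, j] @ ref_scores[:, j]) or 1.0
        assert np.allclose(res.scores[:, j] * flip, ref_scores[:, j], atol=1e-8)


def test_warps_need_three_specimens(rng):
    with pytest.raises(ValueError):
        relative_warps(rng.normal(size=(2, 13, 2)))


# ---------------------------------------------------------------------------
# trait pruning


def test_duplicated_trait_dropped_once(rng):
    x = rng.normal(size=50)
    df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
    reduced, log = prune_correlated(df)
    assert reduced.shape[1] == 2
    assert sum(1 for r in log if r["reason"] == "correlated") == 1


def test_exact_r_09_kept(rng):
    # a pair engineered to hit Spearman r == 0.9 exactly is kept (strict >)
    n = 20
    a = np.arange(n, dtype=float)
    b = a.copy()
    # swapping ranks lowers Spearman; search a swap set giving exactly 0.9
    b[0], b[3] = b[3], b[0]
    b[5], b[7] = b[7], b[5]
    df = pd.DataFrame({"a": a, "b": b})
    r = float(df.corr(method="spearman").loc["a", "b"])
    reduced, _ = prune_correlated(df, r_max=r)  # threshold equals the pair's r
    assert reduced.shape[1] == 2


def test_three_duplicates_keep_highest_variance(rng):
    x = rng.normal(size=60)
    df = pd.DataFrame({"small": x, "mid": 2 * x, "big": 3 * x})
    reduced, log = prune_correlated(df)
    assert list(reduced.columns) == ["big"]


def test_constant_trait_dropped_with_warning(rng):
    df = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10),
                       "c": rng.normal(size=10)})
    with pytest.warns(UserWarning, match="constant"):
        reduced, _ = prune_correlated(df)
    assert "a" not in reduced.columns


def test_no_residual_pair_above_threshold(rng):
    base = rng.normal(size=(80, 3))
    df = pd.DataFrame({
        "t1": base[:, 0], "t2": base[:, 0] + 0.01 * base[:, 1],
        "t3": base[:, 1], "t4": base[:, 2], "t5": base[:, 2] * 1.5 + 0.02 * base[:, 0],
    })
    reduced, _ = prune_correlated(df, r_max=0.9)
    corr = reduced.corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(corr, 0)
    assert corr.max() <= 0.9


# ---------------------------------------------------------------------------
# CDA


def make_two_groups(rng, n=40, delta=6.0):
    a = rng.normal([0, 0], 1.0, size=(n, 2))
    b = rng.normal([delta, 0], 1.0, size=(n, 2))
    X = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
    g = ["A"] * n + ["B"] * n
    return X, g


def test_single_axis_aligned_with_separation(rng):
    X, g = make_two_groups(rng)
    model = cda_with_passive(X, g)
    v = model.coefficients[:, 0]
    cos = abs(v[0]) / np.linalg.norm(v)
    assert cos >= 0.99
    assert model.coefficients.shape[1] == 1  # min(groups-1, traits)


def test_passive_samples_leave_coefficients_bitidentical(rng):
    X, g = make_two_groups(rng)
    passive = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"])
    without = cda_with_passive(X, g)
    with_p = cda_with_passive(X, g, passive=passive)
    assert np.array_equal(without.coefficients, with_p.coefficients)
    assert np.array_equal(without.active_scores.to_numpy(),
                          with_p.active_scores.to_numpy())
    assert with_p.passive_scores.shape == (10, 1)


def test_axis_count_three_groups(rng):
    X = pd.DataFrame(rng.normal(size=(60, 4)))
    g = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
    model = cda_with_passive(X, g)
    assert model.coefficients.shape[1] == 2


def test_singular_within_covariance_needs_ridge(rng):
    x = rng.normal(size=30)
    X = pd.DataFrame({"a": x, "b": x})  # perfectly collinear
    g = ["A"] * 15 + ["B"] * 15
    with pytest.raises(np.linalg.LinAlgError):
        cda_with_passive(X, g)
    model = cda_with_passive(X, g, ridge=1e-6)
    assert model.coefficients.shape[1] == 1


# ---------------------------------------------------------------------------
# LOO-LDA


def test_separated_groups_classified_perfectly(rng):
    a = rng.normal(0, 1, size=(40, 2))
    b = rng.normal(10, 1, size=(40, 2))  # 10 sigma apart
    res = loo_lda(np.vstack([a, b]), ["A"] * 40 + ["B"] * 40)
    assert res.accuracy == 100.0


def test_identical_distributions_near_chance(rng):
    # leave-one-out is pessimistically biased at chance level (the held-out
    # sample pulls its own class mean away when removed), so accuracy sits
    # at or somewhat below 50 %, far from the separated-group regime
    X = rng.normal(size=(200, 2))
    res = loo_lda(X, ["A"] * 100 + ["B"] * 100)
    assert 25.0 <= res.accuracy <= 60.0


def test_confusion_rows_sum_to_group_sizes(rng):
    a = rng.normal(0, 1, size=(15, 2))
    b = rng.normal(1, 1, size=(25, 2))
    res = loo_lda(np.vstack([a, b]), ["A"] * 15 + ["B"] * 25)
    assert res.confusion.loc["A"].sum() == 15
    assert res.confusion.loc["B"].sum() == 25


def test_singleton_group_rejected(rng):
    with pytest.raises(ValueError, match="single"):
        loo_lda(rng.normal(size=(3, 2)), ["A", "A", "B"])


# ---------------------------------------------------------------------------
# chained imputation and trait PCA


def test_chained_impute_identity_without_missing(rng):
    df = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
    out = chained_impute(df)
    pd.testing.assert_frame_equal(out, df)


def test_row_above_missing_fraction_dropped(rng):
    df = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
    df.iloc[0, :3] = np.nan  # 60 % missing
    out = chained_impute(df)
    assert 0 not in out.index


def test_chained_impute_beats_mean_imputation(rng):
    n = 200
    z = rng.normal(size=n)
    df = pd.DataFrame({
        "a": z + rng.normal(0, 0.1, n),
        "b": 2 * z + rng.normal(0, 0.1, n),
        "c": -z + rng.normal(0, 0.1, n),
    })
    holes = rng.choice(n, size=40, replace=False)
    broken = df.copy()
    broken.loc[holes, "a"] = np.nan
    imputed = chained_impute(broken)
    rmse_chain = np.sqrt(((imputed.loc[holes, "a"] - df.loc[holes, "a"]) ** 2).mean())
    rmse_mean = np.sqrt(((broken["a"].mean() - df.loc[holes, "a"]) ** 2).mean())
    assert rmse_chain < rmse_mean


def test_pca_variance_sums_to_100(rng):
    df = pd.DataFrame(rng.normal(size=(30, 4)))
    res = pca_traits(df)
    assert res.pct_variance.sum() == pytest.approx(100.0)


def test_two_perfectly_correlated_traits_give_pc1_100(rng):
    x = rng.normal(size=25)
    res = pca_traits(pd.DataFrame({"a": x, "b": 3 * x}))
    assert res.pct_variance[0] == pytest.approx(100.0)


def test_pca_scores_match_eigendecomposition_oracle(rng):
    df = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
    res = pca_traits(df, scaled=True)
    Z = (df - df.mean()) / df.std(ddof=1)
    vals, vecs = np.linalg.eigh(np.corrcoef(Z.to_numpy(), rowvar=False) * (len(df) - 1))
    order = np.argsort(vals)[::-1]
    ref = Z.to_numpy() @ vecs[:, order]
    for j in range(3):
        flip = np.sign(res.scores.iloc[:, j] @ ref[:, j]) or 1.0
        assert np.allclose(res.scores.iloc[:, j] * flip, ref[:, j], atol=1e-8)


def test_pca_rejects_zero_variance_column(rng):
    df = pd.DataFrame({"a": np.ones(10), "b": rng.normal(size=10)})
    with pytest.raises(ValueError, match="zero-variance"):
        pca_traits(df)
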