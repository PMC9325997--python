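"""Spectral PCA: flattening, eigen-images, normalization, RGB composition."""

import numpy as np
import pytest

from eigenfluor import (
    DegenerateInputError,
    ParameterError,
    PipelineConfig,
    compose_rgb,
    flatten_row_major,
    normalize_to_255,
    run_pipeline,
    spectral_pca,
)
from eigenfluor.preprocess import PreprocessedCube

from .oracles import dense_pca_components


def _pre(channels, branch="std"):
    return PreprocessedCube(
        channels=[np.asarray(c, dtype=float) for c in channels],
        channel_names=[f"ch{i}" for i in range(len(channels))],
        branch=branch,
    )


# ------------------------------------------------------------------- flatten

def test_flatten_ccd_geometry_dimensionality():
    """A 1392x1040 channel flattens to a 1,447,680-dimensional vector."""
    grid = np.zeros((1040, 1392))
    assert flatten_row_major(grid).shape == (1_447_680,)


def test_flatten_is_row_major():
    grid = np.array([["a", "b", "c"], ["d", "e", "f"]])
    assert flatten_row_major(grid).tolist() == list("abcdef")


def test_flatten_reshape_inverse(rng):
    g = rng.normal(size=(7, 11))
    np.testing.assert_array_equal(flatten_row_major(g).reshape(7, 11), g)


# -------------------------------------------------------------- spectral_pca

def test_rank_one_cube_closed_form(rng):
    """Two identical pattern pairs: PC1 is the (A - B) direction and
    carries all the variance."""
    a = rng.normal(size=(8, 8))
    b = rng.normal(size=(8, 8))
    b -= a.ravel().dot(b.ravel()) / a.ravel().dot(a.ravel()) * a  # A ⟂ B
    es = spectral_pca(_pre([a, a, b, b]), 3)
    np.testing.assert_allclose(es.explained_variance_ratio, [1.0, 0.0, 0.0], atol=1e-12)
    direction = (a - b).ravel()
    pc1 = es.components[0].ravel()
    cos = pc1.dot(direction) / (np.linalg.norm(pc1) * np.linalg.norm(direction))
    assert cos > 1 - 1e-12  # sign rule orients PC1 along A - B
    assert not es.components[1].any() and not es.components[2].any()


def test_evr_sums_to_one_for_four_channels(rng):
    """Centering 4 observations leaves rank <= 3, so 3 ratios sum to 1."""
    es = spectral_pca(_pre([rng.normal(size=(10, 12)) for _ in range(4)]), 3)
    assert abs(es.explained_variance_ratio.sum() - 1.0) < 1e-9


def test_matches_dense_covariance_oracle(rng):
    channels = [rng.normal(size=(16, 16)) for _ in range(4)]
    es = spectral_pca(_pre(channels), 3)
    comps, ratios = dense_pca_components(channels, 3)
    np.testing.assert_allclose(es.explained_variance_ratio, ratios, atol=1e-12)
    for mine, ref in zip(es.components, comps):
        ref = ref.ravel()
        if mine.ravel().dot(ref) < 0:
            ref = -ref
        assert np.abs(mine.ravel() - ref).max() < 1e-8


def test_matches_sklearn_pca(rng):
    from sklearn.decomposition import PCA

    channels = [rng.normal(size=(12, 12)) for _ in range(4)]
    X = np.stack([c.ravel() for c in channels])
    sk = PCA(n_components=3, svd_solver="full").fit(X)
    es = spectral_pca(_pre(channels), 3)
    np.testing.assert_allclose(
        es.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-12
    )
    for mine, ref in zip(es.components, sk.components_):
        if mine.ravel().dot(ref) < 0:
            ref = -ref
        np.testing.assert_allclose(mine.ravel(), ref, atol=1e-10)


def test_components_are_orthogonal(rng):
    es = spectral_pca(_pre([rng.normal(size=(9, 9)) for _ in range(5)]), 3)
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = es.components[i].ravel(), es.components[j].ravel()
            assert abs(a.dot(b)) < 1e-6 * np.linalg.norm(a) * np.linalg.norm(b)


def test_loadings_reconstruct_centered_channels(rng):
    """With full rank retained, loadings @ axes rebuild the centered data."""
    channels = [rng.normal(size=(6, 6)) for _ in range(4)]
    es = spectral_pca(_pre(channels), 3)
    X = np.stack([c.ravel() for c in channels])
    Xc = X - X.mean(axis=0)
    axes = np.stack([c.ravel() for c in es.components])
    np.testing.assert_allclose(es.loadings.T @ axes, Xc, atol=1e-10)


def test_sign_rule_largest_loading_positive(rng):
    es = spectral_pca(_pre([rng.normal(size=(8, 8)) for _ in range(4)]), 3)
    for comp_loadings in es.loadings:
        assert comp_loadings[np.argmax(np.abs(comp_loadings))] > 0


def test_too_many_components_rejected(rng):
    with pytest.raises(ParameterError):
        spectral_pca(_pre([np.zeros((4, 4)), np.ones((4, 4))]), 3)


def test_constant_cube_is_degenerate():
    with pytest.raises(DegenerateInputError):
        spectral_pca(_pre([np.full((5, 5), 2.0) for _ in range(4)]), 3)


# ------------------------------------------------------------- normalization

def test_normalize_affine_endpoints_and_half_even():
    comp = np.array([[-2.0, 0.0, 2.0]])
    np.testing.assert_array_equal(normalize_to_255(comp), [[0, 128, 255]])


def test_normalize_constant_maps_to_zero():
    assert not normalize_to_255(np.full((3, 3), 7.0)).any()


def test_normalize_range_contract(rng):
    out = normalize_to_255(rng.normal(size=(10, 10)))
    assert out.min() == 0 and out.max() == 255


# ---------------------------------------------------------------- composite

def test_compose_maps_pc123_to_rgb(rng):
    es = spectral_pca(_pre([rng.normal(size=(8, 8)) for _ in range(4)]), 3)
    comp = compose_rgb(es)
    for plane, pc in zip(comp.planes, es.components):
        np.testing.assert_array_equal(plane, normalize_to_255(pc))


def test_compose_requires_three_components(rng):
    es = spectral_pca(_pre([rng.normal(size=(8, 8)) for _ in range(4)]), 2)
    with pytest.raises(ParameterError):
        compose_rgb(es)


def test_compose_permutation_functoriality(rng):
    es = spectral_pca(_pre([rng.normal(size=(8, 8)) for _ in range(4)]), 3)
    comp = compose_rgb(es)
    es.components = [es.components[2], es.components[0], es.components[1]]
    permuted = compose_rgb(es)
    np.testing.assert_array_equal(permuted.planes[0], comp.planes[2])
    np.testing.assert_array_equal(permuted.planes[1], comp.planes[0])
    np.testing.assert_array_equal(permuted.planes[2], comp.planes[1])


# ------------------------------------------------------------------ pipeline

def test_pipeline_shape_contract(small_phantom):
    cube, _ = small_phantom
    results = run_pipeline(cube)
    assert set(results) == {"std", "clahe"}
    for res in results.values():
        arr = res.composite.as_array()
        assert arr.shape == (cube.height, cube.width, 3)
        assert arr.dtype == np.uint8


def test_branches_differ_on_structured_input(small_phantom):
    cube, _ = small_phantom
    results = run_pipeline(cube)
    assert not np.array_equal(
        results["std"].composite.as_array(), results["clahe"].composite.as_array()
    )


def test_clahe_branch_composition_limit(small_phantom):
    """median 1 + clip->inf + one tile: the clahe branch is exactly the PCA
    of globally equalized channels."""
    from eigenfluor.preprocess import PreprocessedCube

    from .oracles import global_equalize

    cube, _ = small_phantom
    config = PipelineConfig(
        branch="clahe", clip_limit=float("inf"), tile_grid=(1, 1), median_size=1
    )
    res = run_pipeline(cube, config)["clahe"]
    # oracle path: quantize each channel to 8 bits, equalize globally, PCA
    from eigenfluor.preprocess import _quantize_to_8bit

    eq = [global_equalize(_quantize_to_8bit(ch)).astype(float) for ch in cube.channels]
    ref = spectral_pca(
        PreprocessedCube(channels=eq, channel_names=cube.channel_names, branch="clahe")
    )
    np.testing.assert_allclose(
        res.eigen.explained_variance_ratio, ref.explained_variance_ratio, atol=1e-12
    )
    for a, b in zip(res.eigen.components, ref.components):
        np.testing.assert_allclose(a, b, atol=1e-10)


def test_std_composite_scale_equivariance(small_phantom):
    """Scaling all std-branch channels by a positive constant leaves the
    composite unchanged (min-max normalization absorbs scale)."""
    from eigenfluor.preprocess import preprocess

    cube, _ = small_phantom
    pre = preprocess(cube, branch="std")
    comp = compose_rgb(spectral_pca(pre))
    pre_scaled = PreprocessedCube(
        channels=[3.7 * ch for ch in pre.channels],
        channel_names=pre.channel_names,
        branch="std",
    )
    comp_scaled = compose_rgb(spectral_pca(pre_scaled))
    np.testing.assert_array_equal(comp.as_array(), comp_scaled.as_array())


def test_pipeline_is_deterministic(small_phantom):
    cube, _ = small_phantom
    a = run_pipeline(cube)
    b = run_pipeline(cube)
    for br in ("std", "clahe"):
        assert a[br].composite.as_array().tobytes() == b[br].composite.as_array().tobytes()
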