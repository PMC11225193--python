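"""Embedding, kernel-density regions, rarefaction and overlap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from callspace.errors import (
    ConfigurationError,
    GridMismatchError,
    InsufficientDataError,
    ValidationError,
)
from callspace.space import (
    GridSpec,
    combine_regions,
    density_region,
    embed,
    make_grid,
    rarefied_area,
    region_iou,
    silverman_bandwidth,
)

from .conftest import UNIT_GRID_10, random_mask, region_from_mask


# ---------------------------------------------------------------------------
# embedding


def _two_clusters(n=100, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n, 17))
    b = rng.normal(sep, 1.0, size=(n, 17))
    return np.vstack([a, b])


def test_embedding_separates_well_separated_clusters():
    x = _two_clusters()
    emb = embed(x, perplexity=30, seed=0).points
    a, b = emb[:100], emb[100:]
    intra = np.mean([np.linalg.norm(a - a.mean(axis=0), axis=1).mean(),
                     np.linalg.norm(b - b.mean(axis=0), axis=1).mean()])
    inter = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
    assert inter > intra


def test_embedding_seed_determinism():
    x = _two_clusters(n=60)
    a = embed(x, perplexity=15, seed=42).points
    b = embed(x, perplexity=15, seed=42).points
    np.testing.assert_array_equal(a, b)


def test_duplicated_rows_land_together():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, size=(200, 17))
    x_dup = np.vstack([x, x[:5]])
    pts = embed(x_dup, perplexity=30, seed=1).points
    span = pts.max(axis=0) - pts.min(axis=0)
    d = np.linalg.norm(pts[200:] - pts[:5], axis=1)
    assert (d < 0.01 * np.linalg.norm(span)).all()


def test_embedding_input_validation():
    with pytest.raises(ConfigurationError):
        embed(np.zeros((10, 17)) + np.arange(17), perplexity=30, seed=0)
    bad = _two_clusters(n=40)
    bad[0, 0] = np.nan
    with pytest.raises(ValidationError):
        embed(bad, perplexity=10, seed=0)


# ---------------------------------------------------------------------------
# density regions


def test_translation_invariant_area():
    rng = np.random.default_rng(1)
    pts = rng.normal(0, 1, size=(400, 2))
    shifted = pts + np.array([37.5, -12.25])
    r1 = density_region(pts, make_grid(pts), level=0.95)
    r2 = density_region(shifted, make_grid(shifted), level=0.95)
    assert r2.area == pytest.approx(r1.area, abs=2 * r1.grid.cell_area)


def test_level_one_covers_all_nonzero_density():
    rng = np.random.default_rng(2)
    pts = rng.normal(0, 1, size=(100, 2))
    grid = make_grid(pts, pad_fraction=0.5, n_cells=60)
    region = density_region(pts, grid, level=1.0)
    # with Gaussian kernels every cell has strictly positive density
    assert region.mask.all()


def test_hdr_area_matches_bivariate_normal_closed_form():
    """The 95% HDR of an isotropic Gaussian KDE has area pi * q95 * sigma_kde^2."""
    rng = np.random.default_rng(7)
    sigma = 1.0
    pts = rng.normal(0, sigma, size=(10_000, 2))
    h = silverman_bandwidth(pts)
    grid = make_grid(pts, pad_fraction=0.1, n_cells=200)
    region = density_region(pts, grid, level=0.95)
    sigma_kde_sq = sigma**2 + np.mean(np.square(h))
    expected = np.pi * chi2.ppf(0.95, df=2) * sigma_kde_sq
    assert region.area == pytest.approx(expected, rel=0.10)


def test_density_region_input_errors():
    grid = UNIT_GRID_10
    with pytest.raises(InsufficientDataError):
        density_region(np.array([[1.0, 1.0]]), grid)
    with pytest.raises(InsufficientDataError):
        density_region(np.ones((5, 2)), grid)  # identical points
    with pytest.raises(ConfigurationError):
        density_region(np.array([[1.0, 1.0], [2.0, 2.0]]), grid, bandwidth=(0.0, 1.0))
    with pytest.raises(ConfigurationError):
        density_region(np.array([[1.0, 1.0], [2.0, 2.0]]), grid, level=0.0)


def test_region_json_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    pts = rng.normal(0, 1, size=(50, 2))
    region = density_region(pts, make_grid(pts))
    path = tmp_path / "region.json"
    region.to_json(path)
    from callspace.space import DensityRegion

    loaded = DensityRegion.from_json(path)
    assert loaded.grid == region.grid
    np.testing.assert_array_equal(loaded.mask, region.mask)
    assert loaded.area == region.area


# ---------------------------------------------------------------------------
# IoU and combination


def test_iou_identity_and_disjoint():
    rng = np.random.default_rng(5)
    a = region_from_mask(random_mask(rng))
    assert region_iou(a, a) == 1.0
    left = np.zeros((10, 10), bool)
    left[:, :3] = True
    right = np.zeros((10, 10), bool)
    right[:, 7:] = True
    assert region_iou(region_from_mask(left), region_from_mask(right)) == 0.0


def test_iou_worked_overlap_example():
    """Columns 0-5 vs 4-9 on a 10x10 grid: 20 shared cells of 100 total."""
    a = np.zeros((10, 10), bool)
    a[:, 0:6] = True
    b = np.zeros((10, 10), bool)
    b[:, 4:10] = True
    assert region_iou(region_from_mask(a), region_from_mask(b)) == pytest.approx(0.2)


def test_iou_requires_matching_grids():
    a = region_from_mask(np.ones((10, 10), bool))
    b = region_from_mask(np.ones((10, 10), bool), grid=GridSpec(0, 5, 0, 5, 10, 10))
    with pytest.raises(GridMismatchError):
        region_iou(a, b)


def test_iou_matches_brute_force_enumeration():
    rng = np.random.default_rng(6)
    for _ in range(100):
        ny, nx = rng.integers(2, 21, size=2)
        grid = GridSpec(0, float(nx), 0, float(ny), int(nx), int(ny))
        a = region_from_mask(random_mask(rng, (ny, nx)), grid)
        b = region_from_mask(random_mask(rng, (ny, nx)), grid)
        inter = union = 0
        for i in range(ny):  # independent cell-by-cell oracle
            for j in range(nx):
                inter += a.mask[i, j] and b.mask[i, j]
                union += a.mask[i, j] or b.mask[i, j]
        assert region_iou(a, b) == inter / union


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_iou_symmetry_and_union_monotonicity(seed):
    rng = np.random.default_rng(seed)
    a = region_from_mask(random_mask(rng))
    b = region_from_mask(random_mask(rng))
    assert region_iou(a, b) == region_iou(b, a)
    assert region_iou(a, combine_regions([a, b])) >= region_iou(a, b)


def test_combine_identity_idempotence_additivity():
    rng = np.random.default_rng(8)
    a = region_from_mask(random_mask(rng))
    np.testing.assert_array_equal(combine_regions([a]).mask, a.mask)
    assert combine_regions([a, a]).area == a.area
    left = np.zeros((10, 10), bool)
    left[:, :3] = True
    right = np.zeros((10, 10), bool)
    right[:, 7:] = True
    la, ra = region_from_mask(left), region_from_mask(right)
    assert combine_regions([la, ra]).area == pytest.approx(la.area + ra.area)


# ---------------------------------------------------------------------------
# rarefaction


def test_rarefaction_exhaustive_subset_equals_full_area():
    rng = np.random.default_rng(9)
    pts = rng.normal(0, 1, size=(120, 2))
    grid = make_grid(pts)
    full = density_region(pts, grid).area
    rar = rarefied_area(pts, subset_size=120, n_subsets=5, grid=grid, seed=1)
    assert rar.mean_area == pytest.approx(full)
    assert np.std(rar.areas) == 0.0


def test_rarefaction_single_subset_mean_is_its_area():
    rng = np.random.default_rng(10)
    pts = rng.normal(0, 1, size=(300, 2))
    grid = make_grid(pts)
    one = rarefied_area(pts, subset_size=100, n_subsets=1, grid=grid, seed=3)
    assert one.mean_area == one.areas[0]


def test_rarefied_area_nondecreasing_in_subset_size():
    rng = np.random.default_rng(11)
    pts = rng.normal(0, 1, size=(500, 2))
    grid = make_grid(pts)
    small = rarefied_area(pts, subset_size=50, n_subsets=30, grid=grid, seed=5)
    large = rarefied_area(pts, subset_size=150, n_subsets=30, grid=grid, seed=5)
    assert small.mean_area <= large.mean_area


def test_rarefaction_seed_reproducibility():
    rng = np.random.default_rng(12)
    pts = rng.normal(0, 1, size=(250, 2))
    grid = make_grid(pts)
    a = rarefied_area(pts, 100, 10, grid, seed=17)
    b = rarefied_area(pts, 100, 10, grid, seed=17)
    np.testing.assert_array_equal(a.areas, b.areas)


def test_rarefaction_shortfall_policies():
    rng = np.random.default_rng(13)
    pts = rng.normal(0, 1, size=(50, 2))
    grid = make_grid(pts)
    with pytest.raises(InsufficientDataError):
        rarefied_area(pts, subset_size=180, n_subsets=5, grid=grid, seed=0)
    rar = rarefied_area(pts, 180, 5, grid, seed=0, shortfall_policy="use-all")
    assert rar.shortfall and rar.n_subsets == 1
    with pytest.raises(ConfigurationError):
        rarefied_area(pts, subset_size=1, n_subsets=5, grid=grid, seed=0)
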