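"""Equal-variance intensity classification."""

import numpy as np
import pytest

from nuquant.errors import ClassificationError, InputError
from nuquant.intensity import ClassBoundaries, classify_voxels, fit_class_boundaries
from nuquant.stack import ImageStack


def brute_force_boundaries(values, k=7, sweeps=400):
    """Independent oracle: coordinate-wise grid refinement on sample splits.

    Works directly on the interpolated empirical law via repeated local
    grid searches that balance the variances of adjacent classes.
    """
    from nuquant.intensity import _InterpolatedLaw, _variances_at

    x = np.sort(np.asarray(values, dtype=float))
    law = _InterpolatedLaw(x - x.mean())
    lo, hi = float(law.xu[0]), float(law.xu[-1])
    borders = np.quantile(law.xu, np.arange(1, k) / k)
    for _ in range(sweeps):
        for i in range(k - 1):
            a = borders[i - 1] if i > 0 else lo
            b = borders[i + 1] if i < k - 2 else hi
            grid = np.linspace(a, b, 41)[1:-1]
            best, best_d = borders[i], np.inf
            for cand in grid:
                trial = borders.copy()
                trial[i] = cand
                v = _variances_at(law, trial, k)
                d = abs(v[i] - v[i + 1])
                if d < best_d:
                    best, best_d = cand, d
            borders[i] = best
    v = _variances_at(law, borders, k)
    return borders + x.mean(), v


@pytest.mark.parametrize("dist", ["uniform", "exponential", "bimodal"])
def test_equal_variance_convergence(dist):
    """Per-class variances equalise to far better than 0.1% CV."""
    rng = np.random.default_rng(11)
    n = 200_000
    if dist == "uniform":
        x = rng.uniform(0, 1, n)
    elif dist == "exponential":
        x = rng.exponential(1.0, n)
    else:
        x = np.concatenate([rng.normal(1, 0.2, n // 2), rng.normal(4, 0.6, n // 2)]).clip(0)
    cb = fit_class_boundaries(x, k=7, tol=1e-3)
    assert cb.variance_cv <= 1e-3
    assert np.all(np.diff(cb.boundaries) > 0)


def test_uniform_boundaries_match_equal_width():
    """For a uniform law equal variance forces equal widths (width^2/12)."""
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 1, 1_000_000)
    cb = fit_class_boundaries(x, k=7, tol=1e-3)
    assert np.abs(cb.boundaries - np.arange(8) / 7).max() < 0.005


def test_exponential_matches_brute_force_oracle():
    """Fitted borders agree with an independent grid-refinement oracle."""
    rng = np.random.default_rng(3)
    x = rng.exponential(1.0, 20_000)
    cb = fit_class_boundaries(x, k=7, tol=1e-3)
    oracle_b, oracle_v = brute_force_boundaries(x, k=7)
    rng_span = x.max() - x.min()
    assert np.abs(cb.boundaries[1:-1] - oracle_b).max() <= 0.005 * rng_span


def test_two_point_degenerate_midpoint():
    cb = fit_class_boundaries([0, 0, 1, 1], k=2)
    assert cb.boundaries.tolist() == [0.0, 0.5, 1.0]
    assert np.allclose(cb.variances, 0)


def test_staircase_one_class_per_step():
    """Seven-level staircase: forced partition, one label per step."""
    vals = np.repeat(np.arange(7, dtype=float), 50)
    cb = fit_class_boundaries(vals, k=7)
    img = np.tile(np.repeat(np.arange(7, dtype=np.float32), 4), (3, 4, 1))
    stack = ImageStack({"DAPI": img}, (100.0, 100.0, 100.0))
    cmap = classify_voxels(stack, "DAPI", np.ones(img.shape, bool), cb)
    labels = cmap.labels[cmap.region]
    assert sorted(np.unique(labels)) == [1, 2, 3, 4, 5, 6, 7]
    assert np.array_equal(labels, img[np.ones(img.shape, bool)].astype(int) + 1)


def test_scale_shift_equivariance():
    """Labels are invariant under a > 0 affine intensity transforms."""
    rng = np.random.default_rng(7)
    x = rng.normal(5, 2, 20_000)
    a, b = 3.2, 10.0
    cb1 = fit_class_boundaries(x, k=7, tol=1e-3)
    cb2 = fit_class_boundaries(a * x + b, k=7, tol=1e-3)
    assert np.allclose(a * cb1.boundaries + b, cb2.boundaries, rtol=1e-6, atol=1e-8)
    lab1 = np.searchsorted(cb1.boundaries[1:-1], x, side="right")
    lab2 = np.searchsorted(cb2.boundaries[1:-1], a * x + b, side="right")
    assert np.array_equal(lab1, lab2)


def test_partition_property_and_min_in_class1():
    rng = np.random.default_rng(5)
    img = rng.exponential(1, (8, 16, 16)).astype(np.float32)
    stack = ImageStack({"DAPI": img}, (125.0, 39.5, 39.5))
    region = np.zeros(img.shape, bool)
    region[2:6, 3:13, 4:12] = True
    cb = fit_class_boundaries(img[region], k=7, tol=1e-3)
    cmap = classify_voxels(stack, "DAPI", region, cb)
    counts = cmap.class_counts()
    assert counts.sum() == region.sum()
    assert np.all(cmap.labels[~region] == 0)
    # the minimum-intensity voxel of the region carries class 1
    flat = np.where(region, img, np.inf)
    zyx = np.unravel_index(np.argmin(flat), img.shape)
    assert cmap.labels[zyx] == 1


def test_classify_clamps_or_raises_out_of_range():
    rng = np.random.default_rng(2)
    x = rng.uniform(0, 1, 5000)
    cb = fit_class_boundaries(x, k=7, tol=1e-3)
    img = np.full((2, 3, 3), 5.0, dtype=np.float32)  # above fitted range
    stack = ImageStack({"DAPI": img}, (100.0, 100.0, 100.0))
    region = np.ones(img.shape, bool)
    cmap = classify_voxels(stack, "DAPI", region, cb)
    assert np.all(cmap.labels[region] == 7)  # clamped into the top class
    with pytest.raises(InputError):
        classify_voxels(stack, "DAPI", region, cb, strict=True)


@pytest.mark.parametrize(
    "values,k",
    [([1.0, 1.0, 1.0], 2), (list(range(5)), 7), ([0.0, 1.0], 1)],
)
def test_fit_rejects_degenerate_input(values, k):
    with pytest.raises(ClassificationError):
        fit_class_boundaries(values, k=k)
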