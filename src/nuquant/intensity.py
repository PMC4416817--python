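"""Threshold-independent voxel intensity classification.

DNA counterstain intensity is partitioned into ``k`` contiguous classes
(default seven) chosen so that the *within-class intensity variance is the
same for every class*. Class 1 collects voxels with intensities close to
background, class ``k`` the densest chromatin. Because the class borders
adapt to the intensity distribution of each region, the partition needs no
manually chosen threshold and is comparable across nuclei imaged at
different signal levels: classifying ``a*I + b`` (``a > 0``) yields the
same labels with boundaries ``a*b_i + b``.

Fitting
-------
The within-class variance is defined on the *interpolated* empirical
intensity law: the empirical CDF is linearly interpolated between adjacent
distinct intensities, giving a piecewise-uniform density. On that law the
variance of an interval is a continuous, increasing function of its upper
border, so exact equalisation is well posed even where the raw sample is
sparse (e.g. the extreme upper tail, where whole-voxel class variances can
only move in coarse jumps). Boundaries always fall strictly between
adjacent distinct values, hence the voxel assignment is identical to what
any boundary in the same inter-value gap would produce and tied
intensities are never split across classes.

The fit itself is a nested bisection: an outer bisection on the shared
per-class target variance ``v`` and, per candidate ``v``, a left-to-right
sweep that closes each class at the border where its variance reaches
``v``. The variance of the leftover top class decreases monotonically in
``v``, so the unique equalising ``v`` is bracketed and bisected
deterministically — no randomness, no dependence on initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import ClassificationError, ConvergenceError, InputError
from .stack import ImageStack

__all__ = ["ClassBoundaries", "IntensityClassMap", "fit_class_boundaries", "classify_voxels"]


@dataclass
class ClassBoundaries:
    """Fitted class borders ``b_0 < b_1 < ... < b_k`` spanning the data range.

    Class ``i`` (1-based) covers ``[b_{i-1}, b_i)``; the top class is closed
    above. ``variances[i-1]`` is the within-class variance under the
    interpolated empirical law the fit equalises; the variances of the
    voxels actually assigned to each class are in
    ``diagnostics['sample_variances']``.
    """

    boundaries: np.ndarray  # length k + 1
    variances: np.ndarray  # length k
    k: int
    tol: float
    n_iter: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def variance_cv(self) -> float:
        """Coefficient of variation of the per-class variances."""
        m = float(np.mean(self.variances))
        if m == 0:
            return 0.0
        return float(np.std(self.variances) / m)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "boundaries": [float(b) for b in self.boundaries],
            "variances": [float(v) for v in self.variances],
            "variance_cv": self.variance_cv,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass
class IntensityClassMap:
    """Per-voxel class labels 1..k inside a region (0 outside)."""

    labels: np.ndarray  # integer array, 0 = outside region
    boundaries: ClassBoundaries
    region: np.ndarray  # boolean mask

    @property
    def k(self) -> int:
        return self.boundaries.k

    def class_counts(self) -> np.ndarray:
        """Voxel count per class (index 0 -> class 1)."""
        return np.bincount(self.labels[self.region], minlength=self.k + 1)[1:]


# --------------------------------------------------------------------------
# interpolated empirical law


class _InterpolatedLaw:
    """Piecewise-uniform interpolation of an empirical distribution.

    Mass ``count_0 / n`` sits as an atom at the minimum; for each following
    distinct value ``xu_j`` the mass ``count_j / n`` is spread uniformly
    over the gap ``(xu_{j-1}, xu_j]``. Cumulative zeroth/first/second
    moments of ``(-inf, b]`` are O(log m) via prefix sums, so interval
    variances are cheap and continuous in the interval borders.
    """

    def __init__(self, values: np.ndarray):
        xu, counts = np.unique(values, return_counts=True)
        self.xu = xu
        n = counts.sum()
        p = counts / n
        self.m = xu.size
        # full-segment prefix moments; segment j spans [xu[j-1], xu[j]]
        u, v = xu[:-1], xu[1:]
        seg_m1 = p[1:] * 0.5 * (u + v)
        seg_m2 = p[1:] * (u * u + u * v + v * v) / 3.0
        self.P = np.concatenate([[p[0]], p[0] + np.cumsum(p[1:])])
        self.M1 = np.concatenate([[p[0] * xu[0]], p[0] * xu[0] + np.cumsum(seg_m1)])
        self.M2 = np.concatenate(
            [[p[0] * xu[0] ** 2], p[0] * xu[0] ** 2 + np.cumsum(seg_m2)]
        )
        self.p = p

    def cum(self, b: float) -> Tuple[float, float, float]:
        """Moments (mass, m1, m2) of (-inf, b]."""
        xu = self.xu
        if b < xu[0]:
            return 0.0, 0.0, 0.0
        if b >= xu[-1]:
            j = self.m - 1
            return self.P[j], self.M1[j], self.M2[j]
        j = int(np.searchsorted(xu, b, side="right"))  # xu[j-1] <= b < xu[j]
        mass, m1, m2 = self.P[j - 1], self.M1[j - 1], self.M2[j - 1]
        u, v = xu[j - 1], xu[j]
        if b > u:
            frac = (b - u) / (v - u)
            w = self.p[j] * frac
            mass += w
            m1 += w * 0.5 * (u + b)
            m2 += w * (u * u + u * b + b * b) / 3.0
        return mass, m1, m2

    def interval_var(self, ca: Tuple[float, float, float], b: float) -> float:
        """Variance of (a, b] given the cumulative moments ``ca`` at a."""
        mass, m1, m2 = self.cum(b)
        w = mass - ca[0]
        if w <= 0:
            return 0.0
        mean = (m1 - ca[1]) / w
        return max((m2 - ca[2]) / w - mean * mean, 0.0)


def _solve_border(law: _InterpolatedLaw, ca, lo: float, v: float, n_bisect: int = 80) -> float:
    """Upper border b in (lo, max] with interval variance v (monotone bisection)."""
    hi = float(law.xu[-1])
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        if law.interval_var(ca, mid) <= v:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sweep(law: _InterpolatedLaw, k: int, v: float) -> Optional[Tuple[np.ndarray, np.ndarray]]:
    """Place k-1 borders at target variance v; None when v over-covers."""
    borders = np.empty(k - 1)
    variances = np.empty(k)
    ca = (0.0, 0.0, 0.0)
    lo = float(law.xu[0])
    top = float(law.xu[-1])
    for c in range(k - 1):
        if law.interval_var(ca, top) <= v:
            return None  # remaining mass cannot fill the remaining classes
        b = _solve_border(law, ca, lo, v)
        borders[c] = b
        cb = law.cum(b)
        w = cb[0] - ca[0]
        if w <= 0:
            return None
        mean = (cb[1] - ca[1]) / w
        variances[c] = max((cb[2] - ca[2]) / w - mean * mean, 0.0)
        ca, lo = cb, b
    variances[k - 1] = law.interval_var(ca, top)
    return borders, variances


def _variances_at(law: _InterpolatedLaw, borders: np.ndarray, k: int) -> np.ndarray:
    out = np.empty(k)
    ca = (0.0, 0.0, 0.0)
    edges = list(borders) + [float(law.xu[-1])]
    for i, b in enumerate(edges):
        cb = law.cum(b)
        w = cb[0] - ca[0]
        if w <= 0:
            out[i] = 0.0
        else:
            mean = (cb[1] - ca[1]) / w
            out[i] = max((cb[2] - ca[2]) / w - mean * mean, 0.0)
        ca = cb
    return out


def _polish(
    law: _InterpolatedLaw, borders: np.ndarray, k: int, tol: float, max_sweeps: int = 300
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Gauss-Seidel equalisation of adjacent class variances.

    Each pass re-solves every border so the variances of its two flanking
    classes agree (sign bisection on their continuous difference). This
    mops up cases where the global target-variance bisection stalls on a
    border whose position responds discontinuously to the target — which
    happens in sparse upper tails, where interval variance is not
    monotone in the lower border.
    """
    borders = borders.astype(float).copy()
    bottom, top = float(law.xu[0]), float(law.xu[-1])
    n_sweeps = 0
    for _ in range(max_sweeps):
        n_sweeps += 1
        for i in range(k - 1):
            lo = borders[i - 1] if i > 0 else bottom
            hi = borders[i + 1] if i < k - 2 else top
            ca = law.cum(lo) if i > 0 else (0.0, 0.0, 0.0)
            ch = law.cum(hi)

            def gap(b: float) -> float:
                cb = law.cum(b)
                wl = cb[0] - ca[0]
                wr = ch[0] - cb[0]
                vl = ((cb[2] - ca[2]) / wl - ((cb[1] - ca[1]) / wl) ** 2) if wl > 0 else 0.0
                vr = ((ch[2] - cb[2]) / wr - ((ch[1] - cb[1]) / wr) ** 2) if wr > 0 else 0.0
                return max(vl, 0.0) - max(vr, 0.0)

            a_, b_ = lo, hi
            for _b in range(60):
                mid = 0.5 * (a_ + b_)
                if gap(mid) <= 0:
                    a_ = mid
                else:
                    b_ = mid
            borders[i] = 0.5 * (a_ + b_)
        variances = _variances_at(law, borders, k)
        m = float(np.mean(variances))
        cv = float(np.std(variances) / m) if m > 0 else 0.0
        if cv <= min(tol, 1e-8):
            break
    return borders, _variances_at(law, borders, k), n_sweeps


# --------------------------------------------------------------------------
# fitting


def fit_class_boundaries(
    intensities: Sequence[float] | np.ndarray,
    k: int = 7,
    tol: float = 1e-3,
    max_iter: int = 10_000,
) -> ClassBoundaries:
    """Fit ``k`` contiguous equal-variance intensity classes.

    Parameters
    ----------
    intensities
        1-D sample of intensities (a flattened region).
    k
        Number of classes (default 7).
    tol
        Convergence target: coefficient of variation of the per-class
        variances must not exceed ``tol``.
    max_iter
        Cap on outer bisection iterations.

    Raises
    ------
    ClassificationError
        Fewer than ``k`` distinct intensity values, or ``k < 2``.
    ConvergenceError
        Variance spread still above ``tol`` when the bisection bracket is
        exhausted (diagnostics attached).
    """
    if k < 2:
        raise ClassificationError("need k >= 2 classes")
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size < k:
        raise ClassificationError(f"need at least {k} values, got {x.size}")
    if np.any(~np.isfinite(x)):
        raise ClassificationError("non-finite intensities")
    xu = np.unique(x)
    if xu.size < k:
        raise ClassificationError(
            f"need >= {k} distinct intensity values, got {xu.size}"
        )

    if xu.size == k:
        # exactly one distinct value per class: the partition is forced and
        # borders sit at midpoints between adjacent distinct values
        boundaries = np.concatenate([[xu[0]], 0.5 * (xu[:-1] + xu[1:]), [xu[-1]]])
        return ClassBoundaries(
            boundaries=boundaries,
            variances=np.zeros(k),
            k=k,
            tol=tol,
            n_iter=0,
            converged=True,
            diagnostics={"forced_partition": True},
        )

    # centre for numerical stability; boundaries shifted back at the end
    mu = float(np.mean(x))
    law = _InterpolatedLaw(x - mu)

    total_var = law.interval_var((0.0, 0.0, 0.0), float(law.xu[-1]))
    lo_v, hi_v = 0.0, total_var
    best = None
    best_cv = np.inf
    n_iter = 0
    while n_iter < max_iter:
        n_iter += 1
        v = 0.5 * (lo_v + hi_v)
        res = _sweep(law, k, v)
        if res is None:
            hi_v = v
            continue
        borders, variances = res
        m = float(np.mean(variances))
        cv = float(np.std(variances) / m) if m > 0 else 0.0
        if cv < best_cv:
            best_cv, best = cv, (borders.copy(), variances.copy())
        if cv <= min(tol, 1e-8):  # polish well below the requested tol
            break
        if variances[-1] > v:
            lo_v = v
        else:
            hi_v = v
        if hi_v - lo_v <= np.finfo(float).eps * max(total_var, 1.0):
            break

    if best is None:
        raise ConvergenceError(
            "no admissible k-class partition found",
            {"k": k, "n": int(x.size), "n_iter": n_iter},
        )
    borders, variances = best
    if best_cv > min(tol, 1e-8):
        borders, variances, n_sweeps = _polish(law, borders, k, tol)
        n_iter += n_sweeps
        m = float(np.mean(variances))
        best_cv = float(np.std(variances) / m) if m > 0 else 0.0
    boundaries = np.concatenate([[law.xu[0]], borders, [law.xu[-1]]]) + mu
    if np.any(np.diff(boundaries) <= 0):
        raise ConvergenceError(
            "degenerate (non-increasing) boundaries",
            {"boundaries": boundaries.tolist(), "n_iter": n_iter},
        )
    # variances of the voxels actually assigned (atoms, not interpolated)
    lab = np.searchsorted(boundaries[1:-1] - mu, x - mu, side="right")
    sample_vars = [float(np.var(x[lab == c])) if np.any(lab == c) else 0.0 for c in range(k)]
    converged = best_cv <= tol
    cb = ClassBoundaries(
        boundaries=boundaries,
        variances=np.asarray(variances),
        k=k,
        tol=tol,
        n_iter=n_iter,
        converged=converged,
        diagnostics={"variance_cv": best_cv, "sample_variances": sample_vars},
    )
    if not converged:
        raise ConvergenceError(
            f"variance spread {best_cv:.3g} above tol {tol:g} after {n_iter} iterations",
            cb.to_dict(),
        )
    return cb


# --------------------------------------------------------------------------
# labelling


def classify_voxels(
    stack: ImageStack,
    channel: str,
    region: np.ndarray,
    boundaries: ClassBoundaries,
    strict: bool = False,
) -> IntensityClassMap:
    """Label every region voxel with its intensity class.

    Voxels fall in class ``i`` when their intensity lies in
    ``[b_{i-1}, b_i)`` (top class closed above). Intensities outside the
    fitted range are clamped into the end classes unless ``strict`` is set,
    in which case they raise :class:`InputError`.
    """
    img = stack.channel(channel)
    region = np.asarray(region, dtype=bool)
    if region.shape != img.shape:
        raise InputError("region mask shape does not match stack")
    vals = img[region].astype(np.float64)
    if vals.size == 0:
        raise InputError("empty region")
    b = boundaries.boundaries
    if strict and (vals.min() < b[0] or vals.max() > b[-1]):
        raise InputError("intensity outside fitted boundary range (strict mode)")
    lab = np.searchsorted(b[1:-1], vals, side="right") + 1
    labels = np.zeros(img.shape, dtype=np.uint8)
    labels[region] = lab.astype(np.uint8)
    return IntensityClassMap(labels=labels, boundaries=boundaries, region=region)
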