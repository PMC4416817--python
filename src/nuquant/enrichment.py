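"""Marker enrichment and depletion across DNA intensity classes.

Given a seven-class intensity partition of a region and a mask of
marker-positive voxels (here NUP153 as a proxy for nuclear pore
complexes), the null hypothesis of a random marker distribution states
that the fraction of marker voxels in class ``c`` equals the fraction of
region voxels in that class. The relative enrichment

    r_c = (M_c / sum M) / (D_c / sum D) - 1

is 0 under the null, positive for accumulation and negative for
depletion. The null is tested globally with a Pearson goodness-of-fit
statistic over the classes, and specific class contrasts (e.g. densest
chromatin vs chromatid periphery) with a 2x2 test on per-class marker
densities ``M_c / D_c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu

from .errors import InputError, StatisticsError
from .intensity import IntensityClassMap
from .stack import ImageStack

__all__ = [
    "MarkerMask",
    "EnrichmentProfile",
    "TestResult",
    "marker_mask",
    "enrichment_profile",
    "gof_test",
    "pairwise_class_test",
]

#: p-values that underflow double precision are reported with this label.
UNDERFLOW_LABEL = "<1e-300"


@dataclass
class MarkerMask:
    """Marker-positive voxels within an analysis region."""

    mask: np.ndarray  # boolean, same shape as stack
    threshold: float
    method: str


@dataclass
class EnrichmentProfile:
    """Per-class voxel counts, fractions and relative enrichment.

    ``dropped`` lists classes with no region voxels (excluded from the
    fractions and from any downstream test's degrees of freedom).
    """

    classes: np.ndarray  # class indices (1-based) retained
    region_counts: np.ndarray  # D_c
    marker_counts: np.ndarray  # M_c
    expected_fraction: np.ndarray  # e_c = D_c / sum D
    observed_fraction: np.ndarray  # o_c = M_c / sum M
    relative_enrichment: np.ndarray  # r_c = o_c / e_c - 1
    dropped: list = field(default_factory=list)

    @property
    def total_region(self) -> int:
        return int(self.region_counts.sum())

    @property
    def total_marker(self) -> int:
        return int(self.marker_counts.sum())

    def density(self, cls: int) -> float:
        """Marker density M_c / D_c of class ``cls`` (1-based)."""
        i = int(np.flatnonzero(self.classes == cls)[0])
        return float(self.marker_counts[i] / self.region_counts[i])


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    comparison: str
    df: int | None = None
    p_label: str | None = None  # set when the p-value underflows
    flags: dict = field(default_factory=dict)

    @property
    def p_display(self) -> str:
        return self.p_label if self.p_label else f"{self.p_value:.3g}"


def _finish_p(p: float) -> tuple[float, str | None]:
    if p == 0.0:
        return 0.0, UNDERFLOW_LABEL
    return float(p), None


# --------------------------------------------------------------------------


def marker_mask(
    stack: ImageStack,
    channel: str,
    region: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> MarkerMask:
    """Threshold a marker channel into positive voxels within a region.

    ``method='otsu'`` picks the threshold by Otsu's criterion on the
    region's intensities; ``method='fixed'`` uses ``threshold`` as given
    (reproducible across stacks).
    """
    img = stack.channel(channel)
    region = np.asarray(region, dtype=bool)
    if region.shape != img.shape:
        raise InputError("region mask shape does not match stack")
    vals = img[region]
    if vals.size == 0:
        raise InputError("empty region")
    if method == "otsu":
        if float(vals.min()) == float(vals.max()):
            raise StatisticsError("constant marker channel: no threshold exists")
        thr = float(threshold_otsu(vals))
    elif method == "fixed":
        if threshold is None:
            raise InputError("method='fixed' requires a threshold")
        thr = float(threshold)
    else:
        raise InputError(f"unknown thresholding method {method!r}")
    mask = np.zeros(img.shape, dtype=bool)
    mask[region] = img[region] > thr
    return MarkerMask(mask=mask, threshold=thr, method=method)


def enrichment_profile(
    classmap: IntensityClassMap,
    marker: MarkerMask | np.ndarray | Sequence[int],
    marker_counts: Sequence[int] | None = None,
) -> EnrichmentProfile:
    """Tabulate marker voxels against intensity classes.

    ``marker`` is either a :class:`MarkerMask` / boolean array (counted
    inside the class map's region), or — together with ``marker_counts`` —
    may be bypassed by passing per-class counts directly (the simulator's
    ground-truth counts take this path).
    """
    k = classmap.k
    D = classmap.class_counts().astype(np.int64)
    if marker_counts is not None:
        M = np.asarray(marker_counts, dtype=np.int64)
        if M.shape != (k,):
            raise InputError(f"marker_counts must have length {k}")
    else:
        mask = marker.mask if isinstance(marker, MarkerMask) else np.asarray(marker, dtype=bool)
        if mask.shape != classmap.labels.shape:
            raise InputError("marker mask shape does not match class map")
        M = np.bincount(classmap.labels[mask & classmap.region], minlength=k + 1)[1:].astype(np.int64)
    if M.sum() == 0:
        raise StatisticsError("no marker signal in region")
    keep = D > 0
    dropped = [int(c) for c in np.flatnonzero(~keep) + 1]
    classes = np.flatnonzero(keep) + 1
    D, M = D[keep], M[keep]
    e = D / D.sum()
    o = M / M.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = o / e - 1.0
    return EnrichmentProfile(
        classes=classes,
        region_counts=D,
        marker_counts=M,
        expected_fraction=e,
        observed_fraction=o,
        relative_enrichment=r,
        dropped=dropped,
    )


def gof_test(profile: EnrichmentProfile) -> TestResult:
    """Pearson goodness-of-fit test of proportional marker placement.

    Tests H0: o_c = e_c for all classes, i.e. marker voxels fall into
    intensity classes proportionally to class size. The statistic is
    ``sum_c (M_c - N e_c)^2 / (N e_c)`` with ``N`` the total marker count
    and ``df = #classes - 1``. When any expected count falls below 5 the
    result is flagged (``small_expected``) for an exact multinomial
    reading.
    """
    if profile.classes.size < 2:
        raise StatisticsError("need >= 2 classes with region voxels")
    N = profile.total_marker
    if N == 0:
        raise StatisticsError("no marker voxels")
    expected = N * profile.expected_fraction
    stat = float(np.sum((profile.marker_counts - expected) ** 2 / expected))
    df = int(profile.classes.size - 1)
    p, label = _finish_p(float(stats.chi2.sf(stat, df)))
    flags = {}
    if np.any(expected < 5):
        flags["small_expected"] = True
    return TestResult(
        statistic=stat,
        p_value=p,
        p_label=label,
        df=df,
        test_name="pearson_gof",
        comparison="marker fraction vs class-size fraction over all classes",
        flags=flags,
    )


def pairwise_class_test(
    profile: EnrichmentProfile,
    class_a: int,
    class_set_b: int | Iterable[int],
    small_count: int = 25,
) -> TestResult:
    """Compare marker density of one class against a pooled class set.

    Builds the 2x2 table of (marker, non-marker) voxels for class ``a``
    versus the pooled classes ``b`` and tests equality of densities,
    two-sided. Fisher's exact test is used when any cell is below
    ``small_count``, otherwise the chi-square test with continuity
    correction.
    """
    if isinstance(class_set_b, (int, np.integer)):
        class_set_b = [int(class_set_b)]
    set_b = sorted(int(c) for c in class_set_b)
    present = set(int(c) for c in profile.classes)
    missing = ({class_a} | set(set_b)) - present
    if missing:
        raise StatisticsError(f"classes {sorted(missing)} have no region voxels")
    if class_a in set_b:
        raise StatisticsError("class_a must not be part of class_set_b")
    ia = np.flatnonzero(profile.classes == class_a)[0]
    ib = np.isin(profile.classes, set_b)
    Ma, Da = int(profile.marker_counts[ia]), int(profile.region_counts[ia])
    Mb, Db = int(profile.marker_counts[ib].sum()), int(profile.region_counts[ib].sum())
    if Da == 0 or Db == 0:
        raise StatisticsError("zero region voxels in a compared class")
    table = np.array([[Ma, Da - Ma], [Mb, Db - Mb]])
    comparison = f"density class {class_a} vs classes {set_b}"
    if table.min() < small_count:
        stat, p = stats.fisher_exact(table, alternative="two-sided")
        p, label = _finish_p(float(p))
        return TestResult(
            statistic=float(stat),
            p_value=p,
            p_label=label,
            test_name="fisher_exact",
            comparison=comparison,
        )
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    p, label = _finish_p(float(p))
    return TestResult(
        statistic=float(stat),
        p_value=p,
        p_label=label,
        df=1,
        test_name="chi2_2x2",
        comparison=comparison,
    )
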