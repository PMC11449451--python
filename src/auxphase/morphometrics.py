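"""Vein-network indices and nuclear-intensity ploidy quantification.

Leaf vasculature is scored per leaf as four feature-point counts — touch (T),
end (E), break (B) and exit (X) points — from which three indices are
computed (operational definitions of this package; plug-in replaceable):

* absolute cardinality ``T + E + B + X`` — how much vein there is;
* connectivity ``T / (T + E + X)`` — how often veins meet rather than end;
* continuity ``1 - B / (T + E + B + X)`` — how uninterrupted the strands are.

Group comparisons follow a two-stage rule: an F-test for equal variances
decides between the pooled-variance and Welch two-sample t-test.

Ploidy is inferred from nuclear fluorescence: the image is binarized,
connected components below a minimum area are discarded as sub-nuclear
debris, and each surviving ROI's mean intensity is measured on the original
image; groups are compared by their median ROI intensity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .profiles import rank_sum_test


@dataclass(frozen=True)
class VeinPointCounts:
    leaf_id: str
    touch: int
    end: int
    brk: int
    exit: int

    def __post_init__(self) -> None:
        counts = (self.touch, self.end, self.brk, self.exit)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.leaf_id}: negative feature-point count")
        if sum(counts) == 0:
            raise ValueError(f"{self.leaf_id}: all feature-point counts are zero")


@dataclass(frozen=True)
class VeinIndices:
    leaf_id: str
    cardinality_abs: float
    connectivity: float
    continuity: float
    rel_cardinality: float | None = None
    rel_connectivity: float | None = None
    rel_continuity: float | None = None


def vein_indices(
    counts: VeinPointCounts, control_means: dict[str, float] | None = None
) -> VeinIndices:
    """Compute the three vein indices; relative variants divide by the
    control-group mean of each index (enables pooling of experiments)."""
    t, e, b, x = counts.touch, counts.end, counts.brk, counts.exit
    total = t + e + b + x
    denom = t + e + x
    connectivity = t / denom if denom else 0.0
    continuity = 1.0 - b / total
    rel = {}
    if control_means is not None:
        for key, value in (
            ("cardinality_abs", total),
            ("connectivity", connectivity),
            ("continuity", continuity),
        ):
            rel_key = "rel_" + key.removesuffix("_abs")
            rel[rel_key] = value / control_means[key] if control_means.get(key) else None
    return VeinIndices(
        leaf_id=counts.leaf_id,
        cardinality_abs=float(total),
        connectivity=float(connectivity),
        continuity=float(continuity),
        rel_cardinality=rel.get("rel_cardinality"),
        rel_connectivity=rel.get("rel_connectivity"),
        rel_continuity=rel.get("rel_continuity"),
    )


@dataclass(frozen=True)
class GroupComparison:
    variance_test_p: float
    mean_test_p: float
    test_flavor: str  # 'pooled-variance' or 'unequal-variance'
    mean_a: float
    mean_b: float


def compare_index_groups(
    group_a: Sequence[float], group_b: Sequence[float], alpha_var: float = 0.05
) -> GroupComparison:
    """Two-stage comparison: F-test for equal variances, then Student's t.

    If the two-sided variance-ratio F-test does not reject at ``alpha_var``,
    a pooled-variance t-test is used; otherwise Welch's unequal-variance t.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    var_a, var_b = a.var(ddof=1), b.var(ddof=1)
    if var_a == var_b:
        p_var = 1.0
    elif min(var_a, var_b) == 0:
        p_var = 0.0
    else:
        f = var_a / var_b
        dist = stats.f(a.size - 1, b.size - 1)
        p_var = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    equal_var = p_var >= alpha_var
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(
        variance_test_p=float(p_var),
        mean_test_p=float(t_res.pvalue),
        test_flavor="pooled-variance" if equal_var else "unequal-variance",
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


@dataclass(frozen=True)
class NucleusROI:
    label: int
    area: int
    mean_intensity: float
    centroid: tuple[float, float]


def segment_nuclei(
    image: np.ndarray,
    threshold: str | float = "otsu",
    min_area: int = 30,
    connectivity: int = 4,
) -> list[NucleusROI]:
    """Segment nuclei and measure their mean intensity on the original image.

    Binarize (Otsu by default, or a fixed threshold value), label connected
    components at 4- or 8-pixel connectivity, discard components with
    ``area < min_area``, and measure each survivor on the unmodified image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D greyscale image")
    if img.min() < 0:
        raise ValueError("intensities must be non-negative")
    if np.ptp(img) == 0:
        raise ValueError("no foreground: image is constant")
    thr = threshold_otsu(img) if threshold == "otsu" else float(threshold)
    mask = img > thr
    if not mask.any():
        raise ValueError("no foreground: threshold above all intensities")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = label(mask, connectivity=1 if connectivity == 4 else 2)
    rois = [
        NucleusROI(
            label=int(region.label),
            area=int(region.area),
            mean_intensity=float(region.intensity_mean),
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
        )
        for region in regionprops(labels, intensity_image=img)
        if region.area >= min_area
    ]
    rois.sort(key=lambda r: r.label)
    return rois


@dataclass(frozen=True)
class IntensitySummary:
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    rank_test_p: float

    @property
    def ratio(self) -> float:
        return self.median_b / self.median_a


def nuclear_intensity_summary(
    rois_a: Sequence[NucleusROI], rois_b: Sequence[NucleusROI]
) -> IntensitySummary:
    """Median nuclear intensity per group, their ratio (b/a) and a two-sided
    rank-sum p-value; a genome-doubling event is expected to double the
    ratio of H2B-GFP signal."""
    if len(rois_a) < 3 or len(rois_b) < 3:
        raise ValueError("each group needs at least 3 ROIs")
    ia = [r.mean_intensity for r in rois_a]
    ib = [r.mean_intensity for r in rois_b]
    return IntensitySummary(
        n_a=len(ia),
        n_b=len(ib),
        median_a=float(np.median(ia)),
        median_b=float(np.median(ib)),
        rank_test_p=rank_sum_test(ia, ib, "two-sided"),
    )
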