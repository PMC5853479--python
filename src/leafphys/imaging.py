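"""Ratiometric membrane-potential imaging analysis.

Protoplasts stained with a dual-excitation potentiometric dye are imaged
at 438 nm and 531 nm excitation (single emission channel).  The membrane
ring of each protoplast is segmented on the 531 nm image, and the ratio of
background-subtracted mean annulus intensities 438/531 reports membrane
potential: a more hyperpolarised (more negative) cell gives a smaller
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure, morphology
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

__all__ = [
    "ProtoplastROI",
    "RatioResult",
    "ProtoplastSegmenter",
    "segment_protoplasts",
    "estimate_background",
    "compute_ratio",
    "compare_ratio_groups",
]


@dataclass
class ProtoplastROI:
    """Ring region of interest for one segmented protoplast.

    ``annulus_mask`` selects the membrane pixels; ``flags`` may contain
    "edge" (ring truncated by the image border, excluded by default) or
    "saturated" (set later if saturated pixels fall inside the annulus).
    """

    center: tuple
    radius: float
    annulus_mask: np.ndarray
    flags: list = field(default_factory=list)

    @property
    def edge_truncated(self) -> bool:
        return "edge" in self.flags


class ProtoplastSegmenter(BaseEstimator):
    """Threshold + connected-component + circle-fit ring segmentation.

    An automatic (Otsu) global threshold on the 531 nm image isolates the
    bright membrane rings; each connected component is fitted with a
    circle (centroid + mean radial distance of its pixels) and an annulus
    of ``annulus_thickness`` px centred on the fitted rim becomes the ROI.
    Components smaller than ``min_area`` px are discarded as debris.
    """

    def __init__(self, annulus_thickness: float = 3.0, min_area: int = 30):
        self.annulus_thickness = annulus_thickness
        self.min_area = min_area

    def segment(self, image) -> list[ProtoplastROI]:
        image = np.asarray(image, dtype=float)
        if image.ndim != 2:
            raise ValueError("expected a single-channel 2-D image")
        if np.ptp(image) == 0:
            return []
        thr = threshold_otsu(image)
        binary = image > thr
        if not binary.any():
            return []
        labels = measure.label(binary)
        rois = []
        h, w = image.shape
        rr, cc = np.mgrid[0:h, 0:w]
        for region in measure.regionprops(labels):
            if region.area < self.min_area:
                continue
            r0, c0 = region.centroid
            coords = region.coords
            radius = float(
                np.hypot(coords[:, 0] - r0, coords[:, 1] - c0).mean()
            )
            dist = np.hypot(rr - r0, cc - c0)
            annulus = np.abs(dist - radius) <= self.annulus_thickness / 2.0
            flags = []
            margin = radius + self.annulus_thickness
            if (r0 - margin < 0 or c0 - margin < 0
                    or r0 + margin >= h or c0 + margin >= w):
                flags.append("edge")
            rois.append(ProtoplastROI(center=(r0, c0), radius=radius,
                                      annulus_mask=annulus, flags=flags))
        return rois

    # alias so the estimator composes as a transformer
    def transform(self, image):
        return self.segment(image)


def segment_protoplasts(image_531, annulus_thickness: float = 3.0,
                        min_area: int = 30,
                        exclude_edge: bool = True) -> list[ProtoplastROI]:
    """Segment membrane rings on the 531 nm-excitation image.

    Edge-truncated rings are excluded by default; pass
    ``exclude_edge=False`` to keep them (still flagged).
    """
    rois = ProtoplastSegmenter(
        annulus_thickness=annulus_thickness, min_area=min_area
    ).segment(image_531)
    if exclude_edge:
        rois = [r for r in rois if not r.edge_truncated]
    return rois


def estimate_background(image, rois=None, quantile: float = 0.2) -> float:
    """Background level: mean of the dimmest ``quantile`` of non-cell pixels."""
    image = np.asarray(image, dtype=float)
    mask = np.zeros(image.shape, dtype=bool)
    for roi in rois or []:
        mask |= roi.annulus_mask
    mask = morphology.dilation(mask, morphology.disk(2))
    outside = image[~mask]
    if outside.size == 0:
        raise ValueError("no non-cell pixels left for background estimation")
    cut = np.quantile(outside, quantile)
    return float(outside[outside <= cut].mean())


@dataclass
class RatioResult:
    """Per-protoplast dual-excitation ratio.

    ``valid`` is False when the annulus was saturated or the
    background-subtracted denominator was non-positive; ``ratio`` is NaN
    in that case.
    """

    mean_438: float
    mean_531: float
    ratio: float
    valid: bool
    group: str = "all"
    flags: list = field(default_factory=list)


def compute_ratio(roi: ProtoplastROI, image_438, image_531,
                  background_438: float | None = None,
                  background_531: float | None = None,
                  saturation_level: float = 65535.0,
                  group: str = "all") -> RatioResult:
    """Ratio of background-subtracted mean annulus intensities, 438/531.

    Saturated pixels (>= ``saturation_level`` in either channel) are
    excluded from the annulus; a fully saturated annulus or a non-positive
    denominator yields an invalid result rather than a number.
    """
    im438 = np.asarray(image_438, dtype=float)
    im531 = np.asarray(image_531, dtype=float)
    if im438.shape != im531.shape:
        raise ValueError("channel images must be registered (same shape)")
    if background_438 is None:
        background_438 = estimate_background(im438, [roi])
    if background_531 is None:
        background_531 = estimate_background(im531, [roi])
    mask = roi.annulus_mask.copy()
    saturated = (im438 >= saturation_level) | (im531 >= saturation_level)
    flags = list(roi.flags)
    if (mask & saturated).any():
        flags.append("saturated")
    mask &= ~saturated
    if not mask.any():
        return RatioResult(float("nan"), float("nan"), float("nan"),
                           valid=False, group=group, flags=flags)
    num = float(im438[mask].mean() - background_438)
    den = float(im531[mask].mean() - background_531)
    if den <= 0 or num <= 0:
        return RatioResult(num, den, float("nan"), valid=False,
                           group=group, flags=flags)
    return RatioResult(num, den, num / den, valid=True, group=group, flags=flags)


def compare_ratio_groups(results: list[RatioResult]):
    """Group means +- SE and a Welch two-sided t-test on valid ratios.

    Returns a DataFrame (one row per group: n, mean, se) plus a dict with
    the P-value and an ordering statement naming the smaller-ratio group.
    """
    valid = [r for r in results if r.valid]
    by_group: dict[str, list[float]] = {}
    for r in valid:
        by_group.setdefault(r.group, []).append(r.ratio)
    if len(by_group) != 2:
        raise ValueError(f"exactly two groups required, got {list(by_group)}")
    (ga, xs), (gb, ys) = by_group.items()
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("need >= 2 valid ratios per group")
    xs, ys = np.array(xs), np.array(ys)
    table = pd.DataFrame({
        "n": [xs.size, ys.size],
        "mean_ratio": [xs.mean(), ys.mean()],
        "se": [xs.std(ddof=1) / np.sqrt(xs.size), ys.std(ddof=1) / np.sqrt(ys.size)],
    }, index=[ga, gb])
    if np.ptp(xs) == 0 and np.ptp(ys) == 0:
        p = 1.0 if xs[0] == ys[0] else 0.0
    else:
        p = float(stats.ttest_ind(xs, ys, equal_var=False).pvalue)
    smaller = ga if xs.mean() < ys.mean() else gb
    summary = {
        "p_value": p,
        "smaller_ratio_group": smaller,
        "statement": f"{smaller} has the smaller mean ratio (P = {p:.3g})",
    }
    return table, summary
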