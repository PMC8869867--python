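"""ROI-restricted co-localization of proteasome and autophagy markers.

Detects punctate structures (autophagosomes) in a reference channel,
computes thresholded Manders coefficients inside those puncta, and
extracts normalized line profiles — the quantitative core of two-channel
confocal co-localization readouts such as LC3B/beta2 or p62/RPN1.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from . import stats as pstats


@dataclasses.dataclass
class TwoChannelImage:
    """Two registered 2-D intensity arrays.

    ``reference`` is the autophagy marker (LC3B or p62) whose puncta
    define the regions of interest; ``partner`` is the proteasome
    subunit channel (beta2, RPN1).
    """

    reference: np.ndarray
    partner: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.partner = np.asarray(self.partner, dtype=float)
        if self.reference.ndim != 2 or self.reference.shape != self.partner.shape:
            raise ValueError("channels must be equal-shape 2-D arrays")
        if (self.reference < 0).any() or (self.partner < 0).any():
            raise ValueError("intensities must be nonnegative")


@dataclasses.dataclass
class ROISet:
    """Connected pixel masks with centroids and areas."""

    labels: np.ndarray          # labeled image, 0 = background
    areas: list[int]
    centroids: list[tuple[float, float]]

    def __len__(self) -> int:
        return len(self.areas)

    @property
    def union_mask(self) -> np.ndarray:
        return self.labels > 0

    def mask(self, i: int) -> np.ndarray:
        return self.labels == (i + 1)


@dataclasses.dataclass
class MandersResult:
    """Thresholded Manders coefficients, per ROI and pooled over ROIs."""

    m1: float
    m2: float
    per_roi_m1: list[float | None]
    per_roi_m2: list[float | None]
    reference_threshold: float
    partner_threshold: float


def _resolve_threshold(channel: np.ndarray, method, mask: np.ndarray | None = None) -> float:
    """``method`` is "otsu" or a fixed numeric threshold."""
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return float(method)
    if method == "otsu":
        vals = channel if mask is None else channel[mask]
        if np.ptp(vals) == 0:
            warnings.warn("flat channel: Otsu threshold degenerate, using max value")
            return float(vals.max())
        return float(threshold_otsu(vals))
    raise ValueError(f"unknown threshold method {method!r}")


def detect_puncta(
    channel: np.ndarray,
    threshold_method="otsu",
    min_area: int = 4,
    max_area: int = 10_000,
) -> ROISet:
    """Segment punctate ROIs: threshold, 8-connected labeling, area filter.

    A flat image under Otsu yields an empty ROI set with a warning
    rather than an error.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty image")
    if np.ptp(channel) == 0 and threshold_method == "otsu":
        warnings.warn("flat image: no puncta detectable under Otsu")
        return ROISet(labels=np.zeros(channel.shape, dtype=int), areas=[], centroids=[])
    thr = _resolve_threshold(channel, threshold_method)
    mask = channel > thr
    labeled = label(mask, connectivity=2)
    keep = np.zeros_like(labeled)
    areas: list[int] = []
    centroids: list[tuple[float, float]] = []
    nxt = 0
    for region in regionprops(labeled):
        if min_area <= region.area <= max_area:
            nxt += 1
            keep[labeled == region.label] = nxt
            areas.append(int(region.area))
            centroids.append(tuple(region.centroid))
    return ROISet(labels=keep, areas=areas, centroids=centroids)


def manders(
    image: TwoChannelImage,
    rois: ROISet,
    partner_threshold="otsu",
    reference_threshold="otsu",
) -> MandersResult:
    """Thresholded Manders coefficients restricted to the ROI union.

    Within the pooled ROI pixels, ``M1`` is the fraction of reference
    intensity falling on pixels where the partner channel exceeds its
    threshold; ``M2`` is symmetric with the channels swapped.  ROIs
    with zero total intensity in a channel report ``None`` for that
    coefficient; the pooled value is computed over all ROI pixels with
    nonzero totals.
    """
    if len(rois) == 0:
        raise ValueError("Manders coefficients need at least one ROI")
    thr_p = _resolve_threshold(image.partner, partner_threshold)
    thr_r = _resolve_threshold(image.reference, reference_threshold)
    partner_pos = image.partner > thr_p
    reference_pos = image.reference > thr_r

    def _coeff(intensity: np.ndarray, other_pos: np.ndarray, mask: np.ndarray):
        total = intensity[mask].sum()
        if total <= 0:
            return None
        return float(intensity[mask & other_pos].sum() / total)

    per_m1 = [_coeff(image.reference, partner_pos, rois.mask(i)) for i in range(len(rois))]
    per_m2 = [_coeff(image.partner, reference_pos, rois.mask(i)) for i in range(len(rois))]
    union = rois.union_mask
    m1 = _coeff(image.reference, partner_pos, union)
    m2 = _coeff(image.partner, reference_pos, union)
    return MandersResult(
        m1=float("nan") if m1 is None else m1,
        m2=float("nan") if m2 is None else m2,
        per_roi_m1=per_m1,
        per_roi_m2=per_m2,
        reference_threshold=thr_r,
        partner_threshold=thr_p,
    )


def line_profile(
    image: TwoChannelImage,
    start: tuple[float, float],
    end: tuple[float, float],
    n_samples: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized intensity traces along a line (row, col endpoints).

    Bilinear interpolation at ``n_samples`` evenly spaced points; each
    trace is divided by its own maximum (a zero-max trace comes back as
    all zeros).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    r0, c0 = start
    r1, c1 = end
    if (r0, c0) == (r1, c1):
        raise ValueError("line endpoints must differ")
    nrow, ncol = image.reference.shape
    for r, c in (start, end):
        if not (0 <= r <= nrow - 1 and 0 <= c <= ncol - 1):
            raise ValueError("endpoints out of image bounds")
    rows = np.linspace(r0, r1, n_samples)
    cols = np.linspace(c0, c1, n_samples)
    coords = np.vstack([rows, cols])

    def _trace(channel: np.ndarray) -> np.ndarray:
        t = ndimage.map_coordinates(channel, coords, order=1, mode="nearest")
        peak = t.max()
        return t / peak if peak > 0 else np.zeros_like(t)

    return _trace(image.reference), _trace(image.partner)


def compare_coloc(values_a, values_b, variant: str = "student"):
    """Compare per-cell coefficients between two groups.

    Returns per-group mean +/- SD and the two-tailed unpaired t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two cells")
    test = pstats.two_sample_ttest(a, b, variant=variant)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "t": test.t,
        "df": test.df,
        "p_value": test.p_value,
    }
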