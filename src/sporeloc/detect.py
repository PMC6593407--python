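"""Image preprocessing, forespore/focus identification and onset calls.

The detection rules mirror the manual analysis regime they automate: a
single 3x3 mean-filter smoothing pass, forespores found from the membrane
stain, loci accepted only when a forespore contains exactly one focus, and
a reporter counted once it is twice as bright as the noise above
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import closing

log = logging.getLogger(__name__)

__all__ = [
    "ForesporeROI",
    "FocusCandidate",
    "OnsetCall",
    "smooth_image",
    "detect_forespores",
    "detect_foci",
    "detect_reporter_onset",
]


@dataclass
class ForesporeROI:
    """One forespore: bounding box (half-open pixel bounds) + circle fit."""

    cell_id: int
    bbox: Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    center_px: Tuple[float, float]  # (row, col)
    radius_px: float


@dataclass
class FocusCandidate:
    """A locus-focus candidate inside an ROI (subpixel position, px)."""

    cell_id: int
    position: Tuple[float, float]  # (row, col)
    peak_intensity: float
    accepted: bool


@dataclass
class OnsetCall:
    """First frame at which a reporter crossed the detection threshold."""

    cell_id: int
    channel: str  # "YFP" | "CFP"
    onset_frame: Optional[int]
    onset_time: Optional[float]

    @property
    def censored(self) -> bool:
        return self.onset_frame is None


def smooth_image(image: np.ndarray) -> np.ndarray:
    """One pass of the 3x3 neighbourhood mean (borders edge-replicated)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("smooth_image expects a non-empty 2D image")
    return uniform_filter(image, size=3, mode="nearest")


def detect_forespores(
    membrane_image: np.ndarray,
    pixel_size: float,
    diameter_range_nm: Tuple[float, float] = (250.0, 1200.0),
    margin_px: int = 4,
    min_area_px: int = 8,
) -> List[ForesporeROI]:
    """Find ring-like bright forespore outlines in a (smoothed) membrane image.

    Bright pixels are selected by Otsu threshold, grouped into connected
    components, and each component is circle-fitted: centre = centroid of
    its bright pixels, radius = their mean distance to the centroid.
    Components whose fitted diameter falls outside ``diameter_range_nm``
    are dropped.  A blank image yields an empty list.
    """
    img = np.asarray(membrane_image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("detect_forespores expects a non-empty 2D image")
    if np.ptp(img) == 0:
        return []
    try:
        thr = threshold_otsu(img)
    except ValueError:
        return []
    # Otsu alone is unstable when the bright outline covers few pixels; keep
    # the threshold above the (robust) background so noise cannot flood in
    med = float(np.median(img))
    mad_sd = 1.4826 * float(np.median(np.abs(img - med)))
    thr = max(thr, med + 5.0 * mad_sd)
    binary = img > thr
    if not binary.any():
        return []
    # bridge single-pixel gaps so shot noise cannot split a ring into arcs
    binary = closing(binary, footprint=np.ones((3, 3), dtype=bool))
    labels = label(binary)
    rois: List[ForesporeROI] = []
    for region in regionprops(labels):
        if region.area < min_area_px:
            continue
        coords = region.coords.astype(float)
        center = coords.mean(axis=0)
        radius = float(np.mean(np.linalg.norm(coords - center, axis=1)))
        diameter_nm = 2.0 * radius * pixel_size
        if not diameter_range_nm[0] <= diameter_nm <= diameter_range_nm[1]:
            continue
        half = int(np.ceil(radius)) + margin_px
        r0 = max(int(round(center[0])) - half, 0)
        c0 = max(int(round(center[1])) - half, 0)
        r1 = min(int(round(center[0])) + half + 1, img.shape[0])
        c1 = min(int(round(center[1])) + half + 1, img.shape[1])
        rois.append(
            ForesporeROI(
                cell_id=len(rois),
                bbox=(r0, c0, r1, c1),
                center_px=(float(center[0]), float(center[1])),
                radius_px=radius,
            )
        )
    return rois


def _quadratic_refine(img: np.ndarray, peak: Tuple[int, int]) -> Tuple[float, float]:
    """Subpixel peak refinement by independent 1D parabola fits per axis."""
    r, c = peak
    out = [float(r), float(c)]
    for axis, idx in ((0, r), (1, c)):
        if idx <= 0 or idx >= img.shape[axis] - 1:
            continue
        if axis == 0:
            ym, y0, yp = img[r - 1, c], img[r, c], img[r + 1, c]
        else:
            ym, y0, yp = img[r, c - 1], img[r, c], img[r, c + 1]
        denom = ym - 2.0 * y0 + yp
        if denom >= 0:  # not a local quadratic maximum
            continue
        delta = 0.5 * (ym - yp) / denom
        out[axis] = idx + float(np.clip(delta, -0.5, 0.5))
    return out[0], out[1]


def background_statistics(
    image: np.ndarray, rois: Sequence[ForesporeROI]
) -> Tuple[float, float]:
    """Mean and sd of the cell-free background (pixels outside all ROIs).

    Statistics are taken on the raw image handed in; the detection rule is
    calibrated against raw (uncorrelated) noise, not smoothed noise.
    """
    img = np.asarray(image, dtype=float)
    mask = np.ones(img.shape, dtype=bool)
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox
        mask[r0:r1, c0:c1] = False
    pixels = img[mask] if mask.any() else img.ravel()
    return float(np.mean(pixels)), float(np.std(pixels))


def detect_foci(
    locus_image: np.ndarray,
    rois: Sequence[ForesporeROI],
    threshold_multiplier: float = 2.0,
    background_stats: Optional[Tuple[float, float]] = None,
    raw_locus_image: Optional[np.ndarray] = None,
    min_distance: int = 2,
) -> List[FocusCandidate]:
    """Locate locus foci per ROI; accept an ROI only with exactly one.

    ``locus_image`` should be the smoothed locus channel.  The detection
    threshold is background mean + ``threshold_multiplier`` x background sd,
    with the statistics taken from the raw image (``raw_locus_image`` if
    given, else the smoothed one) outside all ROIs.  Candidate positions
    are refined to subpixel by a 2D quadratic fit of the 3x3 neighbourhood.
    """
    img = np.asarray(locus_image, dtype=float)
    if background_stats is None:
        stats_img = raw_locus_image if raw_locus_image is not None else img
        background_stats = background_statistics(np.asarray(stats_img, float), rois)
    bg_mean, bg_sd = background_stats
    threshold = bg_mean + threshold_multiplier * bg_sd

    candidates: List[FocusCandidate] = []
    for roi in rois:
        r0, c0, r1, c1 = roi.bbox
        sub = img[r0:r1, c0:c1]
        peaks = peak_local_max(
            sub, min_distance=min_distance, threshold_abs=threshold, exclude_border=False
        )
        accepted = len(peaks) == 1
        if not accepted and len(peaks) == 0:
            log.debug("cell %d: no focus above threshold, ROI rejected", roi.cell_id)
        elif not accepted:
            log.debug(
                "cell %d: %d foci found, ROI rejected (exactly-one rule)",
                roi.cell_id,
                len(peaks),
            )
        for pr, pc in peaks:
            rr, rc = _quadratic_refine(sub, (int(pr), int(pc)))
            candidates.append(
                FocusCandidate(
                    cell_id=roi.cell_id,
                    position=(r0 + rr, c0 + rc),
                    peak_intensity=float(sub[pr, pc]),
                    accepted=accepted,
                )
            )
    return candidates


def detect_reporter_onset(
    trace: np.ndarray,
    background_mean: float,
    background_noise_sd: float,
    frame_interval: float,
    cell_id: int = 0,
    channel: str = "YFP",
    threshold_multiplier: float = 2.0,
    min_consecutive: int = 3,
) -> OnsetCall:
    """First frame whose excess over background reaches the 2x-noise rule.

    Onset = first frame with ``intensity - background_mean >=
    threshold_multiplier * background_noise_sd`` (and strictly positive
    excess, so a flat zero-noise trace has no onset).  Because the 2x rule
    alone false-triggers on ~2% of pre-onset frames under Gaussian noise,
    the crossing must persist for ``min_consecutive`` frames (runs
    truncated by the end of the trace still count) — a reporter rises
    monotonically, noise blips do not.  Censored when the threshold is
    never reached.
    """
    if background_noise_sd < 0:
        raise ValueError("background_noise_sd must be >= 0")
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or trace.size == 0:
        raise ValueError("trace must be a non-empty 1D array")
    excess = trace - background_mean
    above = (excess >= threshold_multiplier * background_noise_sd) & (excess > 0)
    n = above.size
    for i in np.flatnonzero(above):
        run = above[i : min(i + min_consecutive, n)]
        if run.all():
            return OnsetCall(cell_id, channel, int(i), i * frame_interval)
    return OnsetCall(cell_id, channel, None, None)
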