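"""Cell detection and starter/input classification from two-channel images.

The counting contract mirrors validated practice for dense rabies-labelled
slices: binarise each channel (absolute or Otsu threshold), clean the masks by
morphological opening, extract 8-connected components, and classify by channel
overlap — a component of the green-AND-red mask strictly larger than 5 pixels
marks a starter cell, remaining green components are presynaptic input cells,
remaining red components are potential starters that the tracer missed
(red_only).  A starter claims the green and red components it sits in, so no
cell is counted twice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon
from skimage.filters import threshold_yen
from skimage.measure import label, regionprops
from skimage.morphology import opening

logger = logging.getLogger("monotrace")

CLASSES = ("starter", "input", "red_only")


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholding and classification parameters.

    ``threshold`` is an absolute intensity, or None for Otsu's automatic
    threshold per plane.  ``pixel_size_um`` is required metadata; centroids
    are reported in micrometres.
    """

    threshold: float | None = None
    opening_radius_px: int = 1
    min_area_px: int = 5
    min_overlap_px: int = 5  # starter rule: overlap area strictly greater
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.opening_radius_px < 0 or self.min_area_px < 1:
            raise ValueError("opening radius must be >= 0 and min area >= 1")


# ---------------------------------------------------------------------------
# segmentation


def segment_channel(plane: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Binary mask of one image plane: ``plane > threshold``.

    ``threshold=None`` uses Yen's entropy threshold, which stays out of the
    background mode even when labelled cells cover well under 1% of the
    plane (where variance-based splits drift into the noise); a constant
    plane then yields an empty mask with a warning instead of an arbitrary
    split.
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise ValueError("plane must be 2-D")
    if np.any(plane < 0):
        raise ValueError("plane must be non-negative")
    if threshold is None:
        if plane.max() == plane.min():
            warnings.warn("constant plane: automatic threshold undefined, "
                          "returning an empty mask", stacklevel=2)
            return np.zeros(plane.shape, dtype=bool)
        threshold = threshold_yen(plane)
    return plane > threshold


def clean_mask(mask: np.ndarray, opening_radius_px: int = 1) -> np.ndarray:
    """Morphological opening with a (2r+1) x (2r+1) square footprint.

    Removes speckle up to the footprint size while leaving convex blobs of
    cell scale untouched; radius 0 is the identity.
    """
    if opening_radius_px < 0:
        raise ValueError("opening radius must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if opening_radius_px == 0:
        return mask.copy()
    size = 2 * opening_radius_px + 1
    return opening(mask, footprint=np.ones((size, size), dtype=bool))


def extract_components(mask: np.ndarray, min_area_px: int = 5,
                       pixel_size_um: float = 1.0) -> pd.DataFrame:
    """8-connected components of a binary mask.

    Returns one row per surviving component with ``label``, ``area_px`` and
    centroid in µm (``x_um`` = column, ``y_um`` = row); components smaller
    than ``min_area_px`` are dropped.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    lab = label(np.asarray(mask, dtype=bool), connectivity=2)
    rows = [(p.label, p.area, p.centroid[1] * pixel_size_um,
             p.centroid[0] * pixel_size_um)
            for p in regionprops(lab) if p.area >= min_area_px]
    return pd.DataFrame(rows, columns=["label", "area_px", "x_um", "y_um"])


# ---------------------------------------------------------------------------
# classification


def classify_cells(green: np.ndarray, red: np.ndarray,
                   config: DetectionConfig = DetectionConfig(),
                   slice_index: int = 0) -> pd.DataFrame:
    """Classify detected cells as starter / input / red_only.

    Components of ``green AND red`` with area strictly greater than
    ``min_overlap_px`` are starter cells; each starter claims the green and
    red components it overlaps.  Unclaimed green components are inputs,
    unclaimed red components are red_only.  Returns a DetectedCells frame
    with centroid (µm), area (px), class and provenance.
    """
    green = np.asarray(green, dtype=bool)
    red = np.asarray(red, dtype=bool)
    if green.shape != red.shape:
        raise ValueError("green and red masks must have the same shape")
    px = config.pixel_size_um
    lab_g = label(green, connectivity=2)
    lab_r = label(red, connectivity=2)
    lab_o = label(green & red, connectivity=2)

    records = []
    claimed_g, claimed_r = set(), set()
    for p in regionprops(lab_o):
        if p.area <= config.min_overlap_px:
            continue
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        claimed_g.update(np.unique(lab_g[rr, cc]))
        claimed_r.update(np.unique(lab_r[rr, cc]))
        records.append(("starter", p.centroid[1] * px, p.centroid[0] * px,
                        p.area, "green+red"))
    for lab_img, claimed, cls, channel in ((lab_g, claimed_g, "input", "green"),
                                           (lab_r, claimed_r, "red_only", "red")):
        for p in regionprops(lab_img):
            if p.label in claimed or p.area < config.min_area_px:
                continue
            records.append((cls, p.centroid[1] * px, p.centroid[0] * px,
                            p.area, channel))
    df = pd.DataFrame(records,
                      columns=["channel_class", "x_um", "y_um", "area_px",
                               "channels"])
    df["slice_index"] = slice_index
    return df


def detect_slice(green_plane: np.ndarray, red_plane: np.ndarray,
                 config: DetectionConfig = DetectionConfig(),
                 slice_index: int = 0) -> pd.DataFrame:
    """Full per-slice detection: segment both channels, open, classify."""
    masks = []
    for plane in (green_plane, red_plane):
        m = segment_channel(plane, config.threshold)
        masks.append(clean_mask(m, config.opening_radius_px))
    return classify_cells(masks[0], masks[1], config, slice_index=slice_index)


def detect_stack(images: np.ndarray, config: DetectionConfig = DetectionConfig(),
                 slice_indices=None) -> pd.DataFrame:
    """Detection over a (n_slices, 2, H, W) stack, channels (green, red)."""
    if slice_indices is None:
        slice_indices = range(len(images))
    frames = [detect_slice(img[0], img[1], config, slice_index=s)
              for img, s in zip(images, slice_indices)]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class DetectionMetrics:
    n_truth: int
    n_detected: int
    n_matched: int

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 0.0

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_truth if self.n_truth else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def evaluate_detection(detected: pd.DataFrame, truth: pd.DataFrame,
                       match_radius_um: float = 10.0,
                       coords=("x_um", "y_um")) -> DetectionMetrics:
    """Greedy nearest-neighbour matching of detections to truth cells.

    Candidate pairs within ``match_radius_um`` are matched closest-first;
    each truth cell and each detection is used at most once.  The result is
    invariant to row order of either table.
    """
    if detected.empty or truth.empty:
        return DetectionMetrics(len(truth), len(detected), 0)
    d_xy = detected[list(coords)].to_numpy(float)
    t_xy = truth[list(coords)].to_numpy(float)
    pairs = cKDTree(d_xy).sparse_distance_matrix(
        cKDTree(t_xy), match_radius_um, output_type="coo_matrix")
    order = np.argsort(pairs.data, kind="stable")
    used_d, used_t = set(), set()
    matched = 0
    for di, ti in zip(pairs.row[order], pairs.col[order]):
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matched += 1
    return DetectionMetrics(len(truth), len(detected), matched)


@dataclass(frozen=True)
class PairedCountTest:
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool  # all paired differences were zero


def compare_auto_manual(auto_counts, manual_counts) -> PairedCountTest:
    """Two-sided Wilcoxon signed-rank test on paired automatic vs manual
    counts (zeros dropped, as in the classic test).  If every difference is
    zero the comparison is degenerate and reported as p = 1."""
    a = np.asarray(auto_counts, dtype=float)
    m = np.asarray(manual_counts, dtype=float)
    if a.shape != m.shape or a.ndim != 1:
        raise ValueError("paired count vectors must be 1-D and equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    diffs = a - m
    if np.all(diffs == 0):
        logger.warning("compare_auto_manual: all differences zero; p = 1 by convention")
        return PairedCountTest(statistic=0.0, p_value=1.0, n_pairs=len(a),
                               degenerate=True)
    res = wilcoxon(a, m, zero_method="wilcox", alternative="two-sided",
                   method="auto")
    return PairedCountTest(statistic=float(res.statistic),
                           p_value=float(res.pvalue), n_pairs=len(a),
                           degenerate=False)
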