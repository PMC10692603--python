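"""Binarization and connected-component spot detection with morphometrics.

Mirrors a mask-detector workflow: an 8-bit frame is thresholded so that
biological objects become foreground, then each connected component becomes
one *spot* carrying centroid (µm), area (µm²), perimeter (µm), circularity
(4π·area/perimeter², clipped to ≤ 1), equivalent radius (√(area/π)) and a
quality score.  Quality is defined as the component's pixel count — a
monotone proxy for detection confidence — and the default quality threshold
of 1 keeps every spot of at least one pixel, the permissive setting needed
to retain micrometer-sized bacteria.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

logger = logging.getLogger(__name__)

#: advisory threshold band for 8-bit bright-field masks; values below 100
#: start losing small dim objects, values above 118 pick up overexposed
#: background, so anything outside the band triggers a warning
THRESHOLD_BAND = (100, 118)

SPOT_COLUMNS = ["frame", "spot_id", "x_um", "y_um", "area_um2",
                "perimeter_um", "circularity", "radius_um", "pixel_count",
                "quality", "on_border"]


@dataclass
class BinaryMask:
    """A thresholded frame: boolean foreground grid plus provenance."""

    mask: np.ndarray
    threshold_used: int
    polarity: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        frac = self.mask.mean() if self.mask.size else 0.0
        if not 0.0 < frac < 0.5:
            warnings.warn(
                f"foreground fraction {frac:.3f} outside (0, 0.5); "
                "check threshold/polarity", stacklevel=2)


def binarize(frame: np.ndarray, threshold: int,
             polarity: str = "dark_objects") -> BinaryMask:
    """Threshold an 8-bit frame so biological objects become foreground.

    ``dark_objects`` marks pixels strictly below the threshold (dark bodies
    on a bright background); ``bright_objects`` marks pixels strictly
    above.  Deterministic.  Thresholds outside [0, 255] are rejected;
    outside the advisory [100, 118] band a warning is emitted.
    """
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError(f"expected an 8-bit frame, got dtype {frame.dtype}")
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold {threshold} outside [0, 255]")
    lo, hi = THRESHOLD_BAND
    if not lo <= threshold <= hi:
        warnings.warn(f"threshold {threshold} outside the advisory band "
                      f"[{lo}, {hi}]", stacklevel=2)
    if polarity == "dark_objects":
        mask = frame < threshold
    elif polarity == "bright_objects":
        mask = frame > threshold
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return BinaryMask(mask=mask, threshold_used=threshold,
                      polarity=polarity)


def detect_spots(mask: BinaryMask | np.ndarray,
                 pixel_size: float,
                 connectivity: int = 2,
                 quality_threshold: float = 1.0,
                 frame: int = 1,
                 spot_id_start: int = 0) -> pd.DataFrame:
    """Detect spots as connected foreground components of one mask.

    One spot per component (default 8-connectivity, so diagonally touching
    pixels merge).  Centroids are unweighted means of member-pixel centers,
    reported in µm with the pixel-center convention ``x = (col + 0.5)·px``.
    Perimeters use the multi-directional Crofton estimator.  Components
    with quality (pixel count) below ``quality_threshold`` are discarded;
    border-touching components are retained but flagged.  An empty mask
    yields an empty table.
    """
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask,
                                                                    bool)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
    labels = measure.label(arr, connectivity=connectivity)
    if labels.max() == 0:
        return pd.DataFrame(columns=SPOT_COLUMNS)
    props = measure.regionprops(labels)
    ny, nx = arr.shape
    rows = []
    sid = spot_id_start
    for p in props:
        if p.area < quality_threshold:
            continue
        perim = float(p.perimeter_crofton) * pixel_size
        area = float(p.area) * pixel_size ** 2
        circ = 4 * np.pi * area / perim ** 2 if perim > 0 else 1.0
        circ = min(circ, 1.0)
        cy, cx = p.centroid
        minr, minc, maxr, maxc = p.bbox
        on_border = minr == 0 or minc == 0 or maxr == ny or maxc == nx
        rows.append([frame, sid, (cx + 0.5) * pixel_size,
                     (cy + 0.5) * pixel_size, area, perim, circ,
                     float(np.sqrt(area / np.pi)), int(p.area),
                     float(p.area), bool(on_border)])
        sid += 1
    return pd.DataFrame(rows, columns=SPOT_COLUMNS)


def segment_stack(stack: np.ndarray,
                  threshold: int,
                  pixel_size: float,
                  polarity: str = "dark_objects",
                  connectivity: int = 2,
                  quality_threshold: float = 1.0) -> pd.DataFrame:
    """Binarize and detect spots on every frame of an 8-bit stack.

    Frames are numbered 1-based in the output; spot ids are unique across
    the whole stack.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    tables = []
    sid = 0
    for k in range(stack.shape[0]):
        mask = binarize(stack[k], threshold, polarity)
        spots = detect_spots(mask, pixel_size, connectivity=connectivity,
                             quality_threshold=quality_threshold,
                             frame=k + 1, spot_id_start=sid)
        sid += len(spots)
        tables.append(spots)
    out = (pd.concat(tables, ignore_index=True) if tables
           else pd.DataFrame(columns=SPOT_COLUMNS))
    logger.info("segmented %d frames: %d spots", stack.shape[0], len(out))
    return out
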