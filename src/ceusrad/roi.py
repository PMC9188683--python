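"""Analysis-ROI construction, motion-robust frame filtering and fiducial
frame selection.

No motion compensation is attempted.  Instead, frames corrupted by large
(typically out-of-plane) motion are discarded by thresholding the Pearson
correlation between each B-mode frame and the radiologist's reference
frame, computed on the ROI crop; and the three frames used for texture
analysis (wash-in, peak, wash-out) are picked among the valid frames at
fiducial time points of the lesion-mean TIC:

1. a straight line is fitted to the rising limb of the mean TIC where it
   lies between 5% and 50% of the peak value, and another to the second
   half of the interval from contrast appearance to the end of recording;
2. the intersection of the two lines gives an initial guess of the peak
   time, refined by an argmax search in a window of 20 samples before to
   50 samples after the guess;
3. the wash-in (wash-out) frame is the valid frame with the highest
   B-mode correlation to the reference, searched from five samples after
   the appearance time to five samples before the peak (from ten samples
   after the peak to the end).
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .io import Cine, LesionAnnotation
from .perfusion import smooth_tic

logger = logging.getLogger(__name__)


class ROIError(ValueError):
    """ROI cannot be constructed."""


class FrameSelectionError(RuntimeError):
    """A fiducial-frame search window is empty; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclasses.dataclass
class AnalysisROI:
    """Square analysis box on the contrast pane.

    Centered on the center of mass of the union of the manual masks and
    sized to include part of the structures surrounding the lesion.
    """

    box: tuple[int, int, int, int]     # half-open (r0, r1, c0, c1)
    lesion_mask_ref: np.ndarray        # full-frame bool mask at ref_frame
    side_px: int

    def crop(self, frames: np.ndarray) -> np.ndarray:
        r0, r1, c0, c1 = self.box
        return frames[..., r0:r1, c0:c1]

    @property
    def lesion_mask_roi(self) -> np.ndarray:
        """Lesion mask cropped to the ROI box."""
        r0, r1, c0, c1 = self.box
        return self.lesion_mask_ref[r0:r1, c0:c1]


@dataclasses.dataclass
class FiducialFrames:
    """Valid frames and the three selected fiducial frames."""

    valid: np.ndarray                  # sorted frame indices
    wash_in: int
    peak: int
    wash_out: int
    appearance_idx: int
    tic_mean: np.ndarray               # raw lesion-mean TIC
    tic_smooth: np.ndarray             # 5-s moving-average version

    def __post_init__(self) -> None:
        if not (self.wash_in < self.peak < self.wash_out):
            raise FrameSelectionError(
                "ordering", f"wash_in={self.wash_in} peak={self.peak} "
                f"wash_out={self.wash_out} violate wash_in < peak < wash_out"
            )
        for name in ("wash_in", "peak", "wash_out"):
            if getattr(self, name) not in self.valid:
                raise FrameSelectionError(name, "selected frame is not valid")


def square_roi(
    annotation: LesionAnnotation,
    frame_shape: tuple[int, int],
    margin_factor: float = 2.0,
    min_side: int = 200,
    max_side: int = 278,
) -> AnalysisROI:
    """Build the square analysis ROI around the manual delineations.

    side = clip(ceil(margin_factor * max lesion bounding-box side),
    min_side, max_side), centered on the center of mass of the union of
    the masks.  A box exceeding the frame is shifted (and, if the side
    exceeds the frame, clipped) with a logged warning.
    """
    H, W = frame_shape
    union = annotation.mask_union
    rows, cols = np.nonzero(union)
    if rows.size == 0:
        raise ROIError("empty mask union")
    bbox_side = max(rows.max() - rows.min() + 1, cols.max() - cols.min() + 1)
    if bbox_side > min(H, W):
        raise ROIError("lesion bounding box larger than the frame")
    side = int(np.clip(math.ceil(margin_factor * bbox_side), min_side, max_side))
    clipped = False
    if side > min(H, W):
        side = min(H, W)
        clipped = True
    cy = int(round(rows.mean()))
    cx = int(round(cols.mean()))
    r0 = cy - side // 2
    c0 = cx - side // 2
    if r0 < 0 or c0 < 0 or r0 + side > H or c0 + side > W:
        clipped = True
    r0 = int(np.clip(r0, 0, H - side))
    c0 = int(np.clip(c0, 0, W - side))
    if clipped:
        logger.warning(
            "ROI clipped/shifted to fit the %dx%d frame (side=%d, center=(%d,%d))",
            H, W, side, cy, cx,
        )
    mask_ref = annotation.masks[annotation.ref_frame]
    return AnalysisROI(box=(r0, r0 + side, c0, c0 + side),
                       lesion_mask_ref=mask_ref, side_px=side)


def _roi_correlations(
    bmode: np.ndarray, ref_frame: int, roi: AnalysisROI
) -> np.ndarray:
    """Pearson correlation of every B-mode ROI crop with the reference crop."""
    crop = roi.crop(bmode).reshape(bmode.shape[0], -1)
    ref = crop[ref_frame]
    ref_c = ref - ref.mean()
    ref_norm = np.linalg.norm(ref_c)
    if ref_norm == 0:
        raise ValueError("reference B-mode crop has zero variance")
    dev = crop - crop.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(dev, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dev @ ref_c) / (norms * ref_norm)
    r[norms == 0] = 0.0
    return r


def valid_frames(
    bmode: np.ndarray,
    ref_frame: int,
    roi: AnalysisROI,
    threshold: float = 0.8,
) -> np.ndarray:
    """Frames whose B-mode ROI correlation with the reference exceeds the
    threshold (the reference frame is always included)."""
    T = bmode.shape[0]
    if not 0 <= ref_frame < T:
        raise ValueError(f"ref_frame {ref_frame} outside [0, {T})")
    r = _roi_correlations(bmode, ref_frame, roi)
    keep = r > threshold
    keep[ref_frame] = True
    return np.flatnonzero(keep)


def mean_tic(ceus: np.ndarray, lesion_mask: np.ndarray) -> np.ndarray:
    """Lesion-mean TIC: average of the linearized contrast signal over the
    (fixed) reference-frame lesion mask, at every frame."""
    mask = np.asarray(lesion_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    return np.asarray(ceus, dtype=np.float64)[:, mask].mean(axis=1)


def _fit_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept)


def fiducial_frames(
    tic_mean_: np.ndarray,
    times: np.ndarray,
    valid: np.ndarray,
    bmode: np.ndarray,
    ref_frame: int,
    roi: AnalysisROI,
    appearance_fraction: float = 0.10,
    washin_band: tuple[float, float] = (0.05, 0.50),
    peak_window: tuple[int, int] = (-20, 50),
    washin_offsets: tuple[int, int] = (5, -5),
    washout_offset: int = 10,
    smooth_window_s: float = 5.0,
) -> FiducialFrames:
    """Select the wash-in, peak and wash-out fiducial frames.

    All sample-window rules operate on frame indices and are clipped to
    the recording; thresholds are relative to the peak of the smoothed
    lesion-mean TIC restricted to valid frames, so the selection is
    invariant to affine rescaling of the TIC.
    """
    tic_mean_ = np.asarray(tic_mean_, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    valid = np.asarray(sorted(set(int(v) for v in valid)))
    T = tic_mean_.size
    # invalid frames carry motion-corrupted contrast values; bridge them by
    # linear interpolation so the moving average sees only valid samples
    tic_work = np.interp(times, times[valid], tic_mean_[valid])
    s = smooth_tic(tic_work, times, smooth_window_s)
    sv = s[valid]
    if np.ptp(sv) == 0:
        raise FrameSelectionError("appearance", "lesion-mean TIC is constant")
    peak_val = sv.max()

    # (a) appearance: first valid crossing of 10% of the max
    above = sv >= appearance_fraction * peak_val
    if not above.any():
        raise FrameSelectionError("appearance", "no 10%-of-peak crossing")
    appearance_idx = int(valid[np.argmax(above)])

    # provisional peak for the wash-in band
    prov_peak = int(valid[np.argmax(sv)])

    # (b) wash-in line: valid rising-limb samples with TIC in [5%, 50%] of peak
    lo, hi = washin_band
    rising = valid[(valid >= appearance_idx) & (valid <= prov_peak)]
    band = rising[(s[rising] >= lo * peak_val) & (s[rising] <= hi * peak_val)]
    # wash-out line: valid samples in the second half of [appearance, end]
    t_mid = 0.5 * (times[appearance_idx] + times[-1])
    late = valid[times[valid] >= t_mid]

    guess_idx = prov_peak
    if band.size >= 2 and late.size >= 2:
        a1, b1 = _fit_line(times[band], s[band])
        a2, b2 = _fit_line(times[late], s[late])
        if abs(a1 - a2) > 1e-12:
            t_star = (b2 - b1) / (a1 - a2)
            if times[0] <= t_star <= times[-1]:
                guess_idx = int(np.argmin(np.abs(times - t_star)))
            else:
                logger.info("line intersection outside recording; "
                            "falling back to TIC argmax as peak guess")
        else:
            logger.info("parallel fit lines; falling back to TIC argmax")
    else:
        logger.info("too few samples for line fits; using TIC argmax as guess")

    # (d) peak: argmax of smoothed TIC over valid frames near the guess
    w0 = max(0, guess_idx + peak_window[0])
    w1 = min(T - 1, guess_idx + peak_window[1])
    cand = valid[(valid >= w0) & (valid <= w1)]
    if cand.size == 0:
        raise FrameSelectionError("peak", "no valid frames in the peak window")
    peak = int(cand[np.argmax(s[cand])])   # argmax ties -> earliest frame

    corr = _roi_correlations(bmode, ref_frame, roi)

    # (e) wash-in frame: max B-mode correlation in [appearance+5, peak-5]
    wi_lo = appearance_idx + washin_offsets[0]
    wi_hi = peak + washin_offsets[1]
    cand = valid[(valid >= wi_lo) & (valid <= wi_hi)]
    if cand.size == 0:
        raise FrameSelectionError(
            "wash-in", f"no valid frames in [{wi_lo}, {wi_hi}]"
        )
    wash_in = int(cand[np.argmax(corr[cand])])

    # (f) wash-out frame: max B-mode correlation in [peak+10, T)
    cand = valid[valid >= peak + washout_offset]
    if cand.size == 0:
        raise FrameSelectionError(
            "wash-out", f"no valid frames in [{peak + washout_offset}, {T})"
        )
    wash_out = int(cand[np.argmax(corr[cand])])

    return FiducialFrames(
        valid=valid, wash_in=wash_in, peak=peak, wash_out=wash_out,
        appearance_idx=appearance_idx, tic_mean=tic_mean_, tic_smooth=s,
    )


def analyze_frames(
    cine: Cine,
    annotation: LesionAnnotation,
    roi: AnalysisROI,
    correlation_threshold: float = 0.8,
    **fiducial_kwargs,
) -> FiducialFrames:
    """Convenience wrapper: valid frames + mean TIC + fiducial selection.

    Expects a linearized cine.
    """
    if not cine.linearized:
        raise ValueError("cine must be linearized first")
    valid = valid_frames(cine.bmode, annotation.ref_frame, roi,
                         correlation_threshold)
    tic = mean_tic(cine.ceus, roi.lesion_mask_ref)
    return fiducial_frames(
        tic, cine.times, valid, cine.bmode, annotation.ref_frame, roi,
        **fiducial_kwargs,
    )
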