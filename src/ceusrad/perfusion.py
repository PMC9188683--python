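"""Pixel-wise semiquantitative TIC perfusion parameters.

Model fitting of indicator-dilution curves is intentionally avoided: in
the liver the arterial phase overlaps the portal phase and motion makes
fits unreliable.  Instead, after a 5-s moving-average filter, five
semiquantitative parameters are read directly off each pixel's
time-intensity curve (TIC, in linear relative echo power):

==================  =====================================================
Peak intensity      Maximum of the TIC
Peak time           Time at which the peak intensity is reached
Appearance time     Time at which 10% of the peak intensity is reached
Wash-in time        Time between appearance time and peak time
Wash-in rate        Peak intensity divided by the wash-in time
==================  =====================================================

The wash-in rate denominator is configurable (``peak - appearance`` by
default, or time-to-peak from recording start), as the two conventions
coexist in the CEUS literature.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import convolve1d

PERFUSION_MAP_NAMES = (
    "PeakIntensity",
    "PeakTime",
    "AppearanceTime",
    "WashInTime",
    "WashInRate",
)


def smooth_tic(
    tic: np.ndarray, times: np.ndarray, window_s: float = 5.0
) -> np.ndarray:
    """Centered moving average over ``round(window_s * frame_rate)`` samples.

    The window length is forced odd; at the edges the window shrinks so
    constant inputs are preserved exactly.  Works on a 1-D TIC or on a
    T x ... stack (time on axis 0).
    """
    tic = np.asarray(tic, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    dt = float(np.median(np.diff(times)))
    if window_s < dt:
        raise ValueError("smoothing window shorter than the frame interval")
    n = int(round(window_s / dt))
    if n % 2 == 0:
        n += 1
    if n <= 1:
        return tic.copy()
    kernel = np.ones(n)
    summed = convolve1d(tic, kernel, axis=0, mode="constant", cval=0.0)
    counts = convolve1d(np.ones(tic.shape[0]), kernel, mode="constant", cval=0.0)
    shape = (-1,) + (1,) * (tic.ndim - 1)
    return summed / counts.reshape(shape)


@dataclasses.dataclass
class TICParams:
    """Semiquantitative parameters of one TIC; NaN marks a missing value."""

    peak_intensity: float
    peak_time: float
    appearance_time: float
    wash_in_time: float
    wash_in_rate: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.peak_intensity, self.peak_time, self.appearance_time,
            self.wash_in_time, self.wash_in_rate,
        ])


def tic_parameters(
    tic: np.ndarray,
    times: np.ndarray,
    appearance_fraction: float = 0.10,
    rate_denominator: str = "wash_in_time",
) -> TICParams:
    """Extract the five TIC parameters from a (smoothed) pixel TIC.

    An all-zero TIC yields all-NaN parameters (the pixel is excluded from
    summary statistics downstream).  A zero wash-in time flags the
    wash-in rate as missing rather than dividing by zero.
    """
    tic = np.asarray(tic, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    if rate_denominator not in ("wash_in_time", "time_to_peak"):
        raise ValueError(f"unknown rate_denominator {rate_denominator!r}")
    pi = float(tic.max(initial=-np.inf))
    if not np.isfinite(pi) or pi <= 0:
        nan = float("nan")
        return TICParams(nan, nan, nan, nan, nan)
    peak_idx = int(np.argmax(tic))
    app_idx = int(np.argmax(tic >= appearance_fraction * pi))
    pt = float(times[peak_idx])
    at = float(times[app_idx])
    wit = pt - at
    if rate_denominator == "wash_in_time":
        denom = wit
    else:
        denom = pt - times[0]
    wir = pi / denom if denom > 0 else float("nan")
    return TICParams(pi, pt, at, wit, wir)


def perfusion_map_stack(
    ceus: np.ndarray,
    times: np.ndarray,
    roi,
    smooth_window_s: float = 5.0,
    appearance_fraction: float = 0.10,
    rate_denominator: str = "wash_in_time",
) -> dict[str, np.ndarray]:
    """Compute the five TIC parametric maps over an analysis ROI.

    Parameters
    ----------
    ceus : ndarray, shape (T, H, W)
        Linearized contrast stack.
    roi : AnalysisROI or 4-tuple
        Half-open pixel box ``(r0, r1, c0, c1)`` on the contrast pane.

    Returns
    -------
    dict mapping map name -> 2-D float array over the ROI, with NaN where
    a pixel's parameters are undefined.
    """
    box = getattr(roi, "box", roi)
    r0, r1, c0, c1 = box
    crop = np.asarray(ceus, dtype=np.float64)[:, r0:r1, c0:c1]
    T = crop.shape[0]
    s = smooth_tic(crop, times, smooth_window_s)
    flat = s.reshape(T, -1)

    pi = flat.max(axis=0)
    peak_idx = flat.argmax(axis=0)
    app_idx = (flat >= appearance_fraction * pi[None, :]).argmax(axis=0)
    pt = np.asarray(times)[peak_idx].astype(float)
    at = np.asarray(times)[app_idx].astype(float)
    wit = pt - at
    denom = wit if rate_denominator == "wash_in_time" else pt - times[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        wir = np.where(denom > 0, pi / denom, np.nan)

    dead = pi <= 0
    for arr in (pi, pt, at, wit, wir):
        arr[dead] = np.nan

    shape = (r1 - r0, c1 - c0)
    values = (pi, pt, at, wit, wir)
    return {name: v.reshape(shape) for name, v in zip(PERFUSION_MAP_NAMES, values)}
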