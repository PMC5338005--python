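"""Thickness rate from the overlap-region brightness oscillation.

Where the images of the top and bottom basal faces overlap, the two
reflections interfere and the region's mean brightness runs through one full
cycle for every λ/(2 n_ice) of thickness increase. Counting brightness
extrema therefore gives the thickness growth rate dd/dt, and subtracting the
independently measured top-face rate yields the bottom-face rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import AlignmentError, AnalysisError, GeometryError, ParameterError
from .fringes import GrowthTrace
from .synthgram import FrameStack, OpticalConfig

__all__ = [
    "BrightnessTrace",
    "brightness_trace",
    "thickness_rate",
    "bottom_face_rate",
]


@dataclass
class BrightnessTrace:
    """Detrended mean intensity of the overlap region versus time."""

    times_s: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.times_s.shape != self.b.shape:
            raise ParameterError("times and brightness must match in length")
        if not np.all(np.isfinite(self.b)):
            raise ParameterError("brightness trace contains non-finite values")


def brightness_trace(
    stack: FrameStack,
    roi: tuple[int, int, int, int],
    detrend_window_s: float | None = 2.0,
) -> BrightnessTrace:
    """Mean intensity over ``roi`` (y0, y1, x0, x1; half-open) per frame.

    A slowly varying baseline — a first-order Savitzky–Golay trend over
    ``detrend_window_s`` — is subtracted so only the interference oscillation
    remains. ``detrend_window_s=None`` applies a single global linear detrend.
    """
    y0, y1, x0, x1 = roi
    h, w = stack.shape
    if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
        raise GeometryError(f"roi {roi} not inside frames of shape {(h, w)}")
    b = np.asarray(stack.frames, dtype=float)[:, y0:y1, x0:x1].mean(axis=(1, 2))
    times = stack.timestamps
    if detrend_window_s is None:
        coeffs = np.polyfit(times, b, 1)
        baseline = np.polyval(coeffs, times)
    else:
        win = int(round(detrend_window_s * stack.fps))
        win = max(5, win + (win % 2 == 0))
        if win >= len(b):
            coeffs = np.polyfit(times, b, 1)
            baseline = np.polyval(coeffs, times)
        else:
            baseline = savgol_filter(b, win, 1)
    return BrightnessTrace(times_s=times, b=b - baseline)


def _refine_extrema(times: np.ndarray, sig: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample extremum times by parabolic interpolation of 3 points."""
    dt = times[1] - times[0]
    out = []
    for i in idx:
        if 1 <= i < len(sig) - 1:
            denom = sig[i - 1] - 2.0 * sig[i] + sig[i + 1]
            shift = 0.5 * (sig[i - 1] - sig[i + 1]) / denom if denom != 0 else 0.0
            shift = float(np.clip(shift, -0.5, 0.5))
        else:
            shift = 0.0
        out.append(times[i] + shift * dt)
    return np.asarray(out)


def thickness_rate(
    b: BrightnessTrace,
    optics: OpticalConfig,
    prominence: float | None = None,
) -> GrowthTrace:
    """Thickness growth rate dd/dt from brightness extremum spacing.

    Successive extrema (peaks and troughs) of the brightness are half a
    period apart, so the instantaneous brightness frequency is
    f_B = 1/(2·spacing) and dd/dt = f_B · λ/(2 n_ice). Extremum times are
    refined by parabolic interpolation and the piecewise rates are
    interpolated back onto the frame clock within the observed support.

    Raises :class:`AnalysisError` if fewer than three extrema are present.
    """
    sig = b.b
    if prominence is None:
        lo, hi = np.percentile(sig, [2.5, 97.5])
        prominence = 0.25 * (hi - lo) / 2.0
    peaks, _ = find_peaks(sig, prominence=prominence)
    troughs, _ = find_peaks(-sig, prominence=prominence)
    idx = np.sort(np.concatenate([peaks, troughs]))
    if len(idx) < 3:
        raise AnalysisError(
            f"insufficient oscillation: only {len(idx)} brightness extrema found"
        )
    t_ext = _refine_extrema(b.times_s, sig, idx)
    spacing = np.diff(t_ext)
    if np.any(spacing <= 0):
        raise AnalysisError("brightness extrema not strictly ordered in time")
    f_b = 1.0 / (2.0 * spacing)
    t_mid = 0.5 * (t_ext[:-1] + t_ext[1:])
    ddt = f_b * optics.thickness_per_cycle_um  # f_B · λ/(2 n_ice)

    sel = (b.times_s >= t_ext[0]) & (b.times_s <= t_ext[-1])
    times = b.times_s[sel]
    v = np.interp(times, t_mid, ddt)
    return GrowthTrace(times_s=times, v_um_s=v, face="thickness")


def bottom_face_rate(ddt: GrowthTrace, v_top: GrowthTrace) -> GrowthTrace:
    """Bottom-face growth rate V_bottom(t) = dd/dt − V_top on common times.

    Both traces are resampled onto the top-face clock restricted to the
    overlap of their supports. Negative differences are clipped to zero and
    flagged rather than silently dropped. Raises :class:`AlignmentError` on
    disjoint supports.
    """
    t_lo = max(ddt.times_s[0], v_top.times_s[0])
    t_hi = min(ddt.times_s[-1], v_top.times_s[-1])
    if t_hi <= t_lo:
        raise AlignmentError(
            f"disjoint time supports: thickness [{ddt.times_s[0]:.2f}, {ddt.times_s[-1]:.2f}] s "
            f"vs top face [{v_top.times_s[0]:.2f}, {v_top.times_s[-1]:.2f}] s"
        )
    sel = (v_top.times_s >= t_lo) & (v_top.times_s <= t_hi)
    times = v_top.times_s[sel]
    ddt_r = np.interp(times, ddt.times_s, ddt.v_um_s)
    vt = v_top.v_um_s[sel]
    raw = ddt_r - vt
    flags = raw < 0
    v_bottom = np.where(flags, 0.0, raw)
    carried = v_top.flags[sel] if v_top.flags is not None else False
    return GrowthTrace(
        times_s=times, v_um_s=v_bottom, face="bottom", flags=flags | carried
    )
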