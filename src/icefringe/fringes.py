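"""Fringe velocimetry: spacing, phase, migration velocity, growth rate.

The lateral migration of interference fringes encodes the normal displacement
of the reflecting face: one fringe of migration corresponds to λ/(2 n_w) of
displacement. With fringe spacing δ and migration velocity β the normal
growth rate is

    V = β λ / (2 δ n_w).

β is measured here by phase-gradient velocimetry on the kymograph: each row is
converted to its band-limited analytic signal, the phase is unwrapped in
position and time, and β(t) = −(∂φ/∂t)/(∂φ/∂s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _detrend
from scipy.signal import savgol_filter

from .errors import AnalysisError, ParameterError
from .kymo import Kymograph
from .synthgram import OpticalConfig

__all__ = [
    "FringeEstimate",
    "PhaseMap",
    "FringeVelocityTrace",
    "GrowthTrace",
    "estimate_fringe_spacing",
    "extract_phase",
    "fringe_velocity",
    "growth_rate_from_fringes",
]


@dataclass(frozen=True)
class FringeEstimate:
    """Dominant fringe spacing of a kymograph.

    ``quality`` is the ratio of the spectral peak power to the median
    off-peak power of the time-averaged spatial spectrum.
    """

    delta_um: float
    frequency_um: float  # dominant spatial frequency, 1/μm
    quality: float

    def __post_init__(self) -> None:
        if self.delta_um <= 0:
            raise ParameterError("delta_um must be > 0")


@dataclass
class PhaseMap:
    """Unwrapped fringe phase φ(t, s) in radians, plus sampling steps."""

    phi: np.ndarray
    dt_s: float
    ds_um: float
    flagged_rows: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phi.shape[0]) * self.dt_s


@dataclass
class FringeVelocityTrace:
    """Lateral fringe migration velocity β(t), μm/s.

    Positive β means fringes migrate toward increasing line coordinate s.
    ``flags`` marks times where the spatial phase gradient was too small for
    the velocity to be defined.
    """

    times_s: np.ndarray
    beta_um_s: np.ndarray
    flags: np.ndarray


@dataclass
class GrowthTrace:
    """Normal growth rate V(t) of one face, μm/s."""

    times_s: np.ndarray
    v_um_s: np.ndarray
    face: str = "top"
    flags: np.ndarray | None = None
    sign_flipped: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.v_um_s = np.asarray(self.v_um_s, dtype=float)
        if self.times_s.shape != self.v_um_s.shape:
            raise ParameterError("times and rates must have matching shapes")
        if self.flags is None:
            self.flags = np.zeros(self.times_s.shape, dtype=bool)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"time_s": self.times_s, "v_um_s": self.v_um_s, "flag": self.flags.astype(int)}
        )


def estimate_fringe_spacing(
    kymo: Kymograph, quality_threshold: float = 5.0
) -> FringeEstimate:
    """Estimate the fringe interval δ from the time-averaged spatial spectrum.

    Rows are linearly detrended, Hann-windowed and Fourier transformed; the
    power spectra are averaged over time and the dominant positive-frequency
    peak is refined by parabolic interpolation. Raises
    :class:`AnalysisError` ("no fringes detected") when no peak clears
    ``quality_threshold`` or fewer than two fringe periods fit on the line.
    """
    rows = _detrend(kymo.intensity, axis=1, type="linear")
    n = rows.shape[1]
    window = np.hanning(n)
    power = np.abs(np.fft.rfft(rows * window, axis=1)) ** 2
    mean_power = power.mean(axis=0)
    freqs = np.fft.rfftfreq(n, d=kymo.ds_um)
    if len(mean_power) < 4:
        raise AnalysisError("no fringes detected: line too short")

    k = 1 + int(np.argmax(mean_power[1:]))
    peak = mean_power[k]
    # absolute floor: a flat field leaves only rounding residue after detrend
    scale = max(1e-30, float(np.abs(kymo.intensity).max()))
    if peak < (1e-8 * scale) ** 2 * n:
        raise AnalysisError("no fringes detected: flat intensity field")
    off = np.delete(mean_power[1:], slice(max(0, k - 3), k + 2))
    background = float(np.median(off)) if off.size else 0.0
    if peak <= 0 or (background > 0 and peak / background < quality_threshold):
        raise AnalysisError("no fringes detected: spatial spectrum has no clear peak")
    if background == 0 and peak < 1e-20:
        raise AnalysisError("no fringes detected: flat intensity field")
    quality = float(peak / background) if background > 0 else float("inf")

    # parabolic refinement of the peak bin
    if 1 <= k < len(mean_power) - 1:
        pm, p0, pp = mean_power[k - 1], mean_power[k], mean_power[k + 1]
        denom = pm - 2.0 * p0 + pp
        shift = 0.5 * (pm - pp) / denom if denom != 0 else 0.0
    else:
        shift = 0.0
    df = freqs[1] - freqs[0]
    f_star = (k + shift) * df
    delta = 1.0 / f_star
    line_length = (n - 1) * kymo.ds_um
    if delta > line_length / 2.0:
        raise AnalysisError("no fringes detected: fewer than two periods on the line")
    if delta < 2.0 * kymo.ds_um:
        raise AnalysisError("fringes unresolvable: spacing below two samples")
    return FringeEstimate(delta_um=float(delta), frequency_um=float(f_star), quality=quality)


def extract_phase(
    kymo: Kymograph, est: FringeEstimate, band_halfwidth: float = 0.25
) -> PhaseMap:
    """Band-limited analytic-signal phase of the fringe field, unwrapped.

    Each row is filtered to the positive-frequency band
    f* · (1 ± band_halfwidth) around the dominant spatial frequency, giving a
    complex analytic signal whose angle is unwrapped along position; rows are
    then tied together by unwrapping the center column along time. Rows whose
    phase still jumps by more than π between consecutive times are reported
    in ``flagged_rows``.
    """
    rows = _detrend(kymo.intensity, axis=1, type="linear")
    n = rows.shape[1]
    freqs = np.fft.fftfreq(n, d=kymo.ds_um)
    f0 = est.frequency_um
    mask = (freqs > f0 * (1.0 - band_halfwidth)) & (freqs < f0 * (1.0 + band_halfwidth))
    if not mask.any():
        raise AnalysisError("analytic band empty; fringe frequency unresolved")
    z = np.fft.ifft(np.fft.fft(rows, axis=1) * (2.0 * mask), axis=1)
    phi = np.unwrap(np.angle(z), axis=1)

    ref = n // 2
    target = np.unwrap(phi[:, ref])
    phi = phi + (target - phi[:, ref])[:, None]

    jumps = np.abs(np.diff(phi[:, ref]))
    flagged = np.nonzero(jumps > np.pi)[0] + 1
    return PhaseMap(phi=phi, dt_s=kymo.dt_s, ds_um=kymo.ds_um, flagged_rows=flagged)


def _odd_window(n_samples: int, limit: int, minimum: int = 5) -> int:
    w = max(minimum, int(round(n_samples)))
    if w % 2 == 0:
        w += 1
    if w > limit:
        w = limit if limit % 2 == 1 else limit - 1
    return max(w, 3)


def _lsq_deriv_weights(offsets: np.ndarray, at: float) -> tuple[np.ndarray, np.ndarray]:
    """Weights for a quadratic LSQ fit over sample ``offsets``.

    Returns (w_deriv, residual_projector): ``w_deriv @ y`` is the fitted
    derivative (per sample) evaluated at offset ``at``; the projector maps
    ``y`` to its fit residual.
    """
    a = np.column_stack([np.ones_like(offsets), offsets, offsets**2]).astype(float)
    pinv = np.linalg.pinv(a)
    w_deriv = np.array([0.0, 1.0, 2.0 * at]) @ pinv
    resid = np.eye(len(offsets)) - a @ pinv
    return w_deriv, resid


def _eno_derivative(y, dt: float, win: int = 15) -> np.ndarray:
    """Kink-preserving first derivative (windowed ENO).

    At each sample three quadratic least-squares fits are made — over a
    backward window ending at the sample, a centered window, and a forward
    window starting at it — and each fit's derivative is evaluated *at* the
    sample. The centered fit is used unless its residual is markedly larger
    than the best one-sided fit's, in which case the smoother side wins (an
    essentially-non-oscillatory stencil choice). For piecewise-smooth phase
    with corners — the signature of sawtooth growth oscillations — this keeps
    the one-sided slopes at the corners exact instead of averaging across
    them, at near-Savitzky–Golay noise levels elsewhere.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if win % 2 == 0:
        win += 1
    win = max(5, min(win, n if n % 2 == 1 else n - 1))
    grad = np.gradient(y, dt)
    if n < 2 * win:
        return grad

    off_b = np.arange(-(win - 1), 1, dtype=float)
    off_c = np.arange(-(win // 2), win // 2 + 1, dtype=float)
    off_f = np.arange(0, win, dtype=float)
    wb, rb = _lsq_deriv_weights(off_b, 0.0)
    wc, rc = _lsq_deriv_weights(off_c, 0.0)
    wf, rf = _lsq_deriv_weights(off_f, 0.0)

    from numpy.lib.stride_tricks import sliding_window_view

    windows = sliding_window_view(y, win)  # windows[k] = y[k : k + win]
    i = np.arange(win - 1, n - win + 1)
    seg_b = windows[i - win + 1]
    seg_c = windows[i - win // 2]
    seg_f = windows[i]
    d_b = seg_b @ wb
    d_c = seg_c @ wc
    d_f = seg_f @ wf
    rss_b = np.einsum("ij,ij->i", seg_b @ rb.T, seg_b @ rb.T)
    rss_c = np.einsum("ij,ij->i", seg_c @ rc.T, seg_c @ rc.T)
    rss_f = np.einsum("ij,ij->i", seg_f @ rf.T, seg_f @ rf.T)

    side = np.where(rss_b <= rss_f, d_b, d_f)
    rss_side = np.minimum(rss_b, rss_f)
    use_side = rss_c > 2.0 * rss_side + 1e-300
    d = grad.copy()
    d[i] = np.where(use_side, side, d_c) / dt
    return d


def fringe_velocity(
    phase: PhaseMap,
    position: int | None = None,
    smooth_window_s: float = 0.5,
    polyorder: int = 2,
    min_slope_rad_um: float = 1e-3,
    deriv: str = "eno",
) -> FringeVelocityTrace:
    """Fringe migration velocity β(t) = −(∂φ/∂t)/(∂φ/∂s) at one line position.

    The spatial phase slope ∂φ/∂s is a least-squares fit over a column
    neighborhood of ``position``, smoothed over ``smooth_window_s``. The
    temporal phase at the position is averaged over the same columns (the
    spatial ramp cancels because the columns are centered) to suppress pixel
    noise, then differentiated either by a kink-preserving ENO scheme
    (``deriv="eno"``, default — keeps the sharp rate drops and cusps of
    sawtooth oscillations intact) or by Savitzky–Golay local-polynomial
    smoothing with centered differences (``deriv="savgol"``). Edge samples
    are trimmed; times with |∂φ/∂s| < ``min_slope_rad_um`` are flagged and
    set to NaN.
    """
    phi = phase.phi
    n_t, n_s = phi.shape
    j = n_s // 2 if position is None else int(position)
    if not 1 <= j <= n_s - 2:
        raise ParameterError(f"position {j} not interior to the phase map (0..{n_s - 1})")
    if n_t < 5:
        raise ParameterError("phase map too short in time for velocimetry")
    if deriv not in ("eno", "savgol"):
        raise ParameterError(f"deriv must be 'eno' or 'savgol', got {deriv!r}")

    win = _odd_window(smooth_window_s / phase.dt_s, limit=n_t)

    # straight fringes: the temporal phase is common along the line, so a wide
    # symmetric column window around the position gives the best noise
    # averaging without biasing the local estimate; columns within about one
    # fringe of the line ends are excluded (band-pass edge ringing)
    k_est = float(np.median(np.abs(np.gradient(phi[0], phase.ds_um))))
    margin = int(np.ceil(2.0 * np.pi / max(k_est, 1e-6) / phase.ds_um)) if k_est > 0 else 0
    w = min(j - margin, n_s - 1 - margin - j)
    if w < 2:
        w = min(j, n_s - 1 - j)
    cols = np.arange(j - w, j + w + 1)
    s_c = (cols - j) * phase.ds_um
    seg = phi[:, cols]
    slope = (seg - seg.mean(axis=1, keepdims=True)) @ s_c / (s_c @ s_c)
    slope = savgol_filter(slope, win, polyorder)

    theta = seg.mean(axis=1)  # phase at the position; ramp cancels, noise averages down
    if deriv == "eno":
        dphi_dt = _eno_derivative(theta, phase.dt_s, win=win)
        trim = win - 1
    else:
        dphi_dt = savgol_filter(theta, win, polyorder, deriv=1, delta=phase.dt_s)
        trim = win // 2

    ok = np.abs(slope) >= min_slope_rad_um
    beta = np.full(n_t, np.nan)
    beta[ok] = -dphi_dt[ok] / slope[ok]

    sl = slice(trim, n_t - trim) if n_t - 2 * trim >= 2 else slice(None)
    times = np.arange(n_t) * phase.dt_s
    return FringeVelocityTrace(
        times_s=times[sl], beta_um_s=beta[sl], flags=~ok[sl]
    )


def growth_rate_from_fringes(
    beta: FringeVelocityTrace,
    delta_um: float,
    optics: OpticalConfig,
    sign: str = "auto",
) -> GrowthTrace:
    """Convert fringe migration velocity to normal growth rate: V = βλ/(2δn_w).

    ``sign`` is "+" (keep β's sign), "-" (negate), or "auto" (default): flip
    so the median V is non-negative, since the migration direction along a
    single line depends on the unobservable tilt orientation of the face. A
    flip is recorded on the returned trace as ``sign_flipped``.
    """
    if delta_um <= 0:
        raise ParameterError("delta_um must be > 0")
    if sign not in ("+", "-", "auto"):
        raise ParameterError(f"sign must be '+', '-' or 'auto', got {sign!r}")
    v = beta.beta_um_s * optics.lambda_um / (2.0 * delta_um * optics.n_water)
    flipped = False
    if sign == "-":
        v = -v
        flipped = True
    elif sign == "auto":
        med = np.nanmedian(v)
        if np.isfinite(med) and med < 0:
            v = -v
            flipped = True
    return GrowthTrace(
        times_s=beta.times_s,
        v_um_s=v,
        face="top",
        flags=beta.flags.copy(),
        sign_flipped=flipped,
    )
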