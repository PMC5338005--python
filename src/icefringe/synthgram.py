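"""Forward optical model: synthetic interferogram videos with known ground truth.

Emulates what a Michelson interference microscope sees looking down the c-axis
of a polyhedral ice crystal growing in supercooled solution:

* the slightly tilted top basal face produces straight, equally spaced fringes
  (spacing ``delta = lambda / (2 n_w tan(theta))``) that migrate laterally as
  the face advances — one fringe of migration per ``lambda / (2 n_w)`` of
  normal displacement;
* where the images of the top and bottom basal faces overlap, the reflections
  from the two faces interfere and the mean brightness of that region
  oscillates as the crystal thickness grows — one brightness cycle per
  ``lambda / (2 n_ice)`` of thickness increase.

The normal growth rate of each face follows a prescribed sawtooth-like
waveform (slow, optionally curved rise; fast linear fall), the shape reported
for basal-face growth oscillations in antifreeze-glycoprotein solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InfeasibleError, ParameterError, SamplingError

__all__ = [
    "OpticalConfig",
    "CrystalGeometry",
    "GrowthSchedule",
    "Waveform",
    "FrameStack",
    "RenderTruth",
    "BenchmarkCase",
    "make_waveform",
    "calibrate_rise_exponent",
    "cycle_mean",
    "render_video",
    "benchmark_case",
]


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not np.isfinite(v):
            raise ParameterError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class OpticalConfig:
    """Laser and interference parameters.

    Parameters
    ----------
    lambda_vac_nm
        Laser wavelength in vacuum/air, nm.
    n_water, n_ice
        Refractive indices of water and ice at the laser wavelength.
    fringe_contrast, overlap_contrast
        Amplitudes of the top-face/reference and top/bottom-face interference
        terms, as fractions of full scale.
    baseline
        Mean image intensity, in [0, 1].
    """

    lambda_vac_nm: float = 670.0
    n_water: float = 1.3328
    n_ice: float = 1.3100
    fringe_contrast: float = 0.30
    overlap_contrast: float = 0.20
    baseline: float = 0.50

    def __post_init__(self) -> None:
        _require_finite(
            lambda_vac_nm=self.lambda_vac_nm,
            n_water=self.n_water,
            n_ice=self.n_ice,
            fringe_contrast=self.fringe_contrast,
            overlap_contrast=self.overlap_contrast,
            baseline=self.baseline,
        )
        if self.lambda_vac_nm <= 0:
            raise ParameterError("lambda_vac_nm must be > 0")
        if self.n_water <= 1 or self.n_ice <= 1:
            raise ParameterError("refractive indices must exceed 1")
        for name in ("fringe_contrast", "overlap_contrast", "baseline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        total = self.fringe_contrast + self.overlap_contrast
        if self.baseline - total < -1e-12 or self.baseline + total > 1.0 + 1e-12:
            raise ParameterError(
                "baseline +/- (fringe_contrast + overlap_contrast) must stay in [0, 1]"
            )

    @property
    def lambda_um(self) -> float:
        return self.lambda_vac_nm * 1e-3

    @property
    def displacement_per_fringe_um(self) -> float:
        """Normal face displacement per lateral fringe of migration: λ/(2 n_w)."""
        return self.lambda_um / (2.0 * self.n_water)

    @property
    def thickness_per_cycle_um(self) -> float:
        """Thickness increment per brightness cycle of the overlap region: λ/(2 n_ice)."""
        return self.lambda_um / (2.0 * self.n_ice)


@dataclass(frozen=True)
class CrystalGeometry:
    """Field geometry: tilted top face, overlap region, pixel grid.

    The top face is tilted about the image y-axis, so fringes are vertical
    (constant-x) lines and migrate along x. Pixel coordinates are 0-based;
    ``overlap_roi`` is (y0, y1, x0, x1), half-open.
    """

    tilt_angle_rad: float
    h0_um: float = 0.0
    d0_um: float = 20.0
    overlap_roi: tuple[int, int, int, int] = (96, 160, 96, 160)
    field_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        _require_finite(
            tilt_angle_rad=self.tilt_angle_rad,
            h0_um=self.h0_um,
            d0_um=self.d0_um,
            pixel_size_um=self.pixel_size_um,
        )
        if not 0.0 < self.tilt_angle_rad < 0.1:
            raise ParameterError(
                f"tilt_angle_rad must lie in (0, 0.1) rad, got {self.tilt_angle_rad}"
            )
        if self.d0_um <= 0:
            raise ParameterError("d0_um must be > 0")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        h, w = self.field_size
        y0, y1, x0, x1 = self.overlap_roi
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise ParameterError(f"overlap_roi {self.overlap_roi} not inside field {self.field_size}")

    def fringe_spacing_um(self, optics: OpticalConfig) -> float:
        """Fringe interval δ = λ/(2 n_w tanθ) for this tilt."""
        return optics.lambda_um / (2.0 * optics.n_water * math.tan(self.tilt_angle_rad))

    @classmethod
    def from_fringe_spacing(
        cls, delta_um: float, optics: OpticalConfig | None = None, **kwargs
    ) -> "CrystalGeometry":
        """Build a geometry whose tilt produces the requested fringe spacing."""
        if delta_um <= 0:
            raise ParameterError("delta_um must be > 0")
        optics = optics or OpticalConfig()
        tilt = math.atan(optics.lambda_um / (2.0 * optics.n_water * delta_um))
        return cls(tilt_angle_rad=tilt, **kwargs)


@dataclass(frozen=True)
class GrowthSchedule:
    """Prescribed oscillatory normal-growth-rate waveform for one face.

    Over a cycle of length ``period_s`` the rate rises from ``v_min_um_s`` to
    ``v_max_um_s`` during the first ``rise_fraction`` of the cycle as a
    power-law ramp with exponent ``rise_exponent``, then falls back linearly.
    ``delta_T_bulk_K`` tags the bulk supercooling this waveform represents; it
    is metadata only.
    """

    face: str = "top"
    v_min_um_s: float = 0.0
    v_max_um_s: float = 0.5
    period_s: float = 11.0
    rise_fraction: float = 0.92
    rise_exponent: float = 1.0
    phase0_s: float = 0.0
    delta_T_bulk_K: float | None = None

    def __post_init__(self) -> None:
        _require_finite(
            v_min_um_s=self.v_min_um_s,
            v_max_um_s=self.v_max_um_s,
            period_s=self.period_s,
            rise_fraction=self.rise_fraction,
            rise_exponent=self.rise_exponent,
            phase0_s=self.phase0_s,
        )
        if self.face not in ("top", "bottom"):
            raise ParameterError(f"face must be 'top' or 'bottom', got {self.face!r}")
        if not 0.0 <= self.v_min_um_s <= self.v_max_um_s:
            raise ParameterError("require 0 <= v_min <= v_max")
        if self.period_s <= 0:
            raise ParameterError("period_s must be > 0")
        if not 0.0 < self.rise_fraction <= 1.0:
            raise ParameterError("rise_fraction must lie in (0, 1]")
        if self.rise_exponent <= 0:
            raise ParameterError("rise_exponent must be > 0")


class Waveform:
    """Callable periodic growth-rate waveform V(t) with an exact running integral."""

    def __init__(self, schedule: GrowthSchedule):
        self.schedule = schedule

    def __call__(self, t):
        s = self.schedule
        tau = np.mod(np.asarray(t, dtype=float) + s.phase0_s, s.period_s)
        return self._eval_cycle(tau)

    def _eval_cycle(self, tau: np.ndarray) -> np.ndarray:
        s = self.schedule
        amp = s.v_max_um_s - s.v_min_um_s
        t_rise = s.rise_fraction * s.period_s
        rising = tau <= t_rise
        out = np.empty_like(tau)
        with np.errstate(invalid="ignore"):
            out[rising] = s.v_min_um_s + amp * (tau[rising] / t_rise) ** s.rise_exponent
        t_fall = s.period_s - t_rise
        if t_fall > 0:
            u = tau[~rising] - t_rise
            out[~rising] = s.v_max_um_s - amp * u / t_fall
        return out

    def _cycle_integral(self, tau: np.ndarray) -> np.ndarray:
        """∫0^tau V within one cycle, tau in [0, period]."""
        s = self.schedule
        amp = s.v_max_um_s - s.v_min_um_s
        t_rise = s.rise_fraction * s.period_s
        p = s.rise_exponent
        rising = tau <= t_rise
        out = np.empty_like(tau)
        out[rising] = s.v_min_um_s * tau[rising] + amp * t_rise / (p + 1.0) * (
            tau[rising] / t_rise
        ) ** (p + 1.0)
        t_fall = s.period_s - t_rise
        if t_fall > 0:
            i_rise = s.v_min_um_s * t_rise + amp * t_rise / (p + 1.0)
            u = tau[~rising] - t_rise
            out[~rising] = i_rise + s.v_max_um_s * u - amp * u**2 / (2.0 * t_fall)
        return out

    @property
    def mean(self) -> float:
        """Cycle-averaged growth rate (closed form)."""
        s = self.schedule
        return cycle_mean(
            s.v_min_um_s, s.v_max_um_s, s.rise_fraction, s.rise_exponent
        )

    def displacement(self, t):
        """Exact ∫0^t V(t') dt' in μm (piecewise closed form)."""
        s = self.schedule
        t = np.asarray(t, dtype=float)
        cycle_growth = self.mean * s.period_s

        def total(x):
            n, tau = np.divmod(x, s.period_s)
            return n * cycle_growth + self._cycle_integral(tau)

        return total(t + s.phase0_s) - total(np.asarray(s.phase0_s, dtype=float))


def cycle_mean(v_min: float, v_max: float, rise_fraction: float, rise_exponent: float) -> float:
    """Closed-form cycle mean of the rise/fall waveform.

    mean = r·(v_min + (v_max−v_min)/(1+p)) + (1−r)·(v_min+v_max)/2
    """
    amp = v_max - v_min
    r, p = rise_fraction, rise_exponent
    return r * (v_min + amp / (1.0 + p)) + (1.0 - r) * (v_min + v_max) / 2.0


def make_waveform(schedule: GrowthSchedule) -> Waveform:
    """Return the periodic rate waveform V(t) for a growth schedule."""
    return Waveform(schedule)


def calibrate_rise_exponent(
    v_min: float,
    v_max: float,
    target_mean: float,
    rise_fraction: float = 1.0,
    rtol: float = 1e-9,
) -> float:
    """Find the rise exponent p whose waveform mean equals ``target_mean``.

    For ``rise_fraction == 1`` the closed form p = (v_max − mean)/(mean − v_min)
    is used; otherwise the monotone closed-form mean is inverted by bisection.
    Raises :class:`InfeasibleError` if no exponent can reach the target.
    """
    _require_finite(v_min=v_min, v_max=v_max, target_mean=target_mean, rise_fraction=rise_fraction)
    if not (v_min < target_mean < v_max):
        raise InfeasibleError(
            f"target_mean {target_mean} must lie strictly between v_min {v_min} and v_max {v_max}"
        )
    r = rise_fraction
    fall_mean = (1.0 - r) * (v_min + v_max) / 2.0
    # attainable open interval of the mean as p runs over (0, inf)
    hi = r * v_max + fall_mean  # p -> 0
    lo = r * v_min + fall_mean  # p -> inf
    if not (lo < target_mean < hi):
        raise InfeasibleError(
            f"target_mean {target_mean} not attainable for rise_fraction {r}: "
            f"attainable range is ({lo}, {hi})"
        )
    if r == 1.0:
        return (v_max - target_mean) / (target_mean - v_min)
    # mean(p) is strictly decreasing; invert on log-spaced bracket
    from scipy.optimize import brentq

    f = lambda p: cycle_mean(v_min, v_max, r, p) - target_mean
    p_lo, p_hi = 1e-8, 1e8
    return float(brentq(f, p_lo, p_hi, xtol=1e-15, rtol=rtol))


@dataclass
class FrameStack:
    """A time-ordered stack of grayscale frames with physical calibration.

    ``frames`` has shape (n_frames, height, width); intensities are floats on
    a nominal [0, 1] scale (noise may exceed the bounds slightly).
    """

    frames: np.ndarray
    fps: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ParameterError(f"frames must be 3-D (t, y, x), got shape {self.frames.shape}")
        if self.fps <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("fps and pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Frame times in seconds, origin at the first frame."""
        return np.arange(self.n_frames) / self.fps


@dataclass
class RenderTruth:
    """Ground truth returned alongside a rendered video."""

    times_s: np.ndarray
    v_top_um_s: np.ndarray
    v_bottom_um_s: np.ndarray
    thickness_um: np.ndarray
    top_displacement_um: np.ndarray
    bottom_displacement_um: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "v_top_um_s": self.v_top_um_s,
                "v_bottom_um_s": self.v_bottom_um_s,
                "thickness_um": self.thickness_um,
            }
        )


def _min_fps(top: GrowthSchedule, bottom: GrowthSchedule, optics: OpticalConfig) -> float:
    """Smallest fps keeping every per-frame interference phase step under π/2."""
    lam = optics.lambda_um
    rate_fringe = 4.0 * math.pi * optics.n_water * top.v_max_um_s / lam
    rate_overlap = (
        4.0 * math.pi * optics.n_ice * (top.v_max_um_s + bottom.v_max_um_s) / lam
    )
    return max(rate_fringe, rate_overlap) / (math.pi / 2.0)


def render_video(
    top: GrowthSchedule,
    bottom: GrowthSchedule,
    optics: OpticalConfig,
    geom: CrystalGeometry,
    duration_s: float,
    fps: float = 30.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    phi0: float = 0.0,
    psi0: float = 0.0,
) -> tuple[FrameStack, RenderTruth]:
    """Render a synthetic interferogram video and its exact ground truth.

    Pixel intensity is ``baseline + fringe_contrast·cos(4π n_w h(x,t)/λ + φ0)``
    with ``h(x,t) = h0 + tanθ·x + ∫V_top``; inside the overlap ROI an extra
    ``overlap_contrast·cos(4π n_ice d(t)/λ + ψ0)`` term is added with
    ``d(t) = d0 + ∫(V_top + V_bottom)``. Optional i.i.d. Gaussian read noise of
    standard deviation ``noise_sd`` is added per pixel per frame.

    Raises :class:`SamplingError` (naming the minimal fps) if any interference
    phase would step by ≥ π/2 between frames.
    """
    if duration_s <= 0 or fps <= 0:
        raise ParameterError("duration_s and fps must be > 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    need = _min_fps(top, bottom, optics)
    if fps < need:
        raise SamplingError(
            f"fps {fps:g} too low for the scheduled rates: interference phase would "
            f"step by >= pi/2 per frame; minimum fps is {need:.2f}",
            min_fps=need,
        )

    wf_top = make_waveform(top)
    wf_bot = make_waveform(bottom)
    n_frames = max(1, int(round(duration_s * fps)))
    times = np.arange(n_frames) / fps

    disp_top = wf_top.displacement(times)
    disp_bot = wf_bot.displacement(times)
    thickness = geom.d0_um + disp_top + disp_bot

    h_px, w_px = geom.field_size
    x_um = np.arange(w_px) * geom.pixel_size_um
    ramp = math.tan(geom.tilt_angle_rad) * x_um  # height profile across the field
    lam = optics.lambda_um
    k_w = 4.0 * math.pi * optics.n_water / lam
    k_i = 4.0 * math.pi * optics.n_ice / lam
    y0, y1, x0, x1 = geom.overlap_roi

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h_px, w_px), dtype=np.float32)
    for i in range(n_frames):
        row = optics.baseline + optics.fringe_contrast * np.cos(
            k_w * (geom.h0_um + ramp + disp_top[i]) + phi0
        )
        frame = np.tile(row, (h_px, 1))
        frame[y0:y1, x0:x1] += optics.overlap_contrast * math.cos(
            k_i * thickness[i] + psi0
        )
        if noise_sd > 0:
            frame += rng.normal(0.0, noise_sd, size=(h_px, w_px))
        frames[i] = frame

    stack = FrameStack(frames=frames, fps=fps, pixel_size_um=geom.pixel_size_um)
    truth = RenderTruth(
        times_s=times,
        v_top_um_s=wf_top(times),
        v_bottom_um_s=wf_bot(times),
        thickness_um=thickness,
        top_displacement_um=disp_top,
        bottom_displacement_um=disp_bot,
    )
    return stack, truth


@dataclass(frozen=True)
class BenchmarkCase:
    """A fully specified synthetic observation scenario.

    ``line_xyxy`` is a suggested space line (x0, y0, x1, y1) crossing the
    fringes on the top face, oriented so fringes migrate toward increasing
    line coordinate; ``overlap_roi`` mirrors the geometry's ROI.
    """

    top: GrowthSchedule
    bottom: GrowthSchedule
    optics: OpticalConfig
    geometry: CrystalGeometry
    fps: float = 30.0
    noise_sd: float = 0.01
    line_xyxy: tuple[float, float, float, float] = (240.0, 40.0, 16.0, 40.0)

    def render(self, duration_s: float, seed: int | None = None):
        return render_video(
            self.top,
            self.bottom,
            self.optics,
            self.geometry,
            duration_s=duration_s,
            fps=self.fps,
            noise_sd=self.noise_sd,
            seed=seed,
        )


def benchmark_case(
    v_min: float = 0.13,
    v_max: float = 0.73,
    period_s: float = 11.0,
    growth_per_cycle_um: float = 6.33,
    delta_T_bulk_K: float = 0.3,
    delta_um: float = 5.0,
    rise_fraction: float = 0.92,
    noise_sd: float = 0.01,
    fps: float = 30.0,
) -> BenchmarkCase:
    """Canonical oscillating-growth scenario at ΔT∞ = 0.3 K.

    Defaults reproduce the reported basal-face oscillation in 0.07 mg/mL AFGP
    solution at 0.3 K bulk supercooling: rates swinging between 0.13 and
    0.73 μm/s with an 11 s period and about 6.33 μm of growth per cycle. The
    rise exponent is calibrated so the waveform mean equals
    growth_per_cycle / period; both basal faces follow the same schedule.
    """
    p = calibrate_rise_exponent(
        v_min, v_max, growth_per_cycle_um / period_s, rise_fraction=rise_fraction
    )
    top = GrowthSchedule(
        face="top",
        v_min_um_s=v_min,
        v_max_um_s=v_max,
        period_s=period_s,
        rise_fraction=rise_fraction,
        rise_exponent=p,
        delta_T_bulk_K=delta_T_bulk_K,
    )
    bottom = replace(top, face="bottom")
    optics = OpticalConfig()
    geom = CrystalGeometry.from_fringe_spacing(delta_um, optics)
    return BenchmarkCase(
        top=top, bottom=bottom, optics=optics, geometry=geom, fps=fps, noise_sd=noise_sd
    )
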