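"""Time–space (kymograph) construction.

A kymograph stacks the intensity profile sampled along a fixed "space line"
for every frame of a video: row *t* is the profile at frame *t*. Fringes
crossing the line appear as slanted stripes whose gradient δl/δt is the
lateral fringe migration velocity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import GeometryError, ParameterError
from .synthgram import FrameStack

__all__ = ["SpaceLine", "Kymograph", "extract_kymograph"]


@dataclass(frozen=True)
class SpaceLine:
    """A directed line segment in pixel coordinates, sampled equidistantly.

    Endpoints are (x, y) with 0-based, sub-pixel coordinates; the line
    coordinate s runs from ``p_start`` (s = 0) to ``p_end``.
    """

    p_start: tuple[float, float]
    p_end: tuple[float, float]
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if self.length_px <= 0:
            raise ParameterError("space line must have positive length")
        if self.n_samples is not None and self.n_samples < 8:
            raise ParameterError("n_samples must be >= 8")

    @property
    def length_px(self) -> float:
        dx = self.p_end[0] - self.p_start[0]
        dy = self.p_end[1] - self.p_start[1]
        return math.hypot(dx, dy)

    def resolved_n_samples(self) -> int:
        if self.n_samples is not None:
            return self.n_samples
        return max(8, int(math.ceil(self.length_px)) + 1)

    def sample_points(self) -> np.ndarray:
        """(n, 2) array of (x, y) sample coordinates along the line."""
        n = self.resolved_n_samples()
        t = np.linspace(0.0, 1.0, n)
        x = self.p_start[0] + t * (self.p_end[0] - self.p_start[0])
        y = self.p_start[1] + t * (self.p_end[1] - self.p_start[1])
        return np.column_stack([x, y])


@dataclass
class Kymograph:
    """Intensity indexed (time, position-along-line) with physical steps."""

    intensity: np.ndarray
    dt_s: float
    ds_um: float
    line: SpaceLine

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ParameterError("kymograph intensity must be 2-D (time, position)")
        if self.dt_s <= 0 or self.ds_um <= 0:
            raise ParameterError("dt_s and ds_um must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.intensity.shape[0]) * self.dt_s

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.intensity.shape[1]) * self.ds_um

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.intensity, index=self.times, columns=self.positions_um
        ).rename_axis(index="time_s", columns="position_um")


def extract_kymograph(
    stack: FrameStack, line: SpaceLine, interpolation: str = "bilinear"
) -> Kymograph:
    """Sample every frame along the space line and stack the profiles in time.

    ``interpolation`` is "bilinear" (default, supports sub-pixel lines) or
    "nearest". Raises :class:`GeometryError` if the line exits the frame.
    """
    if stack.n_frames == 0:
        raise ParameterError("empty frame stack")
    h, w = stack.shape
    pts = line.sample_points()
    x, y = pts[:, 0], pts[:, 1]
    if x.min() < 0 or y.min() < 0 or x.max() > w - 1 or y.max() > h - 1:
        raise GeometryError(
            f"space line exits frame bounds {h}x{w}: "
            f"x in [{x.min():.1f}, {x.max():.1f}], y in [{y.min():.1f}, {y.max():.1f}]"
        )
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ParameterError(f"unknown interpolation {interpolation!r}")

    coords = np.vstack([y, x])  # map_coordinates expects (row, col)
    rows = [
        map_coordinates(frame, coords, order=order, mode="nearest")
        for frame in np.asarray(stack.frames, dtype=float)
    ]
    n = line.resolved_n_samples()
    ds = line.length_px * stack.pixel_size_um / (n - 1)
    return Kymograph(intensity=np.array(rows), dt_s=1.0 / stack.fps, ds_um=ds, line=line)
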