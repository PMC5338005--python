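"""Readers, writers, configuration and the end-to-end analysis pipeline."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import cycles as cycles_mod
from . import fringes as fringes_mod
from . import thickness as thickness_mod
from .errors import AnalysisError, FormatError, ParameterError
from .kymo import Kymograph, SpaceLine, extract_kymograph
from .synthgram import FrameStack, OpticalConfig, RenderTruth

logger = logging.getLogger("icefringe")

__all__ = [
    "AnalysisConfig",
    "PipelineResult",
    "read_video",
    "write_video",
    "write_truth",
    "read_trace",
    "run_pipeline",
]


def read_video(
    path, fps: float | None = None, pixel_size_um: float | None = None
) -> FrameStack:
    """Read a grayscale multi-page TIFF into a [0, 1]-normalized FrameStack.

    Integer data are normalized by their bit depth (255 or 65535). ``fps`` and
    ``pixel_size_um`` are taken from the caller's configuration; if the file
    carries metadata (written by :func:`write_video`) it is used as a
    fallback, and a warning is logged when the two disagree (config wins).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = {}
        desc = tif.pages[0].description or ""
        if desc.strip().startswith("{"):
            try:
                meta = json.loads(desc)
            except json.JSONDecodeError:
                meta = {}
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(
            f"expected grayscale pages (t, y, x); got array of shape {data.shape}"
        )
    if not all(p.shape == data[0].shape for p in data):
        raise FormatError("mixed-shape TIFF pages")
    if np.issubdtype(data.dtype, np.integer):
        scale = 255.0 if data.dtype.itemsize == 1 else 65535.0
        frames = data.astype(np.float64) / scale
    else:
        frames = data.astype(np.float64)

    for name, given in (("fps", fps), ("pixel_size_um", pixel_size_um)):
        if given is not None and name in meta and not math.isclose(given, meta[name]):
            logger.warning(
                "%s: config %s=%g overrides file metadata %g", path.name, name, given, meta[name]
            )
    fps = fps if fps is not None else meta.get("fps")
    pixel_size_um = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if fps is None or pixel_size_um is None:
        raise ParameterError("fps and pixel_size_um must be given (no file metadata found)")
    return FrameStack(frames=frames, fps=float(fps), pixel_size_um=float(pixel_size_um))


def write_video(stack: FrameStack, path) -> None:
    """Write a FrameStack as a 16-bit grayscale multi-page TIFF.

    Intensities are clipped to [0, 1] and scaled to the full 16-bit range;
    fps and pixel size are stored as a JSON page description.
    """
    frames = np.clip(np.asarray(stack.frames, dtype=float), 0.0, 1.0)
    data = np.round(frames * 65535.0).astype(np.uint16)
    meta = json.dumps({"fps": stack.fps, "pixel_size_um": stack.pixel_size_um})
    tifffile.imwrite(str(path), data, photometric="minisblack", description=meta)


def write_truth(truth: RenderTruth, path) -> None:
    """Write ground truth as CSV: time_s, v_top_um_s, v_bottom_um_s, thickness_um."""
    truth.to_dataframe().to_csv(path, index=False)


def read_trace(path, face: str = "top") -> fringes_mod.GrowthTrace:
    """Read a growth-rate trace CSV (columns time_s, v_um_s[, flag])."""
    import pandas as pd

    df = pd.read_csv(path)
    flags = df["flag"].to_numpy(dtype=bool) if "flag" in df else None
    return fringes_mod.GrowthTrace(
        times_s=df["time_s"].to_numpy(),
        v_um_s=df["v_um_s"].to_numpy(),
        face=face,
        flags=flags,
    )


@dataclass
class AnalysisConfig:
    """Everything the analysis pipeline needs besides the video itself."""

    fps: float = 30.0
    pixel_size_um: float = 0.5
    line_xyxy: tuple[float, float, float, float] = (240.0, 40.0, 16.0, 40.0)
    overlap_roi: tuple[int, int, int, int] = (96, 160, 96, 160)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    smooth_window_s: float = 0.5
    detrend_window_s: float = 2.0
    drop_threshold: float = 2.0
    min_period_s: float = 3.0
    quality_threshold: float = 5.0
    sign: str = "auto"
    delta_T_bulk_K: float | None = None

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("fps and pixel_size_um must be > 0")

    @property
    def space_line(self) -> SpaceLine:
        x0, y0, x1, y1 = self.line_xyxy
        return SpaceLine(p_start=(x0, y0), p_end=(x1, y1))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["line_xyxy"] = list(self.line_xyxy)
        d["overlap_roi"] = list(self.overlap_roi)
        d["optics"] = asdict(self.optics)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "optics" in d and isinstance(d["optics"], dict):
            d["optics"] = OpticalConfig(**d["optics"])
        for key in ("line_xyxy", "overlap_roi"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    """Outputs of the full analysis pipeline on one video."""

    kymograph: Kymograph
    fringe_estimate: fringes_mod.FringeEstimate
    v_top: fringes_mod.GrowthTrace
    ddt: fringes_mod.GrowthTrace | None
    v_bottom: fringes_mod.GrowthTrace | None
    boundaries_s: np.ndarray
    cycles: list[cycles_mod.CycleMetrics]
    log: list[dict]


def run_pipeline(
    config: AnalysisConfig,
    stack: FrameStack,
    outdir=None,
    measure_thickness: bool = True,
) -> PipelineResult:
    """Run kymograph → fringe velocimetry → thickness → cycle statistics.

    Stage outputs are persisted as CSV under ``outdir`` when given, together
    with a machine-readable run log. Thickness/bottom-face analysis is
    skipped (with a logged warning) when the overlap brightness shows too few
    extrema.
    """
    log: list[dict] = [{"stage": "config", "params": config.to_dict()}]

    kym = extract_kymograph(stack, config.space_line)
    log.append({"stage": "kymo", "rows": kym.intensity.shape[0], "cols": kym.intensity.shape[1]})

    est = fringes_mod.estimate_fringe_spacing(kym, quality_threshold=config.quality_threshold)
    log.append({"stage": "fringes.spacing", "delta_um": est.delta_um, "quality": est.quality})

    phase = fringes_mod.extract_phase(kym, est)
    beta = fringes_mod.fringe_velocity(phase, smooth_window_s=config.smooth_window_s)
    v_top = fringes_mod.growth_rate_from_fringes(
        beta, est.delta_um, config.optics, sign=config.sign
    )
    log.append(
        {
            "stage": "fringes.velocity",
            "n": len(v_top.times_s),
            "sign_flipped": v_top.sign_flipped,
            "flagged": int(v_top.flags.sum()),
        }
    )

    ddt = v_bottom = None
    if measure_thickness:
        try:
            b = thickness_mod.brightness_trace(
                stack, config.overlap_roi, detrend_window_s=config.detrend_window_s
            )
            ddt = thickness_mod.thickness_rate(b, config.optics)
            v_bottom = thickness_mod.bottom_face_rate(ddt, v_top)
            log.append({"stage": "thickness", "n": len(ddt.times_s)})
        except AnalysisError as exc:
            logger.warning("thickness stage skipped: %s", exc)
            log.append({"stage": "thickness", "warning": str(exc)})

    boundaries = cycles_mod.segment_cycles(
        v_top,
        drop_threshold=config.drop_threshold,
        min_period_s=config.min_period_s,
        smooth_window_s=config.smooth_window_s,
    )
    cyc = cycles_mod.cycle_metrics(v_top, boundaries)
    log.append({"stage": "cycles", "n_boundaries": len(boundaries), "n_cycles": len(cyc)})

    result = PipelineResult(
        kymograph=kym,
        fringe_estimate=est,
        v_top=v_top,
        ddt=ddt,
        v_bottom=v_bottom,
        boundaries_s=boundaries,
        cycles=cyc,
        log=log,
    )
    if outdir is not None:
        _persist(result, config, Path(outdir))
    return result


def _persist(result: PipelineResult, config: AnalysisConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.v_top.to_dataframe().to_csv(outdir / "trace_top.csv", index=False)
    if result.v_bottom is not None:
        result.v_bottom.to_dataframe().to_csv(outdir / "trace_bottom.csv", index=False)
    if result.ddt is not None:
        result.ddt.to_dataframe().to_csv(outdir / "trace_thickness.csv", index=False)
    cycles_mod.cycles_to_dataframe(result.cycles).to_csv(outdir / "cycles.csv", index=False)
    if result.cycles and config.delta_T_bulk_K is not None:
        table = cycles_mod.condition_summary([(config.delta_T_bulk_K, result.cycles)])
        table.to_dataframe().to_csv(outdir / "summary.csv", index=False)
    with open(outdir / "runlog.json", "w") as fh:
        json.dump(result.log, fh, indent=2, default=str)
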