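"""Shared fixtures: synthetic videos are rendered once per session."""

import numpy as np
import pytest

import icefringe as icf

CANONICAL_SEED = 20170306


@pytest.fixture(scope="session")
def canonical_case():
    """The 0.3 K benchmark scenario (0.13–0.73 μm/s, 11 s, 6.33 μm/cycle)."""
    return icf.benchmark_case()


@pytest.fixture(scope="session")
def canonical_video(canonical_case):
    """60 s of the benchmark video at 30 fps with 1% noise, plus ground truth."""
    stack, truth = canonical_case.render(60.0, seed=CANONICAL_SEED)
    return stack, truth


@pytest.fixture(scope="session")
def canonical_result(canonical_case, canonical_video):
    """Full pipeline output on the benchmark video."""
    stack, _ = canonical_video
    cfg = icf.AnalysisConfig(
        fps=canonical_case.fps,
        pixel_size_um=canonical_case.geometry.pixel_size_um,
        line_xyxy=canonical_case.line_xyxy,
        overlap_roi=canonical_case.geometry.overlap_roi,
        optics=canonical_case.optics,
        delta_T_bulk_K=0.3,
    )
    return icf.run_pipeline(cfg, stack)


def render_constant(v, delta_um=5.0, duration_s=8.0, noise_sd=0.0, seed=7, fps=30.0):
    """Short constant-rate render used by round-trip tests."""
    from dataclasses import replace

    sched = icf.GrowthSchedule(face="top", v_min_um_s=v, v_max_um_s=v, period_s=11.0)
    optics = icf.OpticalConfig()
    geom = icf.CrystalGeometry.from_fringe_spacing(delta_um, optics)
    return (
        icf.render_video(
            sched, replace(sched, face="bottom"), optics, geom,
            duration_s=duration_s, fps=fps, noise_sd=noise_sd, seed=seed,
        ),
        optics,
        geom,
    )


def recover_rate(stack, optics, line_xyxy=(240.0, 40.0, 16.0, 40.0)):
    """Kymograph → spacing → phase → velocity → growth rate, with defaults."""
    line = icf.SpaceLine(p_start=line_xyxy[:2], p_end=line_xyxy[2:])
    kym = icf.extract_kymograph(stack, line)
    est = icf.estimate_fringe_spacing(kym)
    phase = icf.extract_phase(kym, est)
    beta = icf.fringe_velocity(phase)
    return icf.growth_rate_from_fringes(beta, est.delta_um, optics), est
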