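"""Oscillation-cycle segmentation and statistics.

The observed growth-rate waveform is sawtooth-like: a gradual rise followed by
a rapid fall. Cycle boundaries are placed at the rapid-drop events — times
where the smoothed derivative of V(t) falls below a threshold scaled by the
trace amplitude — and per-cycle statistics (period, extrema, growth increment
∫V dt, mean rate, rise fraction) are computed between consecutive drops.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import spearmanr

from .errors import ParameterError
from .fringes import GrowthTrace

__all__ = [
    "CycleMetrics",
    "ConditionSummary",
    "ConditionTable",
    "segment_cycles",
    "cycle_metrics",
    "condition_summary",
    "cycles_to_dataframe",
]


@dataclass(frozen=True)
class CycleMetrics:
    """Statistics of one oscillation cycle of a growth-rate trace."""

    t_start_s: float
    t_end_s: float
    period_s: float
    v_min_um_s: float
    v_max_um_s: float
    amplitude_um_s: float
    growth_um: float
    v_mean_um_s: float
    rise_fraction: float


@dataclass(frozen=True)
class ConditionSummary:
    """Aggregate over all cycles recorded at one bulk supercooling."""

    delta_T_bulk_K: float
    max_of_cycles_um_s: float
    min_of_cycles_um_s: float
    overall_mean_um_s: float
    n_cycles: int


@dataclass
class ConditionTable:
    """Per-condition summaries plus an amplitude-trend diagnostic.

    ``amplitude_spearman`` is the Spearman correlation between bulk
    supercooling and mean cycle amplitude across conditions (NaN when fewer
    than three conditions); it is reported as a diagnostic, never enforced.
    """

    summaries: list[ConditionSummary]
    amplitude_spearman: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([s.__dict__ for s in self.summaries])


def _clean(trace: GrowthTrace) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(trace.times_s, dtype=float)
    v = np.asarray(trace.v_um_s, dtype=float)
    good = np.isfinite(v)
    if not good.all():
        v = np.interp(t, t[good], v[good])
    return t, v


def segment_cycles(
    trace: GrowthTrace,
    drop_threshold: float = 2.0,
    min_period_s: float = 3.0,
    smooth_window_s: float = 0.5,
) -> np.ndarray:
    """Cycle boundary times at rapid-drop events of the growth rate.

    A drop event is a contiguous run where the Savitzky–Golay-smoothed
    derivative dV/dt < −drop_threshold · amplitude / min_period_s (amplitude
    = global range of the smoothed trace); the boundary is placed at the
    steepest point of the run. Events closer than ``min_period_s`` are merged
    keeping the steeper one. A flat trace yields zero boundaries.
    """
    t, v = _clean(trace)
    if len(t) < 4 or t[-1] - t[0] < 2.0 * min_period_s:
        raise ParameterError(
            f"trace span {t[-1] - t[0] if len(t) else 0:.2f} s shorter than 2×min_period"
        )
    dt = float(np.median(np.diff(t)))
    win = max(5, int(round(smooth_window_s / dt)))
    if win % 2 == 0:
        win += 1
    win = min(win, len(v) - (1 - len(v) % 2))
    vs = savgol_filter(v, win, 2)
    dv = savgol_filter(v, win, 2, deriv=1, delta=dt)
    amplitude = float(vs.max() - vs.min())
    if amplitude <= 1e-9 * max(1.0, float(np.abs(vs).max())):
        return np.array([])
    thresh = drop_threshold * amplitude / min_period_s
    mask = dv < -thresh
    if not mask.any():
        return np.array([])

    # steepest point of each contiguous run below threshold
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    cands = []
    for run in runs:
        i = run[np.argmin(dv[run])]
        cands.append((t[i], dv[i]))

    merged: list[tuple[float, float]] = []
    for time, depth in cands:
        if merged and time - merged[-1][0] < min_period_s:
            if depth < merged[-1][1]:
                merged[-1] = (time, depth)
        else:
            merged.append((time, depth))
    return np.array([time for time, _ in merged])


def cycle_metrics(trace: GrowthTrace, boundaries: np.ndarray) -> list[CycleMetrics]:
    """Per-cycle statistics between consecutive boundary times.

    The trace is interpolated at the exact boundary times so the growth
    increment (trapezoidal ∫V dt) is consistent with the period. Incomplete
    leading/trailing segments are excluded by construction.
    """
    boundaries = np.asarray(boundaries, dtype=float)
    if len(boundaries) < 2:
        return []
    t, v = _clean(trace)
    out = []
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        sel = (t > b0) & (t < b1)
        tt = np.concatenate([[b0], t[sel], [b1]])
        vv = np.concatenate([[np.interp(b0, t, v)], v[sel], [np.interp(b1, t, v)]])
        period = b1 - b0
        growth = float(np.trapezoid(vv, tt))
        i_max = int(np.argmax(vv))
        v_min = float(vv.min())
        v_max = float(vv[i_max])
        out.append(
            CycleMetrics(
                t_start_s=float(b0),
                t_end_s=float(b1),
                period_s=float(period),
                v_min_um_s=v_min,
                v_max_um_s=v_max,
                amplitude_um_s=v_max - v_min,
                growth_um=growth,
                v_mean_um_s=growth / period,
                rise_fraction=float((tt[i_max] - b0) / period),
            )
        )
    return out


def cycles_to_dataframe(cycles: list[CycleMetrics]):
    import pandas as pd

    return pd.DataFrame([c.__dict__ for c in cycles])


def condition_summary(
    tagged: list[tuple[float, list[CycleMetrics]]],
) -> ConditionTable:
    """Aggregate cycle statistics per bulk-supercooling condition.

    Per condition: maximum of cycle maxima, minimum of cycle minima, and the
    duration-weighted overall mean rate (total growth / total time). The
    returned table also reports the Spearman correlation between ΔT∞ and mean
    cycle amplitude as a monotonicity diagnostic.
    """
    if not tagged:
        raise ParameterError("need at least one condition")
    summaries = []
    amps = []
    for delta_T, cycles in sorted(tagged, key=lambda x: x[0]):
        if not cycles:
            continue
        total_growth = sum(c.growth_um for c in cycles)
        total_time = sum(c.period_s for c in cycles)
        summaries.append(
            ConditionSummary(
                delta_T_bulk_K=float(delta_T),
                max_of_cycles_um_s=max(c.v_max_um_s for c in cycles),
                min_of_cycles_um_s=min(c.v_min_um_s for c in cycles),
                overall_mean_um_s=total_growth / total_time,
                n_cycles=len(cycles),
            )
        )
        amps.append((delta_T, float(np.mean([c.amplitude_um_s for c in cycles]))))
    if len(amps) >= 3:
        rho = float(spearmanr([a[0] for a in amps], [a[1] for a in amps]).statistic)
    elif len(amps) == 2:
        rho = float(np.sign(amps[1][1] - amps[0][1]))
    else:
        rho = float("nan")
    return ConditionTable(summaries=summaries, amplitude_spearman=rho)
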