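"""Phenomenological oscillation kinetics of impurity-affected crystal growth.

Two qualitative feedback loops between the interfacial supercooling ΔT_int,
the adsorbed impurity coverage C_int and the growth rate V are realized as a
planar ODE with (in one mode) a reset event:

* **inhibition** — the classical impurity picture: adsorbed molecules pin
  steps, so V = k·ΔT_int·max(0, 1 − C_int/C_crit); growth stalls when the
  coverage exceeds the critical value, the coverage then desorbs, ΔT_int
  recovers because less latent heat is released, and growth restarts.
* **promotion** — adsorbed molecules act as step sources, so the V–ΔT_int
  slope steepens with coverage: V = k·(1 + g·C_int)·ΔT_int. The coverage
  builds up by impurity rejection as the face grows until it collapses
  (an opaque event, modelled as C_int → 0 when C_int crosses ``c_drop``),
  abruptly depressing V and starting the next cycle.

Shared couplings: latent heat released in proportion to V depresses ΔT_int
(gain ``gamma``), thermal relaxation restores it toward the bulk supercooling
ΔT∞ with time constant ``tau_T``, rejection accumulates coverage at rate
``rho·V·(1 − C_int)`` and desorption removes it at rate ``kappa·C_int``.

Every functional form here is a modelling choice constrained only by the
qualitative loop structure; none is fitted to data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import IntegrationError, ParameterError

__all__ = [
    "KineticParams",
    "KineticState",
    "KineticTrajectory",
    "growth_law",
    "simulate",
    "promotion_defaults",
    "inhibition_defaults",
]


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the oscillation-kinetics model.

    Units: ``k`` μm/(s·K); ``g`` dimensionless gain per unit coverage
    (promotion); ``c_crit``/``c_drop`` dimensionless coverages; ``tau_T`` s;
    ``gamma`` K/μm; ``rho`` 1/μm; ``kappa`` 1/s; ``delta_T_bulk_K`` K.
    """

    mode: str = "promotion"
    k: float = 0.6
    g: float = 14.0
    c_crit: float = 0.3
    c_drop: float = 0.4
    tau_T: float = 1.0
    gamma: float = 0.15
    rho: float = 0.12
    kappa: float = 0.02
    delta_T_bulk_K: float = 0.3
    stochastic_reset: bool = False
    reset_hazard: float = 2.0  # 1/s, applied above c_drop when stochastic

    def __post_init__(self) -> None:
        if self.mode not in ("promotion", "inhibition"):
            raise ParameterError(f"mode must be 'promotion' or 'inhibition', got {self.mode!r}")
        for name in ("k", "g", "tau_T", "gamma", "rho", "kappa", "reset_hazard"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a finite non-negative number, got {v}")
        if self.tau_T <= 0:
            raise ParameterError("tau_T must be > 0")
        if self.mode == "inhibition" and not 0.0 < self.c_crit <= 1.0:
            raise ParameterError("c_crit must lie in (0, 1] for inhibition mode")
        if self.mode == "promotion" and self.c_drop <= 0.0:
            # c_drop > 1 is allowed: coverage cannot exceed 1, so it disables the reset
            raise ParameterError("c_drop must be > 0 for promotion mode")
        if not np.isfinite(self.delta_T_bulk_K) or self.delta_T_bulk_K < 0:
            raise ParameterError("delta_T_bulk_K must be finite and >= 0")


@dataclass(frozen=True)
class KineticState:
    """Interfacial state: supercooling ΔT_int (K), coverage C_int, rate V (μm/s)."""

    delta_T_int_K: float
    c_int: float
    v_um_s: float = 0.0

    def __post_init__(self) -> None:
        if not -1e-9 <= self.c_int <= 1.0 + 1e-9:
            raise ParameterError(f"c_int must lie in [0, 1], got {self.c_int}")


@dataclass
class KineticTrajectory:
    """Simulated time series of (ΔT_int, C_int, V) plus reset-event times."""

    times_s: np.ndarray
    delta_T_int_K: np.ndarray
    c_int: np.ndarray
    v_um_s: np.ndarray
    events_s: list[float] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        event_flag = np.zeros(len(self.times_s), dtype=int)
        for te in self.events_s:
            event_flag[int(np.argmin(np.abs(self.times_s - te)))] = 1
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "v_um_s": self.v_um_s,
                "dT_int_K": self.delta_T_int_K,
                "c_int": self.c_int,
                "event_flag": event_flag,
            }
        )

    def growth_trace(self):
        from .fringes import GrowthTrace

        return GrowthTrace(times_s=self.times_s, v_um_s=self.v_um_s, face="top")


def promotion_defaults(delta_T_bulk_K: float = 0.3) -> KineticParams:
    """Promotion-mode defaults giving a ~10 s limit cycle with V in the 0.1–0.8 μm/s decade at ΔT∞ = 0.3 K."""
    return KineticParams(mode="promotion", delta_T_bulk_K=delta_T_bulk_K)


def inhibition_defaults(delta_T_bulk_K: float = 0.3) -> KineticParams:
    """Inhibition-mode defaults (classical adsorption-inhibition coupling).

    With the smooth pinning law the coverage settles just below the critical
    value and the system relaxes — possibly through damped oscillations — to
    a strongly depressed steady growth rate; sustained oscillation requires
    the discontinuous coverage-collapse event of the promotion mode.
    """
    return KineticParams(
        mode="inhibition",
        k=2.0,
        c_crit=0.3,
        tau_T=1.0,
        gamma=0.3,
        rho=2.0,
        kappa=0.03,
        delta_T_bulk_K=delta_T_bulk_K,
    )


def _v(delta_T: float, c: float, p: KineticParams) -> float:
    if p.mode == "promotion":
        return p.k * (1.0 + p.g * c) * max(0.0, delta_T)
    return p.k * max(0.0, delta_T) * max(0.0, 1.0 - c / p.c_crit)


def growth_law(state: KineticState, params: KineticParams) -> float:
    """Instantaneous growth rate V(ΔT_int, C_int), μm/s.

    At zero coverage both modes reduce to the linear law V = k·ΔT_int.
    Promotion: V = k·(1 + g·C_int)·ΔT_int. Inhibition:
    V = k·ΔT_int·max(0, 1 − C_int/C_crit), zero at and above the critical
    coverage.
    """
    return _v(state.delta_T_int_K, state.c_int, params)


def _deriv(y: np.ndarray, p: KineticParams) -> np.ndarray:
    dT, c = y
    v = _v(dT, c, p)
    ddT = (p.delta_T_bulk_K - dT) / p.tau_T - p.gamma * v
    dc = p.rho * v * (1.0 - c) - p.kappa * c
    return np.array([ddT, dc])


def _rk4_step(y: np.ndarray, h: float, p: KineticParams) -> np.ndarray:
    k1 = _deriv(y, p)
    k2 = _deriv(y + 0.5 * h * k1, p)
    k3 = _deriv(y + 0.5 * h * k2, p)
    k4 = _deriv(y + h * k3, p)
    return y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def simulate(
    params: KineticParams,
    state0: KineticState | None = None,
    duration_s: float = 120.0,
    dt: float = 0.01,
    seed: int | None = None,
) -> KineticTrajectory:
    """Integrate the kinetic loop by fixed-step RK4 with event handling.

    In promotion mode the coverage-collapse reset C_int → 0 fires whenever
    C_int crosses ``c_drop`` from below; the crossing time is located by
    bisection to dt/100 and recorded in ``events_s``. With
    ``stochastic_reset`` the collapse instead fires with exponential hazard
    ``reset_hazard`` while C_int > c_drop (seeded). Inhibition mode has no
    reset. Requires dt ≤ tau_T/10.
    """
    if dt <= 0 or duration_s <= 0:
        raise ParameterError("dt and duration_s must be > 0")
    if dt > params.tau_T / 10.0:
        raise ParameterError(f"dt must be <= tau_T/10 = {params.tau_T / 10.0:g} s")
    if state0 is None:
        state0 = KineticState(delta_T_int_K=params.delta_T_bulk_K, c_int=0.0)
    rng = np.random.default_rng(seed) if params.stochastic_reset else None

    n = int(round(duration_s / dt)) + 1
    times = np.arange(n) * dt
    dT = np.empty(n)
    cc = np.empty(n)
    vv = np.empty(n)
    events: list[float] = []

    y = np.array([state0.delta_T_int_K, state0.c_int], dtype=float)
    for i in range(n):
        dT[i], cc[i] = y
        vv[i] = _v(y[0], y[1], params)
        if i == n - 1:
            break
        y_new = _rk4_step(y, dt, params)
        if not np.all(np.isfinite(y_new)):
            raise IntegrationError(
                f"non-finite state at step {i} (t = {times[i]:.4f} s)", step=i
            )
        if params.mode == "promotion":
            if params.stochastic_reset:
                if y_new[1] > params.c_drop and rng.random() < -math.expm1(
                    -params.reset_hazard * dt
                ):
                    events.append(float(times[i + 1]))
                    y_new[1] = 0.0
            elif y[1] < params.c_drop <= y_new[1]:
                # bisect the crossing time within the step to dt/100
                lo, hi = 0.0, dt
                while hi - lo > dt / 100.0:
                    mid = 0.5 * (lo + hi)
                    if _rk4_step(y, mid, params)[1] >= params.c_drop:
                        hi = mid
                    else:
                        lo = mid
                t_event = 0.5 * (lo + hi)
                y_mid = _rk4_step(y, t_event, params)
                y_mid[1] = 0.0  # coverage collapse
                events.append(float(times[i] + t_event))
                y_new = _rk4_step(y_mid, dt - t_event, params)
        y_new[1] = float(np.clip(y_new[1], 0.0, 1.0))
        y = y_new
    return KineticTrajectory(
        times_s=times, delta_T_int_K=dT, c_int=cc, v_um_s=vv, events_s=events
    )
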