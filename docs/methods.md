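# Methods

## The measurement problem

A Michelson interference microscope viewing a crystal face nearly
perpendicular to the optical axis shows straight, equally spaced fringes
wherever the face is slightly tilted. As the face grows normal to itself the
optical path of its reflection shortens, and the fringe pattern translates
laterally: one fringe spacing of migration per λ/(2n_w) of normal
displacement (reflection doubles the path; n_w because the beam travels
through water). With fringe spacing δ and lateral migration velocity β the
normal growth rate is

    V = β λ / (2 δ n_w),        δ = λ / (2 n_w tan θ).

Where the images of the top and bottom faces of a plate-like crystal
overlap, the two reflections interfere with each other; their phase
difference is set by the optical thickness of the crystal, so the overlap
brightness runs through one full cycle per λ/(2n_ice) of thickness growth
(the inter-face path is through ice). The brightness-cycle frequency f_B
therefore measures dd/dt = f_B·λ/(2n_ice), and V_bottom = dd/dt − V_top.

Defaults: λ = 670 nm, n_w = 1.3328, n_ice = 1.3100. The ice index enters
only the thickness conversion; 1.3100 is a literature-typical value at this
wavelength and is configurable.

## Synthetic interferograms (`synthgram`)

The generator renders

    I(x, y, t) = B + C_f·cos(4π n_w h(x, t)/λ + φ0)
               + [inside overlap ROI] C_o·cos(4π n_ice d(t)/λ + ψ0) + ε,

with h(x, t) = h0 + tanθ·x + ∫V_top dt, d(t) = d0 + ∫(V_top + V_bottom) dt,
and ε i.i.d. Gaussian read noise. The face tilt is about the image y-axis,
so fringes are vertical and migrate along x; drift, vibration and wave-optics
effects (diffraction, partial coherence) are deliberately absent. Rendering
refuses frame rates at which any interference phase would step by ≥ π/2
between frames, and reports the minimum admissible fps.

The prescribed rate waveform is a power-law rise over a fraction r of the
period followed by a linear fall:

    V(τ) = v_min + (v_max − v_min)(τ/rT)^p   for τ ≤ rT, then linear to v_min.

Its cycle mean has the closed form r·(v_min + Δv/(1+p)) + (1−r)(v_min+v_max)/2,
which `calibrate_rise_exponent` inverts (analytically for r = 1, by Brent
root-finding otherwise). Running integrals of V are evaluated in closed form,
so returned ground truth carries no quadrature error.

`benchmark_case()` freezes the canonical oscillation scenario at 0.3 K bulk
supercooling: v_min = 0.13 μm/s, v_max = 0.73 μm/s, period 11 s, rise
fraction 0.92, rise exponent calibrated so the mean equals 6.33 μm/11 s,
identical schedules on both faces, δ = 5 μm (tilt ≈ 50 mrad), 256×256 px at
0.5 μm/px, 30 fps, noise σ = 0.01 of full scale. What passing tests on this
emulation show is that the *analysis* is correct and noise-tolerant at the
nominal contrast and sampling; they cannot certify behavior under real-data
pathologies the generator omits (fringe curvature, contrast drift,
vibration, convective distortion).

## Kymograph and fringe velocimetry (`kymo`, `fringes`)

Intensity is sampled by bilinear interpolation at equidistant points along a
user-chosen space line (nearest-neighbor available for exactness checks);
rows of the kymograph are consecutive frames. Fringe spacing comes from the
time-averaged spatial power spectrum of linearly detrended, Hann-windowed
rows, with parabolic refinement of the peak bin and a peak-to-median-power
quality ratio (below threshold → "no fringes detected").

The fringe phase is the angle of a band-limited analytic signal: each row is
Fourier filtered to the positive-frequency band f*·(1 ± 0.25), unwrapped
along position, and rows are tied together by unwrapping the center column
along time (valid because the render/sampling contract keeps per-frame phase
steps below π/2). Because the fringes are straight, the temporal phase is
common along the line; it is averaged over a wide symmetric column window
around the evaluation position — excluding roughly one fringe spacing at the
line ends, where the hard band-pass rings — which suppresses pixel noise
without spatial bias.

The velocity is β = −(∂φ/∂t)/(∂φ/∂s). The spatial slope is a least-squares
fit across columns, Savitzky–Golay smoothed in time. For the time derivative
the default is a **windowed ENO scheme**: at each sample, quadratic
least-squares fits over a backward, a centered and a forward window (default
0.5 s) are evaluated *at* the sample, and the centered fit is used unless its
residual exceeds twice the better one-sided residual, in which case the
smoother side wins. The observed waveform is sawtooth-like: V has a corner at
each maximum and a cusp at each minimum, and any centered smoother biases
those extrema toward the cycle interior (at 30 fps the bias on v_min reaches
tens of percent). The ENO choice keeps the one-sided slopes exact across the
corners — the falling flank is locally quadratic in phase — at
Savitzky–Golay-like noise levels elsewhere. A plain Savitzky–Golay centered
derivative remains available (`deriv="savgol"`).

The sign of β along a single line depends on the tilt orientation of the
face, which a single interferogram cannot determine; `growth_rate_from_fringes`
defaults to `sign="auto"` (flip so the median V ≥ 0, recorded on the trace).

## Thickness analysis (`thickness`)

The overlap brightness is averaged over the ROI per frame and detrended by a
first-order Savitzky–Golay baseline (default 2 s window). Instantaneous
frequency comes from extremum spacing — successive peaks/troughs are half a
period apart — with parabolic sub-frame refinement of extremum times;
fewer than three extrema is an explicit "insufficient oscillation" error.
Extremum spacing was chosen over an analytic-signal phase because the
brightness contrast of real overlap regions drifts; an FFT oracle cross-checks
the estimator in the tests. V_bottom = dd/dt − V_top is computed on the
common time support; negative values (measurement noise) are clipped to zero
and flagged, never silently dropped.

## Cycle statistics (`cycles`)

Cycle boundaries are rapid-*drop* events: times where the Savitzky–Golay
smoothed derivative of V falls below −drop_threshold·amplitude/min_period
(defaults 2.0 and 3 s), taking the steepest point of each sub-threshold run
and merging events closer than min_period. Drop events rather than peaks
because the fall is the sharp, well-localized landmark of the sawtooth;
segmentation is exactly invariant to adding a constant to V. Per cycle the
trace is interpolated at the boundary times, so growth = ∫V dt (trapezoid),
v_mean = growth/period, and the identity growth = v_mean·period holds by
construction. Incomplete leading/trailing cycles are excluded. Condition
summaries aggregate per bulk supercooling: max of cycle maxima, min of
cycle minima, duration-weighted mean (total growth / total time — the
windowing of long-run averages is otherwise unconstrained), and a Spearman
amplitude-vs-ΔT∞ trend reported as a diagnostic only.

## Oscillation kinetics (`kinetics`)

A deliberately minimal planar ODE in (ΔT_int, C_int):

    dΔT_int/dt = (ΔT∞ − ΔT_int)/τ_T − γ·V        (thermal relaxation vs latent heat)
    dC_int/dt  = ρ·V·(1 − C_int) − κ·C_int       (rejection-driven adsorption vs desorption)

with V = k·(1 + g·C_int)·ΔT_int in promotion mode (coverage steepens the
kinetic law) and V = k·ΔT_int·max(0, 1 − C_int/C_crit) in inhibition mode
(step pinning). Promotion mode adds the one discontinuous ingredient: when
C_int crosses c_drop from below the adlayer collapses to zero (the physical
trigger — plausibly macrostep burial — is left opaque by design); the
crossing time is located by bisection to dt/100 within an RK4 step. A seeded
stochastic variant (exponential hazard above c_drop) is provided. All
functional forms are qualitative constructions, not fits.

Integration is fixed-step RK4 with dt ≤ τ_T/10 enforced; coverage is clipped
to [0, 1] against rounding. With the reset disabled and ρ = 0 the system is
linear with fixed point ΔT* = ΔT∞/(1 + τ_T·γ·k), used as an exact oracle.

Defaults (k = 0.6 μm s⁻¹ K⁻¹, g = 14, c_drop = 0.4, τ_T = 1 s,
γ = 0.15 K/μm, ρ = 0.12 μm⁻¹, κ = 0.02 s⁻¹) were set by a quasi-steady
analysis (fast thermal pool, slow coverage build-up) so the promotion mode
at ΔT∞ = 0.3 K produces an order-of-magnitude match to the observed
phenomenology — a ~10 s sawtooth with V spanning roughly 0.1–0.8 μm/s whose
amplitude grows and period shrinks with ΔT∞. This is a qualitative
realization, not a parameter fit, and no mechanistic validation is claimed.
A note on the inhibition mode: its Jacobian trace is negative everywhere
(both self-couplings are damping), so by Bendixson's criterion the smooth
pinning law admits no limit cycle — the coverage settles just below
critical and growth stays depressed. Sustained oscillation in this model
family requires the promotion mode's collapse event.

## Numerical and interface choices

- Time origin at the first frame; 0-based pixel coordinates; ROIs half-open;
  all exported columns carry units in their names (`*_um_s`, `*_s`, `*_K`).
- Velocimetry trims one derivative window at each trace end; flagged samples
  (undefined velocity, clipped V_bottom) propagate rather than vanish.
- Analysis defaults (0.5 s derivative window, 0.25 analytic band halfwidth,
  drop threshold 2.0, min period 3 s) were validated against generator ground
  truth; the derivative window must stay well below the oscillation period
  to preserve the sawtooth.
- Determinism: a fixed seed makes rendering bit-identical; the analysis
  pipeline is seed-free and exactly repeatable.
- Problem sizes used throughout tests and the acceptance script — 60 s of
  256×256 video at 30 fps, 100–120 s of ODE integration at dt = 0.01 s —
  were chosen as the smallest that hold 4–10 complete oscillation cycles,
  enough for stable medians.

## Known limitations

- Single space line, single face: no 2-D fringe-orientation estimation, no
  automatic line placement, no multi-face tracking.
- The brightness method observes only rates (periods), not absolute
  thickness; d0 is unobservable.
- The ENO derivative assumes piecewise-smooth phase; pathological noise
  spikes could trigger one-sided stencils spuriously (the trace flags help
  audit this).
- The generator's idealizations (straight fringes, constant contrast, pure
  Gaussian noise) mean quantitative tolerances verified here are best-case
  bounds for real footage.
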