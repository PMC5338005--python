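# icefringe

Interferometric fringe velocimetry of oscillating crystal growth.

`icefringe` measures the normal growth rates of crystal faces from
interference-microscope videos and characterizes growth-rate *oscillations* —
the phenomenology of ice basal faces growing freely in supercooled water that
contains antifreeze glycoprotein (AFGP) as an impurity, where adsorbed protein
molecules accelerate rather than inhibit growth and the rate cycles through a
sawtooth: a gradual rise followed by an abrupt drop.

The package provides, as library modules:

- **`synthgram`** — a forward optical model that renders synthetic
  interferogram videos with exact ground truth (tilted-face fringes, an
  oscillating overlap-region brightness, Gaussian read noise), so every
  analysis stage is testable without proprietary flight data;
- **`kymo`** — time–space (kymograph) images sampled along a "space line";
- **`fringes`** — fringe spacing δ, unwrapped fringe phase, migration
  velocity β, and the growth rate **V = βλ / (2δn_w)**;
- **`thickness`** — the thickness growth rate dd/dt from the brightness
  oscillation of the region where top- and bottom-face images overlap (one
  brightness cycle per λ/(2n_ice) of thickness growth), and from it the
  bottom-face rate V_bottom = dd/dt − V_top;
- **`cycles`** — sawtooth cycle segmentation at rapid-drop events and
  per-cycle statistics (period, v_min, v_max, growth increment ∫V dt, mean
  rate, rise fraction), plus per-supercooling condition summaries;
- **`kinetics`** — a phenomenological relaxation-oscillator ODE coupling the
  interfacial supercooling ΔT_int and adsorbed impurity coverage C_int, in an
  *adsorption-promotion* mode (coverage steepens the V–ΔT_int relation until
  the adlayer collapses) and a classical *adsorption-inhibition* mode.

## Key relations

With laser wavelength λ (670 nm in air), water index n_w = 1.3328 and ice
index n_ice = 1.3100:

- fringe spacing on a face tilted by θ: δ = λ / (2 n_w tan θ);
- one fringe of lateral migration ⇔ λ/(2 n_w) ≈ 0.2513 μm of normal face
  displacement, giving V = βλ/(2δn_w);
- one brightness cycle of the overlap region ⇔ λ/(2 n_ice) ≈ 0.2557 μm of
  thickness increase, giving dd/dt = f_B · λ/(2 n_ice).

## Worked example

```python
import numpy as np
import icefringe as icf

case = icf.benchmark_case()                  # 0.3 K scenario: 0.13-0.73 um/s, 11 s
stack, truth = case.render(60.0, seed=5)     # 60 s of video at 30 fps, 1% noise

cfg = icf.AnalysisConfig(optics=case.optics, line_xyxy=case.line_xyxy,
                         overlap_roi=case.geometry.overlap_roi, delta_T_bulk_K=0.3)
res = icf.run_pipeline(cfg, stack)
for c in res.cycles[:2]:
    print(f"period {c.period_s:.2f} s  v_min {c.v_min_um_s:.3f}  "
          f"v_max {c.v_max_um_s:.3f}  growth {c.growth_um:.2f} um  "
          f"v_mean {c.v_mean_um_s:.3f} um/s")
```

prints (from an actual run):

```
period 11.00 s  v_min 0.130  v_max 0.729  growth 6.33 um  v_mean 0.576 um/s
period 11.00 s  v_min 0.129  v_max 0.731  growth 6.33 um  v_mean 0.576 um/s
```

i.e. the pipeline recovers, from rendered pixels alone, the oscillation
period (11 s), the per-cycle growth increment (6.33 μm), the rate extrema
(0.13 and 0.73 μm/s — a ratio above five) and the cycle-mean rate
(6.33/11 ≈ 0.58 μm/s) that characterize the 0.3 K bulk-supercooling
condition. The scripts in `examples/` walk through each capability —
rendering, velocimetry, thickness analysis, cycle statistics and the
oscillation-kinetics simulator — and print the numbers they compute.

A thin CLI wraps the same pipeline:

```sh
icefringe simulate --out video.tif --truth truth.csv --duration 60 --seed 1
icefringe analyze --video video.tif --out results/
icefringe kinetics --mode promotion --duration 120 --out traj.csv
icefringe report --video video.tif --out figures/
```

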