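"""Measure the top-face growth rate from a video by fringe velocimetry.

Kymograph (time–space image along a line crossing the fringes) → dominant
fringe spacing δ → unwrapped fringe phase → migration velocity β →
V = βλ/(2δn_w). The recovered rate is compared against the generator's
ground truth.
"""

import numpy as np

import icefringe as icf

case = icf.benchmark_case()
stack, truth = case.render(duration_s=40.0, seed=7)

line = icf.SpaceLine(case.line_xyxy[:2], case.line_xyxy[2:])
kym = icf.extract_kymograph(stack, line)
est = icf.estimate_fringe_spacing(kym)
phase = icf.extract_phase(kym, est)
beta = icf.fringe_velocity(phase)
v = icf.growth_rate_from_fringes(beta, est.delta_um, case.optics)

truth_v = np.interp(v.times_s, truth.times_s, truth.v_top_um_s)
rms = np.sqrt(np.nanmean((v.v_um_s - truth_v) ** 2)) / truth_v.mean()

print(f"kymograph:        {kym.intensity.shape[0]} rows x {kym.intensity.shape[1]} samples")
print(f"fringe spacing:   {est.delta_um:.3f} um (quality {est.quality:.0f})")
print(f"median |beta|:    {np.nanmedian(np.abs(beta.beta_um_s)):.2f} um/s lateral migration")
print(f"recovered V:      {np.nanmin(v.v_um_s):.3f} .. {np.nanmax(v.v_um_s):.3f} um/s")
print(f"RMS error vs truth: {100 * rms:.2f} %")
print()
print("V oscillates between about 0.13 and 0.73 um/s: the velocimetry resolves")
print("the slow rise and the abrupt drop of each oscillation cycle.")
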