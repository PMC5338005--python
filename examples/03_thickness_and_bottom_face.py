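"""Recover the bottom-face growth rate from the overlap-region brightness.

The overlap of the top- and bottom-face images interferes; its mean
brightness runs one full cycle per λ/(2 n_ice) of thickness growth. The
brightness-cycle frequency therefore gives dd/dt, and subtracting the
fringe-velocimetry top-face rate isolates the bottom face.
"""

import numpy as np

import icefringe as icf

case = icf.benchmark_case()
stack, truth = case.render(duration_s=40.0, seed=11)

# top face by fringe velocimetry
line = icf.SpaceLine(case.line_xyxy[:2], case.line_xyxy[2:])
kym = icf.extract_kymograph(stack, line)
est = icf.estimate_fringe_spacing(kym)
v_top = icf.growth_rate_from_fringes(
    icf.fringe_velocity(icf.extract_phase(kym, est)), est.delta_um, case.optics
)

# thickness rate from brightness extrema
b = icf.brightness_trace(stack, case.geometry.overlap_roi)
ddt = icf.thickness_rate(b, case.optics)
v_bottom = icf.bottom_face_rate(ddt, v_top)

tb = np.interp(v_bottom.times_s, truth.times_s, truth.v_bottom_um_s)
rms = np.sqrt(np.mean((v_bottom.v_um_s - tb) ** 2)) / tb.mean()

print(f"brightness extrema spacing -> dd/dt median {np.median(ddt.v_um_s):.3f} um/s")
print(f"top-face median V:    {np.nanmedian(v_top.v_um_s):.3f} um/s")
print(f"bottom-face median V: {np.median(v_bottom.v_um_s):.3f} um/s")
print(f"bottom-face RMS error vs truth: {100 * rms:.1f} %")
print(f"clipped (dd/dt < V_top) samples flagged: {int(v_bottom.flags.sum())}")
print()
print("Both basal faces grow at similar oscillating rates here, so dd/dt is")
print("about twice the single-face rate; their difference recovers the face")
print("that is not directly visible in the fringe pattern.")
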