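"""Simulate the two candidate kinetic loops behind growth-rate oscillation.

Promotion mode: adsorbed impurity molecules act as step sources, steepening
the V–ΔT_int relation as coverage builds, until the coverage collapses and
the cycle restarts — a relaxation oscillator. Inhibition mode: the classical
step-pinning picture, which with these smooth laws relaxes to a depressed
steady state instead of oscillating.
"""

import numpy as np

import icefringe as icf

for dT in (0.2, 0.3, 0.4):
    traj = icf.simulate_kinetics(icf.promotion_defaults(dT), duration_s=120.0, dt=0.01)
    sel = traj.times_s > 40.0
    v = traj.v_um_s[sel]
    events = [e for e in traj.events_s if e > 40.0]
    period = np.mean(np.diff(events))
    print(f"promotion dT_inf={dT} K: period {period:5.2f} s, "
          f"V {v.min():.3f}..{v.max():.3f} um/s, amplitude {v.max() - v.min():.3f}")

traj = icf.simulate_kinetics(icf.inhibition_defaults(0.3), duration_s=120.0, dt=0.01)
tail = traj.v_um_s[traj.times_s > 100.0]
print(f"inhibition dT_inf=0.3 K: settles at V = {tail.mean():.4f} um/s, "
      f"coverage {traj.c_int[-1]:.3f} (no sustained oscillation)")
print()
print("The promotion loop reproduces the observed phenomenology: sawtooth")
print("oscillation whose amplitude grows and period shrinks with bulk")
print("supercooling; the smooth inhibition loop merely suppresses growth.")
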