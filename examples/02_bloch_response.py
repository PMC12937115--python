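"""Bloch-simulated velocity response of a preparation pair.

Builds a velocity-selective preparation (90y — four gradient blips with
three 180x refocusing pulses — tip-up) with a 2 µT·s²/m first moment,
evolves isochromats across a velocity grid, and confirms the residual
longitudinal magnetization is cos(γ·m1·v) for the y tip-up and
sin(γ·m1·v) for the x tip-up — the quadrature pair behind the Fourier
encoding.
"""

import numpy as np

import velspec as vs
from velspec.constants import GAMMA

m1 = 2.0e-6  # T·s²/m
tc = vs.build_train(m1, max_grad=0.04, tip_axis=vs.TipAxis.cos_variant)
ts = vs.build_train(m1, max_grad=0.04, tip_axis=vs.TipAxis.sin_variant)
mom = vs.compute_effective_moments(tc)
print(f"requested m1: {m1:.3e}  achieved: {mom.m1:.6e} T·s²/m")
print(f"residual zeroth moment: {mom.m0:.2e} T·s/m")
print(f"diffusion weighting of the preparation: b = {vs.bvalue(tc):.1f} s/mm²")

v = np.linspace(-3, 3, 201)  # cm/s
curve = vs.response(tc, ts, v)
phase = GAMMA * mom.m1 * v * 0.01
print(f"max |Mz_cos − cos(γ m1 v)| over {v.size} velocities: "
      f"{np.abs(curve.mz_cos - np.cos(phase)).max():.2e}")
print(f"max |Mz_sin − sin(γ m1 v)| over {v.size} velocities: "
      f"{np.abs(curve.mz_sin - np.sin(phase)).max():.2e}")
# Errors at machine precision: ideal rotations + analytic phase accrual
# make the simulation and the analytic projection the same physics.
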