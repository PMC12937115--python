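"""Velocity k-space sampling relations.

Builds the two acquisition protocols — 31 half-Fourier encode pairs for
slow (CSF-range) flow and a 30-step asymmetric ladder for the faster
multi-tube phantom — and prints the velocity axes they imply. The bin
width is set by the extent of sampled first moments, the unaliased
half-width by the moment step size.
"""

import velspec as vs

# Human/loop protocol: 0 to m1_max in 31 steps, conjugate symmetry fills
# the negative half. Parameterized by the ±2.6 cm/s spectrum width.
human = vs.ladder_for_axis(31, "half", v_max_cm_s=2.6)
axis = vs.velocity_axis(human)
print("half-Fourier protocol (31 encode pairs):")
print(f"  bins: {axis.n_bins}")
print(f"  bin width: {axis.delta_v:.4f} cm/s")
print(f"  unaliased range: ±{axis.v_max:.2f} cm/s")
print(f"  extreme bin centers: {axis.centers[0]:.3f} .. {axis.centers[-1]:.3f} cm/s")

# Phantom protocol: 30 encodes with the zero encode at index 14, i.e. one
# extra positive moment step.
phantom = vs.ladder_for_axis(30, "asymmetric", delta_v_cm_s=(8.64 + 8.06) / 29)
axis30 = vs.velocity_axis(phantom)
print("\nasymmetric phantom protocol (30 encodes):")
print(f"  bins: {axis30.n_bins}")
print(f"  bin width: {axis30.delta_v:.3f} cm/s")
print(f"  bin centers span {axis30.centers[0]:.2f} .. {axis30.centers[-1]:.2f} cm/s")

# A 61-bin axis resolves 0.085 cm/s; velocities beyond ±v_max alias back
# into the axis modulo its full width (2·v_max).
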