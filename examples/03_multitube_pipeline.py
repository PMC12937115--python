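"""Multi-tube phantom: encode, corrupt, decode, compare with truth.

Eight parallel tubes (2.25–4.0 mm diameter) share one pressure drop, so
their mean velocities scale with diameter squared, anchored at 7.24 cm/s
for the largest. The series is encoded on the 30-step asymmetric ladder
(−8.06..+8.64 cm/s axis), corrupted with 1% complex noise, and decoded
with rephasing + Hanning window. Tubes whose laminar support exceeds the
axis half-width alias into the negative bins.
"""

import numpy as np

import velspec as vs

ladder = vs.ladder_for_axis(30, "asymmetric", delta_v_cm_s=(8.64 + 8.06) / 29)
axis = vs.velocity_axis(ladder)
phantom = vs.build_multitube(axis, shape=(48, 48, 48), model="uniform_area")

print("tube table (equal pressure drop → v_mean ∝ d²):")
for t in phantom.tubes:
    print(f"  d={t.diameter:.2f} mm  v_mean={t.v_mean:5.2f} cm/s  "
          f"v_max={t.v_max_tube:5.2f} cm/s"
          + ("  (aliases)" if t.v_max_tube > axis.centers[-1] else ""))

series = vs.forward_encode(phantom, ladder)
series = vs.corrupt(series, vs.CorruptionSpec(noise_sd=0.01, seed=1))
image = vs.reconstruct(series, vs.ReconConfig(detrend_order=None, window="hanning"))

nz = phantom.shape[0]
print("\nper-tube ROI recovery (central 3 slices, windowed truth):")
for i, t in enumerate(phantom.tubes):
    mask = np.zeros(phantom.shape, bool)
    mask[nz // 2 - 1 : nz // 2 + 2] = (phantom.tube_fractions[i] >= 0.5)[None]
    mask &= phantom.in_phantom
    roi = vs.roi_spectrum(image, mask)
    truth = phantom.densities[mask].mean(0)
    wtruth = vs.windowed_density(vs.DensityVector(axis=axis, fractions=truth / truth.sum()))
    corr = np.corrcoef(roi.fractions, wtruth.fractions)[0, 1]
    neg = roi.fractions[axis.centers < -axis.delta_v / 2].sum()
    print(f"  d={t.diameter:.2f} mm  corr={corr:.4f}  negative-bin mass={neg:.3f}")
# High correlations show the decoded spectra match the laminar truth;
# the fastest tubes' negative-bin mass is the aliased tail of their
# velocity distribution, not reversed flow.
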