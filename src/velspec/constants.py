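"""Physical constants and unit conversions.

Internal unit system is SI throughout: gradients in T/m, time in s,
velocity in m/s, moments in T·s²/m, phase in rad. User-facing interfaces
(configs, CSV, printed tables) use the conventional MR units G/cm and cm/s
and are converted at the boundary.
"""

#: Proton gyromagnetic ratio, rad / s / T.
GAMMA = 2.6752218744e8

#: 1 G/cm in T/m.
G_PER_CM = 0.01

#: 1 cm/s in m/s.
CM_PER_S = 0.01


def gcm_to_si(g: float) -> float:
    """Gradient amplitude G/cm -> T/m."""
    return g * G_PER_CM


def cms_to_si(v: float) -> float:
    """Velocity cm/s -> m/s."""
    return v * CM_PER_S


def si_to_cms(v: float) -> float:
    """Velocity m/s -> cm/s."""
    return v / CM_PER_S
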