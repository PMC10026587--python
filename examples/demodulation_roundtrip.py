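"""Demodulate a polarization modulation series back to its parameters.

Renders one pixel's intensity under ten polarizer angles (18-degree
steps) from known parameters, adds camera noise, and inverts the
modulation law by closed-form harmonic regression.
"""

import numpy as np

from pimidetect import demodulate_series, forward_intensity

angles = np.arange(10) * 18.0
true = dict(i0=1200.0, sindelta=0.62, phi_deg=34.0)

rng = np.random.default_rng(42)
series = forward_intensity(true["i0"], true["sindelta"], true["phi_deg"], angles)
noisy = series + rng.normal(0.0, 2.0, angles.size)  # 2 counts of read noise

r = demodulate_series(noisy, angles)
print(f"true:      i0={true['i0']:.1f}  sindelta={true['sindelta']:.4f}  phi={true['phi_deg']:.2f} deg")
print(f"recovered: i0={r.i0:.1f}  sindelta={r.sindelta:.4f}  phi={r.phi_deg:.2f} deg")
print(f"residual RMS: {r.residual_rms:.3f} counts")
print()
print("i0 is twice the mean frame level, sindelta the modulation depth")
print("(sine of the phase difference between the orthogonal polarization")
print("components), phi the ellipse orientation; the residual shows the")
print("per-pixel misfit, here at the injected noise level.")
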