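"""The four surrogate derivatives of the spike threshold.

Each family is a unit-mass bump centred on the firing threshold; its value
at a membrane potential u is the weight that potential receives in the
backward pass.  All four integrate to one and converge to a Dirac impulse
as the steepness parameter a shrinks.
"""

import numpy as np

from stbp import FAMILIES, SurrogateSpec, dirac_limit_check, surrogate_eval, surrogate_integral

V_TH = 1.5
print(f"{'family':12s} {'peak h(v_th)':>12s} {'integral':>10s}")
for family in FAMILIES:
    spec = SurrogateSpec(family, a=1.0, v_th=V_TH)
    peak = float(surrogate_eval(V_TH, spec))
    mass = surrogate_integral(spec)
    print(f"{family:12s} {peak:12.4f} {mass:10.6f}")

print("\nDirac-limit check: smoothing cos(u - v_th) against the Gaussian")
print("family must approach cos(0) = 1 as a -> 0 (closed form exp(-a/2)):")
a_seq = [1.0, 0.1, 0.01]
vals = dirac_limit_check("gaussian", lambda u: np.cos(u - V_TH), a_seq, v_th=V_TH)
for a, v in zip(a_seq, vals):
    print(f"  a={a:5.2f}: smoothed value {v:.6f}  (exp(-a/2) = {np.exp(-a/2):.6f})")
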