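"""Audit the backward pass against central finite differences.

Replacing the hard spike threshold with each surrogate's smooth
antiderivative makes the network differentiable; the spatio-temporal
backward recursion is then the exact gradient, so central differences of
the relaxed loss are an independent oracle.  Relative errors near 1e-10
mean the recursion and its implementation are correct; anything above 1e-5
would indicate a missing or mis-indexed term.
"""

from stbp import FAMILIES, LIFConfig, SurrogateSpec, gradient_check, parse_architecture

cases = [
    ("dense 4-6-3, T=5", parse_architecture("4-6-3"), 5),
    ("conv 6x6x1-2C3-P2-3, T=3", parse_architecture("6x6x1-2C3-P2-3"), 3),
]
for name, chain, T in cases:
    print(name)
    for family in FAMILIES:
        errs = [
            gradient_check(
                chain, LIFConfig(tau=0.1, v_th=1.5, T=T), SurrogateSpec(family, 1.0), seed=s
            )
            for s in range(5)
        ]
        print(f"  {family:12s} max relative error over 5 seeds: {max(errs):.3e}")
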