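"""Closed-form maximal scalp-elevation height.

A scalp wound wider than 41 mm is hard to close, so the defect-margin
arc can stretch by at most 4.1 mm on the model scale.  Stretching the
approximate ellipse perimeter 2*pi*b + 4*(a - b) by that amount bounds
how high the scalp can be elevated over the defect.
"""

import craniosim as cs

# semi-axes of the scalp arc construction: a = anteroposterior (major),
# b = lateral (minor); pi fixed at 3.14 to reproduce the worked example
a_ap, b_lat, pi = 75.0, 65.0, 3.14

X = cs.ellipse_perimeter_approx(a_ap, b_lat, pi) / 2.0
K = cs.scalp_elevation_K(cs.ScalpFormulaInput(a_ap=a_ap, b_lat=b_lat, X=X, pi_const=pi))

print(f"defect-margin arc length X = {X:.1f} mm (half the approximate perimeter)")
print(f"maximal scalp-elevation height K = {K:.3f} mm")

# K ~ 3.6 mm is what scalp laxity alone allows for a general skull: a
# useful lower bound compared with the 6 mm elevation at which volume
# gains become clinically meaningful.
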