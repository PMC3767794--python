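"""Build the growth-quantifier columns for a season's sampling dates.

Evaluates dimensionless time x, erf x, exp(-x^2) and the leaf/structural/
total quantifiers at the Alabama sampling dates under the shared calibration
(t_ref = 21.2 wk, tau = 8.0 wk, k = 9).  Q is the dimensionless cumulative
growth driver; biomass follows as Y = A*Q once the yield factor A is fitted.
"""

import math

from growthquant import GrowthParams, quantifier_at_time

params = GrowthParams()
times = [21.6, 23.7, 25.9, 28.0, 30.3, 32.4, 34.7, math.inf]

print(f"{'t (wk)':>8} {'x':>7} {'erf x':>7} {'exp(-x^2)':>10} "
      f"{'Q_L':>7} {'Q_S':>7} {'Q':>7}")
for t in times:
    p = quantifier_at_time(t, params)
    label = "inf" if math.isinf(t) else f"{t:.1f}"
    print(f"{label:>8} {p.x:7.3f} {p.erf_x:7.3f} {p.gauss_x:10.4f} "
          f"{p.q_leaf:7.3f} {p.q_struct:7.3f} {p.q_total:7.3f}")

print("\nThe final row is the seasonal limit: Q_L -> 1, Q_S -> k/sqrt(pi)"
      " = 5.08, so a crop with yield factor A tops out at 6.08*A Mg/ha.")
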