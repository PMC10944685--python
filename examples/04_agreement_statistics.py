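"""Agreement statistics on a hand-made rating table.

Shows the weighted-kappa / ICC machinery on its own: a small set of
actual-vs-predicted frailty ratings, the quadratic-weight formula, the
percentile bootstrap, and the interpretation bands.
"""

import numpy as np

from frailgait import RatingSet, bootstrap_ci, icc, interpret_band, weighted_kappa

rng = np.random.default_rng(0)
actual = rng.integers(3, 7, size=150)
# predictions agree mostly, with occasional one-level slips
slip = rng.choice([-1, 0, 0, 0, 0, 1], size=150)
predicted = np.clip(actual + slip, 3, 6)

r = RatingSet(actual, predicted)
kappa = weighted_kappa(r, weights="quadratic")
ic = icc(r)
lo, hi = bootstrap_ci(r, weighted_kappa, n_boot=1000, seed=0)

print(f"n = {len(r)} rating pairs over categories {r.categories}")
print(f"quadratic weighted kappa: {kappa:.3f} "
      f"(95% bootstrap CI {lo:.3f}-{hi:.3f})")
print(f"ICC(2,1):                 {ic:.3f}")
print(f"interpretation: {interpret_band(kappa)!r}")
# With one-level slips on an ordinal scale the quadratic weights punish
# disagreement by squared distance, and kappa tracks ICC closely.
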