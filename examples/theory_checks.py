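"""Numerical checks of the combinatorial theory behind the linear band.

1. The probability that a fixed set U of r samples is contained in a
   without-replacement subsample of size floor(gamma*n) is a hypergeometric
   ratio that approaches gamma^r as n grows.
2. On a mock harness where one feature enters the path exactly when U is
   contained in the subsample, the log of its score falls linearly in r
   with slope log(gamma) — which is why the middle of the sorted log-score
   curve is a straight line, and why everything on it can be discarded.
"""

import numpy as np

from fealect import OverfitSpec, inclusion_probability_exact, mock_overfit_score

gamma, r = 0.75, 3
print(f"Pr(U in B) for r={r}, gamma={gamma} (limit gamma^r = {gamma**r:.6f}):")
for n in (20, 40, 80, 160, 320):
    p = inclusion_probability_exact(n, r, gamma)
    print(f"  n={n:4d}: exact={p:.6f}  |error|={abs(p - gamma**r):.6f}")

print("\nmock over-fit harness, n=400, m=20000 subsamples:")
logs = []
rs = range(1, 7)
for rr in rs:
    s = mock_overfit_score(OverfitSpec(frozenset(range(rr))), n=400, gamma=gamma,
                           m=20_000, K=5, seed=100 + rr)
    logs.append(np.log(s))
    print(f"  r={rr}: score={s:.4f}  log={logs[-1]:+.4f}")
slope = np.polyfit(list(rs), logs, 1)[0]
print(f"OLS slope of log(score) vs r = {slope:.4f} "
      f"(theory: log(gamma) = {np.log(gamma):.4f})")
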