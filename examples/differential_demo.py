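"""Moderated t-test with permutation FDR on a simulated intensity matrix.

Builds a 500-item matrix (6 runs per group) with 50 items shifted by 4
standard deviations, then shows that the permutation-calibrated cutoff
recovers the planted items without false calls.
"""

import numpy as np
import pandas as pd

from plateau import DifferentialConfig, permutation_fdr

rng = np.random.default_rng(0)
cols_a = [f"ctrl_{i}" for i in range(6)]
cols_b = [f"treat_{i}" for i in range(6)]
x = rng.normal(20, 1, size=(500, 12))
x[:50, 6:] += 4.0  # planted up-shift in the treatment group
matrix = pd.DataFrame(x, columns=cols_a + cols_b,
                      index=[f"item{i:03d}" for i in range(500)])

results = permutation_fdr(matrix, cols_a, cols_b,
                          DifferentialConfig(s0=0.2, fdr=0.01, seed=0))
called = [r for r in results if r.significant]
true_pos = sum(1 for r in called if int(r.item_id[4:]) < 50)
print(f"called {len(called)} of 500 items at FDR 0.01")
print(f"{true_pos}/50 planted shifts recovered; "
      f"{len(called) - true_pos} false calls")
print("top hits:")
for r in sorted(called, key=lambda r: -abs(r.t))[:5]:
    print(f"  {r.item_id}  diff={r.diff:+.2f}  t={r.t:+.2f}  {r.direction}")
# diff is in log2 units; the fuzz constant s0 keeps tiny absolute changes
# with accidentally small variance from dominating the ranking.
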