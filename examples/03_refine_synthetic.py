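"""Structural refinement of a synthetic pump-probe dataset.

Simulates a reduced dataset (11 delays) in acetonitrile with 1% noise,
refines every time point, and prints the recovered interfragment
distance r23(t) and the geminate-pair fraction next to the ground
truth. Takes about a minute; the full 41-delay study is run by
scripts/acceptance.py.
"""

import numpy as np

from trixs import RefinementConfig, refine_series
from trixs.scenario import default_scenario

t = np.array([-0.1, 0.05, 0.15, 0.25, 0.35, 0.45, 0.7, 1.0, 3.0, 20.0, 200.0])
sc = default_scenario(seed=11, t=t)
res = refine_series(sc.dataset, sc.fm, RefinementConfig(restarts=4, seed=1))

truth = sc.truth_array
print(f"{'t (ps)':>8} {'r23 fit':>8} {'r23 true':>9} {'A_GP fit':>9} {'A_GP true':>10}")
for i, ti in enumerate(t):
    print(
        f"{ti:8.2f} {res.column('r23')[i]:8.3f} {truth[i, 1]:9.3f}"
        f" {res.column('A_GP')[i]:9.3f} {truth[i, 4]:10.3f}"
    )
print("chi2 per point:", np.round(res.chi2 / (2 * len(sc.q)), 2))
# r23 rises ballistically to the cage-arrest distance (~5.5 A) within
# 0.4 ps, then relaxes to the geminate-pair plateau near 4 A; A_GP
# decays as geminate pairs recombine.
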