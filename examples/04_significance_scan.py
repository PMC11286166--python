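"""Full observed-vs-predicted significance scan of a synthetic surface.

Plants 10 conga chains (12 mm spacing, 5 deg bearing jitter) on a clustered
background, then runs the whole inference: background-model selection,
alignment counting for r = 5..50 mm, Poisson tail probabilities, and the
derived ranges of r with significantly more (or fewer) alignments than
chance predicts.
"""

import warnings

import numpy as np

from congalines import ThomasParams, Window, generate_conga_surface, scan

window = Window(np.array([[0, 0], [2, 0], [2, 2], [0, 2]], dtype=float))
background = ThomasParams(kappa=18.0, mu=6.0, sigma=0.07263)
surface, truth = generate_conga_surface(
    background, window, n_chains=10, seed=11, spacing=0.012, jitter_deg=5.0
)
print(f"{surface.n} points, {truth.n_planted_triples} planted triples")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = scan(surface, theta_deg=30.0, seed=12, m_gof=99)

print(f"selected background: {result.selection.selected}")
print(" r(mm)  observed  expected   p(more)")
for row in result.rows:
    if row.r_mm in (5, 10, 12, 15, 20, 30, 40, 50):
        print(f"{row.r_mm:6.0f}  {row.observed:8d}  {row.expected:8.2f}"
              f"   {row.p_upper:.2e}")
print(f"\nsignificantly MORE than predicted (r in mm): {result.range_str('more')}")
print(f"significantly FEWER than predicted:           {result.range_str('fewer')}")
print("\nThe 'more' range starts at the planted spacing: below 12 mm the")
print("planted chains are invisible to the detector, above it they dominate chance.")
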