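"""Diel activity overlap between a crepuscular and a cathemeral predator.

Draws capture times from von Mises mixtures — a dawn/dusk two-peak
pattern for species A, a flatter day-shifted pattern for species B —
estimates each species' circular kernel density, and prints the Delta-1
coefficient of overlap (0 = activity never coincides, 1 = identical
activity patterns).
"""

import numpy as np

from sympatric import MixtureSpec, activity_overlap_pipeline, simulate_activity

crepuscular = MixtureSpec(means=(np.pi / 2, 3 * np.pi / 2),   # 06:00 and 18:00
                          kappas=(3.0, 3.0), weights=(0.5, 0.5))
cathemeral = MixtureSpec(means=(np.pi,), kappas=(0.6,), weights=(1.0,))

angles_a = simulate_activity(crepuscular, n=250, seed=5, stream=0)
angles_b = simulate_activity(cathemeral, n=180, seed=5, stream=1)

res = activity_overlap_pipeline(angles_a, angles_b,
                                species_a="snow_leopard", species_b="woolly_wolf",
                                season="winter", adjust=0.8, grid_n=128)
print(res)
print(f"kernel concentrations: {res.density_a.kappa:.2f} / {res.density_b.kappa:.2f}")

# Delta-1 integrates the pointwise minimum of the two activity densities
# around the clock; ~0.7-0.8 here means the pair is active at largely the
# same hours despite the different pattern shapes.
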