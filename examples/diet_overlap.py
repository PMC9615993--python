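"""Dietary niche overlap from the reported scat-survey tables.

Loads the bundled frequency-of-occurrence tables for the two predator
pairs of the Upper Bhagirathi basin and prints Pianka's niche-overlap
index for each pair, plus an illustrative relative-biomass conversion
using the example (synthetic) prey-mass configuration.
"""

from importlib import resources

import pandas as pd

from sympatric import biomass_factor, pianka, relative_biomass
from sympatric.diet import read_prey_masses
from sympatric.reference_tables import load_fo_table

gh = load_fo_table("greater_himalaya")
th = load_fo_table("trans_himalaya")
print("Pianka overlap, snow leopard vs common leopard (greater Himalaya):",
      f"{pianka(gh['snow_leopard'], gh['common_leopard']):.3f}")
print("Pianka overlap, snow leopard vs woolly wolf (trans-Himalaya):     ",
      f"{pianka(th['snow_leopard'], th['woolly_wolf']):.3f}")

# Relative biomass re-weights FO by the predator-specific biomass-per-scat
# regression Y(X); the shipped masses are illustrative, not the study's.
with resources.as_file(
    resources.files("sympatric").joinpath("data/prey_masses_example.yaml")
) as p:
    masses = read_prey_masses(p)
fo = th["woolly_wolf"]
y = pd.Series({prey: biomass_factor("woolly_wolf", masses[prey]) for prey in fo.index})
print("\nwoolly wolf relative biomass % (illustrative masses):")
print(relative_biomass(fo, y).round(2).to_string())
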