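"""Reported diet tables from the Upper Bhagirathi basin scat surveys.

Percent frequency of occurrence of prey categories in genetically
confirmed scats, as published for the two predator pairs of the study
area: snow leopard vs common leopard in the greater Himalayan habitat
(39 and 24 scats) and snow leopard vs woolly wolf in the Trans-Himalayan
habitat (15 and 32 scats).  Prey absent from a predator's diet are
recorded as 0.  These tables are inputs for dietary-overlap
computations, e.g. Pianka's index between the two FO columns.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_fo_table", "REGIONS"]

REGIONS = ("greater_himalaya", "trans_himalaya")


def load_fo_table(region: str) -> pd.DataFrame:
    """Load the per-region FO table, prey-indexed, one column per predator."""
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
    ref = resources.files("sympatric").joinpath(f"data/diet_fo_{region}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, index_col="prey")
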