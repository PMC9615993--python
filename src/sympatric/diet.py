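"""Scat-based diet analysis: frequency of occurrence, biomass, niche overlap.

Scats identified to a predator are scored for the prey categories they
contain.  The utilization rate of prey i is its frequency of occurrence
F_i = 100 * n_i / N (n_i scats containing i, N scats analyzed), with a
bias-corrected bootstrap percentile interval.  Because occurrence
understates large prey, F is converted to relative biomass through a
predator-specific regression Y(X) for the biomass of prey consumed per
collectable scat, X being the prey's mean body mass (kg):

    snow leopard    Y = 1.980 + 0.035 X
    woolly wolf     Y = 0.439 + 0.008 X
    common leopard  Y = 2.171 - 1.671 exp(-0.056 X)

Dietary overlap between predators j and k is Pianka's index, the cosine
similarity of their prey-use proportion vectors:

    O_jk = sum_i p_ij p_ik / sqrt(sum_i p_ij^2 * sum_i p_ik^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ScatTable",
    "PREDATORS",
    "frequency_of_occurrence",
    "bootstrap_fo",
    "biomass_factor",
    "relative_biomass",
    "pianka",
    "diet_summary",
    "read_scats",
    "read_prey_masses",
]

PREDATORS = ("snow_leopard", "woolly_wolf", "common_leopard")


@dataclass
class ScatTable:
    """Scat-by-prey incidence records.

    ``df`` has one row per (scat, prey) pair with columns scat_id,
    predator, prey and optionally region.  Every scat carries >= 1 prey
    category; a scat with several rows is a multi-prey scat.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"scat_id", "predator", "prey"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"scat table missing column(s): {sorted(missing)}")
        per_scat = self.df.groupby("scat_id")["predator"].nunique()
        if (per_scat > 1).any():
            bad = per_scat[per_scat > 1].index.tolist()
            raise ValueError(f"scat_id assigned to multiple predators: {bad}")
        dup = self.df.duplicated(["scat_id", "prey"])
        if dup.any():
            raise ValueError("duplicate (scat_id, prey) rows")

    def for_predator(self, predator: str) -> pd.DataFrame:
        return self.df[self.df["predator"] == predator]

    def n_scats(self, predator: str) -> int:
        return self.for_predator(predator)["scat_id"].nunique()

    def incidence(self, predator: str) -> pd.DataFrame:
        """Scats x prey 0/1 incidence matrix for one predator."""
        sub = self.for_predator(predator)
        if sub.empty:
            raise ValueError(f"no scats for predator {predator!r}")
        return (
            pd.crosstab(sub["scat_id"], sub["prey"]).astype(bool).astype(int)
        )


def frequency_of_occurrence(scats: ScatTable, predator: str) -> pd.Series:
    """Percent frequency of occurrence per prey: F_i = 100 * n_i / N.

    Multi-prey scats count once toward each prey they contain, so the
    column can sum past 100% exactly when such scats exist.
    """
    inc = scats.incidence(predator)
    return 100.0 * inc.mean(axis=0).rename("fo_percent")


def bootstrap_fo(
    scats: ScatTable,
    predator: str,
    n_iter: int = 10_000,
    seed: int | None = None,
    mass: float = 0.95,
) -> pd.DataFrame:
    """Bootstrap mean and bias-corrected percentile CI for each prey's FO%.

    Scats are resampled with replacement at the original sample size
    ``n_iter`` times.  The bias correction shifts the percentile levels
    by z0 = Phi^-1(fraction of bootstrap values below the point
    estimate); prey found in every scat or in none get a degenerate
    interval at the estimate.
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is very low for a bootstrap", stacklevel=2)
    inc = scats.incidence(predator).to_numpy()
    n, n_prey = inc.shape
    if n < 2:
        raise ValueError("need >= 2 scats to bootstrap")
    point = 100.0 * inc.mean(axis=0)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_iter, n))
    boots = 100.0 * inc[idx].mean(axis=1)  # (n_iter, n_prey)

    alpha = 1 - mass
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    lo = np.empty(n_prey)
    hi = np.empty(n_prey)
    for j in range(n_prey):
        if point[j] in (0.0, 100.0):
            lo[j] = hi[j] = point[j]
            continue
        frac_below = np.mean(boots[:, j] < point[j])
        # guard: z0 undefined if the bootstrap never (or always) undershoots
        frac_below = min(max(frac_below, 1 / (2 * n_iter)), 1 - 1 / (2 * n_iter))
        z0 = norm.ppf(frac_below)
        q_lo, q_hi = norm.cdf(2 * z0 + z_lo), norm.cdf(2 * z0 + z_hi)
        lo[j], hi[j] = np.quantile(boots[:, j], [q_lo, q_hi])
    prey = scats.incidence(predator).columns
    return pd.DataFrame(
        {"fo_percent": point, "boot_mean": boots.mean(axis=0), "ci_low": lo, "ci_high": hi},
        index=prey,
    )


_BIOMASS_MODELS = {
    "snow_leopard": lambda x: 1.980 + 0.035 * x,
    "woolly_wolf": lambda x: 0.439 + 0.008 * x,
    "common_leopard": lambda x: 2.171 - 1.671 * np.exp(-0.056 * x),
}


def biomass_factor(predator: str, prey_mass_kg: float) -> float:
    """Biomass of prey consumed per collectable scat, Y(X).

    Linear in prey mass for the two linear-regression predators, a
    saturating exponential for the common leopard.  X = 0 is allowed for
    analytic checks only; field masses are positive.
    """
    if predator not in _BIOMASS_MODELS:
        raise ValueError(f"unknown predator {predator!r}; expected one of {PREDATORS}")
    x = float(prey_mass_kg)
    if x < 0:
        raise ValueError("prey mass must be non-negative")
    return float(_BIOMASS_MODELS[predator](x))


def relative_biomass(fo: pd.Series, y: pd.Series) -> pd.Series:
    """Prey-wise biomass share (%): B_i = 100 * F_i Y_i / sum_j F_j Y_j."""
    fo, y = fo.align(y, join="inner")
    if fo.empty:
        raise ValueError("no shared prey categories between FO and Y")
    w = fo * y
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero frequency of occurrence")
    return (100.0 * w / total).rename("relative_biomass_percent")


def pianka(p_j, p_k) -> float:
    """Pianka's niche overlap index — cosine similarity of use vectors.

    Inputs are non-negative proportion (or FO) vectors over a shared,
    aligned prey vocabulary; absent categories enter as zero.  The index
    is symmetric and invariant to rescaling either vector.
    """
    if isinstance(p_j, pd.Series) and isinstance(p_k, pd.Series):
        union = p_j.index.union(p_k.index)
        p_j = p_j.reindex(union, fill_value=0.0)
        p_k = p_k.reindex(union, fill_value=0.0)
    a = np.asarray(p_j, dtype=float)
    b = np.asarray(p_k, dtype=float)
    if a.shape != b.shape:
        raise ValueError("prey vectors not aligned")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative entries in prey-use vector")
    na, nb = np.sqrt((a ** 2).sum()), np.sqrt((b ** 2).sum())
    if na == 0 or nb == 0:
        raise ValueError("zero prey-use vector")
    return float((a * b).sum() / (na * nb))


def diet_summary(
    scats: ScatTable,
    predator: str,
    prey_masses: dict[str, float],
    n_iter: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-prey FO%, bootstrap CI, Y factor and relative biomass %."""
    table = bootstrap_fo(scats, predator, n_iter=n_iter, seed=seed)
    missing = [p for p in table.index if p not in prey_masses]
    if missing:
        raise ValueError(f"no body mass configured for prey: {missing}")
    y = pd.Series({p: biomass_factor(predator, prey_masses[p]) for p in table.index})
    table["biomass_factor"] = y
    table["relative_biomass_percent"] = relative_biomass(table["fo_percent"], y)
    return table


# ---------------------------------------------------------------------------
# IO

def read_scats(path) -> ScatTable:
    """Read scat CSV with one row per (scat_id, prey) pair."""
    return ScatTable(pd.read_csv(path, dtype={"scat_id": str}))


def read_prey_masses(path) -> dict[str, float]:
    """Read a prey body-mass config: YAML mapping or CSV (prey,mass_kg)."""
    import yaml

    text = open(path).read()
    if str(path).endswith((".yml", ".yaml")):
        data = yaml.safe_load(text)
        masses = {str(k): float(v) for k, v in data.items()}
    else:
        df = pd.read_csv(path)
        masses = dict(zip(df["prey"].astype(str), df["mass_kg"].astype(float)))
    for k, v in masses.items():
        if v <= 0:
            raise ValueError(f"prey mass must be > 0: {k}={v}")
    return masses
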