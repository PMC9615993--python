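"""Bayesian conditional two-species occupancy with a species interaction factor.

The model is the single-season conditional parameterization for a dominant
species A and a subordinate species B.  Site-level occupancy states
(zA, zB) follow

    zA ~ Bernoulli(psiA)
    zB | zA=1 ~ Bernoulli(psiBA)        zB | zA=0 ~ Bernoulli(psiBa)

and detection is Bernoulli per surveyed occasion given presence, with
probability pA (resp. pB).  An optional conditional-detection variant uses
rA for A and rBA / rBa for B on occasions where both species are present
(rBA when A was detected on that occasion, rBa when it was not).

The species interaction factor is

    SIF = psiA * psiBA / (psiA * psiB),   psiB = psiA*psiBA + (1-psiA)*psiBa,

the ratio of joint occupancy to the product of the marginals: 1 means the
two species occupy sites independently, < 1 avoidance, > 1 aggregation.

Fitting is by data-augmented Gibbs sampling: all five (or eight)
probability parameters have Beta full conditionals under Uniform(0, 1)
priors once the latent z field is imputed, so the sampler needs no
tuning.  A marginal maximum-likelihood fit is provided as a frequentist
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .detection import DetectionPair

__all__ = [
    "TwoSpeciesParams",
    "GibbsResult",
    "PosteriorSummary",
    "site_likelihood",
    "gibbs_sampler",
    "compute_sif",
    "hdi",
    "rhat",
    "ml_fit",
    "summarize_posterior",
]


@dataclass(frozen=True)
class TwoSpeciesParams:
    """Parameter vector of the conditional two-species occupancy model.

    psiA    occupancy of the dominant species
    psiBA   occupancy of the subordinate given the dominant is present
    psiBa   occupancy of the subordinate given the dominant is absent
    pA, pB  per-occasion detection probabilities
    rA, rBA, rBa  detection at sites where both species are present
            (conditional-detection variant; default to pA / pB / pB,
            i.e. detection independent of the other species)
    """

    psiA: float
    psiBA: float
    psiBa: float
    pA: float
    pB: float
    rA: float | None = None
    rBA: float | None = None
    rBa: float | None = None

    def __post_init__(self) -> None:
        for name in ("psiA", "psiBA", "psiBa", "pA", "pB"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")
        for name in ("rA", "rBA", "rBa"):
            v = getattr(self, name)
            if v is not None and not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")

    @property
    def psiB(self) -> float:
        """Marginal occupancy of the subordinate species."""
        return self.psiA * self.psiBA + (1 - self.psiA) * self.psiBa

    @property
    def sif(self) -> float:
        return compute_sif(self.psiA, self.psiBA, self.psiBa)

    def effective(self) -> "TwoSpeciesParams":
        """Resolve the conditional-detection defaults rA=pA, rBA=rBa=pB."""
        return replace(
            self,
            rA=self.rA if self.rA is not None else self.pA,
            rBA=self.rBA if self.rBA is not None else self.pB,
            rBa=self.rBa if self.rBa is not None else self.pB,
        )


def compute_sif(psiA: float, psiBA: float, psiBa: float) -> float:
    """Species interaction factor: joint occupancy over product of marginals.

    SIF = psiBA / psiB with psiB = psiA*psiBA + (1-psiA)*psiBa.  Equals 1
    when psiBA == psiBa (independence), < 1 for avoidance, > 1 for
    aggregation.  psiBa = 0 is tolerated (SIF -> 1/psiA) but
    psiBA = psiBa = 0 has no defined marginal and raises.
    """
    psiA, psiBA, psiBa = float(psiA), float(psiBA), float(psiBa)
    psiB = psiA * psiBA + (1 - psiA) * psiBa
    if psiB == 0:
        raise ValueError("SIF undefined: subordinate marginal occupancy is zero")
    return psiBA / psiB


def _row_detection_prob(row: np.ndarray, p: float) -> float:
    """P(history row | species present) under constant detection p."""
    obs = row[~np.isnan(row)]
    d = obs.sum()
    return p ** d * (1 - p) ** (obs.size - d)


def site_likelihood(
    params: TwoSpeciesParams, histA: np.ndarray, histB: np.ndarray
) -> float:
    """Marginal probability of one site's paired detection history.

    Sums over the four latent occupancy states (zA, zB), with occupancy
    weights psiA*psiBA, psiA*(1-psiBA), (1-psiA)*psiBa, (1-psiA)*(1-psiBa)
    and Bernoulli detection over the non-missing occasions.  An absent
    species contributes probability 1 to an all-zero history and 0 to any
    history with a detection.  Missing occasions must be missing in both
    histories.
    """
    histA = np.asarray(histA, dtype=float)
    histB = np.asarray(histB, dtype=float)
    if histA.shape != histB.shape:
        raise ValueError("histories differ in length")
    if not np.array_equal(np.isnan(histA), np.isnan(histB)):
        raise ValueError("histories differ in missing pattern")
    if np.nanmax(histA, initial=0) > 1 or np.nanmax(histB, initial=0) > 1:
        raise ValueError("detection histories must be binary (collapse counts first)")

    e = params.effective()
    seenA = np.nansum(histA) > 0
    seenB = np.nansum(histB) > 0
    obs = ~np.isnan(histA)
    yA, yB = histA[obs], histB[obs]

    total = 0.0
    for zA in (0, 1):
        for zB in (0, 1):
            w = (e.psiA if zA else 1 - e.psiA) * (
                (e.psiBA if zB else 1 - e.psiBA)
                if zA
                else (e.psiBa if zB else 1 - e.psiBa)
            )
            if zA == 0 and seenA:
                continue
            if zB == 0 and seenB:
                continue
            pA_eff = e.rA if (zA and zB) else e.pA
            if zA:
                dA = yA.sum()
                like_A = pA_eff ** dA * (1 - pA_eff) ** (yA.size - dA)
            else:
                like_A = 1.0
            if zB:
                if zA:
                    # B's detection may depend on whether A was detected
                    pb = np.where(yA > 0, e.rBA, e.rBa)
                    like_B = float(np.prod(np.where(yB > 0, pb, 1 - pb)))
                else:
                    like_B = _row_detection_prob(histB, e.pB)
            else:
                like_B = 1.0
            total += w * like_A * like_B
    return float(total)


# ---------------------------------------------------------------------------
# Gibbs sampler

@dataclass
class GibbsResult:
    """Post-burn-in draws, shaped (chains, iterations) per parameter."""

    draws: dict[str, np.ndarray]
    burn_in: int
    seed: int | None

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """One row per kept draw, chain-tagged."""
        names = list(self.draws)
        n_chains, n_iter = self.draws[names[0]].shape
        data = {"chain": np.repeat(np.arange(n_chains), n_iter)}
        for k in names:
            data[k] = self.draws[k].reshape(-1)
        return pd.DataFrame(data)


def _prepare(pair: DetectionPair):
    A, B = pair.matrix_A, pair.matrix_B
    if A.size == 0:
        raise ValueError("empty detection pair")
    obs = ~np.isnan(A)
    effort = obs.sum(axis=1)
    if effort.sum() == 0:
        raise ValueError("all occasions missing; nothing to fit")
    dA = np.nansum(A, axis=1)
    dB = np.nansum(B, axis=1)
    if dA.sum() == 0:
        warnings.warn("species A never detected; posterior is prior-driven", stacklevel=3)
    if dB.sum() == 0:
        warnings.warn("species B never detected; posterior is prior-driven", stacklevel=3)
    return A, B, obs, effort, dA, dB


def gibbs_sampler(
    pair: DetectionPair,
    chains: int = 3,
    burn_in: int = 10_000,
    iterations: int = 1_000,
    seed: int | None = None,
    conditional_detection: bool = False,
) -> GibbsResult:
    """Data-augmented Gibbs sampler under Uniform(0, 1) priors.

    Each chain alternates (i) drawing every site's latent states zA, zB
    from their full conditionals given the detection histories and the
    current parameters, and (ii) drawing each probability parameter from
    its Beta full conditional given the z field (a uniform prior is
    Beta(1, 1), so the update is Beta(1 + successes, 1 + failures)).
    Chains are independently seeded substreams of ``seed``; only
    post-burn-in draws are returned.  A per-draw ``SIF`` series is
    included in the result.
    """
    A, B, obs, effort, dA, dB = _prepare(pair)
    seenA, seenB = dA > 0, dB > 0
    n_sites = pair.n_sites
    # per-site sufficient statistics; bA1 = occasions with both detected
    bA1 = (np.nan_to_num(A) * np.nan_to_num(B)).sum(axis=1)
    stats = dict(effort=effort, dA=dA, dB=dB, bA1=bA1, seenA=seenA, seenB=seenB)

    names = ["psiA", "psiBA", "psiBa", "pA", "pB"]
    if conditional_detection:
        names += ["rA", "rBA", "rBa"]
    names.append("SIF")
    out = {k: np.empty((chains, iterations)) for k in names}

    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(ss)
        th = {k: rng.uniform() for k in names if k != "SIF"}
        zA = seenA.astype(float) + (~seenA) * rng.binomial(1, 0.5, n_sites)
        zB = seenB.astype(float) + (~seenB) * rng.binomial(1, 0.5, n_sites)

        for it in range(burn_in + iterations):
            zA, zB = _update_z(rng, th, zA, zB, stats, conditional_detection)
            _update_params(rng, th, zA, zB, stats, conditional_detection)
            if it >= burn_in:
                j = it - burn_in
                for k, v in th.items():
                    out[k][c, j] = v
                out["SIF"][c, j] = compute_sif(th["psiA"], th["psiBA"], th["psiBa"])
    return GibbsResult(out, burn_in, seed)


def _binom(p, k, n):
    return p ** k * (1 - p) ** (n - k)


def _likeB_both(th, stats):
    """P(B history | both present): B detection split by A's occasion outcome."""
    dA, dB, effort, bA1 = stats["dA"], stats["dB"], stats["effort"], stats["bA1"]
    return _binom(th["rBA"], bA1, dA) * _binom(th["rBa"], dB - bA1, effort - dA)


def _update_z(rng, th, zA, zB, stats, cond):
    effort, dA, dB = stats["effort"], stats["dA"], stats["dB"]
    seenA, seenB = stats["seenA"], stats["seenB"]
    n = zA.size
    pA, pB = th["pA"], th["pB"]

    # --- zA, holding zB (seen sites forced to 1)
    if cond:
        likeA1 = np.where(zB > 0, _binom(th["rA"], dA, effort), _binom(pA, dA, effort))
        likeB_if_a1 = np.where(zB > 0, _likeB_both(th, stats), 1.0)
        likeB_if_a0 = np.where(zB > 0, _binom(pB, dB, effort), 1.0)
    else:
        likeA1 = _binom(pA, dA, effort)
        likeB_if_a1 = likeB_if_a0 = 1.0  # B's detection free of zA: cancels
    likeA0 = np.where(seenA, 0.0, 1.0)
    priorB_a1 = np.where(zB > 0, th["psiBA"], 1 - th["psiBA"])
    priorB_a0 = np.where(zB > 0, th["psiBa"], 1 - th["psiBa"])
    w1 = th["psiA"] * likeA1 * priorB_a1 * likeB_if_a1
    w0 = (1 - th["psiA"]) * likeA0 * priorB_a0 * likeB_if_a0
    zA = np.where(seenA, 1.0, (rng.uniform(size=n) * (w1 + w0) < w1).astype(float))

    # --- zB, holding zA
    prior = np.where(zA > 0, th["psiBA"], th["psiBa"])
    if cond:
        likeB1 = np.where(zA > 0, _likeB_both(th, stats), _binom(pB, dB, effort))
        likeA_b1 = np.where(zA > 0, _binom(th["rA"], dA, effort), 1.0)
        likeA_b0 = np.where(zA > 0, _binom(pA, dA, effort), 1.0)
    else:
        likeB1 = _binom(pB, dB, effort)
        likeA_b1 = likeA_b0 = 1.0
    w1 = prior * likeB1 * likeA_b1
    w0 = (1 - prior) * np.where(seenB, 0.0, 1.0) * likeA_b0
    zB = np.where(seenB, 1.0, (rng.uniform(size=n) * (w1 + w0) < w1).astype(float))
    return zA, zB


def _update_params(rng, th, zA, zB, stats, cond):
    effort, dA, dB, bA1 = stats["effort"], stats["dA"], stats["dB"], stats["bA1"]

    def beta(successes, trials):
        return rng.beta(1 + successes, 1 + trials - successes)

    nA1 = zA.sum()
    th["psiA"] = beta(nA1, zA.size)
    th["psiBA"] = beta((zB * zA).sum(), nA1)
    th["psiBa"] = beta((zB * (1 - zA)).sum(), zA.size - nA1)

    occA = zA > 0
    occB = zB > 0
    if not cond:
        th["pA"] = beta(dA[occA].sum(), effort[occA].sum())
        th["pB"] = beta(dB[occB].sum(), effort[occB].sum())
        return

    both = occA & occB
    aOnly = occA & ~occB
    bOnly = occB & ~occA
    th["pA"] = beta(dA[aOnly].sum(), effort[aOnly].sum())
    th["pB"] = beta(dB[bOnly].sum(), effort[bOnly].sum())
    th["rA"] = beta(dA[both].sum(), effort[both].sum())
    th["rBA"] = beta(bA1[both].sum(), dA[both].sum())
    th["rBa"] = beta((dB - bA1)[both].sum(), (effort - dA)[both].sum())


# ---------------------------------------------------------------------------
# Posterior summaries

def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest-density interval: the shortest contiguous interval holding
    ``ceil(mass * n)`` of the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise ValueError("hdi of empty sample")
    if n == 1:
        return float(x[0]), float(x[0])
    if not 0 < mass <= 1:
        raise ValueError(f"mass must be in (0, 1], got {mass}")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def rhat(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is split in half, then R-hat = sqrt(((n-1)/n * W + B/n)/W)
    with W the mean within-half variance and B the between-half variance.
    Approximately 1 for well-mixed chains.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws, shape (chains, iterations)")
    if c.shape[1] < 4:
        raise ValueError("chains too short to split")
    half = c.shape[1] // 2
    halves = np.vstack([c[:, :half], c[:, half : 2 * half]])
    n = half
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass
class PosteriorSummary:
    """Tabular posterior summary with an independence verdict for the SIF."""

    table: pd.DataFrame       # index: parameter; columns mean, sd, hdi_low, hdi_high, rhat
    hdi_excludes_one: bool    # True when the SIF 95% HDI excludes 1

    def __str__(self) -> str:
        verdict = "yes" if self.hdi_excludes_one else "no"
        return f"{self.table.round(4)}\nSIF 95% HDI excludes 1: {verdict}"


def summarize_posterior(result: GibbsResult, mass: float = 0.95) -> PosteriorSummary:
    rows = {}
    for name, draws in result.draws.items():
        pooled = draws.reshape(-1)
        lo, hi = hdi(pooled, mass)
        rows[name] = {
            "mean": pooled.mean(),
            "sd": pooled.std(ddof=1),
            "hdi_low": lo,
            "hdi_high": hi,
            "rhat": rhat(draws),
        }
    table = pd.DataFrame(rows).T
    lo, hi = table.loc["SIF", "hdi_low"], table.loc["SIF", "hdi_high"]
    return PosteriorSummary(table, bool(hi < 1 or lo > 1))


# ---------------------------------------------------------------------------
# Maximum-likelihood cross-check

def ml_fit(pair: DetectionPair) -> tuple[TwoSpeciesParams, bool]:
    """Maximize the marginal likelihood (independent-detection model).

    Works on the logit scale with L-BFGS-B; returns the fitted parameters
    and a convergence flag.  Boundary-drifting estimates (|logit| > 8,
    e.g. a species never present) are reported but flagged as
    non-converged rather than silently clipped.
    """
    A, B, obs, effort, dA, dB = _prepare(pair)
    seenA, seenB = dA > 0, dB > 0

    def nll(x):
        psiA, psiBA, psiBa, pA, pB = expit(x)
        # site marginal via the four latent states, vectorized over sites
        likeA1 = pA ** dA * (1 - pA) ** (effort - dA)
        likeB1 = pB ** dB * (1 - pB) ** (effort - dB)
        likeA0 = np.where(seenA, 0.0, 1.0)
        likeB0 = np.where(seenB, 0.0, 1.0)
        site = (
            psiA * psiBA * likeA1 * likeB1
            + psiA * (1 - psiBA) * likeA1 * likeB0
            + (1 - psiA) * psiBa * likeA0 * likeB1
            + (1 - psiA) * (1 - psiBa) * likeA0 * likeB0
        )
        return -np.log(np.clip(site, 1e-300, None)).sum()

    res = minimize(nll, np.zeros(5), method="L-BFGS-B")
    x = res.x
    converged = bool(res.success) and bool(np.all(np.abs(x) < 8))
    psiA, psiBA, psiBa, pA, pB = np.clip(expit(x), 1e-9, 1 - 1e-9)
    return TwoSpeciesParams(psiA, psiBA, psiBa, pA, pB), converged
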