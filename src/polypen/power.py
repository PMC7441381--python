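"""Retrospective power for the score-by-carrier interaction test.

The design follows the retrospective (phenotype-permutation) idea: the study
size, case total and the noncarrier score effect are fixed at their observed
values, phenotypes are re-simulated conditional on the case total, and the
carrier score effect is varied to find the effect sizes detectable at a
target power.

Phenotypes with a fixed case count follow the conditional-Bernoulli law:
independent Bernoulli(p_i) conditioned on their sum,
P(y) proportional to prod r_i^{y_i} with odds r_i = p_i/(1-p_i). Two exact
samplers are provided. The dynamic-programming sampler builds the
Poisson-binomial recursion in log space (O(n*m) table) and samples
sequentially; it also yields exact pmf values and inclusion probabilities
and is the reference at small n. The rejection sampler exploits the fact
that the conditional law is invariant to multiplying every odds by a common
factor: odds are rescaled so the expected sum equals the target, then
independent Bernoulli vectors are drawn until the sum hits the target
exactly — an exact draw from the same law at O(n / P(S=m)) cost, which is
orders of magnitude faster at biobank sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .models import fit_logistic, interaction_test

__all__ = [
    "PowerScenario",
    "PowerGrid",
    "CASE_CONTROL_SCENARIOS",
    "conditional_phenotype_sample",
    "conditional_logpmf",
    "conditional_inclusion_probabilities",
    "interaction_power",
    "detectable_or_bounds",
]


# ---------------------------------------------------------------------------
# conditional-Bernoulli machinery
# ---------------------------------------------------------------------------

def _force_and_validate(p, n_cases):
    p = np.asarray(p, dtype=float)
    n = len(p)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 <= n_cases <= n:
        raise ValueError(f"n_cases={n_cases} outside [0, {n}]")
    forced_one = p == 1.0
    forced_zero = p == 0.0
    free = ~forced_one & ~forced_zero
    m_free = n_cases - int(forced_one.sum())
    if m_free < 0 or m_free > int(free.sum()):
        raise ValueError("forced assignments incompatible with n_cases")
    return p, free, forced_one, m_free


def _backward_table(logp, log1mp, m):
    """log P(sum of y_i..y_{n-1} = k), shape (n+1, m+1), log-space DP."""
    n = len(logp)
    B = np.full((n + 1, m + 1), -np.inf)
    B[n, 0] = 0.0
    for i in range(n - 1, -1, -1):
        stay = log1mp[i] + B[i + 1]
        move = np.full(m + 1, -np.inf)
        move[1:] = logp[i] + B[i + 1, :-1]
        B[i] = np.logaddexp(stay, move)
    return B


def conditional_logpmf(y, p, n_cases) -> float:
    """Exact log-probability of a binary vector under the conditional law."""
    y = np.asarray(y, dtype=int)
    p = np.asarray(p, dtype=float)
    if y.sum() != n_cases:
        return -np.inf
    logp, log1mp = np.log(p), np.log1p(-p)
    B = _backward_table(logp, log1mp, n_cases)
    return float(np.sum(np.where(y == 1, logp, log1mp)) - B[0, n_cases])


def conditional_inclusion_probabilities(p, n_cases) -> np.ndarray:
    """Exact P(y_i = 1 | sum = n_cases) by forward-backward recursion."""
    p, free, forced_one, m_free = _force_and_validate(p, n_cases)
    out = np.zeros(len(p))
    out[forced_one] = 1.0
    pf = p[free]
    n = len(pf)
    if n == 0 or m_free == 0:
        return out
    logp, log1mp = np.log(pf), np.log1p(-pf)
    B = _backward_table(logp, log1mp, m_free)
    # forward F[i, k] = log P(sum of y_0..y_{i-1} = k)
    F = np.full((n + 1, m_free + 1), -np.inf)
    F[0, 0] = 0.0
    for i in range(n):
        stay = log1mp[i] + F[i]
        move = np.full(m_free + 1, -np.inf)
        move[1:] = logp[i] + F[i, :-1]
        F[i + 1] = np.logaddexp(stay, move)
    total = B[0, m_free]
    incl = np.empty(n)
    for i in range(n):
        # P(sum_{j != i} = m-1), combining prefix before i and suffix after i
        ks = np.arange(m_free)
        terms = F[i, ks] + B[i + 1, m_free - 1 - ks]
        incl[i] = np.exp(logp[i] + special.logsumexp(terms) - total)
    out[free] = incl
    return out


def _dp_sample(pf, m_free, rng, size):
    logp, log1mp = np.log(pf), np.log1p(-pf)
    B = _backward_table(logp, log1mp, m_free)
    n = len(pf)
    draws = np.zeros((size, n), dtype=np.int8)
    for s in range(size):
        r = m_free
        for i in range(n):
            if r == 0:
                break
            if n - i == r:
                draws[s, i:] = 1
                break
            p1 = np.exp(logp[i] + B[i + 1, r - 1] - B[i, r])
            if rng.random() < p1:
                draws[s, i] = 1
                r -= 1
    return draws


def _calibrate_odds(pf, m_free):
    """Common log-odds shift c with sum sigmoid(logit(p)+c) = m_free."""
    logit = np.log(pf) - np.log1p(-pf)

    def f(c):
        return special.expit(logit + c).sum() - m_free

    lo, hi = -60.0, 60.0
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("odds calibration failed to bracket")
    c = optimize.brentq(f, lo, hi, xtol=1e-9)
    return special.expit(logit + c)


def _rejection_sample(pf, m_free, rng, size, max_batches=10_000):
    q = _calibrate_odds(pf, m_free)
    n = len(q)
    var = float(np.sum(q * (1 - q)))
    p_hit = max(1.0 / np.sqrt(2 * np.pi * max(var, 0.25)), 1e-6)
    draws = np.empty((size, n), dtype=np.int8)
    got = 0
    for _ in range(max_batches):
        # aim for ~1.3x the remaining accepts, capped by memory
        batch = int(np.clip(np.ceil(1.3 * (size - got) / p_hit), 8,
                            max(8, 8_000_000 // n)))
        y = (rng.random((batch, n)) < q).astype(np.int8)
        hits = np.flatnonzero(y.sum(axis=1) == m_free)
        take = hits[: size - got]
        draws[got : got + len(take)] = y[take]
        got += len(take)
        if got == size:
            return draws
    raise RuntimeError("rejection sampler failed; use method='dp'")


def conditional_phenotype_sample(
    p, n_cases: int, seed=None, size: int = 1, method: str = "auto"
) -> np.ndarray:
    """Sample binary phenotypes with the case total fixed.

    Draws from independent Bernoulli(p_i) conditioned on sum(y) = n_cases
    (the conditional-Bernoulli law). ``p_i`` of exactly 0 or 1 are treated
    as forced assignments before sampling. ``method`` is "dp" (sequential
    sampler over the log-space Poisson-binomial recursion), "rejection"
    (odds-rescaled exact rejection), or "auto" (DP for small problems,
    rejection otherwise). Returns an array of shape (size, n) (squeezed to
    (n,) when size == 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p, free, forced_one, m_free = _force_and_validate(p, n_cases)
    n = len(p)
    out = np.zeros((size, n), dtype=np.int8)
    out[:, forced_one] = 1
    pf = p[free]
    if len(pf) and m_free > 0:
        if m_free == len(pf):
            out[:, free] = 1
        else:
            if method == "auto":
                method = "dp" if len(pf) * m_free <= 250_000 else "rejection"
            if method == "dp":
                out[:, free] = _dp_sample(pf, m_free, rng, size)
            elif method == "rejection":
                out[:, free] = _rejection_sample(pf, m_free, rng, size)
            else:
                raise ValueError(f"unknown method {method!r}")
    return out[0] if size == 1 else out


# ---------------------------------------------------------------------------
# power simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerScenario:
    """A retrospective interaction-power scenario.

    The case total is fixed (conditional phenotype assignment), the
    noncarrier OR per score SD is pinned to its observed value, and the
    carrier OR per SD is the quantity varied. ``carrier_main_or`` fixes the
    carrier main-effect odds ratio at its observed value; this matters
    because it concentrates carriers among cases, which lowers the Fisher
    information on the carrier score slope and widens the detectable-OR
    bounds. Scores are standard normal by default; ``carrier_z`` optionally
    supplies fixed observed carrier scores.
    """

    n_individuals: int
    n_cases: int
    n_carriers: int
    noncarrier_or_per_sd: float
    carrier_main_or: float = 1.0
    alpha: float = 0.05
    target_power: float = 0.80
    n_reps: int = 600
    seed: int = 0
    carrier_z: np.ndarray | None = None

    def __post_init__(self):
        if not 0 < self.n_cases < self.n_individuals:
            raise ValueError("need 0 < n_cases < n_individuals")
        if self.n_carriers < 1:
            raise ValueError("need at least one carrier")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.carrier_z is not None and len(self.carrier_z) != self.n_carriers:
            raise ValueError("carrier_z length must equal n_carriers")


# Observed dimensions of the two case-control studies: total size, fixed case
# count, carrier count, noncarrier OR per score SD, and the carrier
# main-effect OR, all pinned to their observed values.
CASE_CONTROL_SCENARIOS = {
    "coronary_artery_disease": dict(
        n_individuals=12_852, n_cases=6_432, n_carriers=56,
        noncarrier_or_per_sd=1.74, carrier_main_or=3.21,
    ),
    "breast_cancer": dict(
        n_individuals=19_264, n_cases=1_920, n_carriers=845,
        noncarrier_or_per_sd=1.57, carrier_main_or=3.48,
    ),
}


@dataclass
class PowerGrid:
    grid: pd.DataFrame
    bounds: tuple[float, float]
    target_power: float

    def as_dict(self):
        return {
            "lower_or": self.bounds[0],
            "upper_or": self.bounds[1],
            "target_power": self.target_power,
            "grid": self.grid.to_dict(orient="records"),
        }


def _one_replicate(scenario, carrier_or, rng):
    n = scenario.n_individuals
    carrier = np.zeros(n)
    carrier[: scenario.n_carriers] = 1.0
    z = rng.standard_normal(n)
    if scenario.carrier_z is not None:
        z[: scenario.n_carriers] = scenario.carrier_z
    eta = np.where(
        carrier == 1.0,
        np.log(scenario.carrier_main_or) + np.log(carrier_or) * z,
        np.log(scenario.noncarrier_or_per_sd) * z,
    )
    # intercept calibrated so the expected case count matches the fixed total;
    # the conditional law is invariant to it, so this only tunes sampler cost
    p = _calibrate_odds(special.expit(eta), scenario.n_cases)
    y = conditional_phenotype_sample(p, scenario.n_cases, seed=rng)
    design = pd.DataFrame(
        {"z": z, "carrier": carrier, "z_x_carrier": z * carrier}
    )
    fit = fit_logistic(y, design)
    if not fit.converged or fit.separation:
        return None
    b = fit.coefficients["z_x_carrier"]
    se = fit.se["z_x_carrier"]
    return 2 * stats.norm.sf(abs(b / se))


def interaction_power(
    scenario: PowerScenario, carrier_or: float, n_reps: int | None = None,
    seed=None,
) -> dict:
    """Monte-Carlo power of the Wald interaction test at one carrier OR.

    Each replicate draws scores, calibrates the intercept to the fixed case
    total, samples phenotypes by conditional assignment, fits
    y ~ z + carrier + z:carrier and records rejection at ``alpha``.
    Replicates whose fit fails (separation/non-convergence) are counted and
    excluded from the rejection denominator.
    """
    if carrier_or <= 0:
        raise ValueError("carrier_or must be positive")
    n_reps = n_reps or scenario.n_reps
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(
            np.random.SeedSequence([scenario.seed, int(1e6 * carrier_or) % (2**31)])
            if seed is None
            else seed
        )
    )
    rejections = 0
    valid = 0
    failed = 0
    for _ in range(n_reps):
        pval = _one_replicate(scenario, carrier_or, rng)
        if pval is None:
            failed += 1
            continue
        valid += 1
        rejections += pval < scenario.alpha
    power = rejections / valid if valid else np.nan
    se = np.sqrt(power * (1 - power) / valid) if valid else np.nan
    return {
        "carrier_or": float(carrier_or),
        "power": float(power),
        "mc_se": float(se),
        "n_reps": n_reps,
        "n_valid": valid,
        "n_failed": failed,
    }


def detectable_or_bounds(
    scenario: PowerScenario,
    search_factor: float = 8.0,
    tol_or: float = 0.01,
    max_iter: int = 20,
    seed=None,
) -> PowerGrid:
    """Carrier ORs where interaction power crosses the target, by bisection.

    Power is ~alpha at the null (carrier OR = noncarrier OR) and rises
    monotonically as the carrier OR moves away on either side; each side is
    bisected on the log-OR scale until the bracket is narrower than
    ``tol_or`` (or 1% of the bound) or Monte-Carlo noise dominates the
    remaining bracket. Returns the (lower, upper) bounds plus the grid of
    evaluated points; a side that never reaches the target within the
    search interval is reported as an open bound (nan).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([scenario.seed, 77]))
    )
    null = scenario.noncarrier_or_per_sd
    records = []

    def power_at(or_value, max_factor=4):
        """Pooled power estimate; adds replicates until the comparison with
        the target power is resolved (or the replicate budget is spent), so
        a single noisy evaluation cannot pin the bracket on the wrong side."""
        rejections = valid = failed = total = 0
        while True:
            res = interaction_power(scenario, or_value,
                                    n_reps=scenario.n_reps, seed=rng)
            rejections += round(res["power"] * res["n_valid"])
            valid += res["n_valid"]
            failed += res["n_failed"]
            total += res["n_reps"]
            p = rejections / valid if valid else np.nan
            se = np.sqrt(max(p * (1 - p), 1e-6) / valid) if valid else np.nan
            decisive = abs(p - scenario.target_power) >= 1.5 * se
            if decisive or total >= max_factor * scenario.n_reps:
                break
        records.append(
            {"carrier_or": float(or_value), "power": float(p),
             "mc_se": float(se), "n_reps": total, "n_valid": valid,
             "n_failed": failed}
        )
        return p

    def solve(direction):
        edge = null * search_factor if direction > 0 else null / search_factor
        p_edge = power_at(edge)
        if p_edge < scenario.target_power:
            return np.nan  # open bound: target unreachable in the interval
        lo, hi = (null, edge) if direction > 0 else (edge, null)
        # invariant: power(bracket end nearer the null) < target < power(far end)
        for it in range(max_iter):
            mid = float(np.sqrt(lo * hi))
            width = hi - lo
            if width < max(tol_or, 0.01 * mid):
                break
            p_mid = power_at(mid)
            crossed = p_mid >= scenario.target_power
            if direction > 0:
                lo, hi = (lo, mid) if crossed else (mid, hi)
            else:
                lo, hi = (mid, hi) if crossed else (lo, mid)
        return float(np.sqrt(lo * hi))

    lower = solve(-1)
    upper = solve(+1)
    grid = pd.DataFrame(records).sort_values("carrier_or").reset_index(drop=True)
    return PowerGrid(grid=grid, bounds=(lower, upper),
                     target_power=scenario.target_power)
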