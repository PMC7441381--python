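"""Logistic models for joint monogenic/polygenic risk.

The estimators here mirror a case-control / cohort analysis of how polygenic
background modifies risk in carriers of rare large-effect variants:

* a six-level carrier x score-stratum model (noncarrier/intermediate as the
  reference group),
* odds ratio per SD of the corrected score fit separately in carriers and
  noncarriers,
* a Wald test of the score x carrier product term,
* predicted odds-ratio curves across score percentiles, referenced to
  noncarriers at the median percentile with other covariates at their means,
* a likelihood-ratio test of linearity (linear vs. cubic in the corrected
  score) and a 20-bin observed-vs-expected calibration table.

Fitting is Newton/IRLS maximum likelihood with explicit convergence and
separation status; a Firth-penalized fallback handles sparse carrier cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogisticFit",
    "RiskGroupEstimate",
    "fit_logistic",
    "stratify_scores",
    "six_level_or",
    "or_per_sd_by_stratum",
    "interaction_test",
    "percentile_or_curve",
    "linearity_lrt",
    "calibration_table",
    "two_by_two_or",
]

Z975 = stats.norm.ppf(0.975)


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    coefficients are on the log-odds scale; covariance is the inverse
    observed information. ``converged`` must be True before the fit is used
    downstream; ``separation`` flags quasi-complete separation (coefficients
    diverging), in which case Wald intervals are unreliable. ``method`` is
    "mle" or "firth".
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    loglik: float
    n: int
    converged: bool
    separation: bool = False
    method: str = "mle"
    n_iter: int = 0

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.covariance)), index=self.coefficients.index
        )

    def wald(self, name: str) -> tuple[float, float, float, float]:
        """(OR, ci_low, ci_high, two-sided p) for one coefficient."""
        b = self.coefficients[name]
        se = self.se[name]
        zstat = b / se if se > 0 else np.inf * np.sign(b)
        p = 2 * stats.norm.sf(abs(zstat))
        with np.errstate(over="ignore"):  # separated fits give +/-inf bounds
            return (
                float(np.exp(b)),
                float(np.exp(b - Z975 * se)),
                float(np.exp(b + Z975 * se)),
                float(p),
            )


def _loglik(y, eta):
    # stable Bernoulli log-likelihood sum(y*eta - log(1+exp(eta)))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    outcome,
    design: pd.DataFrame,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    firth: bool = False,
) -> LogisticFit:
    """Fit a logistic regression by Newton iteration (IRLS).

    Parameters
    ----------
    outcome : binary array-like with both classes present.
    design : DataFrame of predictors (no missing values).
    add_intercept : prepend a constant column named "intercept".
    firth : use Firth's bias-reduced penalized likelihood (for separated or
        sparse data); the returned ``method`` records which was used.

    Convergence is declared when the max absolute coefficient change falls
    below ``tol``; quasi-complete separation is flagged when coefficients
    diverge (|beta| growing past 30 on the scale of standardized columns) or
    fitted probabilities pin to 0/1 for the relevant cells.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; model not estimable")
    X = design.to_numpy(dtype=float)
    names = list(design.columns)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in model columns")
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept", *names]
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    separation = False
    ll_old = _loglik(y, X @ beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        w = np.maximum(w, 1e-12)
        if firth:
            # hat diagonal of W^(1/2) X (X' W X)^-1 X' W^(1/2)
            XtW = X.T * w
            info = XtW @ X
            try:
                M = np.linalg.solve(info, X.T)
            except np.linalg.LinAlgError:
                separation = True
                break
            h = np.einsum("ij,ji->i", X * w[:, None], M)
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            info = (X.T * w) @ X
            score = X.T @ (y - p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            separation = True
            break
        # step-halving if the (penalized) log-likelihood worsens
        new_beta = beta + step
        ll_new = _loglik(y, X @ new_beta)
        halvings = 0
        while ll_new < ll_old - 1e-10 and halvings < 20 and not firth:
            step /= 2.0
            new_beta = beta + step
            ll_new = _loglik(y, X @ new_beta)
            halvings += 1
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        ll_old = _loglik(y, X @ beta)
        if delta < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 30:
        separation = True
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(p * (1 - p), 1e-12)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
        separation = True
    return LogisticFit(
        coefficients=pd.Series(beta, index=names),
        covariance=pd.DataFrame(cov, index=names, columns=names),
        loglik=_loglik(y, eta),
        n=n,
        converged=converged,
        separation=separation,
        method="firth" if firth else "mle",
        n_iter=it,
    )


def two_by_two_or(a: int, b: int, c: int, d: int):
    """Unadjusted odds ratio with Woolf CI from a 2x2 table.

    ``a``/``b`` exposed cases/controls, ``c``/``d`` unexposed cases/controls.
    Returns (or, ci_low, ci_high).
    """
    if min(a, b, c, d) <= 0:
        raise ValueError("zero cell; use a penalized estimator")
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (
        float(np.exp(log_or)),
        float(np.exp(log_or - Z975 * se)),
        float(np.exp(log_or + Z975 * se)),
    )


def stratify_scores(percentiles) -> pd.Series:
    """Quintile strata of the score distribution.

    low = percentile <= 20, intermediate = 21-80, high = >= 81 (the lowest
    quintile, middle three quintiles and highest quintile).
    """
    p = np.asarray(percentiles)
    if p.min() < 1 or p.max() > 100:
        raise ValueError("percentiles must lie in [1, 100]")
    labels = np.where(p <= 20, "low", np.where(p <= 80, "intermediate", "high"))
    idx = percentiles.index if isinstance(percentiles, pd.Series) else None
    return pd.Series(
        pd.Categorical(labels, categories=["low", "intermediate", "high"]), index=idx
    )


@dataclass
class RiskGroupEstimate:
    carrier: bool
    score_stratum: str
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_cases: int
    estimable: bool = True

    def as_dict(self):
        return {
            "carrier": self.carrier,
            "score_stratum": self.score_stratum,
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "n_cases": self.n_cases,
            "estimable": self.estimable,
        }


_SIX_LEVELS = [
    (False, "low"),
    (False, "intermediate"),
    (False, "high"),
    (True, "low"),
    (True, "intermediate"),
    (True, "high"),
]
_REFERENCE_LEVEL = (False, "intermediate")


def six_level_or(
    outcome,
    carrier,
    strata: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[list[RiskGroupEstimate], LogisticFit]:
    """Odds ratios for the 2 (carrier) x 3 (score stratum) levels.

    A single logistic fit with five indicator contrasts against the
    noncarrier/intermediate reference (plus adjustment covariates). Empty
    levels are returned as not-estimable records rather than raised.
    """
    y = np.asarray(outcome, dtype=float)
    carr = np.asarray(carrier, dtype=bool)
    strat = np.asarray(strata.astype(str))
    cols = {}
    level_names = {}
    for lev in _SIX_LEVELS:
        if lev == _REFERENCE_LEVEL:
            continue
        name = f"{'carrier' if lev[0] else 'noncarrier'}_{lev[1]}"
        level_names[lev] = name
        cols[name] = ((carr == lev[0]) & (strat == lev[1])).astype(float)
    design = pd.DataFrame(cols)
    present = {
        lev: int(((carr == lev[0]) & (strat == lev[1])).sum()) for lev in _SIX_LEVELS
    }
    drop = [level_names[lev] for lev in level_names if present[lev] == 0]
    design = design.drop(columns=drop)
    if covariates is not None:
        design = pd.concat(
            [design.reset_index(drop=True), covariates.reset_index(drop=True)], axis=1
        )
    fit = fit_logistic(y, design)
    out = []
    for lev in _SIX_LEVELS:
        mask = (carr == lev[0]) & (strat == lev[1])
        n_lev, cases_lev = int(mask.sum()), int(y[mask].sum())
        if lev == _REFERENCE_LEVEL:
            out.append(
                RiskGroupEstimate(lev[0], lev[1], 1.0, 1.0, 1.0, np.nan, n_lev,
                                  cases_lev)
            )
        elif present[lev] == 0:
            out.append(
                RiskGroupEstimate(lev[0], lev[1], np.nan, np.nan, np.nan, np.nan,
                                  0, 0, estimable=False)
            )
        else:
            or_v, lo, hi, p = fit.wald(level_names[lev])
            out.append(
                RiskGroupEstimate(lev[0], lev[1], or_v, lo, hi, p, n_lev, cases_lev)
            )
    return out, fit


def or_per_sd_by_stratum(
    outcome, z, carrier, covariates: pd.DataFrame | None = None,
    min_events: int = 10,
) -> dict[str, dict]:
    """OR per SD of the score fit separately in carriers and noncarriers."""
    y = np.asarray(outcome, dtype=float)
    zz = np.asarray(z, dtype=float)
    carr = np.asarray(carrier, dtype=bool)
    out = {}
    for label, mask in (("carrier", carr), ("noncarrier", ~carr)):
        if mask.sum() == 0:
            raise ValueError(f"{label} stratum is empty")
        design = pd.DataFrame({"z": zz[mask]})
        if covariates is not None:
            design = pd.concat(
                [design, covariates.loc[mask].reset_index(drop=True)], axis=1
            )
        n_events = int(y[mask].sum())
        if n_events < min_events:
            warnings.warn(
                f"{label} stratum has only {n_events} events; estimate unstable",
                stacklevel=2,
            )
        fit = fit_logistic(y[mask], design)
        or_v, lo, hi, p = fit.wald("z")
        out[label] = {
            "or_per_sd": or_v, "ci_low": lo, "ci_high": hi, "p": p,
            "n": int(mask.sum()), "n_events": n_events, "fit": fit,
        }
    return out


def interaction_test(
    outcome, z, carrier, covariates: pd.DataFrame | None = None
) -> dict:
    """Wald test of the score x carrier product term.

    Fits outcome ~ z + carrier + z:carrier (+ covariates) and returns the
    two-sided Wald p-value on the product coefficient.
    """
    zz = np.asarray(z, dtype=float)
    carr = np.asarray(carrier, dtype=float)
    if carr.sum() == 0 or carr.sum() == len(carr):
        raise ValueError("both carrier strata must be non-empty")
    design = pd.DataFrame({"z": zz, "carrier": carr, "z_x_carrier": zz * carr})
    if covariates is not None:
        design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
    fit = fit_logistic(outcome, design)
    b = fit.coefficients["z_x_carrier"]
    se = fit.se["z_x_carrier"]
    wald_z = b / se if se > 0 else np.nan
    return {
        "coef": float(b),
        "se": float(se),
        "wald_z": float(wald_z),
        "p": float(2 * stats.norm.sf(abs(wald_z))),
        "fit": fit,
    }


def percentile_z_map(
    corrected, percentiles, method: str = "bin_mean"
) -> pd.Series:
    """Representative z value per percentile bin 1..100.

    "bin_mean" (default) is the empirical mean corrected score inside each
    percentile bin, linearly interpolated through empty bins; "quantile_mid"
    uses the standard-normal quantile of the bin midpoint. The corrected
    scores are standardized internally so the map is on the SD scale.
    """
    grid = np.arange(1, 101)
    if method == "quantile_mid":
        return pd.Series(stats.norm.ppf((grid - 0.5) / 100.0), index=grid, name="z")
    if method != "bin_mean":
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(corrected, dtype=float)
    z = (x - x.mean()) / x.std(ddof=1)
    p = np.asarray(percentiles)
    means = np.full(100, np.nan)
    for i, pct in enumerate(grid):
        sel = p == pct
        if sel.any():
            means[i] = z[sel].mean()
    if np.isnan(means).any():
        if np.isnan(means).all():
            raise ValueError("no percentile bins populated")
        warnings.warn("empty percentile bins interpolated", stacklevel=2)
        ok = ~np.isnan(means)
        means = np.interp(grid, grid[ok], means[ok])
    return pd.Series(means, index=grid, name="z")


def percentile_or_curve(
    fit: LogisticFit,
    z_map: pd.Series,
    interaction: bool = False,
    carrier_name: str = "carrier",
    z_name: str = "z",
    interaction_name: str = "z_x_carrier",
    reference_percentile: int = 50,
) -> pd.DataFrame:
    """Predicted odds ratio at each score percentile for carriers/noncarriers.

    Reference: noncarriers at the median percentile, all other covariates at
    their means (they cancel in the odds-ratio difference). For percentile p
    and carrier state c the log-OR is
    ``beta_carrier*c + beta_z*(z_p - z_ref) (+ beta_zx*c*z_p if interaction)``
    with a delta-method 95% CI from the coefficient covariance.
    """
    if not fit.converged:
        raise ValueError("logistic fit did not converge")
    beta = fit.coefficients
    cov = fit.covariance
    z_ref = float(z_map.loc[reference_percentile])
    rows = []
    for carrier in (0, 1):
        for pct, z_p in z_map.items():
            grad = pd.Series(0.0, index=beta.index)
            grad[carrier_name] = carrier
            grad[z_name] = z_p - z_ref
            if interaction:
                grad[interaction_name] = carrier * z_p
            delta = float(grad @ beta)
            var = float(grad @ cov @ grad)
            se = np.sqrt(max(var, 0.0))
            rows.append(
                {
                    "percentile": int(pct),
                    "carrier": bool(carrier),
                    "or": float(np.exp(delta)),
                    "ci_low": float(np.exp(delta - Z975 * se)),
                    "ci_high": float(np.exp(delta + Z975 * se)),
                }
            )
    return pd.DataFrame(rows)


def linearity_lrt(
    outcome, corrected, covariates: pd.DataFrame | None = None
) -> dict:
    """Likelihood-ratio test of a linear vs. cubic score-risk relationship.

    Compares logistic models with the corrected score entered linearly
    against one adding square and cube terms; LRT = 2(ll_cubic - ll_linear)
    on 2 df. The score is standardized internally for numerical stability
    (an affine change of basis; the LRT is invariant).
    """
    s = np.asarray(corrected, dtype=float)
    s = (s - s.mean()) / s.std(ddof=1)
    base = pd.DataFrame({"s": s})
    cubic = pd.DataFrame({"s": s, "s2": s**2, "s3": s**3})
    if covariates is not None:
        cv = covariates.reset_index(drop=True)
        base = pd.concat([base, cv], axis=1)
        cubic = pd.concat([cubic, cv], axis=1)
    fit_lin = fit_logistic(outcome, base)
    fit_cub = fit_logistic(outcome, cubic)
    if not (fit_lin.converged and fit_cub.converged):
        raise ValueError("linearity LRT requires both fits to converge")
    lrt = max(0.0, 2.0 * (fit_cub.loglik - fit_lin.loglik))
    return {
        "lrt": lrt,
        "df": 2,
        "p": float(stats.chi2.sf(lrt, 2)),
        "loglik_linear": fit_lin.loglik,
        "loglik_cubic": fit_cub.loglik,
    }


def calibration_table(
    fitted_probabilities, percentiles, outcome, n_bins: int = 20
) -> pd.DataFrame:
    """Observed vs. expected event fraction in percentile bins (default 5% each).

    Bins are fixed percentile ranges (1-5, 6-10, ..., 96-100), the
    Hosmer-Lemeshow-style grouping on the score scale rather than on fitted
    risk.
    """
    p_hat = np.asarray(fitted_probabilities, dtype=float)
    pct = np.asarray(percentiles)
    y = np.asarray(outcome, dtype=float)
    width = 100 // n_bins
    rows = []
    for b in range(n_bins):
        lo, hi = b * width + 1, (b + 1) * width
        sel = (pct >= lo) & (pct <= hi)
        n = int(sel.sum())
        rows.append(
            {
                "bin": f"{lo}-{hi}",
                "n": n,
                "expected": float(p_hat[sel].mean()) if n else np.nan,
                "observed": float(y[sel].mean()) if n else np.nan,
                "n_events": int(y[sel].sum()),
            }
        )
    return pd.DataFrame(rows)
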