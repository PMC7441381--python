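"""Polygenic score computation and ancestry correction.

Raw scores are weighted sums of effect-allele dosages. Because score
distributions shift with genetic ancestry, raw scores are residualized on
the leading principal components of ancestry; the residuals define the
ancestry-corrected score from which standard-deviation units and integer
percentiles (1-100) are derived. Two sensitivity transformations are also
provided: removal of score variants within a flanking window of a set of
gene footprints, and residualization of one score on a second score (plus
PCs) to strip a correlated pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScoreSet",
    "compute_raw_scores",
    "ancestry_correct",
    "standardize",
    "percentile_map",
    "build_score_set",
    "exclude_flanking_variants",
    "residualize_on_secondary_score",
]

WEIGHT_COLUMNS = ("variant_id", "chromosome", "position", "effect_allele", "weight")


@dataclass
class ScoreSet:
    """Per-individual score vectors on every scale the analysis uses.

    Attributes
    ----------
    individual_id : pd.Index
        Row labels shared by all vectors.
    raw : np.ndarray
        Weighted dosage sum per individual.
    corrected : np.ndarray
        Residual of ``raw`` on the ancestry PCs (mean zero by construction).
    z : np.ndarray
        ``corrected`` in reference-standard-deviation units.
    percentile : np.ndarray
        Integer percentile 1-100 of ``corrected`` in the reference set.
    pc_coefficients : pd.Series
        Fitted OLS coefficients of the ancestry regression (intercept first).
    """

    individual_id: pd.Index
    raw: np.ndarray
    corrected: np.ndarray
    z: np.ndarray
    percentile: np.ndarray
    pc_coefficients: pd.Series = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "raw": self.raw,
                "corrected": self.corrected,
                "z": self.z,
                "percentile": self.percentile,
            },
            index=self.individual_id,
        )


def _normalize_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def validate_weights(weights: pd.DataFrame) -> pd.DataFrame:
    """Check a score-weight table (PLINK-score-style columns).

    Requires columns ``variant_id, chromosome, position, effect_allele,
    weight``; enforces unique IDs, positive 1-based positions and finite
    weights.
    """
    missing = [c for c in WEIGHT_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if weights["variant_id"].duplicated().any():
        dups = weights.loc[weights["variant_id"].duplicated(), "variant_id"]
        raise ValueError(f"duplicate variant ids in weights: {list(dups[:5])}")
    if (weights["position"] <= 0).any():
        raise ValueError("weight positions must be positive (1-based)")
    w = np.asarray(weights["weight"], dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weights")
    return weights


def compute_raw_scores(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    missing_policy: str = "mean",
    max_unresolved_fraction: float = 0.5,
) -> pd.Series:
    """Raw polygenic score: sum over variants of weight x effect-allele dosage.

    Parameters
    ----------
    dosages : DataFrame
        individuals x variants, values in [0, 2]; NaN marks missing calls.
        Columns are variant ids matching ``weights.variant_id``.
    weights : DataFrame
        Score weight table (see :func:`validate_weights`). Variants absent
        from ``dosages`` are counted and reported via a warning; if more than
        ``max_unresolved_fraction`` of the weight variants cannot be resolved
        an error is raised.
    missing_policy : {"mean", "zero"}
        "mean" imputes a missing dosage as twice the effect-allele frequency
        estimated from non-missing individuals (the usual score-function
        default); "zero" contributes nothing for missing calls.

    Returns
    -------
    pd.Series of raw scores indexed by individual.
    """
    validate_weights(weights)
    if missing_policy not in ("mean", "zero"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    ids = weights["variant_id"].to_numpy()
    present = np.isin(ids, dosages.columns.to_numpy())
    n_unresolved = int((~present).sum())
    if len(ids) and n_unresolved / len(ids) > max_unresolved_fraction:
        raise ValueError(
            f"{n_unresolved}/{len(ids)} weight variants unresolvable in dosages"
        )
    if n_unresolved:
        warnings.warn(
            f"{n_unresolved} weight variant(s) absent from dosage matrix; skipped",
            stacklevel=2,
        )
    use = weights.loc[present]
    d = dosages.loc[:, use["variant_id"]].to_numpy(dtype=float)
    if d.size and (np.nanmin(d) < 0 or np.nanmax(d) > 2):
        raise ValueError("dosages outside [0, 2]")
    w = use["weight"].to_numpy(dtype=float)
    if np.isnan(d).any():
        if missing_policy == "mean":
            col_mean = np.nanmean(d, axis=0)  # = 2 x effect-allele frequency
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            fill = np.broadcast_to(col_mean, d.shape)
        else:
            fill = np.zeros_like(d)
        d = np.where(np.isnan(d), fill, d)
    raw = d @ w if d.size else np.zeros(len(dosages))
    return pd.Series(raw, index=dosages.index, name="raw")


def _ols_residuals(y: np.ndarray, X: np.ndarray, names: list[str]):
    """OLS residuals of y on [1, X] with a rank check naming bad columns."""
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns by incremental rank
        bad = []
        cur = np.ones((n, 1))
        for j in range(k):
            cand = np.column_stack([cur, X[:, j]])
            if np.linalg.matrix_rank(cand) == cur.shape[1]:
                bad.append(names[j])
            else:
                cur = cand
        raise ValueError(f"rank-deficient ancestry design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid, beta


def ancestry_correct(raw: pd.Series, pcs: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Residualize raw scores on ancestry principal components.

    Fits ``raw ~ 1 + PC1 + ... + PCK`` by ordinary least squares and returns
    the residuals (the ancestry-corrected score) together with the fitted
    coefficients. Requires at least K+2 individuals and a full-rank design.
    """
    raw, pcs = raw.align(pcs, join="inner", axis=0)
    y = raw.to_numpy(dtype=float)
    X = pcs.to_numpy(dtype=float)
    if len(y) < X.shape[1] + 2:
        raise ValueError(f"need >= {X.shape[1] + 2} individuals, got {len(y)}")
    resid, beta = _ols_residuals(y, X, list(pcs.columns))
    coef = pd.Series(beta, index=["intercept", *pcs.columns], name="pc_coefficients")
    return pd.Series(resid, index=raw.index, name="corrected"), coef


def standardize(corrected: pd.Series, reference: pd.Series | None = None) -> pd.Series:
    """Corrected score in reference SD units: z = (x - mean) / sd.

    Uses the sample (n-1) standard deviation of the reference set (the
    corrected scores themselves when ``reference`` is None).
    """
    ref = corrected if reference is None else reference
    mu = float(np.mean(ref))
    sd = float(np.std(ref, ddof=1))
    if not np.isfinite(sd) or sd <= 0:
        raise ValueError("reference standard deviation is zero; cannot standardize")
    return pd.Series((corrected - mu) / sd, index=corrected.index, name="z")


def percentile_map(
    corrected: pd.Series, reference: pd.Series | None = None
) -> pd.Series:
    """Integer percentile (1-100) of each score within a reference distribution.

    The percentile is ``ceil(100 * r / N)`` where r is the mid-rank of the
    value among the N reference values (ties get the mean rank; values
    outside the reference range rank 0.5 below the minimum / at N above the
    maximum), clamped to [1, 100].
    """
    ref = corrected if reference is None else reference
    ref_sorted = np.sort(np.asarray(ref, dtype=float))
    n_ref = len(ref_sorted)
    if n_ref == 0:
        raise ValueError("empty reference distribution")
    x = np.asarray(corrected, dtype=float)
    lt = np.searchsorted(ref_sorted, x, side="left")
    le = np.searchsorted(ref_sorted, x, side="right")
    rank = lt + (le - lt + 1) / 2.0
    pct = np.ceil(100.0 * rank / n_ref)
    pct = np.clip(pct, 1, 100).astype(int)
    return pd.Series(pct, index=corrected.index, name="percentile")


def build_score_set(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    pcs: pd.DataFrame,
    reference: pd.Series | None = None,
    missing_policy: str = "mean",
) -> ScoreSet:
    """Full score pipeline: raw -> ancestry-corrected -> z -> percentile.

    ``reference`` optionally supplies an external corrected-score reference
    distribution for standardization and percentiles; by default the analysis
    sample itself is the reference.
    """
    raw = compute_raw_scores(dosages, weights, missing_policy=missing_policy)
    corrected, coef = ancestry_correct(raw, pcs)
    z = standardize(corrected, reference)
    pct = percentile_map(corrected, reference)
    return ScoreSet(
        individual_id=corrected.index,
        raw=raw.to_numpy(),
        corrected=corrected.to_numpy(),
        z=z.to_numpy(),
        percentile=pct.to_numpy(),
        pc_coefficients=coef,
    )


def exclude_flanking_variants(
    weights: pd.DataFrame,
    gene_regions: pd.DataFrame,
    window: int = 1_000_000,
) -> tuple[pd.DataFrame, int]:
    """Drop score variants within ``window`` bp of any gene footprint.

    ``gene_regions`` must carry 1-based inclusive ``chromosome, start, end``
    columns (BED input is converted on read). A variant on the same
    chromosome with position in [start - window, end + window], bounds
    inclusive, is removed. Chromosome-name dialects ("chr1" vs "1") are
    normalized with a warning when they differ.

    Returns the pruned weight table and the removal count.
    """
    validate_weights(weights)
    if gene_regions.empty:
        return weights.copy(), 0
    w_chr = weights["chromosome"].map(_normalize_chrom)
    g_chr = gene_regions["chromosome"].map(_normalize_chrom)
    if not w_chr.equals(weights["chromosome"].astype(str)) or not g_chr.equals(
        gene_regions["chromosome"].astype(str)
    ):
        warnings.warn("normalized 'chr' prefix in chromosome names", stacklevel=2)
    pos = weights["position"].to_numpy()
    drop = np.zeros(len(weights), dtype=bool)
    for chrom, start, end in zip(g_chr, gene_regions["start"], gene_regions["end"]):
        in_window = (w_chr.to_numpy() == chrom) & (pos >= start - window) & (
            pos <= end + window
        )
        drop |= in_window
    pruned = weights.loc[~drop].copy()
    return pruned, int(drop.sum())


def residualize_on_secondary_score(
    primary: pd.Series, secondary: pd.Series, pcs: pd.DataFrame
) -> tuple[pd.Series, pd.Series]:
    """Residualize a score on a second score plus ancestry PCs.

    OLS of ``primary ~ 1 + secondary + PC1..PCK``; the residuals are, by
    construction, uncorrelated with the secondary score and with every PC.
    Used to strip a correlated pathway (e.g. an LDL-cholesterol score) from
    a disease score before re-estimating per-SD effects.
    """
    df = pd.concat({"secondary": secondary}, axis=1).join(pcs, how="inner")
    primary = primary.loc[df.index]
    resid, beta = _ols_residuals(
        primary.to_numpy(dtype=float), df.to_numpy(dtype=float), list(df.columns)
    )
    coef = pd.Series(beta, index=["intercept", *df.columns])
    return pd.Series(resid, index=primary.index, name="residual"), coef
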