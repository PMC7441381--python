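"""Variant-level filters and monogenic carrier calling.

The clinical classification (pathogenic / likely pathogenic / VUS / benign)
is a human judgement consumed as an input label; this module applies the
mechanical filters around it — consequence and population-frequency
screening, region/quality flags — derives per-individual carrier status for
each condition from the surviving P/LP variants, and fits per-gene
carrier-disease associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import fit_logistic

__all__ = [
    "candidate_filter",
    "region_quality_filter",
    "determine_carrier_status",
    "per_gene_association",
    "FilterReport",
]

ALLOWED_CONSEQUENCES = {
    "synonymous", "missense", "nonsense", "frameshift", "canonical_splice", "other",
}
REQUIRED_FLAGS = ("low_complexity", "segdup", "rf_pass")


@dataclass
class FilterReport:
    """Survivor table plus per-rule drop counts."""

    table: pd.DataFrame
    dropped: dict[str, int]

    def __len__(self):
        return len(self.table)


def _af_columns(annotations: pd.DataFrame) -> list[str]:
    cols = [c for c in annotations.columns if c.startswith("af_")]
    if not cols:
        raise ValueError("no subpopulation allele-frequency columns (af_*)")
    return cols


def candidate_filter(
    annotations: pd.DataFrame,
    af_threshold: float = 0.005,
    mode: str = "any",
) -> FilterReport:
    """Consequence and population-frequency screen.

    Drops synonymous variants, then drops variants whose allele frequency
    strictly exceeds ``af_threshold`` in at least one subpopulation
    (``mode="any"``) or in every subpopulation (``mode="each"``). The
    threshold is a strict ">": a variant at exactly the threshold is kept.
    """
    if mode not in ("any", "each"):
        raise ValueError(f"mode must be 'any' or 'each', got {mode!r}")
    bad = set(annotations["consequence"].unique()) - ALLOWED_CONSEQUENCES
    if bad:
        raise ValueError(
            f"unknown consequence labels {sorted(bad)}; "
            f"allowed: {sorted(ALLOWED_CONSEQUENCES)}"
        )
    af = annotations[_af_columns(annotations)].to_numpy(dtype=float)
    if af.size and (af.min() < 0 or af.max() > 1):
        raise ValueError("allele frequencies outside [0, 1]")
    syn = (annotations["consequence"] == "synonymous").to_numpy()
    exceed = af > af_threshold
    freq_drop = exceed.any(axis=1) if mode == "any" else exceed.all(axis=1)
    keep = ~syn & ~freq_drop
    return FilterReport(
        table=annotations.loc[keep].copy(),
        dropped={
            "synonymous": int(syn.sum()),
            "frequency": int((freq_drop & ~syn).sum()),
        },
    )


def region_quality_filter(annotations: pd.DataFrame) -> FilterReport:
    """Drop variants in low-complexity or segmental-duplication regions, or
    failing the random-forest quality flag."""
    missing = [c for c in REQUIRED_FLAGS if c not in annotations.columns]
    if missing:
        raise ValueError(f"missing region/quality flag columns: {missing}")
    flags = annotations[list(REQUIRED_FLAGS)]
    if flags.isna().any().any():
        raise ValueError("region/quality flags contain missing values")
    lc = annotations["low_complexity"].to_numpy(dtype=bool)
    sd = annotations["segdup"].to_numpy(dtype=bool)
    rf = annotations["rf_pass"].to_numpy(dtype=bool)
    keep = ~lc & ~sd & rf
    return FilterReport(
        table=annotations.loc[keep].copy(),
        dropped={
            "low_complexity": int(lc.sum()),
            "segdup": int((sd & ~lc).sum()),
            "rf_fail": int((~rf & ~lc & ~sd).sum()),
        },
    )


def determine_carrier_status(
    annotations: pd.DataFrame,
    dosages: pd.DataFrame,
    condition_genes: dict[str, list[str]],
    dosage_threshold: float = 0.9,
    multi_variant: str = "error",
) -> pd.DataFrame:
    """Per-individual carrier status from filtered P/LP variants.

    An individual is a carrier for a condition when their dosage is
    ``>= dosage_threshold`` (>= 1 for hard calls; 0.9 tolerates imputed
    dosages) at at least one P/LP variant in the condition's genes.
    Individuals with two or more qualifying variants violate the
    screening-data expectation of at most one; ``multi_variant`` selects
    "error" or "keep_first" (with a warning).

    Returns one row per individual x condition with the qualifying variant
    and gene (or None).
    """
    plp = annotations.loc[annotations["classification"].isin(["P", "LP"])]
    known_genes = set(sum(condition_genes.values(), []))
    stray = set(plp["gene"]) - known_genes
    if stray:
        raise ValueError(
            f"P/LP variants in genes absent from the condition map: {sorted(stray)}"
        )
    rows = []
    for condition, genes in condition_genes.items():
        vids = plp.loc[plp["gene"].isin(genes), "variant_id"]
        vids = [v for v in vids if v in dosages.columns]
        gene_of = dict(zip(plp["variant_id"], plp["gene"]))
        if vids:
            d = dosages[vids].to_numpy(dtype=float)
            qual = d >= dosage_threshold
            counts = qual.sum(axis=1)
            if (counts > 1).any():
                n_multi = int((counts > 1).sum())
                if multi_variant == "error":
                    raise ValueError(
                        f"{n_multi} individual(s) with >1 qualifying variant "
                        f"for {condition}"
                    )
                warnings.warn(
                    f"{n_multi} individual(s) with >1 qualifying variant for "
                    f"{condition}; keeping the first",
                    stacklevel=2,
                )
            first = np.where(counts > 0, qual.argmax(axis=1), -1)
        else:
            counts = np.zeros(len(dosages), dtype=int)
            first = np.full(len(dosages), -1)
        for i, ind in enumerate(dosages.index):
            vid = vids[first[i]] if first[i] >= 0 else None
            rows.append(
                {
                    "individual_id": ind,
                    "condition": condition,
                    "carrier": bool(counts[i] > 0),
                    "variant_id": vid,
                    "gene": gene_of.get(vid),
                }
            )
    return pd.DataFrame(rows)


def per_gene_association(
    carrier_by_gene: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Adjusted logistic association of per-gene carrier status with disease.

    ``carrier_by_gene`` is individuals x genes (boolean). One fit per gene;
    genes with zero carriers are reported as not estimable, and fits showing
    separation are refit with Firth's penalized likelihood and labeled.
    """
    y = np.asarray(outcome, dtype=float)
    rows = []
    for gene in carrier_by_gene.columns:
        flag = carrier_by_gene[gene].to_numpy(dtype=float)
        n_carriers = int(flag.sum())
        rec = {"gene": gene, "n_carriers": n_carriers}
        if n_carriers == 0:
            rows.append({**rec, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "estimable": False, "method": None})
            continue
        design = pd.DataFrame({"carrier": flag})
        if covariates is not None:
            design = pd.concat([design, covariates.reset_index(drop=True)], axis=1)
        fit = fit_logistic(y, design)
        if fit.separation or not fit.converged:
            fit = fit_logistic(y, design, firth=True)
        or_v, lo, hi, p = fit.wald("carrier")
        rows.append({**rec, "or": or_v, "ci_low": lo, "ci_high": hi, "p": p,
                     "estimable": True, "method": fit.method})
    return pd.DataFrame(rows)
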