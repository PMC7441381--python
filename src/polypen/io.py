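"""Readers and writers for the pipeline's file formats.

Conventions: coordinates are 1-based inclusive internally; BED input
(0-based half-open) is converted at the boundary. Chromosome names have any
"chr" prefix stripped with a warning. Dosage input is either a TSV
(individuals x variants, NaN for missing) or a VCF whose DS format field
(or hard GT calls) supplies effect-allele dosages.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_score_weights",
    "read_dosage_tsv",
    "read_dosage_vcf",
    "read_dosage_matrix",
    "write_dosage_tsv",
    "read_phenotypes",
    "read_annotations",
    "read_regions",
]

from .scores import WEIGHT_COLUMNS, validate_weights

_WEIGHT_HEADER_ALIASES = {
    "id": "variant_id", "snp": "variant_id", "variant_id": "variant_id",
    "chrom": "chromosome", "chr": "chromosome", "chromosome": "chromosome",
    "pos": "position", "position": "position", "bp": "position",
    "effect_allele": "effect_allele", "a1": "effect_allele", "ea": "effect_allele",
    "other_allele": "other_allele", "a2": "other_allele",
    "weight": "weight", "beta": "weight", "effect_weight": "weight",
}


def _strip_chr(series: pd.Series) -> pd.Series:
    s = series.astype(str)
    has_prefix = s.str.lower().str.startswith("chr")
    if has_prefix.any():
        warnings.warn("stripped 'chr' prefix from chromosome names", stacklevel=3)
        s = s.where(~has_prefix, s.str[3:])
    return s


def read_score_weights(path) -> pd.DataFrame:
    """Whitespace/tab-delimited score weight file with header.

    Recognized (case-insensitive) header aliases: ID/SNP, CHROM/CHR,
    POS/BP, EFFECT_ALLELE/A1/EA, [OTHER_ALLELE/A2], WEIGHT/BETA.
    Duplicate variant ids are rejected.
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [
        _WEIGHT_HEADER_ALIASES.get(c.lower(), c.lower()) for c in df.columns
    ]
    missing = [c for c in WEIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"weight file {path}: missing columns {missing}")
    df["chromosome"] = _strip_chr(df["chromosome"])
    return validate_weights(df)


def read_dosage_tsv(path) -> pd.DataFrame:
    """Individuals x variants dosage TSV (first column = individual id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    ok = np.isnan(vals) | ((vals >= 0) & (vals <= 2))
    if not ok.all():
        bad = np.argwhere(~ok)[0]
        raise ValueError(
            f"dosage outside [0,2] at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return df


def write_dosage_tsv(dosages: pd.DataFrame, path) -> None:
    dosages.to_csv(path, sep="\t", index_label="individual_id")


def read_dosage_vcf(path) -> pd.DataFrame:
    """Dosages from a VCF: DS format field if present, else hard GT calls.

    Returns individuals x variants with NaN for missing calls; multiallelic
    records are rejected. Variant columns are the ID field (chrom:pos:ref:alt
    when ID is missing).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF dosages requires cyvcf2") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = {}
    for rec in vcf:
        if len(rec.ALT) > 1:
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        name = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0] if rec.ALT else '.'}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            vals = np.asarray(ds, dtype=float).reshape(-1)
            vals = np.where((vals < 0) | (vals > 2), np.nan, vals)
        else:
            gt = np.asarray(rec.genotype.array())[:, :2]
            vals = np.where((gt < 0).any(axis=1), np.nan, gt.clip(0).sum(axis=1))
        cols[name] = vals
    return pd.DataFrame(cols, index=pd.Index(samples, name="individual_id"))


def read_dosage_matrix(path, fmt: str | None = None) -> pd.DataFrame:
    """Dispatch on format: 'vcf' or 'tsv' (guessed from the suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes else "tsv"
    if fmt == "vcf":
        return read_dosage_vcf(path)
    if fmt == "tsv":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown dosage format {fmt!r}")


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype CSV keyed by individual_id.

    Validates unique ids, positive event/censoring ages, and that prevalent
    cases are a subset of cases.
    """
    df = pd.read_csv(path, index_col="individual_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate individual ids in phenotype table")
    if "age_dx_or_censor" in df.columns and (df["age_dx_or_censor"] <= 0).any():
        raise ValueError("age_dx_or_censor must be positive")
    if {"prevalent", "disease"} <= set(df.columns):
        if (df["prevalent"] & ~df["disease"].astype(bool)).any():
            raise ValueError("prevalent flag set on non-cases")
    return df


def read_annotations(path) -> pd.DataFrame:
    """Variant annotation TSV with consequence/flags/classification columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "gene", "consequence", "classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    af_cols = [c for c in df.columns if c.startswith("af_")]
    for c in af_cols:
        if ((df[c] < 0) | (df[c] > 1)).any():
            raise ValueError(f"allele frequencies outside [0,1] in {c}")
    return df


def read_regions(path) -> pd.DataFrame:
    """BED gene regions -> 1-based inclusive chromosome/start/end/gene."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chromosome", "start", "end", "gene"][:4],
    )
    if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
        raise ValueError("malformed BED intervals (need 0 <= start < end)")
    df["chromosome"] = _strip_chr(df["chromosome"])
    df["start"] = df["start"] + 1  # 0-based half-open -> 1-based inclusive
    return df
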