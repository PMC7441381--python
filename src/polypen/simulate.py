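"""Synthetic cohorts with the structure the penetrance analysis assumes.

The generator emulates, with known ground truth, the features the estimators
must cope with: ancestry-structured common-variant dosages (Balding-Nichols
allele-frequency divergence plus individual admixture), a rare large-effect
carrier class confined to a set of disease genes, cross-sectional disease
status from a logistic model, age-at-onset from a Weibull proportional-hazards
model with independent censoring, and case-control subsampling. Admixture
proportions (minus one redundant column) stand in for genotype-derived
principal components, preserving the confounding the ancestry correction has
to remove without an eigen-decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "generate_population",
    "assign_disease_cross_sectional",
    "assign_onset_ages",
    "sample_case_control",
    "generate_variant_annotations",
    "CONDITION_GENES",
]

CONDITION_GENES = {
    "FH": ["LDLR", "APOB", "PCSK9"],
    "HBOC": ["BRCA1", "BRCA2"],
    "Lynch": ["MLH1", "MSH2", "MSH6", "PMS2"],
}

CONSEQUENCES = ["synonymous", "missense", "nonsense", "frameshift",
                "canonical_splice", "other"]
CLASSIFICATIONS = ["P", "LP", "VUS", "LB", "B"]
SUBPOPULATIONS = ["afr", "amr", "eas", "nfe", "sas"]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters of a synthetic cohort.

    Effect sizes are on the log-odds (cross-sectional) or log-hazard
    (onset-age) scale; ``beta_prs_per_sd`` multiplies the true standardized
    polygenic score, so exp(beta_prs_per_sd) is the generating OR (or HR)
    per SD. Defaults are a mid-size biobank-like cohort: middle-aged
    enrollment, ~5% disease prevalence, 0.5% carriers with a three-fold
    odds ratio, OR 1.7 per score SD, and continental-scale allele-frequency
    divergence (Fst 0.1) across 5 ancestry components (4 exported PC
    surrogates).
    """

    n_individuals: int = 20_000
    n_score_variants: int = 200
    n_ancestry_components: int = 5
    fst: float = 0.1
    carrier_frequency: float = 0.005
    beta_carrier: float = float(np.log(3.0))
    beta_prs_per_sd: float = float(np.log(1.7))
    baseline_prevalence: float = 0.05
    age_range: tuple[float, float] = (40.0, 69.0)
    sex_fraction_female: float = 0.54
    beta_age_per_year: float = 0.04
    beta_male: float = 0.5
    hazard_shape: float = 4.0
    hazard_scale: float = 130.0
    censoring_age_range: tuple[float, float] = (55.0, 80.0)
    condition: str = "FH"
    seed: int = 0

    def __post_init__(self):
        for name in ("carrier_frequency", "baseline_prevalence",
                     "sex_fraction_female"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.fst < 1.0:
            raise ValueError(f"fst={self.fst} must lie strictly in (0, 1)")
        for name in ("n_individuals", "n_score_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_ancestry_components < 1:
            raise ValueError("n_ancestry_components must be >= 1")
        if self.hazard_shape <= 0 or self.hazard_scale <= 0:
            raise ValueError("Weibull hazard parameters must be positive")
        if self.condition not in CONDITION_GENES:
            raise ValueError(f"condition must be one of {list(CONDITION_GENES)}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus the truth that generated it.

    ``phenotypes`` carries ids, age, sex, PC surrogates and (once assigned)
    disease status and event times; ``dosages`` are the common score
    variants; ``rare_dosages`` the rare pathogenic-class variants (one
    qualifying variant per carrier, never two); ``truth`` keeps the
    generating config and latent quantities for parameter-recovery tests.
    """

    phenotypes: pd.DataFrame
    dosages: pd.DataFrame
    rare_dosages: pd.DataFrame
    weights: pd.DataFrame
    annotations: pd.DataFrame
    gene_regions: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def pc_columns(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c.startswith("pc")]

    def require_aligned(self):
        assert self.phenotypes.index.equals(self.dosages.index)
        assert self.phenotypes.index.equals(self.rare_dosages.index)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# Toy genome for generated variants: gene footprints on separate chromosomes,
# spaced so 1-Mb flanking windows are exercised by the score variants.
_GENE_REGIONS = pd.DataFrame(
    {
        "chromosome": ["19", "2", "1", "17", "13", "3", "2", "2", "7"],
        "start": [11_200_000, 21_224_000, 55_505_000, 41_196_000, 32_889_000,
                  37_034_000, 47_630_000, 47_922_000, 6_012_000],
        "end": [11_244_000, 21_266_000, 55_530_000, 41_277_000, 32_973_000,
                37_092_000, 47_710_000, 48_037_000, 6_048_000],
        "gene": ["LDLR", "APOB", "PCSK9", "BRCA1", "BRCA2",
                 "MLH1", "MSH2", "MSH6", "PMS2"],
    }
)


def generate_population(config: SimConfig) -> SyntheticCohort:
    """Draw a cohort: ancestry-structured dosages, weights, carriers.

    Ancestral allele frequencies are uniform on (0.05, 0.95); each ancestry
    component gets a Balding-Nichols draw
    ``Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst)``; individual allele frequencies
    mix the component frequencies by Dirichlet admixture proportions, and
    dosages are Binomial(2, p_i). Per-variant score weights are normal.
    Carrier flags are Bernoulli(carrier_frequency); each carrier receives
    exactly one rare pathogenic-class variant in one of the condition's
    genes (never two, matching clinical screening data where compound
    carriers are not observed).
    """
    rng = _rng(config.seed)
    n, m, k = config.n_individuals, config.n_score_variants, config.n_ancestry_components
    ids = pd.Index([f"I{i:06d}" for i in range(n)], name="individual_id")

    p_anc = rng.uniform(0.05, 0.95, size=m)
    a = p_anc * (1 - config.fst) / config.fst
    b = (1 - p_anc) * (1 - config.fst) / config.fst
    p_comp = rng.beta(a, b, size=(k, m))  # component x variant
    admix = rng.dirichlet(np.ones(k), size=n)  # individual x component
    p_ind = admix @ p_comp
    dos = rng.binomial(2, p_ind).astype(np.int8)
    var_ids = [f"rs{100000 + j}" for j in range(m)]
    # place score variants on the toy genome, some inside 1-Mb flanks
    chroms = rng.choice(_GENE_REGIONS["chromosome"].unique(), size=m)
    pos = rng.integers(1, 60_000_000, size=m)
    dosages = pd.DataFrame(dos, index=ids, columns=var_ids)

    weights = pd.DataFrame(
        {
            "variant_id": var_ids,
            "chromosome": chroms,
            "position": pos,
            "effect_allele": rng.choice(list("ACGT"), size=m),
            "weight": rng.normal(0.0, 0.05, size=m),
        }
    )

    raw = dos @ weights["weight"].to_numpy()
    true_z = (raw - raw.mean()) / raw.std(ddof=1)

    carrier = rng.random(n) < config.carrier_frequency
    genes = CONDITION_GENES[config.condition]
    n_rare = max(2 * len(genes), 6)
    rare_ids = [f"rare{j:03d}" for j in range(n_rare)]
    rare_genes = [genes[j % len(genes)] for j in range(n_rare)]
    rare = np.zeros((n, n_rare), dtype=np.int8)
    which = rng.integers(0, n_rare, size=n)
    rare[np.arange(n)[carrier], which[carrier]] = 1  # single-carrier rule
    rare_dosages = pd.DataFrame(rare, index=ids, columns=rare_ids)

    age = rng.uniform(*config.age_range, size=n)
    sex = np.where(rng.random(n) < config.sex_fraction_female, "female", "male")
    pheno = pd.DataFrame({"age_enroll": age, "sex": sex, "carrier": carrier},
                         index=ids)
    for j in range(k - 1):  # drop one redundant admixture column
        pheno[f"pc{j + 1}"] = admix[:, j]

    annotations = _rare_annotations(rng, rare_ids, rare_genes)
    truth = {
        "config": config,
        "true_z": pd.Series(true_z, index=ids),
        "component_admixture": pd.DataFrame(
            admix, index=ids, columns=[f"component{j + 1}" for j in range(k)]
        ),
        "ancestral_freq": p_anc,
    }
    cohort = SyntheticCohort(
        phenotypes=pheno,
        dosages=dosages,
        rare_dosages=rare_dosages,
        weights=weights,
        annotations=annotations,
        gene_regions=_GENE_REGIONS.copy(),
        truth=truth,
    )
    cohort.require_aligned()
    return cohort


def _rare_annotations(rng, rare_ids, rare_genes) -> pd.DataFrame:
    """Clean P/LP annotations for the generated rare carrier variants."""
    n = len(rare_ids)
    rows = {
        "variant_id": rare_ids,
        "gene": rare_genes,
        "consequence": rng.choice(
            ["missense", "nonsense", "frameshift", "canonical_splice"], size=n
        ),
        "low_complexity": np.zeros(n, dtype=bool),
        "segdup": np.zeros(n, dtype=bool),
        "rf_pass": np.ones(n, dtype=bool),
        "classification": rng.choice(["P", "LP"], size=n),
    }
    for sp in SUBPOPULATIONS:
        rows[f"af_{sp}"] = rng.uniform(0.0, 0.002, size=n)
    return pd.DataFrame(rows)


def _logit_prevalence_intercept(eta: np.ndarray, target: float) -> float:
    """Solve for c with mean(sigmoid(c + eta)) = target."""

    def f(c):
        return np.mean(1.0 / (1.0 + np.exp(-(c + eta)))) - target

    lo, hi = -40.0, 40.0
    if f(lo) > 0 or f(hi) < 0:
        raise RuntimeError("prevalence intercept search failed to bracket")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _linear_predictor(cohort: SyntheticCohort, config: SimConfig) -> np.ndarray:
    ph = cohort.phenotypes
    z = cohort.truth["true_z"].to_numpy()
    eta = (
        config.beta_carrier * ph["carrier"].to_numpy(dtype=float)
        + config.beta_prs_per_sd * z
        + config.beta_age_per_year * (ph["age_enroll"].to_numpy() - np.mean(config.age_range))
        + config.beta_male * (ph["sex"].to_numpy() == "male")
    )
    return eta


def assign_disease_cross_sectional(
    cohort: SyntheticCohort, config: SimConfig | None = None
) -> SyntheticCohort:
    """Draw prevalent disease status from a logistic model.

    disease ~ Bernoulli(sigmoid(c + beta_carrier*carrier + beta_prs*z +
    age and sex terms)), with the intercept c solved numerically so the
    marginal prevalence matches ``baseline_prevalence``.
    """
    config = config or cohort.truth["config"]
    rng = _rng(np.random.SeedSequence([config.seed, 1]))
    if config.baseline_prevalence == 0.0:
        disease = np.zeros(len(cohort.phenotypes), dtype=bool)
        intercept = -np.inf
    else:
        eta = _linear_predictor(cohort, config)
        intercept = _logit_prevalence_intercept(eta, config.baseline_prevalence)
        p = 1.0 / (1.0 + np.exp(-(intercept + eta)))
        disease = rng.random(len(p)) < p
    cohort.phenotypes = cohort.phenotypes.assign(disease=disease)
    cohort.truth["prevalence_intercept"] = intercept
    return cohort


def assign_onset_ages(
    cohort: SyntheticCohort, config: SimConfig | None = None
) -> SyntheticCohort:
    """Draw age at onset from a Weibull proportional-hazards model.

    Baseline survivor S0(t) = exp(-(t/scale)^shape); with linear predictor
    eta the onset age is ``scale * (-log(U) * exp(-eta))^(1/shape)``.
    Censoring ages are drawn independently (uniform over
    ``censoring_age_range``); the event indicator is onset <= censoring and
    the recorded time is the minimum. ``prevalent`` flags onset before the
    enrollment age.
    """
    config = config or cohort.truth["config"]
    rng = _rng(np.random.SeedSequence([config.seed, 2]))
    ph = cohort.phenotypes
    z = cohort.truth["true_z"].to_numpy()
    eta = (
        config.beta_carrier * ph["carrier"].to_numpy(dtype=float)
        + config.beta_prs_per_sd * z
        + config.beta_male * (ph["sex"].to_numpy() == "male")
    )
    u = rng.random(len(ph))
    onset = config.hazard_scale * (-np.log(u) * np.exp(-eta)) ** (1.0 / config.hazard_shape)
    lo, hi = config.censoring_age_range
    censor = rng.uniform(lo, hi, size=len(ph)) if hi > lo else np.full(len(ph), lo)
    event = onset <= censor
    time = np.minimum(onset, censor)
    cohort.phenotypes = ph.assign(
        event=event,
        age_dx_or_censor=time,
        prevalent=event & (onset <= ph["age_enroll"].to_numpy()),
    )
    cohort.truth["onset_age"] = pd.Series(onset, index=ph.index)
    return cohort


def sample_case_control(
    cohort: SyntheticCohort, n_cases: int, n_controls: int, seed: int
) -> SyntheticCohort:
    """Uniform subsample without replacement within case/control strata."""
    ph = cohort.phenotypes
    if "disease" not in ph.columns:
        raise ValueError("assign disease status before case-control sampling")
    rng = _rng(seed)
    cases = ph.index[ph["disease"]]
    controls = ph.index[~ph["disease"]]
    if n_cases > len(cases):
        raise ValueError(f"requested {n_cases} cases, only {len(cases)} available")
    if n_controls > len(controls):
        raise ValueError(
            f"requested {n_controls} controls, only {len(controls)} available"
        )
    keep = rng.choice(cases, size=n_cases, replace=False).tolist()
    keep += rng.choice(controls, size=n_controls, replace=False).tolist()
    keep = pd.Index(keep)
    sub = SyntheticCohort(
        phenotypes=ph.loc[keep].copy(),
        dosages=cohort.dosages.loc[keep].copy(),
        rare_dosages=cohort.rare_dosages.loc[keep].copy(),
        weights=cohort.weights.copy(),
        annotations=cohort.annotations.copy(),
        gene_regions=cohort.gene_regions.copy(),
        truth={**cohort.truth, "sample_seed": seed,
               "true_z": cohort.truth["true_z"].loc[keep]},
    )
    sub.require_aligned()
    return sub


def generate_variant_annotations(
    n_variants: int = 100,
    consequence_proportions: dict[str, float] | None = None,
    classification_proportions: dict[str, float] | None = None,
    flag_probability: float = 0.05,
    common_fraction: float = 0.2,
    genes: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy annotation table for exercising the variant filters.

    Consequence classes, pathogenicity classes (P/LP/VUS/LB/B),
    per-subpopulation allele frequencies and low-complexity /
    segmental-duplication / random-forest flags are drawn at configurable
    proportions; ``common_fraction`` of variants get one subpopulation
    frequency pushed above typical rare-variant thresholds.
    """
    rng = _rng(seed)
    cons_p = consequence_proportions or {
        "synonymous": 0.3, "missense": 0.4, "nonsense": 0.1,
        "frameshift": 0.1, "canonical_splice": 0.05, "other": 0.05,
    }
    class_p = classification_proportions or {
        "P": 0.1, "LP": 0.1, "VUS": 0.4, "LB": 0.2, "B": 0.2,
    }
    for label, props in (("consequence", cons_p), ("classification", class_p)):
        bad = set(props) - set(CONSEQUENCES if label == "consequence" else CLASSIFICATIONS)
        if bad:
            raise ValueError(f"unknown {label} labels: {sorted(bad)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError(f"{label} proportions must sum to 1")
    genes = genes or sum(CONDITION_GENES.values(), [])
    tbl = {
        "variant_id": [f"v{j:04d}" for j in range(n_variants)],
        "gene": rng.choice(genes, size=n_variants),
        "consequence": rng.choice(list(cons_p), size=n_variants,
                                  p=list(cons_p.values())),
        "low_complexity": rng.random(n_variants) < flag_probability,
        "segdup": rng.random(n_variants) < flag_probability,
        "rf_pass": rng.random(n_variants) >= flag_probability,
        "classification": rng.choice(list(class_p), size=n_variants,
                                     p=list(class_p.values())),
    }
    for sp in SUBPOPULATIONS:
        tbl[f"af_{sp}"] = rng.uniform(0.0, 0.004, size=n_variants)
    common = rng.random(n_variants) < common_fraction
    which_sp = rng.choice(SUBPOPULATIONS, size=n_variants)
    for sp in SUBPOPULATIONS:
        sel = common & (which_sp == sp)
        tbl[f"af_{sp}"] = np.where(sel, rng.uniform(0.006, 0.5, size=n_variants),
                                   tbl[f"af_{sp}"])
    return pd.DataFrame(tbl)
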