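"""Synthetic cohort generator.

Emulates the schema of a large UK-population cohort with food-liking
questionnaire data: 140 food-liking items on a 9-point scale drawn from a
three-component mixture (one component per food-preference profile),
demographics and clinical measurements, average daily nutrient intakes,
a binary cardiovascular-disease (CVD) outcome from a logistic model whose
profile terms are log odds ratios, and an onset age in which higher-risk
intake levels shift disease onset earlier.

The generator exists so that every downstream stage (profile fitting,
risk harness, survival-based intake limits, recommendation engine) can be
exercised and tested against planted ground truth without any restricted
data access.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROFILES = ("health_conscious", "omnivore", "sweet_tooth")

LIKING_GROUPS = ("fruit_veg", "meat_fish", "sweet", "other")

#: The six nutrients targeted by level-2 advice, plus the remaining intake
#: fields carried by the participant schema.
LEVEL2_NUTRIENTS = ("energy_kj", "protein_g", "sfa_g", "tfa_g", "omega3_g", "omega6_g")
ALL_NUTRIENTS = LEVEL2_NUTRIENTS + ("fat_g", "carbohydrate_g", "alcohol_g", "fiber_g")

CLINICAL_COLUMNS = (
    "age", "sex", "sbp", "dbp", "total_chol", "hdl", "bmi", "wc",
    "smoking", "htn_treatment", "htn_history",
)

PORTION_FOODS = ("oily_fish", "nonoily_fish", "processed_meat", "poultry", "red_meat")

# ---------------------------------------------------------------------------
# Item catalog: 140 liking items partitioned into four food groups.  The 14
# items used by the simplified questionnaire keep their real names; the
# remainder are synthetic fillers named by group.
# ---------------------------------------------------------------------------

_NAMED_ITEMS = {
    "fruit_veg": ["vegetables", "tomatoes", "strawberries", "green_olives",
                  "banana", "fruit", "mushroom", "spinach", "potatoes"],
    "meat_fish": ["roast_chicken", "ham"],
    "sweet": ["tea_with_sugar", "sweet_coffee_drinks", "coffee_with_sugar"],
    "other": [],
}
_GROUP_SIZES = {"fruit_veg": 40, "meat_fish": 35, "sweet": 30, "other": 35}


def _build_catalog() -> dict[str, str]:
    """Return ordered map item-name -> food group (140 entries)."""
    catalog: dict[str, str] = {}
    for group in LIKING_GROUPS:
        names = list(_NAMED_ITEMS[group])
        i = 1
        while len(names) < _GROUP_SIZES[group]:
            names.append(f"{group}_{i:02d}")
            i += 1
        for name in names:
            catalog[name] = group
    return catalog


ITEM_CATALOG: dict[str, str] = _build_catalog()
ITEM_NAMES: tuple[str, ...] = tuple(ITEM_CATALOG)
assert len(ITEM_NAMES) == 140

LIKING_PREFIX = "like_"


def liking_columns() -> list[str]:
    """Column names of the 140 liking items as stored in cohort tables."""
    return [LIKING_PREFIX + n for n in ITEM_NAMES]


def items_in_group(group: str) -> list[str]:
    return [n for n, g in ITEM_CATALOG.items() if g == group]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Per-profile mean liking by food group.  Health-conscious people like
#: fruit & veg most and sweetened drinks least; sweet-tooth the reverse;
#: omnivores like meat/fish most with broad middling preferences.
DEFAULT_LIKING_MEANS = {
    "health_conscious": {"fruit_veg": 7.5, "meat_fish": 4.5, "sweet": 3.0, "other": 5.0},
    "omnivore": {"fruit_veg": 6.0, "meat_fish": 7.0, "sweet": 5.5, "other": 6.0},
    "sweet_tooth": {"fruit_veg": 4.5, "meat_fish": 4.5, "sweet": 7.5, "other": 4.5},
}

#: Lognormal intake parameters (mean, sd of log intake) per nutrient.
DEFAULT_NUTRIENT_LOGPARAMS = {
    "energy_kj": (9.05, 0.22),    # median ~8500 kJ/day
    "protein_g": (4.35, 0.25),    # ~77 g/day
    "sfa_g": (3.25, 0.30),        # ~26 g/day
    "tfa_g": (0.10, 0.45),        # ~1.1 g/day
    "omega3_g": (0.65, 0.35),     # ~1.9 g/day
    "omega6_g": (2.35, 0.30),     # ~10.5 g/day
    "fat_g": (4.30, 0.25),
    "carbohydrate_g": (5.45, 0.22),
    "alcohol_g": (2.20, 0.80),
    "fiber_g": (2.75, 0.28),
}

#: Per-nutrient log-odds coefficient in the CVD outcome model
#: (per unit/day; e.g. 1.6e-5 per kJ of energy).
DEFAULT_INTAKE_LOGIT_COEFS = {
    "energy_kj": 1.6e-5,
    "protein_g": 2.5e-3,
    "sfa_g": 3.0e-3,
    "tfa_g": 3.0e-2,
    "omega3_g": 3.0e-2,
    "omega6_g": 2.0e-2,
}

#: Per-nutrient effect (per SD of log intake) on the log Weibull scale of the
#: onset-age model; positive values shift onset earlier at high intake.
DEFAULT_INTAKE_HAZARD_COEFS = {"energy_kj": 0.15, "sfa_g": 0.10}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    mixing_weights must sum to 1 with every component holding at least 10%
    of the population, mirroring the minimum-profile-size rule applied when
    the latent profiles were originally selected.
    """

    n_participants: int = 2000
    seed: int = 83988
    mixing_weights: tuple[float, float, float] = (0.35, 0.40, 0.25)
    liking_means: dict = field(default_factory=lambda: {
        p: dict(v) for p, v in DEFAULT_LIKING_MEANS.items()})
    liking_sd: float = 1.5
    profile_or: dict = field(default_factory=lambda: {
        "health_conscious": 0.74, "omnivore": 1.16, "sweet_tooth": 1.17})
    baseline_cvd_prob: float = 0.15
    nutrient_logparams: dict = field(default_factory=lambda: dict(DEFAULT_NUTRIENT_LOGPARAMS))
    intake_logit_coefs: dict = field(default_factory=lambda: dict(DEFAULT_INTAKE_LOGIT_COEFS))
    intake_hazard_coefs: dict = field(default_factory=lambda: dict(DEFAULT_INTAKE_HAZARD_COEFS))
    intake_risk_shape: str = "linear"   # "linear" or "ushape" onset-age hazard
    censor_age: float = 68.0
    missing_rate: float = 0.05
    onset_shape: float = 3.0            # Weibull shape of the onset-age model
    onset_scale_years: float = 28.0     # baseline Weibull scale (years past 40)

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be non-negative")
        w = np.asarray(self.mixing_weights, dtype=float)
        if w.shape != (3,):
            raise ConfigurationError("mixing_weights must have 3 components")
        if not np.isclose(w.sum(), 1.0, atol=1e-8):
            raise ConfigurationError(f"mixing_weights must sum to 1, got {w.sum():.4f}")
        if (w < 0.10).any():
            raise ConfigurationError(
                "each mixing weight must be at least 0.10 "
                "(minimum-profile-size rule)")
        if not 0.0 <= self.baseline_cvd_prob <= 1.0:
            raise ConfigurationError("baseline_cvd_prob must be a probability")
        if self.liking_sd <= 0:
            raise ConfigurationError("liking_sd must be positive")
        if self.censor_age <= 0:
            raise ConfigurationError("censor_age must be positive")
        if self.intake_risk_shape not in ("linear", "ushape"):
            raise ConfigurationError("intake_risk_shape must be 'linear' or 'ushape'")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort: one row per participant plus the true profile
    labels used during generation (the oracle for classifier tests)."""

    data: pd.DataFrame
    true_profile: pd.Series
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.data)


def calibrate_profile_logits(config: CohortConfig) -> np.ndarray:
    """Per-profile baseline log-odds of CVD.

    The configured odds ratios are group-vs-rest contrasts (each profile's
    odds against the pooled other profiles), so raw log-OR offsets against
    a common intercept would not reproduce them.  This solves for the
    three profile probabilities that (a) yield the configured
    group-vs-rest odds ratios and (b) give a marginal prevalence equal to
    ``baseline_cvd_prob``, by deterministic least squares on the log-odds
    scale (residuals are negligible for realistic odds-ratio triples)."""
    from scipy.optimize import least_squares
    from scipy.special import expit, logit

    w = np.asarray(config.mixing_weights, dtype=float)
    ors = np.array([config.profile_or[p] for p in PROFILES])

    def resid(x):
        p = expit(x)
        out = []
        for k in range(3):
            rest = np.delete(np.arange(3), k)
            p_rest = (w[rest] * p[rest]).sum() / w[rest].sum()
            out.append(logit(p[k]) - logit(p_rest) - np.log(ors[k]))
        out.append(logit((w * p).sum()) - logit(config.baseline_cvd_prob))
        return out

    x0 = logit(np.full(3, config.baseline_cvd_prob))
    return least_squares(resid, x0).x


def expected_cvd_fraction(config: CohortConfig) -> float:
    """Closed-form marginal CVD probability implied by the configuration:
    the mixture over profiles of the calibrated per-profile probabilities
    (intake effects are mean-centred and contribute no first-order
    shift)."""
    from scipy.special import expit

    p = expit(calibrate_profile_logits(config))
    return float((np.asarray(config.mixing_weights) * p).sum())


def generate_cohort(config: CohortConfig | None = None, **overrides) -> SyntheticCohort:
    """Generate a synthetic cohort.

    Deterministic for a fixed seed.  Liking scores are drawn from the
    three-component mixture, rounded to integers and clipped to [1, 9];
    the CVD outcome comes from a logistic model whose profile terms are
    calibrated so the group-vs-rest odds ratios equal ``profile_or`` (see
    :func:`calibrate_profile_logits`), plus small mean-centred intake
    terms; onset age is Weibull with scale shrinking in the intake linear
    predictor so that higher-risk intakes have earlier onset.
    """
    if config is None:
        config = CohortConfig()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    cols = liking_columns()
    if n == 0:
        empty = pd.DataFrame(columns=list(CLINICAL_COLUMNS) + cols
                             + list(ALL_NUTRIENTS)
                             + [f"portions_{f}" for f in PORTION_FOODS]
                             + ["cvd", "onset_age", "censored", "first_recall_age"])
        return SyntheticCohort(empty, pd.Series([], dtype=object, name="true_profile"), config)

    profile_idx = rng.choice(3, size=n, p=np.asarray(config.mixing_weights))
    profile = np.array(PROFILES, dtype=object)[profile_idx]

    # --- liking scores -----------------------------------------------------
    group_of_item = np.array([ITEM_CATALOG[name] for name in ITEM_NAMES])
    means = np.empty((n, 140))
    for k, prof in enumerate(PROFILES):
        mask = profile_idx == k
        if not mask.any():
            continue
        item_means = np.array([config.liking_means[prof][g] for g in group_of_item])
        means[mask] = item_means
    liking = rng.normal(means, config.liking_sd)
    liking = np.clip(np.rint(liking), 1, 9).astype(float)

    # --- demographics & clinical ------------------------------------------
    age = np.clip(rng.normal(57.0, 8.0, n), 40.0, 70.0)
    sex = rng.integers(0, 2, n)
    sbp = np.clip(rng.normal(138.0, 18.0, n), 90.0, 220.0)
    dbp = np.clip(rng.normal(82.0, 10.0, n), 50.0, 130.0)
    total_chol = np.clip(rng.normal(5.7, 1.1, n), 2.5, 12.0)
    hdl = np.clip(rng.normal(1.45, 0.38, n), 0.5, 4.0)
    bmi = np.clip(rng.normal(27.3, 4.5, n), 15.0, 55.0)
    wc = np.clip(rng.normal(90.0, 12.5, n), 55.0, 160.0)
    smoking = rng.choice(["never", "previous", "current"], size=n, p=[0.55, 0.35, 0.10])
    htn_treatment = (rng.random(n) < 0.20).astype(int)
    htn_history = np.where(htn_treatment == 1, 1, (rng.random(n) < 0.12).astype(int))

    # --- nutrient intakes (lognormal) -------------------------------------
    intakes = {}
    for nutrient, (mu, sd) in config.nutrient_logparams.items():
        intakes[nutrient] = rng.lognormal(mu, sd, n)

    # --- CVD outcome -------------------------------------------------------
    from scipy.special import expit

    profile_logits = calibrate_profile_logits(config)
    lp = profile_logits[profile_idx].astype(float)
    for nutrient, coef in config.intake_logit_coefs.items():
        x = intakes[nutrient]
        mu, sd = config.nutrient_logparams[nutrient]
        lp += coef * (x - np.exp(mu + 0.5 * sd ** 2))
    cvd = (rng.random(n) < expit(lp)).astype(int)

    # --- onset age ---------------------------------------------------------
    hz = np.zeros(n)
    for nutrient, coef in config.intake_hazard_coefs.items():
        mu, sd = config.nutrient_logparams[nutrient]
        z = (np.log(intakes[nutrient]) - mu) / sd
        if config.intake_risk_shape == "ushape":
            hz += coef * (z ** 2 - 1.0)   # middle intakes safest
        else:
            hz += coef * z
    weib = rng.weibull(config.onset_shape, n)
    latent_onset = 40.0 + config.onset_scale_years * weib * np.exp(-hz)

    first_recall_age = age  # dietary recall taken at recruitment
    onset_age = np.where(cvd == 1, latent_onset, config.censor_age)
    censored = (cvd == 0)

    # --- level-1 food-group portions (portions/week) -----------------------
    portion_rates = {"oily_fish": 0.8, "nonoily_fish": 1.2, "processed_meat": 2.5,
                     "poultry": 2.0, "red_meat": 2.8}
    portions = {f: rng.poisson(portion_rates[f], n).astype(float) for f in PORTION_FOODS}

    columns: dict[str, np.ndarray] = {
        "age": age, "sex": sex, "sbp": sbp, "dbp": dbp,
        "total_chol": total_chol, "hdl": hdl, "bmi": bmi, "wc": wc,
        "smoking": smoking, "htn_treatment": htn_treatment,
        "htn_history": htn_history,
    }
    for j, col in enumerate(cols):
        columns[col] = liking[:, j]
    for nutrient in ALL_NUTRIENTS:
        columns[nutrient] = intakes[nutrient]
    for f in PORTION_FOODS:
        columns[f"portions_{f}"] = portions[f]
    columns["cvd"] = cvd
    columns["onset_age"] = onset_age
    columns["censored"] = censored.astype(int)
    columns["first_recall_age"] = first_recall_age
    data = pd.DataFrame(columns)

    # --- missingness (MAR) -------------------------------------------------
    if config.missing_rate > 0:
        missable = cols + list(ALL_NUTRIENTS) + ["sbp", "dbp", "total_chol",
                                                 "hdl", "bmi", "wc"]
        mask = rng.random((n, len(missable))) < config.missing_rate
        vals = data[missable].to_numpy(dtype=float)
        vals[mask] = np.nan
        data[missable] = vals

    true_profile = pd.Series(profile, name="true_profile")
    return SyntheticCohort(data, true_profile, config)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, path: str, sidecar: bool = True) -> None:
    """Write the cohort as CSV (with the true profile as a final column)
    plus a JSON sidecar of the generation parameters."""
    out = cohort.data.copy()
    out["true_profile"] = cohort.true_profile.values
    out.to_csv(path, index=False)
    if sidecar:
        params = dataclasses.asdict(cohort.config)
        with open(str(path) + ".params.json", "w") as fh:
            json.dump(params, fh, indent=2, default=str)


def read_cohort(path: str) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    return pd.read_csv(path)
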