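"""Per-profile optimal nutrient intake ranges and required changes.

The optimal range [min_val, max_val] for each (profile, nutrient) comes
from survival analysis of disease onset over intake bins: intakes are
split into equal-frequency bins, a Kaplan-Meier curve of CVD-free
survival (age axis, right-censored at 68 years) is estimated per bin, and
the bin with the best survival — largest restricted-mean survival up to
the censoring age — defines the range.  Trans-fatty acids have no known
safe lower limit, so their minimum is fixed at 0.

The required change per nutrient converts a target risk decrease on the
log-odds scale into an intake change through the per-profile logistic
coefficient: delta_n = delta_r / beta.

The constants published for the three profiles and six level-2 nutrients
ship as package data (see ``packaged_params``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cohort import PROFILES

LEVEL2_NUTRIENTS = ("energy_kj", "protein_g", "sfa_g", "tfa_g", "omega3_g", "omega6_g")
NO_LOWER_LIMIT_NUTRIENTS = ("tfa_g",)
DEFAULT_CENSOR_AGE = 68.0
DEFAULT_DELTA_R = 0.01


# ---------------------------------------------------------------------------
# Kaplan-Meier estimator
# ---------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Product-limit survival estimate over distinct event ages."""

    times: np.ndarray       # ascending distinct event ages
    survival: np.ndarray    # S(t) just after each event age
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival just after age t (1 before the first event)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def restricted_mean(self, horizon: float) -> float:
        """Area under the step curve from 0 to ``horizon``."""
        rmst, prev_t, prev_s = 0.0, 0.0, 1.0
        for t, s in zip(self.times, self.survival):
            if t >= horizon:
                break
            rmst += prev_s * (t - prev_t)
            prev_t, prev_s = t, s
        rmst += prev_s * (horizon - prev_t)
        return rmst


def km_estimate(onset_ages, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i).

    ``onset_ages`` are event or censoring ages; ``event_flags`` is 1 when
    the age is a disease onset and 0 when censored.  Ties between events
    and censorings at the same age follow the standard convention that
    censored subjects remain at risk for events at that age.
    """
    ages = np.asarray(onset_ages, dtype=float)
    flags = np.asarray(event_flags, dtype=int)
    if ages.size == 0:
        raise ValueError("empty input: no subjects")
    if (ages <= 0).any():
        raise ValueError("onset/censoring ages must be positive")
    if not np.isin(flags, [0, 1]).all():
        raise ValueError("event flags must be binary")

    event_times = np.unique(ages[flags == 1])
    times, surv, at_risk, events = [], [], [], []
    s = 1.0
    for t in event_times:
        n_i = int((ages >= t).sum())
        d_i = int(((ages == t) & (flags == 1)).sum())
        s *= 1.0 - d_i / n_i
        times.append(t)
        surv.append(s)
        at_risk.append(n_i)
        events.append(d_i)
    return SurvivalCurve(np.asarray(times), np.asarray(surv),
                         np.asarray(at_risk), np.asarray(events))


# ---------------------------------------------------------------------------
# Survival cohort preparation
# ---------------------------------------------------------------------------

def prepare_survival_cohort(records: pd.DataFrame,
                            censor_age: float = DEFAULT_CENSOR_AGE,
                            first_recall_col: str = "first_recall_age") -> pd.DataFrame:
    """Apply the survival-analysis filters.

    Participants whose CVD onset precedes their first dietary recall are
    removed (their reported diet could reflect the diagnosis); all
    remaining follow-up is right-censored at ``censor_age``: events after
    that age have their flag cleared and age set to the censoring age.
    """
    if censor_age <= 0:
        raise ValueError("censor_age must be positive")
    out = records.copy()
    if first_recall_col in out.columns:
        pre_dx = (out["cvd"] == 1) & (out["onset_age"] < out[first_recall_col])
        out = out[~pre_dx].copy()
    late = out["onset_age"] > censor_age
    out.loc[late, "cvd"] = 0
    out.loc[late & (out["cvd"] == 0), "censored"] = 1
    out.loc[late, "onset_age"] = censor_age
    return out


# ---------------------------------------------------------------------------
# Optimal range derivation
# ---------------------------------------------------------------------------

@dataclass
class LimitResult:
    min_val: float
    max_val: float
    best_bin: int
    n_bins: int
    bin_edges: np.ndarray
    rmst_per_bin: list[float]
    stability: float | None = None   # bootstrap agreement with best_bin


def derive_limits(records: pd.DataFrame, profile: str, nutrient: str,
                  n_bins: int = 4, censor_age: float = DEFAULT_CENSOR_AGE,
                  profile_col: str = "profile",
                  n_bootstrap: int = 0, seed: int = 0) -> LimitResult:
    """Optimal intake range for one (profile, nutrient).

    Intake is split into ``n_bins`` equal-frequency bins; a KM curve is
    estimated per bin and the bin with the largest restricted-mean
    survival up to ``censor_age`` (ties: later median onset, then lower
    bin index) supplies the range boundaries.  When ``n_bootstrap`` > 0, a
    bootstrap stability score (fraction of resamples selecting the same
    bin) is attached — low values flag an intake with no real effect.
    """
    sub = records[records[profile_col] == profile] if profile_col in records.columns \
        else records
    sub = sub.dropna(subset=[nutrient, "onset_age", "cvd"])
    if len(sub) < n_bins * 20:
        raise ValueError(f"need at least {n_bins * 20} records per profile, "
                         f"got {len(sub)}")
    intake = sub[nutrient].to_numpy(dtype=float)
    ages = sub["onset_age"].to_numpy(dtype=float)
    flags = sub["cvd"].to_numpy(dtype=int)

    binned, edges = _equal_frequency_bins(intake, n_bins)
    n_bins_eff = len(edges) - 1
    best, rmst = _select_best_bin(binned, edges, intake, ages, flags,
                                  n_bins_eff, censor_age)

    stability = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        agree = 0
        for _ in range(n_bootstrap):
            idx = rng.integers(0, len(sub), len(sub))
            b, e = _equal_frequency_bins(intake[idx], n_bins)
            bb, _ = _select_best_bin(b, e, intake[idx], ages[idx], flags[idx],
                                     len(e) - 1, censor_age)
            agree += (bb == best)
        stability = agree / n_bootstrap

    min_val = float(edges[best])
    max_val = float(edges[best + 1])
    if nutrient in NO_LOWER_LIMIT_NUTRIENTS:
        min_val = 0.0
    return LimitResult(min_val, max_val, best, n_bins_eff, edges, rmst, stability)


def _equal_frequency_bins(x: np.ndarray, n_bins: int):
    quantiles = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(x, quantiles))
    if len(edges) - 1 < n_bins:
        warnings.warn(f"ties in intake reduce bins from {n_bins} to {len(edges) - 1}")
    binned = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    return binned, edges


def _select_best_bin(binned, edges, intake, ages, flags, n_bins, censor_age):
    rmst, median_onset = [], []
    for b in range(n_bins):
        mask = binned == b
        curve = km_estimate(ages[mask], flags[mask])
        rmst.append(curve.restricted_mean(censor_age))
        ev = ages[mask & (flags == 1)]
        median_onset.append(float(np.median(ev)) if ev.size else np.inf)
    rmst_arr = np.asarray(rmst)
    top = np.isclose(rmst_arr, rmst_arr.max(), rtol=0, atol=1e-9)
    cand = np.where(top)[0]
    if len(cand) > 1:   # tie: later median onset wins, then lower index
        onset = np.asarray(median_onset)[cand]
        cand = cand[onset == onset.max()]
    return int(cand[0]), rmst


# ---------------------------------------------------------------------------
# Required change (target risk decrease -> intake change)
# ---------------------------------------------------------------------------

def required_change(beta: float, delta_r: float = DEFAULT_DELTA_R) -> float:
    """Intake change achieving a log-odds decrease of ``delta_r``:
    delta_n = delta_r / beta.  Signs carry through; beta = 0 has no finite
    solution and raises."""
    if beta == 0 or not np.isfinite(beta):
        raise ValueError("beta must be nonzero and finite")
    return delta_r / beta


def probability_target_to_logodds(delta_p: float, at_probability: float = 0.41) -> float:
    """Convert a probability-scale risk target into the local log-odds
    change at ``at_probability`` (derivative of the logistic link)."""
    p = at_probability
    return delta_p / (p * (1.0 - p))


# ---------------------------------------------------------------------------
# Packaged per-profile constants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NutrientParams:
    profile: str
    nutrient: str
    delta_n: float
    min_val: float
    max_val: float
    units: str


class ParamsTable:
    """The packaged per-profile nutrient parameter table."""

    def __init__(self, raw: dict):
        validate_params_schema(raw)
        self._raw = raw
        self.delta_r = float(raw.get("delta_r", DEFAULT_DELTA_R))
        self._cells: dict[tuple[str, str], NutrientParams] = {}
        for prof, nutrients in raw["profiles"].items():
            for nut, cell in nutrients.items():
                self._cells[(prof, nut)] = NutrientParams(
                    profile=prof, nutrient=nut,
                    delta_n=float(cell["delta_n"]),
                    min_val=float(cell["min"]), max_val=float(cell["max"]),
                    units=raw.get("units", {}).get(nut, ""))

    def lookup(self, profile: str, nutrient: str) -> NutrientParams:
        try:
            return self._cells[(profile, nutrient)]
        except KeyError:
            raise KeyError(f"no parameters for ({profile!r}, {nutrient!r})") from None

    def nutrients(self) -> list[str]:
        return sorted({n for _, n in self._cells})

    def profiles(self) -> list[str]:
        return sorted({p for p, _ in self._cells})

    def to_frame(self) -> pd.DataFrame:
        rows = [{"profile": c.profile, "nutrient": c.nutrient,
                 "delta_n": c.delta_n, "min_val": c.min_val,
                 "max_val": c.max_val, "units": c.units}
                for c in self._cells.values()]
        return pd.DataFrame(rows)


def validate_params_schema(raw: dict) -> None:
    """Schema check for a parameter table; raises ValueError naming the
    offending field."""
    if "profiles" not in raw:
        raise ValueError("params file missing 'profiles' section")
    for prof, nutrients in raw["profiles"].items():
        if prof not in PROFILES:
            raise ValueError(f"unknown profile '{prof}' in params file")
        for nut, cell in nutrients.items():
            for key in ("delta_n", "min", "max"):
                if key not in cell:
                    raise ValueError(f"params cell ({prof}, {nut}) missing '{key}'")
            if float(cell["min"]) > float(cell["max"]):
                raise ValueError(f"params cell ({prof}, {nut}): min > max")
            if nut in NO_LOWER_LIMIT_NUTRIENTS and float(cell["min"]) != 0:
                raise ValueError(f"params cell ({prof}, {nut}): TFA min must be 0")


def load_params(path: str | None = None) -> ParamsTable:
    """Load a parameter table from YAML; default is the packaged table."""
    if path is None:
        src = resources.files("nutriprofile.data").joinpath("table3.yaml")
        with src.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return ParamsTable(raw)


def packaged_params() -> ParamsTable:
    """The published per-profile constants (delta_n and optimal ranges for
    energy, protein, SFA, TFA, omega-3 and omega-6, for the three
    profiles)."""
    return load_params(None)
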