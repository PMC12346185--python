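"""Kaplan-Meier estimation, survival preparation and intake-limit derivation."""

import numpy as np
import pandas as pd
import pytest

from nutriprofile import (km_estimate, prepare_survival_cohort, derive_limits,
                          required_change, packaged_params)
from nutriprofile.cohort import PROFILES
from nutriprofile.limits import (LEVEL2_NUTRIENTS, ParamsTable,
                                 probability_target_to_logodds,
                                 validate_params_schema)


# --- Kaplan-Meier -------------------------------------------------------------

def test_hand_product_limit_three_subjects():
    """Events at ages 1 and 2, one censored at 3: S=2/3 then 1/3."""
    curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
    np.testing.assert_allclose(curve.times, [1.0, 2.0])
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3])
    assert curve.at(0.5) == 1.0
    assert curve.at(1.5) == pytest.approx(2 / 3)
    assert curve.at(10.0) == pytest.approx(1 / 3)


def test_all_censored_survival_is_one():
    curve = km_estimate([5.0, 6.0, 7.0], [0, 0, 0])
    assert curve.times.size == 0
    assert curve.at(100.0) == 1.0


def test_no_censoring_equals_empirical_survival():
    ages = np.array([2.0, 4.0, 4.0, 6.0, 9.0])
    curve = km_estimate(ages, np.ones(5, dtype=int))
    for t in [1, 3, 5, 8, 10]:
        assert curve.at(t) == pytest.approx((ages > t).mean())


def test_matches_reference_implementation_on_random_instances():
    """Dual route: our product-limit vs lifelines on 100 random datasets."""
    from lifelines import KaplanMeierFitter
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(3, 40)
        ages = rng.uniform(1, 80, n).round(1)
        flags = rng.integers(0, 2, n)
        curve = km_estimate(ages, flags)
        kmf = KaplanMeierFitter().fit(ages, flags)
        for t in rng.uniform(0, 90, 5):
            assert curve.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)


def test_empty_input_raises():
    with pytest.raises(ValueError):
        km_estimate([], [])


def test_restricted_mean_of_step_curve():
    curve = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
    # area: 1*1 + (2/3)*1 + (1/3)*2 up to horizon 4
    assert curve.restricted_mean(4.0) == pytest.approx(1 + 2 / 3 + 2 / 3)


# --- survival cohort preparation ---------------------------------------------

def _records(rows):
    return pd.DataFrame(rows, columns=["cvd", "onset_age", "censored",
                                       "first_recall_age"])


def test_event_after_censor_age_becomes_censored_at_68():
    rec = _records([[1, 70.0, 0, 55.0]])
    out = prepare_survival_cohort(rec, censor_age=68)
    assert out.iloc[0]["cvd"] == 0
    assert out.iloc[0]["onset_age"] == 68.0
    assert out.iloc[0]["censored"] == 1


def test_pre_recall_diagnosis_removed():
    rec = _records([[1, 50.0, 0, 55.0], [1, 60.0, 0, 55.0]])
    out = prepare_survival_cohort(rec)
    assert len(out) == 1
    assert out.iloc[0]["onset_age"] == 60.0


def test_cohort_without_exclusions_unchanged():
    rec = _records([[1, 60.0, 0, 55.0], [0, 68.0, 1, 50.0]])
    out = prepare_survival_cohort(rec)
    assert len(out) == 2


def test_invalid_censor_age_raises():
    with pytest.raises(ValueError):
        prepare_survival_cohort(_records([[0, 68.0, 1, 50.0]]), censor_age=0)


# --- limit derivation ---------------------------------------------------------

def _survival_frame(n, rng, ushape=False):
    intake = rng.lognormal(9.0, 0.25, n)
    z = (np.log(intake) - 9.0) / 0.25
    risk = (z ** 2 - 1) if ushape else z
    onset = 40 + 28 * rng.weibull(3.0, n) * np.exp(-0.4 * risk)
    cvd = (rng.random(n) < 0.35).astype(int)
    onset_age = np.where(cvd == 1, onset, 68.0)
    return pd.DataFrame({"intake": intake, "onset_age": onset_age,
                         "cvd": cvd, "profile": "omnivore"})


def test_u_shaped_risk_selects_a_middle_bin():
    rng = np.random.default_rng(8)
    frame = _survival_frame(4000, rng, ushape=True)
    res = derive_limits(frame, "omnivore", "intake", n_bins=4)
    assert res.best_bin in (1, 2)
    assert res.min_val >= np.quantile(frame["intake"], 0.2)
    assert res.max_val <= np.quantile(frame["intake"], 0.8)


def test_monotone_risk_selects_lowest_intake_bin():
    rng = np.random.default_rng(9)
    frame = _survival_frame(4000, rng, ushape=False)
    res = derive_limits(frame, "omnivore", "intake", n_bins=4)
    assert res.best_bin == 0


def test_equal_frequency_bins_and_order_invariance():
    rng = np.random.default_rng(10)
    frame = _survival_frame(800, rng)
    res = derive_limits(frame, "omnivore", "intake", n_bins=4)
    binned = pd.cut(frame["intake"], bins=res.bin_edges, include_lowest=True)
    counts = binned.value_counts()
    assert counts.max() - counts.min() <= 2
    shuffled = frame.sample(frac=1.0, random_state=1)
    res2 = derive_limits(shuffled, "omnivore", "intake", n_bins=4)
    assert res2.best_bin == res.best_bin
    assert res2.min_val == res.min_val


def test_null_intake_effect_has_low_bootstrap_stability():
    rng = np.random.default_rng(11)
    frame = _survival_frame(800, rng)
    frame["onset_age"] = np.where(frame["cvd"] == 1,
                                  40 + 28 * rng.weibull(3.0, len(frame)), 68.0)
    res = derive_limits(frame, "omnivore", "intake", n_bins=4,
                        n_bootstrap=40, seed=0)
    assert res.stability is not None and res.stability < 0.9


def test_tfa_lower_bound_forced_to_zero():
    rng = np.random.default_rng(12)
    frame = _survival_frame(800, rng).rename(columns={"intake": "tfa_g"})
    res = derive_limits(frame, "omnivore", "tfa_g", n_bins=4)
    assert res.min_val == 0.0


def test_ties_reduce_bins_with_warning():
    frame = pd.DataFrame({
        "intake": [1.0] * 90 + [2.0] * 10,
        "onset_age": np.linspace(41, 67, 100),
        "cvd": [1] * 100,
        "profile": "omnivore",
    })
    with pytest.warns(UserWarning, match="reduce bins"):
        res = derive_limits(frame, "omnivore", "intake", n_bins=4)
    assert res.n_bins < 4


def test_too_few_records_raises():
    frame = pd.DataFrame({"intake": [1.0] * 10, "onset_age": [50.0] * 10,
                          "cvd": [1] * 10, "profile": "omnivore"})
    with pytest.raises(ValueError):
        derive_limits(frame, "omnivore", "intake", n_bins=4)


# --- required change ----------------------------------------------------------

def test_unit_beta_gives_delta_r():
    assert required_change(1.0, 0.01) == pytest.approx(0.01)


def test_energy_coefficient_reproduces_published_omnivore_change():
    assert required_change(-1.6051e-5, 0.01) == pytest.approx(-623, abs=0.5)


def test_required_change_monotone_shrinks_with_beta():
    vals = [abs(required_change(b, 0.01)) for b in (0.1, 1.0, 10.0, 100.0)]
    assert vals == sorted(vals, reverse=True)


def test_zero_beta_raises():
    with pytest.raises(ValueError):
        required_change(0.0)


def test_probability_target_local_conversion():
    # at P=0.41 the logistic derivative is p(1-p)=0.2419
    assert probability_target_to_logodds(0.01, 0.41) == pytest.approx(
        0.01 / (0.41 * 0.59))


# --- packaged constants -------------------------------------------------------

def test_packaged_lookup_values():
    params = packaged_params()
    assert params.lookup("omnivore", "energy_kj").delta_n == -623
    assert params.lookup("health_conscious", "protein_g").max_val == 87.85
    for prof in PROFILES:
        assert params.lookup(prof, "tfa_g").min_val == 0.0


def test_packaged_table_complete_and_ordered():
    params = packaged_params()
    frame = params.to_frame()
    assert len(frame) == 18        # 3 profiles x 6 nutrients
    assert (frame["min_val"] <= frame["max_val"]).all()
    assert set(params.nutrients()) == set(LEVEL2_NUTRIENTS)


def test_schema_validation_names_offending_field():
    bad = {"profiles": {"omnivore": {"tfa_g": {"delta_n": -0.3, "min": 0.1,
                                               "max": 1.5}}}}
    with pytest.raises(ValueError, match="TFA min"):
        validate_params_schema(bad)
    with pytest.raises(ValueError, match="min > max"):
        ParamsTable({"profiles": {"omnivore": {"energy_kj":
                    {"delta_n": -1, "min": 10, "max": 5}}}})
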