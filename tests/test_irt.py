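import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from feverseek.irt import (
    AbilityModel,
    FeverTreatmentModel,
    ItemParameters,
    McmcConfig,
    PosteriorSamples,
    PriorSpec,
    item_probability,
    log_likelihood,
    log_prior,
    retained_draws,
)


# ---------------------------------------------------------------------------
# item probability (3PL)
# ---------------------------------------------------------------------------

def test_floor_at_large_negative_ability():
    p = item_probability(-50.0, a=1.0, b=0.0, c=0.3)
    assert p == pytest.approx(0.3, abs=1e-15)


def test_logistic_midpoint_and_arithmetic():
    assert item_probability(0.0, a=1.0, b=0.0, c=1e-300) == pytest.approx(0.5)
    assert item_probability(0.0, a=1.0, b=0.0, c=0.2) == pytest.approx(0.6)


def test_extreme_linear_predictor_stable():
    assert item_probability(700.0, a=1.0, b=0.0, c=0.2) == pytest.approx(1.0)
    assert item_probability(-700.0, a=1.0, b=0.0, c=0.2) == pytest.approx(0.2)


def test_invalid_item_parameters_rejected():
    with pytest.raises(ValueError):
        item_probability(0.0, a=1.0, b=0.0, c=1.5)
    with pytest.raises(ValueError):
        item_probability(0.0, a=-1.0, b=0.0, c=0.5)
    with pytest.raises(ValueError):
        ItemParameters(c=0.0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(
    theta=st.floats(-8, 8),
    dtheta=st.floats(0.01, 10),
    a=st.floats(0.1, 3),
    b=st.floats(-5, 5),
    c=st.floats(0.01, 0.99),
)
def test_probability_monotone_in_theta_and_bounded(theta, dtheta, a, b, c):
    p1 = item_probability(theta, a=a, b=b, c=c)
    p2 = item_probability(theta + dtheta, a=a, b=b, c=c)
    assert p2 >= p1
    assert c < p1 < 1.0  # open bounds hold away from float saturation
    # decreasing in difficulty b
    assert item_probability(theta, a=a, b=b + 1.0, c=c) <= p1


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _frame(y, t, u, item=None):
    d = {"y": y, "travel_time_min": t, "urban": u}
    if item is not None:
        d["item_id"] = item
    return pd.DataFrame(d)


def test_empty_and_single_response():
    items = ItemParameters(1.0, 0.0, 0.2)
    ability = AbilityModel(0.0, 0.0, 0.0)
    empty = _frame([np.nan, np.nan], [10.0, 20.0], [0, 1])
    assert log_likelihood(empty, items, ability) == 0.0
    one = _frame([1.0], [0.0], [0])
    # P = 0.2 + 0.8 * 0.5 = 0.6
    assert log_likelihood(one, items, ability) == pytest.approx(np.log(0.6))


def test_likelihood_matches_naive_loop_oracle():
    rng = np.random.default_rng(21)
    n = 20
    t = rng.uniform(0, 200, n)
    u = rng.integers(0, 2, n).astype(float)
    y = rng.integers(0, 2, n).astype(float)
    y[rng.choice(n, 3, replace=False)] = np.nan
    items = ItemParameters(1.3, 0.4, 0.15)
    ability = AbilityModel(0.6, -0.012, 0.25)
    expected = 0.0
    for yi, ti, ui in zip(y, t, u):
        if np.isnan(yi):
            continue
        theta = 0.6 - 0.012 * ti + 0.25 * ui
        p = 0.15 + 0.85 * expit(1.3 * theta - 0.4)
        expected += yi * np.log(p) + (1 - yi) * np.log(1 - p)
    got = log_likelihood(_frame(y, t, u), items, ability)
    assert got == pytest.approx(expected, abs=1e-12)


def test_likelihood_permutation_invariant():
    rng = np.random.default_rng(5)
    n = 50
    frame = _frame(
        rng.integers(0, 2, n).astype(float), rng.uniform(0, 120, n),
        rng.integers(0, 2, n),
    )
    items = ItemParameters(1.0, 0.0, 0.2)
    ability = AbilityModel(0.3, -0.01, 0.2)
    base = log_likelihood(frame, items, ability)
    perm = frame.sample(frac=1.0, random_state=9).reset_index(drop=True)
    assert log_likelihood(perm, items, ability) == pytest.approx(base, abs=1e-12)


def test_invalid_response_values_rejected():
    frame = _frame([2.0], [0.0], [0])
    with pytest.raises(ValueError, match="0, 1 or missing"):
        log_likelihood(frame, ItemParameters(), AbilityModel())


def test_unregistered_item_rejected():
    frame = _frame([1.0], [0.0], [0], item=["clinic"])
    with pytest.raises(ValueError, match="unregistered"):
        log_likelihood(frame, {"hospital": ItemParameters()}, AbilityModel())


# ---------------------------------------------------------------------------
# prior
# ---------------------------------------------------------------------------

def test_prior_indicator_on_discrimination():
    priors = PriorSpec()
    bad = ItemParameters.__new__(ItemParameters)
    bad.a, bad.b, bad.c = -0.5, 0.0, 0.2  # bypass validation to probe support
    assert log_prior(bad, AbilityModel(), priors) == -np.inf


def test_uniform_beta_prior_contributes_zero():
    priors = PriorSpec(c_shape1=1.0, c_shape2=1.0)
    base = log_prior(ItemParameters(c=0.5), AbilityModel(), priors)
    other = log_prior(ItemParameters(c=0.9), AbilityModel(), priors)
    assert base == pytest.approx(other, abs=1e-12)  # flat in c


def test_prior_matches_reference_densities():
    priors = PriorSpec()
    items = ItemParameters(1.7, -0.3, 0.35)
    ability = AbilityModel(0.4, -0.008, 0.6)
    expected = (
        stats.truncnorm.logpdf(1.7, -priors.mu_a / priors.sigma_a, np.inf,
                               loc=priors.mu_a, scale=priors.sigma_a)
        + stats.beta.logpdf(0.35, priors.c_shape1, priors.c_shape2)
        + stats.norm.logpdf(-0.3, priors.b_mean, priors.b_sd)
        + stats.norm.logpdf(0.4, priors.alpha_mean, priors.alpha_sd)
        + stats.norm.logpdf(-0.008, priors.beta_time_mean, priors.beta_time_sd)
        + stats.norm.logpdf(0.6, priors.beta_urban_mean, priors.beta_urban_sd)
    )
    assert log_prior(items, ability, priors) == pytest.approx(expected,
                                                              abs=1e-12)


def test_model_internal_posterior_matches_reference_decomposition():
    rng = np.random.default_rng(3)
    frame = _frame(
        rng.integers(0, 2, 30).astype(float), rng.uniform(0, 180, 30),
        rng.integers(0, 2, 30),
    )
    model = FeverTreatmentModel(frame)
    params = {"alpha": 0.3, "beta_time": -0.009, "beta_urban": 0.4, "c": 0.22}
    items = ItemParameters(1.0, 0.0, 0.22)
    ability = AbilityModel(0.3, -0.009, 0.4)
    priors = model.priors
    # a, b fixed in the single-item default: only sampled-parameter priors count
    expected = (
        log_likelihood(frame, items, ability)
        + stats.beta.logpdf(0.22, priors.c_shape1, priors.c_shape2)
        + stats.norm.logpdf(0.3, priors.alpha_mean, priors.alpha_sd)
        + stats.norm.logpdf(-0.009, priors.beta_time_mean, priors.beta_time_sd)
        + stats.norm.logpdf(0.4, priors.beta_urban_mean, priors.beta_urban_sd)
    )
    assert model.log_posterior(params) == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_iter,burn,thin,expected",
    [
        (550_000, 50_000, 500, 1000),
        (22_000, 2_000, 10, 2000),
        (107, 7, 10, 10),
        (106, 7, 10, 9),
    ],
)
def test_retained_draw_count_closed_form(n_iter, burn, thin, expected):
    assert retained_draws(n_iter, burn, thin) == expected
    assert McmcConfig(n_iterations=n_iter, burn_in=burn,
                      thinning=thin).retained_per_chain == expected


def test_invalid_schedules_rejected():
    with pytest.raises(ValueError):
        McmcConfig(n_iterations=100, burn_in=100)
    with pytest.raises(ValueError):
        McmcConfig(thinning=0)
    with pytest.raises(ValueError):
        retained_draws(10, 20, 1)


def test_sampler_respects_retained_count_and_constraints():
    rng = np.random.default_rng(1)
    frame = _frame(
        rng.integers(0, 2, 40).astype(float), rng.uniform(0, 120, 40),
        rng.integers(0, 2, 40),
    )
    res = FeverTreatmentModel(frame).fit(
        McmcConfig(n_iterations=203, burn_in=23, thinning=7, n_chains=2, seed=0)
    )
    assert res.samples.n_retained == (203 - 23) // 7
    c = res.samples.get("c")
    assert np.all((c > 0) & (c <= 1))
    assert set(res.samples.names) == {"alpha", "beta_time", "beta_urban", "c"}


def test_sampler_deterministic_given_seed():
    frame = _frame([1.0, 0.0, 1.0, 1.0] * 10, list(range(40)), [0, 1] * 20)
    cfg = McmcConfig(n_iterations=300, burn_in=50, thinning=5, n_chains=2, seed=7)
    r1 = FeverTreatmentModel(frame).fit(cfg)
    r2 = FeverTreatmentModel(frame).fit(cfg)
    np.testing.assert_array_equal(r1.samples.draws, r2.samples.draws)


def test_all_missing_responses_rejected():
    frame = _frame([np.nan, np.nan], [0.0, 1.0], [0, 0])
    with pytest.raises(ValueError, match="missing"):
        FeverTreatmentModel(frame)


def test_multi_item_anchoring():
    rng = np.random.default_rng(2)
    n = 60
    frame = _frame(
        rng.integers(0, 2, n).astype(float), rng.uniform(0, 120, n),
        rng.integers(0, 2, n),
        item=rng.choice(["hospital", "dispensary"], n),
    )
    model = FeverTreatmentModel(frame)
    # first item (data order) anchored at (a=1, b=0); other item's a, b free
    first, second = model.item_ids
    assert model.fix[f"a[{first}]"] == 1.0
    assert model.fix[f"b[{first}]"] == 0.0
    assert f"a[{second}]" in model.param_names
    assert f"c[{first}]" in model.param_names
    assert f"c[{second}]" in model.param_names


def test_posterior_samples_roundtrip_frame():
    rng = np.random.default_rng(0)
    s = PosteriorSamples(rng.normal(size=(2, 5, 3)), ["alpha", "beta_time", "c"])
    back = PosteriorSamples.from_frame(s.to_frame())
    np.testing.assert_allclose(back.draws, s.draws)
    assert back.names == s.names
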