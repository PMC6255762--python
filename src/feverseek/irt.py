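"""Bayesian 3PL item-response model of fever treatment-seeking.

The probability that a carer sought public-sector treatment for a child's
fever episode is modelled with a unidimensional three-parameter logistic
(3PL) item-response model in which the latent ability to seek treatment is a
linear function of travel time to the nearest public health facility and of
urban/rural residence:

    P(Y_ij = 1 | theta_j, a_i, b_i, c_i)
        = c_i + (1 - c_i) * exp(a_i * theta_j - b_i) / (1 + exp(a_i * theta_j - b_i))
    theta_j = alpha + beta_time * t_j + beta_urban * urban_j

with discrimination a_i > 0, difficulty b_i real, and threshold (minimum)
probability c_i in (0, 1] — the floor the probability decays to at large
travel time. The posterior

    f(theta, a, b, c | y)  ∝  L(y | theta, a, b, c) f(a) f(b) f(c) f(alpha, beta)

is sampled with a Metropolis-within-Gibbs scheme: the ability coefficients
form one block; each item's (a, b, c) form a block, proposed on unconstrained
scales (log a, logit c) with Gaussian random walks whose scales adapt during
burn-in to a 20-50% acceptance rate.

The public classes follow the statsmodels pattern:
``FeverTreatmentModel`` is built from the analysis table and its ``fit()``
returns a ``FeverTreatmentResults`` carrying the posterior draws,
convergence diagnostics, a ``summary()`` table, treatment curves and
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, expit, logit

__all__ = [
    "ItemParameters",
    "AbilityModel",
    "PriorSpec",
    "McmcConfig",
    "PosteriorSamples",
    "item_probability",
    "log_likelihood",
    "log_prior",
    "retained_draws",
    "fit_mcmc",
    "FeverTreatmentModel",
    "FeverTreatmentResults",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ItemParameters:
    """Per-item 3PL parameters: discrimination, difficulty, threshold floor."""

    a: float = 1.0
    b: float = 0.0
    c: float = 0.2

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"discrimination a must be > 0, got {self.a}")
        if not 0 < self.c <= 1:
            raise ValueError(f"threshold c must be in (0, 1], got {self.c}")


@dataclass
class AbilityModel:
    """Linear model of the latent ability theta on travel time and residence.

    ``beta_time`` is per minute of travel time; ``beta_urban`` applies to the
    urban indicator.
    """

    alpha: float = 0.0
    beta_time: float = 0.0
    beta_urban: float = 0.0

    def theta(self, travel_time_min, urban) -> np.ndarray:
        return (
            self.alpha
            + self.beta_time * np.asarray(travel_time_min, dtype=float)
            + self.beta_urban * np.asarray(urban, dtype=float)
        )


@dataclass
class PriorSpec:
    """Prior hyperparameters.

    a ~ N(mu_a, sigma_a^2) truncated to a > 0; c ~ Beta(c_shape1, c_shape2) on
    (0, 1); normal priors on b, alpha and the beta coefficients. The default
    beta_time sd of 1/60 per minute is a standard-normal prior on the
    per-hour coefficient, keeping the coefficient scales comparable.
    """

    mu_a: float = 0.0
    sigma_a: float = 2.5
    c_shape1: float = 2.0
    c_shape2: float = 5.0
    b_mean: float = 0.0
    b_sd: float = 5.0
    alpha_mean: float = 0.0
    alpha_sd: float = 5.0
    beta_time_mean: float = 0.0
    beta_time_sd: float = 1.0 / 60.0
    beta_urban_mean: float = 0.0
    beta_urban_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma_a > 0:
            raise ValueError("sigma_a must be positive")
        if not (self.c_shape1 > 0 and self.c_shape2 > 0):
            raise ValueError("beta-prior shapes must be positive")
        for sd in (self.b_sd, self.alpha_sd, self.beta_time_sd, self.beta_urban_sd):
            if not sd > 0:
                raise ValueError("prior standard deviations must be positive")


@dataclass
class McmcConfig:
    """Sampler schedule and tuning.

    The desk-scale default (22,000 iterations, 2,000 burn-in, thinning 10,
    three chains) retains 2,000 draws per chain. ``McmcConfig.reference()``
    gives the long reference schedule of 550,000 iterations with 50,000
    burn-in and thinning 500, which retains exactly 1,000 draws per chain.
    """

    n_iterations: int = 22_000
    burn_in: int = 2_000
    thinning: int = 10
    n_chains: int = 3
    seed: int = 0
    proposal_scales: dict[str, float] | None = None
    adapt: bool = True

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return retained_draws(self.n_iterations, self.burn_in, self.thinning)

    @classmethod
    def reference(cls, **kw) -> "McmcConfig":
        return cls(n_iterations=550_000, burn_in=50_000, thinning=500, **kw)


def retained_draws(n_iterations: int, burn_in: int, thinning: int) -> int:
    """Retained draws per chain: floor((n_iterations - burn_in) / thinning)."""
    if burn_in >= n_iterations:
        raise ValueError("burn_in must be smaller than n_iterations")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    return (n_iterations - burn_in) // thinning


@dataclass
class PosteriorSamples:
    """Posterior draws indexed by (chain, retained iteration, parameter)."""

    draws: np.ndarray  # (n_chains, n_retained, n_params)
    names: list[str]

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must be (n_chains, n_retained, n_params)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (n_chains, n_retained)."""
        return self.draws[:, :, self.names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).ravel()

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iter, parameter, value."""
        n_c, n_r, n_p = self.draws.shape
        chain = np.repeat(np.arange(n_c), n_r * n_p)
        it = np.tile(np.repeat(np.arange(n_r), n_p), n_c)
        par = np.tile(self.names, n_c * n_r)
        return pd.DataFrame(
            {"chain": chain, "iter": it, "parameter": par,
             "value": self.draws.ravel()}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PosteriorSamples":
        names = list(pd.unique(frame["parameter"]))
        n_c = frame["chain"].nunique()
        n_r = frame["iter"].nunique()
        wide = frame.pivot_table(
            index=["chain", "iter"], columns="parameter", values="value",
            sort=False,
        )[names]
        return cls(wide.to_numpy().reshape(n_c, n_r, len(names)), names)


# ---------------------------------------------------------------------------
# likelihood, prior
# ---------------------------------------------------------------------------

def item_probability(theta, item: ItemParameters | None = None, *,
                     a: float | None = None, b: float | None = None,
                     c: float | None = None):
    """3PL response probability c + (1 - c) * logistic(a*theta - b).

    Numerically stable for extreme linear predictors; strictly increasing in
    theta with infimum exactly c.
    """
    if item is not None:
        a, b, c = item.a, item.b, item.c
    if not 0 < c <= 1:
        raise ValueError(f"threshold c must be in (0, 1], got {c}")
    if not a > 0:
        raise ValueError(f"discrimination a must be > 0, got {a}")
    return c + (1.0 - c) * expit(a * np.asarray(theta, dtype=float) - b)


def _validate_responses(y: np.ndarray) -> None:
    obs = y[~np.isnan(y)]
    if not np.isin(obs, (0.0, 1.0)).all():
        bad = obs[~np.isin(obs, (0.0, 1.0))]
        raise ValueError(f"responses must be 0, 1 or missing; got {bad[:5]}")


def log_likelihood(
    data: pd.DataFrame,
    items: ItemParameters | dict[str, ItemParameters],
    ability: AbilityModel,
) -> float:
    """Bernoulli log likelihood over non-missing responses.

    ``data`` needs columns ``y`` (0/1/NaN), ``travel_time_min`` and ``urban``;
    with multiple items also ``item_id``. Missing responses contribute zero
    (missing-at-random drop).
    """
    y = data["y"].to_numpy(dtype=float)
    _validate_responses(y)
    keep = ~np.isnan(y)
    if not keep.any():
        return 0.0
    y = y[keep]
    theta = ability.theta(
        data["travel_time_min"].to_numpy(dtype=float)[keep],
        data["urban"].to_numpy(dtype=float)[keep],
    )
    if isinstance(items, ItemParameters):
        p = item_probability(theta, items)
    else:
        ids = data["item_id"].to_numpy()[keep]
        unknown = set(ids) - set(items)
        if unknown:
            raise ValueError(f"responses reference unregistered items: {unknown}")
        p = np.empty_like(theta)
        for iid, it in items.items():
            sel = ids == iid
            p[sel] = item_probability(theta[sel], it)
    return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def log_prior(
    items: ItemParameters | dict[str, ItemParameters],
    ability: AbilityModel,
    priors: PriorSpec,
) -> float:
    """Joint log prior density; -inf outside the support."""
    item_list = [items] if isinstance(items, ItemParameters) else list(items.values())
    lp = 0.0
    a_lo = (0.0 - priors.mu_a) / priors.sigma_a
    for it in item_list:
        if it.a <= 0 or not 0 < it.c <= 1:
            return -np.inf
        lp += stats.truncnorm.logpdf(
            it.a, a_lo, np.inf, loc=priors.mu_a, scale=priors.sigma_a
        )
        lp += stats.beta.logpdf(it.c, priors.c_shape1, priors.c_shape2)
        lp += stats.norm.logpdf(it.b, priors.b_mean, priors.b_sd)
    lp += stats.norm.logpdf(ability.alpha, priors.alpha_mean, priors.alpha_sd)
    lp += stats.norm.logpdf(ability.beta_time, priors.beta_time_mean,
                            priors.beta_time_sd)
    lp += stats.norm.logpdf(ability.beta_urban, priors.beta_urban_mean,
                            priors.beta_urban_sd)
    return float(lp)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

_ABILITY_NAMES = ("alpha", "beta_time", "beta_urban")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI

# default initial random-walk scales on the sampling (unconstrained) scale
_DEFAULT_SCALES = {
    "alpha": 0.5, "beta_time": 0.01, "beta_urban": 0.5,
    "log_a": 0.2, "b": 0.5, "logit_c": 0.3,
}


class FeverTreatmentModel:
    """3PL treatment-seeking model bound to an analysis table.

    Parameters
    ----------
    data
        Child-level table with columns ``y`` (0/1, NaN = missing),
        ``travel_time_min``, ``urban`` and optionally ``item_id`` (facility
        tier of the response). Rows with missing ``y`` are dropped from the
        likelihood.
    priors
        Prior hyperparameters; defaults per :class:`PriorSpec`.
    fix
        Mapping of parameter names to fixed values, e.g. ``{"beta_urban": 0}``
        or ``{"c": 0.2}``. Item parameters of a single-item model are named
        ``a``, ``b``, ``c``; with multiple items ``a[tier]`` etc.
    estimate_items
        Whether discrimination/difficulty are estimated. Default: fixed at
        (a=1, b=0) for a single item, where they are confounded with the
        ability scale and location; estimated for multi-item data with the
        first item anchored at (a=1, b=0).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        priors: PriorSpec | None = None,
        fix: dict[str, float] | None = None,
        estimate_items: bool | None = None,
    ) -> None:
        required = {"y", "travel_time_min", "urban"}
        if not required <= set(data.columns):
            raise ValueError(f"data must have columns {sorted(required)}")
        y = data["y"].to_numpy(dtype=float)
        _validate_responses(y)
        keep = ~np.isnan(y)
        if not keep.any():
            raise ValueError("all responses are missing; nothing to fit")

        self.data = data
        self.priors = priors or PriorSpec()
        self.n_obs = int(keep.sum())

        self._y = y[keep]
        self._t = data["travel_time_min"].to_numpy(dtype=float)[keep]
        self._u = data["urban"].to_numpy(dtype=float)[keep]
        if "item_id" in data.columns:
            ids = data["item_id"].to_numpy()[keep]
            self.item_ids = list(pd.unique(ids))
        else:
            ids = np.array(["public"] * self.n_obs)
            self.item_ids = ["public"]
        if len(self.item_ids) > 1:
            order = {iid: k for k, iid in enumerate(self.item_ids)}
            self._item_idx = np.array([order[i] for i in ids], dtype=int)
        else:
            self._item_idx = np.zeros(self.n_obs, dtype=int)

        self.single_item = len(self.item_ids) == 1
        if estimate_items is None:
            estimate_items = not self.single_item
        self.estimate_items = estimate_items

        fix = dict(fix or {})
        if not estimate_items:
            for k, iid in enumerate(self.item_ids):
                fix.setdefault(self._pname("a", k), 1.0)
                fix.setdefault(self._pname("b", k), 0.0)
        elif not self.single_item:
            # anchor the first item for identifiability
            fix.setdefault(self._pname("a", 0), 1.0)
            fix.setdefault(self._pname("b", 0), 0.0)
        self.fix = fix

        # free-parameter registry: (public name, kind, item index or -1)
        self._free: list[tuple[str, str, int]] = []
        for name in _ABILITY_NAMES:
            if name not in fix:
                self._free.append((name, name, -1))
        for k in range(len(self.item_ids)):
            for sym, kind in (("a", "log_a"), ("b", "b"), ("c", "logit_c")):
                name = self._pname(sym, k)
                if name not in fix:
                    self._free.append((name, kind, k))
        if not self._free:
            raise ValueError("all parameters fixed; nothing to sample")
        self.param_names = [n for n, _, _ in self._free]

        pr = self.priors
        self._log_trunc_mass = float(stats.norm.logsf(-pr.mu_a / pr.sigma_a))
        self._log_beta_const = float(betaln(pr.c_shape1, pr.c_shape2))

    # -- naming ------------------------------------------------------------
    def _pname(self, sym: str, k: int) -> str:
        return sym if self.single_item else f"{sym}[{self.item_ids[k]}]"

    # -- parameter plumbing -------------------------------------------------
    def _unpack(self, z: np.ndarray):
        """Sampling vector -> (alpha, bt, bu, a[], b[], c[], log-Jacobian)."""
        vals: dict[str, float] = {}
        jac = 0.0
        for (name, kind, _), zv in zip(self._free, z):
            if kind == "log_a":
                vals[name] = np.exp(zv)
                jac += zv
            elif kind == "logit_c":
                cv = expit(zv)
                vals[name] = cv
                jac += np.log(cv) + np.log1p(-cv)
            else:
                vals[name] = zv

        def value(sym: str, k: int = -1) -> float:
            name = sym if k < 0 else self._pname(sym, k)
            if name in vals:
                return vals[name]
            return self.fix[name] if name in self.fix else 0.0

        n_items = len(self.item_ids)
        a = np.array([value("a", k) for k in range(n_items)])
        b = np.array([value("b", k) for k in range(n_items)])
        c = np.array([value("c", k) for k in range(n_items)])
        return (value("alpha"), value("beta_time"), value("beta_urban"),
                a, b, c, jac)

    def _pack(self, constrained: dict[str, float]) -> np.ndarray:
        z = np.empty(len(self._free))
        for i, (name, kind, _) in enumerate(self._free):
            v = constrained[name]
            z[i] = np.log(v) if kind == "log_a" else (
                logit(v) if kind == "logit_c" else v
            )
        return z

    # -- densities -----------------------------------------------------------
    def _log_posterior_z(self, z: np.ndarray) -> float:
        alpha, bt, bu, a, b, c, jac = self._unpack(z)
        if (a <= 0).any() or (c <= 0).any() or (c > 1).any():
            return -np.inf
        theta = alpha + bt * self._t + bu * self._u
        lin = a[self._item_idx] * theta - b[self._item_idx]
        p = c[self._item_idx] + (1.0 - c[self._item_idx]) * expit(lin)
        ll = np.sum(self._y * np.log(p) + (1.0 - self._y) * np.log1p(-p))
        pr = self._log_prior_constrained(alpha, bt, bu, a, b, c)
        return float(ll + pr + jac)

    def _log_prior_constrained(self, alpha, bt, bu, a, b, c) -> float:
        # closed-form log densities (normalising constants cached): scipy's
        # frozen-distribution calls are too slow for the per-iteration path
        pr = self.priors
        lp = 0.0
        for k in range(len(self.item_ids)):
            if self._pname("a", k) not in self.fix:
                lp += (
                    _norm_logpdf(a[k], pr.mu_a, pr.sigma_a)
                    - self._log_trunc_mass
                )
            if self._pname("b", k) not in self.fix:
                lp += _norm_logpdf(b[k], pr.b_mean, pr.b_sd)
            if self._pname("c", k) not in self.fix:
                lp += (
                    (pr.c_shape1 - 1.0) * np.log(c[k])
                    + (pr.c_shape2 - 1.0) * np.log1p(-c[k])
                    - self._log_beta_const
                )
        if "alpha" not in self.fix:
            lp += _norm_logpdf(alpha, pr.alpha_mean, pr.alpha_sd)
        if "beta_time" not in self.fix:
            lp += _norm_logpdf(bt, pr.beta_time_mean, pr.beta_time_sd)
        if "beta_urban" not in self.fix:
            lp += _norm_logpdf(bu, pr.beta_urban_mean, pr.beta_urban_sd)
        return lp

    def log_posterior(self, params: dict[str, float]) -> float:
        """Unnormalised log posterior at constrained parameter values."""
        z = self._pack({n: params[n] for n in self.param_names})
        alpha, bt, bu, a, b, c, jac = self._unpack(z)
        theta = alpha + bt * self._t + bu * self._u
        lin = a[self._item_idx] * theta - b[self._item_idx]
        p = c[self._item_idx] + (1.0 - c[self._item_idx]) * expit(lin)
        ll = np.sum(self._y * np.log(p) + (1.0 - self._y) * np.log1p(-p))
        return float(ll + self._log_prior_constrained(alpha, bt, bu, a, b, c))

    # -- sampling -------------------------------------------------------------
    def _blocks(self) -> list[np.ndarray]:
        ability = [i for i, (_, _, k) in enumerate(self._free) if k < 0]
        blocks = [np.array(ability, dtype=int)] if ability else []
        for k in range(len(self.item_ids)):
            idx = [i for i, (_, _, kk) in enumerate(self._free) if kk == k]
            if idx:
                blocks.append(np.array(idx, dtype=int))
        return blocks

    def _start(self, rng: np.random.Generator) -> np.ndarray:
        """Over-dispersed start: a prior-scale draw on the sampling scale."""
        pr = self.priors
        z = np.empty(len(self._free))
        for i, (name, kind, _) in enumerate(self._free):
            if kind == "log_a":
                z[i] = rng.normal(0.0, 0.5)
            elif kind == "logit_c":
                z[i] = rng.normal(-1.0, 1.0)
            elif name == "alpha":
                z[i] = rng.normal(pr.alpha_mean, min(pr.alpha_sd, 2.0))
            elif name == "beta_time":
                z[i] = rng.normal(pr.beta_time_mean, pr.beta_time_sd)
            elif name == "beta_urban":
                z[i] = rng.normal(pr.beta_urban_mean, min(pr.beta_urban_sd, 2.0))
            else:
                z[i] = rng.normal(0.0, 1.0)
        return z

    def fit(self, config: McmcConfig | None = None) -> "FeverTreatmentResults":
        """Run the Metropolis-within-Gibbs sampler and collect retained draws."""
        config = config or McmcConfig()
        n_ret = config.retained_per_chain
        blocks = self._blocks()
        scale_overrides = config.proposal_scales or {}
        base_scales = np.array(
            [scale_overrides.get(name, _DEFAULT_SCALES[kind])
             for name, kind, _ in self._free]
        )

        draws = np.empty((config.n_chains, n_ret, len(self._free)))
        child_seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
        for ch, ss in enumerate(child_seeds):
            rng = np.random.default_rng(ss)
            z = self._start(rng)
            scales = base_scales.copy()
            cur = self._log_posterior_z(z)
            guard = 0
            while not np.isfinite(cur) and guard < 100:
                z = self._start(rng)
                cur = self._log_posterior_z(z)
                guard += 1
            if not np.isfinite(cur):
                raise RuntimeError("could not find a finite-density start")
            acc = np.zeros(len(blocks))
            tries = np.zeros(len(blocks))
            stored = 0
            for it in range(config.n_iterations):
                for bi, idx in enumerate(blocks):
                    prop = z.copy()
                    prop[idx] += scales[idx] * rng.standard_normal(idx.size)
                    lp = self._log_posterior_z(prop)
                    tries[bi] += 1
                    if np.log(rng.random()) < lp - cur:
                        z, cur = prop, lp
                        acc[bi] += 1
                    if (
                        config.adapt
                        and it < config.burn_in
                        and tries[bi] >= 50
                    ):
                        rate = acc[bi] / tries[bi]
                        scales[idx] *= np.exp(1.2 * (rate - 0.3))
                        acc[bi] = tries[bi] = 0.0
                if (
                    it >= config.burn_in
                    and (it - config.burn_in + 1) % config.thinning == 0
                    and stored < n_ret
                ):
                    alpha, bt, bu, a, b, c, _ = self._unpack(z)
                    row = []
                    for name, kind, k in self._free:
                        if kind == "log_a":
                            row.append(a[k])
                        elif kind == "logit_c":
                            row.append(c[k])
                        elif kind == "b":
                            row.append(b[k])
                        elif name == "alpha":
                            row.append(alpha)
                        elif name == "beta_time":
                            row.append(bt)
                        else:
                            row.append(bu)
                    draws[ch, stored] = row
                    stored += 1
        samples = PosteriorSamples(draws, list(self.param_names))
        return FeverTreatmentResults(self, samples, config)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "FeverTreatmentModel":
        return cls(data, **kw)


def fit_mcmc(
    data: pd.DataFrame,
    priors: PriorSpec | None = None,
    config: McmcConfig | None = None,
    fix: dict[str, float] | None = None,
    estimate_items: bool | None = None,
) -> "FeverTreatmentResults":
    """Functional wrapper: build a :class:`FeverTreatmentModel` and fit it."""
    model = FeverTreatmentModel(data, priors=priors, fix=fix,
                                estimate_items=estimate_items)
    return model.fit(config)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class FeverTreatmentResults:
    """Posterior fit: draws, summaries, diagnostics, curves and prediction."""

    def __init__(self, model: FeverTreatmentModel, samples: PosteriorSamples,
                 config: McmcConfig) -> None:
        self.model = model
        self.samples = samples
        self.config = config

    # -- summaries -----------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior medians of the free parameters."""
        med = np.median(self.samples.draws.reshape(-1, len(self.samples.names)),
                        axis=0)
        return pd.Series(med, index=self.samples.names)

    def credible_interval(self, name: str, level: float = 0.95):
        lo = (1.0 - level) / 2.0
        x = self.samples.flat(name)
        return float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior summary table with Gelman-Rubin PSRF where computable."""
        from .diagnostics import gelman_rubin

        rows = []
        lo = (1.0 - level) / 2.0
        for name in self.samples.names:
            x = self.samples.flat(name)
            psrf = (
                gelman_rubin(self.samples, name)
                if self.samples.n_chains >= 2 else np.nan
            )
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "median": np.median(x),
                    f"{100 * lo:g}%": np.quantile(x, lo),
                    f"{100 * (1 - lo):g}%": np.quantile(x, 1 - lo),
                    "psrf": psrf,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<FeverTreatmentResults: {self.model.n_obs} responses, "
            f"{self.samples.n_chains} chains x {self.samples.n_retained} draws>"
        )

    # -- diagnostics ----------------------------------------------------------
    def convergence_report(self, q: float = 0.025, r: float = 0.005,
                           s: float = 0.95, psrf_limit: float = 1.1):
        from .diagnostics import convergence_report

        return convergence_report(self.samples, q=q, r=r, s=s,
                                  psrf_limit=psrf_limit)

    # -- draw access ----------------------------------------------------------
    def draw_frame(self, item: str | None = None) -> pd.DataFrame:
        """Flattened draws of (alpha, beta_time, beta_urban, a, b, c).

        Fixed parameters are filled in as constant columns, so every row is a
        complete 3PL parameter set for ``item`` (default: the single/first
        item) — the form the back-calculation and prediction steps consume.
        """
        m = self.model
        if item is None:
            item = m.item_ids[0]
        k = m.item_ids.index(item)
        n = self.samples.n_chains * self.samples.n_retained
        out = {}
        for sym in ("alpha", "beta_time", "beta_urban"):
            out[sym] = (
                self.samples.flat(sym) if sym in self.samples.names
                else np.full(n, m.fix.get(sym, 0.0))
            )
        for sym in ("a", "b", "c"):
            name = m._pname(sym, k)
            out[sym] = (
                self.samples.flat(name) if name in self.samples.names
                else np.full(n, m.fix[name])
            )
        return pd.DataFrame(out)

    # -- probability surfaces -------------------------------------------------
    def treatment_curve(self, time_grid=None, residence: str = "rural",
                        item: str | None = None):
        from .curves import treatment_curve

        if time_grid is None:
            time_grid = np.arange(0.0, 241.0, 5.0)
        return treatment_curve(self.draw_frame(item), time_grid, residence,
                               item=item or self.model.item_ids[0])

    def summarize_at_thresholds(self, thresholds=(10, 30, 60, 120),
                                residence: str = "rural",
                                item: str | None = None) -> pd.DataFrame:
        from .curves import summarize_at_thresholds, treatment_curve

        grid = np.unique(np.concatenate(
            [np.arange(0.0, 241.0, 5.0), np.asarray(thresholds, dtype=float)]
        ))
        curve = treatment_curve(self.draw_frame(item), grid, residence,
                                item=item or self.model.item_ids[0])
        return summarize_at_thresholds(curve, list(thresholds))

    def threshold_floor(self, item: str | None = None):
        from .curves import threshold_floor

        return threshold_floor(self.draw_frame(item))

    def probability_raster(self, travel_time_raster, urban_raster,
                           item: str | None = None):
        from .curves import probability_raster

        return probability_raster(self.draw_frame(item), travel_time_raster,
                                  urban_raster)

    def predict(self, travel_time_min, urban, item: str | None = None,
                mode: str = "median") -> np.ndarray:
        """Posterior predicted probability at covariates (draw-wise)."""
        from .curves import predict_probability

        return predict_probability(self.draw_frame(item), travel_time_min,
                                   urban, mode=mode)

    # -- plotting -------------------------------------------------------------
    def plot_curve(self, time_grid=None, residence: str = "rural",
                   item: str | None = None, ax=None):
        """Plot the median treatment-seeking curve with its 95% credible band."""
        import matplotlib.pyplot as plt

        curve = self.treatment_curve(time_grid, residence, item)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(curve.time_grid, curve.lower, curve.upper, alpha=0.25,
                        label="95% CrI")
        ax.plot(curve.time_grid, curve.median, label="posterior median")
        ax.set_xlabel("travel time to nearest facility (min)")
        ax.set_ylabel("P(seek public treatment | fever)")
        ax.set_ylim(0, 1)
        ax.legend()
        return ax
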