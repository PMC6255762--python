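"""MCMC convergence diagnostics: Gelman-Rubin PSRF and Raftery-Lewis.

The potential scale reduction factor (PSRF) compares between- and
within-chain variance over parallel chains started from over-dispersed
points; values near 1 indicate mixing. The Raftery-Lewis diagnostic
estimates the run length needed to estimate a posterior quantile ``q`` to
precision ``r`` with confidence ``s`` from a single chain, via a binarised
first-order Markov approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .irt import PosteriorSamples

__all__ = [
    "gelman_rubin",
    "raftery_lewis",
    "raftery_lewis_nmin",
    "RafteryLewisResult",
    "ConvergenceReport",
    "convergence_report",
]


def _chain_matrix(samples, parameter=None) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        return samples.get(parameter)
    return np.asarray(samples, dtype=float)


def gelman_rubin(samples, parameter: str | None = None) -> float:
    """Potential scale reduction factor sqrt(((n-1)/n * W + B/n) / W).

    ``samples`` is a PosteriorSamples (with ``parameter`` naming the draws) or
    an (n_chains, n_draws) array. Requires at least two chains and ten
    retained draws per chain.
    """
    x = _chain_matrix(samples, parameter)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("Gelman-Rubin requires >= 2 chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("Gelman-Rubin requires >= 10 retained draws per chain")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    v_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(v_hat / w))


def raftery_lewis_nmin(q: float = 0.025, r: float = 0.005,
                       s: float = 0.95) -> int:
    """Independent-chain minimum run length ceil(z^2 * q * (1-q) / r^2)."""
    z = norm.ppf((1.0 + s) / 2.0)
    return int(math.ceil(z * z * q * (1.0 - q) / (r * r)))


@dataclass
class RafteryLewisResult:
    q: float
    r: float
    s: float
    n_min: int        # independent-chain minimum run length
    burn_in: int      # estimated burn-in M
    n_required: int   # estimated total run length N
    thinning: int     # selected first-order Markov thinning k
    dependence_factor: float  # I = (M + N) / N_min


def _transition_counts(z: np.ndarray, order: int) -> np.ndarray:
    """Counts of (order+1)-grams of a binary sequence."""
    shape = (2,) * (order + 1)
    counts = np.zeros(shape, dtype=float)
    idx = tuple(z[i: len(z) - order + i] for i in range(order + 1))
    np.add.at(counts, idx, 1.0)
    return counts


def _first_order_thinning(z: np.ndarray, max_k: int = 64) -> int:
    """Smallest thinning at which a first-order chain is preferred (BIC) over
    a second-order one on the binarised sequence."""
    for k in range(1, max_k + 1):
        zt = z[::k]
        if len(zt) < 8:
            break
        tri = _transition_counts(zt, 2)
        n = tri.sum()
        g2 = 0.0
        for i in range(2):
            for j in range(2):
                for l in range(2):
                    obs = tri[i, j, l]
                    if obs == 0:
                        continue
                    expected = tri[i, j].sum() * tri[:, j, l].sum() / max(
                        tri[:, j].sum(), 1.0
                    )
                    g2 += 2.0 * obs * np.log(obs / expected)
        bic = g2 - 2.0 * np.log(n)
        if bic < 0:
            return k
    return max_k


def raftery_lewis(chain, q: float = 0.025, r: float = 0.005,
                  s: float = 0.95, eps: float = 0.001) -> RafteryLewisResult:
    """Raftery-Lewis run-length diagnostic for a single chain.

    Binarises the chain at its ``q``-quantile, selects the smallest thinning
    at which the binary sequence is adequately first-order Markov (BIC), and
    from the estimated transition probabilities returns the required burn-in
    M, run length N and the dependence factor I = (M + N)/N_min.
    """
    x = np.asarray(chain, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("Raftery-Lewis requires a chain of length >= 100")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) chain")
    cutoff = np.quantile(x, q)
    z = (x <= cutoff).astype(int)
    if z.min() == z.max():
        raise ValueError("binarised chain is constant; cannot estimate transitions")

    k = _first_order_thinning(z)
    zt = z[::k]
    pairs = _transition_counts(zt, 1)
    # alpha = P(0 -> 1), beta = P(1 -> 0), with a half-count guard
    alpha = (pairs[0, 1] + 0.5) / (pairs[0].sum() + 1.0)
    beta = (pairs[1, 0] + 0.5) / (pairs[1].sum() + 1.0)

    z_s = norm.ppf((1.0 + s) / 2.0)
    ab = alpha + beta
    if abs(1.0 - ab) < 1e-12:  # transitions mix in one step
        burn = k
    else:
        m = math.log(eps * ab / max(alpha, beta)) / math.log(abs(1.0 - ab))
        burn = int(math.ceil(m)) * k
    n_req = (2.0 - ab) * alpha * beta * z_s ** 2 / (ab ** 3 * r ** 2)
    n_req = int(math.ceil(n_req)) * k
    n_min = raftery_lewis_nmin(q, r, s)
    return RafteryLewisResult(
        q=q, r=r, s=s, n_min=n_min, burn_in=burn, n_required=n_req,
        thinning=k, dependence_factor=(burn + n_req) / n_min,
    )


@dataclass
class ConvergenceReport:
    """Per-parameter PSRF and Raftery-Lewis summaries with pass flags."""

    psrf: dict[str, float]
    raftery: dict[str, RafteryLewisResult]
    psrf_limit: float
    passed: dict[str, bool] = field(default_factory=dict)

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())

    def to_dict(self) -> dict:
        return {
            "psrf_limit": self.psrf_limit,
            "parameters": {
                name: {
                    "psrf": self.psrf[name],
                    "passed": self.passed[name],
                    "raftery_lewis": {
                        "n_min": rl.n_min,
                        "burn_in": rl.burn_in,
                        "n_required": rl.n_required,
                        "thinning": rl.thinning,
                        "dependence_factor": rl.dependence_factor,
                    },
                }
                for name, rl in self.raftery.items()
            },
        }


def convergence_report(samples: PosteriorSamples, q: float = 0.025,
                       r: float = 0.005, s: float = 0.95,
                       psrf_limit: float = 1.1) -> ConvergenceReport:
    """PSRF and Raftery-Lewis for every sampled parameter.

    A parameter passes when its PSRF is below ``psrf_limit``. The
    Raftery-Lewis diagnostic is evaluated on the first chain.
    """
    psrf: dict[str, float] = {}
    raftery: dict[str, RafteryLewisResult] = {}
    passed: dict[str, bool] = {}
    for name in samples.names:
        psrf[name] = gelman_rubin(samples, name)
        raftery[name] = raftery_lewis(samples.get(name)[0], q=q, r=r, s=s)
        passed[name] = psrf[name] < psrf_limit
    return ConvergenceReport(psrf=psrf, raftery=raftery,
                             psrf_limit=psrf_limit, passed=passed)
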