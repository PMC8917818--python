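"""Posterior inference for the skin/chamber parameters (q1, q2).

The measurement model for subject (or episode) i at sample time j*tau is

    V_j^i = y_j^{n,i}(q) + eps_j^i,      eps_j^i ~ iid N(0, sigma^2),

where y^{n,i} is the Galerkin forward model's TAC response to the episode's
BrAC input.  With a truncated multivariate normal prior on q = (q1, q2) over a
rectangle Q, the (unnormalized) posterior density is the Gaussian likelihood
times the prior density, supported on Q.  The posterior is explored by
random-walk Metropolis-Hastings and summarized by its mean together with a
"credible circle": the smallest Euclidean ball centred at the posterior mean
containing a stated fraction of the retained draws.  Grid evaluation of the
normalized density (a posterior surface) provides an independent quadrature
route to the same distribution.

The likelihood products run over time indices j = 1..K; the j = 0 samples are
identically zero on both sides (episodes begin at zero concentration) and
carry no information.  Episodes are treated as independent even when recorded
from the same subject or from two devices worn simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .forward import (
    ModelParameters,
    ParameterDomain,
    assemble_system,
    compute_filter,
    simulate_tac,
)

__all__ = [
    "DrinkingEpisode",
    "NoiseModel",
    "TruncatedMVNPrior",
    "PosteriorChain",
    "CredibleCircle",
    "PosteriorSurface",
    "log_likelihood",
    "log_posterior",
    "mh_sample",
    "fit_posterior",
    "credible_circle",
    "posterior_surface",
    "default_prior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class DrinkingEpisode:
    """Uniformly sampled paired BrAC/TAC vectors for one session.

    Both series start at zero (sessions begin and end sober); TAC values may
    dip below zero because the Gaussian noise model admits negative noise.
    """

    subject: str
    times: np.ndarray
    brac: np.ndarray
    tac: np.ndarray
    arm: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        brac = np.asarray(self.brac, dtype=float)
        tac = np.asarray(self.tac, dtype=float)
        if not (len(times) == len(brac) == len(tac)):
            raise ValueError("times, brac and tac must have equal lengths")
        if len(times) < 2:
            raise ValueError("an episode needs at least two samples")
        steps = np.diff(times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
            raise ValueError("times must form a uniform, increasing grid")
        if brac[0] != 0.0 or tac[0] != 0.0:
            raise ValueError("episodes must start at zero BrAC and zero TAC")
        if brac.min() < 0.0 or brac.max() > 1.0:
            raise ValueError("BrAC values must lie in [0, 1]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "brac", brac)
        object.__setattr__(self, "tac", tac)

    @property
    def tau(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class NoiseModel:
    """I.i.d. Gaussian measurement noise on TAC, standard deviation in
    concentration units."""

    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0.0:
            raise ValueError(f"sigma must be strictly positive, got {self.sigma}")


class TruncatedMVNPrior:
    """Bivariate normal prior restricted to the rectangle Q, renormalized.

    The normalization constant (the Gaussian mass of Q) is computed once by
    numerical integration of the bivariate normal CDF over the rectangle.
    """

    def __init__(self, mean: Sequence[float], cov: np.ndarray, domain: ParameterDomain):
        self.mean = np.asarray(mean, dtype=float)
        self.cov = np.asarray(cov, dtype=float)
        self.domain = domain
        if self.mean.shape != (2,) or self.cov.shape != (2, 2):
            raise ValueError("prior mean must be a 2-vector and cov a 2x2 matrix")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("prior covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(self.cov) <= 0.0):
            raise ValueError("prior covariance must be positive definite")
        self._mvn = stats.multivariate_normal(self.mean, self.cov)
        lower = np.array([domain.a1, domain.a2])
        upper = np.array([domain.b1, domain.b2])
        mass = float(self._mvn.cdf(upper, lower_limit=lower))
        if mass <= 0.0:
            raise ValueError("prior assigns zero mass to the feasible domain")
        self._log_mass = float(np.log(mass))

    def logpdf(self, q: Sequence[float]) -> float:
        q = np.asarray(q, dtype=float)
        if not self.domain.contains(q[0], q[1]):
            return -np.inf
        return float(self._mvn.logpdf(q)) - self._log_mass

    def pdf(self, q: Sequence[float]) -> float:
        return float(np.exp(self.logpdf(q)))

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Independent draws by rejection against the untruncated Gaussian."""
        out = np.empty((size, 2))
        got = 0
        while got < size:
            cand = rng.multivariate_normal(self.mean, self.cov, size=max(size, 64))
            keep = cand[
                (cand[:, 0] >= self.domain.a1)
                & (cand[:, 0] <= self.domain.b1)
                & (cand[:, 1] >= self.domain.a2)
                & (cand[:, 1] <= self.domain.b2)
            ]
            take = min(len(keep), size - got)
            out[got : got + take] = keep[:take]
            got += take
        return out


def default_prior() -> TruncatedMVNPrior:
    """The informative prior used throughout the numerical studies: a truncated
    MVN with mean (0.6318, 1.0295), covariance [[0.0259, 0.0077], [0.0077,
    0.1232]], on Q = [0.01, 2.2877] x [0.01, 2.1410]."""
    return TruncatedMVNPrior(
        mean=[0.6318, 1.0295],
        cov=np.array([[0.0259, 0.0077], [0.0077, 0.1232]]),
        domain=ParameterDomain(0.01, 2.2877, 0.01, 2.1410),
    )


@dataclass
class PosteriorChain:
    """Retained MCMC draws of (q1, q2) with sampler metadata."""

    draws: np.ndarray
    burn_in: int
    acceptance_rate: float
    seed: int
    n: int
    log_posteriors: np.ndarray | None = None
    accepted: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[1] != 2:
            raise ValueError("draws must be an (N, 2) array")

    def __len__(self) -> int:
        return len(self.draws)

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "iteration": np.arange(len(self.draws)),
                "q1": self.draws[:, 0],
                "q2": self.draws[:, 1],
            }
        )
        if self.log_posteriors is not None:
            frame["log_posterior"] = self.log_posteriors
        if self.accepted is not None:
            frame["accepted"] = self.accepted.astype(int)
        return frame


@dataclass(frozen=True)
class CredibleCircle:
    """Smallest Euclidean ball about the posterior mean covering a stated
    fraction of retained draws."""

    center: np.ndarray
    radius: float
    level: float = 0.90


def _episode_tac(
    params: ModelParameters, episodes: Sequence[DrinkingEpisode], n: int
) -> list[np.ndarray]:
    """Model TAC for each episode at the given parameters (one filter build)."""
    tau = episodes[0].tau
    horizon = max(len(ep) for ep in episodes) - 1
    system = assemble_system(params, n=n, tau=tau)
    filt = compute_filter(system, horizon)
    return [simulate_tac(filt, ep.brac) for ep in episodes]


def log_likelihood(
    params: ModelParameters | Sequence[float],
    episodes: Sequence[DrinkingEpisode],
    noise: NoiseModel,
    n: int,
) -> float:
    """Gaussian log likelihood of q over all episodes and time indices j >= 1."""
    if len(episodes) == 0:
        raise ValueError("episodes must be nonempty")
    tau0 = episodes[0].tau
    for ep in episodes:
        if not np.isclose(ep.tau, tau0):
            raise ValueError("all episodes must share the same sampling interval")
    if not isinstance(params, ModelParameters):
        q = np.asarray(params, dtype=float)
        if np.any(q[:2] <= 0.0):
            return -np.inf
        params = ModelParameters(q1=float(q[0]), q2=float(q[1]))
    sigma = noise.sigma
    total = 0.0
    count = 0
    for ep, y in zip(episodes, _episode_tac(params, episodes, n)):
        resid = ep.tac[1:] - y[1:]
        total += float(resid @ resid)
        count += len(resid)
    return -0.5 * count * (_LOG_2PI + 2.0 * np.log(sigma)) - 0.5 * total / sigma**2


def log_posterior(
    params: ModelParameters | Sequence[float],
    prior: TruncatedMVNPrior,
    episodes: Sequence[DrinkingEpisode],
    noise: NoiseModel,
    n: int,
) -> float:
    """Unnormalized log posterior: log likelihood + log prior density.

    Returns -inf outside the feasible rectangle.  With zero episodes the
    posterior reduces to the prior.
    """
    if isinstance(params, ModelParameters):
        q = np.array([params.q1, params.q2])
    else:
        q = np.asarray(params, dtype=float)
    lp = prior.logpdf(q)
    if not np.isfinite(lp):
        return -np.inf
    if len(episodes) == 0:
        return lp
    return lp + log_likelihood(q, episodes, noise, n)


def mh_sample(
    log_post: Callable[[np.ndarray], float],
    prior: TruncatedMVNPrior,
    n_draws: int = 1500,
    burn_in: int = 100,
    proposal_scale: float = 0.1,
    seed: int = 0,
    adapt: bool = True,
) -> PosteriorChain:
    """Random-walk Metropolis-Hastings with isotropic Gaussian proposals.

    The chain starts at the prior mean (projected into Q if necessary).
    During burn-in the proposal scale is optionally adapted toward a 20-40%
    acceptance rate (multiplied or divided by 1.5 every 25 proposals); after
    burn-in the scale is frozen so the retained chain is a valid MH sample.
    Proposals outside Q receive -inf log posterior and are rejected.
    """
    if proposal_scale <= 0.0:
        raise ValueError(f"proposal_scale must be positive, got {proposal_scale}")
    if not (n_draws > burn_in >= 0):
        raise ValueError(f"need n_draws > burn_in >= 0, got {n_draws}, {burn_in}")
    rng = np.random.default_rng(seed)
    dom = prior.domain
    current = np.array(
        [
            np.clip(prior.mean[0], dom.a1, dom.b1),
            np.clip(prior.mean[1], dom.a2, dom.b2),
        ]
    )
    current_lp = log_post(current)
    scale = proposal_scale
    window_accepts = 0

    draws = np.empty((n_draws, 2))
    lps = np.empty(n_draws)
    accept_flags = np.zeros(n_draws, dtype=bool)
    for i in range(n_draws):
        proposal = current + scale * rng.standard_normal(2)
        prop_lp = log_post(proposal)
        if np.log(rng.random()) < prop_lp - current_lp:
            current, current_lp = proposal, prop_lp
            accept_flags[i] = True
            window_accepts += 1
        draws[i] = current
        lps[i] = current_lp
        if adapt and i < burn_in and (i + 1) % 25 == 0:
            rate = window_accepts / 25.0
            if rate < 0.20:
                scale /= 1.5
            elif rate > 0.40:
                scale *= 1.5
            window_accepts = 0

    retained = slice(burn_in, n_draws)
    return PosteriorChain(
        draws=draws[retained],
        burn_in=burn_in,
        acceptance_rate=float(accept_flags[retained].mean()),
        seed=seed,
        n=-1,
        log_posteriors=lps[retained],
        accepted=accept_flags[retained],
    )


def fit_posterior(
    prior: TruncatedMVNPrior,
    episodes: Sequence[DrinkingEpisode],
    noise: NoiseModel,
    n: int = 8,
    n_draws: int = 1500,
    burn_in: int = 100,
    proposal_scale: float = 0.1,
    seed: int = 0,
    adapt: bool = True,
) -> PosteriorChain:
    """Sample the posterior of (q1, q2) given episodes; see :func:`mh_sample`."""

    def target(q: np.ndarray) -> float:
        return log_posterior(q, prior, episodes, noise, n)

    chain = mh_sample(
        target,
        prior,
        n_draws=n_draws,
        burn_in=burn_in,
        proposal_scale=proposal_scale,
        seed=seed,
        adapt=adapt,
    )
    chain.n = n
    return chain


def credible_circle(chain: PosteriorChain, level: float = 0.90) -> CredibleCircle:
    """Posterior mean and the level-quantile of draw distances to the mean."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if len(chain) == 0:
        raise ValueError("chain has no retained draws")
    center = chain.mean
    dists = np.linalg.norm(chain.draws - center, axis=1)
    radius = float(np.quantile(dists, level))
    return CredibleCircle(center=center, radius=radius, level=level)


@dataclass(frozen=True)
class PosteriorSurface:
    """Normalized posterior density evaluated on a uniform lattice over Q."""

    q1: np.ndarray
    q2: np.ndarray
    density: np.ndarray  # shape (len(q1), len(q2))
    domain: ParameterDomain

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.q2, axis=1), self.q1))

    def sup_diff(self, other: "PosteriorSurface") -> float:
        if self.density.shape != other.density.shape:
            raise ValueError("surfaces must share the same lattice")
        return float(np.max(np.abs(self.density - other.density)))


def posterior_surface(
    prior: TruncatedMVNPrior,
    episodes: Sequence[DrinkingEpisode],
    noise: NoiseModel,
    n: int,
    m1: int = 100,
    m2: int = 100,
) -> PosteriorSurface:
    """Evaluate the posterior on an (m1+1) x (m2+1) lattice and normalize by
    trapezoidal quadrature over Q (doubling as the evidence estimate)."""
    dom = prior.domain
    q1s = np.linspace(dom.a1, dom.b1, m1 + 1)
    q2s = np.linspace(dom.a2, dom.b2, m2 + 1)
    log_dens = np.empty((len(q1s), len(q2s)))
    for i, q1 in enumerate(q1s):
        for j, q2 in enumerate(q2s):
            log_dens[i, j] = log_posterior([q1, q2], prior, episodes, noise, n)
    log_dens -= log_dens.max()
    dens = np.exp(log_dens)
    norm = float(np.trapezoid(np.trapezoid(dens, q2s, axis=1), q1s))
    return PosteriorSurface(q1=q1s, q2=q2s, density=dens / norm, domain=dom)
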