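"""Synthetic drinking episodes with the statistical structure the analysis assumes.

Real paired BrAC/TAC sessions from wearable transdermal sensors are not
publicly distributable, so every downstream module is exercised on generated
data instead.  An episode is a breath-alcohol curve that starts and ends at
zero, rises linearly during one of three drinking patterns (single: one 15-min
period; dual: two 15-min periods spaced 30 minutes apart; steady: one 60-min
period) and then decays exponentially over several hours, paired with a TAC
trace obtained by pushing the BrAC through the forward model and adding
i.i.d. Gaussian measurement noise.

Two signal-to-noise regimes are provided as presets, expressed as the ratio of
peak TAC to the noise standard deviation: a low-noise regime (ratio ~20 at
sigma = 0.005) and a noisy regime (ratio ~8 at sigma = 0.025).  Because the
skin/chamber dynamics attenuate the peak by a factor of roughly 0.35-0.45 for
multi-hour episodes, the preset peak BrAC values are calibrated to hit those
TAC ratios rather than to sit inside the typical human breath-alcohol range
(0.02-0.12); realistic-range designs are available through
:func:`realistic_designs`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .forward import (
    DEFAULT_TAU,
    ImpulseFilter,
    ModelParameters,
    assemble_system,
    compute_filter,
    simulate_tac,
)
from .bayes import DrinkingEpisode, NoiseModel

__all__ = [
    "EpisodeDesign",
    "generate_brac",
    "generate_episode",
    "generate_cohort",
    "resample_to_grid",
    "realistic_designs",
    "idealized_designs",
]

_PATTERNS = ("single", "dual", "steady")

#: Drinking-window lengths in hours per pattern.
_RISE_HOURS = {"single": 0.25, "dual": 0.25, "steady": 1.0}

#: Gap between the two drinking windows of the dual pattern (hours).
_DUAL_GAP = 0.5

#: Fraction of the peak below which the decaying curve is treated as zero,
#: so episodes end exactly at zero concentration.
_ZERO_FRACTION = 1e-4


@dataclass(frozen=True)
class EpisodeDesign:
    """Shape parameters of one synthetic drinking episode.

    ``decay_hours`` is the first-order decay time constant after drinking ends;
    ``total_hours`` must allow the curve to fall below 1e-4 of its peak.  When
    ``jitter`` is set, the seed perturbs the peak (+-10%) and the onset timing
    (up to one sampling interval).
    """

    peak_brac: float = 0.08
    rise_hours: float | None = None
    decay_hours: float = 0.75
    pattern: str = "single"
    tau: float = DEFAULT_TAU
    total_hours: float = 8.0
    seed: int = 0
    jitter: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"pattern must be one of {_PATTERNS}, got {self.pattern!r}")
        if not (0.0 <= self.peak_brac < 1.0):
            raise ValueError(f"peak_brac must lie in [0, 1), got {self.peak_brac}")
        if self.decay_hours <= 0.0 or self.tau <= 0.0:
            raise ValueError("decay_hours and tau must be positive")
        rise_end = self.drinking_end
        needed = rise_end + self.decay_hours * np.log(1.0 / _ZERO_FRACTION)
        if self.total_hours < needed:
            raise ValueError(
                f"total_hours={self.total_hours} too short for the decay to reach zero; "
                f"need at least {needed:.2f} hr for pattern {self.pattern!r}"
            )

    @property
    def rise(self) -> float:
        return self.rise_hours if self.rise_hours is not None else _RISE_HOURS[self.pattern]

    @property
    def drinking_end(self) -> float:
        if self.pattern == "dual":
            return 2.0 * self.rise + _DUAL_GAP
        return self.rise


def _pulse(t: np.ndarray, start: float, rise: float, decay: float) -> np.ndarray:
    """Unit-peak pulse: linear rise on [start, start+rise], exponential decay after."""
    s = t - start
    up = np.clip(s / rise, 0.0, 1.0)
    down = np.where(s > rise, np.exp(-(s - rise) / decay), 1.0)
    return np.where(s > 0.0, up * down, 0.0)


def generate_brac(design: EpisodeDesign) -> tuple[np.ndarray, np.ndarray]:
    """BrAC curve on the uniform tau grid for one episode design.

    Returns ``(times, brac)``.  The curve starts and ends at exactly zero, is
    nonnegative, attains ``peak_brac`` within one grid step's interpolation
    error, and for the dual pattern has exactly two local maxima before the
    final decay.
    """
    rng = np.random.default_rng(design.seed)
    peak = design.peak_brac
    start = 0.0
    if design.jitter:
        peak *= 1.0 + 0.1 * (2.0 * rng.random() - 1.0)
        start = design.tau * rng.random()

    times = np.arange(0.0, design.total_hours + 0.5 * design.tau, design.tau)
    if peak == 0.0:
        return times, np.zeros_like(times)

    if design.pattern == "dual":
        second = start + design.rise + _DUAL_GAP
        curve = _pulse(times, start, design.rise, design.decay_hours) + _pulse(
            times, second, design.rise, design.decay_hours
        )
    else:
        curve = _pulse(times, start, design.rise, design.decay_hours)

    curve = curve / curve.max() * peak
    curve[curve < _ZERO_FRACTION * peak] = 0.0
    return times, curve


def generate_episode(
    design: EpisodeDesign,
    params: ModelParameters,
    noise: NoiseModel | None,
    n: int = 8,
    seed: int | None = None,
    subject: str = "synthetic",
    filt: ImpulseFilter | None = None,
) -> DrinkingEpisode:
    """One paired BrAC/TAC episode: model TAC plus i.i.d. Gaussian noise.

    ``noise=None`` yields the noise-free model output.  The initial TAC sample
    is forced to zero (sessions begin at zero measured concentration).
    Passing a precomputed ``filt`` for the same (params, n, tau) skips
    reassembly when generating many episodes.
    """
    if seed is None:
        seed = design.seed
    times, brac = generate_brac(design)
    if filt is None:
        system = assemble_system(params, n=n, tau=design.tau)
        filt = compute_filter(system, max(len(brac) - 1, 1))
    y = simulate_tac(filt, brac)
    if noise is None:
        tac = y.copy()
    else:
        rng = np.random.default_rng(seed)
        tac = y + rng.normal(0.0, noise.sigma, size=len(y))
    tac[0] = 0.0
    return DrinkingEpisode(subject=subject, times=times, brac=brac, tac=tac)


def generate_cohort(
    R: int,
    q_scheme: ModelParameters | Callable[[np.random.Generator], ModelParameters],
    designs: Sequence[EpisodeDesign],
    noise: NoiseModel | None,
    n: int = 8,
    seed: int = 0,
) -> list[DrinkingEpisode]:
    """R independent episodes cycling through ``designs``.

    Under a fixed ``q_scheme`` all episodes share one parameter vector (the
    repeated-measurement design); a callable draws a fresh vector per episode
    (a population design).  Episode seeds are derived deterministically from
    the master seed, so distinct episodes get independent noise streams.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    if not designs:
        raise ValueError("designs must be nonempty")
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * R)
    fixed_q = q_scheme if isinstance(q_scheme, ModelParameters) else None

    filters: dict[tuple, ImpulseFilter] = {}
    episodes = []
    for i in range(R):
        design = replace(designs[i % len(designs)], seed=int(child_seeds[2 * i]))
        if fixed_q is not None:
            params = fixed_q
        else:
            params = q_scheme(np.random.default_rng(int(child_seeds[2 * i])))
        key = (params.q1, params.q2, params.q3, params.q4, design.tau, design.total_hours)
        if key not in filters:
            system = assemble_system(params, n=n, tau=design.tau)
            n_steps = int(round(design.total_hours / design.tau))
            filters[key] = compute_filter(system, n_steps)
        episodes.append(
            generate_episode(
                design,
                params,
                noise,
                n=n,
                seed=int(child_seeds[2 * i + 1]),
                subject=f"synthetic-{i:03d}",
                filt=filters[key],
            )
        )
    return episodes


def resample_to_grid(
    times: np.ndarray, values: np.ndarray, tau: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of irregular samples, re-sampled on the k*tau grid.

    Grid points outside the observed time range are set to zero.  Returns
    ``(grid_times, grid_values)``.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape:
        raise ValueError("times and values must be one-dimensional and equally long")
    if len(t) < 2:
        raise ValueError("need at least two samples to interpolate")
    if np.any(np.diff(t) <= 0.0):
        raise ValueError("times must be strictly increasing")
    if tau <= 0.0:
        raise ValueError(f"tau must be positive, got {tau}")
    grid = np.arange(0.0, t[-1] + 0.5 * tau, tau)
    out = np.interp(grid, t, v)
    out[(grid < t[0]) | (grid > t[-1])] = 0.0
    return grid, out


def realistic_designs(tau: float = DEFAULT_TAU) -> list[EpisodeDesign]:
    """One design per drinking pattern with peaks in the human BrAC range."""
    return [
        EpisodeDesign(peak_brac=0.08, pattern="single", tau=tau, jitter=True),
        EpisodeDesign(peak_brac=0.06, pattern="dual", tau=tau, jitter=True),
        EpisodeDesign(peak_brac=0.10, pattern="steady", tau=tau, jitter=True),
    ]


def idealized_designs(sigma: float, tau: float = DEFAULT_TAU) -> list[EpisodeDesign]:
    """Designs calibrated so the cohort's typical peak-TAC-to-noise ratio matches
    the study regime for the given noise level: ~20 at sigma = 0.005 and ~8 at
    sigma = 0.025 (peaks scale linearly with sigma in between)."""
    # Peak TAC ~= 0.36 * peak BrAC for these shapes at q = [1, 1, 1, 1].
    target_peak_tac = 8.0 * 0.025 if sigma >= 0.015 else 20.0 * 0.005
    peak = target_peak_tac / 0.36
    return [
        EpisodeDesign(peak_brac=peak, pattern="single", tau=tau, jitter=True),
        EpisodeDesign(peak_brac=0.8 * peak, pattern="dual", tau=tau, jitter=True),
        EpisodeDesign(peak_brac=peak, pattern="steady", tau=tau, jitter=True),
    ]
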