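"""Run configuration and plain-text episode/chain file I/O.

All experiment drivers read a single YAML config with four sections --
``model`` (Galerkin dimension, sampling interval, device constants), ``prior``
(truncated-normal mean/covariance and feasible bounds), ``noise`` (measurement
SD), ``mcmc`` (draw counts, proposal scale, seed) and ``deconv`` (time and
parameter discretizations, regularization weights or tuning grid, band level).
Every field is validated against the module preconditions before any
computation starts; an invalid field raises ``ConfigError`` naming it.

Episodes travel as delimited text with a one-line header
``time_hr,brac,tac,subject,arm``; chains as ``iteration,q1,q2,log_posterior,
accepted``; summaries mirror the mean / credible-radius table layout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes import DrinkingEpisode, NoiseModel, TruncatedMVNPrior, default_prior
from .forward import DEFAULT_TAU, ParameterDomain

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "read_episode",
    "write_episode",
    "read_episodes",
]


class ConfigError(ValueError):
    """A config field failed validation; the message names the field."""


@dataclass
class ModelConfig:
    n: int = 8
    tau: float = DEFAULT_TAU
    q3: float = 1.0
    q4: float = 1.0

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"model.n must be >= 1, got {self.n}")
        if self.tau <= 0:
            raise ConfigError(f"model.tau must be positive, got {self.tau}")
        if self.q3 <= 0 or self.q4 <= 0:
            raise ConfigError("model.q3 and model.q4 must be positive")


@dataclass
class PriorConfig:
    mu: list[float] = field(default_factory=lambda: [0.6318, 1.0295])
    Sigma: list[list[float]] = field(
        default_factory=lambda: [[0.0259, 0.0077], [0.0077, 0.1232]]
    )
    bounds: list[list[float]] = field(
        default_factory=lambda: [[0.01, 2.2877], [0.01, 2.1410]]
    )

    def validate(self) -> None:
        if len(self.mu) != 2:
            raise ConfigError(f"prior.mu must be a 2-vector, got {self.mu}")
        S = np.asarray(self.Sigma, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T) or np.any(np.linalg.eigvalsh(S) <= 0):
            raise ConfigError("prior.Sigma must be a symmetric positive-definite 2x2 matrix")
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (2, 2) or np.any(b[:, 0] >= b[:, 1]) or np.any(b <= 0):
            raise ConfigError("prior.bounds must be two positive (low, high) pairs")

    def build(self) -> TruncatedMVNPrior:
        domain = ParameterDomain(
            self.bounds[0][0], self.bounds[0][1], self.bounds[1][0], self.bounds[1][1]
        )
        return TruncatedMVNPrior(mean=self.mu, cov=np.asarray(self.Sigma), domain=domain)


@dataclass
class NoiseConfig:
    sigma: float = 0.025

    def validate(self) -> None:
        # sigma == 0 is allowed for noise-free simulation; inference needs > 0.
        if self.sigma < 0:
            raise ConfigError(f"noise.sigma must be nonnegative, got {self.sigma}")

    def build(self) -> NoiseModel:
        if self.sigma == 0:
            raise ConfigError("noise.sigma must be strictly positive for inference")
        return NoiseModel(sigma=self.sigma)

    def build_or_none(self) -> NoiseModel | None:
        return None if self.sigma == 0 else NoiseModel(sigma=self.sigma)


@dataclass
class McmcConfig:
    draws: int = 1500
    burn_in: int = 100
    proposal_scale: float = 0.1
    seed: int = 0
    adapt: bool = True

    def validate(self) -> None:
        if not (self.draws > self.burn_in >= 0):
            raise ConfigError(
                f"mcmc.draws must exceed mcmc.burn_in >= 0, got {self.draws}, {self.burn_in}"
            )
        if self.proposal_scale <= 0:
            raise ConfigError(f"mcmc.proposal_scale must be positive, got {self.proposal_scale}")


@dataclass
class DeconvConfig:
    m: int = 64
    m1: int = 10
    m2: int = 10
    r1: float = 1e-3
    r2: float = 1e-2
    level: float = 0.90
    tune: bool = False
    tune_grid: list[float] = field(default_factory=lambda: [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2])

    def validate(self) -> None:
        if self.m < 1 or self.m1 < 1 or self.m2 < 1:
            raise ConfigError("deconv.m, deconv.m1, deconv.m2 must all be >= 1")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ConfigError("deconv.r1 and deconv.r2 must be positive")
        if not (0 < self.level < 1):
            raise ConfigError(f"deconv.level must lie in (0, 1), got {self.level}")
        if self.tune and len(self.tune_grid) == 0:
            raise ConfigError("deconv.tune_grid must be nonempty when deconv.tune is set")


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    prior: PriorConfig = field(default_factory=PriorConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    deconv: DeconvConfig = field(default_factory=DeconvConfig)

    def validate(self) -> "RunConfig":
        for section in (self.model, self.prior, self.noise, self.mcmc, self.deconv):
            section.validate()
        return self


def _build_section(cls: type, data: dict[str, Any], name: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; ``None`` yields defaults."""
    if path is None:
        return RunConfig().validate()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping of sections")
    sections = {
        "model": ModelConfig,
        "prior": PriorConfig,
        "noise": NoiseConfig,
        "mcmc": McmcConfig,
        "deconv": DeconvConfig,
    }
    unknown = set(raw) - set(sections)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, raw.get(name, {}) or {}, name)
        for name, cls in sections.items()
    }
    return RunConfig(**kwargs).validate()


def write_episode(episode: DrinkingEpisode, path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "time_hr": episode.times,
            "brac": episode.brac,
            "tac": episode.tac,
            "subject": episode.subject,
            "arm": episode.arm if episode.arm is not None else "",
        }
    )
    frame.to_csv(path, index=False, float_format="%.10g")


def read_episode(path: str | Path) -> DrinkingEpisode:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"could not parse episode file {path}: {exc}") from exc
    for col in ("time_hr", "brac", "tac"):
        if col not in frame.columns:
            raise ValueError(f"episode file {path} is missing column {col!r}")
        bad = frame[col].isna()
        if bad.any():
            raise ValueError(
                f"episode file {path}: unparseable value in column {col!r} "
                f"at row {int(bad.idxmax()) + 2}"
            )
    subject = str(frame["subject"].iloc[0]) if "subject" in frame.columns else Path(path).stem
    arm = None
    if "arm" in frame.columns and isinstance(frame["arm"].iloc[0], str) and frame["arm"].iloc[0]:
        arm = str(frame["arm"].iloc[0])
    return DrinkingEpisode(
        subject=subject,
        times=frame["time_hr"].to_numpy(float),
        brac=frame["brac"].to_numpy(float),
        tac=frame["tac"].to_numpy(float),
        arm=arm,
    )


def read_episodes(paths: Sequence[str | Path]) -> list[DrinkingEpisode]:
    return [read_episode(p) for p in paths]
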