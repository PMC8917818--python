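"""Forward model: skin-diffusion / collection-chamber dynamics as a sampled LTI system.

Alcohol transport from the blood supply through the epidermal layer into a
wearable biosensor's vapor collection chamber is modeled as a one-dimensional
diffusion equation (depth ``eta`` in [0, 1] after nondimensionalizing the skin
thickness) coupled to a first-order inflow/outflow compartment for the chamber.
After a change of variables the system is governed by four positive constants

* ``q1`` -- effective diffusivity over squared epidermal thickness (1/hr),
* ``q2`` -- lumped input gain from breath alcohol (BrAC) into the skin (1/hr),
* ``q3`` -- chamber inflow gain (1/hr),
* ``q4`` -- chamber outflow rate (1/hr),

with BrAC ``u(t)`` entering through the flux boundary condition at the deep
(dermal) side and transdermal alcohol (TAC) ``y(t)`` read out as the chamber
concentration.  Under zero-order-hold sampling with interval ``tau`` the
input/output map is an exact discrete-time convolution

    y_k = sum_{j=0}^{k-1} h_{k-j-1} u_j,        h_i = C_hat A_hat^i B_hat,

where ``A_hat = exp(A tau)`` is the one-step transition operator.  This module
assembles the Galerkin approximation of that system on the span of ``n + 1``
linear B-splines (hat functions), builds the impulse filter ``h``, and runs the
convolution.  The weighted state inner product carries a ``q1/q3`` point mass at
the skin surface, so the mass matrix is the hat-function Gram matrix with
``q1/q3`` added to its (0, 0) entry, and the stiffness matrix is
``(q1 q4 / q3) e0 e0^T + q1 * (first-derivative Gram)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, expm

__all__ = [
    "ModelParameters",
    "ParameterDomain",
    "DiscreteSystem",
    "ImpulseFilter",
    "assemble_system",
    "compute_filter",
    "simulate_tac",
    "simulate_state",
    "spline_mass_matrix",
    "spline_stiffness_matrix",
]

#: Sampling interval of 5 minutes, in hours (typical biosensor resampling rate).
DEFAULT_TAU = 1.0 / 12.0

#: Negative filter coefficients with magnitude below this are discretization
#: noise and are clamped to zero (the physical impulse response is nonnegative).
_FILTER_CLAMP = 1e-10


@dataclass(frozen=True)
class ModelParameters:
    """The transformed physiological/device parameter vector ``q``.

    ``q1`` and ``q2`` are subject-dependent and are the targets of inference;
    ``q3`` and ``q4`` are device constants, fixed to 1 by default.
    """

    q1: float
    q2: float
    q3: float = 1.0
    q4: float = 1.0

    def __post_init__(self) -> None:
        for name in ("q1", "q2", "q3", "q4"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.q1, self.q2, self.q3, self.q4])

    @property
    def dc_gain(self) -> float:
        """Steady-state TAC response to a unit constant BrAC: q2*q3/(q1*q4)."""
        return self.q2 * self.q3 / (self.q1 * self.q4)


@dataclass(frozen=True)
class ParameterDomain:
    """Rectangular feasible region Q = [a1, b1] x [a2, b2] for (q1, q2)."""

    a1: float
    b1: float
    a2: float
    b2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a1 < self.b1):
            raise ValueError(f"require 0 < a1 < b1, got a1={self.a1}, b1={self.b1}")
        if not (0.0 < self.a2 < self.b2):
            raise ValueError(f"require 0 < a2 < b2, got a2={self.a2}, b2={self.b2}")

    def contains(self, q1: float, q2: float) -> bool:
        return (self.a1 <= q1 <= self.b1) and (self.a2 <= q2 <= self.b2)

    @property
    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return ((self.a1, self.b1), (self.a2, self.b2))

    @property
    def area(self) -> float:
        return (self.b1 - self.a1) * (self.b2 - self.a2)

    def cell_edges(self, m1: int, m2: int) -> tuple[np.ndarray, np.ndarray]:
        """Edges of a uniform m1 x m2 partition of Q (ascending)."""
        return (
            np.linspace(self.a1, self.b1, m1 + 1),
            np.linspace(self.a2, self.b2, m2 + 1),
        )

    def cell_centers(self, m1: int, m2: int) -> tuple[np.ndarray, np.ndarray]:
        e1, e2 = self.cell_edges(m1, m2)
        return 0.5 * (e1[:-1] + e1[1:]), 0.5 * (e2[:-1] + e2[1:])


@dataclass(frozen=True)
class DiscreteSystem:
    """Galerkin matrices of the sampled system at a fixed parameter vector.

    ``M`` and ``K`` are the (n+1) x (n+1) mass and stiffness matrices in the hat
    function basis, ``A_hat = exp(-M^{-1} K tau)`` the one-step transition
    matrix, ``B_hat`` the zero-order-hold input vector, ``C_hat`` the output
    functional (first nodal value = chamber concentration), and ``Xi`` the
    nodal lifting vector (q2/q1) * eta used in the change of variables.
    """

    params: ModelParameters
    n: int
    tau: float
    M: np.ndarray
    K: np.ndarray
    A_hat: np.ndarray
    B_hat: np.ndarray
    C_hat: np.ndarray
    Xi: np.ndarray

    @property
    def A(self) -> np.ndarray:
        """Continuous-time generator matrix -M^{-1} K."""
        return -np.linalg.solve(self.M, self.K)

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A_hat))))

    def dc_gain(self) -> float:
        """C_hat (I - A_hat)^{-1} B_hat, the discrete steady-state gain."""
        eye = np.eye(self.A_hat.shape[0])
        return float(self.C_hat @ np.linalg.solve(eye - self.A_hat, self.B_hat))


@dataclass(frozen=True)
class ImpulseFilter:
    """Finite impulse response h such that TAC = conv(BrAC, h), shifted by one."""

    h: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.h)):
            raise ValueError("filter coefficients must be finite")
        if self.tau <= 0.0:
            raise ValueError(f"tau must be positive, got {self.tau}")

    def __len__(self) -> int:
        return len(self.h)


def spline_mass_matrix(n: int, length: float = 1.0) -> np.ndarray:
    """Gram matrix of the n+1 linear hat functions on [0, length], n intervals.

    Exact closed-form integrals of piecewise-linear products: interior diagonal
    2h/3, boundary diagonal h/3, off-diagonal h/6 with h = length / n.
    """
    h = length / n
    M = np.zeros((n + 1, n + 1))
    diag = np.full(n + 1, 2.0 * h / 3.0)
    diag[0] = diag[-1] = h / 3.0
    np.fill_diagonal(M, diag)
    off = np.full(n, h / 6.0)
    M[np.arange(n), np.arange(1, n + 1)] = off
    M[np.arange(1, n + 1), np.arange(n)] = off
    return M


def spline_stiffness_matrix(n: int, length: float = 1.0) -> np.ndarray:
    """Gram matrix of first derivatives of the hat functions on [0, length]."""
    h = length / n
    S = np.zeros((n + 1, n + 1))
    diag = np.full(n + 1, 2.0 / h)
    diag[0] = diag[-1] = 1.0 / h
    np.fill_diagonal(S, diag)
    off = np.full(n, -1.0 / h)
    S[np.arange(n), np.arange(1, n + 1)] = off
    S[np.arange(1, n + 1), np.arange(n)] = off
    return S


def assemble_system(params: ModelParameters, n: int, tau: float = DEFAULT_TAU) -> DiscreteSystem:
    """Assemble the n-dimensional Galerkin approximation at parameters ``params``.

    Parameters
    ----------
    params
        Positive parameter vector q.
    n
        Number of spline intervals on [0, 1]; the state dimension is n + 1.
    tau
        Sampling interval in hours.

    Returns
    -------
    DiscreteSystem
        Mass/stiffness matrices and the sampled (A_hat, B_hat, C_hat) triple.
    """
    if not isinstance(params, ModelParameters):
        raise TypeError("params must be a ModelParameters instance")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if tau <= 0.0:
        raise ValueError(f"tau must be positive, got {tau}")

    q1, q2, q3, q4 = params.q1, params.q2, params.q3, params.q4

    M = spline_mass_matrix(n)
    M[0, 0] += q1 / q3  # boundary point mass of the weighted inner product

    K = q1 * spline_stiffness_matrix(n)
    K[0, 0] += q1 * q4 / q3

    # K is SPD (coercive bilinear form); guard against numerical degeneracy.
    try:
        K_factor = cho_factor(K)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - cannot occur for valid q
        raise ArithmeticError("stiffness matrix is numerically singular") from exc

    A = -np.linalg.solve(M, K)
    A_hat = expm(A * tau)

    Xi = (q2 / q1) * np.linspace(0.0, 1.0, n + 1)
    load = np.zeros(n + 1)
    load[0] = q2
    B_hat = (np.eye(n + 1) - A_hat) @ (Xi + cho_solve(K_factor, load))

    C_hat = np.zeros(n + 1)
    C_hat[0] = 1.0

    return DiscreteSystem(
        params=params, n=n, tau=tau, M=M, K=K, A_hat=A_hat, B_hat=B_hat, C_hat=C_hat, Xi=Xi
    )


def compute_filter(system: DiscreteSystem, K_steps: int) -> ImpulseFilter:
    """Impulse-response coefficients h_i = C_hat A_hat^i B_hat, i < K_steps.

    Computed by iterated matrix-vector products; A_hat^i is never formed.
    Tiny negative coefficients (FEM sign noise below 1e-10) are clamped to 0.
    """
    if K_steps < 1:
        raise ValueError(f"K_steps must be >= 1, got {K_steps}")
    h = np.empty(K_steps)
    v = system.B_hat.copy()
    for i in range(K_steps):
        h[i] = v[0]  # C_hat picks the first coordinate
        v = system.A_hat @ v
    h[(h < 0.0) & (h > -_FILTER_CLAMP)] = 0.0
    return ImpulseFilter(h=h, tau=system.tau)


def simulate_tac(filt: ImpulseFilter, brac: np.ndarray) -> np.ndarray:
    """Noise-free TAC from BrAC by discrete convolution (zero initial state).

    ``y[0] = 0`` and ``y[k] = sum_{j<k} h[k-j-1] * brac[j]``.  The filter must
    cover the episode horizon: ``len(filt) >= len(brac) - 1``.
    """
    u = np.asarray(brac, dtype=float)
    if u.ndim != 1:
        raise ValueError("brac must be a one-dimensional vector")
    if len(u) >= 2 and len(filt) < len(u) - 1:
        raise ValueError(
            f"filter horizon {len(filt)} too short for episode of length {len(u)}"
        )
    y = np.zeros_like(u)
    if len(u) > 1:
        y[1:] = np.convolve(filt.h, u)[: len(u) - 1]
    return y


def simulate_state(system: DiscreteSystem, brac: np.ndarray) -> np.ndarray:
    """State-coefficient trajectory X_k, k = 0..len(brac)-1, from zero state.

    Row k holds the spline coefficients of the state at step k; its first entry
    is the TAC output and agrees with :func:`simulate_tac`.
    """
    u = np.asarray(brac, dtype=float)
    if u.ndim != 1:
        raise ValueError("brac must be a one-dimensional vector")
    X = np.zeros((len(u), system.n + 1))
    for k in range(len(u) - 1):
        X[k + 1] = system.A_hat @ X[k] + system.B_hat * u[k]
    return X
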