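"""Consumer-resource model of community nitrate reduction.

A single effective functional biomass ``x`` reduces nitrate ``A`` (mM) while
consuming a non-substitutable growth-limiting carbon nutrient ``C`` (mM), both
with Monod uptake kinetics.  Growth of the biomass requires both resources
(product of Monod terms); consumption of one resource continues after the other
is exhausted, but growth stops.  Rescaling x̃ = r_A·x, C̃ = C·r_A/r_C,
K̃_C = K_C·r_A/r_C removes the unidentifiable rates r_A, r_C, leaving nitrate
dynamics that depend only on (x̃(0), C̃(0), A0, γ, K_A, K̃_C).

The chloramphenicol-treated arm is the same system with γ forced to 0: protein
synthesis is arrested, so pre-existing enzymes reduce nitrate at the constant
rate x̃(0) while A ≫ K_A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.special import wrightomega

__all__ = [
    "CRMParamsRaw",
    "CRMParams",
    "Trajectory",
    "rescale_params",
    "simulate",
    "growth_stop_time",
    "closed_form",
]


class InvalidRescalingError(ValueError):
    """Raised when the raw → rescaled parameter map is undefined (r_C = 0)."""


class IntegrationError(RuntimeError):
    """ODE solver failure, carrying the solver's diagnostic message."""


@dataclass(frozen=True)
class CRMParamsRaw:
    """Unrescaled model parameters.

    The raw biomass unit (g) is never anchored to data; this form exists for
    the rescaling-equivalence property, not for fitting.
    """

    x0: float  # initial biomass (g)
    r_A: float  # nitrate reduction rate (mM per g biomass per day)
    r_C: float  # nutrient consumption rate (mM per g biomass per day)
    K_A: float  # nitrate affinity (mM)
    K_C: float  # nutrient affinity (mM)
    gamma: float  # max growth rate (1/day)
    A0: float  # initial nitrate (mM)
    C0: float  # initial limiting nutrient (mM)

    def __post_init__(self) -> None:
        for name in ("x0", "r_A", "r_C", "K_A", "K_C", "gamma", "A0", "C0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class CRMParams:
    """Rescaled (identifiable) parameter set.

    ``x0_tilde`` is the indigenous biomass activity in mM nitrate per day;
    ``C0_tilde`` the limiting nutrient in nitrate-equivalent mM.  ``A0`` and
    ``A0c`` are the initial nitrate of the untreated and chloramphenicol arms.
    """

    x0_tilde: float  # mM/day
    C0_tilde: float  # mM
    A0: float  # mM
    A0c: float  # mM
    gamma: float  # 1/day
    K_A: float = 0.01  # mM
    K_C_tilde: float = 0.01  # mM

    def __post_init__(self) -> None:
        for name in ("x0_tilde", "C0_tilde", "A0", "A0c", "gamma", "K_A", "K_C_tilde"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.K_A <= 0 or self.K_C_tilde <= 0:
            raise ValueError("affinities must be strictly positive for integration")


@dataclass(frozen=True)
class Trajectory:
    """Solution curves on a time grid (days)."""

    times: np.ndarray
    A: np.ndarray  # nitrate, mM
    C_tilde: np.ndarray  # rescaled nutrient, mM
    x_tilde: np.ndarray  # biomass activity, mM/day

    def to_frame(self):
        """Long-format table (time, variable, value)."""
        import pandas as pd

        frames = []
        for name, arr in (("A", self.A), ("C_tilde", self.C_tilde), ("x_tilde", self.x_tilde)):
            frames.append(pd.DataFrame({"time": self.times, "variable": name, "value": arr}))
        return pd.concat(frames, ignore_index=True)


def rescale_params(raw: CRMParamsRaw, A0c: float | None = None) -> CRMParams:
    """Map raw parameters onto the identifiable rescaled set.

    x̃(0) = r_A·x(0), C̃(0) = C(0)·r_A/r_C, K̃_C = K_C·r_A/r_C; γ, K_A and A0
    carry through.  A0c (chloramphenicol-arm initial nitrate) is supplied
    separately; defaults to A0.
    """
    if raw.r_C == 0 and raw.C0 > 0:
        raise InvalidRescalingError("r_C = 0 with C0 > 0: rescaled nutrient undefined")
    ratio = raw.r_A / raw.r_C if raw.r_C > 0 else 0.0
    return CRMParams(
        x0_tilde=raw.r_A * raw.x0,
        C0_tilde=raw.C0 * ratio,
        A0=raw.A0,
        A0c=raw.A0 if A0c is None else A0c,
        gamma=raw.gamma,
        K_A=raw.K_A,
        K_C_tilde=raw.K_C * ratio if raw.K_C * ratio > 0 else 1e-12,
    )


def _rhs(t, y, gamma, K_A, K_C):
    A, C, x = np.maximum(y, 0.0)
    mA = A / (A + K_A)
    mC = C / (C + K_C)
    return (-x * mA, -x * mC, gamma * x * mA * mC)


def _jac(t, y, gamma, K_A, K_C):
    A, C, x = np.maximum(y, 0.0)
    dmA = K_A / (A + K_A) ** 2
    dmC = K_C / (C + K_C) ** 2
    mA = A / (A + K_A)
    mC = C / (C + K_C)
    return np.array(
        [
            [-x * dmA, 0.0, -mA],
            [0.0, -x * dmC, -mC],
            [gamma * x * dmA * mC, gamma * x * mA * dmC, gamma * mA * mC],
        ]
    )


def simulate(
    params: CRMParams,
    times: np.ndarray,
    growth_on: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the rescaled system on a sorted day grid.

    ``growth_on=False`` models the chloramphenicol arm: γ is forced to 0 and
    the initial nitrate is ``A0c``.  State is clipped at 0 (Monod terms are
    undefined for negative resources); an implicit stepper (LSODA) handles the
    stiffness at resource exhaustion.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) < 0) or (times.size and times[0] < 0):
        raise ValueError("times must be a sorted 1-D array of non-negative days")
    gamma = params.gamma if growth_on else 0.0
    A0 = params.A0 if growth_on else params.A0c
    y0 = np.array([A0, params.C0_tilde, params.x0_tilde])
    if not np.all(np.isfinite(y0)):
        raise IntegrationError("non-finite initial state")
    if params.x0_tilde == 0.0 or times.size == 0:
        n = times.size
        return Trajectory(
            times=times,
            A=np.full(n, A0),
            C_tilde=np.full(n, params.C0_tilde),
            x_tilde=np.full(n, params.x0_tilde),
        )
    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1e-12)
    sol = solve_ivp(
        _rhs,
        t_span,
        y0,
        t_eval=times,
        method="LSODA",
        jac=_jac,
        args=(gamma, params.K_A, params.K_C_tilde),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    y = np.maximum(sol.y, 0.0)
    return Trajectory(times=times, A=y[0], C_tilde=y[1], x_tilde=y[2])


def simulate_chl_arm(params: CRMParams, times: np.ndarray) -> np.ndarray:
    """Nitrate of the growth-arrested arm via the exact implicit solution.

    With γ = 0 the nitrate equation decouples: A + K_A·ln(A/A0c) = A0c − x̃(0)t,
    solved in log space with the Wright omega function.  Used as a fast exact
    path inside the fitting loop; agrees with :func:`simulate` to solver
    tolerance.
    """
    times = np.asarray(times, dtype=float)
    if params.x0_tilde == 0.0:
        return np.full(times.shape, params.A0c)
    K = params.K_A
    if params.A0c == 0.0:
        return np.zeros(times.shape)
    # A/K = omega(ln(A0/K) + (A0 - x t)/K) where omega solves w + ln w = z
    z = np.log(params.A0c / K) + (params.A0c - params.x0_tilde * times) / K
    return K * np.real(wrightomega(z))


def growth_stop_time(params: CRMParams) -> float:
    """Time t* at which growth arrests (first resource exhausted).

    t* = ln(min(A0, C̃(0))·γ/x̃(0) + 1)/γ, with the γ→0 limit
    min(A0, C̃(0))/x̃(0); +inf if x̃(0) = 0.
    """
    if params.x0_tilde == 0.0:
        return np.inf
    m = min(params.A0, params.C0_tilde)
    if params.gamma == 0.0:
        return m / params.x0_tilde
    return float(np.log1p(m * params.gamma / params.x0_tilde) / params.gamma)


def closed_form(params: CRMParams, times: np.ndarray) -> Trajectory:
    """Piecewise small-affinity approximation for the untreated arm.

    Before t* the biomass grows exponentially, so
    A = A0 − x̃(0)(e^{γt} − 1)/γ; after t* (when C̃(0) < A0) nitrate declines
    linearly with slope γC̃(0) + x̃(0).  Valid when K_A ≪ A0 and K̃_C ≪ C̃(0);
    returned regardless, clipped at 0.
    """
    times = np.asarray(times, dtype=float)
    x0, C0, A0, g = params.x0_tilde, params.C0_tilde, params.A0, params.gamma
    if x0 == 0.0:
        return Trajectory(times, np.full(times.shape, A0), np.full(times.shape, C0), np.zeros(times.shape))
    tstar = growth_stop_time(params)

    def consumed(t):
        # cumulative x̃ integral: x̃(0)(e^{γt}-1)/γ, γ→0 limit x̃(0)t
        if g == 0.0:
            return x0 * t
        return x0 * np.expm1(g * t) / g

    pre = times < tstar
    A = np.empty_like(times)
    C = np.empty_like(times)
    xt = np.empty_like(times)
    A[pre] = A0 - consumed(times[pre])
    C[pre] = C0 - consumed(times[pre])
    xt[pre] = x0 * np.exp(g * times[pre])
    post = ~pre
    if np.any(post):
        x_star = x0 + g * min(A0, C0)  # x̃(t*) = x̃(0) + γ·min(A0, C̃(0))
        if C0 < A0:
            A_star = A0 - C0  # A(t*) = A0 − min(A0, C̃0)
            A[post] = A_star - x_star * (times[post] - tstar)
            C[post] = 0.0
        else:
            A[post] = 0.0
            C[post] = C0 - A0 - x_star * (times[post] - tstar)
        xt[post] = x_star
    return Trajectory(times, np.maximum(A, 0.0), np.maximum(C, 0.0), xt)
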