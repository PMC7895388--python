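"""Two-cell model of oocyte selection and its reductions.

The model describes the positive-feedback localization of an autoregulatory
translational regulator (Orb) in the two central cells of the *Drosophila*
germline cyst.  Free mRNA and protein exchange between the two cells through
a ring canal; protein promotes both the binding (immobilization) of its own
mRNA and its own translation, each through a sigmoidal (Hill) switch.

Four model variants are provided:

* the full six-dimensional system tracking unbound mRNA ``u_i``, bound mRNA
  ``b_i`` and protein ``p_i`` in each cell (dimensional parameters);
* the reduced four-dimensional system for total mRNA ``m_i = u_i + b_i``,
  obtained under a rapid-equilibrium approximation of binding/unbinding;
* the nondimensionalized four-dimensional system in rescaled variables
  ``(M1, M2, P1, P2)`` with eight dimensionless parameter groups — this is
  the system all downstream analysis operates on;
* a one-dimensional autocatalytic toy model used to illustrate the
  sharp-switch decomposition machinery.

Each switch can be evaluated with a finite Hill exponent or in the
sharp-switch (Heaviside) limit ``n -> infinity``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "DimensionalParameters",
    "DimensionlessParameters",
    "ToyParameters",
    "SwitchSpec",
    "FullState",
    "ReducedState",
    "ScaledState",
    "hill",
    "nondimensionalize",
    "reduce_rapid_equilibrium",
    "rhs_full",
    "rhs_reduced",
    "rhs_scaled",
    "rhs_toy",
    "PARAM_NAMES",
]

#: canonical ordering of the dimensionless parameters in array form
PARAM_NAMES = ("theta1", "theta2", "mu", "gamma", "eta", "kappa", "pi", "epsilon")


def _require_positive(**kwargs) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DimensionalParameters:
    """Dimensional rate constants and thresholds of the full model.

    Rates carry units of 1/time (concentration/time for ``alpha_hat``),
    thresholds carry concentration units; ``n`` and ``nu`` are the Hill
    exponents of the binding and translation switches.
    """

    alpha_hat: float   # mRNA transcription rate
    mu_hat: float      # mRNA degradation rate constant
    k_minus: float     # mRNA unbinding rate constant
    k_plus_0: float    # basal mRNA binding rate constant
    k_plus_delta: float  # protein-induced binding increment
    delta_hat: float   # intercellular mRNA exchange rate constant
    beta_hat: float    # basal translation rate
    gamma_hat: float   # protein-induced translation increment
    pi_hat: float      # protein degradation rate constant
    D_hat: float       # intercellular protein exchange rate constant
    Theta1: float      # protein threshold for induced mRNA binding
    Theta2: float      # protein threshold for induced translation
    n: float = 10.0
    nu: float = 10.0

    def __post_init__(self) -> None:
        d = asdict(self)
        n, nu = d.pop("n"), d.pop("nu")
        # zero protein-induced binding is a legitimate boundary case
        kpd = d.pop("k_plus_delta")
        if kpd < 0:
            raise ValueError("k_plus_delta must be nonnegative")
        _require_positive(**d)
        if not (n > 1 and nu > 1):
            raise ValueError("Hill exponents n and nu must exceed 1")

    @property
    def K0(self) -> float:
        """Basal binding equilibrium constant ``k_plus_0 / k_minus``."""
        return self.k_plus_0 / self.k_minus

    @property
    def K(self) -> float:
        """Induced binding equilibrium constant ``k_plus_delta / k_minus``."""
        return self.k_plus_delta / self.k_minus


@dataclass(frozen=True)
class DimensionlessParameters:
    """The eight dimensionless groups of the rescaled two-cell model.

    ``mu``, ``pi`` and ``epsilon`` compare mRNA degradation, protein
    degradation and protein transport against the maximal rate of
    intercellular mRNA transport; ``gamma`` is the fold increase of
    translation above basal; ``theta1``/``theta2`` are the rescaled switch
    thresholds for transport inhibition and autocatalytic translation; and
    ``kappa``/``eta`` measure induced mRNA binding against total and basal
    binding turnover.  Any parameter set derived from positive dimensional
    rates satisfies ``eta > kappa`` since ``eta = K/K0 > K/(1+K0) = kappa``.
    """

    theta1: float
    theta2: float
    mu: float
    gamma: float
    eta: float
    kappa: float
    pi: float
    epsilon: float
    n: float = 10.0
    nu: float = 10.0

    def __post_init__(self) -> None:
        d = asdict(self)
        n, nu = d.pop("n"), d.pop("nu")
        # kappa and eta vanish together when there is no induced binding
        kap, eta = d.pop("kappa"), d.pop("eta")
        if kap < 0 or eta < 0:
            raise ValueError("kappa and eta must be nonnegative")
        _require_positive(**d)
        if not (n > 1 and nu > 1):
            raise ValueError("Hill exponents n and nu must exceed 1")
        if self.theta1 == self.theta2:
            raise ValueError(
                "theta1 == theta2 lies on the measure-zero boundary between "
                "threshold orderings and is rejected"
            )

    def as_array(self) -> np.ndarray:
        """Parameter vector in the canonical :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, name) for name in PARAM_NAMES])

    @classmethod
    def from_array(cls, x, n: float = 10.0, nu: float = 10.0) -> "DimensionlessParameters":
        return cls(**dict(zip(PARAM_NAMES, map(float, x))), n=n, nu=nu)

    def to_json(self, path) -> None:
        d = {k: getattr(self, k) for k in PARAM_NAMES + ("n", "nu")}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path) -> "DimensionlessParameters":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ToyParameters:
    """Parameters of the one-dimensional autocatalytic toy model."""

    b: float       # basal production rate
    theta: float   # self-activation threshold
    gamma: float   # degradation rate
    n: float = 10.0

    def __post_init__(self) -> None:
        _require_positive(b=self.b, theta=self.theta, gamma=self.gamma)
        if not self.n > 1:
            raise ValueError("Hill exponent n must exceed 1")


@dataclass(frozen=True)
class SwitchSpec:
    """Choice of switch nonlinearity: finite Hill exponent or Heaviside limit."""

    mode: Literal["finite", "heaviside"] = "finite"
    exponent: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("finite", "heaviside"):
            raise ValueError(f"unknown switch mode {self.mode!r}")
        if self.mode == "finite" and not self.exponent > 1:
            raise ValueError("finite-mode Hill exponent must exceed 1")


HEAVISIDE = SwitchSpec(mode="heaviside")


@dataclass(frozen=True)
class FullState:
    """State of the six-dimensional model: unbound/bound mRNA and protein."""

    u1: float
    u2: float
    b1: float
    b2: float
    p1: float
    p2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.u2, self.b1, self.b2, self.p1, self.p2])


@dataclass(frozen=True)
class ReducedState:
    """State of the reduced model: total mRNA ``m_i = u_i + b_i`` and protein."""

    m1: float
    m2: float
    p1: float
    p2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m1, self.m2, self.p1, self.p2])


@dataclass(frozen=True)
class ScaledState:
    """State of the nondimensionalized model ``(M1, M2, P1, P2)``."""

    M1: float
    M2: float
    P1: float
    P2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.M1, self.M2, self.P1, self.P2])

    def swapped(self) -> "ScaledState":
        """State with the two cells exchanged."""
        return ScaledState(self.M2, self.M1, self.P2, self.P1)


def hill(x, theta, spec: SwitchSpec = SwitchSpec()):
    """Sigmoidal switch ``x^n / (theta^n + x^n)`` or its Heaviside limit.

    In ``heaviside`` mode returns 0 below the threshold, 1 above it, and 1/2
    exactly at ``x == theta`` (the finite-Hill value at threshold; region
    definitions only ever use strict inequalities, so the value on this
    measure-zero set is a convention).

    Accepts scalars or arrays for ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill is defined for nonnegative arguments only")
    if not theta > 0:
        raise ValueError("hill threshold must be strictly positive")
    if spec.mode == "heaviside":
        out = np.where(x > theta, 1.0, np.where(x < theta, 0.0, 0.5))
    else:
        # evaluated as 1 / (1 + (theta/x)^n), which neither overflows for
        # large x nor loses the exact value 1/2 at x = theta
        n = spec.exponent
        with np.errstate(over="ignore"):
            ratio = np.where(x > 0, (theta / np.where(x > 0, x, 1.0)) ** n, np.inf)
        out = 1.0 / (1.0 + ratio)
    return out if out.ndim else float(out)


def nondimensionalize(p: DimensionalParameters) -> DimensionlessParameters:
    """Map dimensional rate constants onto the eight dimensionless groups.

    Time is rescaled by the maximal intercellular mRNA transport rate
    ``delta_hat / (1 + K0)``, mRNA by transcription over maximal transport,
    and protein by basal translation of bound mRNA over unbinding and
    transport of free mRNA.  The Hill exponents are unchanged.
    """
    K0, K = p.K0, p.K
    scale = (1.0 + K0) / p.delta_hat
    theta_scale = p.delta_hat ** 2 / (p.alpha_hat * p.beta_hat * K0 * (1.0 + K0))
    return DimensionlessParameters(
        theta1=p.Theta1 * theta_scale,
        theta2=p.Theta2 * theta_scale,
        mu=p.mu_hat * scale,
        gamma=p.gamma_hat / p.beta_hat,
        eta=K / K0,
        kappa=K / (1.0 + K0),
        pi=p.pi_hat * scale,
        epsilon=p.D_hat * scale,
        n=p.n,
        nu=p.nu,
    )


def reduce_rapid_equilibrium(s: FullState, p: DimensionalParameters) -> ReducedState:
    """Collapse bound/unbound mRNA onto total mRNA at binding equilibrium.

    When binding and unbinding are fast, ``m_i = u_i (1 + K0 + K h(p_i))``
    with ``h`` the binding switch; protein concentrations are unchanged.
    """
    spec = SwitchSpec("finite", p.n)
    f1 = 1.0 + p.K0 + p.K * hill(s.p1, p.Theta1, spec)
    f2 = 1.0 + p.K0 + p.K * hill(s.p2, p.Theta1, spec)
    return ReducedState(m1=s.u1 * f1, m2=s.u2 * f2, p1=s.p1, p2=s.p2)


def rhs_full(s, p: DimensionalParameters) -> np.ndarray:
    """Time derivatives of the six-dimensional model ``(u1,u2,b1,b2,p1,p2)``.

    Provided as a consistency oracle for the reduced and rescaled systems.
    """
    u1, u2, b1, b2, p1, p2 = (s.as_array() if isinstance(s, FullState) else np.asarray(s, float))
    bind = SwitchSpec("finite", p.n)
    transl = SwitchSpec("finite", p.nu)
    kp1 = p.k_plus_0 + p.k_plus_delta * hill(p1, p.Theta1, bind)
    kp2 = p.k_plus_0 + p.k_plus_delta * hill(p2, p.Theta1, bind)
    tr1 = p.beta_hat + p.gamma_hat * hill(p1, p.Theta2, transl)
    tr2 = p.beta_hat + p.gamma_hat * hill(p2, p.Theta2, transl)
    return np.array([
        p.alpha_hat - p.mu_hat * u1 + p.k_minus * b1 - kp1 * u1 + p.delta_hat * (u2 - u1),
        p.alpha_hat - p.mu_hat * u2 + p.k_minus * b2 - kp2 * u2 + p.delta_hat * (u1 - u2),
        kp1 * u1 - p.k_minus * b1 - p.mu_hat * b1,
        kp2 * u2 - p.k_minus * b2 - p.mu_hat * b2,
        tr1 * b1 - p.pi_hat * p1 + p.D_hat * (p2 - p1),
        tr2 * b2 - p.pi_hat * p2 + p.D_hat * (p1 - p2),
    ])


def rhs_reduced(s, p: DimensionalParameters) -> np.ndarray:
    """Time derivatives of the reduced four-dimensional model ``(m1,m2,p1,p2)``."""
    m1, m2, p1, p2 = (s.as_array() if isinstance(s, ReducedState) else np.asarray(s, float))
    K0, K = p.K0, p.K
    bind = SwitchSpec("finite", p.n)
    transl = SwitchSpec("finite", p.nu)
    h1, h2 = hill(p1, p.Theta1, bind), hill(p2, p.Theta1, bind)
    bound1 = (K0 + K * h1) / (1.0 + K0 + K * h1)
    bound2 = (K0 + K * h2) / (1.0 + K0 + K * h2)
    free1 = 1.0 / (1.0 + K0 + K * h1)
    free2 = 1.0 / (1.0 + K0 + K * h2)
    tr1 = p.beta_hat + p.gamma_hat * hill(p1, p.Theta2, transl)
    tr2 = p.beta_hat + p.gamma_hat * hill(p2, p.Theta2, transl)
    return np.array([
        p.alpha_hat - p.mu_hat * m1 - p.delta_hat * free1 * m1 + p.delta_hat * free2 * m2,
        p.alpha_hat - p.mu_hat * m2 + p.delta_hat * free1 * m1 - p.delta_hat * free2 * m2,
        tr1 * bound1 * m1 - p.pi_hat * p1 + p.D_hat * (p2 - p1),
        tr2 * bound2 * m2 - p.pi_hat * p2 + p.D_hat * (p1 - p2),
    ])


def _switch_pair(p: DimensionlessParameters, mode: str):
    if mode == "heaviside":
        return HEAVISIDE, HEAVISIDE
    return SwitchSpec("finite", p.n), SwitchSpec("finite", p.nu)


def rhs_scaled(s, p: DimensionlessParameters, mode: str = "finite") -> np.ndarray:
    """Time derivatives of the nondimensionalized model ``(M1,M2,P1,P2)``.

    ``mode`` selects finite Hill exponents (``p.n``, ``p.nu``) or the
    sharp-switch Heaviside limit.  Transient small negative protein values
    produced by an integrator are clipped to zero before evaluating the
    switches.
    """
    M1, M2, P1, P2 = (s.as_array() if isinstance(s, ScaledState) else np.asarray(s, float))
    P1, P2 = max(P1, 0.0), max(P2, 0.0)
    bind, transl = _switch_pair(p, mode)
    h11, h12 = hill(P1, p.theta1, bind), hill(P2, p.theta1, bind)
    h21, h22 = hill(P1, p.theta2, transl), hill(P2, p.theta2, transl)
    T1, T2 = 1.0 / (1.0 + p.kappa * h11), 1.0 / (1.0 + p.kappa * h12)
    G1 = (1.0 + p.gamma * h21) * (1.0 + p.eta * h11) * T1
    G2 = (1.0 + p.gamma * h22) * (1.0 + p.eta * h12) * T2
    return np.array([
        1.0 - p.mu * M1 - T1 * M1 + T2 * M2,
        1.0 - p.mu * M2 + T1 * M1 - T2 * M2,
        G1 * M1 - p.pi * P1 + p.epsilon * (P2 - P1),
        G2 * M2 - p.pi * P2 + p.epsilon * (P1 - P2),
    ])


def rhs_toy(X, p: ToyParameters, spec: SwitchSpec = SwitchSpec()) -> float:
    """Time derivative of the toy model ``dX/dt = b + switch(X) - gamma X``."""
    if spec.mode == "finite":
        spec = SwitchSpec("finite", p.n)
    return float(p.b + hill(max(float(X), 0.0), p.theta, spec) - p.gamma * float(X))
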