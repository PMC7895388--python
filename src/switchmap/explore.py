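"""Region-guided numerical exploration with finite Hill exponents.

The sharp-switch catalog predicts which switching domains attract in the
``n -> infinity`` limit.  At finite exponents those predictions deform:
fixed points move, some disappear, and new stable states can pin near a
threshold.  This module samples parameter sets (optionally restricted to a
catalog region), enumerates their stable steady states by long-time
integration from a structured grid of initial conditions followed by root
polishing and a Jacobian spectral test, classifies each phase portrait as
symmetric-only / mixed / asymmetric-only, and estimates the density of
symmetry-breaking (asymmetric-only) parameter sets.

The integrator is a compiled Dormand–Prince 4(5) scheme with per-trajectory
adaptive steps and an equilibrium stopping rule, which keeps thousand-set
density studies to a few minutes on one core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy.optimize import root

from .model import ToyParameters

__all__ = [
    "SampleSpec",
    "SampleResult",
    "SteadyState",
    "PhasePortraitSummary",
    "DensityEstimate",
    "sample_parameters",
    "find_stable_steady_states",
    "classify",
    "density_study",
    "toy_stable_states",
    "toy_stable_states_by_integration",
    "toy_configuration_match",
    "toy_preservation_table",
    "heaviside_fixed_points",
    "default_initial_conditions",
]

#: tolerances of the steady-state pipeline
RESIDUAL_TOL = 1e-9        # max |rhs| per unit state scale after polishing
DEDUP_RTOL = 1e-4          # relative max-norm tolerance for distinct states
ASYMMETRY_RTOL = 1e-3      # |P1-P2| > tol * max(P1, P2, theta2) is asymmetric
CONVERGENCE_FTOL = 1e-8    # stop integrating when max |rhs| falls below this
T_MAX = 1.0e4              # integration horizon in rescaled time units


# ---------------------------------------------------------------------------
# compiled right-hand side and integrator


@njit(cache=True, fastmath=False)
def _rhs4(y, out, th1, th2, mu, gam, eta, kap, pi_, eps, n, nu):
    M1, M2 = y[0], y[1]
    P1 = y[2] if y[2] > 0.0 else 0.0
    P2 = y[3] if y[3] > 0.0 else 0.0
    # overflow-safe Hill: h = 1 / (1 + (theta/x)^n), h(0) = 0
    h11 = 0.0 if P1 == 0.0 else 1.0 / (1.0 + (th1 / P1) ** n)
    h12 = 0.0 if P2 == 0.0 else 1.0 / (1.0 + (th1 / P2) ** n)
    h21 = 0.0 if P1 == 0.0 else 1.0 / (1.0 + (th2 / P1) ** nu)
    h22 = 0.0 if P2 == 0.0 else 1.0 / (1.0 + (th2 / P2) ** nu)
    T1 = 1.0 / (1.0 + kap * h11)
    T2 = 1.0 / (1.0 + kap * h12)
    G1 = (1.0 + gam * h21) * (1.0 + eta * h11) * T1
    G2 = (1.0 + gam * h22) * (1.0 + eta * h12) * T2
    out[0] = 1.0 - mu * M1 - T1 * M1 + T2 * M2
    out[1] = 1.0 - mu * M2 + T1 * M1 - T2 * M2
    out[2] = G1 * M1 - pi_ * P1 + eps * (P2 - P1)
    out[3] = G2 * M2 - pi_ * P2 + eps * (P1 - P2)


@njit(cache=True)
def _integrate_one(y0, th1, th2, mu, gam, eta, kap, pi_, eps, n, nu,
                   tmax, ftol, rtol, atol):
    """Adaptive Dormand-Prince 4(5); stops at equilibrium (max|rhs| < ftol)."""
    y = y0.copy()
    k = np.zeros((7, 4))
    tmp = np.zeros(4)
    ynew = np.zeros(4)
    A = np.array([
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0, 0.0],
        [44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0, 0.0, 0.0, 0.0],
        [19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0, 0.0, 0.0],
        [9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0, 49.0 / 176.0, -5103.0 / 18656.0, 0.0],
        [35.0 / 384.0, 0.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0],
    ])
    B = np.array([35.0 / 384.0, 0.0, 500.0 / 1113.0, 125.0 / 192.0,
                  -2187.0 / 6784.0, 11.0 / 84.0, 0.0])
    E = np.array([35.0 / 384.0 - 5179.0 / 57600.0, 0.0,
                  500.0 / 1113.0 - 7571.0 / 16695.0,
                  125.0 / 192.0 - 393.0 / 640.0,
                  -2187.0 / 6784.0 + 92097.0 / 339200.0,
                  11.0 / 84.0 - 187.0 / 2100.0, -1.0 / 40.0])
    t = 0.0
    h = 0.01
    nsteps = 0
    _rhs4(y, k[0], th1, th2, mu, gam, eta, kap, pi_, eps, n, nu)
    while t < tmax and nsteps < 200000:
        mx = 0.0
        for j in range(4):
            if abs(k[0][j]) > mx:
                mx = abs(k[0][j])
        if mx < ftol:
            break
        if t + h > tmax:
            h = tmax - t
        for s in range(1, 7):
            for j in range(4):
                acc = 0.0
                for q in range(s):
                    acc += A[s][q] * k[q][j]
                tmp[j] = y[j] + h * acc
            _rhs4(tmp, k[s], th1, th2, mu, gam, eta, kap, pi_, eps, n, nu)
        errnorm = 0.0
        for j in range(4):
            acc = 0.0
            ea = 0.0
            for s in range(7):
                acc += B[s] * k[s][j]
                ea += E[s] * k[s][j]
            ynew[j] = y[j] + h * acc
            sc = atol + rtol * max(abs(y[j]), abs(ynew[j]))
            e = h * ea / sc
            errnorm += e * e
        errnorm = (errnorm / 4.0) ** 0.5
        if errnorm <= 1.0:
            t += h
            for j in range(4):
                y[j] = ynew[j]
                k[0][j] = k[6][j]
            fac = 5.0 if errnorm == 0.0 else 0.9 * errnorm ** -0.2
        else:
            fac = 0.9 * errnorm ** -0.2
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        nsteps += 1
    converged = False
    mx = 0.0
    for j in range(4):
        if abs(k[0][j]) > mx:
            mx = abs(k[0][j])
    if mx < 100.0 * ftol:
        converged = True
    return y, converged


@njit(cache=True)
def _integrate_batch(Y0, th1, th2, mu, gam, eta, kap, pi_, eps, n, nu, tmax, ftol):
    K = Y0.shape[0]
    out = np.zeros((K, 4))
    conv = np.zeros(K, dtype=np.bool_)
    for i in range(K):
        y, ok = _integrate_one(Y0[i], th1, th2, mu, gam, eta, kap, pi_, eps,
                               n, nu, tmax, ftol, 1e-7, 1e-10)
        out[i] = y
        conv[i] = ok
    return out, conv


# ---------------------------------------------------------------------------
# plain-numpy right-hand side and Jacobian (used for polishing/stability)


def _hill_safe(x, th, m):
    """Overflow-safe Hill function ``1 / (1 + (th/x)^m)`` with value 0 at 0."""
    x = np.asarray(x, float)
    with np.errstate(over="ignore", divide="ignore"):
        r = np.where(x > 0.0, (th / np.where(x > 0.0, x, 1.0)) ** m, np.inf)
    return 1.0 / (1.0 + r)


def _params_tuple(params) -> tuple:
    if hasattr(params, "as_array"):
        return tuple(float(v) for v in params.as_array())
    return tuple(float(v) for v in params)


def rhs_finite(y, params, n, nu):
    """Vectorized finite-Hill right-hand side; ``y`` has trailing axis 4."""
    th1, th2, mu, gam, eta, kap, pi_, eps = _params_tuple(params)
    y = np.asarray(y, float)
    out = np.empty_like(y)
    M1, M2 = y[..., 0], y[..., 1]
    P1 = np.maximum(y[..., 2], 0.0)
    P2 = np.maximum(y[..., 3], 0.0)
    h11 = _hill_safe(P1, th1, n)
    h12 = _hill_safe(P2, th1, n)
    h21 = _hill_safe(P1, th2, nu)
    h22 = _hill_safe(P2, th2, nu)
    T1 = 1.0 / (1.0 + kap * h11)
    T2 = 1.0 / (1.0 + kap * h12)
    G1 = (1.0 + gam * h21) * (1.0 + eta * h11) * T1
    G2 = (1.0 + gam * h22) * (1.0 + eta * h12) * T2
    out[..., 0] = 1.0 - mu * M1 - T1 * M1 + T2 * M2
    out[..., 1] = 1.0 - mu * M2 + T1 * M1 - T2 * M2
    out[..., 2] = G1 * M1 - pi_ * P1 + eps * (P2 - P1)
    out[..., 3] = G2 * M2 - pi_ * P2 + eps * (P1 - P2)
    return out


def jacobian_finite(y, params, n, nu) -> np.ndarray:
    """Analytic Jacobian of the finite-Hill system at a single state."""
    th1, th2, mu, gam, eta, kap, pi_, eps = _params_tuple(params)
    M1, M2 = float(y[0]), float(y[1])
    P1, P2 = max(float(y[2]), 0.0), max(float(y[3]), 0.0)

    def h(x, th, m):
        return float(_hill_safe(x, th, m))

    def dh(x, th, m):
        if x == 0.0:
            return 0.0
        hv = h(x, th, m)
        return m * hv * (1.0 - hv) / x

    h11, h12 = h(P1, th1, n), h(P2, th1, n)
    h21, h22 = h(P1, th2, nu), h(P2, th2, nu)
    d11, d12 = dh(P1, th1, n), dh(P2, th1, n)
    d21, d22 = dh(P1, th2, nu), dh(P2, th2, nu)
    T1, T2 = 1.0 / (1.0 + kap * h11), 1.0 / (1.0 + kap * h12)
    dT1, dT2 = -kap * d11 * T1 ** 2, -kap * d12 * T2 ** 2
    G1 = (1.0 + gam * h21) * (1.0 + eta * h11) * T1
    G2 = (1.0 + gam * h22) * (1.0 + eta * h12) * T2
    dG1 = gam * d21 * (1.0 + eta * h11) * T1 + \
        (1.0 + gam * h21) * (eta * d11 * T1 + (1.0 + eta * h11) * dT1)
    dG2 = gam * d22 * (1.0 + eta * h12) * T2 + \
        (1.0 + gam * h22) * (eta * d12 * T2 + (1.0 + eta * h12) * dT2)
    J = np.zeros((4, 4))
    J[0, 0] = -mu - T1
    J[0, 1] = T2
    J[0, 2] = -dT1 * M1
    J[0, 3] = dT2 * M2
    J[1, 0] = T1
    J[1, 1] = -mu - T2
    J[1, 2] = dT1 * M1
    J[1, 3] = -dT2 * M2
    J[2, 0] = G1
    J[2, 2] = dG1 * M1 - pi_ - eps
    J[2, 3] = eps
    J[3, 1] = G2
    J[3, 2] = eps
    J[3, 3] = dG2 * M2 - pi_ - eps
    return J


# ---------------------------------------------------------------------------
# initial conditions


def heaviside_fixed_points(params) -> np.ndarray:
    """Closed-form fixed points of all nine sharp-switch domains.

    These seed the initial-condition grid: at finite exponents the surviving
    attractors sit near them.
    """
    th1, th2, mu, gam, eta, kap, pi_, eps = _params_tuple(params)
    th_lo, th_hi = (th2, th1) if th2 < th1 else (th1, th2)
    reps = [0.5 * th_lo, 0.5 * (th_lo + th_hi), 2.0 * th_hi]
    fps = []
    for c2 in range(3):
        for c1 in range(3):
            P1r, P2r = reps[c1], reps[c2]
            a1 = 1.0 if P1r > th1 else 0.0
            a2 = 1.0 if P2r > th1 else 0.0
            s1 = 1.0 if P1r > th2 else 0.0
            s2 = 1.0 if P2r > th2 else 0.0
            T1, T2 = 1.0 / (1.0 + kap * a1), 1.0 / (1.0 + kap * a2)
            G1 = (1.0 + gam * s1) * (1.0 + eta * a1) * T1
            G2 = (1.0 + gam * s2) * (1.0 + eta * a2) * T2
            M1 = (mu + 2.0 * T2) / (mu * (mu + T1 + T2))
            M2 = (mu + 2.0 * T1) / (mu * (mu + T1 + T2))
            den = pi_ * (pi_ + 2.0 * eps)
            P1 = ((pi_ + eps) * G1 * M1 + eps * G2 * M2) / den
            P2 = (eps * G1 * M1 + (pi_ + eps) * G2 * M2) / den
            fps.append([M1, M2, P1, P2])
    return np.array(fps)


def default_initial_conditions(params) -> np.ndarray:
    """34 starts: a 5x5 protein grid spanning all switching domains with
    mRNA at its conserved mean, plus the nine sharp-switch fixed points."""
    th1, th2, mu = (_params_tuple(params))[0:3]
    vals = [0.2 * th2, th2, 0.5 * (th1 + th2), th1, 2.0 * th1]
    grid = [[1.0 / mu, 1.0 / mu, a, b] for a in vals for b in vals]
    return np.concatenate([np.asarray(grid), heaviside_fixed_points(params)])


# ---------------------------------------------------------------------------
# steady-state enumeration


@dataclass(frozen=True)
class SteadyState:
    """A certified stable equilibrium of the finite-Hill system."""

    state: np.ndarray          # (M1, M2, P1, P2)
    residual: float            # max |rhs|
    max_eig_real: float        # spectral abscissa of the Jacobian
    symmetric: bool

    @property
    def stable(self) -> bool:
        return self.max_eig_real < 0


@dataclass(frozen=True)
class PhasePortraitSummary:
    """Stable steady states of one parameter set and their symmetry class."""

    params: tuple
    states: tuple
    classification: str        # symmetric_only | mixed | asymmetric_only
    n_failed_starts: int = 0

    @property
    def n_states(self) -> int:
        return len(self.states)


def _is_symmetric(state, th2, tol=ASYMMETRY_RTOL) -> bool:
    P1, P2 = state[2], state[3]
    return abs(P1 - P2) <= tol * max(P1, P2, th2)


def _enumerate_states(params, n, nu, initial_conditions=None, tmax=T_MAX):
    """Enumerate stable equilibria by relaxation, polishing and certification.

    Every initial condition is integrated until the state is numerically
    stationary; endpoints are deduplicated, polished to residual
    ``RESIDUAL_TOL`` with a Newton-type root solve, certified stable via the
    analytic Jacobian's eigenvalues, and returned as a swap-closed set.
    """
    p = _params_tuple(params)
    th2 = p[1]
    Y0 = default_initial_conditions(p) if initial_conditions is None \
        else np.asarray(initial_conditions, float)
    ends, conv = _integrate_batch(np.ascontiguousarray(Y0), *p,
                                  float(n), float(nu), float(tmax),
                                  CONVERGENCE_FTOL)
    n_failed = int((~conv).sum())
    uniq: list[np.ndarray] = []
    for e, ok in zip(ends, conv):
        if not ok:
            continue
        for u in uniq:
            if np.max(np.abs(u - e)) < 1e-6 * max(1e-12, np.max(np.abs(u))):
                break
        else:
            uniq.append(e)
    states: list[SteadyState] = []
    for e in uniq:
        sol = root(lambda v: rhs_finite(v, p, n, nu), e, method="hybr", tol=1e-13)
        v = np.maximum(sol.x, 0.0)
        if np.max(np.abs(rhs_finite(v, p, n, nu))) > np.max(np.abs(rhs_finite(e, p, n, nu))):
            v = np.maximum(e, 0.0)
        scale = max(1.0, float(np.max(np.abs(v))))
        res = float(np.max(np.abs(rhs_finite(v, p, n, nu))))
        if res > RESIDUAL_TOL * scale * 100.0:
            continue
        ev = float(np.max(np.linalg.eigvals(jacobian_finite(v, p, n, nu)).real))
        if ev > -1e-9:
            continue
        for s in states:
            if np.max(np.abs(s.state - v)) < DEDUP_RTOL * max(1e-30, np.max(np.abs(v))):
                break
        else:
            states.append(SteadyState(state=v, residual=res, max_eig_real=ev,
                                      symmetric=_is_symmetric(v, th2)))
    return states, n_failed


def find_stable_steady_states(params, n: float = 10.0, nu: float = 10.0,
                              initial_conditions: np.ndarray | None = None,
                              tmax: float = T_MAX) -> list[SteadyState]:
    """Public wrapper around the enumeration pipeline (drops the count of
    non-convergent starts; use :func:`phase_portrait` to retain it)."""
    states, _ = _enumerate_states(params, n, nu, initial_conditions, tmax)
    return states


def classify(states: Sequence[SteadyState] | Sequence[np.ndarray],
             th2: float | None = None) -> str:
    """Symmetry class of a phase portrait from its stable states."""
    if len(states) == 0:
        raise ValueError("no stable steady state found; cannot classify")
    if isinstance(states[0], SteadyState):
        flags = [s.symmetric for s in states]
    else:
        if th2 is None:
            raise ValueError("th2 required when classifying raw state arrays")
        flags = [_is_symmetric(np.asarray(s, float), th2) for s in states]
    if all(flags):
        return "symmetric_only"
    if not any(flags):
        return "asymmetric_only"
    return "mixed"


def phase_portrait(params, n: float = 10.0, nu: float = 10.0) -> PhasePortraitSummary:
    p = _params_tuple(params)
    states, n_failed = _enumerate_states(p, n, nu)
    return PhasePortraitSummary(
        params=p,
        states=tuple(states),
        classification=classify(states) if states else "none",
        n_failed_starts=n_failed,
    )


# ---------------------------------------------------------------------------
# sampling and density studies


@dataclass(frozen=True)
class SampleSpec:
    """Uniform sampling box with an optional region membership filter."""

    count: int
    box: tuple = ((0.01, 3.0),) * 8
    region_filter: Callable[[np.ndarray], np.ndarray] | None = None
    region_label: str = "box"
    seed: int = 0
    max_draws: int = 100_000_000

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be at least 1")
        for lo, hi in self.box:
            if not (0 < lo < hi):
                raise ValueError("box bounds must satisfy 0 < lo < hi")


def sample_parameters(spec: SampleSpec) -> np.ndarray:
    """Accepted parameter rows, uniform over the box intersected with the
    region filter (rejection sampling); reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lo = np.array([b[0] for b in spec.box])
    hi = np.array([b[1] for b in spec.box])
    out = []
    n_drawn = 0
    n_kept = 0
    need = spec.count
    batch = max(4096, 4 * need)
    while need > 0:
        n_drawn += batch
        if n_drawn > spec.max_draws:
            raise RuntimeError(
                f"acceptance rate too low sampling region "
                f"{spec.region_label!r} within the box")
        draws = rng.uniform(lo, hi, size=(batch, len(lo)))
        if spec.region_filter is not None:
            draws = draws[spec.region_filter(draws)]
        take = draws[:need]
        out.append(take)
        need -= len(take)
        n_kept += len(take)
        # adapt the batch to the observed acceptance rate
        rate = max(n_kept / n_drawn, 1.0 / n_drawn)
        batch = int(np.clip(2.0 * need / rate, 4096, 1_000_000))
    return np.concatenate(out)[: spec.count]


@dataclass(frozen=True)
class SampleResult:
    """Per-sample outcome of a density study."""

    classification: str
    n_states: int
    max_asymmetry: float


@dataclass(frozen=True)
class DensityEstimate:
    """Proportion of sampled parameter sets in the class of interest."""

    region_label: str
    n_sampled: int
    n_in_class: int
    target_class: str
    seed: int
    exponents: tuple
    per_sample: tuple = field(repr=False, default=())

    @property
    def classifications(self) -> tuple:
        return tuple(r.classification for r in self.per_sample)

    @property
    def proportion(self) -> float:
        return self.n_in_class / self.n_sampled

    def to_dict(self) -> dict:
        return {
            "region": self.region_label,
            "n_sampled": self.n_sampled,
            "n_in_class": self.n_in_class,
            "proportion": self.proportion,
            "target_class": self.target_class,
            "seed": self.seed,
            "n": self.exponents[0],
            "nu": self.exponents[1],
        }


def density_study(spec: SampleSpec, n: float = 10.0, nu: float = 10.0,
                  target_class: str = "asymmetric_only",
                  progress: Callable[[int], None] | None = None) -> DensityEstimate:
    """Sample, enumerate stable states per set and report the proportion of
    sets whose phase portrait falls in ``target_class``."""
    samples = sample_parameters(spec)
    hits = 0
    records = []
    for i, row in enumerate(samples):
        states, _ = _enumerate_states(tuple(row), n, nu)
        label = classify(states) if states else "none"
        asym = max((abs(s.state[2] - s.state[3]) for s in states), default=0.0)
        records.append(SampleResult(label, len(states), float(asym)))
        if label == target_class:
            hits += 1
        if progress is not None:
            progress(i + 1)
    return DensityEstimate(
        region_label=spec.region_label,
        n_sampled=len(samples),
        n_in_class=hits,
        target_class=target_class,
        seed=spec.seed,
        exponents=(n, nu),
        per_sample=tuple(records),
    )


# ---------------------------------------------------------------------------
# toy model


def toy_stable_states(params: ToyParameters | tuple, n: float | None = None,
                      ngrid: int = 400) -> np.ndarray:
    """Stable fixed points of the 1-D toy model by sign-change scan plus
    bisection; stability from the sign of the derivative."""
    if isinstance(params, ToyParameters):
        b, th, g = params.b, params.theta, params.gamma
        n = params.n if n is None else n
    else:
        b, th, g = params
        if n is None:
            raise ValueError("Hill exponent n required")

    def f(x):
        return b + _hill_safe(x, th, n) - g * x

    hi = 1.2 * (b + 1.0) / g
    xs = np.linspace(0.0, hi, ngrid)
    fv = f(xs)
    roots = []
    for i in range(len(xs) - 1):
        if fv[i] == 0.0:
            roots.append(xs[i])
        elif fv[i] * fv[i + 1] < 0.0:
            a, c = xs[i], xs[i + 1]
            fa = fv[i]
            for _ in range(80):
                m = 0.5 * (a + c)
                fm = f(m)
                if fa * fm <= 0.0:
                    c = m
                else:
                    a, fa = m, fm
            roots.append(0.5 * (a + c))
    stable = []
    for r in roots:
        if r > 0:
            hv = float(_hill_safe(r, th, n))
            d = n * hv * (1.0 - hv) / r - g
        else:
            d = -g
        if d < 0.0:
            stable.append(r)
    return np.array(stable)


def toy_stable_states_by_integration(params: ToyParameters | tuple,
                                     n: float | None = None,
                                     n_starts: int = 12,
                                     tmax: float = 2000.0) -> np.ndarray:
    """Independent route to the toy attractors: relax a spread of initial
    conditions with a stiff-capable integrator, polish endpoints by Newton
    steps, keep those with negative derivative, and deduplicate."""
    from scipy.integrate import solve_ivp
    if isinstance(params, ToyParameters):
        b, th, g = params.b, params.theta, params.gamma
        n = params.n if n is None else n
    else:
        b, th, g = params
    hi = 1.5 * (b + 1.0) / g
    xs = np.linspace(1e-6, hi, n_starts)

    def f(x):
        x = np.maximum(x, 0.0)
        return b + _hill_safe(x, th, n) - g * x

    def fprime(x):
        x = np.maximum(x, 1e-300)
        hv = _hill_safe(x, th, n)
        return n * hv * (1.0 - hv) / x - g

    T = max(100.0, 30.0 / g)
    sol = solve_ivp(lambda t, y: f(y), (0.0, min(T, tmax)), xs,
                    method="LSODA", rtol=1e-9, atol=1e-12)
    ends = sol.y[:, -1]
    uniq = []
    for e in np.sort(ends):
        x = e
        for _ in range(60):
            fx = f(x)
            if abs(fx) < 1e-13:
                break
            d = fprime(x)
            if d == 0:
                break
            step = fx / d
            x -= np.clip(step, -0.1 * hi, 0.1 * hi)
            x = max(x, 0.0)
        if abs(f(x)) > 1e-9 or fprime(x) >= 0:
            continue
        if not uniq or abs(x - uniq[-1]) > 1e-4 * max(1.0, abs(x)):
            uniq.append(x)
    return np.array(uniq)


def toy_configuration_match(params: ToyParameters | tuple, n: float | None = None) -> bool:
    """Does the finite-``n`` stable-state pattern match the sharp-switch
    prediction for the region containing ``params``?

    The pattern is the number of stable states below and above the
    threshold; the sharp-switch prediction per region is D1: one high state,
    D2: one of each (bistable), D3: one low state.
    """
    if isinstance(params, ToyParameters):
        b, th, g = params.b, params.theta, params.gamma
        n = params.n if n is None else n
    else:
        b, th, g = params
    from .sharp import ToyAnalysis
    toy = ToyAnalysis()
    region = toy.region_of(b, th, g)
    want_low, want_high = toy.heaviside_state_pattern(region)
    st = toy_stable_states((b, th, g), n)
    return (int(np.sum(st < th)), int(np.sum(st > th))) == (want_low, want_high)


def toy_preservation_table(n_values: Sequence[float] = (5.0, 10.0, 20.0),
                           n_samples: int = 1000, seed: int = 0,
                           box: tuple = ((0.01, 3.0),) * 3) -> dict:
    """Proportion of parameter sets per sharp-switch region whose finite-``n``
    state pattern matches the sharp-switch prediction.

    Samples ``(b, gamma, theta)`` uniformly from the box, rejected into each
    region; returns ``{region: {n: proportion}}``.
    """
    from .sharp import ToyAnalysis
    toy = ToyAnalysis()
    rng = np.random.default_rng(seed)
    lo = [bb[0] for bb in box]
    hi = [bb[1] for bb in box]
    out: dict = {}
    for region in ("D1", "D2", "D3"):
        samples = []
        while len(samples) < n_samples:
            b, g, th = rng.uniform(lo, hi)
            if toy.region_of(b, th, g) == region:
                samples.append((b, th, g))
        out[region] = {
            nv: sum(toy_configuration_match(s, nv) for s in samples) / n_samples
            for nv in n_values
        }
    return out


# ---------------------------------------------------------------------------
# serialization helpers


def density_report_json(estimates: Sequence[DensityEstimate], path) -> None:
    Path(path).write_text(
        json.dumps([e.to_dict() for e in estimates], indent=1, sort_keys=True) + "\n")


def per_sample_csv(samples: np.ndarray, results, path) -> None:
    import pandas as pd
    from .model import PARAM_NAMES
    df = pd.DataFrame(samples, columns=list(PARAM_NAMES))
    df["classification"] = [r.classification for r in results]
    df["n_states"] = [r.n_states for r in results]
    df["max_asymmetry"] = [r.max_asymmetry for r in results]
    df.to_csv(path, index=False)
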