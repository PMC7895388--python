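"""Sharp-switch (Heaviside-limit) decomposition of parameter space.

In the limit of infinitely steep switches the two-cell model becomes
piecewise affine: the positive ``(P1, P2)`` quadrant splits into nine
switching domains (three threshold intervals per protein coordinate), and
inside each domain the dynamics are linear with a unique, globally stable
fixed point whose coordinates are closed-form rational functions of the
parameters.  A domain is *attracting* exactly when its fixed point lies
inside it, which turns the enumeration of phase portraits into a finite
semialgebraic problem over the parameter space:

* each domain contributes one or two *wall values* — the protein
  coordinates of its fixed point, rational functions of the six
  non-threshold parameters;
* a domain is attracting iff its wall values fall in prescribed positions
  relative to the two thresholds;
* consequently the set of attracting domains (the *configuration*) is
  constant on the cells of the arrangement generated by comparing every
  wall value against the two thresholds.

This module derives the affine subsystems, fixed points and
attractor-membership inequalities symbolically (sympy), enumerates the
feasible cells of the arrangement by dense parameter sampling backed by
numeric slack maximization, groups cells into configurations and connected
parameter regions, and certifies codimension-1 boundaries between cells.

The parameter domain is the open positive orthant restricted by
``eta > kappa`` — the constraint inherited from the dimensional model,
where both groups are ratios of the same protein-induced binding constant
(``eta = K/K0``, ``kappa = K/(1+K0)``).  Threshold-order boundaries and all
wall/threshold coincidences are measure-zero and excluded.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import sympy as sp
from scipy.optimize import minimize

__all__ = [
    "ThresholdOrder",
    "SwitchingDomain",
    "AffineSubsystem",
    "DomainFixedPoint",
    "AttractorCondition",
    "Configuration",
    "ParameterRegion",
    "RegionCatalog",
    "SharpSwitchAnalysis",
    "ToyAnalysis",
    "enumerate_domains",
    "affine_subsystem",
    "domain_fixed_point",
    "attractor_condition",
    "enumerate_configurations",
    "decompose_regions",
    "get_analysis",
    "inequality_equivalent",
    "verify_region16_equivalence",
    "region16_chain",
    "region16_predicate",
    "SYMS",
]

# ---------------------------------------------------------------------------
# symbols and orderings

_mu, _gamma, _eta, _kappa, _pi, _eps = sp.symbols(
    "mu gamma eta kappa pi epsilon", positive=True
)
_th1, _th2 = sp.symbols("theta1 theta2", positive=True)
_M1, _M2, _P1, _P2 = sp.symbols("M1 M2 P1 P2", nonnegative=True)
_delta = sp.Symbol("delta_ek", positive=True)  # eta - kappa > 0

#: the six non-threshold parameter symbols, in canonical order
SYMS = (_mu, _gamma, _eta, _kappa, _pi, _eps)

DIAGONAL_DOMAINS = frozenset({0, 4, 8})
CONJUGATE = {0: 0, 1: 3, 2: 6, 3: 1, 4: 4, 5: 7, 6: 2, 7: 5, 8: 8}


class ThresholdOrder(Enum):
    """Which switch threshold is the smaller one (the equality case is excluded)."""

    theta2_lt_theta1 = "theta2_lt_theta1"
    theta1_lt_theta2 = "theta1_lt_theta2"

    @property
    def low_high(self) -> tuple[sp.Symbol, sp.Symbol]:
        if self is ThresholdOrder.theta2_lt_theta1:
            return _th2, _th1
        return _th1, _th2


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SwitchingDomain:
    """One cell of the ``(P1, P2)`` switching-domain grid.

    ``c1``/``c2`` index the threshold interval of each protein coordinate
    (0: below both thresholds, 1: between them, 2: above both); ``index``
    is ``3*c2 + c1``, so the diagonal domains are 0, 4, 8 and conjugate
    (cell-swap) pairs are (1,3), (2,6), (5,7).  The toy model has the two
    domains ``X < theta`` and ``X > theta``.
    """

    index: int
    c1: int
    c2: int
    order: ThresholdOrder

    @property
    def p1_interval(self):
        return self._interval(self.c1)

    @property
    def p2_interval(self):
        return self._interval(self.c2)

    def _interval(self, c):
        lo, hi = self.order.low_high
        return ((sp.S.Zero, lo), (lo, hi), (hi, sp.oo))[c]

    def switch_values(self) -> tuple[int, int, int, int]:
        """Heaviside values ``(a1, s1, a2, s2)`` of the binding (theta1) and
        translation (theta2) switches of each cell inside this domain."""

        def pair(c):
            lo, hi = self.order.low_high
            above = {0: (), 1: (lo,), 2: (lo, hi)}[c]
            a = int(_th1 in above)
            s = int(_th2 in above)
            return a, s

        a1, s1 = pair(self.c1)
        a2, s2 = pair(self.c2)
        return a1, s1, a2, s2


@dataclass(frozen=True)
class AffineSubsystem:
    """Affine dynamics ``x' = A x + c`` valid inside one switching domain."""

    domain: SwitchingDomain
    A: sp.Matrix
    c: sp.Matrix


@dataclass(frozen=True)
class DomainFixedPoint:
    """Closed-form fixed point ``f = -A^{-1} c`` of a domain's affine system."""

    domain: SwitchingDomain
    f: tuple  # sympy expressions (M1, M2, P1, P2)


@dataclass(frozen=True)
class AttractorCondition:
    """Inequalities equivalent to "the domain's fixed point lies inside it".

    ``inequalities`` is a conjunction of strict sympy relations between the
    fixed point's protein components and the thresholds. ``bin_constraints``
    is the same condition in arrangement form: pairs ``(wall_id, c)``
    requiring the wall value to lie in threshold interval ``c``.
    """

    domain: SwitchingDomain
    inequalities: tuple
    bin_constraints: tuple  # ((wall_id, c), ...)


@dataclass(frozen=True)
class Configuration:
    """A realizable set of simultaneously attracting switching domains."""

    attractors: frozenset
    config_id: int = -1

    @property
    def symmetric_attractors(self) -> frozenset:
        return self.attractors & DIAGONAL_DOMAINS

    @property
    def asymmetric_attractors(self) -> frozenset:
        return self.attractors - DIAGONAL_DOMAINS

    @property
    def bitmask(self) -> int:
        return sum(1 << i for i in self.attractors)

    def is_conjugation_closed(self) -> bool:
        return frozenset(CONJUGATE[i] for i in self.attractors) == self.attractors


@dataclass
class ParameterRegion:
    """A connected component of parameter space with constant configuration."""

    configuration: Configuration
    component_index: int
    n_components_of_configuration: int
    cells: tuple            # bin-assignment tuples of the member cells
    defining_cells: list    # one list of inequality strings per cell
    representative: dict    # interior parameter point (Table-2 names)
    label: str = ""

    def __post_init__(self):
        if not self.label:
            cid = self.configuration.config_id
            if self.n_components_of_configuration > 1:
                self.label = f"{cid}:{self.component_index + 1}"
            else:
                self.label = f"{cid}"


# ---------------------------------------------------------------------------
# symbolic derivation


def _scaled_rhs_symbolic(h11, h21, h12, h22):
    """Rescaled two-cell right-hand side with switch factors substituted."""
    T1 = 1 / (1 + _kappa * h11)
    T2 = 1 / (1 + _kappa * h12)
    G1 = (1 + _gamma * h21) * (1 + _eta * h11) * T1
    G2 = (1 + _gamma * h22) * (1 + _eta * h12) * T2
    return sp.Matrix([
        1 - _mu * _M1 - T1 * _M1 + T2 * _M2,
        1 - _mu * _M2 + T1 * _M1 - T2 * _M2,
        G1 * _M1 - _pi * _P1 + _eps * (_P2 - _P1),
        G2 * _M2 - _pi * _P2 + _eps * (_P1 - _P2),
    ])


def enumerate_domains(order: ThresholdOrder = ThresholdOrder.theta2_lt_theta1,
                      model: str = "main"):
    """The switching domains: nine for the two-cell model, two for the toy."""
    if model == "toy":
        return [SwitchingDomain(index=c, c1=c, c2=c, order=order) for c in (0, 1)]
    return [
        SwitchingDomain(index=3 * c2 + c1, c1=c1, c2=c2, order=order)
        for c2 in range(3) for c1 in range(3)
    ]


def affine_subsystem(domain: SwitchingDomain,
                     order: ThresholdOrder | None = None) -> AffineSubsystem:
    """Substitute the domain's Heaviside values into the rescaled equations."""
    a1, s1, a2, s2 = domain.switch_values()
    rhs = _scaled_rhs_symbolic(a1, s1, a2, s2)
    state = sp.Matrix([_M1, _M2, _P1, _P2])
    A = rhs.jacobian(state)
    c = rhs.subs({_M1: 0, _M2: 0, _P1: 0, _P2: 0})
    return AffineSubsystem(domain=domain, A=sp.simplify(A), c=sp.simplify(c))


def domain_fixed_point(sub: AffineSubsystem) -> DomainFixedPoint:
    """Solve the affine system in closed form: ``f = -A^{-1} c``."""
    f = sub.A.LUsolve(-sub.c)
    f = tuple(sp.cancel(sp.together(expr)) for expr in f)
    return DomainFixedPoint(domain=sub.domain, f=f)


def attractor_condition(domain: SwitchingDomain, fixed_point: DomainFixedPoint,
                        order: ThresholdOrder | None = None,
                        wall_ids: dict | None = None) -> AttractorCondition:
    """Strict inequalities placing the fixed point's protein coordinates
    inside the domain's threshold intervals."""
    ineqs = []
    bins = []
    for comp, c in ((fixed_point.f[2], domain.c1), (fixed_point.f[3], domain.c2)):
        lo, hi = {0: (None, domain.order.low_high[0]),
                  1: domain.order.low_high,
                  2: (domain.order.low_high[1], None)}[c]
        if lo is not None:
            ineqs.append(sp.StrictGreaterThan(comp, lo))
        if hi is not None:
            ineqs.append(sp.StrictLessThan(comp, hi))
        if wall_ids is not None:
            bins.append((wall_ids[sp.srepr(comp)], c))
    return AttractorCondition(domain=domain, inequalities=tuple(ineqs),
                              bin_constraints=tuple(bins))


def _provably_positive(expr) -> bool:
    """True if ``expr`` is provably positive for all positive parameters with
    ``eta > kappa`` (substituting ``eta = kappa + delta``, ``delta > 0``)."""
    e = sp.together(sp.expand(expr.subs(_eta, _kappa + _delta)))
    num, den = sp.fraction(sp.cancel(e))
    def poly_pos(p):
        p = sp.expand(p)
        if p.is_number:
            return p > 0
        gens = sorted(p.free_symbols, key=str)
        if not all(s.is_positive for s in gens):
            return False
        coeffs = sp.Poly(p, *gens).coeffs()
        return all(c.is_number and c > 0 for c in coeffs)
    def poly_neg(p):
        return poly_pos(sp.expand(-p))
    return (poly_pos(num) and poly_pos(den)) or (poly_neg(num) and poly_neg(den))


# ---------------------------------------------------------------------------
# the analysis driver


class SharpSwitchAnalysis:
    """Symbolic derivation plus feasibility machinery for one threshold order.

    Construction is cheap except for the symbolic fixed-point solves and the
    pairwise wall-order proofs (a few seconds).  The expensive enumeration
    lives in :meth:`decompose`.
    """

    def __init__(self, order: ThresholdOrder = ThresholdOrder.theta2_lt_theta1):
        self.order = order
        self.domains = enumerate_domains(order)
        self.subsystems = [affine_subsystem(d) for d in self.domains]
        self.fixed_points = [domain_fixed_point(s) for s in self.subsystems]

        # wall registry: unique protein components of the fixed points
        self.wall_exprs: list = []
        self._wall_ids: dict = {}
        for fp in self.fixed_points:
            for comp in (fp.f[2], fp.f[3]):
                key = sp.srepr(comp)
                if key not in self._wall_ids:
                    # check symbolic identity with an existing wall
                    for wid, w in enumerate(self.wall_exprs):
                        if sp.cancel(w - comp) == 0:
                            self._wall_ids[key] = wid
                            break
                    else:
                        self._wall_ids[key] = len(self.wall_exprs)
                        self.wall_exprs.append(comp)
        self.n_walls = len(self.wall_exprs)

        self.conditions = [
            attractor_condition(d, fp, wall_ids=self._wall_ids)
            for d, fp in zip(self.domains, self.fixed_points)
        ]

        self._wall_fn = sp.lambdify(SYMS, self.wall_exprs, "numpy")
        self._A_fns = [sp.lambdify(SYMS, s.A, "numpy") for s in self.subsystems]
        self._c_fns = [sp.lambdify(SYMS, s.c, "numpy") for s in self.subsystems]

        # provable pairwise wall orderings (partial order used for pruning
        # candidate cells and for symbolic implication arguments)
        self.proven_less: set[tuple[int, int]] = set()
        for i, j in itertools.permutations(range(self.n_walls), 2):
            if _provably_positive(self.wall_exprs[j] - self.wall_exprs[i]):
                self.proven_less.add((i, j))

    # -- numeric helpers ----------------------------------------------------

    def wall_values(self, params6: np.ndarray) -> np.ndarray:
        """Wall values for parameter rows ``(mu, gamma, eta, kappa, pi, eps)``."""
        params6 = np.asarray(params6, float)
        cols = [np.asarray(c, float) for c in params6.T] if params6.ndim == 2 \
            else [np.asarray(v, float) for v in params6]
        vals = self._wall_fn(*cols)
        return np.stack([np.broadcast_to(v, np.shape(cols[0])) for v in vals], axis=-1)

    def attracting_set_symbolic(self, params6, th_lo, th_hi) -> frozenset:
        """Attracting domains via the derived wall/threshold inequalities."""
        w = self.wall_values(np.asarray(params6))
        bins = np.digitize(w, [th_lo, th_hi])
        out = set()
        for cond in self.conditions:
            if all(bins[wid] == c for wid, c in cond.bin_constraints):
                out.add(cond.domain.index)
        return frozenset(out)

    def attracting_set_bruteforce(self, params6, th_lo, th_hi) -> frozenset:
        """Independent route: solve each domain's affine system numerically
        and test interval membership of the protein components."""
        out = set()
        edges = [0.0, th_lo, th_hi, np.inf]
        for dom, Afn, cfn in zip(self.domains, self._A_fns, self._c_fns):
            A = np.asarray(Afn(*params6), float)
            c = np.asarray(cfn(*params6), float).ravel()
            f = np.linalg.solve(A, -c)
            ok1 = edges[dom.c1] < f[2] < edges[dom.c1 + 1]
            ok2 = edges[dom.c2] < f[3] < edges[dom.c2 + 1]
            if ok1 and ok2:
                out.add(dom.index)
        return frozenset(out)

    def configuration_of_cell(self, cell: tuple) -> Configuration:
        S = set()
        for cond in self.conditions:
            if all(cell[wid] == c for wid, c in cond.bin_constraints):
                S.add(cond.domain.index)
        return Configuration(attractors=frozenset(S))

    def _cell_respects_order(self, cell) -> bool:
        return all(cell[i] <= cell[j] for i, j in self.proven_less)

    # -- feasibility: sampling certification --------------------------------

    def _sample_walls(self, n_samples: int, seed: int):
        rng = np.random.default_rng(seed)
        logs = rng.uniform(-9.0, 9.0, size=(n_samples, 6))
        mu, gam, kap, dlt, pi_, eps = np.exp(logs).T
        eta = kap + dlt  # enforces eta > kappa over the whole orthant
        params = np.column_stack([mu, gam, eta, kap, pi_, eps])
        walls = self.wall_values(params)
        return params, walls

    def _certify_by_sampling(self, n_samples: int, seed: int):
        """Enumerate feasible cells and codimension-1 cell boundaries seen in
        a dense parameter sample.  Every hit is a constructive witness."""
        params, walls = self._sample_walls(n_samples, seed)
        logw = np.log(walls)
        order_idx = np.argsort(logw, axis=1, kind="stable")
        sorted_logw = np.take_along_axis(logw, order_idx, axis=1)
        gaps = np.diff(sorted_logw, axis=1)
        min_gap = gaps.min(axis=1)

        patterns, inverse = np.unique(order_idx, axis=0, return_inverse=True)
        best = {}
        for row, (pat_i, g) in enumerate(zip(inverse, min_gap)):
            cur = best.get(pat_i)
            if cur is None or g > cur[1]:
                best[pat_i] = (row, g)

        nw = self.n_walls
        cells: dict[tuple, tuple] = {}     # cell -> witness (params6, th_lo, th_hi, slack)
        edges: dict[frozenset, tuple] = {}  # {cellA, cellB} -> witness
        pad = 2.0  # log-units beyond the extreme walls
        for pat_i, (row, _) in best.items():
            pat = patterns[pat_i]
            lw = logw[row]
            svals = lw[pat]
            pos = np.empty(nw, int)
            pos[pat] = np.arange(nw)
            cuts = np.concatenate(([svals[0] - pad], svals, [svals[-1] + pad]))
            mids = 0.5 * (cuts[:-1] + cuts[1:])          # gap midpoints, log scale
            half = 0.5 * np.diff(cuts)                    # half-gap widths

            def bins_for(i_lo, i_hi):
                return tuple(0 if p < i_lo else (1 if p < i_hi else 2) for p in pos)

            p6 = params[row]
            for i_lo in range(nw + 1):
                if half[i_lo] <= 0:
                    continue
                for i_hi in range(i_lo, nw + 1):
                    if half[i_hi] <= 0:
                        continue
                    cell = bins_for(i_lo, i_hi)
                    x_lo, x_hi = mids[i_lo], mids[i_hi]
                    if i_lo == i_hi:
                        x_lo, x_hi = mids[i_lo] - 0.25 * half[i_lo], mids[i_hi] + 0.25 * half[i_hi]
                    slack = min(half[i_lo], half[i_hi], 0.5 * (x_hi - x_lo) if i_lo == i_hi else np.inf)
                    wit = (p6, float(np.exp(x_lo)), float(np.exp(x_hi)), float(slack))
                    cur = cells.get(cell)
                    if cur is None or slack > cur[3]:
                        cells[cell] = wit
            # boundary placements: one threshold pinned at a wall
            for k in range(nw):
                wall_pos = svals[k]
                # low threshold at wall k, high threshold in gap i_hi > k
                for i_hi in range(k + 1, nw + 1):
                    if half[i_hi] <= 0:
                        continue
                    lo_cells = (bins_for(k, i_hi), bins_for(k + 1, i_hi))
                    slack = min(half[i_hi],
                                0.5 * min(wall_pos - cuts[k], cuts[k + 1] - wall_pos)
                                if 0 < k < nw else pad)
                    wit = (p6, float(np.exp(wall_pos)), float(np.exp(mids[i_hi])), float(slack))
                    key = frozenset(lo_cells)
                    cur = edges.get(key)
                    if cur is None or slack > cur[3]:
                        edges[key] = wit
                # high threshold at wall k, low threshold in gap i_lo <= k
                for i_lo in range(k + 1):
                    if half[i_lo] <= 0:
                        continue
                    hi_cells = (bins_for(i_lo, k), bins_for(i_lo, k + 1))
                    slack = half[i_lo]
                    wit = (p6, float(np.exp(mids[i_lo])), float(np.exp(wall_pos)), float(slack))
                    key = frozenset(hi_cells)
                    cur = edges.get(key)
                    if cur is None or slack > cur[3]:
                        edges[key] = wit
        return cells, edges

    # -- feasibility: slack maximization ------------------------------------

    def _slack_maximize(self, constraints, seed, n_starts=6, bound=10.0):
        """Maximize the minimum log-scale slack of signed inequality
        constraints over (log-parameters, log-thresholds).

        ``constraints(z) -> array`` of quantities required to be positive;
        ``z = (log mu, log gamma, log delta, log kappa, log pi, log eps,
        log th_lo, log th_hi)``.  Returns the best (slack, z).
        """
        rng = np.random.default_rng(seed)
        best = (-np.inf, None)
        for _ in range(n_starts):
            z0 = rng.uniform(-3.0, 3.0, size=8)
            t0 = float(np.min(constraints(z0)))
            x0 = np.concatenate([z0, [min(t0, 0.0)]])
            res = minimize(
                lambda x: -x[-1],
                x0,
                constraints=[{"type": "ineq",
                              "fun": lambda x: constraints(x[:8]) - x[-1]}],
                bounds=[(-bound, bound)] * 8 + [(None, bound)],
                method="SLSQP",
                options={"maxiter": 200, "ftol": 1e-10},
            )
            slack = float(np.min(constraints(res.x[:8])))
            if slack > best[0]:
                best = (slack, res.x[:8].copy())
            if best[0] > 1e-4:
                break
        return best

    def _cell_constraints(self, cell, pinned_wall=None, pinned_thr=None):
        """Constraint function for a cell (optionally with one wall pinned to
        one threshold, for boundary feasibility tests)."""
        wall_fn = self._wall_fn

        def constraints(z):
            mu, gam, dlt, kap, pi_, eps = np.exp(z[:6])
            eta = kap + dlt
            lw = np.log(np.asarray(wall_fn(mu, gam, eta, kap, pi_, eps), float))
            l_lo, l_hi = z[6], z[7]
            if pinned_wall is not None:
                if pinned_thr == 0:
                    l_lo = lw[pinned_wall]
                else:
                    l_hi = lw[pinned_wall]
            out = [l_hi - l_lo]
            for wid in range(self.n_walls):
                if wid == pinned_wall:
                    continue
                b = cell[wid]
                if b == 0:
                    out.append(l_lo - lw[wid])
                elif b == 1:
                    out.append(lw[wid] - l_lo)
                    out.append(l_hi - lw[wid])
                else:
                    out.append(lw[wid] - l_hi)
            return np.asarray(out)

        return constraints

    def _boundary_cells(self, edge_key):
        """The pinned wall/threshold of a candidate boundary between two
        bin-adjacent cells, or None if the cells are not bin-adjacent."""
        a, b = tuple(edge_key)
        diff = [i for i in range(self.n_walls) if a[i] != b[i]]
        if len(diff) != 1:
            return None
        wid = diff[0]
        lo_bin, hi_bin = sorted((a[wid], b[wid]))
        if hi_bin - lo_bin != 1:
            return None
        thr = 0 if (lo_bin, hi_bin) == (0, 1) else 1
        return wid, thr

    # -- the full decomposition ---------------------------------------------

    def decompose(self, n_samples: int = 400_000, seed: int = 0,
                  slack_tol: float = 1e-6) -> "RegionCatalog":
        """Enumerate feasible cells, configurations, connected regions and
        certified cell boundaries.

        Sampling provides constructive feasibility witnesses; candidate cells
        and boundaries not seen in the sample are decided by multi-start
        slack maximization.  Candidates whose best slack lands in
        ``(0, slack_tol]`` are flagged inconclusive.
        """
        cells, edges = self._certify_by_sampling(n_samples, seed)

        inconclusive = []
        # undecided candidate cells
        for cand in itertools.product(range(3), repeat=self.n_walls):
            if cand in cells or not self._cell_respects_order(cand):
                continue
            slack, z = self._slack_maximize(self._cell_constraints(cand),
                                            seed=seed + hash(cand) % 100_000)
            if slack > slack_tol:
                mu, gam, dlt, kap, pi_, eps = np.exp(z[:6])
                cells[cand] = (np.array([mu, gam, kap + dlt, kap, pi_, eps]),
                               float(np.exp(z[6])), float(np.exp(z[7])), slack)
            elif slack > 0:
                inconclusive.append(cand)

        # undecided candidate boundaries between feasible cells
        cell_list = sorted(cells)
        cell_set = set(cell_list)
        for cell in cell_list:
            for wid in range(self.n_walls):
                if cell[wid] == 2:
                    continue
                nb = list(cell)
                nb[wid] += 1
                nb = tuple(nb)
                if nb not in cell_set:
                    continue
                key = frozenset((cell, nb))
                if key in edges:
                    continue
                pin = self._boundary_cells(key)
                wid_, thr = pin
                slack, z = self._slack_maximize(
                    self._cell_constraints(cell, pinned_wall=wid_, pinned_thr=thr),
                    seed=seed + 7 + hash(key) % 100_000, n_starts=4)
                if slack > slack_tol:
                    mu, gam, dlt, kap, pi_, eps = np.exp(z[:6])
                    edges[key] = (np.array([mu, gam, kap + dlt, kap, pi_, eps]),
                                  float(np.exp(z[6])), float(np.exp(z[7])), slack)
                elif slack > 0:
                    inconclusive.append(key)

        # drop edges whose endpoints were never certified as cells
        edges = {k: v for k, v in edges.items() if all(c in cell_set for c in k)}
        return RegionCatalog(self, cells, edges, tuple(inconclusive))


# ---------------------------------------------------------------------------
# catalog


def _components(cells: Sequence[tuple], edges) -> list[list[tuple]]:
    adj = {c: [] for c in cells}
    for key in edges:
        a, b = tuple(key)
        if a in adj and b in adj:
            adj[a].append(b)
            adj[b].append(a)
    seen, comps = set(), []
    for c in sorted(adj):
        if c in seen:
            continue
        stack, comp = [c], []
        seen.add(c)
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(sorted(comp))
    return comps


class RegionCatalog:
    """The result of a sharp-switch decomposition.

    Holds the feasible arrangement cells with witnesses, the realizable
    configurations, the connected parameter regions and the certified
    codimension-1 boundaries between cells.
    """

    def __init__(self, analysis: SharpSwitchAnalysis, cells, edges, inconclusive=()):
        self.analysis = analysis
        self.order = analysis.order
        self.cells = cells
        self.cell_edges = edges
        self.inconclusive = tuple(inconclusive)

        by_config: dict[frozenset, list] = {}
        for cell in sorted(cells):
            S = analysis.configuration_of_cell(cell).attractors
            by_config.setdefault(S, []).append(cell)

        self.configurations = [
            Configuration(attractors=S, config_id=i + 1)
            for i, S in enumerate(sorted(by_config, key=lambda S: sum(1 << b for b in S)))
        ]

        self.regions: list[ParameterRegion] = []
        self._cell_to_region: dict[tuple, ParameterRegion] = {}
        for cfg in self.configurations:
            member_cells = by_config[cfg.attractors]
            same_cfg_edges = {k for k in edges
                              if all(c in member_cells for c in k)}
            comps = _components(member_cells, same_cfg_edges)
            # order components by their representative point for stable labels
            comps.sort(key=lambda comp: comp[0])
            for ci, comp in enumerate(comps):
                wit = max((cells[c] for c in comp), key=lambda w: w[3])
                region = ParameterRegion(
                    configuration=cfg,
                    component_index=ci,
                    n_components_of_configuration=len(comps),
                    cells=tuple(comp),
                    defining_cells=[self._cell_inequality_strings(c) for c in comp],
                    representative=self._witness_to_point(wit),
                )
                self.regions.append(region)
                for c in comp:
                    self._cell_to_region[c] = region

    # -- helpers -------------------------------------------------------------

    def _witness_to_point(self, wit) -> dict:
        params6, th_lo, th_hi, slack = wit
        mu, gam, eta, kap, pi_, eps = map(float, params6)
        if self.order is ThresholdOrder.theta2_lt_theta1:
            th2, th1 = th_lo, th_hi
        else:
            th1, th2 = th_lo, th_hi
        return {"theta1": th1, "theta2": th2, "mu": mu, "gamma": gam,
                "eta": eta, "kappa": kap, "pi": pi_, "epsilon": eps,
                "slack": float(slack)}

    def _cell_inequality_strings(self, cell) -> list[str]:
        lo, hi = self.order.low_high
        out = []
        for wid, b in enumerate(cell):
            w = self.analysis.wall_exprs[wid]
            if b == 0:
                out.append(f"{w} < {lo}")
            elif b == 1:
                out.append(f"{lo} < {w}")
                out.append(f"{w} < {hi}")
            else:
                out.append(f"{hi} < {w}")
        return out

    def membership_predicate(self, label: str) -> Callable[[np.ndarray], np.ndarray]:
        """Vectorized membership test for one region, over parameter rows
        ``(theta1, theta2, mu, gamma, eta, kappa, pi, epsilon)``."""
        by_label = {r.label: r for r in self.regions}
        if label not in by_label:
            raise KeyError(
                f"unknown region {label!r}; available: "
                + ", ".join(sorted(by_label)))
        cells = set(by_label[label].cells)
        analysis = self.analysis
        lo_first = self.order is ThresholdOrder.theta2_lt_theta1

        def predicate(rows: np.ndarray) -> np.ndarray:
            rows = np.atleast_2d(np.asarray(rows, float))
            th_lo = rows[:, 1] if lo_first else rows[:, 0]
            th_hi = rows[:, 0] if lo_first else rows[:, 1]
            walls = analysis.wall_values(rows[:, 2:8])
            bins = (walls > th_lo[:, None]).astype(int) + \
                (walls > th_hi[:, None]).astype(int)
            return np.array([tuple(b) in cells for b in bins])

        return predicate

    def region_of(self, params: dict | Sequence) -> ParameterRegion | None:
        """Catalog region containing a parameter point (None if the point's
        arrangement cell was not certified — should not happen for points
        respecting ``eta > kappa`` off the boundary hypersurfaces)."""
        if isinstance(params, dict):
            p6 = np.array([params[k] for k in ("mu", "gamma", "eta", "kappa", "pi", "epsilon")])
            th1, th2 = params["theta1"], params["theta2"]
        else:
            th1, th2, mu, gam, eta, kap, pi_, eps = params
            p6 = np.array([mu, gam, eta, kap, pi_, eps])
        th_lo, th_hi = (th2, th1) if self.order is ThresholdOrder.theta2_lt_theta1 else (th1, th2)
        w = self.analysis.wall_values(p6)
        cell = tuple(int(b) for b in np.digitize(w, [th_lo, th_hi]))
        return self._cell_to_region.get(cell)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "order": self.order.value,
            "n_configurations": len(self.configurations),
            "n_regions": len(self.regions),
            "inconclusive": [str(x) for x in self.inconclusive],
            "regions": [
                {
                    "label": r.label,
                    "attractors": sorted(r.configuration.attractors),
                    "n_symmetric": len(r.configuration.symmetric_attractors),
                    "n_asymmetric": len(r.configuration.asymmetric_attractors),
                    "component_index": r.component_index,
                    "cells": [list(c) for c in r.cells],
                    "defining_cells": r.defining_cells,
                    "representative": {k: float(v) for k, v in r.representative.items()},
                }
                for r in self.regions
            ],
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = []
        for r in self.regions:
            rows.append({
                "label": r.label,
                "attractors": "|".join(map(str, sorted(r.configuration.attractors))),
                "n_symmetric": len(r.configuration.symmetric_attractors),
                "n_asymmetric": len(r.configuration.asymmetric_attractors),
                "component_index": r.component_index,
                "n_cells": len(r.cells),
                **{f"rep_{k}": v for k, v in r.representative.items()},
            })
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# toy model decomposition


class ToyAnalysis:
    """Sharp-switch decomposition of the one-dimensional autocatalytic model.

    The two switching domains ``X < theta`` and ``X > theta`` have fixed
    points ``b/gamma`` and ``(b+1)/gamma``; the attractor conditions
    ``b/gamma < theta`` and ``(b+1)/gamma > theta`` carve parameter space
    into the three regions D1 (high state only), D2 (bistable) and
    D3 (low state only).
    """

    b, theta, gamma = sp.symbols("b theta gamma", positive=True)

    def __init__(self):
        self.f0 = self.b / self.gamma
        self.f1 = (self.b + 1) / self.gamma
        # condition for each domain to attract
        self.cond_low = sp.StrictLessThan(self.f0, self.theta)
        self.cond_high = sp.StrictGreaterThan(self.f1, self.theta)

    def region_definitions(self):
        b, th, g = self.b, self.theta, self.gamma
        return {
            "D1": [sp.StrictGreaterThan(b, g * th)],
            "D2": [sp.StrictLessThan(b, g * th), sp.StrictLessThan(g * th, b + 1)],
            "D3": [sp.StrictLessThan(b + 1, g * th)],
        }

    def region_of(self, b: float, theta: float, gamma: float) -> str:
        if b > gamma * theta:
            return "D1"
        if b + 1 < gamma * theta:
            return "D3"
        return "D2"

    def heaviside_state_pattern(self, region: str) -> tuple[int, int]:
        """Number of (low, high) stable states predicted in the sharp limit."""
        return {"D1": (0, 1), "D2": (1, 1), "D3": (1, 0)}[region]

    def adjacency(self):
        return [("D1", "D2"), ("D2", "D3")]


# ---------------------------------------------------------------------------
# symbolic equivalence of inequality systems


def inequality_equivalent(rel_a, rel_b) -> bool:
    """Are two strict inequalities equivalent over positive parameters with
    ``eta > kappa``?  Both are normalized to ``lts < gts``; equivalence holds
    when the ratio of the two differences is provably positive."""
    da = sp.together(rel_a.gts - rel_a.lts)
    db = sp.together(rel_b.gts - rel_b.lts)
    return _provably_positive(sp.cancel(da / db))


def _transitive_closure(pairs, nodes):
    reach = {u: set() for u in nodes}
    for u, v in pairs:
        reach[u].add(v)
    changed = True
    while changed:
        changed = False
        for u in nodes:
            new = set()
            for v in reach[u]:
                new |= reach[v]
            if not new <= reach[u]:
                reach[u] |= new
                changed = True
    return reach


def verify_region16_equivalence(catalog: "RegionCatalog") -> dict:
    """Prove that the catalog regions covered by the benchmark chain are,
    as a union, exactly the chain's solution set.

    The argument is order-theoretic over the atoms "wall < threshold" /
    "wall < wall": using the symbolically proven pairwise wall orderings,
    (i) every chain inequality is implied by each covered cell, (ii) every
    cell inequality not referring to the free wall is implied by the chain,
    and (iii) the feasible positions of the free wall relative to the
    thresholds exactly exhaust the cells of the covered regions.  Returns a
    dict of booleans (all must be True) plus the covered region labels.
    """
    an = catalog.analysis
    if an.order is not ThresholdOrder.theta2_lt_theta1:
        raise ValueError("the benchmark chain is stated for theta2 < theta1")
    wid = an._wall_ids
    fp = {d.index: f for d, f in zip(an.domains, an.fixed_points)}
    LO, HI = "LO", "HI"
    nodes = list(range(an.n_walls)) + [LO, HI]
    K = set(an.proven_less) | {(LO, HI)}

    def wall_of(expr):
        return wid[sp.srepr(expr)]

    v0, v8 = wall_of(fp[0].f[2]), wall_of(fp[8].f[2])
    Ch, Cl = wall_of(fp[2].f[2]), wall_of(fp[2].f[3])
    chain = {(Cl, LO), (LO, v0), (v0, v8), (v8, HI), (HI, Ch)}

    def cell_facts(cell):
        facts = {(LO, HI)}
        for w, b in enumerate(cell):
            if b == 0:
                facts.add((w, LO))
            elif b == 1:
                facts.add((LO, w))
                facts.add((w, HI))
            else:
                facts.add((HI, w))
        return facts

    def consistent(facts):
        reach = _transitive_closure(facts, nodes)
        return not any(u in reach[u] for u in nodes)

    # regions covered by the chain: all of whose cells are consistent with it
    covered = [r for r in catalog.regions
               if all(consistent(chain | K | cell_facts(c)) for c in r.cells)]
    covered_cells = [c for r in covered for c in r.cells]

    # the free walls: bins that differ between covered cells
    free = {w for w in range(an.n_walls)
            if len({c[w] for c in covered_cells}) > 1}

    chain_reach = _transitive_closure(chain | K, nodes)
    results = {
        "covered_regions": [r.label for r in covered],
        # (i) each covered cell implies every chain inequality
        "cells_imply_chain": all(
            v in _transitive_closure(cell_facts(c) | K, nodes)[u]
            for c in covered_cells for (u, v) in chain),
        # (ii) the chain implies every non-free cell inequality
        "chain_implies_cells": all(
            v in chain_reach[u]
            for c in covered_cells for (u, v) in cell_facts(c)
            if u not in free and v not in free),
        # (iii) the free-wall positions consistent with the chain are exactly
        # the ones realized by the covered cells
        "free_positions_exhausted": True,
    }
    for w in free:
        feasible_bins = {b for b in range(3)
                         if consistent(chain | K | cell_facts(
                             tuple(b if i == w else covered_cells[0][i]
                                   for i in range(an.n_walls))))}
        realized = {c[w] for c in covered_cells}
        if feasible_bins != realized:
            results["free_positions_exhausted"] = False
    return results


# ---------------------------------------------------------------------------
# module-level convenience wrappers (cache the heavy decomposition per order)

_ANALYSIS_CACHE: dict = {}
_CATALOG_CACHE: dict = {}


def get_analysis(order: ThresholdOrder = ThresholdOrder.theta2_lt_theta1) -> "SharpSwitchAnalysis":
    """Cached symbolic analysis for one threshold ordering."""
    if order not in _ANALYSIS_CACHE:
        _ANALYSIS_CACHE[order] = SharpSwitchAnalysis(order)
    return _ANALYSIS_CACHE[order]


def decompose_regions(order: ThresholdOrder = ThresholdOrder.theta2_lt_theta1,
                      model: str = "main", n_samples: int = 400_000,
                      seed: int = 0, use_cache: bool = True):
    """Full decomposition; returns a :class:`RegionCatalog` (main model) or
    the three labeled toy regions (toy model)."""
    if model == "toy":
        toy = ToyAnalysis()
        return toy.region_definitions()
    key = (order, n_samples, seed)
    if use_cache and key in _CATALOG_CACHE:
        return _CATALOG_CACHE[key]
    catalog = get_analysis(order).decompose(n_samples=n_samples, seed=seed)
    if use_cache:
        _CATALOG_CACHE[key] = catalog
    return catalog


def enumerate_configurations(order: ThresholdOrder = ThresholdOrder.theta2_lt_theta1,
                             model: str = "main", **kwargs):
    """Realizable steady-state configurations (the toy model has three)."""
    if model == "toy":
        return [frozenset({"low"}), frozenset({"low", "high"}), frozenset({"high"})]
    return decompose_regions(order, **kwargs).configurations


# ---------------------------------------------------------------------------
# the bistable-and-beyond benchmark region of the Results section


def region16_chain(analysis: SharpSwitchAnalysis | None = None):
    """The inequality chain defining the benchmark region dense in
    symmetry breaking (stated for the theta2 < theta1 ordering).

    Expressed through the derived wall values: ``Cl < theta2 < v0`` and
    ``v0 < v8 < theta1 < Ch`` where ``v0``/``v8`` are the symmetric fixed
    points of the all-off/all-on domains and ``Ch``/``Cl`` the protein
    coordinates of the high/low cell of the mixed domain with one cell
    above ``theta1`` and the other below ``theta2``.
    """
    if analysis is None:
        analysis = get_analysis(ThresholdOrder.theta2_lt_theta1)
    fp = {d.index: f for d, f in
          zip(analysis.domains, analysis.fixed_points)}
    v0 = fp[0].f[2]
    v8 = fp[8].f[2]
    Ch = fp[2].f[2]   # domain 2: P1 high, P2 low
    Cl = fp[2].f[3]
    return [
        sp.StrictLessThan(Cl, _th2),
        sp.StrictLessThan(_th2, v0),
        sp.StrictLessThan(v0, v8),
        sp.StrictLessThan(v8, _th1),
        sp.StrictLessThan(_th1, Ch),
    ]


def region16_predicate() -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized membership test for the benchmark region chain.

    Accepts arrays of parameter rows ``(theta1, theta2, mu, gamma, eta,
    kappa, pi, epsilon)`` and returns a boolean array.
    """
    analysis = get_analysis(ThresholdOrder.theta2_lt_theta1)
    chain = region16_chain(analysis)
    syms = (_th1, _th2) + SYMS
    fns = [(sp.lambdify(syms, r.lts, "numpy"), sp.lambdify(syms, r.gts, "numpy"))
           for r in chain]

    def predicate(params: np.ndarray) -> np.ndarray:
        params = np.atleast_2d(np.asarray(params, float))
        cols = [params[:, i] for i in (0, 1, 2, 3, 4, 5, 6, 7)]
        ok = np.ones(len(params), dtype=bool)
        for flt, fgt in fns:
            lo = np.broadcast_to(np.asarray(flt(*cols), float), (len(params),))
            hi = np.broadcast_to(np.asarray(fgt(*cols), float), (len(params),))
            ok &= lo < hi
        return ok

    return predicate
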