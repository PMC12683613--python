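"""Consumer-resource competition with density-dependent excess mortality.

Two (or more) consumer species compete for a single shared resource in a
chemostat-style community:

    dR/dt   = D (S_supply − R) − Σ_i c_i f_i(R) N_i
    dN_i/dt = N_i [ g_i f_i(R) − m_i − δ_i N_i^θ_i ]

with Monod uptake ``f_i(R) = R / (K_i + R)`` (or linear ``f_i(R) = R``).
With all δ = 0 this is classical R* theory: the species able to grow at the
lowest resource level, ``R*_i = m_i K_i / (g_i − m_i)`` (Monod), excludes
all others.  Giving the dominant (lower-R*) species a conspecific
density-dependent excess mortality δ_1 N_1^θ — interference competition such
as territorial fighting between neighbouring colonies — caps its equilibrium
density, leaves resource standing for the subordinate, and above a critical
δ produces a feasible, locally stable interior equilibrium: exploitative
dominance plus intraspecific interference yields stable coexistence.

For θ = 1 and δ only on species 1 the interior equilibrium is closed-form:

    R̂   = R*_2
    N̂_1 = (g_1 f_1(R̂) − m_1) / δ_1
    N̂_2 = [D (S_supply − R̂) − c_1 f_1(R̂) N̂_1] / (c_2 f_2(R̂))

feasible iff both densities are positive, which happens exactly when

    δ_1 > δ_crit = c_1 f_1(R*_2) (g_1 f_1(R*_2) − m_1) / (D (S_supply − R*_2)).

Time is in weeks (the field experiment's census interval); the unit is
purely conventional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "ConsumerResourceSystem",
    "CommunityState",
    "OutcomeClassification",
    "NonviableSpeciesError",
    "per_capita_growth",
    "rstar",
    "simulate",
    "interior_equilibrium",
    "delta_crit_closed_form",
    "coexistence_threshold",
    "classify_outcome",
]

#: Default integrator tolerances and classification thresholds.
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10
EXTINCTION_FRACTION = 1e-6     # x initial density
STABILITY_TOL = 1e-8           # on eigenvalue real parts


class NonviableSpeciesError(ValueError):
    """Species cannot grow even at saturating resource (g <= m)."""


@dataclass(frozen=True)
class Species:
    """One consumer's parameters (rates per week).

    g: maximal resource-conversion growth rate; K: half-saturation constant
    (resource units; ignored in linear uptake mode); c: per-capita
    consumption scale; m: baseline mortality; delta: excess-mortality
    strength per consumer; theta: excess-mortality exponent (>= 1).
    """

    g: float
    K: float
    c: float
    m: float
    delta: float = 0.0
    theta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g", "K", "c", "m", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.theta < 1:
            raise ValueError(f"theta must be >= 1, got {self.theta}")


@dataclass(frozen=True)
class ConsumerResourceSystem:
    """Chemostat community: resource turnover D, supply S_supply, consumers."""

    D: float
    S_supply: float
    species: tuple[Species, ...]
    uptake: str = "monod"  # "monod" | "linear"

    def __post_init__(self) -> None:
        if self.D < 0 or self.S_supply < 0:
            raise ValueError("D and S_supply must be >= 0")
        if self.uptake not in ("monod", "linear"):
            raise ValueError(f"unknown uptake mode {self.uptake!r}")

    def f(self, i: int, R: float | np.ndarray) -> float | np.ndarray:
        sp = self.species[i]
        if self.uptake == "monod":
            return R / (sp.K + R)
        return R


@dataclass
class CommunityState:
    """Resource level, consumer density vector, and time (weeks)."""

    R: float
    N: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.N = np.asarray(self.N, dtype=float)
        if self.R < 0 or np.any(self.N < 0):
            raise ValueError("resource and densities must be >= 0")


@dataclass
class OutcomeClassification:
    """Classified long-run outcome of a simulated community."""

    label: Optional[str]          # "exclusion" | "stable_coexistence" | "collapse"
    winner: Optional[int]         # surviving species index for exclusion
    equilibrium: CommunityState
    eigenvalues: np.ndarray
    residual: float
    reason: str = ""
    delta_crit: Optional[float] = None


def per_capita_growth(i: int, R: float, N_i: float,
                      system: ConsumerResourceSystem) -> float:
    """Per-capita growth of species i: g f(R) − m − δ N_i^θ."""
    sp = system.species[i]
    return sp.g * system.f(i, R) - sp.m - sp.delta * N_i ** sp.theta


def rstar(i: int, system: ConsumerResourceSystem) -> float:
    """Minimum resource requirement R*_i (at which growth is zero, δ aside).

    Monod: ``m K / (g − m)``; linear uptake: ``m / g``.  Raises
    :class:`NonviableSpeciesError` when the species cannot grow at any
    resource level (g <= m in Monod mode).
    """
    sp = system.species[i]
    if system.uptake == "monod":
        if sp.g <= sp.m:
            raise NonviableSpeciesError(
                f"species {i}: g={sp.g} <= m={sp.m}, nonviable at saturating R")
        return sp.m * sp.K / (sp.g - sp.m)
    if sp.g == 0:
        raise NonviableSpeciesError(f"species {i}: g=0 with linear uptake")
    return sp.m / sp.g


def _rhs(t: float, y: np.ndarray, system: ConsumerResourceSystem) -> np.ndarray:
    R = max(y[0], 0.0)
    N = np.maximum(y[1:], 0.0)
    dR = system.D * (system.S_supply - R)
    dN = np.empty_like(N)
    for i, sp in enumerate(system.species):
        fi = system.f(i, R)
        dR -= sp.c * fi * N[i]
        dN[i] = N[i] * (sp.g * fi - sp.m - sp.delta * N[i] ** sp.theta)
    return np.concatenate([[dR], dN])


def simulate(system: ConsumerResourceSystem, initial: CommunityState,
             t_end: float, rtol: float = DEFAULT_RTOL,
             atol: float = DEFAULT_ATOL, events=None,
             dense: bool = False):
    """Integrate the community ODE from *initial* to ``t_end``.

    Uses a stiff-capable adaptive integrator (LSODA).  Densities more
    negative than the absolute tolerance are a solver error; smaller
    excursions are clipped to zero in the returned trajectory.
    """
    y0 = np.concatenate([[initial.R], initial.N])
    sol = solve_ivp(_rhs, (initial.t, initial.t + t_end), y0, args=(system,),
                    method="LSODA", rtol=rtol, atol=atol, events=events,
                    dense_output=dense)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t={sol.t[-1]:.4g}: "
                           f"{sol.message}")
    if np.min(sol.y) < -100 * atol:
        raise RuntimeError(
            f"negative density beyond tolerance ({np.min(sol.y):.3g}) at "
            f"t={sol.t[np.argmin(np.min(sol.y, axis=0))]:.4g}")
    sol.y = np.clip(sol.y, 0.0, None)
    return sol


def interior_equilibrium(system: ConsumerResourceSystem
                         ) -> tuple[CommunityState, bool]:
    """Closed-form interior equilibrium for (δ_1 > 0, δ_2 = 0, θ_1 = 1).

    Returns the candidate state and a feasibility flag (both densities
    strictly positive).  General θ_1 > 1 is solved numerically for N̂_1 from
    ``g_1 f_1(R*_2) − m_1 = δ_1 N̂_1^θ``.
    """
    if len(system.species) != 2:
        raise ValueError("interior equilibrium is defined for two species")
    s1, s2 = system.species
    if s1.delta <= 0 or s2.delta != 0:
        raise ValueError("need delta_1 > 0 and delta_2 = 0")
    Rhat = rstar(1, system)
    f1 = system.f(0, Rhat)
    surplus = s1.g * f1 - s1.m
    if surplus <= 0:
        return CommunityState(Rhat, np.array([0.0, 0.0])), False
    N1 = (surplus / s1.delta) ** (1.0 / s1.theta)
    f2 = system.f(1, Rhat)
    denom = s2.c * f2
    N2 = (system.D * (system.S_supply - Rhat) - s1.c * f1 * N1) / denom
    feasible = N1 > 0 and N2 > 0
    return CommunityState(Rhat, np.array([N1, max(N2, 0.0) if not feasible else N2])), feasible


def delta_crit_closed_form(system: ConsumerResourceSystem) -> float:
    """Feasibility boundary for δ_1 at θ_1 = 1.

    ``δ_crit = c_1 f_1(R*_2) (g_1 f_1(R*_2) − m_1) / (D (S_supply − R*_2))``:
    the N̂_2 > 0 condition of the interior equilibrium rearranged for δ_1.
    """
    s1, _ = system.species
    Rhat = rstar(1, system)
    if Rhat >= system.S_supply:
        raise ValueError("subordinate species cannot persist: R*_2 >= S_supply")
    f1 = system.f(0, Rhat)
    surplus = s1.g * f1 - s1.m
    if surplus <= 0:
        raise ValueError("species 1 cannot grow at R*_2; no threshold exists")
    return s1.c * f1 * surplus / (system.D * (system.S_supply - Rhat))


def jacobian(system: ConsumerResourceSystem, state: CommunityState,
             eps: float = 1e-7) -> np.ndarray:
    """Central-difference Jacobian of the RHS at *state*."""
    y = np.concatenate([[state.R], state.N])
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = eps * max(1.0, abs(y[j]))
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (_rhs(0.0, yp, system) - _rhs(0.0, ym, system)) / (2 * h)
    return J


def coexistence_threshold(system: ConsumerResourceSystem,
                          delta_max: float = 10.0,
                          tol: float = 1e-10) -> float:
    """Smallest δ_1 giving a feasible *and* locally stable interior equilibrium.

    Sweeps δ_1 upward by bisection against the joint
    feasible-and-stable predicate.  For θ = 1 the feasibility boundary is the
    closed form of :func:`delta_crit_closed_form`; stability is checked by
    the numerical Jacobian at each candidate.
    """
    s1 = system.species[0]

    def ok(delta: float) -> bool:
        sys_d = ConsumerResourceSystem(
            system.D, system.S_supply,
            (Species(s1.g, s1.K, s1.c, s1.m, delta, s1.theta),
             system.species[1]),
            system.uptake)
        eq, feasible = interior_equilibrium(sys_d)
        if not feasible:
            return False
        eig = np.linalg.eigvals(jacobian(sys_d, eq))
        return bool(np.max(eig.real) < -STABILITY_TOL)

    if not ok(delta_max):
        raise ValueError(f"no stable interior equilibrium up to "
                         f"delta_1 = {delta_max}")
    lo, hi = 0.0, delta_max
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def classify_outcome(system: ConsumerResourceSystem, initial: CommunityState,
                     t_end: float = 2000.0,
                     residual_tol: float = 1e-6) -> OutcomeClassification:
    """Integrate to ``t_end`` and classify the endpoint.

    Applies the extinction threshold (``1e-6`` x initial density), checks the
    equilibrium residual of the surviving subsystem and the eigenvalues of
    the numerical Jacobian.  The label is withheld (``None``) when the
    trajectory has not settled (residual above tolerance) or when the
    equilibrium is non-hyperbolic (an eigenvalue's real part within the
    stability tolerance of zero — e.g. the neutral line of two identical
    species).
    """
    sol = simulate(system, initial, t_end)
    yT = sol.y[:, -1]
    thresh = EXTINCTION_FRACTION * np.maximum(initial.N, 1e-300)
    alive = yT[1:] > thresh
    N_end = np.where(alive, yT[1:], 0.0)
    state = CommunityState(yT[0], N_end, t=sol.t[-1])

    resid = float(np.max(np.abs(_rhs(0.0, np.concatenate([[state.R], state.N]),
                                     system))))
    eig = np.linalg.eigvals(jacobian(system, state))
    # eigenvalue directions along extinct species are growth rates into the
    # boundary; for a boundary equilibrium they are part of stability proper
    if resid > residual_tol:
        return OutcomeClassification(None, None, state, eig, resid,
                                     reason="trajectory not settled "
                                            f"(residual {resid:.3g})")
    if np.min(np.abs(eig.real)) < STABILITY_TOL:
        return OutcomeClassification(None, None, state, eig, resid,
                                     reason="non-hyperbolic equilibrium "
                                            "(eigenvalue real part ~ 0)")
    stable = bool(np.max(eig.real) < -STABILITY_TOL)
    n_alive = int(alive.sum())
    if n_alive == 0:
        label, winner = "collapse", None
    elif n_alive == 1:
        label, winner = "exclusion", int(np.argmax(alive))
    elif n_alive == len(system.species):
        label = "stable_coexistence" if stable else None
        winner = None
        if label is None:
            return OutcomeClassification(None, None, state, eig, resid,
                                         reason="interior endpoint unstable")
    else:
        # several survivors but not all (only possible with > 2 species)
        label, winner = "exclusion", None
    return OutcomeClassification(label, winner, state, eig, resid)
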