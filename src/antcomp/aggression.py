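"""Inclusive-fitness model of distance-dependent territorial aggression.

A worker encounters a conspecific alien at distance ``d`` from its own nest.
If unopposed, the alien goes on to steal brood or usurp the nest with
probability ``p(d)`` — highest at the nest entrance and decaying with
distance, since an alien met far away is unlikely to be targeting this
colony.  Fighting repels the alien with probability ``q`` but kills the
focal worker with probability ``mu``.  In inclusive-fitness currency the
worker weighs the expected theft loss it can prevent, ``p(d) * q * r_b * V``
(resources valued at ``V`` and devalued by its relatedness ``r_b`` to the
brood), against the expected cost of its own death, ``mu * v_w`` (its
residual value as a worker).  Because ``p(d)`` is monotone decreasing, the
optimal behaviour is a step function of distance: fight for every encounter
closer than a threshold ``d*``, avoid beyond it.  With exponential decay
``p(d) = p0 * exp(-lam * d)`` the threshold is closed-form:

    d* = (1/lam) * ln( p0 * q * r_b * V / (mu * v_w) )

clamped to [0, inf).  Heterospecific encounters are modelled by zeroing the
stealable resource value (other species cannot exploit this ant's brood or
nest as social resources), which makes avoidance optimal at every distance —
aggression is reserved for conspecific aliens near the nest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "AggressionScenario",
    "AggressionDecision",
    "theft_probability",
    "net_fight_gain",
    "decide",
    "threshold_distance",
    "heterospecific_variant",
]


@dataclass(frozen=True)
class AggressionScenario:
    """Parameters of one encounter context.

    p0: theft/usurpation probability if the alien is met at the nest (d=0);
    lam: spatial decay of that probability (per m); V: value of the defended
    resources (brood + nest) in colony-productivity units; r_b: the worker's
    relatedness to the defended brood; mu: probability the focal worker dies
    if it fights; q: probability a fight repels the alien; v_w: residual
    inclusive-fitness value of the worker itself; p_form: "exponential"
    (default) or "logistic" decay of p(d); d_half: midpoint (m) of the
    logistic form.
    """

    p0: float
    lam: float
    V: float
    r_b: float
    mu: float
    q: float
    v_w: float
    p_form: str = "exponential"
    d_half: float = 2.0

    def __post_init__(self) -> None:
        for name, lo, hi in (("p0", 0.0, 1.0), ("r_b", 0.0, 1.0),
                             ("mu", 0.0, 1.0)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must be in [{lo}, {hi}], got {v}")
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"q must be in (0, 1], got {self.q}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.V < 0 or self.v_w < 0:
            raise ValueError("V and v_w must be >= 0")
        if self.p_form not in ("exponential", "logistic"):
            raise ValueError(f"unknown p_form {self.p_form!r}")


@dataclass(frozen=True)
class AggressionDecision:
    fight: bool
    net_gain: float
    d_star: float  # 0 if never fight, math.inf if always fight


def theft_probability(d: float, scenario: AggressionScenario) -> float:
    """Probability the alien, if unopposed, steals/usurps when met at d."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    if scenario.p_form == "exponential":
        return scenario.p0 * math.exp(-scenario.lam * d)
    # logistic decay, normalised so p(0) = p0
    s = scenario
    return s.p0 * expit(s.lam * (s.d_half - d)) / expit(s.lam * s.d_half)


def net_fight_gain(d: float, scenario: AggressionScenario) -> float:
    """Inclusive-fitness difference, fight minus avoid.

    Prevented expected resource loss ``p(d) q r_b V`` minus expected cost of
    the worker's own death ``mu v_w``.
    """
    s = scenario
    return theft_probability(d, s) * s.q * s.r_b * s.V - s.mu * s.v_w


def threshold_distance(scenario: AggressionScenario) -> float:
    """Distance below which fighting pays: the root of the net gain.

    Exponential form, closed-form ``(1/lam) ln(p0 q r_b V / (mu v_w))``
    clamped to [0, inf); logistic form solved by bisection.  With ``lam = 0``
    the gain is distance-independent: 0 or inf by its sign (ties avoid).
    """
    s = scenario
    gain0 = net_fight_gain(0.0, s)
    if gain0 <= 0:
        return 0.0
    if s.lam == 0 or (s.p_form == "exponential" and s.mu * s.v_w == 0):
        return math.inf
    if s.p_form == "exponential":
        return math.log(s.p0 * s.q * s.r_b * s.V / (s.mu * s.v_w)) / s.lam
    # logistic: gain at large d tends to ~0 - mu*v_w < 0 when mu*v_w > 0
    if s.mu * s.v_w == 0:
        return math.inf
    hi = s.d_half + 1.0
    while net_fight_gain(hi, s) > 0:
        hi *= 2.0
        if hi > 1e9:
            return math.inf
    return brentq(lambda d: net_fight_gain(d, s), 0.0, hi, xtol=1e-12)


def decide(d: float, scenario: AggressionScenario) -> AggressionDecision:
    """Fight iff the net inclusive-fitness gain is strictly positive.

    Ties (net gain exactly zero) resolve to avoid; the decision is a step in
    distance — fight on [0, d*), avoid on [d*, inf).
    """
    gain = net_fight_gain(d, scenario)
    return AggressionDecision(fight=gain > 0, net_gain=gain,
                              d_star=threshold_distance(scenario))


def heterospecific_variant(scenario: AggressionScenario) -> AggressionScenario:
    """The same encounter against a heterospecific: no stealable social
    resources (V -> 0), so avoidance is optimal at every distance."""
    return AggressionScenario(scenario.p0, scenario.lam, 0.0, scenario.r_b,
                              scenario.mu, scenario.q, scenario.v_w,
                              scenario.p_form, scenario.d_half)
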