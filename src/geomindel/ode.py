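"""Finite-time transition probabilities of the 3-state alignment machine.

The approximation: a 3-state pair HMM F(t) with transition matrix

        M    I    D
    M [ a    b    c ]
    I [ f    g    h ]
    D [ p    q    r ]

evolves so that composing F(t) with the infinitesimal indel machine G(dt)
stays (approximately) within the 3-state family: F(t)·G(dt) ≈ F(t+dt).
Matching expected class-transition counts between the 9-state product and
the 3-state machine, and taking dt → 0, yields a closed, self-consistent
ODE system for the four primary expected counts

    d/dt T_MM = μ b f (1−y) / (1−g y) − (λ+μ) a
    d/dt T_MI = −μ b (1−g) / (1−g y) + λ (1−b)
    d/dt T_IM = λ a − μ f (1−g) (b(1−r) + c q) / ((1−g y)(f(1−r) + h p))
    d/dt T_DI = μ (1−g) (b(1−r−hq) + c g q) / ((1−g y)(f(1−r) + h p))

with boundary T_MM(0)=1 and all other counts 0. The remaining counts follow
from linear occupancy identities, the insert/delete occupancies have the
closed forms S_I = exp(λt/(1−x)) − 1, S_D = exp(μt/(1−y)) − 1, and the
transition probabilities are count ratios (a = T_MM, f = T_IM / S_I, ...).

Restricting to single-residue indels (x = y = 0) the system is solved
exactly by the classical TKF91 birth-death closed form, implemented in
:func:`tkf91_probs`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .machines import StateMachine
from .model import GGIParams

__all__ = [
    "TransitionCounts",
    "TransitionProbs",
    "occupancy_closed_form",
    "boundary_probs",
    "counts_to_probs",
    "derived_counts",
    "count_derivatives",
    "solve_transition_probs",
    "tkf91_probs",
    "finite_machine",
]

#: occupancy below which the 0/0 count ratios fall back to their t=0 limits
OCCUPANCY_EPS = 1e-12


@dataclass(frozen=True)
class TransitionProbs:
    """Transition probabilities a...r of the 3-state machine at time t."""

    t: float
    a: float
    b: float
    c: float
    f: float
    g: float
    h: float
    p: float
    q: float
    r: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.a, self.b, self.c], [self.f, self.g, self.h], [self.p, self.q, self.r]]
        )

    def validate(self, tol: float = 1e-7) -> None:
        m = self.matrix
        if np.any(m < -tol) or np.any(m > 1 + tol):
            raise ValueError(f"transition probabilities outside [0,1]: {m}")
        rows = m.sum(axis=1)
        if np.any(np.abs(rows - 1) > tol):
            raise ValueError(f"rows of transition matrix do not sum to 1: {rows}")

    def machine(self) -> StateMachine:
        from .machines import three_state_machine

        return three_state_machine(np.clip(self.matrix, 0.0, 1.0))


@dataclass(frozen=True)
class TransitionCounts:
    """Expected class-transition counts and occupancies at time t."""

    t: float
    T_MM: float
    T_MI: float
    T_MD: float
    T_IM: float
    T_II: float
    T_ID: float
    T_DM: float
    T_DI: float
    T_DD: float
    S_I: float
    S_D: float


def occupancy_closed_form(p: GGIParams, t: float) -> tuple[float, float]:
    """Expected inserted/deleted residues per inter-match interval.

    S_I(t) = exp(λt/(1−x)) − 1 and S_D(t) = exp(μt/(1−y)) − 1; to first
    order in t these are (initiation rate) × (mean geometric event length).
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    return (math.expm1(p.lam * t / (1.0 - p.x)), math.expm1(p.mu * t / (1.0 - p.y)))


def boundary_probs(p: GGIParams, t: float = 0.0) -> TransitionProbs:
    """The t = 0 limit: a = 1, f = 1−x, g = x, p = 1−y, r = y, rest 0."""
    return TransitionProbs(
        t=t, a=1.0, b=0.0, c=0.0, f=1.0 - p.x, g=p.x, h=0.0, p=1.0 - p.y, q=0.0, r=p.y
    )


def derived_counts(
    t: float,
    T_MM: float,
    T_MI: float,
    T_IM: float,
    T_DI: float,
    S_I: float,
    S_D: float,
    tol: float = 1e-8,
) -> TransitionCounts:
    """Complete the count vector from the four primary counts and the
    occupancies, using the linear occupancy identities.

    Raises a consistency error if any derived count falls below −tol.
    """
    T_MD = 1.0 - T_MM - T_MI
    T_II = S_I - T_MI - T_DI
    T_ID = T_MI + T_DI - T_IM
    T_DM = 1.0 - T_MM - T_IM
    T_DD = S_D + T_MM + T_IM - T_DI - 1.0
    counts = TransitionCounts(
        t=t, T_MM=T_MM, T_MI=T_MI, T_MD=T_MD, T_IM=T_IM, T_II=T_II,
        T_ID=T_ID, T_DM=T_DM, T_DI=T_DI, T_DD=T_DD, S_I=S_I, S_D=S_D,
    )
    for name in ("T_MD", "T_II", "T_ID", "T_DM", "T_DD"):
        v = getattr(counts, name)
        if v < -tol:
            raise ValueError(
                f"derived count {name} = {v:.3g} < 0: inconsistent primary counts"
            )
    return counts


def counts_to_probs(c: TransitionCounts, p: GGIParams) -> TransitionProbs:
    """Count ratios a = T_MM, b = T_MI, c = T_MD, f = T_IM/S_I, ...

    When an occupancy is below :data:`OCCUPANCY_EPS` the 0/0 ratios are
    replaced by their t = 0 limits (f, g, h) = (1−x, x, 0) and
    (p, q, r) = (1−y, 0, y).
    """
    a, b, cc = c.T_MM, c.T_MI, c.T_MD
    if c.S_I < OCCUPANCY_EPS:
        f, g, h = 1.0 - p.x, p.x, 0.0
    else:
        f, g, h = c.T_IM / c.S_I, c.T_II / c.S_I, c.T_ID / c.S_I
    if c.S_D < OCCUPANCY_EPS:
        pp, q, r = 1.0 - p.y, 0.0, p.y
    else:
        pp, q, r = c.T_DM / c.S_D, c.T_DI / c.S_D, c.T_DD / c.S_D
    vals = [a, b, cc, f, g, h, pp, q, r]
    # integration round-off can leave counts a hair below zero
    vals = [0.0 if -1e-9 < v < 0.0 else v for v in vals]
    return TransitionProbs(c.t, *vals)


def count_derivatives(probs: TransitionProbs, p: GGIParams) -> np.ndarray:
    """Time derivatives of the four primary counts (T_MM, T_MI, T_IM, T_DI)
    at the given transition probabilities."""
    a, b, c = probs.a, probs.b, probs.c
    f, g, h = probs.f, probs.g, probs.h
    pp, q, r = probs.p, probs.q, probs.r
    lam, mu, y = p.lam, p.mu, p.y
    gy = 1.0 - g * y
    denom = gy * (f * (1.0 - r) + h * pp)
    d_MM = mu * b * f * (1.0 - y) / gy - (lam + mu) * a
    d_MI = -mu * b * (1.0 - g) / gy + lam * (1.0 - b)
    d_IM = lam * a - mu * f * (1.0 - g) * (b * (1.0 - r) + c * q) / denom
    d_DI = mu * (1.0 - g) * (b * (1.0 - r - h * q) + c * g * q) / denom
    return np.array([d_MM, d_MI, d_IM, d_DI])


def _ode_rhs(t: float, u: np.ndarray, p: GGIParams) -> np.ndarray:
    T_MM, T_MI, T_IM, T_DI = u
    S_I, S_D = occupancy_closed_form(p, t)
    counts = derived_counts(t, T_MM, T_MI, T_IM, T_DI, S_I, S_D, tol=np.inf)
    probs = counts_to_probs(counts, p)
    return count_derivatives(probs, p)


def solve_transition_probs(
    p: GGIParams,
    t: float,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "DOP853",
) -> TransitionProbs | list[TransitionProbs]:
    """Integrate the count ODEs from 0 to ``t`` and return the transition
    probabilities of the 3-state machine.

    With ``t_eval`` (a sorted grid in [0, t]), returns the probabilities at
    every grid time instead of only the endpoint. Integration failure
    raises with the solver's diagnostic message.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    want_grid = t_eval is not None
    grid = np.atleast_1d(np.asarray(t_eval, dtype=float)) if want_grid else np.array([t])
    if t == 0.0 or p.total_rate == 0.0:
        out = [boundary_probs(p, tt) for tt in grid]
        return out if want_grid else out[0]

    u0 = np.array([1.0, 0.0, 0.0, 0.0])
    first_step = min(1e-6 / p.total_rate, t / 2)
    sol = solve_ivp(
        _ode_rhs,
        (0.0, t),
        u0,
        t_eval=grid,
        args=(p,),
        method=method,
        rtol=rtol,
        atol=atol,
        first_step=first_step,
    )
    if not sol.success:
        raise RuntimeError(f"transition-probability ODE integration failed: {sol.message}")
    out = []
    for tt, u in zip(sol.t, sol.y.T):
        if tt == 0.0:
            out.append(boundary_probs(p, 0.0))
            continue
        S_I, S_D = occupancy_closed_form(p, tt)
        counts = derived_counts(tt, *u, S_I, S_D)
        out.append(counts_to_probs(counts, p))
    return out if want_grid else out[0]


# ---------------------------------------------------------------------------
# exact single-residue-indel (TKF91) limit


def tkf91_probs(lam: float, mu: float, t: float) -> TransitionProbs:
    """Closed-form transition probabilities of the TKF91 links model.

    a = (1−β)α, b = β, c = (1−β)(1−α) (Insert row identical to the Match
    row), p = (1−γ)α, q = γ, r = (1−γ)(1−α), with

        α = exp(−μt)
        β = λ(exp(−λt) − exp(−μt)) / (μ exp(−λt) − λ exp(−μt))
        γ = 1 − μβ / (λ(1−α))

    The removable singularities (λ = μ, λ = 0, μ = 0, t = 0) are evaluated
    by their analytic limits. λ < μ is not required.
    """
    if lam < 0 or mu < 0:
        raise ValueError("rates must be nonnegative")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    alpha = math.exp(-mu * t)
    if t == 0.0:
        beta = gamma = 0.0
    elif lam == 0.0:
        beta = gamma = 0.0
    elif abs(lam - mu) <= 1e-9 * max(lam, mu):
        beta = lam * t / (1.0 + lam * t)
        # γ limit: 1 − μβ/(λ(1−α)) with λ = μ
        gamma = 1.0 - beta / -math.expm1(-lam * t) if mu > 0 else 0.0
    else:
        beta = (
            lam
            * (math.exp(-lam * t) - math.exp(-mu * t))
            / (mu * math.exp(-lam * t) - lam * math.exp(-mu * t))
        )
        if mu == 0.0:
            gamma = 1.0 - beta / (lam * t)
        else:
            gamma = 1.0 - mu * beta / (lam * -math.expm1(-mu * t))
    beta = min(max(beta, 0.0), 1.0)
    gamma = min(max(gamma, 0.0), 1.0)
    return TransitionProbs(
        t=t,
        a=(1 - beta) * alpha,
        b=beta,
        c=(1 - beta) * (1 - alpha),
        f=(1 - beta) * alpha,
        g=beta,
        h=(1 - beta) * (1 - alpha),
        p=(1 - gamma) * alpha,
        q=gamma,
        r=(1 - gamma) * (1 - alpha),
    )


# ---------------------------------------------------------------------------
# finite-sequence machine


def finite_machine(probs: TransitionProbs) -> StateMachine:
    """Augment the 3-state machine with start and end states for finite
    sequences.

    This is a heuristic: the start state copies the Match row (the left
    sequence edge behaves like an immortal match, so insertions may precede
    the first residue), and each state ends the alignment with its total
    probability of *not* inserting (1−b from M and Start, 1−g from I, 1−q
    from D); the match/delete choice is resolved by input exhaustion, as
    usual for conditionally normalized machines. With x = y = 0 this
    reproduces the exact TKF91 finite-sequence machine. Removing the start
    and end states leaves exactly the 3-state interior block.
    """
    a, b, c = probs.a, probs.b, probs.c
    f, g, h = probs.f, probs.g, probs.h
    p, q, r = probs.p, probs.q, probs.r
    Q = np.array(
        [
            [a, b, c, 0.0, 1.0 - b],
            [f, g, h, 0.0, 1.0 - g],
            [p, q, r, 0.0, 1.0 - q],
            [a, b, c, 0.0, 1.0 - b],
            [0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    states = (("M", "M"), ("I", "I"), ("D", "D"), ("S", "N"), ("E", "N"))
    return StateMachine(states=states, Q=np.clip(Q, 0.0, None))
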