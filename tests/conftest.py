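"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's matrix-inversion and
dynamic-programming code paths: expected transition counts are summed over
explicit truncated walks, gap distributions over enumerated in-gap paths,
and alignment likelihoods over enumerated gap profiles.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
import pytest

from geomindel import GGIParams
from geomindel.machines import StateMachine


@pytest.fixture
def central_params() -> GGIParams:
    """The indel-symmetric parameter point used throughout the study."""
    return GGIParams(1.0, 1.0, 0.5, 0.5)


def random_probs_matrix(rng: np.random.Generator) -> np.ndarray:
    """A random valid 3x3 transition matrix (rows on the simplex, all
    entries positive so every series in the count calculus converges)."""
    return rng.dirichlet(np.ones(3) * 2.0, size=3)


def brute_force_expected_count(
    machine: StateMachine, X, Y, max_steps: int = 25
) -> tuple[float, float]:
    """Sum of P(walk) * T_XY(walk) over match-to-match walks of <= max_steps
    transitions, plus an upper bound on the neglected tail.

    Walks start in the match state, pass through insert/delete/null states,
    and end at the first return to a match state. T_XY counts transitions
    from class X, through any number of null states, into class Y.
    Computed by explicit forward/backward sweeps over (state, last
    non-null class) — no geometric-series inverses.
    """
    X = {X} if isinstance(X, str) else set(X)
    Y = {Y} if isinstance(Y, str) else set(Y)
    K = machine.n_states
    cls = [c for _, c in machine.states]
    Q = machine.Q

    # comp[d][j]: P(reach an M state in <= d further transitions | at j)
    comp = [np.zeros(K)]
    m_states = [j for j in range(K) if cls[j] == "M"]
    idn = [j for j in range(K) if cls[j] != "M"]
    for d in range(1, max_steps + 1):
        nxt = np.zeros(K)
        for j in idn:
            nxt[j] = sum(Q[j, k] for k in m_states) + sum(
                Q[j, k] * comp[d - 1][k] for k in idn
            )
        comp.append(nxt)

    alive: dict[tuple[int, str], float] = defaultdict(float)
    alive[(0, "M")] = 1.0
    expect = 0.0
    for step in range(max_steps):
        remaining = max_steps - step - 1
        nxt: dict[tuple[int, str], float] = defaultdict(float)
        for (i, lc), w in alive.items():
            for j in range(K):
                wj = w * Q[i, j]
                if wj == 0.0:
                    continue
                cj = cls[j]
                if cj == "N":
                    nxt[(j, lc)] += wj
                    continue
                increment = 1.0 if (lc in X and cj in Y) else 0.0
                if cj == "M":
                    expect += wj * increment
                else:
                    expect += wj * increment * comp[remaining][j]
                    nxt[(j, cj)] += wj
        alive = nxt
    # any walk still alive could contribute at most ~max_steps more counts
    tail = sum(alive.values()) * max_steps
    return expect, tail


def brute_force_gap_distribution(probs, max_len: int = 12) -> np.ndarray:
    """P(S_I = i, S_D = j) by explicit enumeration of every in-gap path of
    at most max_len emissions. Cells with i + j <= max_len are exact."""
    a, b, c = probs.a, probs.b, probs.c
    f, g, h = probs.f, probs.g, probs.h
    p, q, r = probs.p, probs.q, probs.r
    P = np.zeros((max_len + 1, max_len + 1))
    P[0, 0] = a
    # stack entries: (state 'I' or 'D', i, j, weight of prefix from M)
    stack = [("I", 1, 0, b), ("D", 0, 1, c)]
    while stack:
        s, i, j, w = stack.pop()
        if w == 0.0:
            continue
        P[i, j] += w * (f if s == "I" else p)  # close the gap now
        if i + j < max_len:
            if s == "I":
                stack.append(("I", i + 1, j, w * g))
                stack.append(("D", i, j + 1, w * h))
            else:
                stack.append(("I", i + 1, j, w * q))
                stack.append(("D", i, j + 1, w * r))
    return P


def enumerate_alignment_likelihood(probs, subst, t, ancestor, descendant) -> float:
    """P(descendant | ancestor) by explicit recursion over every gap
    profile and its emissions, under the finite-sequence machine reading
    (start behaves like Match; end weight = probability of not inserting)."""
    M = subst.substitution_probs(t)
    rho = subst.rho
    anc = subst.encode(ancestor)
    dsc = subst.encode(descendant)
    row = {
        "S": (probs.a, probs.b, probs.c, 1.0 - probs.b),
        "M": (probs.a, probs.b, probs.c, 1.0 - probs.b),
        "I": (probs.f, probs.g, probs.h, 1.0 - probs.g),
        "D": (probs.p, probs.q, probs.r, 1.0 - probs.q),
    }

    def rec(state: str, i: int, j: int) -> float:
        to_m, to_i, to_d, to_e = row[state]
        if i == len(anc) and j == len(dsc):
            return to_e
        total = 0.0
        if i < len(anc) and j < len(dsc):
            total += to_m * M[anc[i], dsc[j]] * rec("M", i + 1, j + 1)
        if j < len(dsc):
            total += to_i * rho[dsc[j]] * rec("I", i, j + 1)
        if i < len(anc):
            total += to_d * rec("D", i + 1, j)
        return total

    return rec("S", 0, 0)


def series_expm(R: np.ndarray, t: float, terms: int = 60) -> np.ndarray:
    """Matrix exponential by direct Taylor series (oracle use only)."""
    A = R * t
    out = np.eye(R.shape[0])
    term = np.eye(R.shape[0])
    for k in range(1, terms):
        term = term @ A / k
        out = out + term
    return out


def naive_column_simulation(p: GGIParams, L: int, t: float, rng) -> str:
    """Reference indel simulation on an explicit per-column list.

    Re-implements the Gillespie scheme with the same random-variate
    consumption order as the production simulator (waiting time, event
    type, event length, position) but tracks the alignment as a plain
    list of single characters, recomputing descendant positions by
    scanning. O(L^2) per event; for tiny inputs only.
    """
    cols = ["M"] * L
    lam, mu, x, y = p.lam, p.mu, p.x, p.y
    now = 0.0

    def geometric(ext):
        if ext <= 0.0:
            return 1
        return 1 + int(math.log(rng.random()) / math.log(ext))

    while True:
        desc_positions = [k for k, c in enumerate(cols) if c in "MI"]
        m = len(desc_positions)
        rate = lam * (m + 1) + mu * m
        if rate <= 0.0:
            break
        now += rng.expovariate(rate)
        if now > t:
            break
        if rng.random() * rate < lam * (m + 1):
            n = geometric(x)
            j = rng.randrange(m + 1)
            cpos = 0 if j == 0 else desc_positions[j - 1] + 1
            cols[cpos:cpos] = ["I"] * n
        else:
            n = geometric(y)
            s = rng.randrange(m)
            for cp in desc_positions[s : s + n]:
                cols[cp] = "D" if cols[cp] == "M" else "x"
    return "".join(c for c in cols if c != "x")
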