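"""Weighted pair state machines and the expected-transition-count calculus.

A pair machine has states classed Match (reads one input symbol, writes one
output symbol), Insert (writes only), Delete (reads only), or Null (neither).
Machines here are conditionally normalized transducers, P(output | input).

The central quantity is the expectation, over random walks that begin and
end in the (unique) Match state, of the number of X → Y class transitions
*after null states are removed from the walk*:

    E[T_XY] = [ U (J_XY ∘ (V Q)) W ]_{1,1}

with geometric-series sums

    U = (I − Q_{all→IDN})^{-1}     paths M → {I,D,N}* → (entry point)
    V = (I − Q_{all→N})^{-1}       null-state bridges X → N* → Y
    W = (I − Q_{IDN→all})^{-1}     return paths → M

where ``J_XY`` selects transitions from class-X rows to class-Y columns and
``∘`` is the elementwise product. State occupancies follow as row or column
sums of the T-expectations; the Match occupancy is exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StateMachine",
    "select_transitions",
    "expected_transition_count",
    "expected_occupancy",
    "infinitesimal_machine",
    "three_state_machine",
    "compose_fg",
    "MachineError",
]

CLASSES = ("M", "I", "D", "N")

#: emission behavior implied by state class
EMISSION = {"M": ("read", "write"), "I": ("write",), "D": ("read",), "N": ()}


class MachineError(ValueError):
    """Raised for structurally invalid or non-terminating machines."""


@dataclass(frozen=True)
class StateMachine:
    """A weighted finite-state pair machine.

    ``states`` is an ordered list of (name, class) pairs; ``Q`` the K x K
    nonnegative transition weight matrix. Exactly one state has class M and
    it must be the first.
    """

    states: tuple[tuple[str, str], ...]
    Q: np.ndarray

    def __post_init__(self) -> None:
        states = tuple((str(n), str(c)) for n, c in self.states)
        object.__setattr__(self, "states", states)
        Q = np.asarray(self.Q, dtype=float)
        K = len(states)
        if Q.shape != (K, K):
            raise MachineError(f"Q must be {K}x{K}, got {Q.shape}")
        if np.any(Q < 0):
            raise MachineError("transition weights must be nonnegative")
        object.__setattr__(self, "Q", Q)
        for name, cls in states:
            if cls not in CLASSES:
                raise MachineError(f"state {name!r} has unknown class {cls!r}")
        m_states = [i for i, (_, c) in enumerate(states) if c == "M"]
        if m_states != [0]:
            raise MachineError(
                "machine must have exactly one Match state, in first position; "
                f"found M states at {m_states}"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def class_indices(self, classes: Iterable[str]) -> np.ndarray:
        """Indices of states whose class is in ``classes``."""
        cs = set(classes)
        unknown = cs - set(CLASSES)
        if unknown:
            raise MachineError(f"unknown state classes {sorted(unknown)}")
        if not cs:
            raise MachineError("class selector must be nonempty")
        return np.array(
            [i for i, (_, c) in enumerate(self.states) if c in cs], dtype=np.intp
        )

    def emission_tags(self) -> tuple[tuple[str, ...], ...]:
        return tuple(EMISSION[c] for _, c in self.states)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "states": [{"name": n, "class": c} for n, c in self.states],
                "weights": self.Q.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "StateMachine":
        d = json.loads(text)
        return cls(
            states=tuple((s["name"], s["class"]) for s in d["states"]),
            Q=np.array(d["weights"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "StateMachine":
        return cls.from_json(Path(path).read_text())


def select_transitions(
    m: StateMachine, frm: Iterable[str], to: Iterable[str]
) -> np.ndarray:
    """The matrix with entry (i, j) = Q[i, j] when state i's class is in
    ``frm`` and state j's class is in ``to``, else 0."""
    out = np.zeros_like(m.Q)
    rows = m.class_indices(frm)
    cols = m.class_indices(to)
    out[np.ix_(rows, cols)] = m.Q[np.ix_(rows, cols)]
    return out


# ---------------------------------------------------------------------------
# expected transition counts


def _series_inverse(A: np.ndarray, what: str) -> np.ndarray:
    """(I − A)^{-1} as a geometric series sum; requires spectral radius < 1."""
    radius = np.max(np.abs(np.linalg.eigvals(A))) if A.any() else 0.0
    if radius >= 1.0 - 1e-12:
        raise MachineError(
            f"geometric series for {what} does not converge "
            f"(spectral radius {radius:.6g}): non-terminating machine"
        )
    return np.linalg.inv(np.eye(A.shape[0]) - A)


def _uvw(m: StateMachine) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    all_classes = set(CLASSES)
    U = _series_inverse(select_transitions(m, all_classes, {"I", "D", "N"}), "U")
    V = _series_inverse(select_transitions(m, all_classes, {"N"}), "V")
    W = _series_inverse(select_transitions(m, {"I", "D", "N"}, all_classes), "W")
    return U, V, W


def expected_transition_count(
    m: StateMachine, X: Iterable[str] | str, Y: Iterable[str] | str
) -> float:
    """Expected number of X → Y class transitions (null states removed) over
    walks that begin and end in the Match state.

    Null states are removed from walks before counting, so a selector
    containing only class N yields 0.
    """
    X = ({X} if isinstance(X, str) else set(X)) - {"N"}
    Y = ({Y} if isinstance(Y, str) else set(Y)) - {"N"}
    if not X or not Y:
        return 0.0
    U, V, W = _uvw(m)
    J = np.zeros_like(m.Q)
    rows = m.class_indices(X)
    cols = m.class_indices(Y)
    J[np.ix_(rows, cols)] = 1.0
    core = J * (V @ m.Q)
    return float((U @ core @ W)[0, 0])


def expected_occupancy(m: StateMachine, X: Iterable[str] | str) -> float:
    """Expected number of class-X states visited per Match-to-Match walk
    (the final state excluded), as the row sum of transition expectations."""
    X = {X} if isinstance(X, str) else set(X)
    return sum(expected_transition_count(m, X, {c}) for c in CLASSES)


# ---------------------------------------------------------------------------
# the concrete machines of the geometric indel calculus

from .model import GGIParams  # noqa: E402  (only the dataclass; no cycle)


def three_state_machine(Q: np.ndarray | Sequence[Sequence[float]]) -> StateMachine:
    """The 3-state pair machine with states M, I, D and transition matrix Q."""
    return StateMachine(states=(("M", "M"), ("I", "I"), ("D", "D")), Q=np.asarray(Q))


def infinitesimal_machine(p: GGIParams, dt: float) -> StateMachine:
    """The machine G(dt) encoding one instant of geometric-indel evolution.

    Rows: from M, start an insertion (λ dt), a deletion (μ dt), or nothing;
    from I, extend with probability x else return to M; from D likewise
    with y. Valid for dt << 1/(λ+μ).
    """
    if dt < 0:
        raise MachineError(f"dt must be >= 0, got {dt}")
    if dt * p.total_rate >= 1.0:
        raise MachineError(
            f"dt={dt} too large for total indel rate {p.total_rate}: "
            "first row would leave the probability simplex"
        )
    Q = np.array(
        [
            [1.0 - p.total_rate * dt, p.lam * dt, p.mu * dt],
            [1.0 - p.x, p.x, 0.0],
            [1.0 - p.y, 0.0, p.y],
        ]
    )
    return three_state_machine(Q)


#: state names of the composite machine, in matrix order
FG_STATE_NAMES = ("MM", "mI", "IM", "iI", "MD", "Dm", "Dd", "Di", "ID")
FG_STATE_CLASSES = ("M", "I", "I", "I", "D", "D", "D", "D", "N")


def compose_fg(F: StateMachine, p: GGIParams, dt: float) -> StateMachine:
    """The 9-state product machine F·G(dt).

    Each composite state XY pairs a state of the 3-state alignment machine F
    with a state of the infinitesimal machine G; uppercase marks the
    component that transitions on entry. Transitions synchronize so that
    F's output feeds G's input. State ID (F inserting, G deleting) neither
    reads input nor writes output and is classed Null.

    The weight matrix is hard-coded for this one composition rather than
    produced by a general transducer-product algorithm; at ``dt = 0`` the
    expected class-transition counts of F·G equal those of F.
    """
    if F.n_states != 3:
        raise MachineError("compose_fg expects the 3-state alignment machine")
    if dt < 0 or dt * p.total_rate >= 1.0:
        raise MachineError(f"invalid dt={dt} for total rate {p.total_rate}")
    (a, b, c), (f, g, h), (pp, q, r) = F.Q
    x, y, lam, mu = p.x, p.y, p.lam, p.mu
    e = 1.0 - (lam + mu) * dt
    Q = np.array(
        [
            [a * e, lam * dt, b * e, 0, a * mu * dt, c, 0, 0, b * mu * dt],
            [a * (1 - x), x, b * (1 - x), 0, 0, 0, 0, c, 0],
            [f * e, 0, g * e, lam * dt, f * mu * dt, h, 0, 0, g * mu * dt],
            [f * (1 - x), 0, g * (1 - x), x, 0, 0, 0, h, 0],
            [a * (1 - y), 0, b * (1 - y), 0, a * y, 0, c, 0, b * y],
            [pp * e, 0, q * e, 0, pp * mu * dt, r, 0, 0, q * mu * dt],
            [pp * (1 - y), 0, q * (1 - y), 0, pp * y, 0, r, 0, q * y],
            [pp * (1 - x), 0, q * (1 - x), 0, 0, 0, 0, r, 0],
            [f * (1 - y), 0, g * (1 - y), 0, f * y, 0, h, 0, g * y],
        ]
    )
    states = tuple(zip(FG_STATE_NAMES, FG_STATE_CLASSES))
    return StateMachine(states=states, Q=Q)
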