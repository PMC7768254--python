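"""Pairwise alignment under the finite-sequence 3-state machine.

The machine is conditionally normalized, P(descendant | ancestor): Match
states emit a descendant residue with probability ``expm(R t)[anc, desc]``,
Insert states emit from the stationary distribution ρ, Delete states emit
nothing. The forward algorithm sums over all alignments (state paths); the
Viterbi recursion finds the single best path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .machines import StateMachine
from .model import SubstModel

__all__ = ["AlignmentResult", "forward_likelihood", "viterbi_align"]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentResult:
    """Forward log-likelihood plus the best path and its gapped rendering."""

    log_likelihood: float
    best_path: str
    path_log_prob: float
    aligned_ancestor: str
    aligned_descendant: str


def _machine_blocks(machine: StateMachine):
    """Extract the interior 3x3 block, start row, and end column by class."""
    names = [n for n, _ in machine.states]
    if machine.n_states != 5 or names[:3] != ["M", "I", "D"]:
        raise ValueError(
            "alignment expects the finite-sequence machine (states M, I, D, S, E); "
            "build one with geomindel.ode.finite_machine"
        )
    i_s, i_e = names.index("S"), names.index("E")
    Q = machine.Q
    with np.errstate(divide="ignore"):
        logT = np.log(Q[:3, :3])          # interior transitions
        logS = np.log(Q[i_s, :3])         # start -> {M,I,D}
        logE = np.log(Q[:3, i_e])         # {M,I,D} -> end
        logSE = np.log(Q[i_s, i_e]) if Q[i_s, i_e] > 0 else _NEG_INF
    return logT, logS, logE, logSE


def _dp(machine, subst, t, ancestor, descendant, viterbi: bool):
    logT, logS, logE, logSE = _machine_blocks(machine)
    anc = subst.encode(ancestor)
    dsc = subst.encode(descendant)
    n, m = len(anc), len(dsc)
    with np.errstate(divide="ignore"):
        logM = np.log(subst.substitution_probs(t))
        logrho = np.log(subst.rho)

    # dp[s, i, j]: log-mass of paths ending in state s having consumed
    # i ancestor and j descendant residues; state order M=0, I=1, D=2
    dp = np.full((3, n + 1, m + 1), _NEG_INF)
    if viterbi:
        ptr = np.full((3, n + 1, m + 1), -1, dtype=np.int8)  # predecessor state, -2 = start

    def into(s: int, i: int, j: int):
        """Combine predecessor scores at source cell (i, j) into state s."""
        cands = [dp[y, i, j] + logT[y, s] for y in range(3)]
        start = logS[s] if (i == 0 and j == 0) else _NEG_INF
        if viterbi:
            # tie-break: prefer M over D over I on equal scores
            order = (0, 2, 1)
            best, arg = start, -2
            for y in order:
                if cands[y] > best:
                    best, arg = cands[y], y
            return best, arg
        vals = np.array(cands + [start])
        hi = vals.max()
        return (hi + np.log(np.exp(vals - hi).sum()) if hi > _NEG_INF else _NEG_INF), -1

    for i in range(n + 1):
        for j in range(m + 1):
            if i >= 1 and j >= 1:
                v, y = into(0, i - 1, j - 1)
                dp[0, i, j] = v + logM[anc[i - 1], dsc[j - 1]]
                if viterbi:
                    ptr[0, i, j] = y
            if j >= 1:
                v, y = into(1, i, j - 1)
                dp[1, i, j] = v + logrho[dsc[j - 1]]
                if viterbi:
                    ptr[1, i, j] = y
            if i >= 1:
                v, y = into(2, i - 1, j)
                dp[2, i, j] = v
                if viterbi:
                    ptr[2, i, j] = y

    finals = [dp[s, n, m] + logE[s] for s in range(3)]
    if n == 0 and m == 0:
        finals.append(logSE)
    if viterbi:
        if n == 0 and m == 0:
            return logSE, None, ptr, dp
        best = max(finals[s] for s in range(3))
        best_s = next(s for s in (0, 2, 1) if finals[s] == best)  # prefer M, then D
        return finals[best_s], best_s, ptr, dp
    vals = np.array(finals)
    hi = vals.max()
    ll = hi + np.log(np.exp(vals - hi).sum()) if hi > _NEG_INF else _NEG_INF
    return ll, None, None, dp


def forward_likelihood(
    machine: StateMachine, subst: SubstModel, t: float, ancestor: str, descendant: str
) -> float:
    """Log of P(descendant | ancestor) summed over all alignments and paths."""
    ll, *_ = _dp(machine, subst, t, ancestor, descendant, viterbi=False)
    return float(ll)


def viterbi_align(
    machine: StateMachine, subst: SubstModel, t: float, ancestor: str, descendant: str
) -> AlignmentResult:
    """Best single state path and its gapped alignment.

    Ties are broken deterministically, preferring Match over Delete over
    Insert. The best-path log-probability never exceeds the forward
    log-likelihood.
    """
    ll = forward_likelihood(machine, subst, t, ancestor, descendant)
    score, best_s, ptr, dp = _dp(machine, subst, t, ancestor, descendant, viterbi=True)
    n, m = len(ancestor), len(descendant)
    path: list[str] = []
    if best_s is not None:
        s, i, j = best_s, n, m
        while True:
            path.append("MID"[s])
            y = ptr[s, i, j]
            if s == 0:
                i, j = i - 1, j - 1
            elif s == 1:
                j -= 1
            else:
                i -= 1
            if y == -2:
                break
            s = int(y)
        path.reverse()
    cols = "".join(path)
    ai = di = 0
    arow, drow = [], []
    for c in cols:
        if c in "MD":
            arow.append(ancestor[ai])
            ai += 1
        else:
            arow.append("-")
        if c in "MI":
            drow.append(descendant[di])
            di += 1
        else:
            drow.append("-")
    if ai != n or di != m:
        raise AssertionError("best path does not cover both sequences")
    return AlignmentResult(
        log_likelihood=float(ll),
        best_path=cols,
        path_log_prob=float(score),
        aligned_ancestor="".join(arow),
        aligned_descendant="".join(drow),
    )
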