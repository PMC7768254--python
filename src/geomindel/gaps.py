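"""Joint gap-length distributions P(S_I, S_D), their moments, and relative
entropy between them.

A gap is a maximal run of insert/delete columns between two match columns
of a pairwise alignment; S_I and S_D count the inserted and deleted
residues in one such inter-match interval (the (0, 0) cell is the event
that two match columns are adjacent). Every interval contributes exactly
one observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ode import TransitionProbs

__all__ = [
    "GapDistribution",
    "GapMoments",
    "hmm_gap_distribution",
    "moments",
    "kl_divergence",
    "tail_bound",
]


@dataclass(frozen=True)
class GapDistribution:
    """Probability (kind='exact') or count (kind='empirical') grid over
    (S_I, S_D), truncated at G per axis.

    ``P[i, j]`` is the mass/count of intervals with i inserted and j
    deleted residues. For empirical grids, ``n_intervals`` is the total
    number of observed intervals (including ``overflow`` observations that
    exceeded G on either axis); for exact grids, ``tail`` is an upper bound
    on the probability mass beyond the grid.
    """

    P: np.ndarray
    kind: str
    n_intervals: int | None = None
    overflow: float = 0.0
    tail: float = 0.0

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError(f"gap grid must be square, got shape {P.shape}")
        if np.any(P < 0):
            raise ValueError("gap grid entries must be nonnegative")
        if self.kind not in ("exact", "empirical"):
            raise ValueError(f"kind must be 'exact' or 'empirical', got {self.kind!r}")
        if self.kind == "empirical" and self.n_intervals is None:
            raise ValueError("empirical distributions need n_intervals")
        object.__setattr__(self, "P", P)

    @property
    def G(self) -> int:
        return self.P.shape[0] - 1

    def frequencies(self) -> np.ndarray:
        """The grid normalized to total mass 1 (empirical: includes the
        overflow bucket in the denominator)."""
        if self.kind == "empirical":
            if not self.n_intervals:
                raise ValueError("empty empirical distribution (no intervals observed)")
            return self.P / self.n_intervals
        total = self.P.sum()
        if total <= 0:
            raise ValueError("exact distribution has zero mass")
        return self.P / total

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write nonzero cells as (S_I, S_D, value) rows."""
        with open(path, "w") as fh:
            fh.write("S_I\tS_D\tvalue\n")
            for i, j in zip(*np.nonzero(self.P)):
                v = self.P[i, j]
                fh.write(f"{i}\t{j}\t{v:.17g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, G: int, kind: str = "empirical",
                 n_intervals: int | None = None, overflow: float = 0.0) -> "GapDistribution":
        P = np.zeros((G + 1, G + 1))
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("S_I"):
                raise ValueError(f"unrecognized gap-distribution TSV header: {header!r}")
            for line in fh:
                i, j, v = line.split("\t")
                P[int(i), int(j)] = float(v)
        if kind == "empirical" and n_intervals is None:
            n_intervals = int(round(P.sum() + overflow))
        return cls(P=P, kind=kind, n_intervals=n_intervals, overflow=overflow)

    def sidecar(self) -> dict:
        d = {"kind": self.kind, "G": self.G}
        if self.kind == "empirical":
            d.update(n_intervals=self.n_intervals, overflow=self.overflow)
        else:
            d.update(mass=float(self.P.sum()), tail_bound=self.tail)
        return d


@dataclass(frozen=True)
class GapMoments:
    """Low-order summaries of a gap-length distribution."""

    mean_SI: float
    mean_SD: float
    p00: float
    cov: float
    tail_mass: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def hmm_gap_distribution(probs: TransitionProbs, G: int) -> GapDistribution:
    """Exact joint gap-length distribution of the 3-state machine, up to G.

    Dynamic program over match-to-match walks: ``w_I[i, j]`` (``w_D``) is
    the probability of being in the Insert (Delete) state having emitted i
    insertions and j deletions since the last match column. One emission
    per step, so

        w_I[i, j] = g w_I[i-1, j] + q w_D[i-1, j]   (+ b at (1, 0))
        w_D[i, j] = h w_I[i, j-1] + r w_D[i, j-1]   (+ c at (0, 1))

    and P(0,0) = a, P(i,j) = f w_I[i,j] + p w_D[i,j] otherwise.
    """
    if G < 1:
        raise ValueError(f"G must be >= 1, got {G}")
    a, b, c = probs.a, probs.b, probs.c
    f, g, h = probs.f, probs.g, probs.h
    p, q, r = probs.p, probs.q, probs.r
    wI = np.zeros((G + 1, G + 1))
    wD = np.zeros((G + 1, G + 1))
    for i in range(G + 1):
        for j in range(G + 1):
            vI = g * wI[i - 1, j] + q * wD[i - 1, j] if i >= 1 else 0.0
            vD = h * wI[i, j - 1] + r * wD[i, j - 1] if j >= 1 else 0.0
            if i == 1 and j == 0:
                vI += b
            if i == 0 and j == 1:
                vD += c
            wI[i, j] = vI
            wD[i, j] = vD
    P = f * wI + p * wD
    P[0, 0] = a
    return GapDistribution(P=P, kind="exact", tail=tail_bound(probs, G))


def tail_bound(probs: TransitionProbs, G: int) -> float:
    """Upper bound on the gap-distribution mass outside the G x G grid.

    Any interval outside the grid emits more than G columns; after the
    first emission the in-gap state weights evolve by the 2x2 extension
    matrix [[g, h], [q, r]], so the bound is the surviving in-gap mass
    after G further extension steps, (b, c) · A^G · (1, 1)'. Decays at the
    spectral radius of A, and is monotone nonincreasing in G.
    """
    A = np.array([[probs.g, probs.h], [probs.q, probs.r]])
    v = np.array([probs.b, probs.c])
    v = v @ np.linalg.matrix_power(A, G)
    return float(v.sum())


def moments(d: GapDistribution) -> GapMoments:
    """Means, empty-gap probability, and insertion-deletion covariance of
    the (truncated) grid. ``tail_mass`` reports the mass not on the grid
    (empirical: overflow fraction; exact: 1 − grid mass)."""
    F = d.frequencies()
    G = d.G
    idx = np.arange(G + 1, dtype=float)
    mi = F.sum(axis=1)
    mj = F.sum(axis=0)
    mean_SI = float(idx @ mi)
    mean_SD = float(idx @ mj)
    e_prod = float(idx @ F @ idx)
    cov = e_prod - mean_SI * mean_SD
    if d.kind == "empirical":
        tail_mass = float(d.overflow) / d.n_intervals
    else:
        tail_mass = max(0.0, 1.0 - float(d.P.sum()))
    return GapMoments(
        mean_SI=mean_SI, mean_SD=mean_SD, p00=float(F[0, 0]), cov=cov, tail_mass=tail_mass
    )


def kl_divergence(
    P_ref: GapDistribution, P_model: GapDistribution, truncate_to: int | None = None
) -> float:
    """Relative entropy sum(P_ref log(P_ref / P_model)) over the grid.

    Cells with zero reference mass contribute nothing; a supported cell
    with zero model mass makes the divergence +inf (no pseudocounts). With
    ``truncate_to = G'``, both distributions are first conditioned on
    {S_I <= G', S_D <= G'} and renormalized.
    """
    if P_ref.P.shape != P_model.P.shape:
        raise ValueError(
            f"shape mismatch: reference grid {P_ref.P.shape} vs model {P_model.P.shape}"
        )
    pr = P_ref.frequencies()
    pm = P_model.frequencies()
    if truncate_to is not None:
        if not 0 <= truncate_to <= P_ref.G:
            raise ValueError(f"truncate_to must be in [0, {P_ref.G}]")
        k = truncate_to + 1
        pr = pr[:k, :k]
        pm = pm[:k, :k]
        if pr.sum() <= 0 or pm.sum() <= 0:
            raise ValueError("truncation leaves an empty distribution")
        pr = pr / pr.sum()
        pm = pm / pm.sum()
    sup = pr > 0
    if np.any(sup & (pm <= 0)):
        return float("inf")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(sup, pr * np.log(np.where(sup, pr, 1.0) / np.where(sup, pm, 1.0)), 0.0)
    return float(terms.sum())
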