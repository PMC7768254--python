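"""Exact stochastic simulation of the geometric indel process with
alignment tracking.

Standard Gillespie scheme on the descendant sequence: with m residues, the
total event rate is λ(m+1) + μm — one insertion opportunity at each of the
m+1 junctions (including the left edge, so the single-residue limit matches
the birth-death links model exactly), and one rightward deletion
opportunity at each residue. Event lengths are geometric; a deletion
overrunning the sequence end is truncated, which (dropping the 1−y
normalization for end-hitting lengths) keeps the per-residue deletion rate
at exactly μ regardless of distance from the end.

Residue identities and substitutions are not simulated: gap statistics
under the model factorize away from residue content, so only the alignment
silhouette of M/I/D columns is tracked. Later events can overlap earlier
ones — inserted residues are deletable and disappear from the alignment if
deleted; deleted ancestral residues leave a D column.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import numpy as np

from .gaps import GapDistribution
from .model import GGIParams

__all__ = ["SimConfig", "AlignmentRLE", "evolve", "extract_gaps", "simulate_distribution"]

# column codes used internally
_M, _D, _I, _DEAD = 0, 1, 2, 3
_CODE_TO_CHAR = {_M: "M", _D: "D", _I: "I"}


@dataclass(frozen=True)
class SimConfig:
    """Replicate count N, ancestral length L, max recorded gap size G,
    divergence time t, and RNG seed."""

    N: int
    L: int
    G: int
    t: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1 or self.L < 2 or self.G < 1 or self.t < 0:
            raise ValueError(f"invalid simulation config: {self}")


@dataclass(frozen=True)
class AlignmentRLE:
    """Run-length-encoded M/I/D column sequence of a pairwise alignment."""

    runs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        runs = tuple((str(c), int(n)) for c, n in self.runs)
        for (c, n) in runs:
            if c not in "MID" or n < 1:
                raise ValueError(f"invalid run {(c, n)}")
        for (c1, _), (c2, _) in zip(runs, runs[1:]):
            if c1 == c2:
                raise ValueError("adjacent runs must have distinct column types")
        object.__setattr__(self, "runs", runs)

    @classmethod
    def from_columns(cls, columns: str) -> "AlignmentRLE":
        runs: list[tuple[str, int]] = []
        for ch in columns:
            if runs and runs[-1][0] == ch:
                runs[-1] = (ch, runs[-1][1] + 1)
            else:
                runs.append((ch, 1))
        return cls(tuple(runs))

    def columns(self) -> str:
        return "".join(c * n for c, n in self.runs)

    @property
    def ancestral_length(self) -> int:
        return sum(n for c, n in self.runs if c in "MD")

    @property
    def descendant_length(self) -> int:
        return sum(n for c, n in self.runs if c in "MI")


def _geometric(rng: random.Random, ext: float) -> int:
    """Sample an indel event length: P(n) = ext^(n-1) (1-ext), n >= 1."""
    if ext <= 0.0:
        return 1
    return 1 + int(math.log(rng.random()) / math.log(ext))


def evolve(p: GGIParams, L: int, t: float, rng: random.Random) -> AlignmentRLE:
    """Simulate one replicate: ancestor of length L evolved for time t.

    Returns the run-length-encoded alignment. An extinct sequence (all
    residues deleted before t) is a valid outcome, yielding an all-D
    alignment (possibly with later re-insertions).
    """
    if L < 1:
        raise ValueError(f"ancestral length must be >= 1, got {L}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    # cols: alignment columns in order (codes M/D/I/DEAD); dmap: indices
    # into cols of the current descendant residues, ascending.
    cols: list[int] = [_M] * L
    dmap = np.arange(L, dtype=np.int64)
    lam, mu, x, y = p.lam, p.mu, p.x, p.y
    now = 0.0
    while True:
        m = dmap.shape[0]
        rate = lam * (m + 1) + mu * m
        if rate <= 0.0:
            break
        now += rng.expovariate(rate)
        if now > t:
            break
        if rng.random() * rate < lam * (m + 1):
            # insertion of n residues at junction j (0 = before first residue)
            n = _geometric(rng, x)
            j = rng.randrange(m + 1)
            cpos = 0 if j == 0 else int(dmap[j - 1]) + 1
            cols[cpos:cpos] = [_I] * n
            dmap = np.concatenate(
                [dmap[:j], cpos + np.arange(n, dtype=np.int64), dmap[j:] + n]
            )
        else:
            # deletion starting at residue s, extending rightward
            n = _geometric(rng, y)
            s = rng.randrange(m)
            n = min(n, m - s)  # truncate at the sequence end
            for cp in dmap[s : s + n]:
                cols[cp] = _D if cols[cp] == _M else _DEAD
            dmap = np.concatenate([dmap[:s], dmap[s + n :]])
    columns = "".join(_CODE_TO_CHAR[c] for c in cols if c != _DEAD)
    return AlignmentRLE.from_columns(columns)


def extract_gaps(a: AlignmentRLE, G: int) -> tuple[np.ndarray, int, int]:
    """Interval observations (S_I, S_D) between consecutive match columns.

    Returns ``(grid, overflow, n_intervals)`` where ``grid[i, j]`` counts
    interior intervals with i insertions and j deletions, ``overflow``
    counts intervals exceeding G on either axis, and ``n_intervals`` is
    their total. Adjacent match columns contribute (0, 0); runs before the
    first and after the last match column are discarded (end gaps have
    different statistics). Fewer than two match columns yields zero
    observations.
    """
    if G < 1:
        raise ValueError(f"G must be >= 1, got {G}")
    grid = np.zeros((G + 1, G + 1), dtype=np.int64)
    overflow = 0
    n_intervals = 0
    seen_m = False
    cur_i = cur_d = 0
    for c, n in a.runs:
        if c == "M":
            if seen_m:
                if cur_i > G or cur_d > G:
                    overflow += 1
                else:
                    grid[cur_i, cur_d] += 1
                n_intervals += 1
            # adjacent match pairs within the run
            grid[0, 0] += n - 1
            n_intervals += n - 1
            seen_m = True
            cur_i = cur_d = 0
        elif c == "I":
            cur_i += n
        else:
            cur_d += n
    # a trailing non-M stretch is an end gap: discarded with its interval
    return grid, overflow, n_intervals


def simulate_distribution(p: GGIParams, cfg: SimConfig) -> GapDistribution:
    """Empirical gap-length distribution pooled over N replicates.

    Each replicate gets an independent, reproducible RNG stream derived
    from ``cfg.seed`` and the replicate index, so the pooling is invariant
    to execution order. Intervals are pooled with equal weight.
    """
    grid = np.zeros((cfg.G + 1, cfg.G + 1), dtype=np.int64)
    overflow = 0
    n_intervals = 0
    root = np.random.SeedSequence(cfg.seed)
    for child in root.spawn(cfg.N):
        rng = random.Random(int(child.generate_state(1, np.uint64)[0]))
        aln = evolve(p, cfg.L, cfg.t, rng)
        g, o, n = extract_gaps(aln, cfg.G)
        grid += g
        overflow += o
        n_intervals += n
    return GapDistribution(
        P=grid.astype(float), kind="empirical", n_intervals=n_intervals,
        overflow=float(overflow),
    )
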