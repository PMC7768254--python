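"""Parameters and substitution layer of the general geometric indel (GGI) model.

The GGI model is a continuous-time Markov chain on sequences. At any site,
an event inserting ``n`` residues has rate ``lambda * x**(n-1) * (1-x)`` and
an event deleting ``n`` residues has rate ``mu * y**(n-1) * (1-y)``: event
lengths are geometric with means ``1/(1-x)`` and ``1/(1-y)``. Inserted
residues are drawn independently from the stationary distribution ``rho`` of
a point substitution rate matrix ``R``; substitutions act independently of
the indel process, with finite-time probabilities ``M = expm(R t)``.

The sequence-level generator of the full process is never materialized as a
matrix (its state space, the set of all sequences, is infinite); it is
realized operationally by :mod:`geomindel.simulate`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.linalg import expm, null_space

__all__ = [
    "GGIParams",
    "SubstModel",
    "validate_params",
    "indel_event_rate",
    "stationary_distribution",
    "jukes_cantor",
    "hky_like",
]

#: default absolute tolerance for "within tolerance" checks
DEFAULT_TOL = 1e-9


class ParameterError(ValueError):
    """Raised when GGI or substitution parameters are out of range."""


@dataclass(frozen=True)
class GGIParams:
    """Rate and length parameters of the geometric indel process.

    Parameters
    ----------
    lam
        Insertion initiation rate per site (events per unit time), >= 0.
    mu
        Deletion initiation rate per site, >= 0.
    x
        Insertion extension probability in [0, 1); mean insertion
        length is ``1/(1-x)``.
    y
        Deletion extension probability in [0, 1); mean deletion length
        is ``1/(1-y)``.
    """

    lam: float
    mu: float
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lam", "mu", "x", "y"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ParameterError(f"{name} must be finite, got {v!r}")
        if self.lam < 0 or self.mu < 0:
            raise ParameterError(
                f"rates must be nonnegative: lambda={self.lam}, mu={self.mu}"
            )
        if not (0.0 <= self.x < 1.0):
            raise ParameterError(
                f"insertion extension x must lie in [0, 1), got {self.x}"
            )
        if not (0.0 <= self.y < 1.0):
            raise ParameterError(
                f"deletion extension y must lie in [0, 1), got {self.y}"
            )

    @property
    def total_rate(self) -> float:
        """Total indel initiation rate per site, ``lambda + mu``."""
        return self.lam + self.mu

    def reversible(self, tol: float = DEFAULT_TOL) -> bool:
        """True iff the detailed-balance condition λy(1−x) = μx(1−y) holds."""
        return abs(self.lam * self.y * (1 - self.x) - self.mu * self.x * (1 - self.y)) <= tol

    def mean_insertion_length(self) -> float:
        return 1.0 / (1.0 - self.x)

    def mean_deletion_length(self) -> float:
        return 1.0 / (1.0 - self.y)


def validate_params(lam: float, mu: float, x: float, y: float) -> GGIParams:
    """Validate GGI parameters, returning a :class:`GGIParams` container.

    Raises :class:`ParameterError` for negative rates or extension
    probabilities outside [0, 1) (at ``x == 1`` the mean event length
    diverges).
    """
    return GGIParams(float(lam), float(mu), float(x), float(y))


def indel_event_rate(p: GGIParams, kind: str, n: int) -> float:
    """Rate of an indel event of length ``n``.

    ``lambda * x**(n-1) * (1-x)`` for insertions, ``mu * y**(n-1) * (1-y)``
    for deletions. Summed over all ``n >= 1`` these give back ``lambda``
    (resp. ``mu``).
    """
    if n < 1:
        raise ParameterError(f"indel event length must be >= 1, got {n}")
    if kind == "ins":
        return p.lam * self_pow(p.x, n - 1) * (1.0 - p.x)
    if kind == "del":
        return p.mu * self_pow(p.y, n - 1) * (1.0 - p.y)
    raise ParameterError(f"kind must be 'ins' or 'del', got {kind!r}")


def self_pow(base: float, k: int) -> float:
    # 0**0 == 1 by the geometric-law convention (single-residue events)
    return 1.0 if k == 0 else base**k


# ---------------------------------------------------------------------------
# substitution layer


def stationary_distribution(R: np.ndarray, tol: float = DEFAULT_TOL) -> np.ndarray:
    """Stationary distribution ``rho`` of a substitution rate matrix, ρR = 0.

    Raises :class:`ParameterError` if the stationary vector is not unique
    (reducible generator) or not a probability vector.
    """
    R = np.asarray(R, dtype=float)
    _check_rate_matrix(R, tol)
    ns = null_space(R.T, rcond=1e-10)
    if ns.shape[1] != 1:
        raise ParameterError(
            "stationary distribution is not unique: the rate matrix has a "
            f"{ns.shape[1]}-dimensional left null space (reducible generator?)"
        )
    rho = ns[:, 0]
    rho = rho / rho.sum()
    if np.any(rho < -tol):
        raise ParameterError("stationary vector has negative entries")
    return np.clip(rho, 0.0, None)


def _check_rate_matrix(R: np.ndarray, tol: float = DEFAULT_TOL) -> None:
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ParameterError(f"rate matrix must be square, got shape {R.shape}")
    off = R - np.diag(np.diag(R))
    if np.any(off < -tol):
        raise ParameterError("off-diagonal rate matrix entries must be >= 0")
    rowsums = R.sum(axis=1)
    if np.any(np.abs(rowsums) > max(tol, 1e-9 * np.abs(R).max())):
        raise ParameterError("rate matrix rows must sum to 0")


@dataclass(frozen=True)
class SubstModel:
    """A point substitution model: ordered alphabet, rate matrix, and ρ.

    ``rho`` defaults to the stationary distribution of ``R``.
    """

    alphabet: tuple[str, ...]
    R: np.ndarray
    rho: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphabet", tuple(self.alphabet))
        R = np.asarray(self.R, dtype=float)
        _check_rate_matrix(R)
        if len(self.alphabet) != R.shape[0]:
            raise ParameterError("alphabet size does not match rate matrix")
        object.__setattr__(self, "R", R)
        rho = self.rho
        if rho is None:
            rho = stationary_distribution(R)
        else:
            rho = np.asarray(rho, dtype=float)
            if rho.shape != (R.shape[0],) or np.any(rho < 0):
                raise ParameterError("rho must be a nonnegative vector over the alphabet")
            if abs(rho.sum() - 1.0) > 1e-9:
                raise ParameterError("rho must sum to 1")
            if np.max(np.abs(rho @ R)) > 1e-8 * max(1.0, np.abs(R).max()):
                raise ParameterError("rho is not stationary: ||rho R|| too large")
        object.__setattr__(self, "rho", rho)

    @property
    def size(self) -> int:
        return len(self.alphabet)

    def index(self, symbol: str) -> int:
        try:
            return self.alphabet.index(symbol)
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in alphabet {self.alphabet}") from None

    def encode(self, seq: Sequence[str]) -> np.ndarray:
        """Map a sequence of symbols to alphabet indices (error names position)."""
        out = np.empty(len(seq), dtype=np.intp)
        for i, s in enumerate(seq):
            try:
                out[i] = self.alphabet.index(s)
            except ValueError:
                raise ParameterError(
                    f"symbol {s!r} at position {i} is not in the model alphabet"
                ) from None
        return out

    def substitution_probs(self, t: float) -> np.ndarray:
        """Finite-time substitution matrix ``M = expm(R t)`` (row-stochastic)."""
        if t < 0:
            raise ParameterError(f"time must be >= 0, got {t}")
        return expm(self.R * t)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphabet": list(self.alphabet),
                "rate_matrix": self.R.tolist(),
                "rho": self.rho.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SubstModel":
        d = json.loads(text)
        return cls(
            alphabet=tuple(d["alphabet"]),
            R=np.array(d["rate_matrix"], dtype=float),
            rho=np.array(d["rho"], dtype=float) if d.get("rho") is not None else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "SubstModel":
        return cls.from_json(Path(path).read_text())


def jukes_cantor(rate: float = 1.0, alphabet: str = "ACGT") -> SubstModel:
    """Symmetric one-parameter model: all exchanges at equal rate.

    ``rate`` is the total substitution rate per site.
    """
    k = len(alphabet)
    r = rate / (k - 1)
    R = np.full((k, k), r)
    np.fill_diagonal(R, -rate)
    return SubstModel(tuple(alphabet), R)


def hky_like(rho: Sequence[float], rate: float = 1.0, alphabet: str = "ACGT") -> SubstModel:
    """A reversible model with prescribed stationary distribution.

    Exchangeabilities are uniform (an F81-style construction), scaled so the
    expected substitution rate at stationarity is ``rate``.
    """
    rho = np.asarray(rho, dtype=float)
    rho = rho / rho.sum()
    k = len(rho)
    if len(alphabet) != k:
        raise ParameterError("alphabet size does not match rho")
    R = np.tile(rho, (k, 1)).astype(float)
    np.fill_diagonal(R, 0.0)
    np.fill_diagonal(R, -R.sum(axis=1))
    scale = -float(rho @ np.diag(R))
    R = R * (rate / scale)
    return SubstModel(tuple(alphabet), R, rho)
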