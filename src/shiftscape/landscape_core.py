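"""Fitness landscapes, substitution rate matrices and stationary distributions.

The substitution process at a single position is a continuous-time Markov
chain over the alphabet.  A landscape is a vector of population-size-scaled
additive fitness values, one per allele (``F_i = 2 N f_i``).  Together with a
matrix ``M`` of relative mutation rates it determines the instantaneous
substitution rate from allele ``i`` to allele ``j`` through the classical
mutation-selection (Halpern-Bruno style) fixation factor

    ``q_ij = M_ij * (F_j - F_i) / (1 - exp(F_i - F_j))``   for ``i != j``,

which reduces to the neutral rate ``M_ij`` when ``F_i == F_j``.  Diagonal
entries are set so that each row sums to zero.

The stationary distribution ``pi`` of that chain satisfies ``pi Q = 0`` with
``sum(pi) = 1``.  When every mutation rate equals 1 the chain is reversible
with the Boltzmann form ``pi_i = exp(F_i) / sum_j exp(F_j)`` (a softmax of
the fitnesses); in general ``pi`` is obtained by a linear solve.

Three scalings of ``Q`` are supported:

``raw``
    the matrix exactly as produced by the formula above;
``normalized`` (default)
    ``Q`` divided by the expected substitution rate ``-sum_i pi_i q_ii`` so
    one substitution is expected per position per unit branch length;
``flat_scaled``
    ``Q`` divided by ``|A| - 1``, which normalizes only the neutral (flat)
    landscape and lets selection slow the clock below 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Alphabet",
    "FitnessVector",
    "MutationMatrix",
    "RateMatrix",
    "StationaryDistribution",
    "build_raw_rate_matrix",
    "stationary_distribution",
    "rescale_rate_matrix",
    "expected_substitution_rate",
    "build_rate_system",
]

#: Below this |F_i - F_j| the fixation factor is replaced by its neutral
#: limit to avoid catastrophic cancellation in (F_j-F_i)/(1-exp(F_i-F_j)).
DEGENERATE_FITNESS_DIFF = 1e-9

ScalingMode = Literal["raw", "normalized", "flat_scaled"]

_SCALING_MODES = ("raw", "normalized", "flat_scaled")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of distinct single-character allele symbols."""

    symbols: tuple[str, ...]

    def __init__(self, symbols: Iterable[str]):
        syms = tuple(symbols)
        if len(syms) < 2:
            raise ValueError("alphabet needs at least 2 symbols, got %d" % len(syms))
        if any(len(s) != 1 for s in syms):
            bad = [s for s in syms if len(s) != 1]
            raise ValueError(f"alphabet symbols must be single characters: {bad!r}")
        if len(set(syms)) != len(syms):
            dupes = sorted({s for s in syms if syms.count(s) > 1})
            raise ValueError(f"duplicate alphabet symbols: {dupes!r}")
        object.__setattr__(self, "symbols", syms)

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in alphabet {''.join(self.symbols)!r}") from None

    def encode(self, sequence: str) -> np.ndarray:
        """Map a string of symbols to an integer index array."""
        lookup = {s: i for i, s in enumerate(self.symbols)}
        try:
            return np.array([lookup[c] for c in sequence], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(
                f"symbol {exc.args[0]!r} not in alphabet {''.join(self.symbols)!r}"
            ) from None

    def decode(self, indices: Sequence[int]) -> str:
        return "".join(self.symbols[i] for i in indices)

    @classmethod
    def dna(cls) -> "Alphabet":
        return cls("ACGT")

    @classmethod
    def protein(cls) -> "Alphabet":
        return cls("ACDEFGHIKLMNPQRSTVWY")


def _as_checked_array(values, alphabet: Alphabet, what: str, shape) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != shape:
        raise ValueError(
            f"{what} shape {arr.shape} does not match alphabet of size {alphabet.size}"
        )
    return arr


@dataclass(frozen=True)
class FitnessVector:
    """Scaled additive fitness per allele (dimensionless, any finite real)."""

    values: np.ndarray
    alphabet: Alphabet

    def __post_init__(self):
        arr = _as_checked_array(self.values, self.alphabet, "fitness vector", (self.alphabet.size,))
        if not np.all(np.isfinite(arr)):
            raise ValueError("fitness values must all be finite")
        object.__setattr__(self, "values", arr)

    def with_values(self, values: np.ndarray) -> "FitnessVector":
        return FitnessVector(values, self.alphabet)


@dataclass(frozen=True)
class MutationMatrix:
    """Relative mutation rates between alleles; the diagonal is unused."""

    rates: np.ndarray
    alphabet: Alphabet

    def __post_init__(self):
        n = self.alphabet.size
        arr = _as_checked_array(self.rates, self.alphabet, "mutation matrix", (n, n))
        off = ~np.eye(n, dtype=bool)
        if np.any(arr[off] < 0) or not np.all(np.isfinite(arr[off])):
            raise ValueError("off-diagonal mutation rates must be finite and >= 0")
        object.__setattr__(self, "rates", arr)

    @classmethod
    def uniform(cls, alphabet: Alphabet) -> "MutationMatrix":
        """The default matrix with every entry equal to 1."""
        n = alphabet.size
        return cls(np.ones((n, n)), alphabet)

    @property
    def is_uniform(self) -> bool:
        """True when every off-diagonal rate is exactly 1 (the default)."""
        n = self.alphabet.size
        off = ~np.eye(n, dtype=bool)
        return bool(np.all(self.rates[off] == 1.0))


@dataclass(frozen=True)
class RateMatrix:
    """Instantaneous substitution rates with zero row sums."""

    rates: np.ndarray
    scaling_mode: ScalingMode
    alphabet: Alphabet

    def __post_init__(self):
        n = self.alphabet.size
        arr = _as_checked_array(self.rates, self.alphabet, "rate matrix", (n, n))
        if self.scaling_mode not in _SCALING_MODES:
            raise ValueError(f"unknown scaling mode {self.scaling_mode!r}")
        off = ~np.eye(n, dtype=bool)
        if np.any(arr[off] < 0):
            raise ValueError("off-diagonal substitution rates must be >= 0")
        if np.any(np.abs(arr.sum(axis=1)) > 1e-10):
            raise ValueError("rate matrix rows must sum to 0")
        object.__setattr__(self, "rates", arr)

    @property
    def exit_rates(self) -> np.ndarray:
        """Total rate of leaving each allele, ``-q_ii``."""
        return -np.diag(self.rates)


@dataclass(frozen=True)
class StationaryDistribution:
    """Long-run allele frequencies of the substitution chain."""

    probs: np.ndarray
    alphabet: Alphabet

    def __post_init__(self):
        arr = _as_checked_array(self.probs, self.alphabet, "stationary distribution", (self.alphabet.size,))
        if np.any(arr < -1e-12):
            raise ValueError("stationary probabilities must be nonnegative")
        arr = np.clip(arr, 0.0, None)
        if abs(arr.sum() - 1.0) > 1e-10:
            raise ValueError("stationary probabilities must sum to 1")
        object.__setattr__(self, "probs", arr / arr.sum())


def _check_same_alphabet(*objs) -> Alphabet:
    alphabets = {o.alphabet.symbols for o in objs}
    if len(alphabets) != 1:
        raise ValueError("fitness vector, mutation matrix and rate matrix must share one alphabet")
    return objs[0].alphabet


def raw_rates(F: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Raw rate array for fitness values ``F`` and mutation rates ``M``.

    Array-level workhorse behind :func:`build_raw_rate_matrix`; used directly
    in hot loops where constructing the wrapper objects would dominate.
    """
    F = np.asarray(F, dtype=float)
    diff = F[None, :] - F[:, None]  # diff[i, j] = F_j - F_i
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        factor = diff / (1.0 - np.exp(-diff))
    near = np.abs(diff) < DEGENERATE_FITNESS_DIFF
    factor[near] = 1.0
    q = M * factor
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def build_raw_rate_matrix(F: FitnessVector, M: MutationMatrix) -> RateMatrix:
    """Convert a fitness vector and mutation matrix into the raw rate matrix.

    Off-diagonal entries follow the fixation-factor formula, with the neutral
    limit ``q_ij = M_ij`` applied whenever ``|F_i - F_j|`` falls below
    :data:`DEGENERATE_FITNESS_DIFF`; each diagonal entry is the negative of
    its row's off-diagonal sum.
    """
    alphabet = _check_same_alphabet(F, M)
    return RateMatrix(raw_rates(F.values, M.rates), "raw", alphabet)


def softmax_probs(F: np.ndarray) -> np.ndarray:
    z = np.exp(F - np.max(F))
    return z / z.sum()


def _check_irreducible(M: MutationMatrix) -> None:
    n = M.alphabet.size
    adj = (M.rates > 0) & ~np.eye(n, dtype=bool)
    ncomp, labels = connected_components(csr_matrix(adj), directed=True, connection="strong")
    if ncomp > 1:
        groups: dict[int, list[str]] = {}
        for sym, lab in zip(M.alphabet.symbols, labels):
            groups.setdefault(int(lab), []).append(sym)
        detail = "; ".join("{" + ",".join(g) + "}" for g in groups.values())
        raise ValueError(
            "mutation matrix is reducible: alleles fall into disconnected "
            f"groups {detail}; the stationary distribution is not unique"
        )


def solve_stationary(Q: np.ndarray) -> np.ndarray:
    """Solve ``pi Q = 0, sum(pi) = 1`` by least squares on the augmented system."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def stationary_distribution(
    F: FitnessVector,
    M: MutationMatrix,
    Q: Optional[RateMatrix] = None,
) -> StationaryDistribution:
    """Stationary distribution of the chain built from ``(F, M)``.

    With the default all-ones mutation matrix the closed-form softmax
    ``pi_i = exp(F_i) / sum_j exp(F_j)`` is used; otherwise ``pi Q = 0`` is
    solved as the null space of ``Q^T`` augmented with the normalization row.
    A reducible mutation matrix (some allele unreachable) is reported as an
    error naming the disconnected symbol groups.
    """
    alphabet = _check_same_alphabet(F, M)
    _check_irreducible(M)
    if M.is_uniform:
        probs = softmax_probs(F.values)
    else:
        if Q is None:
            Q = build_raw_rate_matrix(F, M)
        probs = solve_stationary(Q.rates)
    if Q is not None:
        resid = probs @ Q.rates
        scale = max(1.0, float(np.max(np.abs(Q.rates))))
        if np.max(np.abs(resid)) > 1e-8 * scale:
            raise ValueError("stationary solve failed: pi Q != 0 (ill-conditioned system)")
    return StationaryDistribution(probs, alphabet)


def expected_substitution_rate(Q: RateMatrix, pi: StationaryDistribution) -> float:
    """Expected substitutions per position per unit time, ``-sum_i pi_i q_ii``."""
    return float(-np.dot(pi.probs, np.diag(Q.rates)))


def rescale_rate_matrix(
    Qraw: RateMatrix,
    pi: StationaryDistribution,
    mode: ScalingMode = "normalized",
) -> RateMatrix:
    """Rescale a raw rate matrix.

    ``normalized`` divides by the expected substitution rate under ``pi`` so
    the clock ticks at one substitution per position per unit branch length;
    ``flat_scaled`` divides by ``|A| - 1`` (the flat landscape's expected
    rate), and ``raw`` returns the input unchanged.
    """
    if mode == "raw":
        return Qraw
    if mode == "normalized":
        rate = expected_substitution_rate(Qraw, pi)
        if rate <= 1e-300:
            raise ValueError("cannot normalize: expected substitution rate is zero")
        return RateMatrix(Qraw.rates / rate, "normalized", Qraw.alphabet)
    if mode == "flat_scaled":
        return RateMatrix(Qraw.rates / (Qraw.alphabet.size - 1), "flat_scaled", Qraw.alphabet)
    raise ValueError(f"unknown scaling mode {mode!r}")


def build_rate_system(
    F: FitnessVector,
    M: MutationMatrix,
    mode: ScalingMode = "normalized",
) -> tuple[RateMatrix, StationaryDistribution]:
    """Build ``(Q, pi)`` for a landscape in one call; ``Q`` carries ``mode``."""
    Qraw = build_raw_rate_matrix(F, M)
    pi = stationary_distribution(F, M, Qraw)
    return rescale_rate_matrix(Qraw, pi, mode), pi
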