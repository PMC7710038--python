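"""Creating the initial fitness landscape and deriving replacements.

The initial landscape is either read from a file or drawn i.i.d. per allele
from a gamma(shape, scale) or lognormal(mu, sigma) distribution (sigma and
mu parameterize the underlying normal).  When the landscape changes, the new
vector is produced by one of five rules:

``resample``
    fresh i.i.d. draws from the same distribution as the initial vector;
``permute``
    a uniform random permutation of the previous vector's values (the
    identity permutation is possible);
``explicit``
    the next user-supplied vector, taken verbatim;
``increase_current`` / ``decrease_current``
    the previous vector with the fitness of the allele currently occupying
    the position shifted by ``+delta`` / ``-delta`` (additive, on the scaled
    fitness axis); all other entries untouched.  These two rules only make
    sense for a landscape governing a single position, where "the current
    allele" is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .landscape_core import Alphabet, FitnessVector

__all__ = ["InitSource", "LandscapeRule", "sample_fitness_vector", "derive_new_landscape"]

_CHANGE_RULES = ("none", "resample", "permute", "explicit", "increase_current", "decrease_current")


@dataclass(frozen=True)
class InitSource:
    """Where the initial fitness vector comes from.

    kind is "file" (vector supplied by the caller), "gamma" or "lognormal".
    For gamma, params are (shape, scale); for lognormal, (mu, sigma) of the
    underlying normal.
    """

    kind: str
    params: tuple[float, float] = (0.0, 0.0)
    vector: Optional[FitnessVector] = None

    def __post_init__(self):
        if self.kind not in ("file", "gamma", "lognormal", "flat"):
            raise ValueError(f"unknown initial-landscape source {self.kind!r}")
        if self.kind == "gamma":
            shape, scale = self.params
            if shape <= 0 or scale <= 0:
                raise ValueError(f"gamma parameters must be positive, got shape={shape}, scale={scale}")
        elif self.kind == "lognormal":
            _, sigma = self.params
            if sigma <= 0:
                raise ValueError(f"lognormal sigma must be positive, got {sigma}")
        elif self.kind == "file" and self.vector is None:
            raise ValueError("file-based initial landscape requires the vector")

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "InitSource":
        return cls("gamma", (shape, scale))

    @classmethod
    def lognormal(cls, mu: float, sigma: float) -> "InitSource":
        return cls("lognormal", (mu, sigma))

    @classmethod
    def fixed(cls, vector: FitnessVector) -> "InitSource":
        return cls("file", vector=vector)

    @classmethod
    def flat(cls) -> "InitSource":
        """All-zero fitness vector: every substitution is neutral."""
        return cls("flat")


@dataclass(frozen=True)
class LandscapeRule:
    """Initial-landscape source plus the rule applied at every change."""

    init_source: InitSource
    change_rule: str = "none"
    delta: Optional[float] = None
    explicit_vectors: Optional[tuple[FitnessVector, ...]] = None

    def __post_init__(self):
        if self.change_rule not in _CHANGE_RULES:
            raise ValueError(
                f"unknown change rule {self.change_rule!r}; expected one of {_CHANGE_RULES}"
            )
        if self.change_rule in ("increase_current", "decrease_current"):
            if self.delta is None or self.delta <= 0:
                raise ValueError(f"{self.change_rule} requires a positive delta")
        elif self.delta is not None:
            raise ValueError(f"delta is only meaningful for increase_current/decrease_current")
        if self.change_rule == "explicit":
            if not self.explicit_vectors:
                raise ValueError("explicit change rule requires explicit_vectors")
        elif self.explicit_vectors:
            raise ValueError("explicit_vectors are only allowed with the explicit change rule")


def sample_fitness_vector(rule: LandscapeRule, alphabet: Alphabet, rng: np.random.Generator) -> FitnessVector:
    """Draw the initial fitness vector for ``alphabet`` under ``rule``."""
    src = rule.init_source
    if src.kind == "file":
        if src.vector.alphabet.symbols != alphabet.symbols:
            raise ValueError("initial fitness vector alphabet does not match the configured alphabet")
        return src.vector
    if src.kind == "flat":
        return FitnessVector(np.zeros(alphabet.size), alphabet)
    if src.kind == "gamma":
        shape, scale = src.params
        values = rng.gamma(shape, scale, size=alphabet.size)
    else:  # lognormal
        mu, sigma = src.params
        values = rng.lognormal(mu, sigma, size=alphabet.size)
    return FitnessVector(values, alphabet)


def derive_new_landscape(
    rule: LandscapeRule,
    previous: FitnessVector,
    current_allele: Optional[int],
    change_index: int,
    rng: np.random.Generator,
) -> FitnessVector:
    """Produce the landscape instated by change number ``change_index`` (0-based).

    ``current_allele`` is the index of the allele occupying the position at
    the moment of the change; it is required by (and only by) the
    increase_current / decrease_current rules.
    """
    kind = rule.change_rule
    if kind == "resample":
        return sample_fitness_vector(
            LandscapeRule(rule.init_source), previous.alphabet, rng
        )
    if kind == "permute":
        return previous.with_values(rng.permutation(previous.values))
    if kind == "explicit":
        if change_index >= len(rule.explicit_vectors):
            raise ValueError(
                f"explicit landscape list exhausted: change {change_index + 1} requested "
                f"but only {len(rule.explicit_vectors)} vectors were supplied"
            )
        vec = rule.explicit_vectors[change_index]
        if vec.alphabet.symbols != previous.alphabet.symbols:
            raise ValueError("explicit fitness vector alphabet mismatch")
        return vec
    if kind in ("increase_current", "decrease_current"):
        if current_allele is None:
            raise ValueError(f"{kind} requires the allele currently occupying the position")
        sign = 1.0 if kind == "increase_current" else -1.0
        values = previous.values.copy()
        values[current_allele] += sign * rule.delta
        return previous.with_values(values)
    raise ValueError(f"change rule {kind!r} does not generate new landscapes")
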