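"""Prior specifications for transmission and mutation parameters.

Each scalar parameter gets either a ``Uniform(lo, hi)`` prior or a ``Fixed``
value; fixed parameters bypass sampling but still enter every density (as a
point mass).  A prior configuration is a plain mapping from parameter name
(e.g. ``"d"``, ``"q12"``) to one of these.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Uniform", "Fixed", "sample_params", "param_means"]


@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"uniform prior needs lo < hi, got ({self.lo}, {self.hi})")

    @property
    def fixed(self) -> bool:
        return False

    @property
    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.lo, self.hi))

    def contains(self, x: float) -> bool:
        return self.lo <= x <= self.hi

    def reflect(self, x: float) -> float:
        """Reflect a random-walk proposal back into [lo, hi]."""
        width = self.hi - self.lo
        y = (x - self.lo) % (2.0 * width)
        if y > width:
            y = 2.0 * width - y
        return self.lo + y


@dataclass(frozen=True)
class Fixed:
    value: float

    @property
    def fixed(self) -> bool:
        return True

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator) -> float:
        return self.value

    def contains(self, x: float) -> bool:
        return x == self.value


def sample_params(priors: dict, rng: np.random.Generator) -> dict[str, float]:
    return {name: pr.sample(rng) for name, pr in priors.items()}


def param_means(priors: dict) -> dict[str, float]:
    return {name: pr.mean for name, pr in priors.items()}
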