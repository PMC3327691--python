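"""Theoretical log R ratio (LRR) per copy state and the intensity noise model.

The LRR is log2 of total allelic intensity relative to a two-copy
reference: 0 for two copies, -1 for one, log2(3/2) for three, log2(4/2)=1
for four.  The zero-copy value tends to minus infinity in theory but stays
finite in practice because of background intensity; we represent it with a
configurable floor.  Real arrays show damped means (about half the
theoretical values) and additive Gaussian noise Z_o = Z + Delta_Z whose sd
is near 0.15 for high-quality DNA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["LRRModel", "theoretical_lrr", "simulate_lrr", "theoretical_preset", "array_preset"]

#: Theoretical LRR means for states 1..4 (state 0 is the configurable floor).
_THEORETICAL_MEANS = (-1.0, 0.0, math.log2(3 / 2), 1.0)


@dataclass(frozen=True)
class LRRModel:
    """Per-state LRR means with damping and additive Gaussian noise.

    Parameters
    ----------
    damping
        Multiplicative shrinkage of the theoretical means as seen on real
        arrays; in (0, 1].
    noise_sd
        Standard deviation of the measurement noise Delta_Z (log2 units).
    floor
        Finite stand-in for the zero-copy theoretical mean (which diverges
        to minus infinity without background intensity).
    """

    damping: float = 1.0
    noise_sd: float = 0.15
    floor: float = -2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.damping <= 1.0:
            raise ValueError("damping must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.floor > -1.0:
            raise ValueError("zero-copy floor must not exceed the one-copy mean")

    @property
    def state_means(self) -> np.ndarray:
        """Undamped LRR means z0..z4 (z0 is the floor)."""
        return np.array([self.floor, *_THEORETICAL_MEANS])

    def damped_means(self) -> np.ndarray:
        """Expected observed LRR per copy state 0..4."""
        return self.damping * self.state_means


def theoretical_preset() -> LRRModel:
    """Undamped theoretical means (damping 1)."""
    return LRRModel(damping=1.0, noise_sd=0.15)


def array_preset() -> LRRModel:
    """Array-realistic preset: damping 0.5, noise sd 0.15.

    This is the configuration behind every reproduced power number.
    """
    return LRRModel(damping=0.5, noise_sd=0.15)


def theoretical_lrr(state: int | np.ndarray, model: LRRModel) -> float | np.ndarray:
    """Damped noise-free LRR for integer copy state(s) in {0..4}."""
    s = np.asarray(state)
    if s.size and (s.min() < 0 or s.max() > 4):
        raise ValueError("copy state must lie in {0..4}")
    out = model.damped_means()[s]
    return float(out) if np.isscalar(state) else out


def simulate_lrr(
    states: np.ndarray, model: LRRModel, rng: np.random.Generator
) -> np.ndarray:
    """Independent Gaussian LRR draws conditional on copy state.

    Each value is N(damping * z_state, noise_sd^2).
    """
    means = theoretical_lrr(np.asarray(states), model)
    return rng.normal(means, model.noise_sd)
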