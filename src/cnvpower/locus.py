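"""CNV locus genotype distributions and the call-error model.

A biallelic or multiallelic CNV locus segregates a deletion allele (zero
copies on one chromosome), the normal allele (one copy), and optionally a
duplication allele (two copies).  Under Hardy-Weinberg equilibrium the true
integer copy number ``X`` of a diploid individual is the sum of the two
parental allele copy counts and lives on ``{0, 1, 2, 3, 4}``.

HMM-based callers make two kinds of errors that we model here: a false
negative (a true non-reference state called as the reference state 2, rate
``nu_n``) and a false positive (a true 2 called as some non-reference state,
rate ``nu_p``).  Mis-assignment between non-reference states is deliberately
not modelled.  The call error is ``Delta = X_o - X`` where ``X_o`` is the
called state; its closed-form moments quantify the variance a caller injects
into downstream association tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "STATES",
    "LocusModel",
    "ErrorRates",
    "JointCallDistribution",
    "DeltaMoments",
    "make_locus_model",
    "joint_call_distribution",
    "delta_moments",
    "sd_delta_table",
    "equivalence_contour",
    "sample_observed_calls",
]

#: Integer copy-number state space shared by X and X_o.
STATES = np.arange(5)

_REF = 2  # reference (normal diploid) copy number


@dataclass(frozen=True)
class LocusModel:
    """Population frequencies of the true copy states 0..4 at one locus.

    Parameters
    ----------
    kind
        ``"deletion"``, ``"duplication"`` or ``"multiallelic"``.
    freqs
        Probabilities ``g0..g4`` of true copy states 0..4; must sum to 1.
    """

    kind: str
    freqs: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        g = np.asarray(self.freqs, dtype=float)
        if g.shape != (5,):
            raise ValueError("freqs must have exactly 5 entries (states 0..4)")
        if (g < 0).any():
            raise ValueError("genotype frequencies must be non-negative")
        if abs(g.sum() - 1.0) > 1e-12:
            raise ValueError(f"genotype frequencies must sum to 1, got {g.sum()!r}")
        if self.kind not in ("deletion", "duplication", "multiallelic"):
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if self.kind == "deletion" and (g[3] != 0 or g[4] != 0):
            raise ValueError("deletion locus cannot carry states 3 or 4")
        if self.kind == "duplication" and (g[0] != 0 or g[1] != 0):
            raise ValueError("duplication locus cannot carry states 0 or 1")
        if g[2] <= 0:
            raise ValueError("reference state must have positive frequency")
        object.__setattr__(self, "freqs", tuple(float(x) for x in g))

    @property
    def g(self) -> np.ndarray:
        return np.asarray(self.freqs, dtype=float)

    @property
    def nonref_mass(self) -> float:
        """Total probability of non-reference states (1 - g2)."""
        return 1.0 - self.freqs[_REF]


@dataclass(frozen=True)
class ErrorRates:
    """False-positive (``nu_p``) and false-negative (``nu_n``) call rates."""

    nu_p: float
    nu_n: float

    def __post_init__(self) -> None:
        for name in ("nu_p", "nu_n"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class JointCallDistribution:
    """5x5 joint law P(X = j, X_o = k) of true and called copy state."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (5, 5):
            raise ValueError("joint table must be 5x5")
        if (p < -1e-15).any():
            raise ValueError("joint probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("joint probabilities must sum to 1")
        object.__setattr__(self, "probs", p)

    def marginal_true(self) -> np.ndarray:
        """Marginal distribution of X (rows)."""
        return self.probs.sum(axis=1)

    def marginal_observed(self) -> np.ndarray:
        """Marginal distribution of X_o (columns)."""
        return self.probs.sum(axis=0)

    def conditional_observed(self) -> np.ndarray:
        """Row-stochastic matrix P(X_o = k | X = j); rows with g_j = 0 get identity."""
        g = self.marginal_true()
        cond = np.eye(5)
        nz = g > 0
        cond[nz] = self.probs[nz] / g[nz, None]
        return cond


@dataclass(frozen=True)
class DeltaMoments:
    """Mean, variance and sd of the call error Delta = X_o - X."""

    mean: float
    variance: float
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if self.variance < -1e-15:
            raise ValueError("variance must be non-negative")
        object.__setattr__(self, "variance", max(self.variance, 0.0))
        object.__setattr__(self, "sd", math.sqrt(self.variance))


def make_locus_model(kind: str, *allele_freqs: float) -> LocusModel:
    """Build a Hardy-Weinberg locus from per-chromosome variant allele frequencies.

    The per-chromosome alleles are deletion (0 copies), normal (1 copy) and
    duplication (2 copies); a diploid genotype is the sum of two independent
    draws.  A ``deletion`` or ``duplication`` locus takes one allele
    frequency ``q``; a ``multiallelic`` locus takes ``q_del, q_dup``.  The
    deletion/duplication heterozygote (0 + 2 copies) counts as true state 2.

    Examples
    --------
    >>> make_locus_model("deletion", 0.1).freqs
    (0.010000000000000002, 0.18000000000000002, 0.81, 0.0, 0.0)
    """
    for q in allele_freqs:
        if not 0.0 <= q <= 0.5:
            raise ValueError(f"variant allele frequency must lie in [0, 0.5], got {q!r}")
    if kind in ("deletion", "duplication"):
        if len(allele_freqs) != 1:
            raise ValueError(f"{kind} locus takes exactly one allele frequency")
        (q,) = allele_freqs
        hw = (q * q, 2.0 * q * (1.0 - q), (1.0 - q) ** 2)  # 0, 1, 2 variant alleles
        if kind == "deletion":
            freqs = (hw[0], hw[1], hw[2], 0.0, 0.0)
        else:
            freqs = (0.0, 0.0, hw[2], hw[1], hw[0])
    elif kind == "multiallelic":
        if len(allele_freqs) != 2:
            raise ValueError("multiallelic locus takes (q_del, q_dup)")
        qd, qu = allele_freqs
        qn = 1.0 - qd - qu
        if qn < 0:
            raise ValueError("allele frequencies sum above 1")
        # trinomial HWE over per-chromosome copies {0, 1, 2}; X = sum
        freqs = (
            qd * qd,
            2.0 * qd * qn,
            qn * qn + 2.0 * qd * qu,  # includes the del/dup heterozygote
            2.0 * qu * qn,
            qu * qu,
        )
    else:
        raise ValueError(f"unknown locus kind {kind!r}")
    return LocusModel(kind=kind, freqs=freqs)


def _check_fp_destination(locus: LocusModel, rates: ErrorRates) -> None:
    if rates.nu_p > 0 and locus.nonref_mass <= 0:
        raise ValueError(
            "nu_p > 0 requires a locus with non-reference mass: false positives "
            "are redistributed over non-reference states"
        )


def joint_call_distribution(locus: LocusModel, rates: ErrorRates) -> JointCallDistribution:
    """Joint law of (X, X_o) under the two-error call model.

    A true non-reference state ``j`` is called 2 with probability ``nu_n``
    and correctly otherwise.  A true 2 is mis-called with probability
    ``nu_p``; the destination non-reference state is drawn proportionally to
    the population genotype frequencies ``g_k / (1 - g2)``.  No other
    transitions occur.
    """
    _check_fp_destination(locus, rates)
    g = locus.g
    p = np.zeros((5, 5))
    for j in range(5):
        if j == _REF:
            continue
        p[j, j] = g[j] * (1.0 - rates.nu_n)
        p[j, _REF] = g[j] * rates.nu_n
    g2 = g[_REF]
    p[_REF, _REF] = g2 * (1.0 - rates.nu_p)
    if rates.nu_p > 0:
        dest = g / locus.nonref_mass
        for k in range(5):
            if k != _REF:
                p[_REF, k] = g2 * rates.nu_p * dest[k]
    return JointCallDistribution(probs=p)


def delta_moments(locus: LocusModel, rates: ErrorRates) -> DeltaMoments:
    """Closed-form mean and variance of Delta = X_o - X.

    With ``S1 = sum_{k != 2} g_k (2 - k)``, ``S2 = sum_{k != 2} g_k (2 - k)^2``
    and ``r = g2 / (1 - g2)``::

        E[Delta]   = (nu_n - nu_p * r) * S1
        E[Delta^2] = (nu_n + nu_p * r) * S2

    For a degenerate locus with no non-reference mass both moments are zero
    (and ``nu_p > 0`` is rejected, as false positives would have no
    destination state).
    """
    if rates.nu_p > 0:
        _check_fp_destination(locus, rates)
    g = locus.g
    k = STATES
    mask = k != _REF
    s1 = float(np.sum(g[mask] * (_REF - k[mask])))
    s2 = float(np.sum(g[mask] * (_REF - k[mask]) ** 2))
    if locus.nonref_mass > 0:
        r = g[_REF] / locus.nonref_mass
    else:
        r = 0.0
    mean = (rates.nu_n - rates.nu_p * r) * s1
    second = (rates.nu_n + rates.nu_p * r) * s2
    return DeltaMoments(mean=mean, variance=second - mean * mean)


def delta_moments_from_joint(joint: JointCallDistribution) -> DeltaMoments:
    """Moments of Delta by direct summation over the 25-cell joint table.

    Independent of the closed forms; used to cross-validate them.
    """
    j, k = np.meshgrid(STATES, STATES, indexing="ij")
    d = (k - j).astype(float)
    mean = float(np.sum(joint.probs * d))
    second = float(np.sum(joint.probs * d * d))
    return DeltaMoments(mean=mean, variance=second - mean * mean)


def sd_delta_table(
    locus: LocusModel,
    nu_n_list: Iterable[float],
    nu_p_list: Iterable[float],
    decimals: int | None = 3,
) -> pd.DataFrame:
    """Grid of sd(Delta) values: rows indexed by nu_n, columns by nu_p.

    ``decimals=None`` returns unrounded values.
    """
    nu_n = list(nu_n_list)
    nu_p = list(nu_p_list)
    cells = np.array(
        [[delta_moments(locus, ErrorRates(nu_p=p, nu_n=n)).sd for p in nu_p] for n in nu_n]
    )
    if decimals is not None:
        cells = np.round(cells, decimals)
    return pd.DataFrame(cells, index=pd.Index(nu_n, name="nu_n"), columns=pd.Index(nu_p, name="nu_p"))


def equivalence_contour(
    locus: LocusModel,
    target_sd: float,
    nu_n_grid: Sequence[float] | None = None,
) -> list[tuple[float, float]]:
    """(nu_n, nu_p) pairs on the contour Var(Delta) = target_sd^2.

    For each ``nu_n`` on the grid, solves the quadratic in ``nu_p``::

        (nu_n + nu_p r) S2 - ((nu_n - nu_p r) S1)^2 = target_sd^2

    keeping the smaller admissible root in [0, 1]; grid points with no such
    root are omitted.  The contour bounds the error-rate region inside which
    a caller injects less variance than a given intensity-noise level.
    """
    if target_sd < 0:
        raise ValueError("target_sd must be non-negative")
    if nu_n_grid is None:
        nu_n_grid = np.arange(0.0, 1.0 + 1e-9, 0.001)
    g = locus.g
    mask = STATES != _REF
    s1 = float(np.sum(g[mask] * (_REF - STATES[mask])))
    s2 = float(np.sum(g[mask] * (_REF - STATES[mask]) ** 2))
    r = g[_REF] / locus.nonref_mass if locus.nonref_mass > 0 else 0.0
    tv = target_sd * target_sd
    out: list[tuple[float, float]] = []
    for nu_n in nu_n_grid:
        # Var(nu_p) = a*nu_p^2 + b*nu_p + c with
        a = -(r * s1) ** 2
        b = r * s2 + 2.0 * nu_n * r * s1 * s1
        c = nu_n * s2 - (nu_n * s1) ** 2 - tv
        roots = []
        if abs(a) < 1e-12:  # S1 ~ 0: the quadratic degenerates to a line
            if b != 0.0:
                roots = [-c / b]
            elif c == 0.0:
                roots = [0.0]
        else:
            disc = b * b - 4.0 * a * c
            if disc >= 0:
                sq = math.sqrt(disc)
                roots = [(-b + sq) / (2 * a), (-b - sq) / (2 * a)]
        admissible = sorted(x for x in roots if -1e-12 <= x <= 1.0)
        if admissible:
            out.append((float(nu_n), max(admissible[0], 0.0)))
    return out


def sample_observed_calls(
    true_states: np.ndarray,
    locus: LocusModel,
    rates: ErrorRates,
    rng: np.random.Generator,
) -> np.ndarray:
    """Monte-Carlo twin of the closed forms: perturb true states per the call model.

    Each state is perturbed independently: non-reference states drop to 2
    with probability ``nu_n``; reference states jump to a non-reference
    state (chosen proportionally to the locus genotype frequencies) with
    probability ``nu_p``.
    """
    x = np.asarray(true_states)
    if x.size and (x.min() < 0 or x.max() > 4):
        raise ValueError("true states must lie in {0..4}")
    if rates.nu_p > 0:
        _check_fp_destination(locus, rates)
    out = x.copy()
    u = rng.random(x.shape)
    nonref = x != _REF
    out[nonref & (u < rates.nu_n)] = _REF
    ref = ~nonref
    flip = ref & (u < rates.nu_p)
    n_flip = int(flip.sum())
    if n_flip:
        dest_probs = locus.g.copy()
        dest_probs[_REF] = 0.0
        dest_probs /= dest_probs.sum()
        out[flip] = rng.choice(STATES, size=n_flip, p=dest_probs)
    return out
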