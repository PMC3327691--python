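"""Association-test power under CNV call errors and under raw LRR intensities.

A quantitative trait follows Y = X*beta + eps with X a binary carrier
indicator, eps Gaussian, and the residual variance chosen so Var(Y) is held
fixed across carrier frequencies.  Power is estimated by Monte-Carlo
simulation of an OLS slope test of Y on either (a) the called carrier
indicator, degraded by false-negative/false-positive call errors, or (b) a
single noisy LRR measurement per subject.  A closed-form oracle based on
the noncentral F distribution and measurement-error attenuation of the
squared correlation accompanies the simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .locus import ErrorRates
from .lrr import LRRModel

__all__ = [
    "TraitModel",
    "PowerConfig",
    "PowerEstimate",
    "HalfPowerResult",
    "simulate_phenotype",
    "slope_test",
    "estimate_power_calls",
    "estimate_power_lrr",
    "analytic_power",
    "rho_sq_calls",
    "rho_sq_lrr",
    "base_r_squared",
    "half_power_crossing",
    "find_half_power_crossing",
    "simulate_power_curve",
    "compose_power_vs_size",
]

_CHUNK_REPS = 2000  # replicates per vectorized block, caps peak memory


@dataclass(frozen=True)
class TraitModel:
    """Additive trait model Y = X*beta + eps with fixed total variance.

    ``beta`` is the carrier effect in trait units; ``var_y`` the total
    phenotypic variance.  The residual variance at carrier frequency ``p``
    is ``var_y - beta^2 p (1-p)``, so a CNV with beta 2.5 and var_y 100
    carried by 20% of subjects explains exactly 1% of the trait variance.
    """

    beta: float = 2.5
    var_y: float = 100.0

    def residual_var(self, carrier_freq: float) -> float:
        s2 = self.var_y - self.beta**2 * carrier_freq * (1.0 - carrier_freq)
        if s2 <= 0:
            raise ValueError(
                f"residual variance non-positive at carrier frequency {carrier_freq}"
            )
        return s2


@dataclass(frozen=True)
class PowerConfig:
    """Monte-Carlo settings for a power estimate."""

    n_subjects: int = 1000
    n_replicates: int = 10_000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects for a slope test")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PowerEstimate:
    """Empirical power with its binomial Monte-Carlo standard error."""

    power: float
    n_replicates: int
    mc_se: float = field(init=False)

    def __post_init__(self) -> None:
        se = math.sqrt(self.power * (1.0 - self.power) / self.n_replicates)
        object.__setattr__(self, "mc_se", se)


@dataclass(frozen=True)
class HalfPowerResult:
    """Location of the false-negative rate at which power halves."""

    crossing: float | None
    baseline_power: float
    reliable: bool


def simulate_phenotype(
    carrier_indicators: np.ndarray,
    trait: TraitModel,
    rng: np.random.Generator,
    carrier_freq: float | None = None,
) -> np.ndarray:
    """Trait values y_i = x_i * beta + eps_i with Var(Y) = trait.var_y.

    The residual variance is set from ``carrier_freq`` (the population
    carrier frequency; defaults to the empirical frequency of the supplied
    indicators).
    """
    x = np.asarray(carrier_indicators, dtype=float)
    p = float(x.mean()) if carrier_freq is None else carrier_freq
    sigma = math.sqrt(trait.residual_var(p))
    return x * trait.beta + rng.normal(0.0, sigma, size=x.shape)


def slope_test(y: np.ndarray, predictor: np.ndarray, alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided t-test of the OLS slope of y on the predictor.

    A zero-variance predictor is degenerate: the test cannot reject, so the
    replicate counts as non-significant (p-value 1).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1 or y.size < 3:
        raise ValueError("y and predictor must be equal-length 1-D arrays, length >= 3")
    if np.ptp(x) == 0:
        return 1.0, False
    res = stats.linregress(x, y)
    return float(res.pvalue), bool(res.pvalue < alpha)


def _significant_fraction(y: np.ndarray, x: np.ndarray, alpha: float) -> int:
    """Count replicates (rows) whose slope t-test rejects at level alpha.

    Vectorized over the replicate axis; zero-variance predictors never reject.
    """
    n = y.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    ok = (sxx > 0) & (syy > 0)
    r2 = np.zeros(len(sxx))
    r2[ok] = sxy[ok] ** 2 / (sxx[ok] * syy[ok])
    r2 = np.clip(r2, 0.0, 1.0)
    # two-sided slope t-test via the equivalent F(1, n-2) statistic on r^2
    with np.errstate(divide="ignore"):
        f = (n - 2) * r2 / (1.0 - r2)
    crit = stats.f.isf(alpha, 1, n - 2)
    return int(np.count_nonzero(ok & (f > crit)))


def _power_loop(
    config: PowerConfig,
    rng: np.random.Generator,
    replicate_block: Callable[[int, np.random.Generator], tuple[np.ndarray, np.ndarray]],
) -> PowerEstimate:
    hits = 0
    done = 0
    while done < config.n_replicates:
        block = min(_CHUNK_REPS, config.n_replicates - done)
        y, x = replicate_block(block, rng)
        hits += _significant_fraction(y, x, config.alpha)
        done += block
    return PowerEstimate(power=hits / config.n_replicates, n_replicates=config.n_replicates)


def estimate_power_calls(
    freq: float,
    rates: ErrorRates,
    trait: TraitModel,
    config: PowerConfig,
    rng: np.random.Generator | None = None,
) -> PowerEstimate:
    """Power of regressing the trait on the error-prone called carrier indicator.

    Per replicate: carriers drawn Bernoulli(freq) over subjects, phenotype
    simulated on the true indicator, and the observed indicator obtained by
    flipping carriers to non-carrier with probability nu_n and non-carriers
    to carrier with probability nu_p.
    """
    if not 0.0 < freq < 1.0:
        raise ValueError("carrier frequency must lie in (0, 1)")
    rng = config.rng() if rng is None else rng
    sigma = math.sqrt(trait.residual_var(freq))

    def block(reps: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        x = rng.random((reps, config.n_subjects)) < freq
        y = x * trait.beta + rng.normal(0.0, sigma, size=x.shape)
        u = rng.random(x.shape)
        x_o = np.where(x, u >= rates.nu_n, u < rates.nu_p)
        return y, x_o.astype(float)

    return _power_loop(config, rng, block)


def estimate_power_lrr(
    freq: float,
    cnv_type: str,
    lrr_model: LRRModel,
    trait: TraitModel,
    config: PowerConfig,
    rng: np.random.Generator | None = None,
) -> PowerEstimate:
    """Power of regressing the trait on a single noisy LRR measurement.

    Carriers have expected LRR equal to the damped one-copy mean
    (deletions) or three-copy mean (duplications); non-carriers 0.  The
    result does not depend on CNV size: a single locus is tested.
    """
    if cnv_type not in ("deletion", "duplication"):
        raise ValueError("cnv_type must be 'deletion' or 'duplication'")
    if not 0.0 < freq < 1.0:
        raise ValueError("carrier frequency must lie in (0, 1)")
    rng = config.rng() if rng is None else rng
    sigma = math.sqrt(trait.residual_var(freq))
    carrier_state = 1 if cnv_type == "deletion" else 3
    carrier_mean = lrr_model.damped_means()[carrier_state]

    def block(reps: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        x = rng.random((reps, config.n_subjects)) < freq
        y = x * trait.beta + rng.normal(0.0, sigma, size=x.shape)
        z = x * carrier_mean + rng.normal(0.0, lrr_model.noise_sd, size=x.shape)
        return y, z

    return _power_loop(config, rng, block)


def base_r_squared(freq: float, trait: TraitModel) -> float:
    """Fraction of trait variance explained by the true carrier indicator."""
    return trait.beta**2 * freq * (1.0 - freq) / trait.var_y


def rho_sq_calls(nu_n: float, freq: float, nu_p: float = 0.0) -> float:
    """Squared correlation between true and called carrier indicators.

    With a = 1 - nu_n and b = nu_p the called indicator is Bernoulli with
    success probability a for carriers and b for non-carriers, giving
    corr^2 = p(1-p)(a-b)^2 / (p_o (1-p_o)) where p_o = p a + (1-p) b.
    """
    a, b, p = 1.0 - nu_n, nu_p, freq
    p_o = p * a + (1.0 - p) * b
    if p_o <= 0.0 or p_o >= 1.0:
        return 0.0
    return p * (1.0 - p) * (a - b) ** 2 / (p_o * (1.0 - p_o))


def rho_sq_lrr(cnv_type: str, lrr_model: LRRModel, freq: float) -> float:
    """Squared correlation between the carrier indicator and its noisy LRR proxy.

    The LRR predictor is a linear relabeling of the indicator plus
    independent noise, so the classical attenuation
    m^2 p(1-p) / (m^2 p(1-p) + noise_sd^2) applies, with m the damped
    carrier mean shift.
    """
    state = 1 if cnv_type == "deletion" else 3
    m = lrr_model.damped_means()[state]
    signal = m * m * freq * (1.0 - freq)
    total = signal + lrr_model.noise_sd**2
    return signal / total if total > 0 else 1.0


def analytic_power(rho_sq: float, base_r2: float, n: int, alpha: float = 0.05) -> float:
    """Closed-form slope-test power via the noncentral F(1, n-2) distribution.

    The effective coefficient of determination is ``rho_sq * base_r2``
    (attenuation of the true R^2 by the squared correlation between the
    predictor used and the true indicator); the noncentrality parameter is
    ``lambda = n R^2 / (1 - R^2)``.
    """
    if not 0.0 <= rho_sq <= 1.0:
        raise ValueError("rho_sq must lie in [0, 1]")
    if not 0.0 <= base_r2 < 1.0:
        raise ValueError("base_r2 must lie in [0, 1)")
    r2 = rho_sq * base_r2
    lam = n * r2 / (1.0 - r2)
    crit = stats.f.isf(alpha, 1, n - 2)
    if lam == 0.0:
        return alpha
    return float(stats.ncf.sf(crit, 1, n - 2, lam))


def simulate_power_curve(
    freq: float,
    nu_n_grid: Sequence[float],
    trait: TraitModel,
    config: PowerConfig,
    rng: np.random.Generator | None = None,
    nu_p: float = 0.0,
) -> np.ndarray:
    """Empirical power at each false-negative rate on the grid (nu_p fixed)."""
    rng = config.rng() if rng is None else rng
    return np.array(
        [
            estimate_power_calls(freq, ErrorRates(nu_p=nu_p, nu_n=nn), trait, config, rng).power
            for nn in nu_n_grid
        ]
    )


def find_half_power_crossing(
    nu_n_grid: np.ndarray,
    power_values: np.ndarray,
    smooth: bool = True,
) -> tuple[float | None, np.ndarray]:
    """Smallest grid nu_n at which power drops to half its nu_n=0 value.

    Power is optionally smoothed to be monotone non-increasing (isotonic
    regression) before thresholding; returns (crossing or None, the curve
    actually thresholded).
    """
    grid = np.asarray(nu_n_grid, dtype=float)
    pw = np.asarray(power_values, dtype=float)
    if smooth:
        pw = IsotonicRegression(increasing=False).fit_transform(grid, pw)
    half = pw[0] / 2.0
    below = np.nonzero(pw <= half)[0]
    if len(below) == 0:
        return None, pw
    return float(grid[below[0]]), pw


def half_power_crossing(
    freq: float,
    trait: TraitModel,
    config: PowerConfig,
    nu_n_grid: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> HalfPowerResult:
    """False-negative rate at which simulated power halves relative to nu_n=0.

    The estimate is unreliable when the error-free power sits near the
    alpha floor (baseline <= 2 alpha): the ratio is then dominated by the
    null rejection rate.
    """
    if nu_n_grid is None:
        nu_n_grid = np.arange(0.0, 1.0 + 1e-9, 0.01)
    grid = np.asarray(nu_n_grid, dtype=float)
    curve = simulate_power_curve(freq, grid, trait, config, rng=rng)
    crossing, smoothed = find_half_power_crossing(grid, curve)
    baseline = float(smoothed[0])
    return HalfPowerResult(
        crossing=crossing, baseline_power=baseline, reliable=baseline > 2.0 * config.alpha
    )


def compose_power_vs_size(
    recovery_by_size: dict[int, float],
    nu_n_grid: Sequence[float],
    power_by_nu_n: Sequence[float],
) -> dict[int, float]:
    """Power as a function of CNV size via the recovery-rate composition.

    Each size maps to an effective false-negative rate 1 - recovery(size);
    the power curve is evaluated there with linear interpolation.
    """
    grid = np.asarray(nu_n_grid, dtype=float)
    pw = np.asarray(power_by_nu_n, dtype=float)
    order = np.argsort(grid)
    grid, pw = grid[order], pw[order]
    out: dict[int, float] = {}
    for size, rec in recovery_by_size.items():
        if not 0.0 <= rec <= 1.0:
            raise ValueError(f"recovery rate out of [0, 1] at size {size}")
        out[size] = float(np.interp(1.0 - rec, grid, pw))
    return out
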