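"""Five-state HMM Viterbi segmentation of LRR vectors and recovery rates.

A homogeneous hidden Markov model over copy states {0..4} with Gaussian
emissions stands in for production CNV callers such as PennCNV: the
diagonal of the transition matrix carries ``stay_prob`` and the remaining
mass is split evenly over the other four states; the initial distribution
puts ``cnv_prior`` on each non-reference state.  Maximal runs of non-2
states in the Viterbi path are emitted as CNV call segments.

Recovery rate — the fraction of true carriers for whom the caller finds an
overlapping, direction-matched segment — is one minus the false-negative
rate and is the bridge from caller behaviour to association power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import CNVRegion, CohortConfig, LRRMatrix, simulate_cohort
from .lrr import LRRModel, array_preset
from .power import PowerConfig, TraitModel, _significant_fraction

__all__ = [
    "HMMParams",
    "CNVCallSegment",
    "RecoveryCurve",
    "viterbi_path",
    "viterbi_segment",
    "segments_from_path",
    "recovery_rate",
    "recovery_curve",
    "end_to_end_power",
]


@dataclass(frozen=True)
class HMMParams:
    """Emission and transition parameters of the 5-state caller surrogate.

    Defaults: emission means are the array-damped theoretical LRR values
    with a finite zero-copy floor, all sds 0.15, ``stay_prob`` 0.99999
    (a strong prior against state changes, so that segments shorter than a
    few probes rarely overcome the transition penalty — the hallmark of
    production callers) and ``cnv_prior`` 1e-4 of initial mass on each
    non-reference state.
    """

    state_means: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.2925, 0.45)
    state_sds: tuple[float, ...] = (0.15, 0.15, 0.15, 0.15, 0.15)
    stay_prob: float = 0.99999
    cnv_prior: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.state_means) != 5 or len(self.state_sds) != 5:
            raise ValueError("need exactly 5 emission means and sds")
        if any(s <= 0 for s in self.state_sds):
            raise ValueError("emission sds must be positive")
        if not 0.0 < self.stay_prob < 1.0:
            raise ValueError("stay_prob must lie in (0, 1)")
        if not 0.0 < 4 * self.cnv_prior < 1.0:
            raise ValueError("cnv_prior must leave positive mass on state 2")

    def log_transition(self) -> np.ndarray:
        t = np.full((5, 5), (1.0 - self.stay_prob) / 4.0)
        np.fill_diagonal(t, self.stay_prob)
        return np.log(t)

    def log_initial(self) -> np.ndarray:
        pi = np.full(5, self.cnv_prior)
        pi[2] = 1.0 - 4.0 * self.cnv_prior
        return np.log(pi)


@dataclass(frozen=True)
class CNVCallSegment:
    """One called non-reference segment (1-based inclusive probe indices)."""

    subject: str
    start_index: int
    end_index: int
    called_state: int

    def __post_init__(self) -> None:
        if self.start_index < 1 or self.end_index < self.start_index:
            raise ValueError("need 1 <= start_index <= end_index")
        if self.called_state not in (0, 1, 3, 4):
            raise ValueError("called_state must be non-reference (reference runs are implicit)")

    @property
    def n_probes(self) -> int:
        return self.end_index - self.start_index + 1

    def is_deletion(self) -> bool:
        return self.called_state < 2


@dataclass(frozen=True)
class RecoveryCurve:
    """Recovery rate by CNV size (probes) for one CNV type."""

    cnv_type: str
    sizes: tuple[int, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) != len(self.rates):
            raise ValueError("sizes and rates must align")
        if any(not 0.0 <= r <= 1.0 for r in self.rates):
            raise ValueError("recovery rates must lie in [0, 1]")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.sizes, self.rates))

    def false_negative_rates(self) -> dict[int, float]:
        """nu_n = 1 - recovery, per size."""
        return {s: 1.0 - r for s, r in zip(self.sizes, self.rates)}


def viterbi_path(lrr: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most probable copy-state path(s) for one or many LRR vectors.

    Accepts shape (L,) or (n_subjects, L); returns integer states of the
    same leading shape.  Vectorized across subjects; ties in the
    maximization resolve to the lowest state index (argmax convention),
    making calls deterministic in the input.
    """
    obs = np.atleast_2d(np.asarray(lrr, dtype=float))
    if obs.shape[1] == 0:
        raise ValueError("empty LRR vector")
    if not np.isfinite(obs).all():
        raise ValueError("LRR values must be finite")
    n, length = obs.shape
    means = np.asarray(params.state_means)
    sds = np.asarray(params.state_sds)
    log_t = params.log_transition()  # (from, to)

    # log emission densities, computed per probe column to bound memory
    def log_emit(t: int) -> np.ndarray:
        return stats.norm.logpdf(obs[:, t, None], means[None, :], sds[None, :])

    back = np.empty((n, length, 5), dtype=np.int8)
    score = params.log_initial()[None, :] + log_emit(0)
    back[:, 0] = 0
    for t in range(1, length):
        # cand[s, from, to] = score[s, from] + log_t[from, to]
        cand = score[:, :, None] + log_t[None, :, :]
        best_from = cand.argmax(axis=1)
        back[:, t] = best_from
        score = np.take_along_axis(cand, best_from[:, None, :], axis=1)[:, 0, :] + log_emit(t)

    path = np.empty((n, length), dtype=np.int8)
    path[:, -1] = score.argmax(axis=1)
    for t in range(length - 1, 0, -1):
        path[:, t - 1] = np.take_along_axis(back[:, t], path[:, t, None].astype(np.intp), axis=1)[:, 0]
    return path[0] if np.asarray(lrr).ndim == 1 else path


def segments_from_path(states: np.ndarray, subject: str = "subject") -> list[CNVCallSegment]:
    """Maximal runs of non-reference states as 1-based inclusive segments."""
    s = np.asarray(states)
    if s.ndim != 1:
        raise ValueError("expected a single state path")
    segs: list[CNVCallSegment] = []
    boundaries = np.nonzero(np.diff(s) != 0)[0]
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries, [len(s) - 1]))
    for a, b in zip(starts, ends):
        state = int(s[a])
        if state != 2:
            segs.append(
                CNVCallSegment(
                    subject=subject, start_index=int(a) + 1, end_index=int(b) + 1,
                    called_state=state,
                )
            )
    return segs


def viterbi_segment(
    lrr_vector: np.ndarray, params: HMMParams | None = None, subject: str = "subject"
) -> list[CNVCallSegment]:
    """Call CNV segments on one subject's LRR vector via the Viterbi path."""
    params = HMMParams() if params is None else params
    return segments_from_path(viterbi_path(np.asarray(lrr_vector), params), subject=subject)


def _recovered(segments: list[CNVCallSegment], truth: CNVRegion) -> bool:
    """A carrier is recovered iff some segment overlaps the true region by
    at least one probe with a called state on the same side of 2."""
    true_del = truth.state < 2
    for seg in segments:
        if seg.is_deletion() != true_del:
            continue
        if seg.start_index <= truth.end_index and seg.end_index >= truth.start_index:
            return True
    return False


def recovery_rate(
    calls_by_subject: dict[str, list[CNVCallSegment]], truth: CNVRegion
) -> float:
    """Fraction of true carriers with an overlapping, direction-matched call."""
    if not truth.carriers:
        raise ValueError("truth region has no carriers")
    hits = sum(
        _recovered(calls_by_subject.get(subj, []), truth) for subj in truth.carriers
    )
    return hits / len(truth.carriers)


def call_matrix(
    lrr_matrix: LRRMatrix, params: HMMParams | None = None
) -> dict[str, list[CNVCallSegment]]:
    """Viterbi-call every subject in an LRR matrix."""
    params = HMMParams() if params is None else params
    paths = viterbi_path(lrr_matrix.values, params)
    return {
        subj: segments_from_path(paths[i], subject=subj)
        for i, subj in enumerate(lrr_matrix.subjects)
    }


def recovery_curve(
    sizes: list[int],
    cnv_type: str,
    rng: np.random.Generator,
    cohort_config: CohortConfig | None = None,
    params: HMMParams | None = None,
    lrr_model: LRRModel | None = None,
) -> RecoveryCurve:
    """Recovery rate versus CNV size from simulated cohorts.

    For each size a fresh cohort is simulated and only the carriers are
    called (non-carrier calls cannot change the recovery rate).
    """
    cohort_config = CohortConfig() if cohort_config is None else cohort_config
    params = HMMParams() if params is None else params
    lrr_model = array_preset() if lrr_model is None else lrr_model
    rates = []
    for size in sizes:
        if size < 1:
            raise ValueError("CNV sizes must be >= 1 probes")
        probe_map, region, matrix = simulate_cohort(
            size, cnv_type, rng, config=cohort_config, lrr_model=lrr_model
        )
        assert region is not None
        carrier_rows = [matrix.subjects.index(c) for c in region.carriers]
        paths = viterbi_path(matrix.values[carrier_rows], params)
        calls = {
            c: segments_from_path(paths[i], subject=c)
            for i, c in enumerate(region.carriers)
        }
        rates.append(recovery_rate(calls, region))
    return RecoveryCurve(cnv_type=cnv_type, sizes=tuple(sizes), rates=tuple(rates))


def end_to_end_power(
    sizes: list[int],
    cnv_type: str,
    trait: TraitModel,
    power_config: PowerConfig,
    rng: np.random.Generator,
    cohort_config: CohortConfig | None = None,
    params: HMMParams | None = None,
    lrr_model: LRRModel | None = None,
) -> dict[int, float]:
    """Association power by CNV size with the caller in the loop.

    Per replicate: simulate a cohort, simulate the trait on the true
    carriers, call every subject, and regress the trait on the
    called-carrier indicator (any direction-matched segment overlapping the
    true region).  Cross-checks the recovery-curve/power-curve composition.
    """
    cohort_config = CohortConfig() if cohort_config is None else cohort_config
    params = HMMParams() if params is None else params
    lrr_model = array_preset() if lrr_model is None else lrr_model
    freq = cohort_config.n_carriers / cohort_config.n_subjects
    sigma = np.sqrt(trait.residual_var(freq))
    out: dict[int, float] = {}
    for size in sizes:
        hits = 0
        for _ in range(power_config.n_replicates):
            probe_map, region, matrix = simulate_cohort(
                size, cnv_type, rng, config=cohort_config, lrr_model=lrr_model
            )
            assert region is not None
            carriers = set(region.carriers)
            x_true = np.array([s in carriers for s in matrix.subjects], dtype=float)
            y = x_true * trait.beta + rng.normal(0.0, sigma, size=len(x_true))
            paths = viterbi_path(matrix.values, params)
            x_obs = np.array(
                [
                    _recovered(segments_from_path(paths[i], subject=s), region)
                    for i, s in enumerate(matrix.subjects)
                ],
                dtype=float,
            )
            hits += _significant_fraction(y[None, :], x_obs[None, :], power_config.alpha)
        out[size] = hits / power_config.n_replicates
    return out
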