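"""Synthetic probe-grid LRR cohorts with one embedded CNV region.

Emulates a SNP-array experiment: a uniformly spaced probe grid (default
10,000 probes, 1 kb apart) that is copy-number invariant everywhere except
a centered region of 1-25 probes, carried as a single-copy deletion or
duplication by a fixed subset of subjects (default 200 of 1,000).  Observed
LRR values are independent Gaussians conditional on the underlying copy
state, with array-damped means and sd 0.15 by default.

Signal matrices round-trip through PennCNV-style tab-delimited text files
(``Name  Chr  Position  <subject>.Log R Ratio``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .lrr import LRRModel, array_preset

__all__ = [
    "ProbeMap",
    "CNVRegion",
    "LRRMatrix",
    "CohortConfig",
    "simulate_cohort",
    "write_signal_file",
    "read_signal_file",
]


@dataclass(frozen=True)
class ProbeMap:
    """Uniformly spaced probe grid on one chromosome (1-based bp positions)."""

    names: tuple[str, ...]
    chrom: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        if len(self.names) != len(pos):
            raise ValueError("names and positions must have equal length")
        if len(pos) == 0:
            raise ValueError("probe map cannot be empty")
        d = np.diff(pos)
        if len(d) and ((d <= 0).any() or (d != d[0]).any()):
            raise ValueError("positions must be strictly increasing with constant spacing")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def uniform(cls, n_probes: int, spacing_bp: int = 1000, chrom: str = "1") -> "ProbeMap":
        idx = np.arange(1, n_probes + 1)
        return cls(
            names=tuple(f"probe_{i}" for i in idx),
            chrom=chrom,
            positions=idx * spacing_bp,
        )


@dataclass(frozen=True)
class CNVRegion:
    """Ground-truth variant region: 1-based inclusive probe indices and carriers."""

    start_index: int
    end_index: int
    state: int
    carriers: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start_index < 1 or self.end_index < self.start_index:
            raise ValueError("need 1 <= start_index <= end_index")
        if self.state not in (0, 1, 3, 4):
            raise ValueError("true CNV state must be a non-reference integer in {0,1,3,4}")

    @property
    def size(self) -> int:
        return self.end_index - self.start_index + 1

    def probe_slice(self) -> slice:
        """0-based half-open slice selecting the region's probes."""
        return slice(self.start_index - 1, self.end_index)


@dataclass(frozen=True)
class LRRMatrix:
    """Observed LRR values, subjects x probes."""

    subjects: tuple[str, ...]
    probe_map: ProbeMap
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.subjects), len(self.probe_map)):
            raise ValueError("values must be shaped (n_subjects, n_probes)")
        if not np.isfinite(v).all():
            raise ValueError("LRR values must be finite")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.T,
            index=pd.Index(self.probe_map.names, name="Name"),
            columns=list(self.subjects),
        )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions for the probe-grid simulation."""

    n_subjects: int = 1000
    n_probes: int = 10_000
    n_carriers: int = 200
    spacing_bp: int = 1000

    def __post_init__(self) -> None:
        if not 0 <= self.n_carriers <= self.n_subjects:
            raise ValueError("n_carriers must lie in [0, n_subjects]")
        if self.n_probes < 1:
            raise ValueError("need at least one probe")


def simulate_cohort(
    cnv_size: int,
    cnv_type: str,
    rng: np.random.Generator,
    config: CohortConfig | None = None,
    lrr_model: LRRModel | None = None,
) -> tuple[ProbeMap, CNVRegion | None, LRRMatrix]:
    """Simulate the probe-grid cohort with a centered CNV.

    Exactly ``config.n_carriers`` subjects (chosen without replacement)
    carry a single-copy deletion (state 1) or duplication (state 3) across
    a centered run of ``cnv_size`` probes; every other cell is state 2.
    LRR values are independent N(damped state mean, noise_sd^2) draws.
    ``cnv_size=0`` produces a pure-noise cohort with region ``None``.
    """
    config = CohortConfig() if config is None else config
    lrr_model = array_preset() if lrr_model is None else lrr_model
    if cnv_type not in ("deletion", "duplication"):
        raise ValueError("cnv_type must be 'deletion' or 'duplication'")
    if cnv_size < 0 or cnv_size > config.n_probes:
        raise ValueError("cnv_size must lie in [0, n_probes]")

    probe_map = ProbeMap.uniform(config.n_probes, config.spacing_bp)
    subjects = tuple(f"subject_{i + 1}" for i in range(config.n_subjects))
    noise = rng.normal(0.0, lrr_model.noise_sd, size=(config.n_subjects, config.n_probes))

    region: CNVRegion | None = None
    if cnv_size > 0:
        carrier_idx = np.sort(
            rng.choice(config.n_subjects, size=config.n_carriers, replace=False)
        )
        state = 1 if cnv_type == "deletion" else 3
        start = (config.n_probes - cnv_size) // 2 + 1  # centered, 1-based inclusive
        region = CNVRegion(
            start_index=start,
            end_index=start + cnv_size - 1,
            state=state,
            carriers=tuple(subjects[i] for i in carrier_idx),
        )
        carrier_mean = lrr_model.damped_means()[state]
        noise[np.ix_(carrier_idx, np.arange(start - 1, start - 1 + cnv_size))] += carrier_mean

    return probe_map, region, LRRMatrix(subjects=subjects, probe_map=probe_map, values=noise)


def write_signal_file(probe_map: ProbeMap, lrr_matrix: LRRMatrix, path: str | Path) -> None:
    """Write a PennCNV-style tab-delimited signal-intensity file.

    One ``<subject>.Log R Ratio`` column per subject; values to 6 decimals.
    """
    if lrr_matrix.probe_map is not probe_map and not np.array_equal(
        lrr_matrix.probe_map.positions, probe_map.positions
    ):
        raise ValueError("probe map does not match the LRR matrix")
    df = pd.DataFrame(
        {
            "Name": probe_map.names,
            "Chr": probe_map.chrom,
            "Position": probe_map.positions,
        }
    )
    for i, subj in enumerate(lrr_matrix.subjects):
        df[f"{subj}.Log R Ratio"] = lrr_matrix.values[i]
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_signal_file(path: str | Path) -> tuple[ProbeMap, LRRMatrix]:
    """Read a PennCNV-style signal file back into (ProbeMap, LRRMatrix).

    Raises ``ValueError`` naming the offending line for malformed headers,
    non-numeric LRR values, or non-increasing positions.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    required = ["Name", "Chr", "Position"]
    if header[: len(required)] != required:
        raise ValueError(
            f"{path}:1: malformed header: expected columns {required} first, got {header[:3]}"
        )
    lrr_cols = [c for c in header[3:] if c.endswith(".Log R Ratio")]
    if len(lrr_cols) != len(header) - 3:
        bad = [c for c in header[3:] if not c.endswith(".Log R Ratio")]
        raise ValueError(f"{path}:1: unrecognized signal columns {bad}")
    if not lrr_cols:
        raise ValueError(f"{path}:1: no '<subject>.Log R Ratio' columns found")
    df = pd.read_csv(path, sep="\t")
    for col in ["Position", *lrr_cols]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad_rows = np.nonzero(numeric.isna().to_numpy())[0]
        if len(bad_rows):
            raise ValueError(
                f"{path}:{bad_rows[0] + 2}: non-numeric value in column {col!r}"
            )
        df[col] = numeric
    pos = df["Position"].to_numpy(dtype=np.int64)
    drops = np.nonzero(np.diff(pos) <= 0)[0]
    if len(drops):
        raise ValueError(f"{path}:{drops[0] + 3}: positions not strictly increasing")
    chrom_vals = df["Chr"].astype(str).unique()
    if len(chrom_vals) != 1:
        raise ValueError(f"{path}: expected a single chromosome, got {list(chrom_vals)}")
    probe_map = ProbeMap(
        names=tuple(df["Name"].astype(str)), chrom=chrom_vals[0], positions=pos
    )
    subjects = tuple(c[: -len(".Log R Ratio")] for c in lrr_cols)
    values = df[lrr_cols].to_numpy(dtype=float).T
    return probe_map, LRRMatrix(subjects=subjects, probe_map=probe_map, values=values)
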