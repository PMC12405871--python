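"""Summary statistics computed from raw seed measurements.

Germination percentage (GP) is the cumulative fraction of seeds germinated by
a given day, on the 0-100 scale. The germination index (GI) is a weighted GP
that rewards early germination: a seed germinating on day ``d`` of a test
with horizon ``T`` carries weight ``T + 1 - d``, so

    GI = 100 * sum_d n_d * (T + 1 - d) / (N * T).

The weight rule reproduces both standard counting schedules (daily counts on
days 2..7 give weights 6..1; counts on days 3, 5, 7 give weights 5, 3, 1)
without special cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .genetic_design import DigenicGenotype

__all__ = [
    "GerminationRecord",
    "ExpressionSample",
    "ImbibitionSeries",
    "cumulative_gp",
    "germination_index",
    "water_content",
    "relative_expression",
]

#: Measurement grid (hours after soaking) used by the imbibition assay:
#: 0.5 h, then every 2 h to 12 h, every 4 h to 60 h, every 12 h to 96 h.
IMBIBITION_TIME_GRID: tuple[float, ...] = tuple(
    [0.5] + list(range(2, 13, 2)) + list(range(16, 61, 4)) + list(range(72, 97, 12))
)


@dataclass(frozen=True)
class GerminationRecord:
    """Incremental daily germination counts for one seed sample.

    ``counts[k]`` is the number of seeds observed germinated ON
    ``schedule[k]`` (newly germinated since the previous count); cumulative
    input must be differenced before construction.
    """

    sample_id: str
    genotype: DigenicGenotype
    n_total: int
    schedule: tuple[int, ...]
    counts: tuple[int, ...]
    horizon: int = 7

    def __post_init__(self):
        object.__setattr__(self, "schedule", tuple(int(d) for d in self.schedule))
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))
        if not self.schedule:
            raise ValidationError(f"sample {self.sample_id!r}: empty counting schedule")
        if len(self.counts) != len(self.schedule):
            raise ValidationError(
                f"sample {self.sample_id!r}: {len(self.counts)} counts for "
                f"{len(self.schedule)} scheduled days"
            )
        if self.n_total <= 0:
            raise ValidationError(f"sample {self.sample_id!r}: n_total must be positive")
        if any(c < 0 for c in self.counts):
            raise ValidationError(f"sample {self.sample_id!r}: negative germination count")
        if sum(self.counts) > self.n_total:
            raise ValidationError(
                f"sample {self.sample_id!r}: germinated total {sum(self.counts)} "
                f"exceeds seed total {self.n_total}"
            )
        if any(b <= a for a, b in zip(self.schedule, self.schedule[1:])):
            raise ValidationError(f"sample {self.sample_id!r}: schedule must be strictly increasing")
        if max(self.schedule) > self.horizon:
            raise ValidationError(
                f"sample {self.sample_id!r}: schedule extends past horizon {self.horizon}"
            )

    @property
    def total_germinated(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class ExpressionSample:
    """One qRT-PCR replicate: target and internal-control cycle thresholds."""

    gene: str
    ct_target: float
    ct_control: float
    replicate: int = 0

    def __post_init__(self):
        for name, ct in (("ct_target", self.ct_target), ("ct_control", self.ct_control)):
            if not np.isfinite(ct) or ct <= 0:
                raise ValidationError(f"{name} must be finite and positive, got {ct!r}")


@dataclass(frozen=True)
class ImbibitionSeries:
    """Sample weights over the soaking time grid, with initial dry weight w0."""

    sample_id: str
    genotype: DigenicGenotype
    w0: float
    times: tuple[float, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if self.w0 <= 0:
            raise ValidationError(f"sample {self.sample_id!r}: w0 must be positive")
        if len(self.times) != len(self.weights):
            raise ValidationError(f"sample {self.sample_id!r}: times/weights length mismatch")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError(f"sample {self.sample_id!r}: times must be strictly increasing")
        if any(w < 0 for w in self.weights):
            raise ValidationError(f"sample {self.sample_id!r}: negative weight")


def cumulative_gp(record: GerminationRecord, day: int) -> float:
    """Cumulative germination percentage by ``day``, in [0, 100].

    ``day`` may be any day at or after the first counting day; counts on
    scheduled days up to and including ``day`` are accumulated. Asking for a
    day before the first count is an error (GP undefined there).
    """
    if day < record.schedule[0]:
        raise ValidationError(
            f"GP undefined before the first counting day {record.schedule[0]} (asked for {day})"
        )
    germinated = sum(c for d, c in zip(record.schedule, record.counts) if d <= day)
    return 100.0 * germinated / record.n_total


def germination_index(record: GerminationRecord) -> float:
    """Weighted germination percentage; earlier germination weighs more."""
    T = record.horizon
    weighted = sum(c * (T + 1 - d) for d, c in zip(record.schedule, record.counts))
    return 100.0 * weighted / (record.n_total * T)


def water_content(series: ImbibitionSeries) -> np.ndarray:
    """Per-timepoint water-content fraction ``(w_i - w0) / w0``."""
    w = np.asarray(series.weights, dtype=float)
    return (w - series.w0) / series.w0


def relative_expression(sample: ExpressionSample) -> float:
    """Relative transcript abundance ``2**-(Ct_target - Ct_control)``."""
    return float(2.0 ** -(sample.ct_target - sample.ct_control))
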