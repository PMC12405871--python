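"""Per-timepoint digenic fits of imbibition curves and three-phase segmentation.

Water uptake by a germinating seed is triphasic: rapid imbibition (I), a
plateau (II), and renewed uptake after radicle emergence (III). The
background level ``mu(t)`` of the per-timepoint genotype model is free of
genetic effects, so its trajectory is the natural substrate for locating the
phase boundaries. Segmentation fits a continuous two-breakpoint piecewise
linear function by exhaustive search over breakpoint pairs on the observed
time grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, SegmentationError, ValidationError
from .genetic_design import DigenicGenotype, ModelSpec
from .metrics import ImbibitionSeries, water_content
from .model_fitting import fit_ols
from . import genetic_design

__all__ = [
    "EffectTrajectory",
    "PhaseSegmentation",
    "fit_per_timepoint",
    "segment_phases",
]

_TERMS = ("a1", "a2", "i_a1a2")


@dataclass
class EffectTrajectory:
    """Per-timepoint model estimates over the imbibition grid."""

    times: np.ndarray
    mu: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    i_a1a2: np.ndarray
    a1_p: np.ndarray
    a2_p: np.ndarray
    i_a1a2_p: np.ndarray
    a1_sig: np.ndarray
    a2_sig: np.ndarray
    i_a1a2_sig: np.ndarray
    r2_total: np.ndarray

    def __post_init__(self):
        n = len(self.times)
        for name in (
            "mu", "a1", "a2", "i_a1a2", "a1_p", "a2_p", "i_a1a2_p",
            "a1_sig", "a2_sig", "i_a1a2_sig", "r2_total",
        ):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"trajectory field {name!r} has mismatched length")

    def first_significant_time(self, term: str) -> float | None:
        """Earliest time at which ``term`` is flagged significant, or None."""
        flags = {"a1": self.a1_sig, "a2": self.a2_sig, "i_a1a2": self.i_a1a2_sig}[term]
        hits = np.flatnonzero(flags)
        return float(self.times[hits[0]]) if hits.size else None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "mu": self.mu,
                "a1": self.a1,
                "a1_p": self.a1_p,
                "a1_sig": self.a1_sig,
                "a2": self.a2,
                "a2_p": self.a2_p,
                "a2_sig": self.a2_sig,
                "i_a1a2": self.i_a1a2,
                "i_a1a2_p": self.i_a1a2_p,
                "i_a1a2_sig": self.i_a1a2_sig,
                "r2_total": self.r2_total,
            }
        )


@dataclass
class PhaseSegmentation:
    """Continuous 3-segment piecewise-linear fit of a trajectory."""

    breakpoints: tuple[float, float]
    slopes: tuple[float, float, float]
    intercept: float
    fit_sse: float
    valid_plateau: bool

    def predict(self, times: Sequence[float]) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        b1, b2 = self.breakpoints
        s1, s2, s3 = self.slopes
        return (
            self.intercept
            + s1 * np.minimum(t, b1)
            + s2 * np.clip(t - b1, 0.0, b2 - b1)
            + s3 * np.maximum(t - b2, 0.0)
        )


def _wc_panel(
    panel: Sequence[ImbibitionSeries], values: str
) -> tuple[np.ndarray, list[DigenicGenotype], np.ndarray]:
    if not panel:
        raise ValidationError("empty imbibition panel")
    times = np.asarray(panel[0].times, dtype=float)
    for s in panel:
        if not np.array_equal(np.asarray(s.times, float), times):
            raise ValidationError(f"sample {s.sample_id!r}: time grid differs from the panel's")
    if values == "weight":
        wc = np.vstack([water_content(s) for s in panel])
    elif values == "wc":
        wc = np.vstack([np.asarray(s.weights, float) for s in panel])
    else:
        raise ValidationError(f"values must be 'weight' or 'wc', got {values!r}")
    return times, [s.genotype for s in panel], wc


def fit_per_timepoint(
    panel: Sequence[ImbibitionSeries],
    alpha: float = 0.05,
    values: str = "weight",
) -> EffectTrajectory:
    """Fit the homozygous additive+epistasis model at every time point.

    All three genetic terms are always estimated (no selection); the
    significance flags carry the per-time ``p < alpha`` decisions. Every
    genotype class must be present with at least 2 replicates at each time.

    ``values="wc"`` treats the series' ``weights`` as ready-made water-content
    fractions instead of raw weights.
    """
    times, genotypes, wc = _wc_panel(panel, values)

    classes = {(0, 0), (2, 0), (0, 2), (2, 2)}
    seen: dict[tuple[int, int], int] = {}
    for g in genotypes:
        seen[tuple(g)] = seen.get(tuple(g), 0) + 1
    missing = classes - set(seen)
    if missing:
        raise FitError(f"missing homozygous genotype class(es): {sorted(missing)}")
    thin = [c for c in classes if seen[c] < 2]
    if thin:
        raise FitError(f"need >=2 replicates per genotype class, short: {sorted(thin)}")

    spec = ModelSpec(model_kind="additive")
    n_t = len(times)
    out = {k: np.empty(n_t) for k in ("mu", "a1", "a2", "i_a1a2", "a1_p", "a2_p", "i_a1a2_p", "r2")}
    for k in range(n_t):
        records = [(g, wc[i, k]) for i, g in enumerate(genotypes)]
        design = genetic_design.build_design(records, spec)
        ols = fit_ols(design)
        y = design.response
        ss_tot = float(((y - y.mean()) ** 2).sum())
        out["mu"][k] = ols.coefficients[0]
        for j, term in enumerate(_TERMS, start=1):
            out[term][k] = ols.coefficients[j]
            out[f"{term}_p"][k] = ols.p_values[j]
        out["r2"][k] = 1.0 - ols.sse / ss_tot if ss_tot > 0 else 0.0

    with np.errstate(invalid="ignore"):
        sig = {t: out[f"{t}_p"] < alpha for t in _TERMS}
    return EffectTrajectory(
        times=times,
        mu=out["mu"],
        a1=out["a1"],
        a2=out["a2"],
        i_a1a2=out["i_a1a2"],
        a1_p=out["a1_p"],
        a2_p=out["a2_p"],
        i_a1a2_p=out["i_a1a2_p"],
        a1_sig=sig["a1"],
        a2_sig=sig["a2"],
        i_a1a2_sig=sig["i_a1a2"],
        r2_total=out["r2"],
    )


def _piecewise_basis(t: np.ndarray, b1: float, b2: float) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(t), t, np.maximum(t - b1, 0.0), np.maximum(t - b2, 0.0)]
    )


def segment_phases(
    times: Sequence[float],
    mu_values: Sequence[float],
    min_points_per_phase: int = 2,
) -> PhaseSegmentation:
    """Segment a trajectory into three linear phases by exhaustive search.

    Breakpoint pairs ``(b1, b2)`` range over the observed grid, each segment
    required to contain at least ``min_points_per_phase`` points; the pair
    minimizing the SSE of the continuous piecewise-linear least-squares fit
    wins. A trajectory already explained by a single straight line has no
    identifiable phases and raises :class:`SegmentationError`.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(mu_values, dtype=float)
    if t.shape != y.shape:
        raise ValidationError("times and mu_values must have equal length")
    if t.size < 6:
        raise SegmentationError("need at least 6 points to identify three phases")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")

    ss_y = float(((y - y.mean()) ** 2).sum())
    scale = max(ss_y, 1e-30)

    # Degenerate check: a plain line already fits.
    line_sse = _lstsq_sse_local(np.column_stack([np.ones_like(t), t]), y)
    if line_sse <= 1e-9 * scale:
        raise SegmentationError(
            "trajectory is indistinguishable from a single straight line; "
            "phase breakpoints are not identifiable"
        )

    m = min_points_per_phase
    best = None
    for i in range(m - 1, t.size - 1):  # b1 = t[i]; phase I covers t[0..i]
        for j in range(i + m, t.size - 1):  # b2 = t[j]; phase II covers t(i..j]
            if t.size - 1 - j < m:
                continue
            X = _piecewise_basis(t, t[i], t[j])
            sse = _lstsq_sse_local(X, y)
            if best is None or sse < best[0] - 1e-15 * scale:
                best = (sse, t[i], t[j])
    if best is None:
        raise SegmentationError("no admissible breakpoint pair on this grid")

    sse, b1, b2 = best
    X = _piecewise_basis(t, b1, b2)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    s1 = float(beta[1])
    s2 = float(beta[1] + beta[2])
    s3 = float(beta[1] + beta[2] + beta[3])
    valid = abs(s2) <= min(abs(s1), abs(s3)) + 1e-12
    return PhaseSegmentation(
        breakpoints=(float(b1), float(b2)),
        slopes=(s1, s2, s3),
        intercept=float(beta[0]),
        fit_sse=float(sse),
        valid_plateau=bool(valid),
    )


def _lstsq_sse_local(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)
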