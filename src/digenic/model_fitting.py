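"""Ordinary least squares with forward selection and sequential variance partition.

The fitting pipeline mirrors a classical stepwise GLM analysis: candidate
terms are entered one at a time, each step admitting the candidate with the
largest sum-of-squares reduction whose partial F-test clears ``alpha``; the
variance explained by a term is its sequential sum-of-squares increment *at
entry*, divided by the total sum of squares about the mean. On a balanced
orthogonal design these increments coincide with the order-free
``SS_term / SS_total`` decomposition; on unbalanced or time-coded designs
they are the natural output of the stepwise procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, RankDeficiencyError, ValidationError
from .genetic_design import DesignMatrix, ModelSpec, build_design

__all__ = [
    "EffectEstimate",
    "FitResult",
    "OLSFit",
    "SelectionResult",
    "fit_ols",
    "forward_select",
    "partition_r2",
    "fit_digenic",
    "dominance_ratio",
    "reconstruct_replicates",
]


@dataclass(frozen=True)
class EffectEstimate:
    """One retained model term."""

    term: str
    coefficient: float
    standard_error: float
    p_value: float
    r2_increment: float
    entry_order: int


@dataclass
class FitResult:
    """Outcome of fitting one digenic model."""

    mu: float
    estimates: list[EffectEstimate]
    total_r2: float
    residual_variance: float
    n_obs: int
    model_kind: str
    mu_p_value: float = float("nan")

    def estimate(self, term: str) -> EffectEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)

    @property
    def terms(self) -> list[str]:
        return [e.term for e in self.estimates]


@dataclass
class OLSFit:
    """Raw least-squares output for an intercept-plus-terms design."""

    labels: tuple[str, ...]  # includes "mu" first
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    residuals: np.ndarray
    sse: float
    df_resid: int

    def coefficient(self, label: str) -> float:
        return float(self.coefficients[self.labels.index(label)])


def _lstsq_sse(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _collinear_columns(X: np.ndarray, labels: tuple[str, ...]) -> list[str]:
    """Columns not supportable by a pivoted-QR basis of X (order-stable)."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > diag.max() * max(X.shape) * np.finfo(float).eps).sum()) if diag.size else 0
    dropped = sorted(piv[rank:])
    return [labels[j] for j in dropped]


def fit_ols(design: DesignMatrix, terms: tuple[str, ...] | None = None) -> OLSFit:
    """Least-squares fit of the intercept plus ``terms`` (default: all columns).

    Per-coefficient p-values come from the two-sided t test, equivalent to
    the 1-df partial F test. With zero residual degrees of freedom the fit is
    exact and standard errors / p-values are NaN.
    """
    labels = ("mu",) + (tuple(terms) if terms is not None else design.term_labels)
    X = design.subset(labels[1:])
    y = design.response
    n, p = X.shape
    if n < p:
        raise FitError(f"{n} observations cannot identify {p} coefficients")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError(_collinear_columns(X, labels))

    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = n - p
    if df > 0:
        sigma2 = sse / df
        se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    else:
        se = np.full(p, np.nan)
        pvals = np.full(p, np.nan)
    return OLSFit(
        labels=labels,
        coefficients=beta,
        standard_errors=se,
        p_values=pvals,
        residuals=resid,
        sse=sse,
        df_resid=df,
    )


@dataclass
class SelectionResult:
    """Terms retained by forward entry, with bookkeeping for the R2 partition."""

    retained: list[str] = field(default_factory=list)
    ss_increments: dict[str, float] = field(default_factory=dict)
    ss_total: float = 0.0
    sse_final: float = 0.0

    @property
    def entry_order(self) -> dict[str, int]:
        return {t: k + 1 for k, t in enumerate(self.retained)}


def forward_select(design: DesignMatrix, alpha: float = 0.05) -> SelectionResult:
    """Forward stepwise entry over the design's candidate terms.

    At each step the candidate with the largest SSE reduction is tested with
    the partial F statistic against the residual of the augmented model; it
    enters if ``p < alpha``. Ties go to the earlier candidate in the design's
    term order. An empty retained set is a valid outcome.
    """
    y = design.response
    n = design.n_obs
    ss_total = float(((y - y.mean()) ** 2).sum())
    result = SelectionResult(ss_total=ss_total, sse_final=ss_total)
    if ss_total == 0.0:
        return result

    current: list[str] = []
    sse_cur = ss_total
    candidates = list(design.term_labels)
    while len(current) < len(candidates):
        best = None
        for term in candidates:
            if term in current:
                continue
            sse = _lstsq_sse(design.subset(current + [term]), y)
            inc = sse_cur - sse
            if best is None or inc > best[1] + 1e-12 * ss_total:
                best = (term, inc, sse)
        term, inc, sse = best
        df_new = n - (len(current) + 2)
        if sse <= 1e-12 * ss_total:
            p = 0.0  # exact fit: the term removes all remaining variation
        elif df_new <= 0:
            break  # no residual df left to test against
        else:
            F = inc / (sse / df_new)
            p = float(stats.f.sf(F, 1, df_new))
        if p >= alpha:
            break
        current.append(term)
        result.retained.append(term)
        result.ss_increments[term] = inc
        sse_cur = sse
        result.sse_final = sse
        if sse_cur <= 1e-12 * ss_total:
            break
    return result


def partition_r2(design: DesignMatrix, retained: list[str]) -> dict[str, float]:
    """Sequential R2 increments for ``retained`` terms, in the given entry order.

    Each increment is the drop in residual SS when the term entered divided
    by the total SS about the mean; the increments sum to the final model R2.
    """
    y = design.response
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total == 0.0:
        return {t: 0.0 for t in retained}
    out: dict[str, float] = {}
    sse_prev = ss_total
    for k in range(len(retained)):
        sse = _lstsq_sse(design.subset(retained[: k + 1]), y)
        out[retained[k]] = (sse_prev - sse) / ss_total
        sse_prev = sse
    return out


def _prune_degenerate(design: DesignMatrix) -> DesignMatrix:
    """Drop zero-variance or duplicated predictor columns, with a warning."""
    keep: list[str] = []
    seen: list[np.ndarray] = []
    dropped: list[str] = []
    for label in design.term_labels:
        col = design.column(label)
        if np.ptp(col) == 0.0:
            dropped.append(label)
            continue
        if any(np.array_equal(col, s) for s in seen):
            dropped.append(label)
            continue
        keep.append(label)
        seen.append(col)
    if not dropped:
        return design
    warnings.warn(
        f"dropping degenerate design columns before fitting: {', '.join(dropped)}",
        stacklevel=3,
    )
    idx = [0] + [design.term_labels.index(l) + 1 for l in keep]
    return DesignMatrix(
        term_labels=tuple(keep),
        matrix=design.matrix[:, idx],
        response=design.response,
        observation_ids=design.observation_ids,
    )


def fit_digenic(records, spec: ModelSpec, select: bool = True) -> FitResult:
    """Build the design, optionally forward-select terms, fit, and partition R2.

    With ``select=False`` every candidate term is fitted and the sequential
    partition follows candidate order; this is the right mode for saturated
    designs (e.g. one observation per genotype class) where no residual
    degrees of freedom exist for entry tests.
    """
    design = _prune_degenerate(build_design(records, spec))

    if select:
        sel = forward_select(design, spec.selection_alpha)
        retained = sel.retained
    else:
        retained = list(design.term_labels)

    increments = partition_r2(design, retained)
    ols = fit_ols(design, tuple(retained))

    estimates = [
        EffectEstimate(
            term=t,
            coefficient=float(ols.coefficients[k + 1]),
            standard_error=float(ols.standard_errors[k + 1]),
            p_value=float(ols.p_values[k + 1]),
            r2_increment=float(increments[t]),
            entry_order=k + 1,
        )
        for k, t in enumerate(retained)
    ]
    y = design.response
    ss_total = float(((y - y.mean()) ** 2).sum())
    total_r2 = 1.0 - ols.sse / ss_total if ss_total > 0 else 0.0
    if ols.df_resid > 0:
        residual_variance = ols.sse / ols.df_resid
    else:
        residual_variance = 0.0 if ols.sse <= 1e-12 * max(ss_total, 1.0) else float("nan")
    return FitResult(
        mu=float(ols.coefficients[0]),
        estimates=estimates,
        total_r2=float(total_r2),
        residual_variance=float(residual_variance),
        n_obs=design.n_obs,
        model_kind=spec.model_kind,
        mu_p_value=float(ols.p_values[0]),
    )


def dominance_ratio(fit: FitResult, locus: int = 1) -> float:
    """``|d/a|`` for a locus (1 or 2); 0 when no dominance term was retained."""
    if locus not in (1, 2):
        raise ValidationError(f"locus must be 1 or 2, got {locus!r}")
    a_term, d_term = f"a{locus}", f"d{locus}"
    try:
        a = fit.estimate(a_term).coefficient
    except KeyError:
        raise FitError(f"fit does not contain the additive term {a_term!r}") from None
    if a == 0.0:
        raise FitError(f"additive coefficient {a_term!r} is zero; dominance ratio undefined")
    try:
        d = fit.estimate(d_term).coefficient
    except KeyError:
        return 0.0
    return abs(d / a)


def reconstruct_replicates(mean: float, se: float, n: int = 3) -> np.ndarray:
    """``n`` values whose sample mean and sample standard error are exact.

    Uses a symmetric pattern around the mean scaled so that the sample
    standard deviation equals ``se * sqrt(n)``. For n=3 this is
    ``{m - se*sqrt(3), m, m + se*sqrt(3)}``. Because the reconstruction
    preserves cell means and within-cell sums of squares, any linear model
    whose predictors are constant within cells gives identical fits on the
    reconstructed data and on the raw data it summarizes.
    """
    if se < 0:
        raise ValidationError(f"standard error must be non-negative, got {se!r}")
    if n < 2:
        if se > 0:
            raise ValidationError("cannot reconstruct spread from a single replicate")
        return np.full(max(n, 1), float(mean))
    if n % 2:
        pattern = np.concatenate([-np.ones(n // 2), [0.0], np.ones(n // 2)])
    else:
        pattern = np.concatenate([-np.ones(n // 2), np.ones(n // 2)])
    sd = pattern.std(ddof=1)
    unit = pattern / sd  # sample SD exactly 1, mean exactly 0
    return mean + se * np.sqrt(n) * unit
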