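"""Orthogonal-contrast coding of two-locus genotypes and design-matrix assembly.

Three linear models are supported, named by their structure:

``genotype_time``
    Homozygous lines crossed with a two-level development-time factor:
    additive terms for each locus, their product (additive-by-additive
    epistasis), a 0/1 time contrast, and genotype-by-time products.
``f2``
    A segregating F2 population: additive and dominance terms at each locus
    plus the four digenic epistatic products. No time factor.
``additive``
    Homozygous lines only: additive terms and their product.

Additive dosage is coded -1/0/+1 for 0/1/2 functional alleles; dominance is
+0.5 for the heterozygote and -0.5 for either homozygote, which is orthogonal
to the additive contrast under exact 1:2:1 frequencies. Interaction columns
are element-wise products of their parent columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError

__all__ = [
    "DigenicGenotype",
    "ModelSpec",
    "DesignMatrix",
    "MODEL_KINDS",
    "MODEL_TERMS",
    "code_additive",
    "code_dominance",
    "code_time",
    "build_design",
    "check_orthogonality",
    "parse_genotype_label",
]

#: Candidate terms per model kind, in equationally conventional order; this
#: order breaks ties during forward selection.
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "genotype_time": ("a1", "a2", "i_a1a2", "tau", "i_a1tau", "i_a2tau"),
    "f2": ("a1", "d1", "a2", "d2", "i_a1a2", "i_a1d2", "i_d1a2", "i_d1d2"),
    "additive": ("a1", "a2", "i_a1a2"),
}

MODEL_KINDS = tuple(MODEL_TERMS)

_HOMOZYGOUS_ONLY = {"genotype_time", "additive"}


@dataclass(frozen=True)
class DigenicGenotype:
    """Functional-allele dosage (0, 1 or 2) at each of two unlinked loci."""

    rc_dosage: int
    pb_dosage: int

    def __post_init__(self):
        for name, dosage in (("rc_dosage", self.rc_dosage), ("pb_dosage", self.pb_dosage)):
            if dosage not in (0, 1, 2):
                raise ValidationError(f"{name} must be 0, 1 or 2, got {dosage!r}")

    @property
    def is_homozygous(self) -> bool:
        return self.rc_dosage != 1 and self.pb_dosage != 1

    def __iter__(self):
        return iter((self.rc_dosage, self.pb_dosage))


def parse_genotype_label(label: str) -> DigenicGenotype:
    """Map an allele-string label like ``"RcRcPbpb"`` or ``"rcpb"`` to dosages.

    Two-letter shorthand (``"Rcpb"``) denotes the homozygote for each symbol.
    """

    def locus_dosage(s: str, upper: str, lower: str) -> int:
        if s in (upper + upper, upper):
            return 2
        if s in (upper + lower, lower + upper):
            return 1
        if s in (lower + lower, lower):
            return 0
        raise ValidationError(f"cannot parse locus genotype {s!r}")

    for split in (2, 4):
        rc_part, pb_part = label[:split], label[split:]
        try:
            return DigenicGenotype(
                locus_dosage(rc_part, "Rc", "rc"), locus_dosage(pb_part, "Pb", "pb")
            )
        except ValidationError:
            continue
    raise ValidationError(f"cannot parse genotype label {label!r}")


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, which terms are candidates, and the entry threshold."""

    model_kind: str
    candidate_terms: tuple[str, ...] = ()
    selection_alpha: float = 0.05

    def __post_init__(self):
        if self.model_kind not in MODEL_TERMS:
            raise ValidationError(
                f"unknown model_kind {self.model_kind!r}; expected one of {MODEL_KINDS}"
            )
        allowed = MODEL_TERMS[self.model_kind]
        terms = tuple(self.candidate_terms) or allowed
        for t in terms:
            if t not in allowed:
                raise ValidationError(
                    f"term {t!r} is not admissible for model {self.model_kind!r}"
                )
        object.__setattr__(self, "candidate_terms", terms)
        if not 0 < self.selection_alpha < 1:
            raise ValidationError("selection_alpha must lie in (0, 1)")


def code_additive(dosage: int) -> float:
    """-1 for the null homozygote, 0 for the heterozygote, +1 for the functional homozygote."""
    if dosage not in (0, 1, 2):
        raise ValidationError(f"dosage must be 0, 1 or 2, got {dosage!r}")
    return float(dosage - 1)


def code_dominance(dosage: int) -> float:
    """+0.5 for the heterozygote, -0.5 for either homozygote."""
    if dosage not in (0, 1, 2):
        raise ValidationError(f"dosage must be 0, 1 or 2, got {dosage!r}")
    return 0.5 if dosage == 1 else -0.5


def code_time(value, levels: Sequence | None = None) -> float:
    """Code a two-level development-time factor 0 (earlier) / 1 (later).

    ``levels`` declares the two ordered levels; the default is ``(5, 40)``
    days post-anthesis. A single-level or >2-level declaration is an error
    because the contrast is undefined.
    """
    levels = tuple(levels) if levels is not None else (5, 40)
    if len(set(levels)) != 2:
        raise ValidationError(
            f"time factor must have exactly two distinct levels, got {levels!r}"
        )
    lo, hi = sorted(set(levels))
    if value == lo:
        return 0.0
    if value == hi:
        return 1.0
    raise ValidationError(f"time value {value!r} is not one of the declared levels {levels!r}")


@dataclass
class DesignMatrix:
    """Coded predictors plus the response.

    ``matrix`` holds the intercept column (all ones, label ``"mu"``) first,
    followed by one column per entry of ``term_labels`` in order.
    """

    term_labels: tuple[str, ...]
    matrix: np.ndarray
    response: np.ndarray
    observation_ids: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.matrix.ndim != 2:
            raise DesignError("design matrix must be 2-dimensional")
        if self.matrix.shape[0] != self.response.shape[0]:
            raise DesignError("matrix and response row counts differ")
        if self.matrix.shape[1] != len(self.term_labels) + 1:
            raise DesignError("matrix has a column count inconsistent with term_labels")
        if not np.allclose(self.matrix[:, 0], 1.0):
            raise DesignError("first column must be the intercept (all ones)")
        if not self.observation_ids:
            self.observation_ids = tuple(range(self.n_obs))

    @property
    def n_obs(self) -> int:
        return self.matrix.shape[0]

    def column(self, label: str) -> np.ndarray:
        if label == "mu":
            return self.matrix[:, 0]
        try:
            j = self.term_labels.index(label)
        except ValueError:
            raise KeyError(label) from None
        return self.matrix[:, j + 1]

    def subset(self, labels: Iterable[str]) -> np.ndarray:
        """Intercept plus the named columns, in the given order."""
        cols = [np.ones(self.n_obs)] + [self.column(l) for l in labels]
        return np.column_stack(cols)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=("mu",) + tuple(self.term_labels))
        df["response"] = self.response
        df.insert(0, "observation_id", list(self.observation_ids))
        return df


def _term_value(term: str, xi: float, zi: float, xj: float, zj: float, zk: float | None) -> float:
    if term in ("tau", "i_a1tau", "i_a2tau") and zk is None:
        raise DesignError(f"term {term!r} requires a time value for every record")
    return {
        "a1": lambda: xi,
        "d1": lambda: zi,
        "a2": lambda: xj,
        "d2": lambda: zj,
        "i_a1a2": lambda: xi * xj,
        "i_a1d2": lambda: xi * zj,
        "i_d1a2": lambda: zi * xj,
        "i_d1d2": lambda: zi * zj,
        "tau": lambda: zk,
        "i_a1tau": lambda: zk * xi,
        "i_a2tau": lambda: zk * xj,
    }[term]()


def build_design(records: Sequence[tuple], spec: ModelSpec) -> DesignMatrix:
    """Assemble a :class:`DesignMatrix` from ``(genotype, time, y)`` records.

    Each record is ``(DigenicGenotype, time_or_None, response)``; an
    ``(genotype, response)`` 2-tuple is accepted for models without a time
    factor. Row order is preserved and the construction is deterministic.
    """
    if not records:
        raise DesignError("no records supplied")

    parsed = []
    for rec in records:
        if len(rec) == 2:
            gt, y = rec
            t = None
        else:
            gt, t, y = rec
        if not isinstance(gt, DigenicGenotype):
            gt = DigenicGenotype(*gt)
        parsed.append((gt, t, float(y)))

    if spec.model_kind in _HOMOZYGOUS_ONLY:
        for idx, (gt, _, _) in enumerate(parsed):
            if not gt.is_homozygous:
                raise DesignError(
                    f"model {spec.model_kind!r} admits homozygous genotypes only; "
                    f"record {idx} has dosages {tuple(gt)}"
                )

    needs_time = spec.model_kind == "genotype_time"
    if needs_time:
        times = [t for _, t, _ in parsed]
        if any(t is None for t in times):
            raise DesignError("genotype_time model requires a time value for every record")
        levels = sorted(set(times))
        if len(levels) != 2:
            raise ValidationError(
                f"time factor must have exactly two observed levels, got {levels!r}"
            )
    else:
        levels = None

    rows = []
    for gt, t, y in parsed:
        xi, xj = code_additive(gt.rc_dosage), code_additive(gt.pb_dosage)
        zi, zj = code_dominance(gt.rc_dosage), code_dominance(gt.pb_dosage)
        zk = code_time(t, levels) if needs_time else None
        rows.append([1.0] + [_term_value(term, xi, zi, xj, zj, zk) for term in spec.candidate_terms])

    return DesignMatrix(
        term_labels=tuple(spec.candidate_terms),
        matrix=np.array(rows, dtype=float),
        response=np.array([y for _, _, y in parsed], dtype=float),
    )


@dataclass
class OrthogonalityReport:
    """Pairwise centered inner products of non-intercept columns."""

    labels: tuple[str, ...]
    inner_products: np.ndarray  # symmetric, zero diagonal ignored
    orthogonal: np.ndarray  # boolean mask per pair
    tolerance: float

    def pair(self, a: str, b: str) -> tuple[float, bool]:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.inner_products[i, j]), bool(self.orthogonal[i, j])

    @property
    def all_orthogonal(self) -> bool:
        mask = ~np.eye(len(self.labels), dtype=bool)
        return bool(self.orthogonal[mask].all())


def check_orthogonality(design: DesignMatrix, tol_scale: float = 1e-9) -> OrthogonalityReport:
    """Report centered inner products between every pair of predictor columns.

    A pair is flagged orthogonal when ``|<xc, yc>| < tol_scale * n``.
    """
    labels = design.term_labels
    if len(labels) < 2:
        raise DesignError("orthogonality check needs at least two non-intercept columns")
    X = design.matrix[:, 1:]
    Xc = X - X.mean(axis=0)
    G = Xc.T @ Xc
    tol = tol_scale * design.n_obs
    return OrthogonalityReport(
        labels=labels,
        inner_products=G,
        orthogonal=np.abs(G) < tol,
        tolerance=tol,
    )
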