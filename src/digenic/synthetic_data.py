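"""Generators for every input the pipeline consumes.

All generators are deterministic under a fixed seed. A
:class:`SimulationConfig` carries one master seed; sub-generators draw from
streams split off a single :class:`numpy.random.SeedSequence`, so adding a
generator to a run does not perturb the draws of the others.

Distributional choices (documented per generator) are pragmatic stand-ins
for processes the experimental design does not model mechanistically:
germination timing is a discretized logistic, measurement noise is Gaussian,
and the imbibition base curve is continuous piecewise linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from . import reference
from .errors import ValidationError
from .genetic_design import DigenicGenotype, code_additive, code_dominance
from .metrics import IMBIBITION_TIME_GRID, GerminationRecord, ImbibitionSeries

__all__ = [
    "SimulationConfig",
    "GerminationClassConfig",
    "GerminationConfig",
    "FlavonoidConfig",
    "ImbibitionConfig",
    "FlavonoidSample",
    "simulate_f2_genotypes",
    "simulate_phenotypes",
    "simulate_germination_counts",
    "simulate_flavonoid_panel",
    "simulate_imbibition",
    "default_config",
]

#: Genotype terms a generative linear predictor may reference.
_CODERS = {
    "a1": lambda g: code_additive(g.rc_dosage),
    "d1": lambda g: code_dominance(g.rc_dosage),
    "a2": lambda g: code_additive(g.pb_dosage),
    "d2": lambda g: code_dominance(g.pb_dosage),
    "i_a1a2": lambda g: code_additive(g.rc_dosage) * code_additive(g.pb_dosage),
    "i_a1d2": lambda g: code_additive(g.rc_dosage) * code_dominance(g.pb_dosage),
    "i_d1a2": lambda g: code_dominance(g.rc_dosage) * code_additive(g.pb_dosage),
    "i_d1d2": lambda g: code_dominance(g.rc_dosage) * code_dominance(g.pb_dosage),
}


def linear_predictor(genotype: DigenicGenotype, mu: float, effects: Mapping[str, float]) -> float:
    """Deterministic part of a genotype's phenotype under an effects map."""
    total = mu
    for term, value in effects.items():
        try:
            coder = _CODERS[term]
        except KeyError:
            raise ValidationError(f"unknown effect term {term!r}") from None
        total += value * coder(genotype)
    return total


@dataclass
class GerminationClassConfig:
    """Germination behaviour of one genotype class."""

    p_g: float  # probability a seed germinates within the test
    mean_day: float  # logistic location of the germination day
    dispersion: float  # logistic scale; 0 = all seeds on round(mean_day)

    def __post_init__(self):
        if not 0.0 <= self.p_g <= 1.0:
            raise ValidationError(f"p_g must be in [0, 1], got {self.p_g!r}")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")


@dataclass
class GerminationConfig:
    per_genotype: dict[tuple[int, int], GerminationClassConfig]
    n_total: int = 60
    schedule: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    horizon: int = 7


@dataclass
class FlavonoidConfig:
    """Cell means/SEs for the genotype x time x chemical panel."""

    cells: dict[tuple[int, int, int], dict[str, tuple[float, float] | None]] = field(
        default_factory=lambda: {k: dict(v) for k, v in reference.FLAVONOID_PANEL.items()}
    )
    n_replicates: int = 3
    #: Replicate count the cell SEs summarize; per-replicate SD = SE * sqrt(se_replicates).
    se_replicates: int = 3
    detect_floor: float = 0.0


@dataclass
class ImbibitionConfig:
    """Triphasic water-uptake curve plus genotype effect onsets."""

    time_grid: tuple[float, ...] = IMBIBITION_TIME_GRID
    #: Nearest grid points to the published ~30/~50 h phase ends; keeping the
    #: kinks on the measurement grid makes noise-free curves exactly
    #: recoverable by segment_phases.
    breakpoints: tuple[float, float] = (28.0, 52.0)
    slopes: tuple[float, float, float] = (0.0115, 0.0008, 0.0030)
    noise_sd: float = 0.004
    w0: float = 2.0
    #: term -> (effect size on the wc scale, onset hour); the full effect
    #: applies from the onset hour onward and is absent before it.
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Master configuration for a simulation run."""

    seed: int = 0
    n: int = reference.N_F2_PLANTS
    effects: dict[str, float] = field(default_factory=lambda: {
        k: v for k, v in reference.F2_GP_EFFECTS.items() if k != "mu"
    })
    mu: float = reference.F2_GP_EFFECTS["mu"]
    residual_sd: float = 14.0
    germination: GerminationConfig | None = None
    imbibition: ImbibitionConfig | None = None
    flavonoid: FlavonoidConfig | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("n must be at least 1")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be non-negative")

    def rngs(self, *names: str) -> dict[str, np.random.Generator]:
        """Named independent generators split off the master seed.

        Streams are assigned by position in a fixed registry, so a given name
        maps to the same stream regardless of which names are requested.
        """
        registry = ("genotypes", "phenotypes", "germination", "flavonoid", "imbibition")
        children = np.random.SeedSequence(self.seed).spawn(len(registry))
        out = {}
        for name in names:
            if name not in registry:
                raise ValidationError(f"unknown RNG stream {name!r}")
            out[name] = np.random.default_rng(children[registry.index(name)])
        return out


def config_to_mapping(config: SimulationConfig) -> dict:
    """Plain-mapping rendering of a config (tuple keys become ':'-joined strings)."""
    d = asdict(config)
    if config.germination is not None:
        d["germination"]["per_genotype"] = {
            f"{rc}:{pb}": asdict(c) for (rc, pb), c in config.germination.per_genotype.items()
        }
    if config.flavonoid is not None:
        d["flavonoid"]["cells"] = {
            f"{rc}:{pb}:{dpa}": {
                chem: (list(v) if v is not None else None) for chem, v in chems.items()
            }
            for (rc, pb, dpa), chems in config.flavonoid.cells.items()
        }
    if config.imbibition is not None:
        d["imbibition"]["effects"] = {
            term: list(v) for term, v in config.imbibition.effects.items()
        }
    return d


def config_from_mapping(mapping: Mapping) -> SimulationConfig:
    """Inverse of :func:`config_to_mapping`; unknown keys are rejected."""
    d = dict(mapping)
    germ = d.pop("germination", None)
    imb = d.pop("imbibition", None)
    flav = d.pop("flavonoid", None)
    try:
        cfg = SimulationConfig(**d)
    except TypeError as exc:
        raise ValidationError(f"bad simulation config: {exc}") from None
    if germ is not None:
        germ = dict(germ)
        per = {
            tuple(int(x) for x in key.split(":")): GerminationClassConfig(**val)
            for key, val in dict(germ.pop("per_genotype")).items()
        }
        sched = germ.pop("schedule", (2, 3, 4, 5, 6, 7))
        cfg.germination = GerminationConfig(per_genotype=per, schedule=tuple(sched), **germ)
    if imb is not None:
        imb = dict(imb)
        for key in ("time_grid", "breakpoints", "slopes"):
            if key in imb:
                imb[key] = tuple(imb[key])
        if "effects" in imb:
            imb["effects"] = {t: tuple(v) for t, v in dict(imb["effects"]).items()}
        cfg.imbibition = ImbibitionConfig(**imb)
    if flav is not None:
        flav = dict(flav)
        cells = {
            tuple(int(x) for x in key.split(":")): {
                chem: (tuple(v) if v is not None else None) for chem, v in val.items()
            }
            for key, val in dict(flav.pop("cells")).items()
        }
        cfg.flavonoid = FlavonoidConfig(cells=cells, **flav)
    return cfg


def default_config(seed: int = 0) -> SimulationConfig:
    """A fully-populated configuration using the shipped reference defaults."""
    per_geno = {}
    mean_days = {(0, 0): 2.6, (2, 0): 3.4, (0, 2): 3.0, (2, 2): 4.2}
    for key, gp in reference.IL_GP7_MEANS.items():
        per_geno[key] = GerminationClassConfig(
            p_g=gp / 100.0, mean_day=mean_days[key], dispersion=0.6
        )
    return SimulationConfig(
        seed=seed,
        germination=GerminationConfig(per_genotype=per_geno),
        imbibition=ImbibitionConfig(
            effects={"a1": (-0.010, 28.0), "a2": (-0.012, 6.0), "i_a1a2": (-0.002, 6.0)}
        ),
        flavonoid=FlavonoidConfig(),
    )


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_f2_genotypes(n: int, rng) -> list[DigenicGenotype]:
    """Genotypes of n F2 plants from selfing a double heterozygote.

    Each locus segregates independently 1:2:1 over dosages (0, 1, 2); the
    two loci are unlinked.
    """
    if n < 1:
        raise ValidationError("n must be at least 1")
    r = _as_rng(rng)
    probs = [0.25, 0.5, 0.25]
    rc = r.choice(3, size=n, p=probs)
    pb = r.choice(3, size=n, p=probs)
    return [DigenicGenotype(int(a), int(b)) for a, b in zip(rc, pb)]


def simulate_phenotypes(
    genotypes: Sequence[DigenicGenotype],
    effects: Mapping[str, float],
    mu: float,
    residual_sd: float,
    rng,
) -> np.ndarray:
    """Phenotypes = coded linear predictor + Gaussian residual."""
    r = _as_rng(rng)
    mean = np.array([linear_predictor(g, mu, effects) for g in genotypes])
    if residual_sd < 0:
        raise ValidationError("residual_sd must be non-negative")
    return mean + r.normal(0.0, residual_sd, size=len(genotypes))


def simulate_germination_counts(
    genotypes: Sequence[DigenicGenotype],
    config: GerminationConfig,
    rng,
) -> list[GerminationRecord]:
    """One germination record per supplied genotype.

    Each seed germinates with its class probability; the germination day is a
    rounded logistic draw. Seeds whose day falls after the horizon are not
    counted (they did not germinate within the test); days before a counting
    day are credited to the next scheduled count, matching how cumulative
    daily counting works.
    """
    r = _as_rng(rng)
    schedule = tuple(config.schedule)
    records = []
    for idx, g in enumerate(genotypes):
        key = (g.rc_dosage, g.pb_dosage)
        try:
            cls = config.per_genotype[key]
        except KeyError:
            raise ValidationError(f"no germination config for genotype class {key}") from None
        counts = [0] * len(schedule)
        n_germ = r.binomial(config.n_total, cls.p_g)
        if cls.dispersion == 0.0:
            days = np.full(n_germ, round(cls.mean_day))
        else:
            days = np.rint(r.logistic(cls.mean_day, cls.dispersion, size=n_germ))
        for day in days:
            if day > config.horizon:
                continue  # germinated after the test window
            slot = next((k for k, d in enumerate(schedule) if d >= day), None)
            if slot is None:
                continue
            counts[slot] += 1
        records.append(
            GerminationRecord(
                sample_id=f"sim{idx}",
                genotype=g,
                n_total=config.n_total,
                schedule=schedule,
                counts=tuple(counts),
                horizon=config.horizon,
            )
        )
    return records


@dataclass(frozen=True)
class FlavonoidSample:
    """One replicate measurement of one chemical in one genotype x time cell."""

    genotype: DigenicGenotype
    dpa: int
    chemical: str
    replicate: int
    value: float
    detected: bool


def simulate_flavonoid_panel(config: FlavonoidConfig, rng) -> list[FlavonoidSample]:
    """Gaussian replicates around each cell mean with SD = SE * sqrt(se_replicates).

    Non-detectable cells yield exact zeros flagged ``detected=False``; draws
    below ``detect_floor`` are floored to zero and likewise flagged.
    """
    r = _as_rng(rng)
    out = []
    for (rc, pb, dpa), chems in sorted(config.cells.items()):
        g = DigenicGenotype(rc, pb)
        for chem in sorted(chems):
            cell = chems[chem]
            for rep in range(config.n_replicates):
                if cell is None:
                    out.append(FlavonoidSample(g, dpa, chem, rep, 0.0, False))
                    continue
                mean, se = cell
                if mean < 0:
                    raise ValidationError(
                        f"negative cell mean for {chem} at genotype {(rc, pb)}, {dpa} DPA"
                    )
                value = float(r.normal(mean, se * np.sqrt(config.se_replicates)))
                if value < config.detect_floor:
                    out.append(FlavonoidSample(g, dpa, chem, rep, 0.0, False))
                else:
                    out.append(FlavonoidSample(g, dpa, chem, rep, value, True))
    return out


def _base_wc(t: np.ndarray, breakpoints: tuple[float, float], slopes) -> np.ndarray:
    b1, b2 = breakpoints
    s1, s2, s3 = slopes
    return (
        s1 * np.minimum(t, b1)
        + s2 * np.clip(t - b1, 0.0, b2 - b1)
        + s3 * np.maximum(t - b2, 0.0)
    )


def simulate_imbibition(
    genotypes: Sequence[DigenicGenotype],
    config: ImbibitionConfig,
    rng,
) -> list[ImbibitionSeries]:
    """Triphasic water-content curves with genotype effects switching on at onsets.

    ``wc(t) = base(t) + sum_term size * code * [t >= onset] + noise``; weights
    are derived as ``w0 * (1 + wc)``. ``wc`` is exactly 0 at t = 0.
    """
    r = _as_rng(rng)
    t = np.asarray(config.time_grid, dtype=float)
    b1, b2 = config.breakpoints
    if not (t.min() <= b1 < b2 <= t.max()):
        raise ValidationError(
            f"breakpoints {config.breakpoints!r} must lie within the time grid and be increasing"
        )
    base = _base_wc(t, config.breakpoints, config.slopes)
    out = []
    for idx, g in enumerate(genotypes):
        wc = base.copy()
        for term, (size, onset) in config.effects.items():
            try:
                code = _CODERS[term](g)
            except KeyError:
                raise ValidationError(f"unknown effect term {term!r}") from None
            wc = wc + size * code * (t >= onset)
        if config.noise_sd > 0:
            wc = wc + r.normal(0.0, config.noise_sd, size=t.size)
        wc[t == 0.0] = 0.0
        out.append(
            ImbibitionSeries(
                sample_id=f"imb{idx}",
                genotype=g,
                w0=config.w0,
                times=tuple(t),
                weights=tuple(config.w0 * (1.0 + wc)),
            )
        )
    return out
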