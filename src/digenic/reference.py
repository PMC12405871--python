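"""Reference dataset: published summary statistics for the rice Rc/Pb digenic system.

These constants are transcribed summary statistics (cell means, standard
errors, and fitted genetic effects) for the four-introgression-line and F2
experiments the pipeline was designed around. They serve as default
parameters for the simulators and as frozen inputs for deterministic
re-analysis; they are NOT raw data.

Genotype keys are ``(rc_dosage, pb_dosage)`` functional-allele dosages;
flavonoid cells are keyed ``(rc_dosage, pb_dosage, dpa)`` with values
``(mean_ug_per_g, se)`` or ``None`` for a non-detectable cell.
"""

from __future__ import annotations

__all__ = [
    "FLAVONOID_CHEMICALS",
    "FLAVONOID_PANEL",
    "FLAVONOID_TIMES",
    "IL_GP7_MEANS",
    "F2_GP_EFFECTS",
    "F2_GI_EFFECTS",
    "IL_GP_EFFECTS",
    "IL_GI_EFFECTS",
    "N_F2_PLANTS",
    "IMBIBITION_BREAKPOINTS_H",
]

#: Flavonoid chemical panel: catechin, procyanidin B3, epicatechin,
#: procyanidin B2, anthocyanins.
FLAVONOID_CHEMICALS: tuple[str, ...] = ("CA", "PB3", "EC", "PB2", "AC")

#: Caryopsis sampling times, days post-anthesis.
FLAVONOID_TIMES: tuple[int, int] = (5, 40)

#: Mean (SE) flavonoid content per genotype x development-time cell, ug/g,
#: from 3 replicates; None = not detectable.
FLAVONOID_PANEL: dict[tuple[int, int, int], dict[str, tuple[float, float] | None]] = {
    (0, 0, 5): {"CA": (1.0, 0.3), "PB3": None, "EC": None, "PB2": None, "AC": None},
    (0, 0, 40): {"CA": (248.0, 53.0), "PB3": None, "EC": None, "PB2": None, "AC": None},
    (2, 0, 5): {
        "CA": (5627.0, 262.0),
        "PB3": (1673.0, 84.0),
        "EC": (106.0, 18.0),
        "PB2": (209.0, 26.0),
        "AC": None,
    },
    (2, 0, 40): {
        "CA": (10167.0, 637.0),
        "PB3": (3072.0, 168.0),
        "EC": (202.0, 11.0),
        "PB2": (510.0, 36.0),
        "AC": None,
    },
    (0, 2, 5): {"CA": (17.9, 4.3), "PB3": None, "EC": None, "PB2": None, "AC": (2331.0, 128.0)},
    (0, 2, 40): {"CA": (9.7, 3.3), "PB3": None, "EC": None, "PB2": None, "AC": (3271.0, 231.0)},
    (2, 2, 5): {
        "CA": (6306.0, 239.0),
        "PB3": (2154.0, 107.0),
        "EC": (125.0, 16.0),
        "PB2": (297.0, 30.0),
        "AC": (125.0, 13.0),
    },
    (2, 2, 40): {
        "CA": (10149.0, 768.0),
        "PB3": (3062.0, 215.0),
        "EC": (234.0, 9.0),
        "PB2": (555.0, 26.0),
        "AC": (3326.0, 168.0),
    },
}

#: Mean 7-day germination percentage per homozygous introgression-line class.
IL_GP7_MEANS: dict[tuple[int, int], float] = {
    (0, 0): 82.0,
    (2, 0): 50.0,
    (0, 2): 69.0,
    (2, 2): 16.0,
}

#: Fitted genetic effects (percent scale) for the F2 germination-percentage
#: model: background, additive, dominance and additive-by-additive epistasis.
F2_GP_EFFECTS: dict[str, float] = {
    "mu": 78.6,
    "a1": -15.0,
    "d1": -3.9,
    "a2": -8.2,
    "i_a1a2": -6.2,
}

#: Fitted effects for the F2 germination-index model.
F2_GI_EFFECTS: dict[str, float] = {"mu": 43.1, "a1": -12.3, "d1": -5.7, "a2": -9.7}

#: Fitted effects for the introgression-line germination models.
IL_GP_EFFECTS: dict[str, float] = {"mu": 54.4, "a1": -21.3, "a2": -11.7, "i_a1a2": -5.2}
IL_GI_EFFECTS: dict[str, float] = {"mu": 32.7, "a1": -13.4, "a2": -9.0, "i_a1a2": -2.6}

#: Number of F2 plants with germination phenotypes.
N_F2_PLANTS: int = 259

#: Approximate ends of imbibition phases I and II, hours after soaking.
IMBIBITION_BREAKPOINTS_H: tuple[float, float] = (30.0, 50.0)
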