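"""Reference parameter sets for the E. coli PNP aging study.

Published global-fit parameters and sample bookkeeping for the hexameric
purine nucleoside phosphorylase experiments that this package models; the
validation studies, the worked examples and the analysis drivers all
simulate from these sets and refit them.  Concentrations are µM in trimer
units, enthalpies kcal/mol, times days, activities U/mg.
"""

from __future__ import annotations

from .binding import BindingSystem
from .decay import DecayModelSpec

__all__ = [
    "PHOSPHATE_ITC_SYSTEM",
    "PHOSPHATE_ITC_CELL_CONCS",
    "FORMYCIN_ITC_SYSTEM",
    "FORMYCIN_ITC_CELL_CONCS",
    "ITC_SAMPLES",
    "EXP_LINEAR_DECAY",
    "LOGISTIC3_HALF_TIMES",
    "LOGISTIC3_DECAY",
    "MC_TITRATION_KD",
    "MC_PROTEIN_TRIMER_UM",
    "MC_ALPHA",
]

#: three-site global ITC fit, enzyme titrated with phosphate
PHOSPHATE_ITC_SYSTEM = BindingSystem(
    kd=(16.52, 154.24, 79.67), dh=(-5.36, -0.13, -1.34)
)
#: initial cell concentrations (µM trimer) of the three phosphate titrations
PHOSPHATE_ITC_CELL_CONCS = (43.98, 144.87, 699.90)

#: three-site global ITC fit, enzyme-phosphate complex titrated with formycin A
FORMYCIN_ITC_SYSTEM = BindingSystem(
    kd=(8.85, 55.2, 812.8), dh=(-6.57, -3.508, -11.027)
)
FORMYCIN_ITC_CELL_CONCS = (23.48, 69.28, 266.86)

#: the six ITC protein samples: specific activity vs. Ino (U/mg), total trimer
#: concentration (µM) and fitted incompetent fraction
ITC_SAMPLES = (
    {"sample_id": "ITC experiment 1", "specific_activity": 66.22, "total_uM": 43.98, "f_inc": 0.099},
    {"sample_id": "ITC experiment 2", "specific_activity": 59.22, "total_uM": 144.87, "f_inc": 0.229},
    {"sample_id": "ITC experiment 3", "specific_activity": 39.36, "total_uM": 699.90, "f_inc": 0.136},
    {"sample_id": "ITC experiment 4", "specific_activity": 29.16, "total_uM": 23.48, "f_inc": 0.0784},
    {"sample_id": "ITC experiment 5", "specific_activity": 37.11, "total_uM": 69.28, "f_inc": 0.0664},
    {"sample_id": "ITC experiment 6", "specific_activity": 76.69, "total_uM": 266.86, "f_inc": 0.0050},
)

#: biphasic storage decay at -80 °C: exponential phase with half-time 56.7 d
#: followed by a slow linear phase (slope -0.024 U/mg/day, offset 73.3 U/mg).
#: The fast-phase amplitude 146.7 U/mg puts the exponential extrapolation to
#: time zero at ~220 U/mg, matching the observed fresh-sample activity.
EXP_LINEAR_DECAY = DecayModelSpec(
    "exp_linear",
    {"a1": 146.7, "t1": 56.7 / 0.6931471805599453, "k": -0.024, "a2": 73.3},
)

#: three-phase logistic inactivation vs. Ino in phosphate buffer at 25 °C
LOGISTIC3_HALF_TIMES = (19.0, 81.1, 227.2)
LOGISTIC3_DECAY = DecayModelSpec(
    "logistic3",
    {
        "a0": 110.0, "a_inf": 0.0,
        "t1": LOGISTIC3_HALF_TIMES[0], "h1": -0.05,
        "t2": LOGISTIC3_HALF_TIMES[1], "h2": -0.05,
        "t3": LOGISTIC3_HALF_TIMES[2], "h3": -0.05,
        "p": 1 / 3, "q": 1 / 3,
    },
)

#: Monte-Carlo robustness study: well-separated site classes, five protein
#: concentrations 0.5-2.5 µM monomer, strong quench led by the tightest class
MC_TITRATION_KD = (5.0, 50.0, 800.0)
MC_PROTEIN_TRIMER_UM = (0.5 / 3, 1.0 / 3, 1.5 / 3, 2.0 / 3, 2.5 / 3)
MC_ALPHA = (-0.5, -0.25, -0.2)


def mc_ligand_grid():
    """Titration grid: zero plus 35 log-spaced points from 0.5 µM to 70 mM."""
    import numpy as np

    return np.concatenate([[0.0], np.logspace(np.log10(0.5), np.log10(70_000.0), 35)])
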