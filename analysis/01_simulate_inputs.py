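#!/usr/bin/env python
"""Generate the synthetic input datasets for the downstream analyses.

Emulates the three experiment types of the aging study with the reference
parameter sets: three-concentration ITC isotherm sets for phosphate and
formycin A binding, a five-concentration fluorescence titration series with
well-separated site classes, and two activity-decay series (biphasic
exp+linear storage decay and three-phase logistic inactivation).  All files
go to results/inputs/ as plain CSV with metadata headers.
"""

from pathlib import Path

import numpy as np

from pnpaging import NoiseModel, generate_decay_series, generate_itc_experiments, generate_titration_series
from pnpaging.io import write_decay_csv, write_itc_csv, write_titration_csv
from pnpaging.reference import (
    EXP_LINEAR_DECAY,
    FORMYCIN_ITC_CELL_CONCS,
    FORMYCIN_ITC_SYSTEM,
    LOGISTIC3_DECAY,
    MC_ALPHA,
    MC_PROTEIN_TRIMER_UM,
    MC_TITRATION_KD,
    PHOSPHATE_ITC_CELL_CONCS,
    PHOSPHATE_ITC_SYSTEM,
    mc_ligand_grid,
)
from pnpaging import BindingSystem
from pnpaging.synthetic import ItcDesign

SEED = 20260301
OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # ITC isotherm sets (noiseless: used for recovery benchmarks)
    for label, system, cells in [
        ("phosphate", PHOSPHATE_ITC_SYSTEM, PHOSPHATE_ITC_CELL_CONCS),
        ("formycinA", FORMYCIN_ITC_SYSTEM, FORMYCIN_ITC_CELL_CONCS),
    ]:
        designs = [
            ItcDesign(c, c * 3 * 20.0, experiment_id=f"{label}_{i}")
            for i, c in enumerate(cells)
        ]
        exps = generate_itc_experiments(designs, system, NoiseModel(scale=0.0))
        for exp in exps:
            write_itc_csv(exp, OUT / f"itc_{exp.experiment_id}.csv", seed=SEED)
        print(f"wrote 3 {label} ITC isotherms (cells {cells} µM trimer)")

    # fluorescence titration series at 1% noise
    curves = generate_titration_series(
        np.asarray(MC_PROTEIN_TRIMER_UM),
        mc_ligand_grid(),
        MC_ALPHA,
        BindingSystem(MC_TITRATION_KD),
        NoiseModel(scale=0.01, seed=SEED),
    )
    write_titration_csv(curves, OUT / "titration_series.csv", seed=SEED)
    print(f"wrote titration series: {len(curves)} curves x {curves[0].signal.size} points, 1% noise")

    # activity-decay series with replicate noise (<=5% relative, 4 replicates)
    for label, spec, t in [
        ("storage_explinear", EXP_LINEAR_DECAY, np.linspace(0, 1000, 40)),
        ("inactivation_logistic3", LOGISTIC3_DECAY, np.linspace(0, 400, 60)),
    ]:
        series = generate_decay_series(
            spec, t, NoiseModel(scale=0.03, replicates=4, seed=SEED),
            buffer="phosphate", substrate="Ino",
        )
        write_decay_csv(series, OUT / f"decay_{label}.csv", seed=SEED, family=spec.family)
        print(f"wrote decay series {label}: {t.size} points, family {spec.family}")


if __name__ == "__main__":
    main()
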