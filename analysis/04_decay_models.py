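#!/usr/bin/env python
"""Fit the decay-model catalogue to the simulated inactivation series.

For each decay series written by 01_simulate_inputs.py, fits every family
in the catalogue by inverse-variance-weighted least squares, ranks them by
AICc, and reports the preferred family with its per-phase half-times (and
linear slopes).  Writes results/decay_model_ranking.csv.
"""

from pathlib import Path

import pandas as pd

from pnpaging import compare_decay_models
from pnpaging.io import read_decay_csv

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for path in sorted(ROOT.glob("inputs/decay_*.csv")):
        series = read_decay_csv(path)
        ranking = compare_decay_models(series, weighted=True)
        print(f"\n{path.name}:")
        for rank, (family, fit, score) in enumerate(ranking, start=1):
            if fit is None:
                print(f"  {rank}. {family}: fit failed")
                continue
            marker = " *preferred*" if rank == 1 else ""
            print(f"  {rank}. {family}: AICc={score:.1f}{marker}")
            rows.append(
                {
                    "series": path.stem,
                    "rank": rank,
                    "family": family,
                    "aicc": score,
                    "rss": fit.rss,
                    "k": fit.k,
                    **{name: val for name, val in fit.half_times.items()},
                }
            )
        best_family, best_fit, _ = ranking[0]
        ht = ", ".join(f"{k}={v:.3g}" for k, v in best_fit.half_times.items())
        print(f"  preferred {best_family}: {ht}")
    pd.DataFrame(rows).to_csv(ROOT / "decay_model_ranking.csv", index=False)
    print(f"\nwrote {ROOT / 'decay_model_ranking.csv'}")


if __name__ == "__main__":
    main()
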