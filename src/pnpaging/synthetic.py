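"""Seeded generators emulating the three experimental input types.

Every generator draws replicate-level heteroscedastic Gaussian noise with a
NumPy integer-seeded Generator, so fixed seeds give identical data across
platforms and ``scale=0`` reproduces the forward model exactly.  Defaults
mirror the study conditions: activity points are means of 3–5 replicates
whose relative error stays below ~5%; titration series consist of five
curves at different protein concentrations with ~1% signal noise; ITC sets
are three experiments spanning a 10–30-fold receptor-concentration range
with 20 × 2 µL injections into a 200 µL cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding import BindingSystem
from .decay import DecayModelSpec, DecaySeries, eval_decay
from .fluorescence import FluorModelParams, TitrationCurve, predict_fluorescence
from .itc import ItcExperiment, simulate_itc

__all__ = [
    "NoiseModel",
    "ItcDesign",
    "generate_decay_series",
    "generate_titration_series",
    "generate_itc_experiments",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level Gaussian noise specification.

    ``gaussian_relative`` scales the SD with the signal magnitude (scale is
    the relative error), ``gaussian_constant`` uses an absolute SD in signal
    units.  ``replicates`` draws are averaged per point, mirroring the 3–5
    repeated activity measurements.
    """

    kind: str = "gaussian_relative"
    scale: float = 0.01
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian_constant", "gaussian_relative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def sd_for(self, value: np.ndarray) -> np.ndarray:
        if self.kind == "gaussian_relative":
            return self.scale * np.abs(value)
        return np.full_like(np.asarray(value, dtype=float), self.scale)


def generate_decay_series(
    spec: DecayModelSpec,
    t: np.ndarray,
    noise: NoiseModel,
    buffer: str = "",
    substrate: str = "",
) -> DecaySeries:
    """Replicate-averaged activity-decay series from a decay model.

    Each time point is the mean of ``noise.replicates`` noisy draws, with
    the replicate standard deviation of the mean as its SD — the structure
    the inverse-variance weighting of the decay fits assumes.  With
    ``scale=0`` the means equal the model exactly and unit SDs are emitted
    so weighted fits reduce to unweighted ones.
    """
    t = np.asarray(t, dtype=float)
    truth = eval_decay(spec, t)
    if noise.scale == 0.0:
        return DecaySeries(t, truth.copy(), np.ones_like(truth), buffer, substrate)
    rng = np.random.default_rng(noise.seed)
    sd_point = noise.sd_for(truth)
    reps = truth[None, :] + rng.standard_normal((noise.replicates, t.size)) * sd_point[None, :]
    mean = reps.mean(axis=0)
    if noise.replicates > 1:
        sd = reps.std(axis=0, ddof=1) / np.sqrt(noise.replicates)
        sd = np.maximum(sd, 1e-12)
    else:
        sd = np.maximum(sd_point, 1e-12)
    return DecaySeries(t, mean, sd, buffer, substrate)


def generate_titration_series(
    protein_concs: np.ndarray,
    ligand_grid: np.ndarray,
    alpha: tuple[float, ...],
    system: BindingSystem,
    noise: NoiseModel,
    i0: float | np.ndarray = 1.0,
    incompetent_fractions: float | np.ndarray = 0.0,
) -> list[TitrationCurve]:
    """Titration series: one curve per protein concentration (µM trimer).

    ``ligand_grid`` is the shared total-ligand grid in µM.  Per-curve i0
    and incompetent fractions may be scalars (broadcast) or sequences.
    """
    protein_concs = np.asarray(protein_concs, dtype=float)
    i0s = np.broadcast_to(np.asarray(i0, dtype=float), protein_concs.shape)
    fincs = np.broadcast_to(np.asarray(incompetent_fractions, dtype=float), protein_concs.shape)
    rng = np.random.default_rng(noise.seed)
    curves = []
    for ci, p_tot in enumerate(protein_concs):
        params = FluorModelParams(alpha=alpha, i0=float(i0s[ci]), incompetent_fraction=float(fincs[ci]))
        clean_curve = TitrationCurve(f"curve_{ci}", float(p_tot), ligand_grid, np.zeros_like(ligand_grid))
        truth = predict_fluorescence(clean_curve, params, system)
        if noise.scale == 0.0:
            signal, sd = truth, None
        else:
            sd = np.maximum(noise.sd_for(truth), 1e-12)
            signal = truth + rng.standard_normal(truth.shape) * sd
        curves.append(TitrationCurve(f"curve_{ci}", float(p_tot), ligand_grid, signal, sd))
    return curves


@dataclass(frozen=True)
class ItcDesign:
    """Injection schedule and concentrations for one simulated ITC run."""

    cell_conc0: float  # µM trimer
    syringe_conc: float  # µM ligand
    n_injections: int = 20
    injection_volume: float = 2.0  # µL
    cell_volume: float = 200.0  # µL
    experiment_id: str = ""


def generate_itc_experiments(
    designs: list[ItcDesign],
    system: BindingSystem,
    noise: NoiseModel,
    incompetent_fractions: float | np.ndarray = 0.0,
    heat_offsets: float | np.ndarray = 0.0,
) -> list[ItcExperiment]:
    """Simulated integrated-heat isotherms for a list of designs."""
    n = len(designs)
    fincs = np.broadcast_to(np.asarray(incompetent_fractions, dtype=float), (n,))
    offsets = np.broadcast_to(np.asarray(heat_offsets, dtype=float), (n,))
    rng = np.random.default_rng(noise.seed)
    out = []
    for ei, d in enumerate(designs):
        exp = ItcExperiment(
            experiment_id=d.experiment_id or f"itc_{ei}",
            cell_volume=d.cell_volume,
            cell_conc0=d.cell_conc0,
            syringe_conc=d.syringe_conc,
            injection_volumes=np.full(d.n_injections, d.injection_volume),
        )
        truth = simulate_itc(exp, system, float(fincs[ei]), float(offsets[ei]))
        if noise.scale == 0.0:
            ndh = truth
        else:
            ndh = truth + rng.standard_normal(truth.shape) * noise.sd_for(truth)
        exp.ndh = ndh
        out.append(exp)
    return out
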