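"""Forward model and global fitter for ITC integrated-heat isotherms.

The observable is the normalized differential heat (NDH, kcal per mole of
injectant) of each injection.  The forward model follows the standard
displacement (perfusion) bookkeeping of fixed-volume cells: every injection
of volume v into a cell of volume V0 displaces an equal volume of the mixed
cell content, so the receptor is diluted by (1 - v/V0) and the injected
ligand enters with the same factor applied to what was already present.

With site-class occupancies theta_i at the post-injection free-ligand level,
the heat content of the cell after injection j is

    Q_j = V0 * [P]_active,j * sum_i dH_i * theta_i(L_free,j)

and the measured heat of injection j includes the part of Q carried out
with the displaced volume (trapezoidal correction):

    NDH_j = (Q_j - Q_{j-1} + (v_j/V0) * (Q_j + Q_{j-1}) / 2) / n_inj,j + offset

where n_inj,j is the number of moles of ligand injected and ``offset`` a
per-experiment constant dilution-heat baseline.

Global fits share (K_d, dH) across experiments; the incompetent fraction
and heat offset are local per experiment, with the incompetent fraction
initialized at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .binding import BindingSystem, ReceptorState, free_ligand, site_occupancies
from .fitting import FitResult, run_multistart

__all__ = ["ItcExperiment", "simulate_itc", "fit_itc_global"]


@dataclass
class ItcExperiment:
    """One ITC titration: design (and, after measurement, NDH values).

    ``cell_conc0`` is the initial receptor concentration in the cell in µM
    *trimer* units; ``syringe_conc`` the ligand concentration in the
    syringe (µM); ``injection_volumes`` in µL.  ``ndh`` is the integrated
    normalized heat per injection in kcal/mol injectant, or None for a bare
    design to be simulated.
    """

    experiment_id: str
    cell_volume: float  # µL
    cell_conc0: float  # µM trimer
    syringe_conc: float  # µM ligand
    injection_volumes: np.ndarray
    ndh: np.ndarray | None = None
    temperature: float = 25.0  # °C

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")
        if self.cell_conc0 < 0 or self.syringe_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.ndh is not None:
            self.ndh = np.asarray(self.ndh, dtype=float)
            if self.ndh.shape != self.injection_volumes.shape:
                raise ValueError("ndh must have one value per injection")

    @property
    def n_injections(self) -> int:
        return self.injection_volumes.size


def simulate_itc(
    exp: ItcExperiment,
    system: BindingSystem,
    incompetent_fraction: float = 0.0,
    heat_offset: float = 0.0,
) -> np.ndarray:
    """Simulate the NDH isotherm (kcal/mol injectant) for one experiment.

    Concentration bookkeeping is done in µM and volumes in µL; the 1e-12
    mol conversion factors cancel between the cell heat content and the
    moles injected, so NDH comes out directly in kcal/mol.
    """
    if system.dh is None:
        raise ValueError("BindingSystem must carry per-site enthalpies for ITC")
    dh = np.asarray(system.dh)
    v0 = exp.cell_volume
    p_tot = exp.cell_conc0
    l_tot = 0.0
    q_prev = 0.0
    out = np.empty(exp.n_injections)
    for j, v in enumerate(exp.injection_volumes):
        d = v / v0
        p_tot *= 1.0 - d
        l_tot = l_tot * (1.0 - d) + exp.syringe_conc * d
        receptor = ReceptorState(p_tot, incompetent_fraction)
        theta = site_occupancies(free_ligand(l_tot, receptor, system), system)
        q = v0 * receptor.active_conc * float(dh @ theta)
        moles_inj = v * exp.syringe_conc
        out[j] = (q - q_prev + d * (q + q_prev) / 2.0) / moles_inj + heat_offset
        q_prev = q
    return out


def fit_itc_global(
    experiments: list[ItcExperiment],
    n_sites: int,
    vary_incompetent: bool = True,
    vary_offset: bool = True,
    exclude_first: bool = False,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Global least-squares fit of 1-3 site models to ITC isotherms.

    (K_d, dH) are global; (incompetent_fraction, heat_offset) are local per
    experiment with the incompetent fraction initialized at zero.  K_d is
    fitted on a log10 scale; multi-start draws log-uniform K_d guesses over
    the explored ligand range (fixed ``seed``) and seeds the enthalpies and
    offsets by linear least squares at the starting K_d before the full
    nonlinear solve.  Site classes are reported sorted by ascending K_d.
    Parameters whose standard error exceeds 100% of the estimate are listed
    in ``warnings`` (such site classes are at the edge of identifiability).
    """
    if not 1 <= n_sites <= 3:
        raise ValueError("n_sites must be 1, 2 or 3")
    if not experiments:
        raise ValueError("need at least one experiment")
    if any(e.ndh is None for e in experiments):
        raise ValueError("every experiment must carry measured NDH values")

    keep = [
        np.arange(1 if exclude_first else 0, e.n_injections) for e in experiments
    ]

    # ligand range explored across all experiments (final total ligand in cell)
    l_final = []
    for e in experiments:
        frac_remaining = np.prod(1.0 - e.injection_volumes / e.cell_volume)
        l_final.append(e.syringe_conc * (1.0 - frac_remaining))
    l_hi = max(l_final)
    l_lo = min(e.syringe_conc * e.injection_volumes[0] / e.cell_volume for e in experiments)

    rng = np.random.default_rng(seed)
    kd_starts = 10 ** rng.uniform(
        np.log10(max(l_lo / 10.0, 1e-6)), np.log10(l_hi * 10.0), size=(n_starts, n_sites)
    )

    def predict(params, with_offset=True):
        kd = tuple(10 ** params[f"log10_kd{i}"].value for i in range(1, n_sites + 1))
        dh = tuple(params[f"dh{i}"].value for i in range(1, n_sites + 1))
        system = BindingSystem(kd, dh)
        chunks = []
        for ei, e in enumerate(experiments):
            sim = simulate_itc(
                e,
                system,
                incompetent_fraction=params[f"finc_{ei}"].value,
                heat_offset=params[f"offset_{ei}"].value if with_offset else 0.0,
            )
            chunks.append(sim[keep[ei]])
        return chunks

    def residual(params):
        chunks = predict(params)
        return np.concatenate(
            [sim - e.ndh[keep[ei]] for ei, (e, sim) in enumerate(zip(experiments, chunks))]
        )

    def _linear_seed(params):
        """Least-squares dH and offsets at the start's K_d (model is linear in them)."""
        n_off = len(experiments) if vary_offset else 0
        cols = n_sites + n_off
        rows = sum(k.size for k in keep)
        design = np.zeros((rows, cols))
        y = np.concatenate([e.ndh[keep[ei]] for ei, e in enumerate(experiments)])
        base = {f"dh{i}": 0.0 for i in range(1, n_sites + 1)}
        pos = 0
        for ei, e in enumerate(experiments):
            m = keep[ei].size
            for i in range(1, n_sites + 1):
                for name, val in base.items():
                    params[name].value = 1.0 if name == f"dh{i}" else 0.0
                design[pos : pos + m, i - 1] = predict(params, with_offset=False)[ei]
            if vary_offset:
                design[pos : pos + m, n_sites + ei] = 1.0
            pos += m
        sol, *_ = np.linalg.lstsq(design, y, rcond=None)
        for i in range(1, n_sites + 1):
            params[f"dh{i}"].value = float(np.clip(sol[i - 1], -99.0, 99.0))
        if vary_offset:
            for ei in range(len(experiments)):
                params[f"offset_{ei}"].value = float(sol[n_sites + ei])
        return params

    starts = []
    for kd0 in kd_starts:
        params = lmfit.Parameters()
        for i, kd in enumerate(sorted(kd0), start=1):
            params.add(f"log10_kd{i}", value=np.log10(kd), min=-6, max=np.log10(l_hi) + 3)
        for i in range(1, n_sites + 1):
            params.add(f"dh{i}", value=-1.0, min=-100.0, max=100.0)
        for ei in range(len(experiments)):
            params.add(f"finc_{ei}", value=0.0, min=0.0, max=0.999, vary=vary_incompetent)
            params.add(f"offset_{ei}", value=0.0, vary=vary_offset)
        starts.append(_linear_seed(params))

    best, ledger = run_multistart(
        residual,
        starts,
        tie_break=lambda res: min(
            res.params[f"log10_kd{i}"].value for i in range(1, n_sites + 1)
        ),
    )

    kd_fit = [10 ** best.params[f"log10_kd{i}"].value for i in range(1, n_sites + 1)]
    order = np.argsort(kd_fit)
    out_params: dict[str, float] = {}
    out_err: dict[str, float | None] = {}
    for rank, idx in enumerate(order, start=1):
        i = idx + 1
        kpar = best.params[f"log10_kd{i}"]
        out_params[f"kd{rank}"] = kd_fit[idx]
        out_err[f"kd{rank}"] = (
            np.log(10) * kd_fit[idx] * kpar.stderr if kpar.stderr is not None else None
        )
        hpar = best.params[f"dh{i}"]
        out_params[f"dh{rank}"] = float(hpar.value)
        out_err[f"dh{rank}"] = hpar.stderr
    for ei in range(len(experiments)):
        for name in (f"finc_{ei}", f"offset_{ei}"):
            out_params[name] = float(best.params[name].value)
            out_err[name] = best.params[name].stderr

    resid = np.asarray(best.residual)
    per_exp: dict[str, np.ndarray] = {}
    pos = 0
    for ei, e in enumerate(experiments):
        m = keep[ei].size
        per_exp[e.experiment_id] = resid[pos : pos + m]
        pos += m

    warnings = []
    for rank in range(1, n_sites + 1):
        for stem in ("kd", "dh"):
            name = f"{stem}{rank}"
            se = out_err[name]
            if se is not None and out_params[name] != 0 and se > abs(out_params[name]):
                warnings.append(f"{name} has relative standard error > 100% (poorly constrained)")

    k = sum(1 for p in best.params.values() if p.vary)
    return FitResult(
        params=out_params,
        stderr=out_err,
        rss=float(np.sum(resid**2)),
        n=resid.size,
        k=k,
        residuals=resid,
        per_dataset_residuals=per_exp,
        warnings=warnings,
        n_starts=len(starts),
        start_ledger=ledger,
    )
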