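"""Forward model and global fitter for fluorescence titrations.

A titration series consists of several curves of the same enzyme sample at
different protein concentrations, titrated with ligand (phosphate).  The
signal model is linear in the site-class occupancies,

    F = i0 * (1 + (1 - f_inc) * sum_i alpha_i * theta_i(L_free)),

with the dissociation constants K_di and response coefficients alpha_i
shared globally across the curves of a series, and the intensity scale i0
(and, optionally, the incompetent fraction f_inc) local to each curve.
Negative alpha_i model quenching.  Ligand depletion is always accounted
for: theta_i is evaluated at the free, not the total, ligand concentration.

Incompetent protein is assumed to fluoresce like unliganded active protein:
it contributes to i0 but not to the ligand-dependent term.  Note that when
receptor depletion is negligible (protein far below every K_d), (1 - f_inc)
multiplies alpha_i exactly and the two are not separately identifiable;
f_inc is therefore held at its initial value 0 unless ``vary_incompetent``
is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .binding import BindingSystem, ReceptorState, free_ligand, site_occupancies
from .fitting import FitResult, run_multistart

__all__ = ["TitrationCurve", "FluorModelParams", "predict_fluorescence", "fit_titration_series"]


@dataclass
class TitrationCurve:
    """One titration: added-ligand grid and fluorescence readings.

    ``protein_total`` is the total protein concentration in µM *trimer*
    units; ``ligand_points`` are total added-ligand concentrations in µM,
    strictly increasing.
    """

    curve_id: str
    protein_total: float
    ligand_points: np.ndarray
    signal: np.ndarray
    signal_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ligand_points = np.asarray(self.ligand_points, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.ligand_points) <= 0):
            raise ValueError(f"curve {self.curve_id}: ligand_points must be strictly increasing")
        if self.signal.shape != self.ligand_points.shape:
            raise ValueError(f"curve {self.curve_id}: signal/ligand length mismatch")
        if self.signal_sd is not None:
            self.signal_sd = np.asarray(self.signal_sd, dtype=float)
            if self.signal_sd.shape != self.ligand_points.shape:
                raise ValueError(f"curve {self.curve_id}: signal_sd length mismatch")
        if self.protein_total < 0:
            raise ValueError("protein_total must be nonnegative")


@dataclass
class FluorModelParams:
    """Signal-model parameters for one curve.

    ``alpha`` (global, one per site class) are relative signal-change
    coefficients at saturation of that class; ``i0`` is the curve's
    zero-ligand intensity and ``incompetent_fraction`` its non-binding
    protein fraction.
    """

    alpha: tuple[float, ...]
    i0: float = 1.0
    incompetent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.i0 <= 0:
            raise ValueError("i0 must be positive")
        if not 0.0 <= self.incompetent_fraction < 1.0:
            raise ValueError("incompetent_fraction must lie in [0, 1)")


def predict_fluorescence(
    curve: TitrationCurve, params: FluorModelParams, system: BindingSystem
) -> np.ndarray:
    if len(params.alpha) != system.n_sites:
        raise ValueError("one alpha per site class required")
    receptor = ReceptorState(curve.protein_total, params.incompetent_fraction)
    alpha = np.asarray(params.alpha)
    out = np.empty_like(curve.ligand_points)
    for j, l_tot in enumerate(curve.ligand_points):
        theta = site_occupancies(free_ligand(l_tot, receptor, system), system)
        out[j] = params.i0 * (1.0 + (1.0 - params.incompetent_fraction) * float(alpha @ theta))
    return out


def _kd_starts(l_points: np.ndarray, n_sites: int, n_starts: int, rng: np.random.Generator):
    pos = l_points[l_points > 0]
    lo = np.log10(max(pos.min() / 10.0, 1e-6))
    hi = np.log10(pos.max() * 10.0)
    return 10 ** rng.uniform(lo, hi, size=(n_starts, n_sites))


def fit_titration_series(
    curves: list[TitrationCurve],
    n_sites: int,
    weighted: bool = False,
    vary_incompetent: bool = False,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Global weighted least-squares fit of a titration series.

    K_d and alpha are shared across curves; i0 (and f_inc when
    ``vary_incompetent``) are local.  K_d is fitted on a log10 scale to stay
    positive; multi-start initialization draws log-uniform K_d guesses over
    the ligand range with a fixed ``seed``, keeping the best-RSS solution
    (near-ties broken toward the lowest K_d1).  Fitted site classes are
    reported sorted by ascending K_d.  A K_d estimated above the highest
    ligand concentration is flagged in ``warnings``.
    """
    if not 1 <= n_sites <= 3:
        raise ValueError("n_sites must be 1, 2 or 3")
    if not curves:
        raise ValueError("need at least one curve")
    if weighted and any(c.signal_sd is None for c in curves):
        raise ValueError("weighted fit requires signal_sd on every curve")

    all_l = np.concatenate([c.ligand_points for c in curves])
    l_max = float(all_l.max())
    rng = np.random.default_rng(seed)
    kd_starts = _kd_starts(all_l, n_sites, n_starts, rng)

    weights = [
        1.0 / c.signal_sd if weighted else np.ones_like(c.signal) for c in curves
    ]

    def residual(params):
        kd = tuple(10 ** params[f"log10_kd{i}"].value for i in range(1, n_sites + 1))
        system = BindingSystem(kd)
        chunks = []
        for ci, c in enumerate(curves):
            p = FluorModelParams(
                alpha=tuple(params[f"alpha{i}"].value for i in range(1, n_sites + 1)),
                i0=params[f"i0_{ci}"].value,
                incompetent_fraction=params[f"finc_{ci}"].value,
            )
            chunks.append((predict_fluorescence(c, p, system) - c.signal) * weights[ci])
        return np.concatenate(chunks)

    # rough alpha guess: total relative signal change split over the classes
    rel_change = float(np.mean([(c.signal[-1] - c.signal[0]) / c.signal[0] for c in curves]))
    alpha0 = rel_change / n_sites if rel_change != 0 else -0.1

    starts = []
    for kd0 in kd_starts:
        params = lmfit.Parameters()
        for i, kd in enumerate(sorted(kd0), start=1):
            params.add(f"log10_kd{i}", value=np.log10(kd), min=-6, max=np.log10(l_max) + 3)
        for i in range(1, n_sites + 1):
            params.add(f"alpha{i}", value=alpha0, min=-1.0, max=5.0)
        for ci, c in enumerate(curves):
            params.add(f"i0_{ci}", value=float(c.signal[0]), min=1e-12)
            params.add(f"finc_{ci}", value=0.0, min=0.0, max=0.999, vary=vary_incompetent)
        starts.append(params)

    best, ledger = run_multistart(
        residual, starts, tie_break=lambda res: min(res.params[f"log10_kd{i}"].value for i in range(1, n_sites + 1))
    )

    # canonical order: site classes sorted by ascending K_d
    kd_fit = [10 ** best.params[f"log10_kd{i}"].value for i in range(1, n_sites + 1)]
    order = np.argsort(kd_fit)
    out_params: dict[str, float] = {}
    out_err: dict[str, float | None] = {}
    for rank, idx in enumerate(order, start=1):
        i = idx + 1
        par = best.params[f"log10_kd{i}"]
        out_params[f"kd{rank}"] = kd_fit[idx]
        # delta method: SE(kd) = ln10 * kd * SE(log10 kd)
        out_err[f"kd{rank}"] = (
            np.log(10) * kd_fit[idx] * par.stderr if par.stderr is not None else None
        )
        apar = best.params[f"alpha{i}"]
        out_params[f"alpha{rank}"] = float(apar.value)
        out_err[f"alpha{rank}"] = apar.stderr
    for ci in range(len(curves)):
        for name in (f"i0_{ci}", f"finc_{ci}"):
            out_params[name] = float(best.params[name].value)
            out_err[name] = best.params[name].stderr

    resid = np.asarray(best.residual)
    per_curve: dict[str, np.ndarray] = {}
    pos = 0
    for c in curves:
        m = c.ligand_points.size
        per_curve[c.curve_id] = resid[pos : pos + m]
        pos += m

    warnings = []
    for rank in range(1, n_sites + 1):
        if out_params[f"kd{rank}"] > l_max:
            warnings.append(
                f"kd{rank} = {out_params[f'kd{rank}']:.4g} µM lies above the highest "
                f"ligand concentration ({l_max:.4g} µM); poorly constrained"
            )

    k = sum(1 for p in best.params.values() if p.vary)
    return FitResult(
        params=out_params,
        stderr=out_err,
        rss=float(np.sum(resid**2)),
        n=resid.size,
        k=k,
        residuals=resid,
        per_dataset_residuals=per_curve,
        warnings=warnings,
        n_starts=len(starts),
        start_ledger=ledger,
    )
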