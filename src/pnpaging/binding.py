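"""Equilibrium binding chemistry for a receptor with up to three nonequivalent sites.

The hexameric enzyme is treated as a trimer of dimers: the global binding
models are written per *trimer*, each trimer carrying one site of every
class.  Site classes are independent (no cooperativity), so the bound ligand
per active trimer is a sum of single-site isotherms

    bound / [P]_active = sum_i  L_free / (K_di + L_free)

and the free-ligand concentration follows from the mass balance

    L_total = L_free + [P]_active * sum_i L_free / (K_di + L_free).

Concentrations are in µM throughout; enthalpies in kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingSystem",
    "ReceptorState",
    "free_ligand",
    "site_occupancies",
    "bound_ligand",
    "monomer_to_trimer",
    "trimer_to_monomer",
]

#: relative tolerance of the free-ligand root solve
_FREE_RTOL = 1e-12


@dataclass(frozen=True)
class BindingSystem:
    """Site-class dissociation constants (and optionally molar enthalpies).

    Parameters
    ----------
    kd
        Dissociation constants in µM, one per site class (1–3 classes).
    dh
        Optional molar binding enthalpies in kcal/mol, one per site class.
    """

    kd: tuple[float, ...]
    dh: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        kd = tuple(float(k) for k in self.kd)
        object.__setattr__(self, "kd", kd)
        if not 1 <= len(kd) <= 3:
            raise ValueError(f"1-3 site classes supported, got {len(kd)}")
        if any(k <= 0 for k in kd):
            raise ValueError(f"dissociation constants must be positive: {kd}")
        if self.dh is not None:
            dh = tuple(float(h) for h in self.dh)
            object.__setattr__(self, "dh", dh)
            if len(dh) != len(kd):
                raise ValueError("dh must have one entry per site class")

    @property
    def n_sites(self) -> int:
        return len(self.kd)


@dataclass(frozen=True)
class ReceptorState:
    """Total receptor concentration and its ligand-binding-incompetent fraction.

    ``total_conc`` is in binding-unit (trimer) terms, µM.  The incompetent
    fraction is the part of the protein that does not bind ligand at all;
    only ``active_conc = total_conc * (1 - incompetent_fraction)`` enters the
    mass balance.
    """

    total_conc: float
    incompetent_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.total_conc < 0:
            raise ValueError("total_conc must be nonnegative")
        if not 0.0 <= self.incompetent_fraction < 1.0:
            raise ValueError("incompetent_fraction must lie in [0, 1)")

    @property
    def active_conc(self) -> float:
        return self.total_conc * (1.0 - self.incompetent_fraction)


def monomer_to_trimer(conc_monomer: float | np.ndarray) -> float | np.ndarray:
    """Convert a monomer concentration to trimer (binding-unit) terms."""
    return np.asarray(conc_monomer, dtype=float) / 3.0 if np.ndim(conc_monomer) else float(conc_monomer) / 3.0


def trimer_to_monomer(conc_trimer: float | np.ndarray) -> float | np.ndarray:
    """Convert a trimer concentration back to monomer terms."""
    return np.asarray(conc_trimer, dtype=float) * 3.0 if np.ndim(conc_trimer) else float(conc_trimer) * 3.0


def site_occupancies(l_free: float, system: BindingSystem) -> np.ndarray:
    """Fractional occupancy of each site class at a given free-ligand level.

    theta_i = L_free / (K_di + L_free), each in [0, 1).
    """
    if l_free < 0:
        raise ValueError("l_free must be nonnegative")
    kd = np.asarray(system.kd)
    return l_free / (kd + l_free)


def _mass_balance(l_free: float, l_total: float, active: float, kd: np.ndarray) -> float:
    return l_free + active * np.sum(l_free / (kd + l_free)) - l_total


def free_ligand(l_total: float, receptor: ReceptorState, system: BindingSystem) -> float:
    """Solve the mass balance for the free-ligand concentration (µM).

    The mass-balance function is strictly increasing in L_free, so the root
    is bracketed on [0, l_total] and found by Brent's method.
    """
    if l_total < 0:
        raise ValueError("l_total must be nonnegative")
    if l_total == 0.0:
        return 0.0
    active = receptor.active_conc
    if active == 0.0:
        return float(l_total)
    kd = np.asarray(system.kd)
    lo, hi = 0.0, float(l_total)
    f_hi = _mass_balance(hi, l_total, active, kd)
    if f_hi < 0:  # cannot happen for a valid monotone balance
        raise RuntimeError("free-ligand bracket failed; invalid inputs")
    return float(
        brentq(_mass_balance, lo, hi, args=(l_total, active, kd), xtol=1e-15, rtol=_FREE_RTOL)
    )


def bound_ligand(l_total: float, receptor: ReceptorState, system: BindingSystem) -> float:
    """Total receptor-bound ligand (µM) at a given total ligand concentration."""
    l_free = free_ligand(l_total, receptor, system)
    return receptor.active_conc * float(np.sum(site_occupancies(l_free, system)))
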