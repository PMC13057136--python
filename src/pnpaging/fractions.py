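"""Concentration and activity bookkeeping for enzyme samples.

Three fractions of a protein sample are distinguished:

* **total** — from UV absorbance, via the 1% extinction coefficient;
* **ligand-binding** — total minus the incompetent fraction fitted in a
  binding experiment;
* **catalytic** — total scaled by the sample's specific activity over the
  maximum specific activity ever observed for the enzyme (117 U/mg vs.
  inosine for the E. coli enzyme).

For a simple two-state picture (active vs. dead) binding and catalytic
concentrations would coincide; an excess of binding over catalytic
concentration is the signature of intermediates that still bind ligand but
no longer turn over the natural substrate.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "EPS_1PCT_ECOLI",
    "EPS_1PCT_HPYLORI",
    "MW_MONOMER",
    "MAX_ACTIVITY_INO",
    "ProteinSample",
    "FractionReport",
    "conc_from_absorbance",
    "specific_activity_from_slope",
    "fraction_report",
]

#: experimental 1% (1 mg/mL) extinction coefficients at 278 nm, (mg/mL)^-1 cm^-1
EPS_1PCT_ECOLI = 2.7
EPS_1PCT_HPYLORI = 5.19
#: subunit molecular weight, Da
MW_MONOMER = 25_950.0
#: maximum specific activity vs. inosine ever observed for the E. coli enzyme, U/mg
MAX_ACTIVITY_INO = 117.0

#: specific activities above this are implausible and trigger a warning flag
_ACTIVITY_CEILING = 300.0


@dataclass
class ProteinSample:
    """UV-absorbance reading and bookkeeping conventions for one sample."""

    a278: float
    path: float = 1.0  # cm
    eps_1pct: float = EPS_1PCT_ECOLI  # (mg/mL)^-1 cm^-1
    mw_unit: float = 3 * MW_MONOMER  # Da of the bookkeeping unit (default: trimer)
    specific_activity: float | None = None  # U/mg
    substrate: str = "Ino"
    max_activity: float = MAX_ACTIVITY_INO

    def __post_init__(self) -> None:
        if self.a278 < 0 or self.path <= 0 or self.eps_1pct <= 0 or self.mw_unit <= 0:
            raise ValueError("absorbance must be nonnegative; path/eps/MW positive")

    @property
    def warnings(self) -> list[str]:
        out = []
        if self.specific_activity is not None and self.specific_activity > _ACTIVITY_CEILING:
            out.append(
                f"specific activity {self.specific_activity} U/mg exceeds the plausible "
                f"ceiling of {_ACTIVITY_CEILING} U/mg"
            )
        return out


@dataclass
class FractionReport:
    """Total / ligand-binding / catalytic concentrations for one sample (µM)."""

    total_conc: float
    incompetent_fraction: float
    binding_conc: float
    catalytic_conc: float
    flags: list[str]

    def rounded(self, ndigits: int = 2) -> "FractionReport":
        """Report-layer rounding; the stored values stay at full precision."""
        return FractionReport(
            round(self.total_conc, ndigits),
            self.incompetent_fraction,
            round(self.binding_conc, ndigits),
            round(self.catalytic_conc, ndigits),
            list(self.flags),
        )


def conc_from_absorbance(sample: ProteinSample) -> float:
    """Concentration in µM of the sample's bookkeeping unit from A278.

    c[mg/mL] = A278 / (eps_1pct * path); µM = c * 1e6 / MW.
    """
    mg_per_ml = sample.a278 / (sample.eps_1pct * sample.path)
    return mg_per_ml * 1e6 / sample.mw_unit


def specific_activity_from_slope(
    dA_per_min: float,
    delta_eps: float,
    path: float,
    cuvette_volume: float,
    enzyme_mg: float,
) -> float:
    """Specific activity (U/mg) from an absorbance-change assay slope.

    ``delta_eps`` in M^-1 cm^-1 (sign is ignored: the 7-methylguanosine
    assay watches substrate depletion and has a negative delta-epsilon),
    ``path`` in cm, ``cuvette_volume`` in mL, ``enzyme_mg`` in mg.
    One unit U = 1 µmol of substrate converted per minute.
    """
    if delta_eps == 0:
        raise ValueError("delta_eps must be nonzero")
    if path <= 0 or cuvette_volume <= 0 or enzyme_mg <= 0:
        raise ValueError("path, volume and enzyme mass must be positive")
    rate_M_per_min = abs(dA_per_min) / (abs(delta_eps) * path)
    umol_per_min = rate_M_per_min * cuvette_volume * 1e-3 * 1e6
    return umol_per_min / enzyme_mg


def fraction_report(
    total_conc: float,
    incompetent_fraction: float,
    specific_activity: float,
    max_activity: float = MAX_ACTIVITY_INO,
) -> FractionReport:
    """Total / binding / catalytic concentration arithmetic for one sample.

    binding = total × (1 − f_inc); catalytic = total × SA / SA_max.
    A sample whose catalytic concentration exceeds its binding concentration
    is internally inconsistent and flagged (every intermediate that
    catalyses must also bind).
    """
    if total_conc < 0 or specific_activity < 0 or max_activity <= 0:
        raise ValueError("concentrations and activities must be nonnegative")
    if not 0.0 <= incompetent_fraction < 1.0:
        raise ValueError("incompetent_fraction must lie in [0, 1)")
    binding = total_conc * (1.0 - incompetent_fraction)
    catalytic = total_conc * specific_activity / max_activity
    flags = []
    if catalytic > binding + 1e-9:
        flags.append(
            "inconsistent sample: catalytic concentration exceeds ligand-binding concentration"
        )
    return FractionReport(total_conc, incompetent_fraction, binding, catalytic, flags)
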