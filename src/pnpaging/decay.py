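"""Multiphase activity-decay models and weighted fitting.

The catalogue covers the shapes seen in long-term inactivation experiments
of hexameric purine nucleoside phosphorylases stored in different buffers:

``linear``        A(t) = k t + A0
``biexp_offset``  A(t) = A1 exp(-t/t1) + A2 exp(-t/t2) + Ainf
``exp_linear``    A(t) = A1 exp(-t/t1) + k t + A2
``logistic1``     A(t) = Ainf + (A0-Ainf) / (1 + 10^((t1-t) h1))
``logistic2/3``   sums of two/three generalized-logistic (Richards) phases
                  with fractions p, q, 1-p-q

For the logistic families ``t_i`` is the half-time of phase i (the time at
which that phase has completed 50% of its activity change) and ``h_i`` its
steepness in 1/day, negative for decreasing activity.  Exponential phases
are parameterized by time constants ``t_i`` (so that the model reads
exp(-t/t_i)); their reported half-times are ``ln 2 × t_i``.

Fits are weighted with w = 1/SD^2 from the replicate standard deviations,
which keeps points with large errors from dominating the solution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .fitting import FitResult, run_multistart
from .selection import aicc

__all__ = [
    "DECAY_FAMILIES",
    "DecayModelSpec",
    "DecaySeries",
    "eval_decay",
    "fit_decay",
    "compare_decay_models",
    "half_times",
]

DECAY_FAMILIES = ("linear", "biexp_offset", "exp_linear", "logistic1", "logistic2", "logistic3")

#: free parameters per family, in canonical order
_FAMILY_PARAMS = {
    "linear": ("k", "a0"),
    "biexp_offset": ("a1", "t1", "a2", "t2", "a_inf"),
    "exp_linear": ("a1", "t1", "k", "a2"),
    "logistic1": ("a0", "a_inf", "t1", "h1"),
    "logistic2": ("a0", "a_inf", "t1", "h1", "t2", "h2", "p"),
    "logistic3": ("a0", "a_inf", "t1", "h1", "t2", "h2", "t3", "h3", "p", "q"),
}


@dataclass(frozen=True)
class DecayModelSpec:
    """One member of the decay-model catalogue with its parameter values."""

    family: str
    params: dict[str, float]

    def __post_init__(self) -> None:
        if self.family not in DECAY_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {DECAY_FAMILIES}")
        wanted = set(_FAMILY_PARAMS[self.family])
        got = set(self.params)
        if wanted != got:
            raise ValueError(f"{self.family} needs params {sorted(wanted)}, got {sorted(got)}")
        p = self.params
        for name in ("t1", "t2", "t3"):
            if name in p and p[name] <= 0:
                raise ValueError(f"{name} must be positive")
        if self.family == "logistic2":
            if not 0.0 <= p["p"] <= 1.0:
                raise ValueError("fraction p must lie in [0, 1]")
        if self.family == "logistic3":
            if p["p"] < 0 or p["q"] < 0 or p["p"] + p["q"] > 1.0:
                raise ValueError("fractions must satisfy p, q >= 0 and p + q <= 1")


@dataclass
class DecaySeries:
    """Mean specific activity vs. storage time with replicate SDs.

    ``t`` in days (nonnegative, strictly increasing), ``a`` in U/mg, ``sd``
    the per-point standard deviation of the replicate mean.
    """

    t: np.ndarray
    a: np.ndarray
    sd: np.ndarray | None = None
    buffer: str = ""
    substrate: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.t.ndim != 1 or self.a.shape != self.t.shape:
            raise ValueError("t and a must be 1-d arrays of equal length")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be nonnegative and strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.t.shape:
                raise ValueError("sd must match t in length")

    @property
    def condition(self) -> str:
        return f"{self.buffer}/{self.substrate}".strip("/")


def _logistic_phase(t: np.ndarray, t_half: float, h: float) -> np.ndarray:
    # exponent clipped: 10**300 would overflow, and the phase is saturated
    # at 0 or 1 long before that
    expo = np.clip((t_half - t) * h, -300.0, 300.0)
    return 1.0 / (1.0 + 10.0**expo)


def eval_decay(spec: DecayModelSpec, t: np.ndarray) -> np.ndarray:
    """Evaluate a decay model on a time grid (days -> U/mg)."""
    t = np.asarray(t, dtype=float)
    p = spec.params
    fam = spec.family
    if fam == "linear":
        return p["k"] * t + p["a0"]
    if fam == "biexp_offset":
        return p["a1"] * np.exp(-t / p["t1"]) + p["a2"] * np.exp(-t / p["t2"]) + p["a_inf"]
    if fam == "exp_linear":
        return p["a1"] * np.exp(-t / p["t1"]) + p["k"] * t + p["a2"]
    if fam == "logistic1":
        return p["a_inf"] + (p["a0"] - p["a_inf"]) * _logistic_phase(t, p["t1"], p["h1"])
    if fam == "logistic2":
        mix = p["p"] * _logistic_phase(t, p["t1"], p["h1"]) + (1 - p["p"]) * _logistic_phase(
            t, p["t2"], p["h2"]
        )
        return p["a_inf"] + (p["a0"] - p["a_inf"]) * mix
    # logistic3: sum of three weighted logistic phases
    mix = (
        p["p"] * _logistic_phase(t, p["t1"], p["h1"])
        + p["q"] * _logistic_phase(t, p["t2"], p["h2"])
        + (1 - p["p"] - p["q"]) * _logistic_phase(t, p["t3"], p["h3"])
    )
    return p["a_inf"] + (p["a0"] - p["a_inf"]) * mix


def half_times(spec_or_params, family: str | None = None) -> dict[str, float]:
    """Per-phase half-times in days (plus linear slopes, labelled as such).

    Logistic half-times are the t_i directly; exponential phases report
    ln 2 × time-constant; linear phases report the slope in (U/mg)/day.
    """
    if isinstance(spec_or_params, DecayModelSpec):
        family, p = spec_or_params.family, spec_or_params.params
    else:
        p = spec_or_params
        if family is None:
            raise ValueError("family required when passing a raw parameter dict")
    out: dict[str, float] = {}
    if family == "linear":
        out["slope_U_per_mg_per_day"] = p["k"]
    elif family == "biexp_offset":
        out["half_time_1_days"] = math.log(2) * p["t1"]
        out["half_time_2_days"] = math.log(2) * p["t2"]
    elif family == "exp_linear":
        out["half_time_1_days"] = math.log(2) * p["t1"]
        out["slope_U_per_mg_per_day"] = p["k"]
    else:
        n = {"logistic1": 1, "logistic2": 2, "logistic3": 3}[family]
        for i in range(1, n + 1):
            out[f"half_time_{i}_days"] = p[f"t{i}"]
    return out


# ---------------------------------------------------------------------------
# fitting


def _simplex_to_fractions(s1: float, s2: float) -> tuple[float, float, float]:
    p = s1
    q = (1.0 - s1) * s2
    return p, q, 1.0 - p - q


def _make_params(family: str, init: dict[str, float], span: float, decreasing: bool) -> lmfit.Parameters:
    params = lmfit.Parameters()
    hmax = -1e-6 if decreasing else 10.0
    hmin = -10.0
    for name in _FAMILY_PARAMS[family]:
        v = init[name]
        if name.startswith("t"):
            params.add(name, value=v, min=span * 1e-4, max=span * 50)
        elif name.startswith("h"):
            params.add(name, value=v, min=hmin, max=hmax)
        elif name in ("p", "q"):
            # fitted on the (s1, s2) simplex scale; mapped below
            continue
        else:
            params.add(name, value=v)
    if family == "logistic2":
        params.add("s1", value=init["p"], min=0.0, max=1.0)
    elif family == "logistic3":
        p0, q0 = init["p"], init["q"]
        s1 = p0
        s2 = q0 / (1.0 - p0) if p0 < 1.0 else 0.5
        params.add("s1", value=min(max(s1, 1e-3), 1 - 1e-3), min=0.0, max=1.0)
        params.add("s2", value=min(max(s2, 1e-3), 1 - 1e-3), min=0.0, max=1.0)
    return params


def _params_to_spec_dict(family: str, params) -> dict[str, float]:
    vals = {name: float(par.value) for name, par in params.items()}
    out = {}
    for name in _FAMILY_PARAMS[family]:
        if name == "p":
            if family == "logistic2":
                out["p"] = vals["s1"]
            else:
                out["p"], out["q"], _ = _simplex_to_fractions(vals["s1"], vals["s2"])
        elif name == "q":
            pass  # filled together with p
        else:
            out[name] = vals[name]
    return out


def _sort_phases(family: str, p: dict[str, float]) -> dict[str, float]:
    """Canonicalize phase order (ascending half-time) for permutable families."""
    if family == "biexp_offset":
        if p["t1"] > p["t2"]:
            p = dict(p)
            p["t1"], p["t2"], p["a1"], p["a2"] = p["t2"], p["t1"], p["a2"], p["a1"]
        return p
    if family == "logistic2":
        if p["t1"] > p["t2"]:
            p = dict(p)
            p["t1"], p["t2"], p["h1"], p["h2"] = p["t2"], p["t1"], p["h2"], p["h1"]
            p["p"] = 1.0 - p["p"]
        return p
    if family == "logistic3":
        fracs = [p["p"], p["q"], 1.0 - p["p"] - p["q"]]
        phases = sorted(
            [(p["t1"], p["h1"], fracs[0]), (p["t2"], p["h2"], fracs[1]), (p["t3"], p["h3"], fracs[2])]
        )
        p = dict(p)
        for i, (t, h, f) in enumerate(phases, start=1):
            p[f"t{i}"], p[f"h{i}"] = t, h
        p["p"], p["q"] = phases[0][2], phases[1][2]
        return p
    return p


def _initial_guesses(family: str, series: DecaySeries) -> list[dict[str, float]]:
    """Multi-start initial parameter sets; half-times seeded at span quantiles."""
    t, a = series.t, series.a
    span = max(float(t[-1] - t[0]), 1.0)
    a_hi, a_lo = float(np.max(a)), float(np.min(a))
    amp = max(a_hi - a_lo, 1e-6)
    decreasing = a[-1] <= a[0]
    quantiles = [0.05, 0.12, 0.25, 0.5, 0.8]
    tq = [t[0] + f * span for f in quantiles]
    slope = float(np.polyfit(t, a, 1)[0]) if t.size >= 2 else 0.0

    starts: list[dict[str, float]] = []
    if family == "linear":
        starts.append({"k": slope, "a0": float(a[0])})
    elif family == "biexp_offset":
        for t1, t2 in itertools.combinations(tq, 2):
            starts.append({"a1": amp / 2, "t1": t1, "a2": amp / 2, "t2": t2, "a_inf": a_lo})
    elif family == "exp_linear":
        tail = t > t[0] + span / 2
        k_tail = float(np.polyfit(t[tail], a[tail], 1)[0]) if tail.sum() >= 2 else slope
        for t1 in tq[:4]:
            a2 = float(a[-1] - k_tail * t[-1])
            starts.append({"a1": max(a[0] - a2, amp / 4), "t1": t1, "k": k_tail, "a2": a2})
    elif family == "logistic1":
        for t1 in tq:
            for h in (-0.02, -0.1):
                starts.append({"a0": a_hi, "a_inf": a_lo, "t1": t1, "h1": h})
    elif family == "logistic2":
        for t1, t2 in itertools.combinations(tq, 2):
            starts.append(
                {"a0": a_hi, "a_inf": a_lo, "t1": t1, "h1": -0.05, "t2": t2, "h2": -0.05, "p": 0.5}
            )
    else:  # logistic3
        for t1, t2, t3 in itertools.combinations(tq, 3):
            starts.append(
                {
                    "a0": a_hi, "a_inf": a_lo,
                    "t1": t1, "h1": -0.05, "t2": t2, "h2": -0.05, "t3": t3, "h3": -0.05,
                    "p": 1 / 3, "q": 1 / 3,
                }
            )
    if not decreasing:
        for s in starts:
            for name in ("h1", "h2", "h3"):
                if name in s:
                    s[name] = -s[name]
    return starts


def fit_decay(series: DecaySeries, family: str, weighted: bool = True) -> FitResult:
    """Weighted least-squares fit of one decay family to an activity series.

    With ``weighted=True`` (requires ``series.sd``) residuals are scaled by
    1/SD per point, i.e. weights w = 1/SD^2 in the normal equations.
    """
    if family not in DECAY_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if weighted:
        if series.sd is None:
            raise ValueError("weighted fit requires per-point SDs")
        if np.any(series.sd <= 0):
            raise ValueError("weighted fit requires strictly positive SDs")
        w = 1.0 / series.sd
    else:
        w = np.ones_like(series.t)

    t, a = series.t, series.a
    n = t.size
    decreasing = a[-1] <= a[0]

    def residual(params):
        spec_p = _params_to_spec_dict(family, params)
        model = eval_decay(DecayModelSpec(family, spec_p), t)
        return (model - a) * w

    starts = [
        _make_params(family, init, span=max(float(t[-1] - t[0]), 1.0), decreasing=decreasing)
        for init in _initial_guesses(family, series)
    ]
    k = len(starts[0])
    if n < k:
        raise ValueError(f"{family} has {k} free parameters but only {n} points given")
    best, ledger = run_multistart(residual, starts)

    spec_p = _sort_phases(family, _params_to_spec_dict(family, best.params))
    resid = np.asarray(best.residual)
    stderr = {name: (par.stderr if par.stderr is not None else None) for name, par in best.params.items()}
    result = FitResult(
        params=spec_p,
        stderr=stderr,
        rss=float(np.sum(resid**2)),
        n=n,
        k=k,
        residuals=resid,
        per_dataset_residuals={series.condition or "series": resid},
        n_starts=len(starts),
        start_ledger=ledger,
    )
    result.params_spec = DecayModelSpec(family, spec_p)
    result.half_times = half_times(spec_p, family)
    return result


def compare_decay_models(
    series: DecaySeries, families=DECAY_FAMILIES, weighted: bool = True
) -> list[tuple[str, FitResult | None, float]]:
    """Fit all candidate families and rank them by AICc on (weighted) residuals.

    Returns ``[(family, fit_or_None, aicc), ...]`` sorted best-first; a
    family whose fit fails or whose AICc is undefined ranks last.  Ties are
    broken toward fewer parameters.  Fits whose RSS is at numerical zero
    (below n × (1e-8 × data scale)^2, as happens on noiseless synthetic
    data) are all treated as exact and ranked among themselves by parameter
    count, since the logarithm of a numerically-zero RSS is meaningless.
    """
    scale = float(np.max(np.abs(series.a))) or 1.0
    floor = series.t.size * (1e-8 * scale) ** 2
    rows = []
    for fam in families:
        try:
            fit = fit_decay(series, fam, weighted=weighted)
        except (ValueError, RuntimeError):
            rows.append((fam, None, float("inf"), (2, float("inf"), len(_FAMILY_PARAMS[fam]))))
            continue
        if fit.rss <= floor:
            score = float("-inf")
            key = (0, fit.k, 0.0)
        else:
            try:
                score = aicc(fit.rss, fit.n, fit.k)
                key = (1, score, fit.k)
            except ValueError:
                score = float("inf")
                key = (2, float("inf"), fit.k)
        rows.append((fam, fit, score, key))
    rows.sort(key=lambda r: r[3])
    return [(fam, fit, score) for fam, fit, score, _ in rows]
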