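"""Model discrimination for nested binding models.

Two criteria are computed for every candidate fit:

* the Wald–Wolfowitz runs test on the signs of the residuals — systematic
  lack of fit shows up as too few runs, and the ladder escalates from the
  one-site model to richer models only when the test rejects randomness;
* the least-squares Akaike information criterion,
  ``AIC = n ln(RSS/n) + 2k`` with the small-sample correction
  ``AICc = AIC + 2k(k+1)/(n-k-1)``.

The escalation ladder always starts from the simplest (one-binding-site)
model; when the two criteria disagree, the runs-test decision wins and the
disagreement is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb
from scipy.stats import norm

__all__ = [
    "RunsTestResult",
    "runs_test",
    "aic",
    "aicc",
    "CandidateRecord",
    "DiscriminationLedger",
    "select_binding_model",
]

#: below this many residuals the exact run-count distribution is used
EXACT_N_MAX = 20


@dataclass(frozen=True)
class RunsTestResult:
    n_runs: int
    n_pos: int
    n_neg: int
    z: float
    p: float
    method: str  # "exact" | "normal" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _runs_count(signs: np.ndarray) -> int:
    return 1 + int(np.sum(signs[1:] != signs[:-1]))


def _exact_run_pmf(n_pos: int, n_neg: int) -> np.ndarray:
    """Probability mass of the run count for random orderings of the signs.

    Index r of the returned array holds P(R = r); entries below r=2 are 0.
    """
    n = n_pos + n_neg
    total = comb(n, n_pos, exact=True)
    pmf = np.zeros(n + 1)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n_pos - 1, k - 1, exact=True) * comb(n_neg - 1, k - 1, exact=True)
        else:
            k = (r - 1) // 2
            ways = comb(n_pos - 1, k, exact=True) * comb(n_neg - 1, k - 1, exact=True) + comb(
                n_pos - 1, k - 1, exact=True
            ) * comb(n_neg - 1, k, exact=True)
        pmf[r] = ways / total
    return pmf


def runs_test(residuals: np.ndarray) -> RunsTestResult:
    """Wald–Wolfowitz runs test on the sign sequence of the residuals.

    Exact zeros are dropped before sign coding.  The normal statistic uses
    mu = 2 n+ n- / n + 1 and sigma^2 = 2 n+ n- (2 n+ n- - n) / (n^2 (n-1));
    the two-sided p-value comes from the exact run-count distribution for
    fewer than 20 residuals and from the normal approximation otherwise.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[r != 0.0]
    if r.size < 2:
        raise ValueError("need at least 2 nonzero residuals")
    signs = np.sign(r)
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n = n_pos + n_neg
    n_runs = _runs_count(signs)

    if n_pos == 0 or n_neg == 0:
        return RunsTestResult(n_runs, n_pos, n_neg, float("nan"), 1.0, "degenerate")

    two_pn = 2.0 * n_pos * n_neg
    mu = two_pn / n + 1.0
    var = two_pn * (two_pn - n) / (n**2 * (n - 1.0))
    z = (n_runs - mu) / math.sqrt(var)

    if n < EXACT_N_MAX:
        pmf = _exact_run_pmf(n_pos, n_neg)
        p_le = float(pmf[: n_runs + 1].sum())
        p_ge = float(pmf[n_runs:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact"
    else:
        p = 2.0 * float(norm.sf(abs(z)))
        method = "normal"
    return RunsTestResult(n_runs, n_pos, n_neg, z, p, method)


def aic(rss: float, n: int, k: int) -> float:
    """Least-squares Akaike information criterion, n ln(RSS/n) + 2k."""
    if rss <= 0:
        raise ValueError("rss must be positive")
    if n <= k:
        raise ValueError("need more observations than parameters")
    return n * math.log(rss / n) + 2 * k


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected AIC; undefined (raises) for n <= k + 1."""
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return aic(rss, n, k) + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class CandidateRecord:
    """Bookkeeping for one candidate model in the discrimination ladder."""

    n_sites: int
    n: int
    k: int
    rss: float
    aic: float
    aicc: float | None
    runs_pooled: RunsTestResult | None
    runs_per_curve: list[RunsTestResult] = field(default_factory=list)
    fit: object | None = None
    error: str | None = None


@dataclass
class DiscriminationLedger:
    candidates: list[CandidateRecord]
    chosen_n_sites: int
    reason: str
    aic_disagreement: bool

    def best_aic_n_sites(self) -> int:
        ok = [c for c in self.candidates if c.error is None]
        return min(ok, key=lambda c: c.aic).n_sites

    def to_text(self) -> str:
        lines = ["model discrimination ledger", "=" * 27]
        for c in self.candidates:
            if c.error is not None:
                lines.append(f"{c.n_sites}-site: FIT FAILED ({c.error})")
                continue
            rt = c.runs_pooled
            lines.append(
                f"{c.n_sites}-site: n={c.n} k={c.k} RSS={c.rss:.6g} AIC={c.aic:.3f}"
                + (f" AICc={c.aicc:.3f}" if c.aicc is not None else "")
            )
            if rt is not None:
                lines.append(
                    f"  pooled runs test: R={rt.n_runs} (n+={rt.n_pos}, n-={rt.n_neg}) "
                    f"z={rt.z:.3f} p={rt.p:.4g} [{rt.method}]"
                )
            for i, prt in enumerate(c.runs_per_curve):
                lines.append(f"  curve {i}: R={prt.n_runs} z={prt.z:.3f} p={prt.p:.4g}")
        lines.append(f"decision: {self.chosen_n_sites}-site model — {self.reason}")
        if self.aic_disagreement:
            lines.append("WARNING: AIC prefers a different candidate than the runs-test ladder")
        return "\n".join(lines)


def select_binding_model(
    curves,
    alpha: float = 0.05,
    max_sites: int = 3,
    **fit_kwargs,
) -> DiscriminationLedger:
    """Simplest-first escalation over 1-, 2- and 3-site global titration fits.

    The one-site model is fitted first; a richer model is fitted only when
    the pooled runs test rejects residual-sign randomness at level ``alpha``.
    AIC/AICc are recorded for every fitted candidate; if the AIC ranking
    disagrees with the ladder decision the disagreement is flagged but the
    runs-test decision stands.
    """
    from .fluorescence import fit_titration_series  # deferred: avoids an import cycle

    # below this RSS a fit is numerically exact and its residual signs are
    # floating-point artifacts, not lack-of-fit structure
    scale = max(float(np.max(np.abs(c.signal))) for c in curves) or 1.0
    n_points = sum(c.signal.size for c in curves)
    rss_floor = n_points * (1e-8 * scale) ** 2

    candidates: list[CandidateRecord] = []
    chosen = 1
    reason = "one-site residuals consistent with randomness"
    for n_sites in range(1, max_sites + 1):
        try:
            fit = fit_titration_series(curves, n_sites=n_sites, **fit_kwargs)
        except Exception as exc:  # candidate failure recorded, ladder continues
            candidates.append(
                CandidateRecord(n_sites, 0, 0, float("nan"), float("nan"), None, None, error=str(exc))
            )
            continue
        def _safe_runs(res):
            if float(np.sum(res**2)) <= rss_floor * (res.size / max(n_points, 1)):
                return RunsTestResult(1, 0, 0, float("nan"), 1.0, "degenerate")
            try:
                return runs_test(res)
            except ValueError:  # all residuals exactly zero: perfect fit
                return RunsTestResult(1, 0, 0, float("nan"), 1.0, "degenerate")

        pooled = _safe_runs(fit.residuals)
        per_curve = [
            _safe_runs(res) for res in fit.per_dataset_residuals.values()
        ] if fit.per_dataset_residuals else []
        rss_safe = max(fit.rss, 1e-300)
        try:
            cand_aicc = aicc(rss_safe, fit.n, fit.k)
        except ValueError:
            cand_aicc = None
        candidates.append(
            CandidateRecord(
                n_sites, fit.n, fit.k, fit.rss, aic(rss_safe, fit.n, fit.k), cand_aicc,
                pooled, per_curve, fit,
            )
        )
        chosen = n_sites
        if pooled.p >= alpha or pooled.degenerate:
            reason = f"{n_sites}-site residuals consistent with randomness (runs p={pooled.p:.3g})"
            break
        reason = (
            f"runs test rejected residual randomness up to the {n_sites}-site model "
            f"(p={pooled.p:.3g}); no richer candidate allowed"
            if n_sites == max_sites
            else f"escalated past {n_sites}-site (runs p={pooled.p:.3g})"
        )

    fitted = [c for c in candidates if c.error is None]
    disagree = bool(fitted) and min(fitted, key=lambda c: c.aic).n_sites != chosen
    return DiscriminationLedger(candidates, chosen, reason, disagree)
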