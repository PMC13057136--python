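"""Shared fit-result container and multi-start least-squares helper."""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

from .selection import aic as _aic
from .selection import aicc as _aicc

__all__ = ["FitResult", "run_multistart"]


@dataclass
class FitResult:
    """Converged (weighted) least-squares solution of a global model fit.

    ``residuals`` is the full (weighted, if weighting was used) residual
    vector in the order the datasets were supplied; ``per_dataset_residuals``
    splits it by dataset id.  ``rss`` is the sum of squared entries of
    ``residuals``; ``n``/``k`` are the observation and free-parameter counts
    entering the information criteria.
    """

    params: dict[str, float]
    stderr: dict[str, float | None]
    rss: float
    n: int
    k: int
    residuals: np.ndarray
    per_dataset_residuals: dict[str, np.ndarray] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    n_starts: int = 1
    start_ledger: list[str] = field(default_factory=list)

    @property
    def aic(self) -> float:
        return _aic(self.rss, self.n, self.k)

    @property
    def aicc(self) -> float | None:
        try:
            return _aicc(self.rss, self.n, self.k)
        except ValueError:
            return None

    def flag_uncertain(self, rel_se: float = 1.0) -> list[str]:
        """Names of parameters whose standard error exceeds ``rel_se``×|value|."""
        out = []
        for name, se in self.stderr.items():
            val = self.params[name]
            if se is not None and val != 0 and se > rel_se * abs(val):
                out.append(name)
        return out


def run_multistart(residual_fn, starts, tie_break=None):
    """Minimize ``residual_fn`` from each Parameters object in ``starts``.

    Returns ``(best_result, ledger)`` where the best solution has the lowest
    RSS; near-ties (within 1e-8 relative) are broken by ``tie_break(result)``
    ascending when given.  Failed starts are recorded, not raised, unless all
    starts fail.
    """
    attempts = []
    ledger: list[str] = []
    for i, params in enumerate(starts):
        try:
            res = lmfit.minimize(residual_fn, params, method="least_squares")
        except Exception as exc:
            ledger.append(f"start {i}: FAILED ({exc})")
            continue
        rss = float(np.sum(np.asarray(res.residual) ** 2))
        attempts.append((rss, i, res))
        ledger.append(f"start {i}: RSS={rss:.6g} nfev={res.nfev}")
    if not attempts:
        raise RuntimeError("all starts failed to converge:\n" + "\n".join(ledger))
    best_rss = min(a[0] for a in attempts)
    thresh = best_rss * (1 + 1e-8) + 1e-300
    near = [a for a in attempts if a[0] <= thresh]
    if tie_break is not None and len(near) > 1:
        near.sort(key=lambda a: tie_break(a[2]))
        best = near[0][2]
    else:
        best = min(attempts, key=lambda a: a[0])[2]
    return best, ledger
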