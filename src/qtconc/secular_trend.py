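"""Second-stage secular-trend model for the cell intercepts.

The estimated mean intercepts Eo_jkt drift upward over the first weeks of
treatment and then plateau — a concentration-independent "secular trend"
(plausibly driven by the normalization of heart rate as the infection
resolves).  The trend is modeled as an asymptotic exponential in treatment
week w,

    E_w = Pmax * (1 - exp(-lambda * w)),

fitted to the first-stage intercept point estimates by nonlinear least
squares weighted by cell sample size (the intercepts' own estimation SEs are
ignored — a deliberate two-stage simplification).  Pmax is the steady-state
plateau in ms; log(2)/lambda is the half-life (weeks) of the approach to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


class TrendFitError(RuntimeError):
    """Weighted NLS failed to converge from every start value tried."""


@dataclass(frozen=True)
class SecularTrendFit:
    """Fitted secular-trend parameters with 95% CIs and the residual SD (ms)."""

    pmax: float
    pmax_ci95: tuple[float, float]
    lam: float
    lam_ci95: tuple[float, float]
    delta_sd: float
    n_cells: int

    @property
    def half_life_weeks(self) -> float:
        return float(np.log(2.0) / self.lam)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "pmax": self.pmax,
                "pmax_ci95": list(self.pmax_ci95),
                "lam": self.lam,
                "lam_ci95": list(self.lam_ci95),
                "delta_sd": self.delta_sd,
                "n_cells": self.n_cells,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SecularTrendFit":
        import json

        d = json.loads(text)
        return cls(
            pmax=d["pmax"],
            pmax_ci95=tuple(d["pmax_ci95"]),
            lam=d["lam"],
            lam_ci95=tuple(d["lam_ci95"]),
            delta_sd=d["delta_sd"],
            n_cells=d["n_cells"],
        )


def _model(week, pmax, lam):
    return pmax * (1.0 - np.exp(-lam * week))


def fit_secular_trend(intercepts) -> SecularTrendFit:
    """Fit E_w = Pmax(1 - e^(-lambda w)) to (week, Eo, sample-size) triples.

    Minimizes sum_cells n * (Eo - E_w)^2, the weighted least squares implied
    by treating each cell intercept as a mean of n unit-variance-scaled
    contributions: a cell's deviation from the curve is assumed to have
    variance delta^2 / n.  Point estimates are invariant to rescaling all
    weights; ``delta_sd`` is the residual SD on that unit-weight scale
    (so a cell of size n sits delta_sd/sqrt(n) from the curve, typically),
    and CIs come from the asymptotic covariance scaled by the weighted
    residual variance.
    """
    arr = np.asarray([(w, e, n) for w, e, n in intercepts], dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need >= 3 cells to fit the secular trend")
    week, eo, size = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(size <= 0):
        raise ValueError("cell sample sizes must be positive")
    if len(np.unique(week)) < 2:
        raise ValueError("all cells at the same week; (Pmax, lambda) not identifiable")

    sigma = 1.0 / np.sqrt(size)

    # deterministic start grid: plateau from the latest-week cells, a few
    # rate scales around 1/typical-week
    pmax0 = float(np.mean(eo[week == week.max()]))
    if pmax0 == 0.0:
        pmax0 = float(np.mean(eo)) or 1.0
    wscale = float(np.mean(week[week > 0])) if np.any(week > 0) else 1.0
    starts = [(pmax0, lam0) for lam0 in (1.0 / wscale, 0.1, 1.0, 3.0)]

    last_err: Exception | None = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _model,
                week,
                eo,
                p0=p0,
                sigma=sigma,
                absolute_sigma=False,
                bounds=([-np.inf, 1e-8], [np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        break
    else:
        raise TrendFitError(f"curve_fit failed from starts {starts}: {last_err}")

    pmax, lam = (float(v) for v in popt)
    resid = eo - _model(week, pmax, lam)
    dof = max(arr.shape[0] - 2, 1)
    delta_sd = float(np.sqrt(np.sum(size * resid**2) / dof))
    z = stats.norm.ppf(0.975)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return SecularTrendFit(
        pmax=pmax,
        pmax_ci95=(pmax - z * se[0], pmax + z * se[0]),
        lam=lam,
        lam_ci95=(lam - z * se[1], lam + z * se[1]),
        delta_sd=delta_sd,
        n_cells=int(arr.shape[0]),
    )


def predict_trend(fit: SecularTrendFit, week: float) -> float:
    """Secular trend E_w (ms) at a given treatment week; 0 at week 0."""
    week = np.asarray(week, dtype=float)
    if np.any(week < 0):
        raise ValueError("week must be non-negative")
    out = _model(week, fit.pmax, fit.lam)
    return float(out) if out.ndim == 0 else out
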