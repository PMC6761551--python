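"""Regimen-level QTc predictions from a fitted exposure-response model.

The concentration-driven effect ("delta-delta QTc", the analogue of the
placebo-corrected change in a thorough QT study) at given concentrations is

    ddQTc = sum_a sl_a * C_a.

For a single drug the 90% CI is analytic: (sl +/- 1.645 se) * C.  For a
combination regimen the slope vector is sampled from a multivariate normal
with the fitted estimates and covariance (1,000 draws by default) and the
empirical mean and 5th/95th percentiles of sum_a sl_a C_a are reported.

The total on-treatment change from baseline adds the steady-state secular
trend:  dQTc = ddQTc + Pmax.  Pmax is added as a constant — its estimation
uncertainty is deliberately not propagated into the CI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exposure_model import Z90, ExposureModelFit
from .secular_trend import SecularTrendFit


@dataclass(frozen=True)
class RegimenScenario:
    """A named set of per-analyte concentrations (ug/ml) to predict for."""

    label: str
    concentrations: dict[str, float]
    n_mc: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        for analyte, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {analyte}")


@dataclass(frozen=True)
class PredictionResult:
    """ddQTc (and, once a trend is added, dQTc) mean and 90% CI in ms."""

    label: str
    method: str  # {"analytic", "monte_carlo"}
    ddqtc_mean: float
    ddqtc_lo90: float
    ddqtc_hi90: float
    dqtc_mean: float | None = None
    dqtc_lo90: float | None = None
    dqtc_hi90: float | None = None


def predict_single_drug(fit: ExposureModelFit, analyte: str, conc: float) -> PredictionResult:
    """Analytic single-drug prediction: mean sl*C, bounds (sl +/- 1.645 se)*C."""
    if analyte not in fit.slopes:
        raise ValueError(f"analyte {analyte!r} not in the fitted model")
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    sl, se = fit.slopes[analyte]
    lo, hi = (sl - Z90 * se) * conc, (sl + Z90 * se) * conc
    if lo > hi:  # negative slope flips the bounds
        lo, hi = hi, lo
    return PredictionResult(
        label=f"{analyte}@{conc}",
        method="analytic",
        ddqtc_mean=sl * conc,
        ddqtc_lo90=lo,
        ddqtc_hi90=hi,
    )


def predict_combination_mc(fit: ExposureModelFit, scenario: RegimenScenario) -> PredictionResult:
    """Monte-Carlo combination prediction from the joint slope distribution.

    Slope vectors are drawn from N(slope estimates, slope covariance)
    restricted to the scenario's analytes; the reported interval is the
    empirical 5th/95th percentile of sum_a sl_a * C_a.  Deterministic for a
    fixed scenario seed.
    """
    unknown = set(scenario.concentrations) - set(fit.analytes)
    if unknown:
        raise ValueError(f"scenario analytes not in the fitted model: {sorted(unknown)}")
    analytes = [a for a in fit.analytes if a in scenario.concentrations]
    idx = [fit.analytes.index(a) for a in analytes]
    mean = np.array([fit.slopes[a][0] for a in analytes])
    cov = np.asarray(fit.slope_cov)[np.ix_(idx, idx)]
    if not np.allclose(cov, cov.T):
        raise ValueError("slope covariance is not symmetric")
    eigmin = float(np.min(np.linalg.eigvalsh(cov))) if cov.size else 0.0
    if eigmin < -1e-10 * max(1.0, float(np.max(np.abs(cov)))):
        raise ValueError("slope covariance is not positive semidefinite")
    conc = np.array([scenario.concentrations[a] for a in analytes])

    rng = np.random.default_rng(scenario.seed)
    draws = rng.multivariate_normal(mean, cov, size=scenario.n_mc, method="svd")
    ddqtc = draws @ conc
    return PredictionResult(
        label=scenario.label,
        method="monte_carlo",
        ddqtc_mean=float(np.mean(ddqtc)),
        ddqtc_lo90=float(np.percentile(ddqtc, 5)),
        ddqtc_hi90=float(np.percentile(ddqtc, 95)),
    )


def add_secular(result: PredictionResult, trend: SecularTrendFit) -> PredictionResult:
    """Shift the ddQTc summaries by the steady-state trend Pmax into dQTc.

    The ddQTc fields are left untouched and Pmax uncertainty is not
    propagated.
    """
    return replace(
        result,
        dqtc_mean=result.ddqtc_mean + trend.pmax,
        dqtc_lo90=result.ddqtc_lo90 + trend.pmax,
        dqtc_hi90=result.ddqtc_hi90 + trend.pmax,
    )
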