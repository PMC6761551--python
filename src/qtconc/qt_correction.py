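"""Heart-rate correction of the QT interval.

The QT interval shortens as heart rate rises, so analyses work with a
corrected interval ``QTc = QT * (HR/60)**r`` (equivalently ``QT / RR**r``
with the interbeat interval ``RR = 60/HR`` in seconds).  Fixed exponents give
the classical corrections — Fridericia (r = 1/3, QTcF) and Bazett (r = 1/2,
QTcB).  A population-specific correction (QTcN) instead estimates ``r`` as
the ordinary-least-squares slope of log(QT) on log(RR) over pretreatment
observations, chosen so the corrected interval is uncorrelated with heart
rate in the population at hand.  Tuberculosis patients have elevated heart
rates that fall on treatment, which makes the fixed corrections biased (QTcF
undercorrects, QTcB overcorrects) and motivates the population-specific fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

FRIDERICIA_EXPONENT = 1.0 / 3.0
BAZETT_EXPONENT = 0.5


class DegenerateDesignError(ValueError):
    """The regression design has no usable heart-rate variation."""


@dataclass(frozen=True)
class CorrectionSpec:
    """A QT correction method: fixed-exponent (F/B) or population-estimated (N).

    ``exponent_se`` and ``n_used`` hold fit diagnostics for method N and are
    None for the fixed corrections.
    """

    method: str  # {"F", "B", "N"}
    exponent: float
    exponent_se: float | None = None
    n_used: int | None = None

    def __post_init__(self) -> None:
        if self.method not in ("F", "B", "N"):
            raise ValueError(f"unknown correction method {self.method!r}")
        if self.method == "F" and self.exponent != FRIDERICIA_EXPONENT:
            raise ValueError("method F requires exponent 1/3")
        if self.method == "B" and self.exponent != BAZETT_EXPONENT:
            raise ValueError("method B requires exponent 1/2")
        if not 0.0 <= self.exponent <= 1.0:
            raise ValueError("exponent must lie in [0, 1]")

    @classmethod
    def fridericia(cls) -> "CorrectionSpec":
        return cls(method="F", exponent=FRIDERICIA_EXPONENT)

    @classmethod
    def bazett(cls) -> "CorrectionSpec":
        return cls(method="B", exponent=BAZETT_EXPONENT)


def correct_qt(qt, hr, spec: CorrectionSpec):
    """Correct QT (ms) for heart rate (bpm): ``QTc = QT * (HR/60)**r``.

    Accepts scalars or numpy arrays.  At HR = 60 bpm (RR = 1 s) the
    correction is the identity for any exponent.
    """
    qt = np.asarray(qt, dtype=float)
    hr = np.asarray(hr, dtype=float)
    if np.any(qt <= 0) or np.any(hr <= 0):
        raise ValueError("qt and hr must be strictly positive")
    qtc = qt * (hr / 60.0) ** spec.exponent
    return float(qtc) if qtc.ndim == 0 else qtc


def estimate_population_exponent(pretreatment_pairs) -> CorrectionSpec:
    """Estimate the population-specific exponent from pretreatment (QT, HR) pairs.

    ``r`` is the OLS slope of log(QT) on log(RR) with RR = 60/HR, pooled over
    all pretreatment points; the same exponent is then applied to every
    subject.  Requires at least 3 pairs spanning at least 2 distinct heart
    rates.
    """
    pairs = np.asarray(list(pretreatment_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (qt, hr) pairs")
    qt, hr = pairs[:, 0], pairs[:, 1]
    if np.any(qt <= 0) or np.any(hr <= 0):
        raise ValueError("qt and hr must be strictly positive")
    log_rr = np.log(60.0 / hr)
    if np.ptp(log_rr) == 0:
        raise DegenerateDesignError("all heart rates identical; exponent not identifiable")
    res = sm.OLS(np.log(qt), sm.add_constant(log_rr)).fit()
    slope = float(res.params[1])
    return CorrectionSpec(
        method="N",
        exponent=min(max(slope, 0.0), 1.0),
        exponent_se=float(res.bse[1]),
        n_used=int(pairs.shape[0]),
    )


def residual_hr_slope(qtc_hr_pairs, ci_level: float = 0.95):
    """Adequacy diagnostic: OLS slope of QTc on HR with a confidence interval.

    An adequate correction leaves no residual QTc-HR relationship, i.e. the
    interval contains 0.  Returns ``(slope_ms_per_bpm, (lo, hi))``.
    """
    pairs = np.asarray(list(qtc_hr_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need >= 3 (qtc, hr) pairs")
    qtc, hr = pairs[:, 0], pairs[:, 1]
    if np.ptp(hr) == 0:
        raise DegenerateDesignError("all heart rates identical; slope not identifiable")
    res = sm.OLS(qtc, sm.add_constant(hr)).fit()
    lo, hi = res.conf_int(alpha=1.0 - ci_level)[1]
    return float(res.params[1]), (float(lo), float(hi))
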