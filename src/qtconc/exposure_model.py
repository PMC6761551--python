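"""Linear mixed-effects concentration-QTc exposure-response model.

The model for the baseline-subtracted QTc of subject *i* at time-postdose
*t* of visit *k* of study *j* is

    dQTc_ijkt = Eo_jkt + eoI * (BQTc_i - median BQTc)
                + sum_a sl_a * C_a(ijkt)  [+ pairwise interaction products]
                + eta_i + eps_ijkt

with a free ("nonparametric") mean intercept Eo_jkt per study x visit x
time-postdose cell, a linear baseline-QTc covariate centered at the
population median, one slope per analyte concentration, a subject random
effect eta ~ N(0, omega^2), and residual eps ~ N(0, sigma^2).

Estimation is maximum likelihood (not REML) so likelihood-ratio tests on
fixed effects between nested fits are valid; term retention uses an LRT at
P < 0.001.  The random-intercept structure makes each subject's marginal
covariance sigma^2 I + omega^2 J, so the likelihood is profiled over the
fixed effects with Sherman-Morrison block inverses and optimized over the
(log) variance parameters only.  Options allow omega to differ by study and
sigma by singleton-vs-triplicate ECGs (both off by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .data_schema_io import ANALYTES, AnalysisRecord, CellKey

logger = logging.getLogger(__name__)

Z90 = 1.6448536269514722  # two-sided 90% normal multiplier

#: relative log-likelihood convergence tolerance for the variance optimizer
LOGLIK_RTOL = 1e-6
MAX_ITER = 500
_LOGVAR_BOUNDS = (-25.0, 16.0)


class ConvergenceError(RuntimeError):
    """The variance-parameter optimization failed to converge."""


class RankDeficiencyError(ValueError):
    """The fixed-effect design is rank deficient (named columns are dependent)."""


@dataclass(frozen=True)
class CellIntercept:
    estimate: float
    n: int
    week: float


@dataclass
class ExposureModelFit:
    """A fitted exposure-response model.

    ``slopes`` maps analyte to (estimate in ms per ug/ml, SE); ``slope_cov``
    is the covariance of the slope estimates in ``analytes`` order.
    ``intercepts`` maps each cell to its estimated mean intercept Eo_jkt
    (at the median baseline QTc), the number of observations in the cell and
    the cell's protocol week.  ``omega``/``sigma`` are the random-effect and
    residual SDs in ms (single values under the default homogeneous model;
    the optional heterogeneous structures additionally fill the by-group
    dicts with the pooled value kept as an observation-weighted summary).
    """

    analytes: tuple[str, ...]
    slopes: dict[str, tuple[float, float]]
    slope_cov: np.ndarray
    baseline_coef: float
    baseline_coef_se: float
    median_bqtc: float
    intercepts: dict[CellKey, CellIntercept]
    omega: float
    sigma: float
    loglik: float
    n_obs: int
    n_subjects: int
    n_fixed_params: int
    interactions: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    omega_by_group: dict[str, float] | None = None
    sigma_by_class: dict[str, float] | None = None
    small_cells: tuple[CellKey, ...] = ()

    def slope_ci90(self, analyte: str) -> tuple[float, float]:
        est, se = self.slopes[analyte]
        return est - Z90 * se, est + Z90 * se

    def intercepts_for_trend(self) -> list[tuple[float, float, int]]:
        """(week, Eo estimate, cell sample size) triples for the secular-trend fit."""
        return [(ci.week, ci.estimate, ci.n) for ci in self.intercepts.values()]

    # -- JSON round trip (full precision) -----------------------------------

    def to_json(self) -> str:
        payload = {
            "analytes": list(self.analytes),
            "slopes": {a: list(v) for a, v in self.slopes.items()},
            "slope_cov": np.asarray(self.slope_cov).tolist(),
            "baseline_coef": self.baseline_coef,
            "baseline_coef_se": self.baseline_coef_se,
            "median_bqtc": self.median_bqtc,
            "intercepts": [
                {
                    "study_id": k.study_id,
                    "visit_id": k.visit_id,
                    "time_postdose": k.time_postdose_label,
                    "estimate": v.estimate,
                    "n": v.n,
                    "week": v.week,
                }
                for k, v in self.intercepts.items()
            ],
            "omega": self.omega,
            "sigma": self.sigma,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "n_fixed_params": self.n_fixed_params,
            "interactions": {"|".join(k): list(v) for k, v in self.interactions.items()},
            "omega_by_group": self.omega_by_group,
            "sigma_by_class": self.sigma_by_class,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExposureModelFit":
        d = json.loads(text)
        return cls(
            analytes=tuple(d["analytes"]),
            slopes={a: tuple(v) for a, v in d["slopes"].items()},
            slope_cov=np.asarray(d["slope_cov"], dtype=float),
            baseline_coef=d["baseline_coef"],
            baseline_coef_se=d["baseline_coef_se"],
            median_bqtc=d["median_bqtc"],
            intercepts={
                CellKey(e["study_id"], e["visit_id"], e["time_postdose"]): CellIntercept(
                    e["estimate"], e["n"], e["week"]
                )
                for e in d["intercepts"]
            },
            omega=d["omega"],
            sigma=d["sigma"],
            loglik=d["loglik"],
            n_obs=d["n_obs"],
            n_subjects=d["n_subjects"],
            n_fixed_params=d["n_fixed_params"],
            interactions={tuple(k.split("|")): tuple(v) for k, v in d["interactions"].items()},
            omega_by_group=d.get("omega_by_group"),
            sigma_by_class=d.get("sigma_by_class"),
        )


# ---------------------------------------------------------------------------
# profiled-likelihood machinery


def _profile(X, y, subj_slices, subj_omega_var, obs_sigma_var):
    """Profiled fixed effects and -2-free log-likelihood pieces at given variances.

    Returns (beta, cov_beta, loglik).  ``subj_slices`` are contiguous row
    ranges per subject (rows pre-sorted by subject); ``subj_omega_var`` is
    omega^2 per subject; ``obs_sigma_var`` is sigma^2 per observation.
    """
    w = 1.0 / obs_sigma_var  # per-observation D^-1 diagonal
    Xw = X * w[:, None]
    A = X.T @ Xw
    b = Xw.T @ y
    logdet = float(np.sum(np.log(obs_sigma_var)))
    yVy = float(np.dot(y * w, y))
    # rank-1 subject corrections: V_i^-1 = D^-1 - c_i (D^-1 1)(D^-1 1)^T
    starts = np.array([lo for lo, _ in subj_slices])
    U = np.add.reduceat(Xw, starts, axis=0)  # per-subject X^T D^-1 1
    v = np.add.reduceat(w * y, starts)  # per-subject 1^T D^-1 y
    s = np.add.reduceat(w, starts)  # per-subject 1^T D^-1 1
    c = subj_omega_var / (1.0 + subj_omega_var * s)
    A -= (U * c[:, None]).T @ U
    b -= U.T @ (c * v)
    yVy -= float(np.dot(c * v, v))
    logdet += float(np.sum(np.log1p(subj_omega_var * s)))
    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise RankDeficiencyError(str(exc)) from exc
    beta = cov_beta @ b
    quad = yVy - float(b @ beta)  # r^T V^-1 r at the profiled beta
    n = X.shape[0]
    loglik = -0.5 * (logdet + quad + n * np.log(2.0 * np.pi))
    return beta, cov_beta, loglik


def _check_rank(X, names):
    """Raise a drop-or-merge error naming the dependent design columns."""
    from scipy.linalg import qr

    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise RankDeficiencyError(
            "rank-deficient fixed-effect design; drop or merge: " + ", ".join(bad)
        )


def _interaction_pairs(analytes, include_interactions):
    if include_interactions is True:
        return [
            (analytes[i], analytes[j])
            for i in range(len(analytes))
            for j in range(i + 1, len(analytes))
        ]
    if not include_interactions:
        return []
    return [tuple(p) for p in include_interactions]


def fit_exposure_model(
    records: list[AnalysisRecord],
    analytes,
    include_interactions=False,
    omega_by_study: bool = False,
    sigma_by_replicate: bool = False,
    random_effect: bool = True,
    include_baseline: bool = True,
) -> ExposureModelFit:
    """Fit the mixed-effects exposure-response model by maximum likelihood.

    ``analytes`` is the ordered set of concentration slopes to estimate;
    ``include_interactions`` may be True (all pairs) or an explicit list of
    analyte pairs.  ``random_effect=False`` drops the subject random
    intercept, reducing the fit to ordinary least squares (useful for
    degenerate designs and as a small-instance oracle).
    ``include_baseline=False`` drops the centered baseline-QTc covariate
    (required when every subject shares the same baseline, e.g. noise-free
    synthetic data, where the covariate column is identically zero).
    """
    analytes = tuple(analytes)
    if len(records) == 0:
        raise ValueError("no records to fit")
    for a in analytes:
        if a not in ANALYTES:
            raise ValueError(f"unknown analyte {a!r}")
        if not any(r.concentrations.get(a, 0.0) > 0 for r in records):
            raise ValueError(f"analyte {a!r} has no nonzero concentrations")
    subjects = sorted({r.subject_id for r in records})
    if random_effect and len(subjects) < 2:
        raise ValueError("need >= 2 subjects for a subject random effect")

    pairs = _interaction_pairs(analytes, include_interactions)

    # median baseline over included subjects (one value per subject), frozen
    subj_bqtc = {}
    for r in records:
        subj_bqtc.setdefault(r.subject_id, r.baseline_qtc)
    median_bqtc = float(np.median(list(subj_bqtc.values())))

    # sort rows by subject for contiguous blocks
    order = sorted(range(len(records)), key=lambda i: records[i].subject_id)
    recs = [records[i] for i in order]

    cells = sorted({r.cell for r in recs})
    cell_index = {c: i for i, c in enumerate(cells)}
    n, p_cells = len(recs), len(cells)
    n_base = 1 if include_baseline else 0
    names = [f"Eo[{c.study_id}/{c.visit_id}/{c.time_postdose_label}]" for c in cells]
    names += ["eoI"] * n_base + [f"sl[{a}]" for a in analytes]
    names += [f"r[{a}*{b}]" for a, b in pairs]
    p = len(names)

    X = np.zeros((n, p))
    y = np.empty(n)
    conc_cols = {a: np.array([r.concentrations.get(a, 0.0) for r in recs]) for a in analytes}
    for i, r in enumerate(recs):
        X[i, cell_index[r.cell]] = 1.0
        if include_baseline:
            X[i, p_cells] = r.baseline_qtc - median_bqtc
        y[i] = r.delta_qtc
    for j, a in enumerate(analytes):
        X[:, p_cells + n_base + j] = conc_cols[a]
    for j, (a, b) in enumerate(pairs):
        X[:, p_cells + n_base + len(analytes) + j] = conc_cols[a] * conc_cols[b]

    _check_rank(X, names)

    subj_of = np.array([r.subject_id for r in recs])
    boundaries = [0] + [i for i in range(1, n) if subj_of[i] != subj_of[i - 1]] + [n]
    subj_slices = [(boundaries[k], boundaries[k + 1]) for k in range(len(boundaries) - 1)]
    subj_ids = [subj_of[lo] for lo, _ in subj_slices]

    # variance-parameter layout
    if omega_by_study and random_effect:
        studies = sorted({r.cell.study_id for r in recs})
        study_of_subj = {}
        for r in recs:
            study_of_subj.setdefault(r.subject_id, r.cell.study_id)
        omega_groups = studies
        subj_omega_idx = np.array([studies.index(study_of_subj[s]) for s in subj_ids])
    else:
        omega_groups = ["all"]
        subj_omega_idx = np.zeros(len(subj_ids), dtype=int)
    if sigma_by_replicate:
        sigma_classes = ["singleton", "triplicate_mean"]
        obs_sigma_idx = np.array([0 if r.n_replicates <= 1 else 1 for r in recs])
    else:
        sigma_classes = ["all"]
        obs_sigma_idx = np.zeros(n, dtype=int)

    n_omega = len(omega_groups) if random_effect else 0
    n_sigma = len(sigma_classes)

    # start values: split the OLS residual variance between omega and sigma
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid_var = float(np.mean((y - X @ beta_ols) ** 2))
    degenerate = resid_var <= 1e-10  # (near-)noise-free data: variances at the floor
    resid_var = max(resid_var, 1e-10)
    x0 = np.full(n_omega + n_sigma, np.log(resid_var / (2.0 if n_omega else 1.0)))

    trace: list[float] = []

    def nll(params):
        om2 = np.exp(params[:n_omega]) if n_omega else None
        sg2 = np.exp(params[n_omega:])
        subj_om = om2[subj_omega_idx] if n_omega else np.zeros(len(subj_ids))
        obs_sg = sg2[obs_sigma_idx]
        _, _, ll = _profile(X, y, subj_slices, subj_om, obs_sg)
        trace.append(ll)
        return -ll

    if degenerate:
        xhat = np.full(n_omega + n_sigma, np.log(resid_var))
        xhat[:n_omega] = _LOGVAR_BOUNDS[0]  # omega indistinguishable from 0
        logger.debug("noise-free data: variance parameters pinned at the floor")
    else:
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[_LOGVAR_BOUNDS] * len(x0),
            options={"maxiter": MAX_ITER, "ftol": LOGLIK_RTOL},
        )
        at_lower_bound = bool(np.any(res.x <= _LOGVAR_BOUNDS[0] + 1e-6))
        if not res.success and not at_lower_bound:
            raise ConvergenceError(
                f"variance optimization did not converge: {res.message}; "
                f"loglik trace tail {trace[-5:]}"
            )
        xhat = res.x

    om2 = np.exp(xhat[:n_omega]) if n_omega else np.array([])
    sg2 = np.exp(xhat[n_omega:])
    subj_om = om2[subj_omega_idx] if n_omega else np.zeros(len(subj_ids))
    obs_sg = sg2[obs_sigma_idx]
    beta, cov_beta, loglik = _profile(X, y, subj_slices, subj_om, obs_sg)

    # pooled summaries (observation/subject weighted) for the scalar fields
    if n_omega:
        counts = np.bincount(subj_omega_idx, minlength=n_omega)
        omega = float(np.sqrt(np.average(om2, weights=counts)))
        omega_by_group = (
            {g: float(np.sqrt(v)) for g, v in zip(omega_groups, om2)} if omega_by_study else None
        )
    else:
        omega, omega_by_group = 0.0, None
    counts_s = np.bincount(obs_sigma_idx, minlength=n_sigma)
    sigma = float(np.sqrt(np.average(sg2, weights=counts_s)))
    sigma_by_class = (
        {c: float(np.sqrt(v)) for c, v in zip(sigma_classes, sg2)} if sigma_by_replicate else None
    )

    k0 = p_cells + n_base
    slopes = {
        a: (float(beta[k0 + j]), float(np.sqrt(cov_beta[k0 + j, k0 + j])))
        for j, a in enumerate(analytes)
    }
    slope_cov = cov_beta[k0 : k0 + len(analytes), k0 : k0 + len(analytes)].copy()
    ki = k0 + len(analytes)
    interactions = {
        (a, b): (float(beta[ki + j]), float(np.sqrt(cov_beta[ki + j, ki + j])))
        for j, (a, b) in enumerate(pairs)
    }

    cell_n = {c: 0 for c in cells}
    cell_weeks: dict[CellKey, list[float]] = {c: [] for c in cells}
    for r in recs:
        cell_n[r.cell] += 1
        cell_weeks[r.cell].append(r.week)
    intercepts = {
        c: CellIntercept(
            estimate=float(beta[cell_index[c]]),
            n=cell_n[c],
            week=float(np.mean(cell_weeks[c])),
        )
        for c in cells
    }
    small = tuple(c for c in cells if cell_n[c] < 3)
    if small:
        logger.warning("%d cells have < 3 records (kept, flagged)", len(small))

    return ExposureModelFit(
        analytes=analytes,
        slopes=slopes,
        slope_cov=slope_cov,
        baseline_coef=float(beta[p_cells]) if include_baseline else 0.0,
        baseline_coef_se=float(np.sqrt(cov_beta[p_cells, p_cells])) if include_baseline else 0.0,
        median_bqtc=median_bqtc,
        intercepts=intercepts,
        omega=omega,
        sigma=sigma,
        loglik=float(loglik),
        n_obs=n,
        n_subjects=len(subjects),
        n_fixed_params=p,
        interactions=interactions,
        omega_by_group=omega_by_group,
        sigma_by_class=sigma_by_class,
        small_cells=small,
    )


def likelihood_ratio_test(full: ExposureModelFit, reduced: ExposureModelFit) -> float:
    """P-value of the LRT of ``reduced`` (nested) against ``full``.

    The statistic 2*(loglik_full - loglik_reduced) is referred to a
    chi-squared distribution with the fixed-effect parameter-count
    difference as degrees of freedom.
    """
    if full.n_obs != reduced.n_obs or full.n_subjects != reduced.n_subjects:
        raise ValueError("fits are not on the same records; LRT is undefined")
    if not set(reduced.analytes) <= set(full.analytes):
        raise ValueError("reduced model's analytes are not a subset of the full model's")
    if not set(reduced.interactions) <= set(full.interactions) | {
        tuple(reversed(k)) for k in full.interactions
    } | set(full.interactions):
        raise ValueError("reduced model's interactions are not nested in the full model's")
    if set(reduced.intercepts) != set(full.intercepts):
        raise ValueError("fits use different intercept cells; LRT is undefined")
    df = full.n_fixed_params - reduced.n_fixed_params
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return 1.0
    return float(stats.chi2.sf(stat, df))


def screen_terms(
    records: list[AnalysisRecord],
    candidate_analytes,
    candidate_interactions=(),
    alpha: float = 0.001,
    **fit_kwargs,
):
    """Forward term retention by LRT at the given significance threshold.

    Each candidate analyte is tested, in order, against the current model;
    interaction pairs (between retained analytes) are screened afterwards.
    Returns ``(retained_analytes, retained_interactions, report)`` where the
    report lists every candidate with its p-value and decision.
    """
    retained: list[str] = []
    retained_inter: list[tuple[str, str]] = []
    report: list[dict] = []
    current = fit_exposure_model(records, retained, **fit_kwargs)
    for cand in candidate_analytes:
        trial = fit_exposure_model(records, retained + [cand], **fit_kwargs)
        p = likelihood_ratio_test(trial, current)
        keep = p < alpha
        report.append({"term": cand, "kind": "analyte", "p_value": p, "retained": keep})
        if keep:
            retained.append(cand)
            current = trial
    for a, b in candidate_interactions:
        if a not in retained or b not in retained:
            report.append(
                {
                    "term": f"{a}*{b}",
                    "kind": "interaction",
                    "p_value": None,
                    "retained": False,
                    "note": "main effects not retained",
                }
            )
            continue
        trial = fit_exposure_model(
            records, retained, include_interactions=retained_inter + [(a, b)], **fit_kwargs
        )
        p = likelihood_ratio_test(trial, current)
        keep = p < alpha
        report.append({"term": f"{a}*{b}", "kind": "interaction", "p_value": p, "retained": keep})
        if keep:
            retained_inter.append((a, b))
            current = trial
    return retained, retained_inter, report
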