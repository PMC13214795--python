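"""Statistical surface: rate tables, hypothesis tests, survival, logistic models.

The logistic fit is an explicit iteratively-reweighted-least-squares
implementation with Wald intervals so that its behaviour on degenerate designs
(separation, 2x2 closed forms) is fully under this package's control; survival
estimation delegates to lifelines.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.special import expit

from .errors import DegenerateTableError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# contingency tables and stratified rates
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    """Integer cell counts with labelled exposure rows and outcome columns."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_percentages(self) -> pd.DataFrame:
        """Cell percentages of each row total; NA (not 0) for empty rows."""
        margins = self.row_margins.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / margins[:, None]
        pct[margins == 0, :] = np.nan
        return pd.DataFrame(pct, index=self.row_labels, columns=self.col_labels)


def percentage(numerator: float, denominator: float) -> float:
    """``100 * numerator / denominator``; NaN (never 0) for an empty denominator."""
    if denominator == 0:
        return float("nan")
    return 100.0 * numerator / denominator


def rate_table_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Stratified AKI/mortality rates from integer counts.

    ``counts`` needs one row per stratum with columns ``stratum``, ``n``,
    ``aki``, ``deaths_aki``, ``deaths_no_aki``.  Percentages document their
    denominators: AKI rate over the stratum total; mortality-with-AKI over the
    AKI subgroup; mortality-without over the complement; overall mortality
    over the stratum total.
    """
    out = counts.copy()
    out["no_aki"] = out["n"] - out["aki"]
    out["aki_pct"] = [percentage(a, n) for a, n in zip(out["aki"], out["n"])]
    out["no_aki_pct"] = [percentage(a, n) for a, n in zip(out["no_aki"], out["n"])]
    out["mortality_aki_pct"] = [
        percentage(d, a) for d, a in zip(out["deaths_aki"], out["aki"])
    ]
    out["mortality_no_aki_pct"] = [
        percentage(d, a) for d, a in zip(out["deaths_no_aki"], out["no_aki"])
    ]
    out["deaths_total"] = out["deaths_aki"] + out["deaths_no_aki"]
    out["mortality_pct"] = [
        percentage(d, n) for d, n in zip(out["deaths_total"], out["n"])
    ]
    return out


def rate_table(frame: pd.DataFrame, stratum_col: str = "procedure") -> pd.DataFrame:
    """Aggregate per-episode booleans ``aki`` and ``death`` into stratified counts.

    Emits an 'All' row followed by one row per stratum, with the same
    percentage columns as :func:`rate_table_from_counts`.
    """
    def _counts(sub: pd.DataFrame, label: str) -> dict:
        aki = sub["aki"].astype(bool)
        return {
            "stratum": label,
            "n": len(sub),
            "aki": int(aki.sum()),
            "deaths_aki": int((aki & sub["death"].astype(bool)).sum()),
            "deaths_no_aki": int((~aki & sub["death"].astype(bool)).sum()),
        }

    rows = [_counts(frame, "All")]
    for label, sub in frame.groupby(stratum_col, sort=True):
        rows.append(_counts(sub, str(label)))
    return rate_table_from_counts(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def chi_square(table: ContingencyTable):
    """Pearson chi-square without continuity correction.

    Returns ``(statistic, df, p)``.  Raises :class:`DegenerateTableError` when
    any expected count is zero.
    """
    observed = table.counts.astype(float)
    expected = np.outer(table.row_margins, table.col_margins) / max(table.total, 1)
    if np.any(expected == 0):
        raise DegenerateTableError("zero expected count; chi-square is undefined")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = (len(table.row_labels) - 1) * (len(table.col_labels) - 1)
    p = float(sps.chi2.sf(statistic, df)) if df > 0 else float("nan")
    return statistic, df, p


def wilcoxon_rank_sum(x, y):
    """Two-sided rank-sum test with tie-corrected normal approximation.

    Returns ``(W, p)`` where ``W`` is the rank sum of ``x`` in the pooled
    sample.  Samples with zero rank variance (all values tied) give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return w, 1.0
    z = (w - mean) / math.sqrt(var)
    return w, float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class SurvivalEstimate:
    """Per-stratum product-limit curves plus the across-strata log-rank test."""

    curves: pd.DataFrame  # columns: stratum, time, survival, at_risk
    logrank_stat: float
    logrank_p: float


def km_logrank(times, events, strata=None) -> SurvivalEstimate:
    """Kaplan-Meier curves per stratum with a log-rank comparison.

    ``times`` are days of follow-up, ``events`` 1 for death and 0 for
    censoring at discharge.  With no events anywhere the log-rank statistic is
    undefined and reported as NaN.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    strata = (
        np.asarray(["all"] * len(times)) if strata is None else np.asarray(strata)
    )

    frames = []
    for label in pd.unique(strata):
        mask = strata == label
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        frames.append(
            pd.DataFrame(
                {
                    "stratum": str(label),
                    "time": surv.index.to_numpy(dtype=float),
                    "survival": surv.to_numpy(dtype=float),
                    "at_risk": at_risk.to_numpy(dtype=float),
                }
            )
        )
    curves = pd.concat(frames, ignore_index=True)

    if events.sum() == 0 or len(pd.unique(strata)) < 2:
        return SurvivalEstimate(curves, float("nan"), float("nan"))
    result = multivariate_logrank_test(times, strata, events)
    return SurvivalEstimate(curves, float(result.test_statistic), float(result.p_value))


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Fitted logistic model: per-term coefficients, ORs, Wald CIs, p-values."""

    terms: pd.DataFrame  # index: term; columns: coef, se, or, ci_low, ci_high, p
    n: int
    deviance: float
    converged: bool
    separated: bool
    n_iter: int
    outcome: str = "outcome"

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def logistic_fit(
    y,
    X: pd.DataFrame,
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
    outcome: str = "outcome",
) -> ModelResult:
    """Maximum-likelihood logistic regression via IRLS with Wald intervals.

    Convergence is declared when the deviance changes by less than ``tol``
    (followed by two polishing Newton steps so coefficients reach closed-form
    identities to ~1e-10).  Complete separation is flagged, never silent:
    separated fits report NaN intervals and p-values.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = pd.DataFrame(X).copy()
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    names = [str(c) for c in X.columns]
    Xm = X.to_numpy(dtype=float)
    n, k = Xm.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    beta = np.zeros(k)
    deviance = np.inf
    converged = False
    it = 0
    polish = 0
    while it < max_iter:
        it += 1
        eta = np.clip(Xm @ beta, -30, 30)
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = Xm.T * w
        try:
            beta = np.linalg.solve(xtw @ Xm, xtw @ z)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(xtw @ Xm, xtw @ z, rcond=None)
        mu_new = expit(np.clip(Xm @ beta, -30, 30))
        mu_c = np.clip(mu_new, 1e-12, 1 - 1e-12)
        new_dev = -2.0 * float(np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
        if abs(deviance - new_dev) < tol:
            converged = True
            polish += 1
        deviance = new_dev
        if polish >= 3:
            break

    eta = np.clip(Xm @ beta, -30, 30)
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    info = (Xm.T * w) @ Xm
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)

    # complete/quasi-complete separation: fitted probabilities pinned at 0/1
    # or runaway coefficients
    separated = bool(
        np.any(np.abs(beta) > 25) or np.any(~np.isfinite(se)) or np.any(se > 1e3)
    )

    with np.errstate(over="ignore"):
        or_ = np.exp(beta)
        ci_low = np.exp(beta - Z_95 * se)
        ci_high = np.exp(beta + Z_95 * se)
    zval = np.divide(beta, se, out=np.full(k, np.nan), where=se > 0)
    pvals = 2.0 * sps.norm.sf(np.abs(zval))
    terms = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "or": or_,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "p": pvals,
        },
        index=names,
    )
    if separated:
        terms[["ci_low", "ci_high", "p"]] = np.nan
    return ModelResult(
        terms=terms,
        n=n,
        deviance=deviance,
        converged=converged,
        separated=separated,
        n_iter=it,
        outcome=outcome,
    )


def stage_design(frame: pd.DataFrame, encoding: str = "max") -> pd.DataFrame:
    """Indicator columns stage1..stage3 versus the no-AKI reference level."""
    col = {"max": "max_stage", "first": "first_stage"}[encoding]
    stage = frame[col].astype(int)
    return pd.DataFrame(
        {f"stage{s}": (stage == s).astype(float) for s in (1, 2, 3)},
        index=frame.index,
    )


# ---------------------------------------------------------------------------
# simulation-based power
# ---------------------------------------------------------------------------

@dataclass
class PowerResult:
    n: int
    exposure_prev: float
    overall_mortality: float
    odds_ratio: float
    alpha: float
    replicates: int
    power: float
    mc_se: float


def _calibrate_intercept(prev: float, overall: float, log_or: float) -> float:
    """Intercept such that the marginal event rate equals ``overall``."""
    def marginal(a):
        return prev * expit(a + log_or) + (1 - prev) * expit(a) - overall

    return float(brentq(marginal, -30.0, 10.0))


def power_simulation(
    n: int,
    exposure_prev: float,
    overall_mortality: float,
    odds_ratio: float,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of the exposure Wald test in a logistic model.

    Each replicate draws exposure ~ Bernoulli(prev) and the outcome from a
    logistic model whose intercept is calibrated so the marginal event rate
    equals ``overall_mortality``.  With a single binary covariate the logistic
    MLE is the 2x2 cross-product ratio, so the Wald z is computed in closed
    form; replicates with an empty cell cannot reject.
    """
    rng = np.random.default_rng(seed)
    log_or = math.log(odds_ratio)
    a = _calibrate_intercept(exposure_prev, overall_mortality, log_or)
    p1, p0 = expit(a + log_or), expit(a)

    n1 = rng.binomial(n, exposure_prev, size=reps)
    n0 = n - n1
    d1 = rng.binomial(n1, p1)
    d0 = rng.binomial(n0, p0)
    s1, s0 = n1 - d1, n0 - d0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.log(d1 * s0 / (d0 * s1))
        se = np.sqrt(1.0 / d1 + 1.0 / s1 + 1.0 / d0 + 1.0 / s0)
        z = beta / se
    valid = np.isfinite(z)
    reject = valid & (2.0 * sps.norm.sf(np.abs(z)) < alpha)
    power = float(reject.mean())
    mc_se = math.sqrt(power * (1 - power) / reps)
    return PowerResult(
        n=n,
        exposure_prev=exposure_prev,
        overall_mortality=overall_mortality,
        odds_ratio=odds_ratio,
        alpha=alpha,
        replicates=reps,
        power=power,
        mc_se=mc_se,
    )


# ---------------------------------------------------------------------------
# cohort-level report builders
# ---------------------------------------------------------------------------

def build_analysis_frame(episodes, assessments) -> pd.DataFrame:
    """One row per episode joining outcomes, covariates and AKI staging."""
    by_pid = {a.patient_id: a for a in assessments}
    rows = []
    for ep in episodes:
        a = by_pid[ep.patient_id]
        rows.append(
            {
                "patient_id": ep.patient_id,
                "procedure": ep.procedure,
                "aki": a.has_aki,
                "first_stage": a.first_stage,
                "max_stage": a.max_stage,
                "trigger_criterion": a.trigger_criterion,
                "death": ep.death,
                "hospital_los_days": ep.hospital_los_days,
                "icu_los_days": ep.icu_los_days,
                **ep.covariates,
            }
        )
    return pd.DataFrame(rows)


_TABLE1_CONTINUOUS = [
    ("age", "Age (years)"),
    ("bmi", "BMI (kg/m2)"),
    ("comorbidity_count", "Comorbidities (n)"),
    ("preop_creatinine", "Pre-op. creatinine (mg/dL)"),
    ("euroscore2", "EuroSCORE II (%)"),
    ("operative_hours", "Operation time (hours)"),
    ("icu_los_days", "ICU stay (days)"),
    ("hospital_los_days", "Hospital stay (days)"),
]


def characteristics_table(frame: pd.DataFrame) -> pd.DataFrame:
    """AKI-vs-no-AKI characteristics: medians [IQR] with rank-sum p-values,
    plus the mortality row compared by chi-square."""
    aki = frame[frame["aki"].astype(bool)]
    no = frame[~frame["aki"].astype(bool)]

    def _fmt(sub, col):
        if not len(sub):
            return "NA"
        q1, med, q3 = np.percentile(sub[col].dropna(), [25, 50, 75])
        return f"{med:.1f} [{q1:.1f}; {q3:.1f}]"

    rows = []
    for col, label in _TABLE1_CONTINUOUS:
        if col not in frame.columns:
            continue
        _, p = wilcoxon_rank_sum(aki[col].dropna(), no[col].dropna())
        rows.append(
            {"variable": label, "aki": _fmt(aki, col), "no_aki": _fmt(no, col), "p": p}
        )
    table = ContingencyTable(
        ["AKI", "no AKI"],
        ["died", "survived"],
        [
            [int(aki["death"].sum()), int((~aki["death"].astype(bool)).sum())],
            [int(no["death"].sum()), int((~no["death"].astype(bool)).sum())],
        ],
    )
    try:
        _, _, p_mort = chi_square(table)
    except DegenerateTableError:
        p_mort = float("nan")
    rows.append(
        {
            "variable": "In-hospital mortality",
            "aki": f"{percentage(int(aki['death'].sum()), len(aki)):.1f}%" if len(aki) else "NA",
            "no_aki": f"{percentage(int(no['death'].sum()), len(no)):.1f}%" if len(no) else "NA",
            "p": p_mort,
        }
    )
    return pd.DataFrame(rows)


_RISK_COVARIATES = ["age", "female", "bmi", "comorbidity_count", "preop_creatinine",
                    "euroscore2", "urgency_mid", "urgency_normal"]


def risk_factor_table(frame: pd.DataFrame, encoding: str = "max") -> ModelResult:
    """Multivariable mortality model: covariates plus AKI-stage indicators.

    Stage enters as three indicators versus the no-AKI reference; urgency
    versus the omitted high/emergent level.
    """
    X = pd.DataFrame(index=frame.index)
    X["age"] = frame["age"].astype(float)
    X["female"] = (frame["sex"] == "female").astype(float)
    X["bmi"] = frame["bmi"].astype(float)
    X["comorbidity_count"] = frame["comorbidity_count"].astype(float)
    X["preop_creatinine"] = frame["preop_creatinine"].astype(float)
    X["euroscore2"] = frame["euroscore2"].astype(float)
    X["urgency_mid"] = (frame["urgency"] == "mid").astype(float)
    X["urgency_normal"] = (frame["urgency"] == "normal").astype(float)
    X = pd.concat([X, stage_design(frame, encoding)], axis=1)
    return logistic_fit(
        frame["death"].astype(float), X, outcome=f"death~{encoding}_stage"
    )
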