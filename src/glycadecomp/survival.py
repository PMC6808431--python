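"""Phenome-wide Cox scan, fixed-effects meta-analysis, and positive FDR.

Each (biomarker, outcome, cohort) triple is tested with a Cox
proportional-hazards model on the *age timescale*: entry at baseline age
(left truncation), exit at the age of the first matching event or at
censoring, Efron tie handling. The biomarker enters log-transformed and
standardised (β is the log hazard ratio per 1 SD), with adjustment for
sex, smoking, BMI, systolic blood pressure, alcohol, prevalent disease
status (where prevalent cases are common enough), and the mortality
biomarkers citrate, albumin, and VLDL particle size; CRP optionally.

Per-cohort estimates are pooled with an inverse-variance weighted
fixed-effects model. P-values are adjusted per (biomarker, cohort)
family with the Storey-Tibshirani positive-FDR q-value (cubic-smoother
π0). An association is significant and replicable when its q-value is
below α/k (default 0.05/3, Bonferroni over the three glycoproteins) in
both cohorts and in the meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from scipy.interpolate import UnivariateSpline

__all__ = [
    "HazardEstimate",
    "MetaEstimate",
    "QValueResult",
    "cox_fit",
    "meta_fixed",
    "storey_pi0",
    "storey_q",
    "replication",
    "scan_outcomes",
    "sensitivity_suite",
]

#: Continuous covariates entered log-transformed and standardised.
ADJUST_COVARIATES = ("bmi", "sbp", "alcohol", "Cit", "Alb", "VLDL_D")
CATEGORICAL_COVARIATES = ("sex", "smoking")


@dataclass
class HazardEstimate:
    """One Cox fit: log HR per SD of the biomarker, with inference."""

    biomarker: str
    outcome: str
    cohort: str
    n: int
    n_events: int
    n_prevalent: int
    beta: float
    se: float
    p: float
    adjusted_for_prevalent: bool
    q: float | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple:
        return (float(np.exp(self.beta - 1.96 * self.se)), float(np.exp(self.beta + 1.96 * self.se)))


@dataclass
class MetaEstimate:
    """Inverse-variance fixed-effects pooling of per-cohort estimates."""

    biomarker: str
    outcome: str
    beta: float
    se: float
    p: float
    inputs: list = field(default_factory=list)
    q: float | None = None
    replicated: bool | None = None
    note: str = ""

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple:
        return (float(np.exp(self.beta - 1.96 * self.se)), float(np.exp(self.beta + 1.96 * self.se)))


@dataclass
class QValueResult:
    """Storey-Tibshirani q-values for one testing family."""

    p: np.ndarray
    pi0: float
    q: np.ndarray
    lambda_grid: np.ndarray


def _log_standardize_col(x: pd.Series, log: bool = True) -> pd.Series:
    v = np.log(x.astype(float)) if log else x.astype(float)
    return (v - v.mean()) / v.std(ddof=1)


def cox_fit(
    biomarker: pd.Series,
    outcome_table: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: str,
    adjust_prevalent: bool = True,
    adjust_crp: bool = False,
    biomarker_name: str = "biomarker",
    cohort: str = "cohort",
    adjust: tuple = ADJUST_COVARIATES,
) -> HazardEstimate:
    """Fit one age-timescale Cox model.

    Parameters
    ----------
    biomarker : Series
        Already log-transformed and standardised (SD = 1); its index
        defines the analysis subset (drop missing imputations upstream).
    outcome_table : DataFrame
        Output of :func:`glycadecomp.outcomes.aggregate`.
    covariates : DataFrame
        Baseline covariates on their natural scales; continuous ones are
        log-standardised here, sex/smoking enter as categories. Pregnant
        women must have been excluded upstream.

    Raises
    ------
    ValueError
        If the subset has zero events (the caller should skip the
        outcome) or the partial-likelihood fit fails to converge.
    """
    ids = biomarker.dropna().index.intersection(covariates.index)
    sub = outcome_table.loc[ids, outcome]
    n_events = int(sub["incident"].sum())
    n_prev = int(sub["prevalent"].sum())
    if n_events == 0:
        raise ValueError(f"zero events for outcome {outcome!r}; skipped")
    cov = covariates.loc[ids]
    df = pd.DataFrame(
        {
            "entry": cov["age"].astype(float),
            "exit": sub["event_age"].astype(float),
            "event": sub["incident"].astype(int),
            "biomarker": biomarker.loc[ids].astype(float),
        }
    )
    for c in CATEGORICAL_COVARIATES:
        if c in cov:
            df[c] = cov[c].astype(float)
    for c in adjust:
        if c in cov:
            df[c] = _log_standardize_col(cov[c])
    if adjust_crp and "CRP" in cov:
        df["CRP"] = _log_standardize_col(cov["CRP"])
    if adjust_prevalent:
        df["prevalent"] = sub["prevalent"].astype(int)
    # guard against zero-length at-risk intervals
    df = df[df["exit"] > df["entry"]]
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="exit", event_col="event", entry_col="entry")
        except Exception as err:  # noqa: BLE001 - lifelines raises several types
            raise ValueError(f"Cox fit failed to converge for {outcome!r}: {err}") from err
    beta = float(cph.params_["biomarker"])
    se = float(cph.standard_errors_["biomarker"])
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return HazardEstimate(
        biomarker=biomarker_name,
        outcome=outcome,
        cohort=cohort,
        n=len(df),
        n_events=n_events,
        n_prevalent=n_prev,
        beta=beta,
        se=se,
        p=p,
        adjusted_for_prevalent=adjust_prevalent,
    )


def meta_fixed(estimates: list) -> MetaEstimate:
    """Inverse-variance weighted fixed-effects pooling.

    pooled β = Σ wᵢβᵢ / Σ wᵢ with wᵢ = 1/SEᵢ²; pooled SE = (Σ wᵢ)^(−1/2);
    two-sided normal p. A single estimate is passed through with a note.
    """
    if not estimates:
        raise ValueError("no estimates to pool")
    first = estimates[0]
    if len(estimates) == 1:
        return MetaEstimate(
            biomarker=first.biomarker,
            outcome=first.outcome,
            beta=first.beta,
            se=first.se,
            p=first.p,
            inputs=list(estimates),
            note="single-cohort estimate; no pooling performed",
        )
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    w = 1.0 / ses**2
    finite = np.isfinite(w)
    beta = float(np.sum(w[finite] * betas[finite]) / np.sum(w[finite]))
    se = float(1.0 / np.sqrt(np.sum(w[finite])))
    p = float(2 * stats.norm.sf(abs(beta / se)))
    return MetaEstimate(
        biomarker=first.biomarker, outcome=first.outcome, beta=beta, se=se, p=p, inputs=list(estimates)
    )


def storey_pi0(p: np.ndarray, lambda_grid: np.ndarray | None = None) -> tuple:
    """Estimate π0 (proportion of true nulls) by the smoother method.

    π0(λ) = #{p > λ} / (m·(1 − λ)) on λ ∈ {0.05, 0.10, …, 0.95}; a cubic
    smoothing spline is fit to π0(λ) and evaluated at the largest λ. The
    estimate is clamped into (0, 1] (with a warning if it fell outside).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)
    pi0_lambda = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambda_grid])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spline = UnivariateSpline(lambda_grid, pi0_lambda, k=3)
        pi0 = float(spline(lambda_grid[-1]))
    if pi0 <= 0:
        warnings.warn(
            f"pi0 smoother estimate {pi0:.4g} is non-positive; falling back to 1 "
            "(equivalent to Benjamini-Hochberg)",
            stacklevel=2,
        )
        pi0 = 1.0
    # estimates slightly above 1 are routine sampling noise under the null
    pi0 = min(pi0, 1.0)
    return pi0, lambda_grid


def storey_q(p, pi0: float | None = None) -> QValueResult:
    """Storey-Tibshirani positive-FDR q-values.

    q(pᵢ) = min over t ≥ pᵢ of π0·m·t / #{p ≤ t}, evaluated at the
    observed p-values (step-down cumulative minimum from the largest p).
    With π0 = 1 this reduces exactly to Benjamini-Hochberg adjusted
    p-values. For small families (m < 10) π0 smoothing is unreliable and
    π0 = 1 is used.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    lambda_grid = np.arange(0.05, 0.96, 0.05)
    if pi0 is None:
        if m >= 10:
            pi0, lambda_grid = storey_pi0(p)
        else:
            pi0 = 1.0
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(p=p, pi0=float(pi0), q=q, lambda_grid=lambda_grid)


def replication(q_cohort1: float, q_cohort2: float, q_meta: float,
                alpha: float = 0.05, k: int = 3) -> bool:
    """Dual-cohort replication rule: all three q-values below α/k
    (default 0.05/3 ≈ 0.0167)."""
    thr = alpha / k
    return bool(q_cohort1 < thr and q_cohort2 < thr and q_meta < thr)


def scan_outcomes(
    biomarker: pd.Series,
    outcome_table: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: list[str] | None = None,
    min_prevalent_adjust: int = 10,
    biomarker_name: str = "biomarker",
    cohort: str = "cohort",
    adjust_crp: bool = False,
) -> list:
    """Cox-scan every outcome in one cohort for one biomarker.

    Prevalent adjustment is applied per outcome when that outcome has at
    least ``min_prevalent_adjust`` prevalent cases in the biomarker's
    subset. Zero-event and non-converged outcomes are skipped (and thus
    excluded from the FDR family). Returns HazardEstimates with q-values
    filled in across the scanned family.
    """
    if outcomes is None:
        outcomes = list(outcome_table.columns.get_level_values("outcome").unique())
    ids = biomarker.dropna().index
    estimates, skipped = [], []
    for outcome in outcomes:
        n_prev = int(outcome_table.loc[ids, (outcome, "prevalent")].sum())
        try:
            est = cox_fit(
                biomarker,
                outcome_table,
                covariates,
                outcome,
                adjust_prevalent=n_prev >= min_prevalent_adjust,
                adjust_crp=adjust_crp,
                biomarker_name=biomarker_name,
                cohort=cohort,
            )
        except ValueError as err:
            skipped.append((outcome, str(err)))
            continue
        estimates.append(est)
    if estimates:
        qres = storey_q(np.array([e.p for e in estimates]))
        for e, q in zip(estimates, qres.q):
            e.q = float(q)
    return estimates


def sensitivity_suite(
    biomarker: pd.Series,
    outcome_table: pd.DataFrame,
    covariates: pd.DataFrame,
    outcomes: list[str] | None = None,
    biomarker_name: str = "biomarker",
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Paired sensitivity analyses for one cohort scan.

    Returns a table with, per outcome, the base HR, the CRP-adjusted HR,
    and the HR in the subset excluding that outcome's prevalent cases —
    the inputs for attenuation plots.
    """
    if outcomes is None:
        outcomes = list(outcome_table.columns.get_level_values("outcome").unique())
    base = {e.outcome: e for e in scan_outcomes(
        biomarker, outcome_table, covariates, outcomes,
        biomarker_name=biomarker_name, cohort=cohort)}
    crp = {e.outcome: e for e in scan_outcomes(
        biomarker, outcome_table, covariates, outcomes,
        biomarker_name=biomarker_name, cohort=cohort, adjust_crp=True)}
    rows = []
    for outcome in outcomes:
        if outcome not in base:
            continue
        keep = outcome_table[(outcome, "prevalent")] == 0
        try:
            excl = cox_fit(
                biomarker[biomarker.index.isin(keep[keep].index)],
                outcome_table,
                covariates,
                outcome,
                adjust_prevalent=False,
                biomarker_name=biomarker_name,
                cohort=cohort,
            )
            hr_excl, se_excl = excl.hr, excl.se
        except ValueError:
            hr_excl, se_excl = np.nan, np.nan
        rows.append(
            {
                "outcome": outcome,
                "hr": base[outcome].hr,
                "se": base[outcome].se,
                "hr_crp_adjusted": crp[outcome].hr if outcome in crp else np.nan,
                "se_crp_adjusted": crp[outcome].se if outcome in crp else np.nan,
                "hr_prevalent_excluded": hr_excl,
                "se_prevalent_excluded": se_excl,
            }
        )
    return pd.DataFrame(rows).set_index("outcome")


def estimates_to_frame(estimates: list) -> pd.DataFrame:
    """Flatten HazardEstimate/MetaEstimate lists into a results table
    (columns mirror the per-biomarker association listing)."""
    rows = []
    for e in estimates:
        lo, hi = e.ci
        rows.append(
            {
                "biomarker": e.biomarker,
                "outcome": e.outcome,
                "cohort": getattr(e, "cohort", "Meta-analysis"),
                "n": getattr(e, "n", np.nan),
                "events": getattr(e, "n_events", np.nan),
                "prevalent": getattr(e, "n_prevalent", np.nan),
                "HR": e.hr,
                "SE": e.se,
                "L95": lo,
                "U95": hi,
                "P": e.p,
                "FDR": e.q,
                "replicated": getattr(e, "replicated", None),
            }
        )
    return pd.DataFrame(rows)
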