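"""Sparse linear imputation of glycoprotein concentrations.

Each glycoprotein (AAT, AGP, HP, TF) is imputed from NMR metabolite
features plus age, sex, and BMI using lasso regression. The penalty λ is
tuned by 10-fold cross-validation over a 100-point grid and selected by
the one-standard-error rule: the largest λ whose mean cross-validated MSE
is within one SE of the smallest mean MSE, i.e. the sparsest model whose
accuracy is statistically indistinguishable from the best.

All model inputs are natural-log transformed and standardised (age
standardised without log; sex coded 1 = men, 2 = women). The fitted model
predicts the target on the natural-log scale; concentrations are obtained
by exponentiation. Imputed values outside the assay's observed range are
discarded, as are samples missing any model input.

The lasso solver is scikit-learn's coordinate descent, with the objective
``(1/2n)·||y − Xb||² + λ·||b||₁`` (the λ grid is on this scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json
import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

__all__ = [
    "CVReport",
    "ImputationModel",
    "EvalMetrics",
    "ASSAY_RANGES",
    "make_lambda_grid",
    "cv_train",
    "select_lambda_1se",
    "fit_final",
    "evaluate",
    "apply_model",
    "train_imputation_model",
]

#: Natural-scale assay validity ranges (min, max) per analyte; imputed
#: values outside these are flagged out-of-range and dropped.
ASSAY_RANGES = {
    "AAT": (0.64, 2.58),  # mg/L
    "AGP": (362.0, 1880.0),  # mg/L
    "HP": (0.14, 3.95),  # mg/L
}

# CV path tolerance is looser than the final fit: fold scores are averaged
# over folds so sub-1e-6 coefficient error is immaterial there
_PATH_TOL = 1e-6
_FINAL_TOL = 1e-10


@dataclass
class CVReport:
    """Cross-validation trace for the λ grid (descending)."""

    lambdas: np.ndarray  # length n_lambda, descending
    fold_mse: np.ndarray  # (n_folds, n_lambda)
    fold_spearman: np.ndarray  # (n_folds, n_lambda)
    fold_assignment: np.ndarray  # fold index per sample
    seed: int

    @property
    def mean_mse(self) -> np.ndarray:
        return self.fold_mse.mean(axis=0)

    @property
    def se_mse(self) -> np.ndarray:
        # SE of the mean MSE: SD of the fold MSEs / sqrt(n_folds)
        k = self.fold_mse.shape[0]
        return self.fold_mse.std(axis=0, ddof=1) / np.sqrt(k)

    @property
    def idx_min(self) -> int:
        return int(np.argmin(self.mean_mse))

    @property
    def idx_1se(self) -> int:
        thresh = self.mean_mse[self.idx_min] + self.se_mse[self.idx_min]
        ok = np.nonzero(self.mean_mse <= thresh)[0]
        return int(ok[0])  # grid descends, so the first qualifying index is the largest λ

    @property
    def cv_spearman_mean(self) -> np.ndarray:
        return self.fold_spearman.mean(axis=0)

    @property
    def cv_spearman_sd(self) -> np.ndarray:
        return self.fold_spearman.std(axis=0, ddof=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "mean_mse": self.mean_mse,
                "se_mse": self.se_mse,
                "cv_spearman_mean": self.cv_spearman_mean,
                "cv_spearman_sd": self.cv_spearman_sd,
            }
        )


@dataclass
class ImputationModel:
    """A fitted sparse imputation model for one analyte.

    Coefficients are stored in both conventions: ``coef_std`` on the
    log-standardised inputs (relative contributions) and
    ``coef_raw``/``intercept_raw`` back-transformed so the model applies
    directly to natural-log inputs (age raw in years, sex coded 1/2).
    The prediction is the natural log of concentration.
    """

    target: str
    unit: str
    lambda_: float
    feature_names: list
    intercept_std: float
    coef_std: dict  # feature -> standardised coefficient (nonzero only)
    intercept_raw: float
    coef_raw: dict  # feature -> coefficient on log-scale (raw) inputs
    input_means: dict  # log-scale (or raw for age) means used in training
    input_sds: dict
    target_log_mean: float
    target_log_sd: float
    validity_range: tuple | None  # natural-scale (min, max) or None

    @property
    def n_features(self) -> int:
        return len(self.coef_std)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["validity_range"] = list(self.validity_range) if self.validity_range else None
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ImputationModel":
        with open(path) as fh:
            d = json.load(fh)
        if d["validity_range"] is not None:
            d["validity_range"] = tuple(d["validity_range"])
        return cls(**d)


@dataclass
class EvalMetrics:
    """Accuracy of an imputation model against observed assays."""

    spearman: float  # in-sample point estimate
    cv_spearman: float | None  # mean across CV test folds
    r2: float  # squared Pearson, log-standardised scales
    overfit_gap: float | None  # spearman − cv_spearman


def make_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100, ratio: float = 1e-4):
    """λ grid: from the smallest λ that zeroes every slope down to
    ``ratio`` times it, log-spaced, descending."""
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Seeded random partition with fold sizes differing by at most 1."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[idx] = np.arange(n) % n_folds
    return folds


def cv_train(
    features: pd.DataFrame,
    target: pd.Series,
    n_folds: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
) -> CVReport:
    """Cross-validate the lasso over the λ grid.

    ``features`` and ``target`` must already be log-standardised (see
    :mod:`glycadecomp.preprocess`). For each λ, a lasso is fit on each
    9/10 of the data and the held-out tenth scored by MSE and Spearman ρ
    between predicted and observed target.
    """
    X = features.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    n = len(y)
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds n={n}")
    if np.ptp(y) == 0:
        raise ValueError("target is constant")
    lambdas = make_lambda_grid(X, y, n_lambda)
    folds = _fold_assignment(n, n_folds, seed)
    fold_mse = np.empty((n_folds, n_lambda))
    fold_rho = np.empty((n_folds, n_lambda))
    for k in range(n_folds):
        test = folds == k
        Xtr, ytr = X[~test], y[~test]
        Xte, yte = X[test], y[test]
        # lasso_path solves the full grid by warm-started coordinate
        # descent; it fits no intercept, so center on the training fold
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=lambdas, tol=_PATH_TOL, max_iter=20000)
        preds = (Xte - xm) @ coefs + ym  # (n_test, n_lambda)
        fold_mse[k] = ((preds - yte[:, None]) ** 2).mean(axis=0)
        for j in range(n_lambda):
            if np.ptp(preds[:, j]) == 0:
                fold_rho[k, j] = 0.0
            else:
                fold_rho[k, j] = spearmanr(preds[:, j], yte).statistic
    return CVReport(lambdas, fold_mse, fold_rho, folds, seed)


def select_lambda_1se(report: CVReport) -> float:
    """One-SE rule: the largest λ with mean MSE within one standard error
    of the smallest mean MSE (ties broken toward the larger λ)."""
    return float(report.lambdas[report.idx_1se])


def fit_final(
    features: pd.DataFrame,
    target: pd.Series,
    lambda_: float,
    target_name: str = "analyte",
    unit: str = "mg/L",
    input_means: dict | None = None,
    input_sds: dict | None = None,
    target_log_mean: float = 0.0,
    target_log_sd: float = 1.0,
    validity_range: tuple | None = None,
) -> ImputationModel:
    """Fit the final lasso at a chosen λ on the full training data.

    ``features``/``target`` are log-standardised. If the standardisation
    parameters are supplied, raw-scale (log-input) coefficients are also
    derived so the model can be applied to a new cohort without
    re-standardising to that cohort's own moments.
    """
    if lambda_ < 0:
        raise ValueError("lambda must be >= 0")
    X = features.to_numpy(dtype=float)
    y = target.to_numpy(dtype=float)
    if lambda_ == 0:
        coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(len(y)), X]), y, rcond=None)
        intercept, slopes = coef[0], coef[1:]
    else:
        model = Lasso(alpha=lambda_, tol=_FINAL_TOL, max_iter=1000000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
        intercept, slopes = float(model.intercept_), model.coef_
    names = list(features.columns)
    coef_std = {nm: float(b) for nm, b in zip(names, slopes) if b != 0.0}
    input_means = input_means or {}
    input_sds = input_sds or {}
    # back-transform: y_log = m_y + s_y*(b0 + sum b_j (x_j - m_j)/s_j)
    intercept_raw = target_log_mean + target_log_sd * intercept
    coef_raw = {}
    for nm, b in coef_std.items():
        s = input_sds.get(nm, 1.0)
        m = input_means.get(nm, 0.0)
        coef_raw[nm] = target_log_sd * b / s
        intercept_raw -= target_log_sd * b * m / s
    return ImputationModel(
        target=target_name,
        unit=unit,
        lambda_=float(lambda_),
        feature_names=names,
        intercept_std=float(intercept),
        coef_std=coef_std,
        intercept_raw=float(intercept_raw),
        coef_raw=coef_raw,
        input_means={k: float(v) for k, v in input_means.items()},
        input_sds={k: float(v) for k, v in input_sds.items()},
        target_log_mean=float(target_log_mean),
        target_log_sd=float(target_log_sd),
        validity_range=validity_range,
    )


def predict_log_std(model: ImputationModel, features: pd.DataFrame) -> pd.Series:
    """Linear predictor on the log-standardised scale."""
    pred = np.full(len(features), model.intercept_std)
    for nm, b in model.coef_std.items():
        pred = pred + b * features[nm].to_numpy(dtype=float)
    return pd.Series(pred, index=features.index)


def evaluate(model: ImputationModel, features: pd.DataFrame, target: pd.Series,
             cv_spearman: float | None = None) -> EvalMetrics:
    """In-sample accuracy: Spearman ρ and squared Pearson r² between
    predicted and observed (both log-standardised); the overfit gap is
    the in-sample ρ minus the CV-mean ρ."""
    if len(features) < 3:
        raise ValueError("need at least 3 paired observations")
    pred = predict_log_std(model, features)
    obs = target.loc[pred.index]
    rho = float(spearmanr(pred, obs).statistic)
    r = float(np.corrcoef(pred, obs)[0, 1])
    gap = None if cv_spearman is None else rho - cv_spearman
    return EvalMetrics(spearman=rho, cv_spearman=cv_spearman, r2=r * r, overfit_gap=gap)


def apply_model(model: ImputationModel, features: pd.DataFrame) -> pd.DataFrame:
    """Impute natural-scale concentrations in a (new) cohort.

    ``features`` are raw-log-scale inputs: natural log of concentrations
    / BMI, raw age in years, sex coded 1/2. Samples missing any model
    input get a missing output with flag ``incomplete-inputs``; imputed
    values outside the assay validity range are set missing with flag
    ``out-of-range``.

    Returns a DataFrame with columns ``imputed`` (natural scale) and
    ``flag`` ('' = ok); summary counts in ``.attrs['counts']``.
    """
    needed = list(model.coef_raw)
    missing_cols = [c for c in needed if c not in features.columns]
    if missing_cols:
        raise ValueError(f"features missing model inputs: {missing_cols}")
    sub = features[needed].astype(float) if needed else features.iloc[:, :0]
    incomplete = sub.isna().any(axis=1) if needed else pd.Series(False, index=features.index)
    pred_log = np.full(len(features), model.intercept_raw)
    for nm, b in model.coef_raw.items():
        pred_log = pred_log + b * sub[nm].to_numpy()
    imputed = np.exp(pred_log)
    flag = np.where(incomplete, "incomplete-inputs", "")
    if model.validity_range is not None:
        lo, hi = model.validity_range
        oor = (~incomplete) & ((imputed < lo) | (imputed > hi))
        flag = np.where(oor, "out-of-range", flag)
    out = pd.DataFrame({"imputed": imputed, "flag": flag}, index=features.index)
    out.loc[out["flag"] != "", "imputed"] = np.nan
    out.attrs["counts"] = {
        "n": len(out),
        "incomplete": int((out["flag"] == "incomplete-inputs").sum()),
        "out_of_range": int((out["flag"] == "out-of-range").sum()),
        "imputed": int(out["imputed"].notna().sum()),
    }
    return out


def train_imputation_model(
    features_std: pd.DataFrame,
    target_std: pd.Series,
    target_name: str,
    unit: str = "mg/L",
    n_folds: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
    input_means: dict | None = None,
    input_sds: dict | None = None,
    target_log_mean: float = 0.0,
    target_log_sd: float = 1.0,
    validity_range: tuple | None = None,
):
    """End-to-end training: CV, 1-SE selection, final fit, evaluation.

    Returns (ImputationModel, CVReport, EvalMetrics).
    """
    report = cv_train(features_std, target_std, n_folds=n_folds, n_lambda=n_lambda, seed=seed)
    lam = select_lambda_1se(report)
    model = fit_final(
        features_std,
        target_std,
        lam,
        target_name=target_name,
        unit=unit,
        input_means=input_means,
        input_sds=input_sds,
        target_log_mean=target_log_mean,
        target_log_sd=target_log_sd,
        validity_range=validity_range,
    )
    cv_rho = float(report.cv_spearman_mean[report.idx_1se])
    metrics = evaluate(model, features_std, target_std, cv_spearman=cv_rho)
    return model, report, metrics
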