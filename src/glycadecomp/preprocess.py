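"""NMR feature and covariate preprocessing.

The imputation models operate on natural-log transformed, standardised
inputs. Preprocessing therefore has three steps, each replayable on new
data from stored parameters:

1. zero replacement — concentrations below the NMR platform's detection
   limit are reported as zero; each zero is replaced by the minimum
   positive value of the same feature within the same cohort, a proxy for
   the lower detection limit that makes the log transform well defined;
2. completeness filtering — samples with any missing feature are dropped;
3. log-standardisation — natural log, then centring/scaling per column
   (sample SD, n−1). Age is standardised without a log; sex is passed
   through as a categorical code (1 = men, 2 = women).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

__all__ = [
    "PreprocessParams",
    "replace_zeros",
    "drop_incomplete",
    "log_standardize",
    "exclude_ratio_features",
]

#: Sex coding used throughout: 1 = men, 2 = women.
SEX_CODING = {"men": 1, "women": 2}


@dataclass
class PreprocessParams:
    """Stored parameters sufficient to replay the transform on new data.

    Attributes
    ----------
    zero_replacements : dict
        Per-feature minimum positive value substituted for zeros.
    log_means, log_sds : dict
        Per-column mean and SD of the log-transformed values (or raw
        values for columns in ``no_log``).
    no_log : list
        Columns standardised without a log transform (e.g. age).
    passthrough : list
        Columns left untouched (e.g. sex category codes).
    """

    zero_replacements: dict = field(default_factory=dict)
    log_means: dict = field(default_factory=dict)
    log_sds: dict = field(default_factory=dict)
    no_log: list = field(default_factory=list)
    passthrough: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PreprocessParams":
        with open(path) as fh:
            return cls(**json.load(fh))


def replace_zeros(matrix: pd.DataFrame, params: PreprocessParams | None = None):
    """Replace zero measurements by the per-feature minimum positive value.

    In fit mode (``params=None``) the replacement value is the cohort's own
    minimum positive value for that feature and is recorded; in apply mode
    stored replacements are reused. Idempotent: a matrix with no zeros is
    returned unchanged.

    Returns
    -------
    (DataFrame, PreprocessParams)

    Raises
    ------
    ValueError
        If a feature with zeros has no positive value to substitute.
    """
    out = matrix.copy()
    fit = params is None
    if fit:
        params = PreprocessParams()
    for col in out.columns:
        vals = out[col]
        has_zero = (vals == 0).any()
        if fit:
            if not has_zero:
                continue
            positive = vals[vals > 0]
            if positive.empty:
                raise ValueError(f"feature {col!r} is entirely zero; no minimum positive value")
            params.zero_replacements[col] = float(positive.min())
        if has_zero and col in params.zero_replacements:
            out.loc[vals == 0, col] = params.zero_replacements[col]
    return out, params


def drop_incomplete(matrix: pd.DataFrame, targets: pd.DataFrame | None = None):
    """Drop samples with any missing feature value.

    Parameters
    ----------
    matrix : DataFrame
        Samples × features.
    targets : DataFrame, optional
        Aligned target table subset to the retained samples.

    Returns
    -------
    DataFrame or (DataFrame, DataFrame)
        The filtered matrix (and targets if given). ``matrix.attrs['n_dropped']``
        records the exclusion count.
    """
    keep = matrix.notna().all(axis=1)
    if not keep.any():
        raise ValueError("all samples have missing features")
    out = matrix.loc[keep]
    out.attrs["n_dropped"] = int((~keep).sum())
    if targets is not None:
        return out, targets.loc[out.index]
    return out


def log_standardize(
    matrix: pd.DataFrame,
    params: PreprocessParams | None = None,
    no_log: tuple = ("age",),
    passthrough: tuple = ("sex",),
):
    """Natural log then (x − mean)/SD per column, with stored parameters.

    Fit mode (``params=None``): means/SDs are computed on this matrix and
    stored. Apply mode: stored parameters are used verbatim, so a shifted
    new cohort keeps its shift (no re-centering).

    Columns named in ``no_log`` are standardised without the log (age);
    columns in ``passthrough`` are returned untouched (sex codes).

    Raises
    ------
    ValueError
        If a log column contains a non-positive value (run
        :func:`replace_zeros` first).
    """
    out = matrix.copy()
    fit = params is None
    if fit:
        params = PreprocessParams(
            no_log=[c for c in out.columns if c in no_log],
            passthrough=[c for c in out.columns if c in passthrough],
        )
    for col in out.columns:
        if col in params.passthrough:
            continue
        x = out[col].astype(float)
        if col not in params.no_log:
            bad = x <= 0
            if bad.any():
                row = x.index[bad][0]
                raise ValueError(
                    f"non-positive value in column {col!r} at row {row!r}; "
                    "apply replace_zeros first"
                )
            x = np.log(x)
        if fit:
            params.log_means[col] = float(x.mean())
            params.log_sds[col] = float(x.std(ddof=1))
            if params.log_sds[col] == 0:
                raise ValueError(f"column {col!r} is constant; cannot standardise")
        out[col] = (x - params.log_means[col]) / params.log_sds[col]
    return out, params


def exclude_ratio_features(matrix: pd.DataFrame, ratio_names: list[str] | None = None):
    """Drop derived-ratio features by name.

    Ratio measures are excluded from model training because missingness in
    a numerator or denominator propagates. By default any feature whose
    name contains a ``%``, ``_pct`` or ``/`` marker, or appears in
    ``ratio_names``, is dropped.
    """
    ratio_names = set(ratio_names or [])
    drop = [
        c
        for c in matrix.columns
        if c in ratio_names or "%" in c or "/" in c or c.endswith("_pct")
    ]
    out = matrix.drop(columns=drop)
    out.attrs["n_ratio_dropped"] = len(drop)
    return out
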