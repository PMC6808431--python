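"""Train a lasso imputation model for AAT and evaluate its accuracy.

Generates a training cohort, preprocesses the NMR features (zero
replacement, log-standardisation), runs 10-fold cross-validation over a
100-point lambda grid, selects the one-standard-error lambda, and prints
the accuracy metrics analogous to the published model summaries.
"""

import numpy as np

from glycadecomp import GeneratorConfig, train_imputation_model
from glycadecomp import preprocess as gp
from glycadecomp.impute import ASSAY_RANGES
from glycadecomp.synth import generate_covariates, generate_nmr, generate_panel

cfg = GeneratorConfig(n_samples=626, seed=7, detection_limit_quantile=0.01)
panel = generate_panel(cfg)
nmr = generate_nmr(panel, cfg)
cov = generate_covariates(panel, cfg)

nmr, zero_params = gp.replace_zeros(nmr)
nmr = gp.drop_incomplete(nmr)
feats = nmr.copy()
feats["age"] = cov.loc[nmr.index, "age"]
feats["sex"] = cov.loc[nmr.index, "sex"]
feats["bmi"] = cov.loc[nmr.index, "bmi"]
std, params = gp.log_standardize(feats)

target = np.log(panel.loc[std.index, "AAT"])
t_mean, t_sd = target.mean(), target.std(ddof=1)
model, report, metrics = train_imputation_model(
    std, (target - t_mean) / t_sd, "AAT", seed=0,
    input_means=params.log_means, input_sds=params.log_sds,
    target_log_mean=float(t_mean), target_log_sd=float(t_sd),
    validity_range=ASSAY_RANGES["AAT"],
)

print(f"selected lambda (1-SE rule): {model.lambda_:.4f} "
      f"(min-MSE index {report.idx_min}, 1-SE index {report.idx_1se})")
print(f"model size: {model.n_features} nonzero features")
print(f"CV Spearman rho: {metrics.cv_spearman:.2f}  (in-sample {metrics.spearman:.2f}, "
      f"overfit gap {metrics.overfit_gap:+.2f})")
print(f"r^2 (variance of assayed AAT explained): {metrics.r2:.2f}")
# Under the default generator the imputable ceiling for AAT is R^2 = 0.43,
# so a CV rho near 0.6 and r^2 near 0.43 indicate the trainer has recovered
# essentially all of the linearly available signal.
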