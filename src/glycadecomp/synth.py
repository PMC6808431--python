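"""Synthetic cohort generator.

The real study cohorts (population surveys with matched NMR metabolomics,
glycoprotein immunoassays, registry-linked hospital/death records, and
whole-blood microarrays) are not publicly deposited, so every downstream
stage of this package is exercised against synthetic cohorts that
reproduce the statistical structure the analysis assumes:

* a glycoprotein panel (GlycA, AAT, AGP, HP, TF) drawn from a log-normal
  model whose log-scale correlation matrix and natural-scale means/SDs
  are configurable, defaulting to the published population values;
* an NMR feature matrix that is linearly informative about each
  glycoprotein at a configurable ceiling (the best linear predictor's R²),
  with detection-limit zeros;
* baseline covariates (age, sex, BMI, smoking, SBP, alcohol, citrate,
  albumin, VLDL particle size, CRP, pregnancy flag);
* registry-style ICD-10 event records generated from proportional-hazards
  models on the age timescale, with both a retrospective (prevalent) and
  a follow-up (incident) window;
* a modular expression matrix whose module latents can be tied to AAT at
  stated effect sizes.

Each data product draws from its own seeded RNG stream, so e.g. adding an
outcome to the hazard specification never perturbs the panel draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "DEFAULT_CORR",
    "DEFAULT_CONC_MEANS",
    "DEFAULT_CONC_SDS",
    "OutcomeHazard",
    "GeneratorConfig",
    "SyntheticCohort",
    "ExpressionData",
    "generate_panel",
    "generate_nmr",
    "generate_covariates",
    "generate_events",
    "generate_expression",
    "generate_cohort",
]

#: Panel analytes, in fixed order. GlycA in mmol/L; glycoproteins in mg/L.
ANALYTES = ("GlycA", "AAT", "AGP", "HP", "TF")

#: Default log-scale correlation targets. GlycA row from the published
#: population correlations (AGP 0.64, HP 0.59, AAT 0.33, TF 0.26,
#: AGP–TF −0.04); remaining glycoprotein pairs sit in the reported
#: moderate 0.12–0.52 band.
DEFAULT_CORR = np.array(
    [
        # GlycA  AAT   AGP   HP    TF
        [1.00, 0.33, 0.64, 0.59, 0.26],
        [0.33, 1.00, 0.32, 0.38, 0.12],
        [0.64, 0.32, 1.00, 0.52, -0.04],
        [0.59, 0.38, 0.52, 1.00, 0.20],
        [0.26, 0.12, -0.04, 0.20, 1.00],
    ]
)

DEFAULT_CONC_MEANS = {"GlycA": 1.30, "AAT": 1.19, "AGP": 789.0, "HP": 1.09, "TF": 2.65}
DEFAULT_CONC_SDS = {"GlycA": 0.18, "AAT": 0.20, "AGP": 203.0, "HP": 0.49, "TF": 0.38}

#: Best-linear-predictor R² ceilings for imputing each glycoprotein from
#: the NMR features (generative calibration targets).
DEFAULT_R2_TARGETS = {"AAT": 0.43, "AGP": 0.64, "HP": 0.56, "TF": 0.18}


@dataclass
class OutcomeHazard:
    """Proportional-hazards specification for one registry outcome.

    ``log_hr`` maps analyte name -> log hazard ratio per 1 SD of the
    log-scale analyte. ``baseline_hazard`` is the per-year event rate for
    a person at the panel mean (events/person-year, age-constant).
    """

    label: str
    icd10: str
    baseline_hazard: float
    log_hr: dict = field(default_factory=dict)
    prevalent_hazard: float | None = None  # defaults to baseline_hazard

    def __post_init__(self):
        if self.baseline_hazard < 0:
            raise ValueError(f"negative baseline hazard for {self.label!r}")


def _default_hazards() -> list[OutcomeHazard]:
    import math

    return [
        OutcomeHazard("heart failure", "I50", 0.006, {"AAT": math.log(1.6)}),
        OutcomeHazard("influenza and pneumonia", "J15", 0.006, {"AAT": math.log(1.37)}),
        OutcomeHazard("liver diseases", "K74", 0.003, {"AAT": math.log(1.81)}),
        OutcomeHazard("fracture of forearm", "S52", 0.005, {}),  # null outcome
        OutcomeHazard("chronic lower respiratory", "J44", 0.005, {"HP": math.log(1.36)}),
    ]


@dataclass
class GeneratorConfig:
    """Full configuration for one synthetic cohort.

    Defaults reproduce the study conditions: n = 626 (training-cohort
    size), the published panel correlation/scale structure, 149 NMR
    features, 8-year follow-up, and a 20-year retrospective window.
    """

    n_samples: int = 626
    target_corr: np.ndarray = field(default_factory=lambda: DEFAULT_CORR.copy())
    conc_means: dict = field(default_factory=lambda: dict(DEFAULT_CONC_MEANS))
    conc_sds: dict = field(default_factory=lambda: dict(DEFAULT_CONC_SDS))
    n_nmr_features: int = 149
    r2_targets: dict = field(default_factory=lambda: dict(DEFAULT_R2_TARGETS))
    nmr_noise_sd: float = 0.3
    detection_limit_quantile: float = 0.0
    hazard_spec: list = field(default_factory=_default_hazards)
    followup_years: float = 8.0
    retrospective_years: float = 20.0
    crp_glyca_corr: float = 0.4
    pregnancy_rate: float = 0.02
    women_fraction: float = 0.53
    expr_n_samples: int = 518
    expr_module_sizes: tuple = (30, 20, 15, 10, 10)
    expr_aat_betas: tuple = (0.23, 0.0, 0.0, 0.0, 0.0)
    expr_loading: float = 0.8
    expr_noise_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        R = np.asarray(self.target_corr, float)
        if R.shape != (5, 5) or not np.allclose(R, R.T):
            raise ValueError("target_corr must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("target_corr must have unit diagonal")
        eig = np.linalg.eigvalsh(R)
        if eig[0] < -1e-10:
            raise ValueError(
                f"target_corr is not positive semi-definite: smallest eigenvalue {eig[0]:.6g}"
            )
        for a in ANALYTES:
            if self.conc_sds[a] <= 0:
                raise ValueError(f"conc_sds[{a!r}] must be > 0")
        if self.followup_years <= 0:
            raise ValueError("followup_years must be > 0")


@dataclass
class SyntheticCohort:
    """One generated cohort; all components share person ids."""

    panel: pd.DataFrame
    nmr: pd.DataFrame
    covariates: pd.DataFrame
    records: pd.DataFrame
    truth: dict


@dataclass
class ExpressionData:
    """Synthetic expression stage: probes × samples plus annotations."""

    expr: pd.DataFrame  # probe × sample, log2-like scale
    annotation: pd.DataFrame  # probe -> gene
    modules: dict  # module id -> list of probe ids
    aat: pd.Series  # immunoassay-like AAT per sample (natural scale)
    covariates: pd.DataFrame  # age, sex per sample
    truth: dict


def _rng(config: GeneratorConfig, tag: int) -> np.random.Generator:
    # one independent stream per data product
    return np.random.default_rng([int(config.seed) % (2**31), tag])


def _lognormal_params(mean: float, sd: float):
    """Moment inversion: natural-scale mean/SD -> log-scale mu/sigma."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def generate_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the glycoprotein/GlycA panel.

    Multivariate log-normal: a Gaussian copula (Cholesky of
    ``target_corr``) on the log scale, with per-analyte log-normal
    marginals matched by moment inversion to ``conc_means``/``conc_sds``.
    Log-scale Pearson correlations therefore target ``target_corr``
    exactly in expectation.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_samples
    L = np.linalg.cholesky(np.asarray(config.target_corr, float) + 1e-12 * np.eye(5))
    z = rng.standard_normal((n, 5)) @ L.T
    cols = {}
    for j, a in enumerate(ANALYTES):
        mu, sigma = _lognormal_params(config.conc_means[a], config.conc_sds[a])
        cols[a] = np.exp(mu + sigma * z[:, j])
    ids = [f"P{i:06d}" for i in range(n)]
    return pd.DataFrame(cols, index=pd.Index(ids, name="person_id"))


def _panel_zscores(panel: pd.DataFrame) -> pd.DataFrame:
    logs = np.log(panel)
    return (logs - logs.mean()) / logs.std(ddof=1)


def _solve_proxy_info(R: np.ndarray, r2_targets: dict) -> dict:
    """Solve per-glycoprotein proxy information shares.

    The NMR features carry information about the panel only through five
    latent channels: a direct GlycA channel v_G = z_G (GlycA is itself an
    NMR measure) and, for each glycoprotein k, a noisy proxy
    v_k = sqrt(t_k) z_k + sqrt(1 − t_k) h_k with h_k independent noise.
    Because the analytes are cross-correlated, every channel is partially
    informative about every glycoprotein; the t_k are solved jointly (by
    coordinate-wise bisection to a fixed point) so that the best linear
    predictor of z_k from all channels attains exactly r2_targets[k].
    """
    from scipy.optimize import brentq

    names = list(ANALYTES)
    gly = [a for a in names if a != "GlycA"]

    def total_r2(t: dict, target_analyte: str) -> float:
        # channels: v_G then v_k for each glycoprotein
        k = len(gly)
        S = np.zeros((k + 1, k + 1))
        c = np.zeros(k + 1)
        idx = {a: names.index(a) for a in names}
        ti = idx[target_analyte]
        S[0, 0] = 1.0
        c[0] = R[idx["GlycA"], ti]
        for i, a in enumerate(gly, start=1):
            sa = np.sqrt(t[a])
            S[0, i] = S[i, 0] = sa * R[idx["GlycA"], idx[a]]
            c[i] = sa * R[idx[a], ti]
            for j, b in enumerate(gly, start=1):
                if j < i:
                    S[i, j] = S[j, i] = sa * np.sqrt(t[b]) * R[idx[a], idx[b]]
            S[i, i] = 1.0
        return float(c @ np.linalg.solve(S, c))

    t = {a: min(0.9, r2_targets.get(a, 0.5)) for a in gly}
    for _ in range(200):
        max_move = 0.0
        for a in gly:
            target = r2_targets.get(a, 0.5)

            def f(x, a=a):
                tt = dict(t)
                tt[a] = x
                return total_r2(tt, a) - target

            lo, hi = 1e-9, 1 - 1e-9
            if f(lo) >= 0:
                new = lo  # cross-channel info alone meets the target
            elif f(hi) <= 0:
                new = hi
            else:
                new = brentq(f, lo, hi, xtol=1e-12)
            max_move = max(max_move, abs(new - t[a]))
            t[a] = new
        if max_move < 1e-10:
            break
    return t


# reserved leading feature names; the remainder are synthetic metabolite slots
_NAMED_FEATURES = ["GlycA", "Cit", "Alb", "VLDL_D", "Glc", "Lac", "Ala", "Gln", "His", "Phe", "Tyr"]


def nmr_feature_names(n: int) -> list[str]:
    names = list(_NAMED_FEATURES[:n])
    i = 1
    while len(names) < n:
        names.append(f"met_{i:03d}")
        i += 1
    return names


def generate_nmr(panel: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Generate the NMR feature matrix (natural-scale concentrations).

    Log-scale features are linear in five latent information channels
    (see :func:`_solve_proxy_info`) plus uninformative latent factors and
    per-feature noise, then mapped to plausible natural concentration
    scales. The lowest ``detection_limit_quantile`` fraction of each
    feature is forced to exactly 0 (below-detection-limit censoring).
    """
    config.validate()
    rng = _rng(config, 2)
    n = len(panel)
    p = config.n_nmr_features
    z = _panel_zscores(panel).to_numpy()
    idx = {a: i for i, a in enumerate(ANALYTES)}
    R = np.asarray(config.target_corr, float)
    t = _solve_proxy_info(R, config.r2_targets)

    # latent channels: v_G, v_AAT, v_AGP, v_HP, v_TF, then 4 noise factors
    gly = [a for a in ANALYTES if a != "GlycA"]
    channels = [z[:, idx["GlycA"]]]
    for a in gly:
        h = rng.standard_normal(n)
        channels.append(np.sqrt(t[a]) * z[:, idx[a]] + np.sqrt(1 - t[a]) * h)
    n_noise_factors = 4
    for _ in range(n_noise_factors):
        channels.append(rng.standard_normal(n))
    V = np.column_stack(channels)
    k = V.shape[1]

    # loadings: feature 0 is GlycA itself; others load mainly on one channel
    loadings = np.zeros((p, k))
    loadings[0, 0] = 1.0
    for f in range(1, p):
        main = f % k
        loadings[f, main] = 0.8 * rng.choice([-1.0, 1.0])
        other = rng.integers(0, k)
        loadings[f, other] += 0.2 * rng.standard_normal()
    noise = rng.standard_normal((n, p)) * config.nmr_noise_sd
    noise[:, 0] *= 0.05  # GlycA is measured nearly exactly by the platform
    logs = V @ loadings.T + noise

    names = nmr_feature_names(p)
    # map to natural concentration scales (arbitrary plausible per-feature)
    scale_rng = np.random.default_rng([int(config.seed) % (2**31), 21])
    mu = scale_rng.uniform(-1.0, 1.5, size=p)
    mu[0], sd0 = _lognormal_params(config.conc_means["GlycA"], config.conc_sds["GlycA"])
    sd = np.full(p, 0.25)
    sd[0] = sd0
    conc = np.exp(mu + sd * (logs / logs.std(axis=0, ddof=1)))

    out = pd.DataFrame(conc, index=panel.index, columns=names)
    q = config.detection_limit_quantile
    if q > 0:
        n_zero = int(np.floor(q * n))
        for c in out.columns:
            cut = out[c].nsmallest(n_zero).index
            out.loc[cut, c] = 0.0
    out.attrs["proxy_info"] = t
    return out


def generate_covariates(panel: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Baseline covariates: age, sex (1=men, 2=women), BMI, smoking, SBP,
    alcohol, citrate, albumin, VLDL particle size, CRP, pregnancy flag."""
    rng = _rng(config, 3)
    n = len(panel)
    z = _panel_zscores(panel)
    age = rng.uniform(25, 74, n)
    sex = np.where(rng.random(n) < config.women_fraction, 2, 1)
    mu_b, sd_b = _lognormal_params(27.0, 4.7)
    bmi = np.exp(mu_b + sd_b * rng.standard_normal(n))
    smoking = (rng.random(n) < 0.25).astype(int)
    sbp = np.exp(_lognormal_params(135.0, 18.0)[0] + _lognormal_params(135.0, 18.0)[1] * rng.standard_normal(n))
    alcohol = np.exp(1.0 + 0.8 * rng.standard_normal(n))
    citrate = np.exp(_lognormal_params(0.11, 0.02)[0] + _lognormal_params(0.11, 0.02)[1] * rng.standard_normal(n))
    albumin = np.exp(_lognormal_params(45.0, 3.0)[0] + _lognormal_params(45.0, 3.0)[1] * rng.standard_normal(n))
    vldl_d = np.exp(_lognormal_params(36.6, 1.0)[0] + _lognormal_params(36.6, 1.0)[1] * rng.standard_normal(n))
    # CRP correlated with the inflammation signal (GlycA) on the log scale
    rho = config.crp_glyca_corr
    crp_z = rho * z["GlycA"].to_numpy() + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    crp = np.exp(_lognormal_params(2.0, 3.0)[0] + _lognormal_params(2.0, 3.0)[1] * crp_z)
    pregnant = ((sex == 2) & (age < 45) & (rng.random(n) < config.pregnancy_rate / 0.25)).astype(int)
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "smoking": smoking,
            "sbp": sbp,
            "alcohol": alcohol,
            "Cit": citrate,
            "Alb": albumin,
            "VLDL_D": vldl_d,
            "CRP": crp,
            "pregnant": pregnant,
        },
        index=panel.index,
    )


def generate_events(
    panel: pd.DataFrame, covariates: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Generate ICD-10 event records under proportional hazards.

    For each person and outcome the per-year hazard is
    ``baseline_hazard * exp(sum_b beta_b * z_b)`` with z the standardised
    log panel analytes. Event times are drawn by inverse-CDF sampling on
    the age timescale with left truncation at baseline age: an incident
    event occurs at baseline + t with t = −ln(U)/rate if t ≤ follow-up.
    An independent draw in the retrospective window populates prevalent
    events (at baseline − t'). The same uniform stream is reused across
    hazard rescalings, so increasing a baseline hazard strictly grows the
    incident event set.
    """
    config.validate()
    codes = [h.icd10 for h in config.hazard_spec]
    if len(set(codes)) != len(codes):
        raise ValueError("hazard_spec outcomes must have distinct ICD-10 codes")
    z = _panel_zscores(panel).to_numpy()
    names = list(ANALYTES)
    n = len(panel)
    baseline_age = covariates["age"].to_numpy()
    rows = []
    for k, haz in enumerate(config.hazard_spec):
        rng = _rng(config, 1000 + k)
        beta = np.array([haz.log_hr.get(a, 0.0) for a in names])
        rate = haz.baseline_hazard * np.exp(z @ beta)
        u_inc = rng.random(n)
        u_pre = rng.random(n)
        side = rng.random(n) < 0.3
        with np.errstate(divide="ignore"):
            t_inc = -np.log(u_inc) / rate
        pre_rate = (haz.prevalent_hazard or haz.baseline_hazard) * np.exp(z @ beta)
        with np.errstate(divide="ignore"):
            t_pre = -np.log(u_pre) / pre_rate
        for i in np.nonzero(t_inc <= config.followup_years)[0]:
            rows.append(
                (
                    panel.index[i],
                    baseline_age[i] + t_inc[i],
                    haz.icd10 + "0",
                    "side" if side[i] else "main",
                )
            )
        for i in np.nonzero(t_pre <= config.retrospective_years)[0]:
            rows.append(
                (
                    panel.index[i],
                    max(baseline_age[i] - t_pre[i], 0.0),
                    haz.icd10 + "1",
                    "main",
                )
            )
    return pd.DataFrame(rows, columns=["person_id", "event_age", "icd10", "source"])


def generate_expression(config: GeneratorConfig) -> ExpressionData:
    """Generate a modular expression matrix tied to AAT.

    Each module's probes share a latent profile; module m's latent is
    ``beta_m * z_AAT + sqrt(1 − beta_m²) * noise`` so that regressing
    standardised log AAT on the module eigengene recovers beta_m. Some
    genes deliberately carry two probes so the probe-collapsing step is
    exercised, and a pool of unstructured background probes provides the
    membership-test null.
    """
    if any(s < 2 for s in config.expr_module_sizes):
        raise ValueError("module sizes must be >= 2")
    rng = _rng(config, 4)
    n = config.expr_n_samples
    mu_a, sd_a = _lognormal_params(config.conc_means["AAT"], config.conc_sds["AAT"])
    z_aat = rng.standard_normal(n)
    aat = np.exp(mu_a + sd_a * z_aat)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    n_module_probes = int(sum(config.expr_module_sizes))
    n_background = max(200, n_module_probes)
    n_probes = n_module_probes + n_background

    probes, genes, rows, modules = [], [], [], {}
    probe_i = 0
    gene_i = 0

    def new_probe(gene=None):
        nonlocal probe_i, gene_i
        pid = f"ILMN_{probe_i:06d}"
        if gene is None:
            gene = f"GENE{gene_i:05d}"
            gene_i += 1
        probes.append(pid)
        genes.append(gene)
        probe_i += 1
        return pid, gene

    for m, (size, beta) in enumerate(zip(config.expr_module_sizes, config.expr_aat_betas)):
        latent = beta * z_aat + np.sqrt(max(0.0, 1 - beta**2)) * rng.standard_normal(n)
        mod_probes = []
        for j in range(size):
            pid, gene = new_probe()
            loading = config.expr_loading
            profile = loading * latent + config.expr_noise_sd * rng.standard_normal(n)
            rows.append(profile)
            mod_probes.append(pid)
            if j == 0:  # duplicate probe for the first gene of each module
                pid2, _ = new_probe(gene=gene)
                rows.append(loading * latent + config.expr_noise_sd * rng.standard_normal(n))
                mod_probes.append(pid2)
        modules[f"module_{m + 1:02d}"] = mod_probes
    while probe_i < n_probes:
        new_probe()
        rows.append(rng.standard_normal(n))

    expr = pd.DataFrame(
        7.0 + np.vstack(rows), index=pd.Index(probes, name="probe_id"), columns=sample_ids
    )
    annotation = pd.DataFrame({"probe_id": probes, "gene": genes}).set_index("probe_id")
    age = rng.uniform(25, 74, n)
    sex = np.where(rng.random(n) < config.women_fraction, 2, 1)
    covs = pd.DataFrame({"age": age, "sex": sex}, index=sample_ids)
    truth = {"z_aat": z_aat, "betas": dict(zip(modules, config.expr_aat_betas))}
    return ExpressionData(expr, annotation, modules, pd.Series(aat, index=sample_ids, name="AAT"), covs, truth)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a full cohort (panel, NMR, covariates, event records)."""
    panel = generate_panel(config)
    nmr = generate_nmr(panel, config)
    covariates = generate_covariates(panel, config)
    records = generate_events(panel, covariates, config)
    truth = {
        "target_corr": np.asarray(config.target_corr).tolist(),
        "r2_targets": dict(config.r2_targets),
        "proxy_info": nmr.attrs.get("proxy_info", {}),
        "log_hr": {h.icd10: dict(h.log_hr) for h in config.hazard_spec},
        "seed": config.seed,
    }
    return SyntheticCohort(panel, nmr, covariates, records, truth)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Serialise a cohort to CSV files in ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.panel.to_csv(out / "panel.csv")
    cohort.nmr.to_csv(out / "nmr.csv")
    cohort.covariates.to_csv(out / "covariates.csv")
    cohort.records.to_csv(out / "records.csv", index=False)
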