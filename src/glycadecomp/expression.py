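"""Transcriptional association stage: GSEA and module eigengenes.

Whole-blood expression (probe × sample, log2 quantile-normalised) is
linked to serum AAT in three ways:

1. **GSEA** on genes ranked by their Pearson correlation with AAT (both
   expression and log AAT residualised on age and sex). The running-sum
   statistic is incremented by a gene's correlation when the gene is in
   the set and decremented by 1/N_total otherwise; the enrichment score
   (ES) is the maximum of the running sum. Normalised enrichment scores
   and empirical p-values come from shuffling the sample labels of the
   AAT vector and re-ranking: NES = ES / mean(permutation ES).

2. **Module eigengenes**: each coexpression module is summarised by the
   first principal component of its probe submatrix; standardised log
   AAT is regressed on the eigengene with age and sex adjustment.

3. **Core membership**: a probe's correlation with its module eigengene
   is compared against the null distribution of correlations between the
   eigengene and all out-of-module probes; probes with BH-FDR < 0.05 are
   core members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "ModuleAssociation",
    "collapse_probes",
    "rank_genes",
    "enrichment_score",
    "normalise_and_test",
    "summary_expression",
    "module_regression",
    "core_membership",
    "read_gmt",
]


@dataclass
class EnrichmentResult:
    """GSEA outcome for one gene set."""

    name: str
    collection: str
    size: int  # genes of the set present in the ranked list
    es: float
    nes: float
    p: float
    fdr: float | None = None


@dataclass
class ModuleAssociation:
    """Eigengene association: SD of AAT per SD of summary expression."""

    module: str
    beta: float
    se: float
    p: float
    family_size: int

    @property
    def ci(self) -> tuple:
        return (self.beta - 1.96 * self.se, self.beta + 1.96 * self.se)

    @property
    def bonferroni_threshold(self) -> float:
        return 0.05 / self.family_size

    @property
    def significant(self) -> bool:
        return self.p < self.bonferroni_threshold


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name -> list of genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def collapse_probes(matrix: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse probes to genes by taking, per gene per sample, the
    highest probe expression. Probes without annotation are dropped (the
    count is recorded in ``.attrs['n_unannotated']``)."""
    gene = annotation["gene"].reindex(matrix.index)
    keep = gene.notna()
    out = matrix.loc[keep].groupby(gene[keep]).max()
    out.index.name = "gene"
    out.attrs["n_unannotated"] = int((~keep).sum())
    return out


def _residualize(y: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Residuals of y on [1, covs] by least squares. y may be 2-D
    (rows = variables, columns = samples)."""
    X = np.column_stack([np.ones(covs.shape[0]), covs])
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    return y - (X @ coef).T


def rank_genes(
    gene_matrix: pd.DataFrame,
    aat: pd.Series,
    age: pd.Series | None = None,
    sex: pd.Series | None = None,
) -> pd.Series:
    """Rank genes by Pearson correlation with age/sex-adjusted log AAT.

    Expression rows and the log-transformed AAT vector are residualised
    on age and sex before correlating. Constant genes get r = 0 by
    convention. Returns correlations sorted descending (ties broken by
    stable gene-id order).
    """
    samples = gene_matrix.columns
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    y = np.log(aat.loc[samples].to_numpy(dtype=float))
    E = gene_matrix.to_numpy(dtype=float)
    covs = []
    if age is not None:
        covs.append(age.loc[samples].to_numpy(dtype=float))
    if sex is not None:
        covs.append(sex.loc[samples].to_numpy(dtype=float))
    if covs:
        C = np.column_stack(covs)
        y = _residualize(y[None, :], C)[0]
        E = _residualize(E, C)
    y = y - y.mean()
    E = E - E.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(E, axis=1) * np.linalg.norm(y)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (E @ y) / denom
    r[~np.isfinite(r)] = 0.0
    s = pd.Series(r, index=gene_matrix.index, name="r")
    return s.sort_values(ascending=False, kind="stable")


def enrichment_score(ranked: pd.Series, gene_set, canonical: bool = False) -> float:
    """Enrichment score of a gene set against a descending-ranked list.

    Default (literal) form: walking the list, a hit adds the gene's
    correlation r, a miss subtracts 1/N_total (N_total = length of the
    ranked list); ES is the maximum of the running sum. The ``canonical``
    switch gives classic GSEA weighting instead (hits normalised by the
    set's Σ|r|, misses by 1/(N − set size)).
    """
    members = set(gene_set) & set(ranked.index)
    if not members:
        raise ValueError("gene set has no overlap with the ranked list")
    hit = ranked.index.isin(members)
    r = ranked.to_numpy(dtype=float)
    n = len(r)
    if canonical:
        denom_hit = np.abs(r[hit]).sum()
        inc = np.where(hit, np.abs(r) / (denom_hit if denom_hit > 0 else 1.0), -1.0 / (n - hit.sum()))
    else:
        inc = np.where(hit, r, -1.0 / n)
    running = np.cumsum(inc)
    return float(running.max())


def _es_extrema(ranked: pd.Series, hit: np.ndarray) -> tuple:
    r = ranked.to_numpy(dtype=float)
    inc = np.where(hit, r, -1.0 / len(r))
    running = np.cumsum(inc)
    return float(running.max()), float(running.min())


def normalise_and_test(
    gene_matrix: pd.DataFrame,
    aat: pd.Series,
    gene_sets: dict,
    age: pd.Series | None = None,
    sex: pd.Series | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    collection: str = "sets",
    permutations: np.ndarray | None = None,
) -> list:
    """Permutation-normalised GSEA over a gene-set collection.

    Sample labels of the AAT vector are shuffled ``n_perm`` times; the
    gene ranking is recomputed for each shuffle and the ES of every set
    re-evaluated. NES = observed ES / mean(permutation ES); the empirical
    p-value uses the add-one convention (b + 1)/(m + 1) on |ES| ≥ |obs|
    of same-sign extremes; BH FDR is applied within the collection.

    ``permutations`` may supply explicit permutation index rows (e.g. an
    exhaustive enumeration on tiny fixtures), overriding ``n_perm``.
    """
    import warnings

    if permutations is None and n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse", stacklevel=2)
    ranked = rank_genes(gene_matrix, aat, age, sex)
    observed = {}
    hits = {}
    for name, genes in gene_sets.items():
        members = set(genes) & set(gene_matrix.index)
        if not members:
            continue
        hit = ranked.index.isin(members)
        hits[name] = members
        es_max, es_min = _es_extrema(ranked, hit)
        # signed extremum: report the larger-magnitude excursion
        observed[name] = es_max if abs(es_max) >= abs(es_min) else es_min
    n_samples = gene_matrix.shape[1]
    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = np.array([rng.permutation(n_samples) for _ in range(n_perm)])
    m = len(permutations)
    perm_es = {name: np.empty(m) for name in observed}
    aat_vals = aat.loc[gene_matrix.columns]
    for b, perm in enumerate(permutations):
        shuffled = pd.Series(aat_vals.to_numpy()[perm], index=gene_matrix.columns)
        ranked_b = rank_genes(gene_matrix, shuffled, age, sex)
        for name in observed:
            hit = ranked_b.index.isin(hits[name])
            es_max, es_min = _es_extrema(ranked_b, hit)
            perm_es[name][b] = es_max if abs(es_max) >= abs(es_min) else es_min
    results = []
    for name, es in observed.items():
        null = perm_es[name]
        mean_null = float(np.abs(null).mean())
        nes = es / mean_null if mean_null > 0 else 0.0
        b = int((np.abs(null) >= abs(es)).sum())
        p = (b + 1) / (m + 1)
        results.append(
            EnrichmentResult(
                name=name,
                collection=collection,
                size=len(hits[name]),
                es=float(es),
                nes=float(nes),
                p=float(p),
            )
        )
    if results:
        fdr = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r_, f in zip(results, fdr):
            r_.fdr = float(f)
    return results


def summary_expression(matrix: pd.DataFrame, module_probes) -> pd.Series:
    """Module eigengene: first principal-component score of the module's
    probe submatrix (probes standardised), sign-aligned to correlate
    positively with mean module expression, then standardised."""
    present = [p for p in module_probes if p in matrix.index]
    if len(present) < 2:
        raise ValueError("module needs >= 2 probes present in the matrix")
    sub = matrix.loc[present].to_numpy(dtype=float)
    sub = (sub - sub.mean(axis=1, keepdims=True)) / sub.std(axis=1, ddof=1, keepdims=True)
    # first right singular vector = PC1 score direction across samples
    _, _, vt = np.linalg.svd(sub, full_matrices=False)
    score = vt[0]
    if np.corrcoef(score, sub.mean(axis=0))[0, 1] < 0:
        score = -score
    score = (score - score.mean()) / score.std(ddof=1)
    return pd.Series(score, index=matrix.columns, name="eigengene")


def module_regression(
    aat: pd.Series,
    summary: pd.Series,
    age: pd.Series | None = None,
    sex: pd.Series | None = None,
    module: str = "module",
    family_size: int = 20,
) -> ModuleAssociation:
    """Regress standardised log AAT on the module eigengene (+ age, sex).

    β is the change in SD of AAT per SD of coordinated module expression.
    Significance is Bonferroni at 0.05/family_size.
    """
    samples = summary.index
    y = np.log(aat.loc[samples].to_numpy(dtype=float))
    y = (y - y.mean()) / y.std(ddof=1)
    cols = [summary.loc[samples].to_numpy(dtype=float)]
    if age is not None:
        cols.append(age.loc[samples].to_numpy(dtype=float))
    if sex is not None:
        cols.append(sex.loc[samples].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(y))] + cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    beta, se = float(coef[1]), float(np.sqrt(cov[1, 1]))
    p = float(2 * stats.t.sf(abs(beta / se), dof))
    return ModuleAssociation(module=module, beta=beta, se=se, p=p, family_size=family_size)


def core_membership(
    matrix: pd.DataFrame,
    module_probes,
    fdr: float = 0.05,
    min_null: int = 50,
) -> pd.DataFrame:
    """Permutation-style membership test for core module probes.

    Each module probe's |correlation| with the module eigengene is
    compared to the null distribution of |correlation| between the
    eigengene and every out-of-module probe; empirical p uses the
    add-one convention. BH FDR within the module; probes with adjusted
    p < ``fdr`` are core members.

    Returns a DataFrame indexed by module probe with columns ``r``,
    ``p``, ``fdr`` and boolean ``core``.
    """
    present = [p for p in module_probes if p in matrix.index]
    null_probes = matrix.index.difference(present)
    if len(null_probes) < min_null:
        raise ValueError(f"need >= {min_null} out-of-module probes for the null")
    eig = summary_expression(matrix, present).to_numpy()
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    e = eig - eig.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r_all = (Xc @ e) / (np.linalg.norm(Xc, axis=1) * np.linalg.norm(e))
    r_all = pd.Series(np.nan_to_num(r_all), index=matrix.index)
    null = np.abs(r_all.loc[null_probes].to_numpy())
    m = len(null)
    rows = []
    for probe in present:
        r = abs(float(r_all.loc[probe]))
        b = int((null >= r).sum())
        rows.append({"probe": probe, "r": float(r_all.loc[probe]), "p": (b + 1) / (m + 1)})
    out = pd.DataFrame(rows).set_index("probe")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["core"] = out["fdr"] < fdr
    return out
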