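"""Transcriptional association: GSEA and module eigengene regression.

Generates a modular expression matrix in which the first module's latent
profile tracks AAT (generative effect size 0.23 SD per SD), collapses
probes to genes, runs the permutation-normalised GSEA over the module
gene sets, and regresses AAT on each module eigengene.
"""

from glycadecomp import GeneratorConfig
from glycadecomp import expression as ge
from glycadecomp.synth import generate_expression

cfg = GeneratorConfig(seed=11, expr_n_samples=518)
ed = generate_expression(cfg)
genes = ge.collapse_probes(ed.expr, ed.annotation)
print(f"{ed.expr.shape[0]} probes collapsed to {genes.shape[0]} genes "
      f"across {ed.expr.shape[1]} samples")

sets = {m: sorted(ed.annotation.loc[list(p), "gene"].unique())
        for m, p in ed.modules.items()}
results = ge.normalise_and_test(genes, ed.aat, sets, age=ed.covariates["age"],
                                sex=ed.covariates["sex"], n_perm=200, seed=0)
print(f"\n{'gene set':12s} {'size':>4s} {'ES':>7s} {'NES':>6s} {'p':>8s} {'FDR':>8s}")
for r in results:
    print(f"{r.name:12s} {r.size:4d} {r.es:7.3f} {r.nes:6.2f} {r.p:8.3g} {r.fdr:8.3g}")

print(f"\n{'module':12s} {'beta':>6s} {'95% CI':>16s} {'p':>9s}  significant(0.05/20)")
for m, probes in ed.modules.items():
    eig = ge.summary_expression(ed.expr, probes)
    a = ge.module_regression(ed.aat, eig, ed.covariates["age"], ed.covariates["sex"],
                             module=m, family_size=20)
    lo, hi = a.ci
    print(f"{m:12s} {a.beta:+6.2f} ({lo:+6.2f}, {hi:+6.2f}) {a.p:9.3g}  {a.significant}")
# module_01 is generated with beta = 0.23 (the effect size of the strongest
# published module association); the remaining modules are nulls, so only
# module_01 should clear the Bonferroni threshold and enrich in GSEA.
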