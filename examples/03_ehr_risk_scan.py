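"""Phenome-wide Cox scan with meta-analysis and replication flags.

Generates two independent cohorts whose heart-failure hazard rises by a
factor 1.6 per SD of AAT, aggregates ICD-10 records into incident and
prevalent outcomes, fits age-timescale Cox models per cohort, pools them
with fixed-effects meta-analysis, and applies the Storey-FDR dual-cohort
replication rule (q < 0.05/3 in both cohorts and the meta-analysis).
"""

import numpy as np

from glycadecomp import GeneratorConfig, generate_cohort
from glycadecomp import outcomes as go, survival as gs

cohorts = {}
for name, (n, retro, seed) in {"cohort1": (4540, 20.0, 1), "cohort2": (7321, 10.0, 2)}.items():
    cfg = GeneratorConfig(n_samples=n, seed=seed, retrospective_years=retro)
    cohorts[name] = (cfg, generate_cohort(cfg))

defs = [go.OutcomeDefinition.parse(h.label, h.icd10)
        for h in cohorts["cohort1"][0].hazard_spec]
per_cohort = {}
for name, (cfg, c) in cohorts.items():
    keep = c.covariates["pregnant"] == 0
    table = go.aggregate(c.records[c.records["person_id"].isin(keep[keep].index)],
                         defs, c.covariates.loc[keep, "age"])
    z = np.log(c.panel.loc[table.index, "AAT"])
    z = (z - z.mean()) / z.std()
    ests = gs.scan_outcomes(z, table, c.covariates.loc[table.index],
                            biomarker_name="AAT", cohort=name)
    per_cohort[name] = {e.outcome: e for e in ests}

print(f"{'outcome':28s} {'HR':>5s} {'95% CI':>14s} {'q_meta':>8s}  replicated")
shared = sorted(set(per_cohort["cohort1"]) & set(per_cohort["cohort2"]))
pooled = [gs.meta_fixed([per_cohort["cohort1"][o], per_cohort["cohort2"][o]]) for o in shared]
qres = gs.storey_q(np.array([m.p for m in pooled]))
for m, q in zip(pooled, qres.q):
    m.q = float(q)
    rep = gs.replication(per_cohort["cohort1"][m.outcome].q,
                         per_cohort["cohort2"][m.outcome].q, m.q)
    lo, hi = m.ci
    print(f"{m.outcome:28s} {m.hr:5.2f} ({lo:5.2f}-{hi:5.2f}) {m.q:8.2g}  {rep}")
# Outcomes generated with a nonzero AAT log-hazard (heart failure 1.60,
# pneumonia 1.37, liver disease 1.81) should replicate; the forearm-fracture
# outcome is a built-in null and should not.
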