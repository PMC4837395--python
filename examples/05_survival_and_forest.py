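"""Kaplan-Meier comparison and odds-ratio forest for predicted risk groups.

Simulates a cohort whose resistant class has a 3x hazard, classifies the
patients with the probit-metagene model, compares the predicted groups with
a log-rank test, and pools event-by-class odds ratios across two simulated
cohorts with Mantel-Haenszel.
"""

import numpy as np

from chemosig import signature, survival
from chemosig.simulate import simulate_cohort

sig = signature.filter_signature_table(signature.load_signature_table())

tables, names = [], []
for seed, name in ((11, "cohortA"), (12, "cohortB")):
    cohort = simulate_cohort(sig.directions, effect_sd=2.0, hazard_ratio=3.0,
                             censor_rate=0.3, seed=seed)
    params = signature.fit_bbr(cohort, genes=sig.genes)
    preds = {r.patient_id: r.predicted
             for r in signature.predict_bbr(params, cohort.table[sig.genes])}
    t = cohort.table
    grp = {c: t.loc[[p for p in cohort.patient_ids if preds[p] == c]] for c in
           ("sensitive", "resistant")}
    chi2, p = survival.logrank(
        (grp["sensitive"]["time"], grp["sensitive"]["event"]),
        (grp["resistant"]["time"], grp["resistant"]["event"]),
    )
    km = survival.km_estimate(grp["resistant"]["time"].to_numpy(),
                              grp["resistant"]["event"].to_numpy(dtype=int))
    print(f"{name}: log-rank chi2={chi2:.2f}, p={p:.3g}; "
          f"predicted-resistant S(12)={km.s_at(12):.2f}")
    ev = t["event"].to_numpy(dtype=int)
    pr = np.array([preds[p_] for p_ in cohort.patient_ids])
    tables.append([[int(((pr == "resistant") & (ev == 1)).sum()),
                    int(((pr == "resistant") & (ev == 0)).sum())],
                   [int(((pr == "sensitive") & (ev == 1)).sum()),
                    int(((pr == "sensitive") & (ev == 0)).sum())]])
    names.append(name)

meta = survival.meta_or(tables, names=names)
print(meta.to_frame().to_string(index=False))
# Predicted-resistant patients relapse faster (low S(12), small log-rank p)
# and the pooled odds ratio > 1 summarises the excess event risk across
# cohorts; per-dataset weights are each cohort's share of the total cases.
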