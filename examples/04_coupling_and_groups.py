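"""Structure-function coupling and its comparison between groups.

Computes each subject's within-subject coupling (Pearson correlation of
FA and FC edge weights over long-range edges) and compares it between
HC, CP and CI with a general linear model adjusting for age and sex.
The cohort plants a stronger coupling slope in CI, which the comparison
should recover.
"""

import numpy as np

from scfc import CohortConfig, generate_cohort, glm_group_compare, within_subject_coupling
from scfc.sc import classify_edges, mask_fc_by_structure, quartile_thresholds

config = CohortConfig(n_hc=15, n_cp=15, n_ci=15, n_nodes=40, seed=23)
cohort = generate_cohort(config, mode="fc")

thr = quartile_thresholds([r.connectome for r in cohort.by_group("HC")])
iu = np.triu_indices(config.n_nodes, k=1)

vals, groups, age, sex = [], [], [], []
for rec in cohort.records:
    mask = classify_edges(rec.connectome, thr)
    fa = rec.connectome.fa[iu][mask.long_mask]
    fc = mask_fc_by_structure(rec.fc["theta"], mask, "long")
    vals.append(within_subject_coupling(fa, fc, rec.subject.id, "long", "theta").r)
    groups.append(rec.subject.group)
    age.append(rec.subject.age)
    sex.append(float(rec.subject.sex))

comp = glm_group_compare(
    np.array(vals), np.array(groups), covariates={"age": age, "sex": sex},
    outcome="long-range coupling", group_order=["HC", "CP", "CI"],
)
print("long-range structure-function coupling (theta band):")
for g, mu in comp.adjusted_means.items():
    print(f"  adjusted mean {g}: {mu:+.3f}")
print(f"omnibus group effect: F = {comp.F:.2f}, p = {comp.p:.2e}")
for (a, b), p in comp.pairwise.items():
    print(f"  pairwise {a} vs {b}: p = {p:.2e}")
print(
    "\nHigher coupling means a subject's functional connectivity tracks their"
    "\nstructural connectivity more closely; the planted effect makes CI > HC."
)
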