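"""Stratify miRNA-target decay by seed class over a 0/2/4-h time course.

Simulates a normalized expression matrix after miRNA overexpression where
true decay rates rise with seed strength, computes per-gene log2
(miRNA / control) ratios per time point, and summarizes them per seed
class with a between-class ANOVA at each time.
"""

from mirutr.kinetics import TargetAnnotation, class_trend_summary, ddct_fold_change, CtRecord, relative_abundance
from mirutr.synthetic_data import gen_decay_matrix

lam = {"8mer": 0.5, "7mer-m8": 0.35, "7mer-A1": 0.2, "6mer": 0.08}
anns = {
    f"g{i:03d}": TargetAnnotation(f"g{i:03d}", cls, 1)
    for i, cls in enumerate([c for c in lam for _ in range(25)])
}
matrix, meta, truth = gen_decay_matrix(anns, 500.0, lam, 0.0, seed=5)
ratios = relative_abundance(matrix, meta)
summary, tests = class_trend_summary(ratios, anns, "seed_class")

for _, row in summary[summary["time"] == 4.0].iterrows():
    print(f"{row['stratum']:8s} 4-h log2 ratio = {row['mean']:+.2f} "
          f"+/- {row['sem']:.2f} (n={row['n']})")
p4 = tests.loc[tests["time"] == 4.0, "anova_p"].iloc[0]
print(f"between-class ANOVA at 4 h: p = {p4:.2e}")

fc = ddct_fold_change(CtRecord(22.0, 18.0, 20.0, 18.0))
print(f"ddCt validation example (target up 2 cycles under treatment): FC = {fc}")
# 8mer targets fall furthest by 4 h and 6mer least, mirroring seed-strength
# repression; the ddCt utility converts a qPCR check into a fold change.
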