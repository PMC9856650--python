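"""Quantify protein-synthesis rates from FRAP build-up traces.

Simulates 21-frame post-bleach traces (30-s intervals) for six reporter
conditions whose true build-up slopes rise with weakening miRNA
repression (full complement slowest, non-targeting control fastest),
then estimates per-cell slopes over frames 5-20, the control's K_R50
level, each condition's crossing time, and the group comparison.
"""

import numpy as np

from mirutr.frap import compare_slopes, crossing_time, kr50, normalize_buildup, summarize_trace
from mirutr.synthetic_data import gen_frap_traces

truth = {"full": 0.4, "8mer": 0.8, "7mer-A1": 1.1, "7mer-m8": 1.2,
         "6mer": 1.6, "control": 2.0}
traces, _ = gen_frap_traces(truth, n_cells=15, seed=3, noise_sd=0.3)
summaries = [summarize_trace(t) for t in traces]

level = kr50([normalize_buildup(t) for t in traces if t.condition == "control"])
print(f"K_R50 level (half of control max recovery): {level:.1f} % of pre-bleach")
for cond in truth:
    sl = [s.slope_per_frame for s in summaries if s.condition == cond]
    curve = np.mean([s.buildup for s in summaries if s.condition == cond], axis=0)
    t50 = crossing_time(curve, traces[0].times, level)
    t50_txt = f"{t50:5.0f} s" if t50 is not None else "never"
    print(f"{cond:8s} slope = {np.mean(sl):.2f} %/frame (truth {truth[cond]}), "
          f"K_R50 crossing at {t50_txt}")

f_stat, p, _ = compare_slopes(summaries)
print(f"one-way ANOVA across conditions: F = {f_stat:.1f}, p = {p:.2e}")
# Slopes track the planted truth; stronger repression crosses K_R50 later
# (or never), and the ANOVA is overwhelmingly significant.
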