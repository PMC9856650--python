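"""Infer APA breakpoints and call 3'UTR lengthening between compartments.

Simulates per-base coverage for 20 transcripts in two compartments (axon
PDUI 0.8 vs soma 0.4, i.e. the long isoform dominates in axons), fits a
shared two-segment breakpoint per transcript, and calls
lengthened/shortened events at FDR < 0.05 and |dPDUI| >= 0.2.
"""

import numpy as np

from mirutr.apa import call_apa_events, fit_transcript
from mirutr.seedscan import MatureMiRNA
from mirutr.synthetic_data import gen_coverage, gen_utrs

mir129 = MatureMiRNA("miR-129-5p", "CUUUUGCGGUCUGGGCUUGC")
utrs, _ = gen_utrs(20, (400, 600), mir129, {}, seed=1)
for u in utrs:
    u.breakpoint = len(u) // 2

profiles, truth = gen_coverage(
    utrs, {"axon": 0.8, "soma": 0.4}, depth=100.0, n_samples=3, seed=2
)
by_tid = {}
for p in profiles:
    by_tid.setdefault(p.transcript_id, []).append(p)

calls = [fit_transcript(ps) for ps in by_tid.values()]
calls = call_apa_events([c for c in calls if c], "axon", "soma")

bp_err = [abs(c.breakpoint - u.breakpoint) for c, u in zip(calls, utrs)]
print(f"median |breakpoint error|: {np.median(bp_err):.0f} bases")
n_len = sum(c.status == "lengthened" for c in calls)
print(f"lengthened calls: {n_len}/{len(calls)}")
c = calls[0]
print(
    f"example {c.transcript_id}: breakpoint={c.breakpoint}, "
    f"dPDUI={c.delta_pdui:+.2f}, FDR={c.fdr:.2e}, status={c.status}"
)
# dPDUI ~ +0.4 (axon minus soma) on every transcript: all 20 should be
# called lengthened, with breakpoints within a few bases of the truth.
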