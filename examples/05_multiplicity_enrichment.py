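"""Compare site-multiplicity spectra of lengthened 3'UTRs between panels.

Builds a cohort of 'lengthened' UTRs where panel-A miRNAs (neuronal-like)
were planted with more multi-site targets than panel-B miRNAs, computes
each miRNA's 1/2/>2-site spectrum, and tests the pooled class counts with
a Pearson chi-square.
"""

from mirutr.enrichment import compare_panels, multiplicity_spectrum
from mirutr.seedscan import MatureMiRNA
from mirutr.synthetic_data import gen_utrs

mir129 = MatureMiRNA("miR-129-5p", "CUUUUGCGGUCUGGGCUUGC")
mir1 = MatureMiRNA("miR-1-3p", "UGGAAUGUAAAGAAGUAUGUAU")


def cohort(mirna, plan, seed0):
    utrs = []
    for i, (spec, n) in enumerate(plan):
        batch, _ = gen_utrs(n, (250, 400), mirna, spec, seed=seed0 + i)
        for j, u in enumerate(batch):
            u.transcript_id = f"s{seed0}_{i}_{j}"
        utrs.extend(batch)
    return utrs


# panel A: multi-site heavy; panel B: mostly single-site
utrs_a = cohort(mir129, [({"7mer-A1": 1}, 20), ({"7mer-A1": 2}, 25), ({"7mer-A1": 3}, 15)], 100)
utrs_b = cohort(mir1, [({"7mer-m8": 1}, 45), ({"7mer-m8": 2}, 10), ({"7mer-m8": 3}, 5)], 200)

spec_a = multiplicity_spectrum(utrs_a, [mir129])
spec_b = multiplicity_spectrum(utrs_b, [mir1])
for label, spec in (("A (multi-site heavy)", spec_a), ("B (single-site heavy)", spec_b)):
    pct = spec.set_index("multiplicity")["pct_of_utrs"]
    print(f"panel {label}: 1 site {pct['1']:.0f}%, 2 sites {pct['2']:.0f}%, "
          f">2 sites {pct['>2']:.0f}%")

res = compare_panels(spec_a, spec_b)
print(f"chi-square = {res['statistic']:.1f}, df = {res['df']}, p = {res['p_value']:.2e}")
# The multi-site shift between panels is strongly significant: lengthened
# UTRs offer panel-A miRNAs many more repeated binding sites.
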