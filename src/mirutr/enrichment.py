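"""Site-multiplicity spectra of lengthened 3'UTRs across miRNA panels.

Given the set of transcripts whose 3'UTR is lengthened in one compartment,
each miRNA of a panel is scanned against every UTR and the transcripts are
binned by how many canonical sites they carry (1, 2, >2; zero reported
separately).  Comparing the pooled class counts of two panels (e.g.
neuronal vs non-neuronal miRNAs) with a Pearson chi-square test asks
whether one panel's miRNAs systematically hit lengthened UTRs with more
site copies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .seedscan import MatureMiRNA, UtrRecord, multiplicity_class, scan_utr

__all__ = ["multiplicity_spectrum", "compare_panels", "spectrum_contingency"]

MULTIPLICITY_CLASSES = ("0", "1", "2", ">2")


def multiplicity_spectrum(
    lengthened_utrs: list[UtrRecord],
    mirna_panel: list[MatureMiRNA],
) -> pd.DataFrame:
    """Per-miRNA counts/percentages of UTRs with 1, 2 or >2 sites.

    One row per (miRNA, multiplicity class).  ``pct_of_utrs`` uses the
    full UTR-set size as denominator (the share of all lengthened
    transcripts); ``pct_of_targets`` uses only UTRs with >=1 site, i.e.
    the share of that miRNA's targets — both denominators are of interest
    and both are emitted.
    """
    if not lengthened_utrs:
        raise ValueError("UTR set must be non-empty")
    if not mirna_panel:
        raise ValueError("miRNA panel must be non-empty")
    n_utrs = len(lengthened_utrs)
    rows = []
    for mirna in mirna_panel:
        counts = dict.fromkeys(MULTIPLICITY_CLASSES, 0)
        for utr in lengthened_utrs:
            counts[multiplicity_class(len(scan_utr(utr, mirna)))] += 1
        n_targets = n_utrs - counts["0"]
        for cls in MULTIPLICITY_CLASSES:
            rows.append(
                {
                    "mirna": mirna.name,
                    "multiplicity": cls,
                    "n_transcripts": counts[cls],
                    "pct_of_utrs": 100.0 * counts[cls] / n_utrs,
                    "pct_of_targets": (
                        100.0 * counts[cls] / n_targets if n_targets else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


def spectrum_contingency(spectrum: pd.DataFrame, include_zero: bool = False) -> np.ndarray:
    """Pool a spectrum's transcript counts into a class-count vector."""
    classes = MULTIPLICITY_CLASSES if include_zero else MULTIPLICITY_CLASSES[1:]
    return np.array(
        [
            spectrum.loc[spectrum["multiplicity"] == cls, "n_transcripts"].sum()
            for cls in classes
        ],
        dtype=float,
    )


def compare_panels(
    spectrum_a: pd.DataFrame,
    spectrum_b: pd.DataFrame,
    include_zero: bool = False,
) -> dict:
    """Pearson chi-square comparison of two panels' multiplicity spectra.

    Rows of the contingency table are panels, columns the multiplicity
    classes (pooled transcript counts over each panel's miRNAs); no
    continuity correction.  Returns statistic, df, p and the expected
    counts, with a warning when any expected count is below 5.
    """
    table = np.vstack(
        [
            spectrum_contingency(spectrum_a, include_zero),
            spectrum_contingency(spectrum_b, include_zero),
        ]
    )
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table (zero margin)")
    res = stats.chi2_contingency(table, correction=False)
    if (res.expected_freq < 5).any():
        warnings.warn("chi-square expected count < 5; test may be unreliable")
    return {
        "statistic": float(res.statistic),
        "df": int(res.dof),
        "p_value": float(res.pvalue),
        "observed": table,
        "expected": res.expected_freq,
    }
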