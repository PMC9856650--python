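"""Seed-class / site-count stratified mRNA decay after miRNA overexpression.

After transfecting a miRNA into cells, its endogenous targets decay at
rates that increase with seed-match strength (8mer > 7mer-m8 > 7mer-A1 >
6mer) and with the number of canonical sites.  This module consumes an
already-normalized expression matrix sampled at 0/2/4 h in miRNA vs
control conditions, computes per-gene log2 abundance ratios, and
summarizes/tests them across seed-class or site-count strata.  A
comparative-Ct (ddCt) utility converts qPCR cycle thresholds into fold
changes for single-gene validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seedscan import SITE_PRIORITY, MatureMiRNA, UtrRecord, scan_utr, multiplicity_class

__all__ = [
    "TargetAnnotation",
    "CtRecord",
    "annotate_targets",
    "relative_abundance",
    "class_trend_summary",
    "ddct_fold_change",
]

#: Seed classes from strongest to weakest repression (``full`` collapses
#: into 8mer for stratification: endogenous full sites are vanishingly rare).
SEED_CLASS_ORDER = ("8mer", "7mer-m8", "7mer-A1", "6mer", "none")


@dataclass(frozen=True)
class TargetAnnotation:
    """Per-gene target status for one focal miRNA."""

    gene: str
    seed_class: str   # strongest site type present, or "none"
    n_sites: int

    def __post_init__(self) -> None:
        if (self.seed_class == "none") != (self.n_sites == 0):
            raise ValueError(
                f"{self.gene}: seed_class 'none' iff n_sites == 0 "
                f"(got {self.seed_class!r}, {self.n_sites})"
            )


@dataclass(frozen=True)
class CtRecord:
    """qPCR cycle thresholds for a target and a reference gene."""

    ct_target_treat: float
    ct_ref_treat: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        for v in (self.ct_target_treat, self.ct_ref_treat,
                  self.ct_target_ctrl, self.ct_ref_ctrl):
            if not v > 0:
                raise ValueError("Ct values must be positive")


def annotate_targets(
    utrs: list[UtrRecord], mirna: MatureMiRNA
) -> dict[str, TargetAnnotation]:
    """Scan every UTR and record its strongest seed class and site count."""
    out: dict[str, TargetAnnotation] = {}
    for utr in utrs:
        if utr.transcript_id in out:
            raise ValueError(f"duplicate gene id {utr.transcript_id!r}")
        sites = scan_utr(utr, mirna)
        if sites:
            best = min(sites, key=lambda s: SITE_PRIORITY.index(s.site_type))
            cls = "8mer" if best.site_type == "full" else best.site_type
            out[utr.transcript_id] = TargetAnnotation(utr.transcript_id, cls, len(sites))
        else:
            out[utr.transcript_id] = TargetAnnotation(utr.transcript_id, "none", 0)
    return out


def relative_abundance(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2 (miRNA / control) abundance ratio at each time point.

    ``matrix`` is genes x samples (normalized, non-negative); ``metadata``
    is indexed by sample with columns ``condition`` ("mir"/"control") and
    ``time`` (hours).  For each gene and time the ratio is
    ``log2((mean_mir + c) / (mean_control + c))`` with pseudocount c, so
    a gene untouched by the miRNA sits at ~0 and halving yields -1.
    Returned frame: genes x sorted time points.
    """
    missing = [s for s in matrix.columns if s not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression matrix must be non-negative")
    times = sorted(metadata["time"].unique())
    cols = {}
    for t in times:
        mir = metadata.index[(metadata["time"] == t) & (metadata["condition"] == "mir")]
        ctl = metadata.index[(metadata["time"] == t) & (metadata["condition"] == "control")]
        if len(mir) == 0 or len(ctl) == 0:
            raise ValueError(f"time {t}: both conditions must be present")
        cols[t] = np.log2(
            (matrix[mir].mean(axis=1) + pseudocount)
            / (matrix[ctl].mean(axis=1) + pseudocount)
        )
    return pd.DataFrame(cols)


def _stratum_of(ann: TargetAnnotation, stratify_by: str) -> str:
    if stratify_by == "seed_class":
        return ann.seed_class
    if stratify_by == "n_sites":
        return multiplicity_class(ann.n_sites)
    raise ValueError(f"unknown stratifier {stratify_by!r}")


def class_trend_summary(
    ratios: pd.DataFrame,
    annotations: dict[str, TargetAnnotation],
    stratify_by: str = "seed_class",
    adjust: str = "holm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratum x time decay summary with a between-stratum test per time.

    Returns ``(summary, tests)``: *summary* holds mean, SEM and n of the
    per-gene log2 ratios for each stratum at each time; *tests* holds, per
    time, the one-way ANOVA F/p across strata and adjusted pairwise
    Welch-t p-values (rows ``stratum_a``/``stratum_b``).  Strata with
    fewer than two genes are dropped with a warning.
    """
    strata: dict[str, list[str]] = {}
    for gene in ratios.index:
        if gene not in annotations:
            warnings.warn(f"gene {gene!r} has no annotation; excluded")
            continue
        strata.setdefault(_stratum_of(annotations[gene], stratify_by), []).append(gene)
    for name in [k for k, v in strata.items() if len(v) < 2]:
        warnings.warn(f"stratum {name!r} has <2 genes; dropped")
        del strata[name]
    if len(strata) < 2:
        raise ValueError("need >=2 strata with >=2 genes each")

    rows, test_rows = [], []
    for t in ratios.columns:
        groups = {k: ratios.loc[genes, t].to_numpy() for k, genes in strata.items()}
        for k, vals in groups.items():
            rows.append(
                {
                    "stratum": k,
                    "time": t,
                    "mean": float(np.mean(vals)),
                    "sem": float(stats.sem(vals)),
                    "n": len(vals),
                }
            )
        arrays = list(groups.values())
        if np.ptp(np.concatenate(arrays)) == 0:
            f_stat, p_anova = 0.0, 1.0
        else:
            res = stats.f_oneway(*arrays)
            f_stat, p_anova = float(res.statistic), float(res.pvalue)
        names = list(groups)
        pairs = list(combinations(names, 2))
        raw = []
        for a, b in pairs:
            x, y = groups[a], groups[b]
            if np.var(x) == 0 and np.var(y) == 0:
                raw.append(1.0 if np.mean(x) == np.mean(y) else 0.0)
            else:
                raw.append(float(stats.ttest_ind(x, y, equal_var=False).pvalue))
        adj = multipletests(raw, method=adjust)[1] if (adjust != "none" and raw) else raw
        for (a, b), p in zip(pairs, adj):
            test_rows.append(
                {
                    "time": t,
                    "anova_F": f_stat,
                    "anova_p": p_anova,
                    "stratum_a": a,
                    "stratum_b": b,
                    "p_adj": float(p),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(test_rows)


def ddct_fold_change(ct: CtRecord) -> float:
    """Comparative-Ct fold change, ``2 ** -ddCt``.

    ``ddCt = (Ct_target - Ct_ref) under treatment minus the same
    difference under control``; equal Cts give 1.0, each extra cycle of
    the target under treatment halves the fold change.
    """
    dct_treat = ct.ct_target_treat - ct.ct_ref_treat
    dct_ctrl = ct.ct_target_ctrl - ct.ct_ref_ctrl
    return float(2.0 ** -(dct_treat - dct_ctrl))
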