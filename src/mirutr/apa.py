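"""Alternative-polyadenylation inference from 3'UTR coverage profiles.

Many transcripts carry two 3'UTR isoforms produced by alternative
polyadenylation (APA): a short isoform ending at a proximal poly(A) site
and a long isoform running to the distal site.  In RNA-seq, per-base
coverage over the annotated (long) 3'UTR is then a two-level step
function: both isoforms contribute up to the proximal site, only the long
isoform beyond it.  Fitting that step yields

* the breakpoint ``P`` (last base of the short isoform), and
* per-sample isoform weights ``w_long`` (depth from the long isoform) and
  ``w_short`` (extra depth from the short isoform),

from which the long-isoform usage index PDUI = w_long / (w_long + w_short)
follows.  Comparing mean PDUI between two groups (e.g. axon vs soma
compartments of neurons) and thresholding the difference calls transcripts
whose 3'UTR is lengthened or shortened in the first group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .seedscan import UtrRecord

__all__ = [
    "CoverageProfile",
    "ApaCall",
    "fit_two_segment",
    "compute_pdui",
    "call_apa_events",
    "utr_isoform_model_from_call",
    "DEFAULT_MIN_SEGMENT",
    "DEFAULT_MIN_MEAN_DEPTH",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEGMENT = 50
#: Transcripts with mean depth below this in any sample are skipped; a
#: proxy for the usual expression filter before APA calling.
DEFAULT_MIN_MEAN_DEPTH = 5.0


@dataclass
class CoverageProfile:
    """Per-base read depth over one transcript's 3'UTR in one sample."""

    transcript_id: str
    sample_id: str
    group: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if np.any(self.depth < 0):
            raise ValueError(
                f"negative depth in {self.transcript_id}/{self.sample_id}"
            )


@dataclass
class ApaCall:
    """Fitted APA state of one transcript plus the group comparison."""

    transcript_id: str
    breakpoint: int
    pdui_per_sample: dict[str, float]
    sample_groups: dict[str, str]
    pdui_group_mean: dict[str, float] = field(default_factory=dict)
    delta_pdui: float = float("nan")
    p_value: float | None = None
    fdr: float | None = None
    status: str = "ns"


def _segment_sse_grid(depth: np.ndarray, min_segment: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SSE of the two-level step model at every candidate breakpoint.

    For a candidate P (1-based, bases 1..P are "short+long"), the
    least-squares level of each segment is its mean; ``w_long`` is the
    distal mean and ``w_short`` the proximal minus distal mean, clipped at
    zero (an inverted step is refit as a flat profile).  Returns
    (sse, w_long, w_short) arrayed over the candidate grid
    ``P = min_segment .. L - min_segment``.
    """
    L = depth.size
    grid = np.arange(min_segment, L - min_segment + 1)
    csum = np.concatenate([[0.0], np.cumsum(depth)])
    csq = np.concatenate([[0.0], np.cumsum(depth**2)])
    n1 = grid.astype(float)
    n2 = L - n1
    s1, s2 = csum[grid], csum[L] - csum[grid]
    q1, q2 = csq[grid], csq[L] - csq[grid]
    m1, m2 = s1 / n1, s2 / n2
    w_short = m1 - m2
    inverted = w_short < 0
    w_long = np.where(inverted, csum[L] / L, m2)
    w_short = np.where(inverted, 0.0, w_short)
    # SSE around the fitted levels, in one pass via sum-of-squares identities
    sse = (q1 - 2 * (w_long + w_short) * s1 + n1 * (w_long + w_short) ** 2) + (
        q2 - 2 * w_long * s2 + n2 * w_long**2
    )
    return sse, w_long, w_short


def fit_two_segment(
    profiles: list[CoverageProfile],
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> tuple[int, dict[str, tuple[float, float]]] | None:
    """Fit one shared APA breakpoint jointly over all samples.

    The breakpoint is chosen on the grid ``[min_segment, L - min_segment]``
    minimising the total squared error summed over samples, each sample
    keeping its own non-negative (w_long, w_short); ties break toward the
    smallest breakpoint.  Returns ``(breakpoint, {sample_id: (w_long,
    w_short)})`` or ``None`` when every sample is all-zero.
    """
    if not profiles:
        raise ValueError("no coverage profiles supplied")
    L = profiles[0].depth.size
    if any(p.depth.size != L for p in profiles):
        raise ValueError(
            f"unequal profile lengths for {profiles[0].transcript_id!r}"
        )
    if min_segment < 1 or L < 2 * min_segment:
        raise ValueError(
            f"UTR length {L} too short for min_segment={min_segment}"
        )
    if all(not p.depth.any() for p in profiles):
        logger.warning(
            "transcript %s skipped: zero coverage in every sample",
            profiles[0].transcript_id,
        )
        return None
    per_sample = [_segment_sse_grid(p.depth, min_segment) for p in profiles]
    total_sse = np.sum([s[0] for s in per_sample], axis=0)
    best = int(np.argmin(total_sse))  # argmin takes the first (smallest P) tie
    breakpoint = min_segment + best
    weights = {
        p.sample_id: (float(w_long[best]), float(w_short[best]))
        for p, (_, w_long, w_short) in zip(profiles, per_sample)
    }
    return breakpoint, weights


def compute_pdui(w_long: float, w_short: float) -> float:
    """Long-isoform usage index in [0, 1]."""
    if w_long < 0 or w_short < 0:
        raise ValueError("isoform weights must be non-negative")
    total = w_long + w_short
    if total == 0:
        raise ValueError("both isoform weights are zero; PDUI undefined")
    return w_long / total


def fit_transcript(
    profiles: list[CoverageProfile],
    min_segment: int = DEFAULT_MIN_SEGMENT,
    min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
) -> ApaCall | None:
    """Breakpoint + per-sample PDUIs for one transcript, or None if skipped."""
    if any(p.depth.mean() < min_mean_depth for p in profiles):
        logger.warning(
            "transcript %s skipped: mean depth < %gx in at least one sample",
            profiles[0].transcript_id,
            min_mean_depth,
        )
        return None
    fitted = fit_two_segment(profiles, min_segment=min_segment)
    if fitted is None:
        return None
    breakpoint, weights = fitted
    pduis, groups = {}, {}
    for p in profiles:
        w_long, w_short = weights[p.sample_id]
        if w_long + w_short == 0:
            continue  # uninformative sample
        pduis[p.sample_id] = compute_pdui(w_long, w_short)
        groups[p.sample_id] = p.group
    if not pduis:
        return None
    return ApaCall(profiles[0].transcript_id, breakpoint, pduis, groups)


def call_apa_events(
    calls: list[ApaCall],
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    min_abs_delta: float = 0.2,
) -> list[ApaCall]:
    """Annotate transcript calls with dPDUI, Welch p, BH-FDR and status.

    ``delta_pdui`` = mean PDUI in ``group_a`` minus mean in ``group_b``
    (with axon as group A, "lengthened" means longer 3'UTRs in axons).
    A transcript is *lengthened* when FDR < alpha and dPDUI >= +threshold,
    *shortened* when FDR < alpha and dPDUI <= -threshold, else *ns*.
    Transcripts with fewer than two samples per group get no p-value.
    """
    tested_idx: list[int] = []
    pvals: list[float] = []
    for i, call in enumerate(calls):
        a = [v for s, v in call.pdui_per_sample.items() if call.sample_groups[s] == group_a]
        b = [v for s, v in call.pdui_per_sample.items() if call.sample_groups[s] == group_b]
        call.pdui_group_mean = {
            group_a: float(np.mean(a)) if a else float("nan"),
            group_b: float(np.mean(b)) if b else float("nan"),
        }
        call.delta_pdui = call.pdui_group_mean[group_a] - call.pdui_group_mean[group_b]
        call.status = "ns"
        if len(a) >= 2 and len(b) >= 2:
            if np.var(a) == 0 and np.var(b) == 0:
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            call.p_value = p
            tested_idx.append(i)
            pvals.append(p)
    if tested_idx:
        fdrs = multipletests(pvals, method="fdr_bh")[1]
        for i, fdr in zip(tested_idx, fdrs):
            call = calls[i]
            call.fdr = float(fdr)
            if call.fdr < alpha and call.delta_pdui >= min_abs_delta:
                call.status = "lengthened"
            elif call.fdr < alpha and call.delta_pdui <= -min_abs_delta:
                call.status = "shortened"
    return calls


def utr_isoform_model_from_call(call: ApaCall, utr: UtrRecord) -> UtrRecord:
    """Copy a fitted breakpoint onto the UTR sequence record."""
    if call.transcript_id != utr.transcript_id:
        raise ValueError(
            f"transcript mismatch: call {call.transcript_id!r} vs "
            f"UTR {utr.transcript_id!r}"
        )
    if not 1 <= call.breakpoint <= len(utr):
        raise ValueError(
            f"breakpoint {call.breakpoint} outside UTR of length {len(utr)}"
        )
    return UtrRecord(utr.transcript_id, utr.sequence, breakpoint=call.breakpoint)
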