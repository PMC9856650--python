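"""Truth-known generators for every input the pipeline consumes.

Each generator emulates one experimental data stream of the study design —
3'UTRs with planted canonical sites, two-isoform coverage mixtures around
an APA breakpoint, miRNA-overexpression decay matrices at 0/2/4 h, and
FRAP build-up traces — and returns the generated objects together with a
tidy *truth* table of the planted parameters, so every downstream module
can be tested for recovery without any external download.

Randomness: a single master seed is fanned out through
``numpy.random.SeedSequence.spawn`` into one independent stream per
generated entity, so regenerating with the same seed is reproducible and
adding entities never perturbs earlier ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .apa import CoverageProfile
from .frap import FrapTrace
from .kinetics import TargetAnnotation
from .seedscan import (
    MatureMiRNA,
    UtrRecord,
    SITE_SPAN,
    reverse_complement,
    site_patterns,
)

__all__ = [
    "gen_utrs",
    "gen_coverage",
    "gen_decay_matrix",
    "gen_frap_traces",
]

_BASES = np.array(list("ACGT"))
#: Retries before a placement/flank draw is declared infeasible.
MAX_RETRIES = 200


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length)) if length else ""


def _corefree_seq(rng: np.random.Generator, length: int, core: str) -> str:
    """Rejection-sample a sequence containing no seed-core occurrence."""
    for _ in range(MAX_RETRIES):
        seq = _random_seq(rng, length)
        if core not in seq:
            return seq
    raise RuntimeError(
        f"could not draw a {length}-nt flank free of core {core!r} "
        f"after {MAX_RETRIES} tries"
    )


def _validate_planting(
    seq: str, planted: list[tuple[str, int]], mirna: MatureMiRNA
) -> bool:
    """Check planted sites classify as intended, by direct string checks.

    Deliberately independent of the scanner: counts seed-core substrings
    and inspects the flanking bases of each planted site so that
    round-trip tests against ``scan_utr`` stay meaningful.
    """
    core = reverse_complement(mirna.seed_core)
    m8 = reverse_complement(mirna.sequence[7])
    n_cores = sum(
        1 for i in range(len(seq) - 5) if seq[i : i + 6] == core
    )
    if n_cores != len(planted):
        return False
    for site_type, start in planted:  # start is 1-based site start
        c = start - 1 if site_type in ("7mer-A1", "6mer") else start  # 0-based core
        if seq[c : c + 6] != core:
            return False
        has_m8 = c >= 1 and seq[c - 1] == m8
        has_a1 = c + 6 < len(seq) and seq[c + 6] == "A"
        want = {
            "8mer": (True, True),
            "7mer-m8": (True, False),
            "7mer-A1": (False, True),
            "6mer": (False, False),
        }[site_type]
        if (has_m8, has_a1) != want:
            return False
        if site_type == "8mer":
            # guard against accidental upgrade to a full-complement site
            n = len(mirna.sequence)
            fs = c - 1 - (n - 8)
            if fs >= 0:
                expect = reverse_complement(mirna.sequence[8:])
                mism = sum(a != b for a, b in zip(seq[fs : c - 1], expect))
                if mism <= 1:
                    return False
    return True


def _plant_one_utr(
    rng: np.random.Generator,
    length: int,
    mirna: MatureMiRNA,
    sites_spec: dict[str, int],
) -> tuple[str, list[tuple[str, int, int]]]:
    """One UTR with the requested sites at random non-overlapping positions."""
    patterns = site_patterns(mirna)
    core = reverse_complement(mirna.seed_core)
    site_types = [t for t, k in sites_spec.items() for _ in range(int(k))]
    total_span = sum(SITE_SPAN[t] for t in site_types)
    # one spacer base on each side of every site keeps guards local
    min_len = total_span + 2 * len(site_types)
    if length < min_len:
        raise ValueError(
            f"UTR length {length} cannot hold {len(site_types)} sites "
            f"(needs >= {min_len})"
        )
    for _ in range(MAX_RETRIES):
        order = list(rng.permutation(len(site_types)))
        types = [site_types[i] for i in order]
        slack = length - total_span
        cuts = np.sort(rng.choice(slack + 1, size=len(types), replace=False)) if len(types) <= slack else None
        if cuts is None:
            continue
        pieces, planted = [], []
        pos = 0  # 0-based length so far
        prev_cut = 0
        ok = True
        for t, cut in zip(types, cuts):
            gap = int(cut) - prev_cut
            prev_cut = int(cut)
            flank = _corefree_seq(rng, gap, core)
            pieces.append(flank)
            pos += gap
            site = patterns[t]
            start = pos + 1  # 1-based
            pieces.append(site)
            pos += len(site)
            planted.append((t, start, start + len(site) - 1))
        pieces.append(_corefree_seq(rng, length - pos, core))
        seq = "".join(pieces)
        assert len(seq) == length
        if _validate_planting(seq, [(t, s) for t, s, _ in planted], mirna):
            return seq, planted
    raise RuntimeError(
        f"site placement failed after {MAX_RETRIES} attempts "
        f"(length {length}, spec {sites_spec})"
    )


def gen_utrs(
    n: int,
    length_range: tuple[int, int],
    mirna: MatureMiRNA,
    sites_spec: dict[str, int],
    seed: int,
) -> tuple[list[UtrRecord], pd.DataFrame]:
    """Generate ``n`` UTRs each carrying exactly the requested planted sites.

    ``sites_spec`` maps site type -> copies per UTR (may be empty for
    site-free sequence).  Flanks are rejection-sampled to contain no
    unintended canonical site for the focal miRNA.  Returns the records
    plus a truth table with one row per planted site (1-based inclusive
    coordinates) and the master seed.
    """
    ss = np.random.SeedSequence(seed)
    utrs, rows = [], []
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        tid = f"utr{i:05d}"
        seq, planted = _plant_one_utr(rng, length, mirna, sites_spec)
        utrs.append(UtrRecord(tid, seq))
        for t, s, e in planted:
            rows.append(
                {"transcript_id": tid, "site_type": t, "start": s, "end": e,
                 "length": length, "seed": seed}
            )
        if not planted:
            rows.append(
                {"transcript_id": tid, "site_type": "none", "start": 0, "end": 0,
                 "length": length, "seed": seed}
            )
    return utrs, pd.DataFrame(rows)


def gen_coverage(
    utr_models: list[UtrRecord],
    pdui_truth: dict[str, float],
    depth: float,
    n_samples: int,
    seed: int,
    noise: str = "poisson",
    groups: tuple[str, str] = ("axon", "soma"),
) -> tuple[list[CoverageProfile], pd.DataFrame]:
    """Two-isoform coverage mixtures around each UTR's APA breakpoint.

    Expected depth at base i is ``depth * (pdui + (1 - pdui) *
    1[i <= breakpoint])``: the common region carries both isoforms, the
    extended region only the long one.  ``pdui_truth`` maps group label ->
    true PDUI (same truth for every transcript); ``n_samples`` replicates
    per group; ``noise`` is "poisson" or "none".
    """
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    for g, p in pdui_truth.items():
        if not 0 <= p <= 1:
            raise ValueError(f"pdui for {g!r} must be in [0,1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(len(utr_models) * len(groups) * n_samples))
    profiles, rows = [], []
    for utr in utr_models:
        if utr.breakpoint is None:
            raise ValueError(f"UTR {utr.transcript_id!r} has no breakpoint")
        L, bp = len(utr), utr.breakpoint
        base = np.arange(1, L + 1)
        for g in groups:
            pdui = pdui_truth[g]
            expected = depth * (pdui + (1 - pdui) * (base <= bp))
            for r in range(n_samples):
                rng = np.random.default_rng(next(streams))
                d = rng.poisson(expected).astype(float) if noise == "poisson" else expected.copy()
                sid = f"{g}{r + 1}"
                profiles.append(CoverageProfile(utr.transcript_id, sid, g, d))
        rows.append(
            {"transcript_id": utr.transcript_id, "breakpoint": bp, "length": L,
             **{f"pdui_{g}": pdui_truth[g] for g in groups}, "seed": seed}
        )
    return profiles, pd.DataFrame(rows)


def gen_decay_matrix(
    annotations: dict[str, TargetAnnotation],
    base_level: float,
    lambda_class: dict[str, float],
    lambda_site: float,
    seed: int,
    times: tuple[float, ...] = (0.0, 2.0, 4.0),
    dispersion: float = 0.05,
    n_reps: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression matrix for a miRNA-overexpression decay time course.

    The miRNA-condition mean of a gene follows first-order decay,
    ``base_level * exp(-lambda_gene * t)`` with
    ``lambda_gene = lambda_class[seed_class] + (n_sites - 1) * lambda_site``
    (per hour); the control condition stays at ``base_level``.  Counts are
    negative-binomial with the given dispersion alpha (variance
    ``mu + alpha * mu**2``); ``dispersion=0`` falls back to Poisson.
    Returns (matrix genes x samples, sample metadata, per-gene truth).
    """
    genes = list(annotations)
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    samples, meta_rows = [], []
    for cond in ("mir", "control"):
        for t in times:
            for r in range(1, n_reps + 1):
                sid = f"{cond}_t{t:g}_r{r}"
                samples.append(sid)
                meta_rows.append({"sample": sid, "condition": cond, "time": t, "replicate": r})
    lam = np.array(
        [
            (
                lambda_class[annotations[g].seed_class]
                + max(annotations[g].n_sites - 1, 0) * lambda_site
            )
            if annotations[g].seed_class != "none"
            else 0.0
            for g in genes
        ]
    )
    data = np.empty((len(genes), len(samples)))
    for j, m in enumerate(meta_rows):
        mu = base_level * np.exp(-lam * m["time"]) if m["condition"] == "mir" else np.full(len(genes), base_level)
        if dispersion > 0:
            size = 1.0 / dispersion
            data[:, j] = rng.negative_binomial(size, size / (size + mu))
        else:
            data[:, j] = rng.poisson(mu)
    matrix = pd.DataFrame(data, index=genes, columns=samples)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = pd.DataFrame(
        {
            "gene": genes,
            "seed_class": [annotations[g].seed_class for g in genes],
            "n_sites": [annotations[g].n_sites for g in genes],
            "lambda": lam,
            "seed": seed,
        }
    )
    return matrix, meta, truth


def gen_frap_traces(
    condition_slopes: dict[str, float],
    n_cells: int,
    seed: int,
    n_frames: int = 21,
    dt: float = 30.0,
    pre_bleach: float = 1000.0,
    floor_frac: float = 0.2,
    noise_sd: float = 0.5,
) -> tuple[list[FrapTrace], pd.DataFrame]:
    """FRAP traces: a post-bleach floor plus noisy linear build-up.

    ``condition_slopes`` maps condition -> true build-up slope in percent
    of pre-bleach per frame; ``noise_sd`` is the per-frame Gaussian noise,
    also in percent of pre-bleach.  Intensities are
    ``floor + slope * frame + noise`` (converted to camera units via
    ``pre_bleach``), with a floor at ``floor_frac`` of pre-bleach emulating
    incomplete bleaching.
    """
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(len(condition_slopes) * n_cells))
    frames = np.arange(n_frames)
    times = frames * dt
    traces, rows = [], []
    for cond, slope_pct in condition_slopes.items():
        for c in range(n_cells):
            rng = np.random.default_rng(next(streams))
            noise = rng.normal(0.0, noise_sd / 100.0 * pre_bleach, size=n_frames) if noise_sd > 0 else 0.0
            f = floor_frac * pre_bleach + slope_pct / 100.0 * pre_bleach * frames + noise
            f = np.clip(f, 0.0, None)
            cid = f"{cond}_cell{c + 1:03d}"
            traces.append(FrapTrace(cid, cond, times, f, pre_bleach))
            rows.append(
                {"cell_id": cid, "condition": cond, "slope_pct_per_frame": slope_pct,
                 "noise_sd": noise_sd, "seed": seed}
            )
    return traces, pd.DataFrame(rows)
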