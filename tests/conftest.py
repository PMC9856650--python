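"""Shared fixtures: reference miRNAs, reporter constructs, and an
exhaustive-window oracle scanner kept deliberately independent of the
production scanner's anchor-based algorithm."""

from __future__ import annotations

import numpy as np
import pytest

from mirutr.seedscan import (
    MatureMiRNA,
    SeedSite,
    UtrRecord,
    full_complement_site,
    site_patterns,
)

# Mature miRNA sequences as published for the reporter experiments.
MIR1_SEQ = "UGGAAUGUAAAGAAGUAUGUAU"
MIR206_SEQ = "UGGAAUGUAAGGAAGUGUGUGG"
MIR124_SEQ = "UAAGGCACGCGGUGAAUGCCAA"
MIR129_SEQ = "CUUUUGCGGUCUGGGCUUGC"

# Reporter 3'UTR constructs carrying exactly one site each, with the
# expected classification and 1-based coordinates.
CONSTRUCTS = {
    "miR-1-3p WT": ("TTACATACTTCTTTACATTCCA", "full", 1, 22),
    "miR-1-3p 8mer": ("CATCATTATAACGGACATTCCA", "8mer", 15, 22),
    "miR-1-3p 7mer-8m": ("CATCATTATAACGGACATTCCT", "7mer-m8", 15, 21),
    "miR-1-3p 7mer-1A": ("CATCATTATAACGGGCATTCCA", "7mer-A1", 16, 22),
    "miR-1-3p 6mer": ("CATCATTATAACGGGCATTCCT", "6mer", 16, 21),
    "miR-206 WT": ("CCACACACTTCCTTACATTCCA", "full", 1, 22),
    "miR-206 8mer": ("AATACTTAGAAAGGACATTCCA", "8mer", 15, 22),
}


@pytest.fixture(scope="session")
def mir1() -> MatureMiRNA:
    return MatureMiRNA("miR-1-3p", MIR1_SEQ)


@pytest.fixture(scope="session")
def mir206() -> MatureMiRNA:
    return MatureMiRNA("miR-206", MIR206_SEQ)


@pytest.fixture(scope="session")
def mir124() -> MatureMiRNA:
    return MatureMiRNA("miR-124-3p", MIR124_SEQ)


@pytest.fixture(scope="session")
def mir129() -> MatureMiRNA:
    return MatureMiRNA("miR-129-5p", MIR129_SEQ)


def oracle_scan(utr: UtrRecord, mirna: MatureMiRNA) -> list[SeedSite]:
    """Brute-force scanner: test every window of lengths 6-8 (and the
    miRNA length, for near-perfect complements) against the canonical
    patterns, then keep one site per seed anchor by priority.

    Anchoring: the position of the seed-core match inside each pattern
    (offset 1 for 8mer/7mer-m8 windows, 0 for 7mer-A1/6mer) identifies
    which physical seed match a window corresponds to.
    """
    seq = utr.sequence
    pats = site_patterns(mirna)
    full = full_complement_site(mirna)
    n = len(mirna.sequence)
    candidates: dict[int, list[tuple[str, int, int]]] = {}

    def add(anchor: int, site_type: str, start0: int, span: int) -> None:
        candidates.setdefault(anchor, []).append((site_type, start0, span))

    for i in range(len(seq)):
        w6, w7, w8 = seq[i : i + 6], seq[i : i + 7], seq[i : i + 8]
        wn = seq[i : i + n]
        if len(wn) == n:
            tail_ok = wn[n - 8 :] == pats["8mer"]
            mism = sum(a != b for a, b in zip(wn[: n - 8], full[: n - 8]))
            if tail_ok and mism <= 1:
                add(i + n - 7, "full", i, n)
        if len(w8) == 8 and w8 == pats["8mer"]:
            add(i + 1, "8mer", i, 8)
        if len(w7) == 7:
            if w7 == pats["7mer-m8"]:
                add(i + 1, "7mer-m8", i, 7)
            if w7 == pats["7mer-A1"]:
                add(i, "7mer-A1", i, 7)
        if len(w6) == 6 and w6 == pats["6mer"]:
            add(i, "6mer", i, 6)

    priority = {"full": 0, "8mer": 1, "7mer-m8": 2, "7mer-A1": 3, "6mer": 4}
    sites = []
    for anchor in sorted(candidates):
        site_type, start0, span = min(candidates[anchor], key=lambda c: priority[c[0]])
        sites.append(SeedSite(mirna.name, site_type, start0 + 1, start0 + span))
    return sorted(sites, key=lambda s: (s.start, s.end))


def random_utr(rng: np.random.Generator, length: int, tid: str = "u") -> UtrRecord:
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return UtrRecord(tid, seq)
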