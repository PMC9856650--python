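"""Canonical miRNA seed-site detection in 3'UTR sequences.

A mature miRNA represses a transcript mainly through short "canonical"
matches between the miRNA seed (positions 2-7 from the 5' end) and the
3'UTR of the target, read on the mRNA sense strand.  Four canonical site
types are recognised, in decreasing repressive strength:

=========  ==============================================================
8mer       perfect Watson-Crick match to miRNA positions 2-8, plus an
           adenosine in the target opposite miRNA position 1 (t1A)
7mer-m8    perfect match to positions 2-8, no t1A
7mer-A1    perfect match to positions 2-7, plus t1A
6mer       perfect match to positions 2-7 only
=========  ==============================================================

The t1 adenosine is a property of the *target* and is required regardless
of the identity of miRNA position 1 (it is bound by Argonaute, not by base
pairing).  A fifth, artificial type ``full`` covers reporter constructs
carrying near-perfect complementarity to the entire mature sequence.

All coordinates in this module are 1-based inclusive on the UTR sense
strand; BED conversion lives in :mod:`mirutr.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

__all__ = [
    "MatureMiRNA",
    "SeedSite",
    "UtrRecord",
    "VariantRecord",
    "SITE_TYPES",
    "SITE_PRIORITY",
    "normalize_sequence",
    "reverse_complement",
    "site_patterns",
    "full_complement_site",
    "scan_utr",
    "count_sites_by_region",
    "multiplicity_class",
    "filter_variants_overlapping_sites",
]

#: Site types ordered from most to least specific; scanning reports the
#: first type in this order that matches at a given seed anchor.
SITE_PRIORITY: tuple[str, ...] = ("full", "8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_TYPES = SITE_PRIORITY

#: Span in target bases of each site type (``full`` spans the miRNA length).
SITE_SPAN: Mapping[str, int] = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_IUPAC = set("ACGTURYSWKMBDHVN")
#: Maximum mismatches tolerated in the miRNA 3'-pairing region (positions
#: 9..N) when upgrading an 8mer to a ``full`` site.  Reporter constructs in
#: the literature frequently mismatch the miRNA's 3'-terminal base.
FULL_SITE_MAX_MISMATCH = 1


def normalize_sequence(raw: str) -> str:
    """Uppercase a nucleotide string and map RNA U to DNA T.

    Accepts any IUPAC nucleotide letters, case-insensitive.  Raises
    ``ValueError`` naming the first offending position otherwise.
    """
    seq = raw.strip().upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in _IUPAC:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {i + 1} of sequence"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (ambiguity codes pass through N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA, the query of every scan.

    ``sequence`` is stored 5'->3' in the DNA alphabet (U mapped to T) so
    that target patterns come straight out of :func:`reverse_complement`.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.name!r} is {len(self.sequence)} nt; "
                "at least 8 nt (positions 1-8) are required"
            )

    @property
    def seed_core(self) -> str:
        """miRNA positions 2-7 (the seed)."""
        return self.sequence[1:7]


@dataclass(frozen=True)
class SeedSite:
    """One classified miRNA binding site on a 3'UTR (1-based inclusive)."""

    mirna_name: str
    site_type: str
    start: int
    end: int
    region: str = "unassigned"

    def __post_init__(self) -> None:
        if self.site_type not in SITE_PRIORITY:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad site span {self.start}-{self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class UtrRecord:
    """A transcript's 3'UTR sequence with an optional proximal APA breakpoint.

    ``breakpoint`` is the 1-based position of the last base of the short
    (common) isoform; bases 1..breakpoint are shared by both isoforms and
    bases breakpoint+1..L exist only on the long, distal isoform.
    """

    transcript_id: str
    sequence: str
    breakpoint: int | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)
        if self.breakpoint is not None and not 1 <= self.breakpoint <= len(self.sequence):
            raise ValueError(
                f"breakpoint {self.breakpoint} outside UTR "
                f"{self.transcript_id!r} of length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """A short variant on UTR coordinates (1-based ``position``)."""

    transcript_id: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref:
            raise ValueError("variant ref allele must be non-empty")
        if self.position < 1:
            raise ValueError("variant position must be >= 1")

    @property
    def is_length_modifying(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive span covered by the reference allele."""
        return self.position, self.position + len(self.ref) - 1


def site_patterns(mirna: MatureMiRNA) -> dict[str, str]:
    """Target-strand DNA patterns (5'->3') for the four canonical site types.

    The 6mer pattern is the reverse complement of seed positions 2-7; the
    7mer-m8 extends the match to position 8; the A1 variants append the t1
    adenosine (a literal target "A" 3' of the seed match).
    """
    core = reverse_complement(mirna.seed_core)        # revcomp of p2-p7
    ext = reverse_complement(mirna.sequence[1:8])     # revcomp of p2-p8
    return {
        "8mer": ext + "A",
        "7mer-m8": ext,
        "7mer-A1": core + "A",
        "6mer": core,
    }


def full_complement_site(mirna: MatureMiRNA) -> str:
    """Perfect reverse complement of the whole mature sequence (DNA)."""
    return reverse_complement(mirna.sequence)


def _classify_anchor(seq: str, c: int, mirna: MatureMiRNA) -> SeedSite | None:
    """Classify the seed-core occurrence starting at 0-based offset ``c``.

    The anchor is a match of the reverse-complemented seed core (p2-7).
    The base 5' of the core decides the m8 match, the base 3' of it the
    t1A; an 8mer with sufficient upstream pairing becomes ``full``.
    """
    m8_target = reverse_complement(mirna.sequence[7])  # complement of p8
    has_m8 = c >= 1 and seq[c - 1] == m8_target
    has_a1 = c + 6 < len(seq) and seq[c + 6] == "A"
    if has_m8 and has_a1:
        # candidate full site: pair p9..N against the bases upstream
        n = len(mirna.sequence)
        full_start = c - 1 - (n - 8)  # 0-based
        if full_start >= 0:
            upstream = seq[full_start : c - 1]
            expect = reverse_complement(mirna.sequence[8:])
            mism = sum(a != b for a, b in zip(upstream, expect))
            if mism <= FULL_SITE_MAX_MISMATCH:
                return SeedSite(mirna.name, "full", full_start + 1, c + 7)
        return SeedSite(mirna.name, "8mer", c, c + 7)
    if has_m8:
        return SeedSite(mirna.name, "7mer-m8", c, c + 6)
    if has_a1:
        return SeedSite(mirna.name, "7mer-A1", c + 1, c + 7)
    return SeedSite(mirna.name, "6mer", c + 1, c + 6)


def scan_utr(utr: UtrRecord, mirna: MatureMiRNA) -> list[SeedSite]:
    """Find and classify every canonical site of ``mirna`` in ``utr``.

    Each occurrence of the reverse-complemented seed core anchors exactly
    one reported site, classified by the most specific matching type
    (full > 8mer > 7mer-m8 > 7mer-A1 > 6mer).  Sites from distinct anchors
    may overlap.  Ambiguity codes never match.  Returns sites sorted by
    start, with ``region`` assigned from the UTR breakpoint when present.
    """
    seq = utr.sequence
    core = reverse_complement(mirna.seed_core)
    sites: list[SeedSite] = []
    c = seq.find(core)
    while c != -1:
        sites.append(_classify_anchor(seq, c, mirna))
        c = seq.find(core, c + 1)
    if utr.breakpoint is not None:
        sites = [
            replace(s, region="extended" if s.start > utr.breakpoint else "common")
            for s in sites
        ]
    return sorted(sites, key=lambda s: (s.start, s.end))


def count_sites_by_region(utr: UtrRecord, sites: Iterable[SeedSite]) -> dict[str, int]:
    """Count sites on the common (short) vs extended (long-only) UTR region.

    A site belongs to the extended region iff its start lies 3' of the
    breakpoint.  Without a breakpoint every site counts as common.
    """
    bp = utr.breakpoint if utr.breakpoint is not None else len(utr)
    counts = {"common": 0, "extended": 0, "total": 0}
    for s in sites:
        if not 1 <= s.start <= s.end <= len(utr):
            raise ValueError(
                f"site {s.start}-{s.end} outside UTR {utr.transcript_id!r} "
                f"of length {len(utr)}"
            )
        counts["extended" if s.start > bp else "common"] += 1
        counts["total"] += 1
    return counts


def multiplicity_class(total_sites: int) -> str:
    """Bin a site count into the multiplicity classes 0 / 1 / 2 / >2."""
    if total_sites < 0:
        raise ValueError("site count must be non-negative")
    return str(total_sites) if total_sites <= 2 else ">2"


def filter_variants_overlapping_sites(
    variants: Iterable[VariantRecord], sites: Iterable[SeedSite]
) -> list[VariantRecord]:
    """Keep length-modifying variants whose reference span hits any site.

    This mirrors the downstream-filter step of a somatic-variant analysis:
    only insertions/deletions that could reshape a miRNA binding site are
    of interest; SNVs and off-site indels are dropped.
    """
    spans = [(s.start, s.end) for s in sites]
    kept = []
    for v in variants:
        if not v.is_length_modifying:
            continue
        v0, v1 = v.ref_span
        if any(v0 <= e and s <= v1 for s, e in spans):
            kept.append(v)
    return kept
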