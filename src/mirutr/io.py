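"""Readers and writers for the pipeline's on-disk formats.

Conventions enforced at this boundary and nowhere else:

* user-facing TSVs carry 1-based inclusive coordinates;
* BED6 and bedGraph are 0-based half-open, converted exactly at read/write;
* FASTA is read wrap-agnostic and case-insensitive via Biopython.

Malformed lines raise ``ValueError`` naming the file, line number and the
rule violated.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .apa import CoverageProfile
from .frap import FrapTrace
from .seedscan import SITE_PRIORITY, MatureMiRNA, SeedSite, UtrRecord, normalize_sequence

__all__ = [
    "BedInterval",
    "read_mirna_fasta",
    "read_utr_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "coverage_from_bedgraph",
    "read_table",
    "write_table",
    "sites_to_frame",
    "sites_to_bed",
    "read_frap_csv",
    "write_frap_csv",
    "bed_to_one_based",
    "one_based_to_bed",
]


@dataclass(frozen=True)
class BedInterval:
    """One BED6 record (0-based half-open, like the file)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."


def bed_to_one_based(start: int, end: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive (e.g. 636,643 -> 637,643)."""
    return start + 1, end


def one_based_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> BED 0-based half-open (inverse of the above)."""
    return start - 1, end


# ---------------------------------------------------------------- FASTA

def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Mature miRNAs from FASTA; U/T and case are normalized."""
    return [MatureMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_utr_fasta(path: str | Path) -> list[UtrRecord]:
    """3'UTR sequences from FASTA (sense strand, 5'->3')."""
    return [UtrRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write MatureMiRNA or UtrRecord objects as unwrapped FASTA."""
    seqrecs = []
    for r in records:
        name = getattr(r, "name", None) or getattr(r, "transcript_id")
        seqrecs.append(SeqRecord(Seq(r.sequence), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seqrecs)


# ------------------------------------------------------------------ BED

def read_bed(path: str | Path) -> list[BedInterval]:
    """BED6 (or BED3/4/5) intervals; coordinates stay 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 tab-separated fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end < start:
                raise ValueError(
                    f"{path}:{lineno}: require 0 <= start <= end (got {start}, {end})"
                )
            out.append(
                BedInterval(
                    chrom=f[0],
                    start=start,
                    end=end,
                    name=f[3] if len(f) > 3 else ".",
                    score=float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                    strand=f[5] if len(f) > 5 else ".",
                )
            )
    return out


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


# ------------------------------------------------------------- bedGraph

def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    """bedGraph intervals (chrom, 0-based start, half-open end, value)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) != 4:
                raise ValueError(f"{path}:{lineno}: bedGraph needs exactly 4 fields")
            try:
                start, end, value = int(f[1]), int(f[2]), float(f[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinate or value") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: require 0 <= start < end")
            out.append((f[0], start, end, value))
    return out


def write_bedgraph(
    depth_by_transcript: dict[str, np.ndarray], path: str | Path
) -> None:
    """Write per-base depth vectors as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for tid, depth in depth_by_transcript.items():
            depth = np.asarray(depth, dtype=float)
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [depth.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{tid}\t{s}\t{e}\t{depth[s]:g}\n")


def coverage_from_bedgraph(
    path: str | Path,
    utr_lengths: dict[str, int],
    sample_id: str,
    group: str,
) -> list[CoverageProfile]:
    """Expand one sample's bedGraph into per-UTR depth vectors.

    Bases not covered by any interval default to 0; intervals beyond the
    annotated UTR length are rejected.
    """
    vectors = {tid: np.zeros(n) for tid, n in utr_lengths.items()}
    for chrom, start, end, value in read_bedgraph(path):
        if chrom not in vectors:
            continue
        if end > utr_lengths[chrom]:
            raise ValueError(
                f"{path}: interval {start}-{end} exceeds UTR {chrom!r} "
                f"length {utr_lengths[chrom]}"
            )
        vectors[chrom][start:end] = value
    return [
        CoverageProfile(tid, sample_id, group, depth)
        for tid, depth in vectors.items()
    ]


# --------------------------------------------------------------- tables

def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """TSV with header row."""
    return pd.read_csv(path, sep="\t", **kwargs)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def sites_to_frame(sites_by_utr: dict[str, list[SeedSite]]) -> pd.DataFrame:
    """Flat site table with 1-based inclusive coordinates."""
    rows = [
        {
            "transcript_id": tid,
            "mirna": s.mirna_name,
            "site_type": s.site_type,
            "start": s.start,
            "end": s.end,
            "region": s.region,
        }
        for tid, sites in sites_by_utr.items()
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["transcript_id", "mirna", "site_type", "start", "end", "region"]
    )


def sites_to_bed(sites_by_utr: dict[str, list[SeedSite]]) -> list[BedInterval]:
    """Sites as BED6; score = site-type rank (full=5 .. 6mer=1)."""
    out = []
    for tid, sites in sites_by_utr.items():
        for s in sites:
            b0, b1 = one_based_to_bed(s.start, s.end)
            rank = len(SITE_PRIORITY) - SITE_PRIORITY.index(s.site_type)
            out.append(BedInterval(tid, b0, b1, f"{s.mirna_name}|{s.site_type}", rank, "+"))
    return out


# ------------------------------------------------------------- FRAP CSV

def read_frap_csv(path: str | Path) -> list[FrapTrace]:
    """FRAP traces from wide CSV: cell_id, condition, pre_bleach, t0, t1, ...

    Frame columns are named ``t<seconds>`` (e.g. t0, t30, t60).
    """
    traces = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"cell_id", "condition", "pre_bleach"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: header must contain {sorted(required)}")
        tcols = [c for c in reader.fieldnames if c.startswith("t") and c[1:].isdigit()]
        if not tcols:
            raise ValueError(f"{path}: no frame columns (t0, t30, ...) found")
        tcols.sort(key=lambda c: int(c[1:]))
        times = np.array([float(c[1:]) for c in tcols])
        for lineno, row in enumerate(reader, 2):
            try:
                intensities = np.array([float(row[c]) for c in tcols])
                pre = float(row["pre_bleach"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric intensity") from exc
            traces.append(
                FrapTrace(row["cell_id"], row["condition"], times, intensities, pre)
            )
    return traces


def write_frap_csv(traces: list[FrapTrace], path: str | Path) -> None:
    if not traces:
        raise ValueError("no traces to write")
    times = traces[0].times
    cols = [f"t{int(t)}" for t in times]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["cell_id", "condition", "pre_bleach", *cols])
        for tr in traces:
            if not np.array_equal(tr.times, times):
                raise ValueError("all traces must share one time grid")
            writer.writerow(
                [tr.cell_id, tr.condition, f"{tr.pre_bleach:g}"]
                + [f"{v:.6g}" for v in tr.intensities]
            )
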