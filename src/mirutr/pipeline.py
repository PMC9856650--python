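"""End-to-end orchestration: scan -> apa -> region counts -> enrich / frap / decay.

A run is driven by a nested key-value config (usually YAML).  Stage
outputs are plain TSVs in the output directory, plus ``manifest.json``
recording package version, seed, parameters and SHA-256 checksums of
every input file, so that a rerun with the same config and seed produces
an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, apa, enrichment, frap, io, kinetics, seedscan

__all__ = ["load_config", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("scan", "apa", "enrich", "frap", "decay")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_config(cfg: dict) -> list[str]:
    """Check stage wiring and input existence before any computation.

    Returns the ordered list of requested stages; raises on a missing
    input file or an unsatisfied inter-stage dependency.
    """
    stages = [s for s in STAGES if s in cfg]
    if not stages:
        raise ValueError("config requests no stages")
    required_files = {
        "scan": ("mirnas", "utrs"),
        "apa": ("utrs",),
        "enrich": ("utrs", "mirnas", "panel_a", "panel_b"),
        "frap": ("traces",),
        "decay": ("matrix", "meta"),
    }
    for stage in stages:
        sect = cfg[stage] or {}
        for key in required_files[stage]:
            if key not in sect:
                raise ValueError(f"stage {stage!r} missing required input {key!r}")
            if not Path(sect[key]).exists():
                raise FileNotFoundError(f"stage {stage!r}: input not found: {sect[key]}")
        if stage == "apa":
            for cov in sect.get("coverage", []):
                if not Path(cov["file"]).exists():
                    raise FileNotFoundError(f"coverage file not found: {cov['file']}")
            if not sect.get("coverage"):
                raise ValueError("stage 'apa' needs at least one coverage entry")
    if "decay" in stages and "sites" not in (cfg["decay"] or {}) and "scan" not in stages:
        raise ValueError("stage 'decay' needs a 'sites' table or an upstream 'scan' stage")
    return stages


def _input_files(cfg: dict, stages: list[str]) -> list[str]:
    files = []
    for stage in stages:
        sect = cfg[stage] or {}
        for v in sect.values():
            if isinstance(v, str) and Path(v).exists():
                files.append(v)
            elif isinstance(v, list):
                for item in v:
                    if isinstance(item, dict) and Path(item.get("file", "")).exists():
                        files.append(item["file"])
    return sorted(set(files))


def run_pipeline(cfg: dict, out_dir: str | Path) -> dict:
    """Execute the configured stages and write outputs plus a manifest."""
    stages = validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "package": "mirutr",
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "parameters": {s: {k: v for k, v in (cfg[s] or {}).items()} for s in stages},
        "inputs": {f: _sha256(f) for f in _input_files(cfg, stages)},
        "outputs": [],
    }
    sites_frame: pd.DataFrame | None = None
    apa_calls: list[apa.ApaCall] = []

    if "scan" in stages:
        sect = cfg["scan"]
        mirnas = io.read_mirna_fasta(sect["mirnas"])
        utrs = io.read_utr_fasta(sect["utrs"])
        if "breakpoints" in sect:
            bps = {iv.chrom: iv for iv in io.read_bed(sect["breakpoints"])}
            for u in utrs:
                if u.transcript_id in bps:
                    u.breakpoint = bps[u.transcript_id].end
        frames = []
        for mirna in mirnas:
            by_utr = {u.transcript_id: seedscan.scan_utr(u, mirna) for u in utrs}
            frames.append(io.sites_to_frame(by_utr))
        sites_frame = pd.concat(frames, ignore_index=True)
        io.write_table(sites_frame, out / "sites.tsv")
        manifest["outputs"].append("sites.tsv")

    if "apa" in stages:
        sect = cfg["apa"]
        utr_iv = io.read_bed(sect["utrs"])
        lengths = {iv.chrom: iv.end - iv.start for iv in utr_iv}
        by_transcript: dict[str, list[apa.CoverageProfile]] = {}
        group_labels = []
        for cov in sect["coverage"]:
            for prof in io.coverage_from_bedgraph(
                cov["file"], lengths, cov["sample"], cov["group"]
            ):
                by_transcript.setdefault(prof.transcript_id, []).append(prof)
            group_labels.append(cov["group"])
        groups = list(dict.fromkeys(group_labels))
        if len(groups) != 2:
            raise ValueError(f"apa stage needs exactly two groups, got {groups}")
        calls = []
        for profiles in by_transcript.values():
            call = apa.fit_transcript(
                profiles, min_segment=int(sect.get("min_segment", apa.DEFAULT_MIN_SEGMENT))
            )
            if call is not None:
                calls.append(call)
        apa_calls = apa.call_apa_events(
            calls,
            group_a=groups[0],
            group_b=groups[1],
            alpha=float(sect.get("alpha", 0.05)),
            min_abs_delta=float(sect.get("min_delta", 0.2)),
        )
        rows = []
        for c in apa_calls:
            row = {
                "transcript_id": c.transcript_id,
                "breakpoint": c.breakpoint,
                "delta_pdui": c.delta_pdui,
                "p_value": c.p_value,
                "fdr": c.fdr,
                "status": c.status,
            }
            row.update({f"pdui_{s}": v for s, v in c.pdui_per_sample.items()})
            rows.append(row)
        io.write_table(pd.DataFrame(rows), out / "apa_calls.tsv")
        manifest["outputs"].append("apa_calls.tsv")

    if sites_frame is not None and apa_calls:
        # region counts: sites on the common vs the axon-specific extended UTR
        bp = {c.transcript_id: c.breakpoint for c in apa_calls}
        rows = []
        for (tid, mirna), grp in sites_frame.groupby(["transcript_id", "mirna"]):
            if tid not in bp:
                continue
            common = int((grp["start"] <= bp[tid]).sum())
            rows.append(
                {
                    "transcript_id": tid,
                    "mirna": mirna,
                    "breakpoint": bp[tid],
                    "common": common,
                    "extended": len(grp) - common,
                    "total": len(grp),
                    "multiplicity": seedscan.multiplicity_class(len(grp)),
                }
            )
        io.write_table(pd.DataFrame(rows), out / "region_counts.tsv")
        manifest["outputs"].append("region_counts.tsv")

    if "enrich" in stages:
        sect = cfg["enrich"]
        mirnas = {m.name: m for m in io.read_mirna_fasta(sect["mirnas"])}
        utrs = io.read_utr_fasta(sect["utrs"])

        def panel(path: str) -> list:
            names = [l.strip() for l in open(path) if l.strip()]
            missing = [n for n in names if n not in mirnas]
            if missing:
                raise ValueError(f"{path}: panel miRNAs absent from FASTA: {missing}")
            return [mirnas[n] for n in names]

        spec_a = enrichment.multiplicity_spectrum(utrs, panel(sect["panel_a"]))
        spec_b = enrichment.multiplicity_spectrum(utrs, panel(sect["panel_b"]))
        cmp = enrichment.compare_panels(spec_a, spec_b)
        spec_a["panel"], spec_b["panel"] = "A", "B"
        io.write_table(pd.concat([spec_a, spec_b]), out / "enrichment_spectra.tsv")
        io.write_table(
            pd.DataFrame(
                [{"statistic": cmp["statistic"], "df": cmp["df"], "p_value": cmp["p_value"]}]
            ),
            out / "enrichment_test.tsv",
        )
        manifest["outputs"] += ["enrichment_spectra.tsv", "enrichment_test.tsv"]

    if "frap" in stages:
        sect = cfg["frap"]
        traces = io.read_frap_csv(sect["traces"])
        window = tuple(sect.get("window", frap.DEFAULT_SLOPE_WINDOW))
        summaries = [frap.summarize_trace(t, window) for t in traces]
        control = sect.get("control")
        rows = []
        level = None
        if control is not None:
            ctl = [s.buildup for s in summaries if s.condition == control]
            if ctl:
                level = frap.kr50(ctl)
        for s in summaries:
            row = {
                "cell_id": s.cell_id,
                "condition": s.condition,
                "slope_pct_per_frame": s.slope_per_frame,
                "slope_pct_per_second": s.slope_per_second,
            }
            if level is not None:
                t = frap.crossing_time(s.buildup, s.times, level)
                row["kr50_value"] = level
                row["kr50_time_s"] = t if t is not None else float("nan")
            rows.append(row)
        io.write_table(pd.DataFrame(rows), out / "frap_summaries.tsv")
        f_stat, p_anova, mat = frap.compare_slopes(
            summaries, adjust=sect.get("adjust", "holm")
        )
        io.write_table(
            pd.DataFrame([{"anova_F": f_stat, "anova_p": p_anova}]),
            out / "frap_anova.tsv",
        )
        io.write_table(mat, out / "frap_pairwise.tsv", index=True)
        manifest["outputs"] += ["frap_summaries.tsv", "frap_anova.tsv", "frap_pairwise.tsv"]

    if "decay" in stages:
        sect = cfg["decay"]
        matrix = io.read_table(sect["matrix"], index_col=0)
        meta = io.read_table(sect["meta"], index_col=0)
        if "sites" in sect:
            site_tab = io.read_table(sect["sites"])
        elif sites_frame is not None:
            site_tab = sites_frame
        else:  # pragma: no cover - guarded by validate_config
            raise ValueError("decay stage has no site table")
        annotations = {}
        for gene in matrix.index:
            grp = site_tab[site_tab["transcript_id"] == gene]
            if len(grp):
                best = min(
                    grp["site_type"], key=lambda t: seedscan.SITE_PRIORITY.index(t)
                )
                cls = "8mer" if best == "full" else best
                annotations[gene] = kinetics.TargetAnnotation(gene, cls, len(grp))
            else:
                annotations[gene] = kinetics.TargetAnnotation(gene, "none", 0)
        ratios = kinetics.relative_abundance(matrix, meta)
        summary, tests = kinetics.class_trend_summary(
            ratios, annotations, stratify_by=sect.get("stratify", "seed_class")
        )
        ratios.insert(0, "gene", ratios.index)
        io.write_table(ratios, out / "decay_ratios.tsv")
        io.write_table(summary, out / "decay_summary.tsv")
        io.write_table(tests, out / "decay_tests.tsv")
        manifest["outputs"] += ["decay_ratios.tsv", "decay_summary.tsv", "decay_tests.tsv"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished: %s", ", ".join(manifest["outputs"]))
    return manifest
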