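"""End-to-end orchestration: preprocess -> discovery -> DE -> targets -> degradome.

A single PipelineConfig (deserializable from YAML) names every input and
output path and carries per-stage parameter blocks.  All randomness flows
from one root seed expanded per stage, and outputs are byte-stable: running
the same config twice changes nothing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .degradome import confirm_targets, events_table, map_degradome, tplot_table
from .diffexpr import build_records, call_de
from .discovery import discover_novel, novel_to_table, summarize_novel
from .preprocess import (
    annotate_tags,
    clean_and_collapse,
    length_stats,
    map_perfect,
    merge_tag_sets,
    sirna_duplex_scan,
    tags_to_fasta,
)
from .seqtools import read_fasta

log = logging.getLogger("plantmir")

STAGES = ("preprocess", "discover", "de", "targets", "degradome")


@dataclass
class PipelineConfig:
    genome: str
    control_fastq: str
    drought_fastq: str
    transcripts: str
    gff3: str
    outdir: str
    degradome_fastq: str | None = None
    known_mature_fasta: str | None = None
    adapter: str = "UCGUAUGCCGUCUUCUGCUUG"
    seed: int = 1
    cleaning: dict = field(default_factory=dict)  # min_len, max_len, min_qual
    discovery: dict = field(default_factory=dict)  # mfe_threshold, flank_max
    de: dict = field(default_factory=dict)  # min_rpm, fold, alpha
    targets: dict = field(default_factory=dict)  # score_cutoff
    degradome: dict = field(default_factory=dict)  # score_cutoff, n_shuffles

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**yaml.safe_load(text))

    def validate(self) -> None:
        for name in ("genome", "control_fastq", "drought_fastq", "transcripts", "gff3"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        for block_name in ("cleaning", "discovery", "de", "targets", "degradome"):
            block = getattr(self, block_name)
            if not isinstance(block, dict):
                raise TypeError(f"stage block {block_name} must be a mapping")


def _digest(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; return (and write) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            name: {"path": getattr(config, name), "sha256_16": _digest(getattr(config, name))}
            for name in ("genome", "control_fastq", "drought_fastq", "transcripts", "gff3")
            if getattr(config, name)
        },
        "parameters": {
            "cleaning": config.cleaning,
            "discovery": config.discovery,
            "de": config.de,
            "targets": config.targets,
            "degradome": config.degradome,
        },
        "stages": [],
    }
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    state: dict = {}
    try:
        for stage in STAGES:
            if stage == "degradome" and not config.degradome_fastq:
                continue
            try:
                log.info("stage %s starting", stage)
                globals()[f"_stage_{stage}"](config, out, state)
                log.info("stage %s done", stage)
            except Exception:
                log.exception("stage %s failed", stage)
                manifest["failed_stage"] = stage
                (out / "manifest.json").write_text(
                    json.dumps(manifest, indent=1, sort_keys=True)
                )
                raise
            manifest["stages"].append(stage)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest["summary"] = report_summary(state)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    _write_report(manifest, out)
    return manifest


def _stage_preprocess(config: PipelineConfig, out: Path, state: dict) -> None:
    clean = dict(min_len=18, max_len=30, min_qual=20.0)
    clean.update(config.cleaning)
    control = clean_and_collapse(
        Path(config.control_fastq).read_text(), config.adapter, library="control", **clean
    )
    drought = clean_and_collapse(
        Path(config.drought_fastq).read_text(), config.adapter, library="drought", **clean
    )
    tags = merge_tag_sets(control, drought)
    genome = read_fasta(Path(config.genome).read_text())
    map_perfect(tags, genome)
    known = {}
    if config.known_mature_fasta and Path(config.known_mature_fasta).exists():
        known = read_fasta(Path(config.known_mature_fasta).read_text())
    annotate_tags(tags, Path(config.gff3).read_text(), known)
    sirna_pairs = sirna_duplex_scan(tags)
    stats = length_stats(tags)
    _write_tsv(stats, out / "length_stats.tsv")
    (out / "tags.fa").write_text(tags_to_fasta(tags))
    state.update(tags=tags, genome=genome, sirna_pairs=sirna_pairs, length_stats=stats)
    state["totals"] = (
        sum(t.count_control for t in tags),
        sum(t.count_drought for t in tags),
    )


def _stage_discover(config: PipelineConfig, out: Path, state: dict) -> None:
    params = dict(mfe_threshold=-30.0, flank_max=280)
    params.update(config.discovery)
    novel, rejections = discover_novel(state["tags"], state["genome"], **params)
    table = novel_to_table(novel)
    _write_tsv(table, out / "novel_mirnas.tsv")
    structures = []
    for m in novel:
        structures.append(f">{m.name} {m.hairpin.locus} mfe={m.hairpin.mfe}")
        structures.append(m.hairpin.precursor)
        structures.append(m.hairpin.structure)
    (out / "novel_structures.txt").write_text("\n".join(structures) + "\n")
    rej = [
        {"locus": str(r.locus), "mature": r.mature, "reason": r.reason} for r in rejections
    ]
    import pandas as pd

    _write_tsv(pd.DataFrame(rej, columns=["locus", "mature", "reason"]), out / "rejections.tsv")
    state.update(novel=novel)


def _stage_de(config: PipelineConfig, out: Path, state: dict) -> None:
    params = dict(min_rpm=1.0, fold=2.0, alpha=0.01)
    params.update(config.de)
    n1, n2 = state["totals"]
    counts = []
    for t in state["tags"]:
        if t.annotation in ("known_mirna", "candidate") and t.total > 0:
            counts.append((t.sequence, t.count_control, t.count_drought))
    records = build_records(counts, max(n1, 1), max(n2, 1))
    table = call_de(records, **params)
    _write_tsv(table, out / "differential_expression.tsv")
    state.update(de_table=table)


def _stage_targets(config: PipelineConfig, out: Path, state: dict) -> None:
    from .targets import scan_targets

    params = dict(score_cutoff=2.5)
    params.update(config.targets)
    transcripts = read_fasta(Path(config.transcripts).read_text())
    rows = []
    predictions = {}
    for m in state.get("novel", []):
        alns = scan_targets(m.mature, transcripts, mirna_name=m.name, **params)
        predictions[m.name] = alns
        for a in alns:
            rows.append(
                {
                    "mirna": a.mirna_name,
                    "transcript": a.transcript_id,
                    "site_start": a.site_start,
                    "site_end": a.site_end,
                    "penalty": a.penalty,
                    "mfe_ratio": round(a.mfe_ratio, 4),
                }
            )
    import pandas as pd

    _write_tsv(
        pd.DataFrame(
            rows,
            columns=["mirna", "transcript", "site_start", "site_end", "penalty", "mfe_ratio"],
        ),
        out / "predicted_targets.tsv",
    )
    state.update(transcripts=transcripts, predictions=predictions)


def _stage_degradome(config: PipelineConfig, out: Path, state: dict) -> None:
    params = dict(score_cutoff=4.0, n_shuffles=100)
    params.update(config.degradome)
    profiles = map_degradome(Path(config.degradome_fastq).read_text(), state["transcripts"])
    mirnas = {m.name: m.mature for m in state.get("novel", [])}
    events = confirm_targets(
        mirnas,
        state["transcripts"],
        profiles,
        score_cutoff=params["score_cutoff"],
        n_shuffles=params["n_shuffles"],
        seed=config.seed,
    )
    _write_tsv(events_table(events), out / "cleavage_events.tsv")
    tdir = out / "tplots"
    tdir.mkdir(exist_ok=True)
    for e in events:
        _write_tsv(
            tplot_table(profiles[e.transcript_id], e),
            tdir / f"{e.mirna_name}_{e.transcript_id}.tsv",
        )
    state.update(events=events, profiles=profiles)


def report_summary(state: dict) -> dict:
    """Headline counts: tags, annotations, novel miRNAs, DE calls, events."""
    tags = state.get("tags", [])
    ann = {}
    for t in tags:
        ann[t.annotation] = ann.get(t.annotation, 0) + 1
    de = state.get("de_table")
    de_calls = (
        {d: int((de["call"] == d).sum()) for d in ("up", "down")} if de is not None else {}
    )
    events = state.get("events", [])
    by_cat = {}
    for e in events:
        by_cat[e.category] = by_cat.get(e.category, 0) + 1
    summary = {
        "n_tags": len(tags),
        "annotations": dict(sorted(ann.items())),
        "n_novel": len(state.get("novel", [])),
        "de_calls": de_calls,
        "n_events": len(events),
        "events_by_category": dict(sorted(by_cat.items())),
        "n_sirna_pairs": len(state.get("sirna_pairs", [])),
    }
    novel = state.get("novel")
    if novel:
        summary["novel_summary"] = {
            k: v
            for k, v in summarize_novel(novel).items()
            if k in ("length_histogram", "n_families")
        }
    return summary


def _write_report(manifest: dict, out: Path) -> None:
    s = manifest["summary"]
    lines = [
        "plantmir run summary",
        f"  unique tags: {s['n_tags']}",
        f"  annotations: {s['annotations']}",
        f"  novel miRNAs: {s['n_novel']}",
        f"  DE calls: {s['de_calls']}",
        f"  siRNA duplex pairs: {s['n_sirna_pairs']}",
        f"  cleavage events: {s['n_events']} by category {s['events_by_category']}",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
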