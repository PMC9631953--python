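"""End-to-end orchestration: adratio -> anchor -> markers -> reconcile.

``run_all`` consumes the tabular inputs produced upstream (depth
summaries, alignments, marker hits, scaffold lengths), runs every stage
with one set of validated parameters, writes all per-stage outputs under
one directory and records a machine-readable manifest (inputs,
parameters, output checksums).  Reruns on identical inputs and
parameters are byte-identical, manifest included.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from . import adratio as _ad
from . import anchor as _anchor
from . import markers as _markers
from .reconcile import (
    reconcile as _reconcile_methods,
    consensus_assignment as _consensus_assignment,
    write_consensus_bed as _write_consensus_bed,
)

__all__ = ["RunConfig", "run_all", "render_summary"]

log = logging.getLogger("sexscaff")


@dataclass
class RunConfig:
    """Validated inputs, outputs and thresholds for a full run."""

    male_depth: str
    female_depth: str
    alignments: str
    lengths: str
    marker_hits: str
    gene_manifest: str
    outdir: str
    aln_dialect: str = "paf"
    normalization_mode: str = "median"
    thresholds: _ad.ADThresholds = field(default_factory=_ad.ADThresholds)
    dominance_min: float = 0.5
    coverage_min: float = 0.05
    evalue_max: float = 1e-10
    ambiguity_margin: float = 1.2
    bin_width: float = 0.025
    hist_range_max: float = 4.0
    log_level: str = "INFO"

    def validate(self) -> None:
        missing = [p for p in (self.male_depth, self.female_depth,
                               self.alignments, self.lengths,
                               self.marker_hits, self.gene_manifest)
                   if not Path(p).exists()]
        if missing:
            raise ConfigError(f"missing input files: {missing}")
        if not 0 < self.dominance_min <= 1:
            raise ConfigError("dominance_min must lie in (0, 1]")
        if not 0 <= self.coverage_min <= 1:
            raise ConfigError("coverage_min must lie in [0, 1]")
        if self.evalue_max <= 0:
            raise ConfigError("evalue_max must be > 0")
        if self.ambiguity_margin < 1:
            raise ConfigError("ambiguity_margin must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        thr = data.pop("thresholds", None)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if thr:
            cfg.thresholds = _ad.ADThresholds(**thr)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_dict(config: RunConfig) -> dict:
    params = asdict(config)
    params["thresholds"] = asdict(config.thresholds)
    return params


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; return the run manifest.

    Any stage failure raises :class:`StageError` tagged with the stage
    name; outputs of completed stages are left in place, the manifest is
    written only on success.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info("parameters: %s", json.dumps(_params_dict(config), default=str))

    stages: list[str] = []
    outputs: dict[str, Path] = {}

    def _stage(name):
        stages.append(name)
        log.info("stage %s", name)

    try:
        _stage("adratio")
        male = _ad.read_mosdepth_summary(config.male_depth)
        female = _ad.read_mosdepth_summary(config.female_depth)
        factor = _ad.compute_normalization(
            male, female, config.normalization_mode, config.thresholds)
        alt_mode = "total" if config.normalization_mode == "median" else "median"
        alt_factor = _ad.compute_normalization(
            male, female, alt_mode, config.thresholds)
        records = _ad.compute_ad_ratios(male, female, factor,
                                        config.thresholds)
        records = _ad.classify_scaffolds(records, config.thresholds)
        hist = _ad.ad_histogram(records, config.bin_width,
                                config.hist_range_max)
        class_summary = _ad.summarize_coverage_classes(records)
        outputs["adratio"] = outdir / "adratio.tsv"
        records.to_csv(outputs["adratio"], sep="\t", index=False)
        outputs["histogram"] = outdir / "ad_histogram.tsv"
        hist.table.to_csv(outputs["histogram"], sep="\t", index=False)
        outputs["class_summary"] = outdir / "class_summary.json"
        outputs["class_summary"].write_text(json.dumps({
            "normalization_mode": config.normalization_mode,
            "normalization_factor": factor,
            f"normalization_factor_{alt_mode}": alt_factor,
            "classes": class_summary.to_dict(orient="records"),
        }, indent=2))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"[adratio] {exc}") from exc

    try:
        _stage("anchor")
        hits = _anchor.parse_alignments(config.alignments, config.aln_dialect)
        lengths = _anchor.parse_scaffold_lengths(config.lengths)
        merged = _anchor.merged_coverage_all(hits)
        assignments = _anchor.assign_chromosomes(
            merged, lengths, config.dominance_min, config.coverage_min)
        anchor_summary, overall = _anchor.summarize_anchoring(assignments)
        outputs["anchors"] = outdir / "anchors.tsv"
        flat = assignments.copy()
        flat["per_chromosome_merged_bp"] = flat[
            "per_chromosome_merged_bp"].map(
            lambda d: ";".join(f"{k}:{v}" for k, v in d.items()))
        flat.to_csv(outputs["anchors"], sep="\t", index=False)
        outputs["anchor_summary"] = outdir / "anchor_summary.json"
        outputs["anchor_summary"].write_text(json.dumps({
            "per_chromosome": anchor_summary.to_dict(orient="records"),
            **overall,
        }, indent=2))
    except Exception as exc:
        raise StageError(f"[anchor] {exc}") from exc

    try:
        _stage("markers")
        marker_hits = _markers.read_blast6(config.marker_hits)
        manifest_df = _markers.read_gene_manifest(config.gene_manifest)
        placements = _markers.place_genes(
            marker_hits, manifest_df, config.evalue_max,
            config.ambiguity_margin)
        confirmations, confirmed_bp = _markers.confirm_y(
            placements, records, config.thresholds.y_max)
        track = _markers.gene_map_report(placements, marker_hits,
                                         confirmations)
        outputs["placements"] = outdir / "gene_placements.tsv"
        placements.to_csv(outputs["placements"], sep="\t", index=False)
        outputs["yconf"] = outdir / "y_confirmations.tsv"
        confirmations.to_csv(outputs["yconf"], sep="\t", index=False)
        outputs["gene_track"] = outdir / "gene_track.gff3"
        _markers.write_gene_track_gff3(track, outputs["gene_track"])
    except Exception as exc:
        raise StageError(f"[markers] {exc}") from exc

    try:
        _stage("reconcile")
        report = _reconcile_methods(records, assignments)
        consensus = _consensus_assignment(records, assignments,
                                          confirmations)
        outputs["reconcile"] = outdir / "reconcile.json"
        outputs["reconcile"].write_text(json.dumps({
            "agree_bp": report.agree_bp,
            "conflict_bp": report.conflict_bp,
            "one_method_unassigned_bp": report.one_method_unassigned_bp,
            "both_unassigned_bp": report.both_unassigned_bp,
            "total_bp": report.total_bp,
            "agree_frac": report.agree_frac,
            "conflict_frac": report.conflict_frac,
            "confirmed_y_bp": confirmed_bp,
        }, indent=2))
        outputs["crosstab"] = outdir / "crosstab.tsv"
        report.crosstab.to_csv(outputs["crosstab"], sep="\t")
        outputs["consensus"] = outdir / "consensus.tsv"
        consensus.to_csv(outputs["consensus"], sep="\t", index=False)
        outputs["consensus_bed"] = outdir / "consensus.bed"
        _write_consensus_bed(consensus, outputs["consensus_bed"])
    except Exception as exc:
        raise StageError(f"[reconcile] {exc}") from exc

    manifest = {
        "tool": "sexscaff",
        "version": __version__,
        "stages": stages,
        "parameters": _params_dict(config),
        "inputs": {k: getattr(config, k) for k in (
            "male_depth", "female_depth", "alignments", "lengths",
            "marker_hits", "gene_manifest")},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)}
                    for k, v in outputs.items()},
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def _section_class_summary(outdir: Path) -> str | None:
    path = outdir / "class_summary.json"
    if not path.exists():
        return None
    data = json.loads(path.read_text())
    lines = ["## Coverage classes (AD-ratio)", "",
             f"Normalization factor ({data['normalization_mode']}): "
             f"{data['normalization_factor']:.4f}", "",
             "| class | scaffolds | total bp | % of genome |",
             "|---|---|---|---|"]
    for row in data["classes"]:
        lines.append(
            f"| {row['coverage_class']} | {row['n_scaffolds']} | "
            f"{row['total_bp']} | {100 * row['fraction_of_genome']:.2f} |")
    return "\n".join(lines)


def _section_anchoring(outdir: Path) -> str | None:
    path = outdir / "anchor_summary.json"
    if not path.exists():
        return None
    data = json.loads(path.read_text())
    lines = ["## Chromosome anchoring", "",
             f"Assigned: {100 * data['assigned_fraction_length']:.2f}% of "
             f"genome length, {100 * data['assigned_fraction_scaffolds']:.2f}%"
             " of scaffolds", "",
             "| chromosome | scaffolds | total bp | % scaffolds | % length |",
             "|---|---|---|---|---|"]
    for row in data["per_chromosome"]:
        lines.append(
            f"| {row['chromosome']} | {row['n_scaffolds']} | "
            f"{row['total_bp']} | {row['pct_of_scaffolds']:.2f} | "
            f"{row['pct_of_genome_length']:.2f} |")
    return "\n".join(lines)


def _section_yconf(outdir: Path) -> str | None:
    path = outdir / "y_confirmations.tsv"
    if not path.exists():
        return None
    df = pd.read_csv(path, sep="\t")
    confirmed = df[df["confirmed"]]
    rec_path = outdir / "reconcile.json"
    total_bp = (json.loads(rec_path.read_text()).get("confirmed_y_bp")
                if rec_path.exists() else None)
    lines = ["## Confirmed Y scaffolds", "",
             f"{len(confirmed)} scaffold(s) confirmed"
             + (f", {total_bp} bp total" if total_bp is not None else ""),
             "", "| scaffold | AD-ratio | supporting genes |", "|---|---|---|"]
    for row in confirmed.itertuples(index=False):
        lines.append(f"| {row.scaffold_id} | {row.ad_ratio:.4f} | "
                     f"{row.supporting_genes} |")
    return "\n".join(lines)


def _section_agreement(outdir: Path) -> str | None:
    path = outdir / "reconcile.json"
    if not path.exists():
        return None
    data = json.loads(path.read_text())
    return "\n".join([
        "## Method agreement", "",
        f"- agree: {100 * data['agree_frac']:.2f}% of genome length",
        f"- conflict: {100 * data['conflict_frac']:.2f}%",
        f"- one method unassigned: "
        f"{100 * data['one_method_unassigned_bp'] / data['total_bp']:.2f}%",
        f"- both unassigned: "
        f"{100 * data['both_unassigned_bp'] / data['total_bp']:.2f}%",
    ])


def render_summary(outdir: str | Path) -> str:
    """Markdown run report assembled purely from the stage outputs.

    Missing stages render as flagged gaps rather than errors, so a
    partial run still produces a usable report.
    """
    outdir = Path(outdir)
    parts = ["# sexscaff run summary", ""]
    sections = [
        ("Coverage classes", _section_class_summary),
        ("Chromosome anchoring", _section_anchoring),
        ("Confirmed Y scaffolds", _section_yconf),
        ("Method agreement", _section_agreement),
    ]
    for title, fn in sections:
        body = fn(outdir)
        parts.append(body if body is not None
                     else f"## {title}\n\n_missing: stage outputs not found_")
        parts.append("")
    return "\n".join(parts)
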