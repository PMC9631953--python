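"""Y marker-gene placement and Y-scaffold confirmation.

Known Y genes (and their X/autosomal homologs) are searched against the
assembly with BLAST; this module turns the tabular hits into per-gene
scaffold placements and combines them with AD-ratio evidence to confirm
Y scaffolds.

Placement: hits above the e-value cutoff are discarded; the surviving
hits of a gene are aggregated per scaffold by summed bitscore (bitscore
rather than e-value because it is database-size independent).  The gene
is PLACED on the top scaffold only when that scaffold's score beats the
runner-up by the ambiguity margin; multi-copy genes whose partial hits
tie across scaffolds (the ATRY pattern) come out UNPLACED_AMBIGUOUS.

Confirmation: a scaffold is confirmed as Y iff at least one Y gene is
placed on it, its AD-ratio is at or below the Y band, and no supporting
gene's homolog is placed on the same scaffold (a co-placed homolog
indicates a non-Y or chimeric scaffold).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "read_blast6",
    "read_gene_manifest",
    "attach_manifest",
    "place_genes",
    "confirm_y",
    "gene_map_report",
    "write_gene_track_gff3",
]

BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore"]

PLACEMENT_STATUS = ("PLACED", "UNPLACED_AMBIGUOUS", "UNPLACED_NO_HIT")
EXCLUSION_REASONS = ("AD_TOO_HIGH", "HOMOLOG_SAME_SCAFFOLD", "NO_GENES")


def read_blast6(path: str | Path) -> pd.DataFrame:
    """Standard 12-column BLAST outfmt-6 table (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 12:
        raise InputError(f"{path}: expected 12 outfmt-6 columns, "
                         f"got {df.shape[1]}")
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    return df


def read_gene_manifest(path: str | Path) -> pd.DataFrame:
    """Gene manifest: gene, gene_class (Y_GENE/HOMOLOG), partner_gene."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "gene_class", "partner_gene"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: manifest needs columns {sorted(required)}")
    bad = set(df["gene_class"]) - {"Y_GENE", "HOMOLOG"}
    if bad:
        raise InputError(f"{path}: unknown gene_class values {sorted(bad)}")
    return df


def attach_manifest(hits: pd.DataFrame,
                    manifest: pd.DataFrame) -> pd.DataFrame:
    """Join outfmt-6 hits with the manifest into MarkerHit records."""
    merged = hits.rename(columns={"qseqid": "gene",
                                  "sseqid": "scaffold_id"}).merge(
        manifest, on="gene", how="left")
    unknown = merged[merged["gene_class"].isna()]["gene"].unique()
    if len(unknown):
        raise InputError(
            f"hits reference genes absent from manifest: {sorted(unknown)[:10]}")
    return merged


def place_genes(
    hits: pd.DataFrame,
    manifest: pd.DataFrame,
    evalue_max: float = 1e-10,
    ambiguity_margin: float = 1.2,
) -> pd.DataFrame:
    """One placement row per manifest gene.

    A gene is PLACED on the scaffold with the highest summed bitscore of
    its surviving hits when that score is at least ``ambiguity_margin``
    times the runner-up scaffold's score (runner-up 0 when only one
    scaffold has hits); otherwise UNPLACED_AMBIGUOUS.  Genes with no hit
    at or below ``evalue_max`` are UNPLACED_NO_HIT.
    """
    if ambiguity_margin < 1.0:
        raise InputError("ambiguity_margin must be >= 1")
    marker = hits if "gene" in hits.columns else attach_manifest(hits, manifest)
    surviving = marker[marker["evalue"] <= evalue_max]
    scores = (surviving.groupby(["gene", "scaffold_id"])["bitscore"]
              .sum().reset_index())
    rows = []
    for rec in manifest.itertuples(index=False):
        sub = scores[scores["gene"] == rec.gene]
        if sub.empty:
            rows.append((rec.gene, rec.gene_class, rec.partner_gene,
                         "UNPLACED_NO_HIT", None, 0.0, 0.0))
            continue
        ranked = sub.sort_values(["bitscore", "scaffold_id"],
                                 ascending=[False, True])
        best = ranked.iloc[0]
        runner_up = float(ranked.iloc[1]["bitscore"]) if len(ranked) > 1 else 0.0
        if float(best["bitscore"]) >= ambiguity_margin * runner_up:
            rows.append((rec.gene, rec.gene_class, rec.partner_gene,
                         "PLACED", best["scaffold_id"],
                         float(best["bitscore"]), runner_up))
        else:
            rows.append((rec.gene, rec.gene_class, rec.partner_gene,
                         "UNPLACED_AMBIGUOUS", None,
                         float(best["bitscore"]), runner_up))
    return pd.DataFrame(rows, columns=[
        "gene", "gene_class", "partner_gene", "status", "scaffold_id",
        "best_bitscore", "runner_up_bitscore"])


def confirm_y(
    placements: pd.DataFrame,
    ad: pd.DataFrame,
    y_max: float = 0.3,
) -> tuple[pd.DataFrame, int]:
    """Confirm Y scaffolds from gene placements plus AD-ratio evidence.

    Candidate scaffolds are those carrying a placed Y gene, plus any
    scaffold the coverage classifier already called Y (so genome-scale
    putative-Y sequence without marker support is reported as NO_GENES).
    Returns the confirmation table and the summed length of confirmed
    scaffolds.
    """
    ad_idx = ad.set_index("scaffold_id")
    placed_y = placements[(placements["gene_class"] == "Y_GENE")
                          & (placements["status"] == "PLACED")]
    missing = sorted(set(placed_y["scaffold_id"]) - set(ad_idx.index))
    if missing:
        raise InputError(
            f"placed scaffolds absent from AD-ratio table: {missing[:10]}")
    homolog_scaffold = (
        placements[(placements["gene_class"] == "HOMOLOG")
                   & (placements["status"] == "PLACED")]
        .set_index("gene")["scaffold_id"].to_dict())

    candidates = list(dict.fromkeys(placed_y["scaffold_id"]))
    if "coverage_class" in ad.columns:
        for scaffold in ad_idx.index[ad_idx["coverage_class"] == "Y"]:
            if scaffold not in candidates:
                candidates.append(scaffold)

    rows = []
    total_bp = 0
    for scaffold in candidates:
        genes_here = placed_y[placed_y["scaffold_id"] == scaffold]
        ratio = float(ad_idx.loc[scaffold, "ad_ratio"])
        supporting = [
            g.gene for g in genes_here.itertuples(index=False)
            if homolog_scaffold.get(g.partner_gene) != scaffold
        ]
        reason = None
        if genes_here.empty:
            confirmed, reason = False, "NO_GENES"
        elif not (ratio <= y_max):  # NaN fails too
            confirmed, reason = False, "AD_TOO_HIGH"
        elif not supporting:
            confirmed, reason = False, "HOMOLOG_SAME_SCAFFOLD"
        else:
            confirmed = True
            total_bp += int(ad_idx.loc[scaffold, "length"])
        rows.append((scaffold, ",".join(supporting), ratio, confirmed,
                     reason))
    table = pd.DataFrame(rows, columns=[
        "scaffold_id", "supporting_genes", "ad_ratio", "confirmed",
        "excluded_reason"])
    return table, total_bp


def gene_map_report(
    placements: pd.DataFrame,
    hits: pd.DataFrame,
    confirmations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Ordered gene track per (confirmed) scaffold.

    For each placed Y gene, the best (highest-bitscore) hit on its
    placed scaffold gives the track coordinates; genes are sorted by
    scaffold then start.  When ``confirmations`` is given, only
    confirmed scaffolds are reported.
    """
    placed = placements[(placements["status"] == "PLACED")
                        & (placements["gene_class"] == "Y_GENE")]
    if confirmations is not None:
        keep = set(confirmations.loc[confirmations["confirmed"],
                                     "scaffold_id"])
        placed = placed[placed["scaffold_id"].isin(keep)]
    marker = hits.rename(columns={"qseqid": "gene",
                                  "sseqid": "scaffold_id"})
    rows = []
    for rec in placed.itertuples(index=False):
        sub = marker[(marker["gene"] == rec.gene)
                     & (marker["scaffold_id"] == rec.scaffold_id)]
        if sub.empty:
            continue
        best = sub.loc[sub["bitscore"].idxmax()]
        start = int(min(best["sstart"], best["send"]))
        end = int(max(best["sstart"], best["send"]))
        strand = "+" if best["sstart"] <= best["send"] else "-"
        rows.append((rec.scaffold_id, rec.gene, start, end, strand,
                     float(best["bitscore"])))
    track = pd.DataFrame(rows, columns=[
        "scaffold_id", "gene", "start", "end", "strand", "bitscore"])
    return track.sort_values(["scaffold_id", "start"]).reset_index(drop=True)


def write_gene_track_gff3(track: pd.DataFrame, path: str | Path) -> None:
    """GFF3 gene track (1-based inclusive coordinates, as GFF3 requires)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in track.itertuples(index=False):
            fh.write("\t".join(map(str, [
                rec.scaffold_id, "sexscaff", "gene", rec.start, rec.end,
                f"{rec.bitscore:.1f}", rec.strand, ".",
                f"ID={rec.gene};Name={rec.gene}",
            ])) + "\n")
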