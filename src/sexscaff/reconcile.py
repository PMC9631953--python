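"""Cross-validation of coverage classes against homology anchoring.

The coverage classifier can only distinguish the AUTOSOME / X / Y
groups, so agreement with the per-chromosome homology assignment is
computed at the group level: chrX maps to X, chrY to Y, every other
chromosome to AUTOSOME.  All quantities are length-weighted — a
kilobase of disagreement on a large scaffold matters more than a whole
small scaffold.

Every scaffold falls into exactly one of four categories: both methods
assigned and agreeing, both assigned and conflicting, exactly one
method assigned, or neither assigned.  Their bp always partition the
genome; the agreement fraction uses total genome bp as its denominator
(scaffolds unassigned by both methods are their own category, not
counted as agreement).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .simulate import chromosome_group

__all__ = ["ReconcileReport", "reconcile", "consensus_assignment",
           "write_consensus_bed"]

PROVENANCE_CODES = {"BOTH": 1000, "COVERAGE_ONLY": 750,
                    "HOMOLOGY_ONLY": 500, "CONFLICT": 250, "NONE": 0}


@dataclass
class ReconcileReport:
    """Length-weighted agreement accounting between the two methods."""

    agree_bp: int
    conflict_bp: int
    one_method_unassigned_bp: int
    both_unassigned_bp: int
    total_bp: int
    agree_frac: float
    conflict_frac: float
    crosstab: pd.DataFrame = field(repr=False)  # coverage_class x group, bp

    def __post_init__(self) -> None:
        parts = (self.agree_bp + self.conflict_bp
                 + self.one_method_unassigned_bp + self.both_unassigned_bp)
        if parts != self.total_bp:
            raise InputError(
                f"category bp {parts} do not partition total {self.total_bp}")


def _merge_methods(ad: pd.DataFrame, anchors: pd.DataFrame) -> pd.DataFrame:
    ad_ids = set(ad["scaffold_id"])
    anchor_ids = set(anchors["scaffold_id"])
    if ad_ids != anchor_ids:
        offenders = sorted(ad_ids ^ anchor_ids)[:10]
        raise InputError(
            "coverage and anchoring tables cover different scaffolds; "
            f"first offenders: {offenders}")
    df = ad[["scaffold_id", "length", "coverage_class"]].merge(
        anchors[["scaffold_id", "assigned_chromosome"]], on="scaffold_id")
    df["homology_group"] = df["assigned_chromosome"].map(chromosome_group)
    return df


def reconcile(ad: pd.DataFrame, anchors: pd.DataFrame) -> ReconcileReport:
    """Length-weighted agreement between coverage classes and anchoring."""
    df = _merge_methods(ad, anchors)
    cov_assigned = df["coverage_class"] != "UNASSIGNED"
    hom_assigned = df["homology_group"] != "UNASSIGNED"
    agree = cov_assigned & hom_assigned & (
        df["coverage_class"] == df["homology_group"])
    conflict = cov_assigned & hom_assigned & (
        df["coverage_class"] != df["homology_group"])
    one_only = cov_assigned ^ hom_assigned
    neither = ~cov_assigned & ~hom_assigned

    total_bp = int(df["length"].sum())
    crosstab = (df.pivot_table(index="coverage_class",
                               columns="homology_group", values="length",
                               aggfunc="sum", fill_value=0)
                .astype("int64"))
    return ReconcileReport(
        agree_bp=int(df.loc[agree, "length"].sum()),
        conflict_bp=int(df.loc[conflict, "length"].sum()),
        one_method_unassigned_bp=int(df.loc[one_only, "length"].sum()),
        both_unassigned_bp=int(df.loc[neither, "length"].sum()),
        total_bp=total_bp,
        agree_frac=float(df.loc[agree, "length"].sum()) / total_bp,
        conflict_frac=float(df.loc[conflict, "length"].sum()) / total_bp,
        crosstab=crosstab,
    )


def consensus_assignment(
    ad: pd.DataFrame,
    anchors: pd.DataFrame,
    confirmations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-scaffold final label with provenance.

    Precedence: (1) marker-confirmed Y scaffolds are chrY regardless of
    homology (the reference's Y is typically incomplete); (2) agreeing
    scaffolds take the homology chromosome; (3) homology-only scaffolds
    take homology; (4) coverage-only scaffolds take their coverage group
    (autosome-group sequence stays "autosome_unplaced" — the coverage
    method cannot pick an autosome); (5) non-Y conflicts are left
    unassigned with provenance CONFLICT.
    """
    df = _merge_methods(ad, anchors)
    confirmed = set()
    if confirmations is not None and len(confirmations):
        confirmed = set(confirmations.loc[confirmations["confirmed"],
                                          "scaffold_id"])
    labels, provenance = [], []
    for rec in df.itertuples(index=False):
        cov, hom = rec.coverage_class, rec.homology_group
        if rec.scaffold_id in confirmed:
            labels.append("chrY")
            provenance.append("BOTH" if hom == "Y" else "COVERAGE_ONLY")
        elif cov != "UNASSIGNED" and hom != "UNASSIGNED":
            if cov == hom:
                labels.append(rec.assigned_chromosome)
                provenance.append("BOTH")
            else:
                labels.append("UNASSIGNED")
                provenance.append("CONFLICT")
        elif hom != "UNASSIGNED":
            labels.append(rec.assigned_chromosome)
            provenance.append("HOMOLOGY_ONLY")
        elif cov != "UNASSIGNED":
            labels.append({"X": "chrX", "Y": "chrY",
                           "AUTOSOME": "autosome_unplaced"}[cov])
            provenance.append("COVERAGE_ONLY")
        else:
            labels.append("UNASSIGNED")
            provenance.append("NONE")
    out = df[["scaffold_id", "length", "coverage_class",
              "assigned_chromosome"]].copy()
    out["final_label"] = labels
    out["provenance"] = provenance
    return out


def write_consensus_bed(consensus: pd.DataFrame, path) -> None:
    """BED of whole scaffolds (0-based half-open), name = final label,
    score = provenance code."""
    with open(path, "w") as fh:
        for rec in consensus.itertuples(index=False):
            fh.write("\t".join(map(str, [
                rec.scaffold_id, 0, int(rec.length), rec.final_label,
                PROVENANCE_CODES[rec.provenance], ".",
            ])) + "\n")
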