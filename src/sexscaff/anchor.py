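"""Reference-guided chromosome anchoring of scaffolds.

Scaffolds are aligned (externally) to a chromosome-level reference of a
related species; this module consumes the tabular alignments, merges
each scaffold's query intervals per target chromosome so repetitive
multi-mapping is not double-counted, and assigns the scaffold to the
chromosome that dominates its merged aligned bases.

Assignment rule: let B_c be the merged aligned bp on chromosome c and
T = sum_c B_c.  A scaffold is assigned to argmax_c B_c iff T > 0, the
argmax is unique with B_best / T >= dominance_min, and T / scaffold
length >= coverage_min.  Otherwise it is UNASSIGNED with reason
NO_HITS, NO_DOMINANT (including exact ties) or LOW_COVERAGE.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "parse_alignments",
    "parse_scaffold_lengths",
    "merge_intervals",
    "merged_coverage",
    "merged_coverage_all",
    "assign_chromosomes",
    "summarize_anchoring",
]

ALIGNMENT_COLUMNS = ["scaffold_id", "q_start", "q_end", "chromosome",
                     "t_start", "t_end", "aligned_len", "identity"]

ASSIGNMENT_REASONS = ("OK", "NO_HITS", "NO_DOMINANT", "LOW_COVERAGE")


def _norm_interval(a: int, b: int, one_based: bool) -> tuple[int, int]:
    """Normalize possibly reversed, possibly 1-based coords to 0-based
    half-open with start < end."""
    if a > b:
        a, b = b, a
    if one_based:
        a -= 1
    return a, b


def _parse_paf_line(parts: list[str]):
    scaffold, _qlen, qs, qe, _strand, chrom, _tlen, ts, te, nmatch, alen = \
        parts[0], parts[1], int(parts[2]), int(parts[3]), parts[4], \
        parts[5], parts[6], int(parts[7]), int(parts[8]), int(parts[9]), \
        int(parts[10])
    qs, qe = _norm_interval(qs, qe, one_based=False)
    ts, te = _norm_interval(ts, te, one_based=False)
    ident = nmatch / alen if alen > 0 else np.nan
    return scaffold, qs, qe, chrom, ts, te, alen, ident


def _parse_coords_line(parts: list[str]):
    # show-coords -T: S1 E1 S2 E2 LEN1 LEN2 %IDY ref_tag qry_tag
    s1, e1, s2, e2 = (int(parts[i]) for i in range(4))
    ident = float(parts[6]) / 100.0
    chrom, scaffold = parts[7], parts[8]
    ts, te = _norm_interval(s1, e1, one_based=True)
    qs, qe = _norm_interval(s2, e2, one_based=True)
    return scaffold, qs, qe, chrom, ts, te, qe - qs, ident


def _parse_blast6_line(parts: list[str]):
    scaffold, chrom = parts[0], parts[1]
    ident = float(parts[2]) / 100.0
    qs, qe = _norm_interval(int(parts[6]), int(parts[7]), one_based=True)
    ts, te = _norm_interval(int(parts[8]), int(parts[9]), one_based=True)
    return scaffold, qs, qe, chrom, ts, te, qe - qs, ident


_PARSERS = {
    "paf": (_parse_paf_line, 11),
    "nucmer_coords": (_parse_coords_line, 9),
    "blast6": (_parse_blast6_line, 12),
}


def parse_alignments(path: str | Path, dialect: str = "paf") -> pd.DataFrame:
    """Read scaffold-to-chromosome hits from PAF, ``show-coords -T`` or
    BLAST outfmt-6 into 0-based half-open alignment records.

    PAF is already 0-based half-open; the other two dialects are 1-based
    inclusive and may carry reversed (strand-encoded) coordinates, which
    are normalized so q_start < q_end.  Header or text lines in nucmer
    output are skipped; any other unparseable row raises with its line
    number.
    """
    if dialect not in _PARSERS:
        raise InputError(
            f"unknown alignment dialect {dialect!r}; "
            f"expected one of {sorted(_PARSERS)}")
    parser, min_cols = _PARSERS[dialect]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if dialect == "nucmer_coords" and (
                    len(parts) < min_cols or not parts[0].lstrip("-").isdigit()):
                continue  # header block emitted by show-coords
            if len(parts) < min_cols:
                raise InputError(
                    f"{path}:{lineno}: expected >= {min_cols} tab-separated "
                    f"fields for dialect {dialect!r}, got {len(parts)}")
            try:
                rows.append(parser(parts))
            except (ValueError, IndexError) as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def parse_scaffold_lengths(path: str | Path) -> pd.Series:
    """Scaffold lengths from a (possibly full five-column) .fai table."""
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] < 2:
        raise InputError(f"{path}: need at least two columns (name, length)")
    return pd.Series(df[1].astype("int64").to_numpy(),
                     index=df[0].astype(str), name="length")


def merge_intervals(starts, ends) -> list[tuple[int, int]]:
    """Union of half-open intervals: merge overlapping or adjacent ones."""
    order = np.argsort(np.asarray(starts), kind="stable")
    merged: list[list[int]] = []
    for i in order:
        s, e = int(starts[i]), int(ends[i])
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_coverage(hits: pd.DataFrame) -> dict[str, int]:
    """Merged query-interval bp per chromosome for ONE scaffold's hits."""
    if hits.empty:
        return {}
    if hits["scaffold_id"].nunique() > 1:
        raise InputError("merged_coverage expects hits of a single scaffold")
    out: dict[str, int] = {}
    for chrom, sub in hits.groupby("chromosome", sort=True):
        merged = merge_intervals(sub["q_start"].to_numpy(),
                                 sub["q_end"].to_numpy())
        out[str(chrom)] = int(sum(e - s for s, e in merged))
    return out


def merged_coverage_all(hits: pd.DataFrame) -> dict[str, dict[str, int]]:
    """merged_coverage applied per scaffold over a full hit table."""
    if hits.empty:
        return {}
    return {
        str(scaffold): merged_coverage(sub)
        for scaffold, sub in hits.groupby("scaffold_id", sort=True)
    }


def assign_chromosomes(
    merged: dict[str, dict[str, int]],
    lengths: pd.Series,
    dominance_min: float = 0.5,
    coverage_min: float = 0.05,
) -> pd.DataFrame:
    """Best-hit dominance assignment over merged per-chromosome coverage.

    Every scaffold in ``lengths`` gets a row; scaffolds absent from
    ``merged`` are UNASSIGNED / NO_HITS.  Exact ties for the best
    chromosome yield NO_DOMINANT regardless of dominance_min.
    """
    rows = []
    for scaffold in lengths.index:
        length = int(lengths[scaffold])
        per_chrom = dict(sorted(merged.get(scaffold, {}).items()))
        total = sum(per_chrom.values())
        assigned, reason, dominance, coverage = "UNASSIGNED", "NO_HITS", 0.0, 0.0
        if total > 0:
            coverage = total / length
            ranked = sorted(per_chrom.items(), key=lambda kv: -kv[1])
            best_chrom, best_bp = ranked[0]
            runner_bp = ranked[1][1] if len(ranked) > 1 else 0
            dominance = best_bp / total
            if best_bp == runner_bp or dominance < dominance_min:
                reason = "NO_DOMINANT"
            elif coverage < coverage_min:
                reason = "LOW_COVERAGE"
            else:
                assigned, reason = best_chrom, "OK"
        rows.append((scaffold, length, assigned, reason, per_chrom,
                     dominance, coverage))
    return pd.DataFrame(rows, columns=[
        "scaffold_id", "length", "assigned_chromosome", "reason",
        "per_chromosome_merged_bp", "dominance", "coverage_fraction"])


def summarize_anchoring(assignments: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-chromosome counts/lengths/percentages plus overall assigned
    fractions (percentages over all scaffolds sum to 100, UNASSIGNED
    included)."""
    if assignments.empty:
        raise InputError("no assignments to summarize")
    total_n = len(assignments)
    total_bp = int(assignments["length"].sum())
    rows = []
    for chrom, sub in assignments.groupby("assigned_chromosome", sort=True):
        bp = int(sub["length"].sum())
        rows.append((chrom, len(sub), bp,
                     100.0 * len(sub) / total_n, 100.0 * bp / total_bp))
    table = pd.DataFrame(rows, columns=[
        "chromosome", "n_scaffolds", "total_bp",
        "pct_of_scaffolds", "pct_of_genome_length"])
    assigned = assignments[assignments["assigned_chromosome"] != "UNASSIGNED"]
    overall = {
        "assigned_fraction_scaffolds": len(assigned) / total_n,
        "assigned_fraction_length":
            int(assigned["length"].sum()) / total_bp,
    }
    return table, overall
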