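"""AD-ratio (average-depth ratio) computation and coverage classification.

The AD-ratio of a scaffold is its normalized female:male mean read
depth.  In an XY system, autosomal scaffolds have equal depth in both
sexes (ratio ~1), X scaffolds carry two female copies against one male
copy (ratio ~2), and Y scaffolds draw essentially no female reads
(ratio ~0).  Scaffolds are classified with the bands

* AUTOSOME:  0.7 < r < 1.3   (open interval)
* X:         1.7 < r < 2.3   (open interval)
* Y:         r <= 0.3        (closed upper bound)
* UNASSIGNED otherwise, including undefined ratios.

A ratio at or below 0.01 additionally raises the ``high_confidence_y``
flag: at that level the female depth is consistent with pure mismapping
background rather than a shared X/Y region.

Normalization makes the autosomal mode of the raw female/male ratio
equal one.  Two modes are offered: ``median`` rescales by the
length-weighted median of per-scaffold raw ratios (robust — sex-linked
sequence is only a few percent of a genome), and ``total`` rescales by
the ratio of total aligned bases (sum of depth x length), emulating a
library-size normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ConfigError

__all__ = [
    "ADThresholds",
    "ADHistogram",
    "read_mosdepth_summary",
    "compute_normalization",
    "compute_ad_ratios",
    "classify_scaffolds",
    "ad_histogram",
    "summarize_coverage_classes",
    "weighted_median",
]

COVERAGE_CLASSES = ("AUTOSOME", "X", "Y", "UNASSIGNED")


@dataclass(frozen=True)
class ADThresholds:
    """Classification bands for the AD-ratio, plus the male-depth floor
    below which a ratio is considered undefined."""

    autosome_lo: float = 0.7
    autosome_hi: float = 1.3
    x_lo: float = 1.7
    x_hi: float = 2.3
    y_max: float = 0.3
    y_high_conf: float = 0.01
    min_male_depth: float = 1.0

    def __post_init__(self) -> None:
        ok = (0.0 <= self.y_high_conf <= self.y_max < self.autosome_lo
              < self.autosome_hi < self.x_lo < self.x_hi)
        if not ok:
            raise ConfigError(
                "thresholds must satisfy 0 <= y_high_conf <= y_max < "
                "autosome_lo < autosome_hi < x_lo < x_hi")
        if self.min_male_depth < 0:
            raise ConfigError("min_male_depth must be >= 0")


@dataclass
class ADHistogram:
    """Length-weighted histogram of AD-ratios.

    ``table`` has one row per half-open bin [lower_edge, lower_edge +
    bin_width); the final row at ``range_max`` pools all ratios at or
    above it.  Bin totals are summed scaffold lengths, so the histogram
    shows where genomic sequence — not scaffold count — concentrates.
    """

    bin_width: float
    range_max: float
    table: pd.DataFrame  # columns: lower_edge, total_length


def read_mosdepth_summary(path: str | Path) -> pd.DataFrame:
    """Parse a mosdepth summary file into (scaffold_id, length, mean_depth).

    Per-region rows (``*_region``) are ignored; the ``total`` row is
    excluded from the per-scaffold table but kept in ``df.attrs['total']``
    for QC.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "mean"}
    if not required.issubset(df.columns):
        raise InputError(
            f"{path} lacks mosdepth summary columns {sorted(required)}")
    df = df[~df["chrom"].astype(str).str.endswith("_region")]
    total = df[df["chrom"] == "total"]
    df = df[df["chrom"] != "total"]
    out = pd.DataFrame({
        "scaffold_id": df["chrom"].astype(str),
        "length": df["length"].astype("int64"),
        "mean_depth": df["mean"].astype(float),
    }).reset_index(drop=True)
    out.attrs["total"] = (
        total.iloc[0].to_dict() if len(total) else None)
    return out


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= half."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        raise InputError("weighted median of empty or zero-weight data")
    order = np.argsort(values, kind="stable")
    cum = np.cumsum(weights[order])
    idx = int(np.searchsorted(cum, 0.5 * cum[-1]))
    return float(values[order][idx])


def _merge_sexes(male: pd.DataFrame, female: pd.DataFrame) -> pd.DataFrame:
    if male.empty or female.empty:
        raise InputError("depth tables must be non-empty")
    m_ids = set(male["scaffold_id"])
    f_ids = set(female["scaffold_id"])
    if m_ids != f_ids:
        offenders = sorted(m_ids ^ f_ids)[:10]
        raise InputError(
            "male and female depth tables cover different scaffolds; "
            f"first offenders: {offenders}")
    merged = male.merge(female, on="scaffold_id", suffixes=("_m", "_f"))
    if not (merged["length_m"] == merged["length_f"]).all():
        bad = merged.loc[merged["length_m"] != merged["length_f"],
                         "scaffold_id"].tolist()[:10]
        raise InputError(f"scaffold lengths disagree between sexes: {bad}")
    return pd.DataFrame({
        "scaffold_id": merged["scaffold_id"],
        "length": merged["length_m"],
        "male_depth": merged["mean_depth_m"],
        "female_depth": merged["mean_depth_f"],
    })


def compute_normalization(
    male: pd.DataFrame,
    female: pd.DataFrame,
    mode: str = "median",
    thresholds: ADThresholds = ADThresholds(),
) -> float:
    """Normalization factor k such that AD-ratio_i = (F_i / M_i) * k.

    ``median`` mode makes the length-weighted median raw ratio equal 1;
    ``total`` mode uses k = sum(M_i * L_i) / sum(F_i * L_i).
    """
    df = _merge_sexes(male, female)
    usable = df[df["male_depth"] >= thresholds.min_male_depth]
    if usable.empty:
        raise InputError(
            "no scaffold has male depth >= "
            f"{thresholds.min_male_depth}; cannot normalize")
    if mode == "total":
        denom = float((df["female_depth"] * df["length"]).sum())
        if denom <= 0:
            raise InputError("total female coverage is zero")
        return float((df["male_depth"] * df["length"]).sum()) / denom
    if mode == "median":
        raw = (usable["female_depth"] / usable["male_depth"]).to_numpy()
        med = weighted_median(raw, usable["length"].to_numpy())
        if med <= 0:
            raise InputError("length-weighted median raw ratio is zero")
        return 1.0 / med
    raise ConfigError(f"unknown normalization mode: {mode!r}")


def compute_ad_ratios(
    male: pd.DataFrame,
    female: pd.DataFrame,
    factor: float,
    thresholds: ADThresholds = ADThresholds(),
) -> pd.DataFrame:
    """Per-scaffold AD-ratio table (ratio NaN where male depth is below
    the floor — the division-blow-up guard)."""
    if factor <= 0:
        raise InputError(f"normalization factor must be > 0, got {factor}")
    df = _merge_sexes(male, female)
    defined = df["male_depth"] >= thresholds.min_male_depth
    ratio = np.where(defined,
                     df["female_depth"] / df["male_depth"] * factor,
                     np.nan)
    df["ad_ratio"] = ratio
    return df


def classify_scaffolds(
    records: pd.DataFrame,
    thresholds: ADThresholds = ADThresholds(),
) -> pd.DataFrame:
    """Fill ``coverage_class`` and ``high_confidence_y`` from the bands.

    Band semantics are strict for the open intervals (values at 0.7,
    1.3, 1.7, 2.3 are UNASSIGNED) and inclusive for the Y bound.
    """
    r = records["ad_ratio"].to_numpy(dtype=float)
    t = thresholds
    cls = np.select(
        [
            r <= t.y_max,
            (r > t.autosome_lo) & (r < t.autosome_hi),
            (r > t.x_lo) & (r < t.x_hi),
        ],
        ["Y", "AUTOSOME", "X"],
        default="UNASSIGNED",
    )
    cls = np.where(np.isnan(r), "UNASSIGNED", cls)
    out = records.copy()
    out["coverage_class"] = cls
    out["high_confidence_y"] = (cls == "Y") & (r <= t.y_high_conf)
    return out


def ad_histogram(
    records: pd.DataFrame,
    bin_width: float = 0.025,
    range_max: float = 4.0,
) -> ADHistogram:
    """Length-weighted histogram over half-open AD-ratio bins.

    Each scaffold with a defined ratio contributes its full length to
    exactly one bin; ratios >= range_max pool into a final overflow bin
    whose lower edge is range_max.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    if range_max <= 0:
        raise ConfigError("range_max must be > 0")
    defined = records.dropna(subset=["ad_ratio"])
    n_bins = int(np.ceil(range_max / bin_width - 1e-9))
    # Nudge the quotient so a ratio sitting exactly on a decimal bin edge
    # lands in the upper bin despite binary-float representation error.
    edges = np.round(np.arange(n_bins + 1) * bin_width, 9)
    idx = np.floor(defined["ad_ratio"].to_numpy() / bin_width
                   + 1e-9).astype(int)
    idx = np.minimum(idx, n_bins)  # overflow bin
    totals = np.zeros(n_bins + 1, dtype="int64")
    np.add.at(totals, idx, defined["length"].to_numpy(dtype="int64"))
    table = pd.DataFrame({
        "lower_edge": np.append(edges[:-1], range_max),
        "total_length": totals,
    })
    return ADHistogram(bin_width=bin_width, range_max=range_max, table=table)


def summarize_coverage_classes(records: pd.DataFrame) -> pd.DataFrame:
    """Per-class scaffold count, total bp and fraction of genome length."""
    if records.empty:
        raise InputError("no scaffolds to summarize")
    total = int(records["length"].sum())
    rows = []
    for cls in COVERAGE_CLASSES:
        sub = records[records["coverage_class"] == cls]
        bp = int(sub["length"].sum())
        rows.append((cls, len(sub), bp, bp / total))
    return pd.DataFrame(
        rows, columns=["coverage_class", "n_scaffolds", "total_bp",
                       "fraction_of_genome"])
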