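"""Synthetic genome, coverage and homology-evidence simulator.

Emulates the inputs of a coverage-based sex-chromosome identification
analysis for a dasyurid-like 2n = 14 karyotype (six autosome pairs plus
XY/XX): a chromosome-level genome fragmented into scaffolds, per-scaffold
mean read depths for one male and one female sample, noisy alignment
evidence against a chromosome-level reference of a related species, and
BLAST-style homology hits for known Y marker genes and their X/autosomal
homologs.  Every output carries known truth labels so downstream stages
can be scored exactly.

The depth model follows the XY expectation: a male carries one X and one
Y, so male depth on the sex chromosomes is half the autosomal depth; a
female carries two X and no Y, so female depth matches the male on
autosomes and X and is near zero on Y (a small mismapping background is
retained, mimicking reads from X/Y homologous regions).  Per-scaffold
depth is Gamma distributed — strictly positive and right-skewed like
real coverage — with configurable mean and coefficient of variation.

All randomness flows from a single seed through named per-stage
substreams (CRC32 of the stage name mixed into the seed sequence), so a
fixed config reproduces byte-identical outputs regardless of which
stages are run.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError

__all__ = [
    "SimulationConfig",
    "MarkerSimulation",
    "Y_GENE_CATALOG",
    "simulate_karyotype",
    "simulate_depths",
    "simulate_alignments",
    "simulate_marker_hits",
    "write_mosdepth_summary",
    "write_paf",
    "write_blast6",
    "write_fai",
    "write_truth",
    "simulate_to_dir",
]

#: Known marsupial/therian Y genes paired with their X or autosomal
#: homologs.  ATRY is the classic multi-copy case whose partial hits
#: scatter across scaffolds.
Y_GENE_CATALOG: list[tuple[str, str]] = [
    ("SRY", "SOX3"),
    ("ATRY", "ATRX"),
    ("RBMY", "RBMX"),
    ("UBE1Y", "UBE1X"),
    ("KDM5D", "KDM5C"),
    ("RPS4Y", "RPS4X"),
    ("HUWE1Y", "HUWE1X"),
    ("PHF6Y", "PHF6X"),
    ("MECP2Y", "MECP2X"),
    ("HCFC1Y", "HCFC1X"),
    ("THOC2Y", "THOC2X"),
    ("RLIMY", "RLIMX"),
    ("USP9Y", "USP9X"),
    ("DDX3Y", "DDX3X"),
    ("EIF1AY", "EIF1AX"),
    ("UTY", "UTX"),
    ("TSPY", "TSPX"),
    ("AMELY", "AMELX"),
    ("GYG2Y", "GYG2"),
    ("FLNAY", "FLNA"),
]


def _default_chrom_lengths(n_autosomes: int) -> dict[str, int]:
    """A ~98 Mb toy genome: autosomes ~95 Mb, X 2.6 Mb, Y 0.3 Mb.

    Autosome sizes decrease roughly like a real karyotype; their total is
    95 Mb so the genome-wide length fractions are ~97 / 2.7 / 0.3 %
    (autosome / X / Y), mirroring the ~95 / 2.6 / 0.3 split of a 3.3 Gb
    genome at toy scale.
    """
    weights = np.linspace(2.0, 1.0, n_autosomes)
    sizes = np.round(95_000_000 * weights / weights.sum()).astype(int)
    lengths = {f"chr{i + 1}": int(s) for i, s in enumerate(sizes)}
    lengths["chrX"] = 2_600_000
    lengths["chrY"] = 300_000
    return lengths


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Depths are in units of fold coverage (x); lengths in bp.  The 55x
    default matches the effective (deduplicated) coverage regime of a
    10x linked-read sequencing run.
    """

    seed: int = 0
    n_autosomes: int = 6
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    scaffold_len_logmean: float = math.log(80_000)
    scaffold_len_logsd: float = 0.8
    min_scaffold_len: int = 10_000
    depth_male: float = 55.0
    depth_female: float = 55.0
    depth_cv: float = 0.10
    depth_shared_frac: float = 0.8
    female_y_background: float = 0.02
    aln_miss_prob: float = 0.05
    aln_chimera_prob: float = 0.05
    n_y_genes: int = 20
    y_gene_ambiguous_frac: float = 0.05

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            self.chrom_lengths = _default_chrom_lengths(self.n_autosomes)
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ConfigError("all chromosome lengths must be > 0")
        if sum(self.chrom_lengths.values()) <= 0:
            raise ConfigError("total genome length must be > 0")
        for name in ("aln_miss_prob", "aln_chimera_prob",
                     "y_gene_ambiguous_frac", "female_y_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        if self.depth_cv <= 0:
            raise ConfigError("depth_cv must be > 0")
        if not 0.0 <= self.depth_shared_frac <= 1.0:
            raise ConfigError("depth_shared_frac must lie in [0, 1]")
        if self.min_scaffold_len <= 0:
            raise ConfigError("min_scaffold_len must be > 0")
        if self.depth_male < 0 or self.depth_female < 0:
            raise ConfigError("mean depths must be non-negative")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"bad config key in {path}: {exc}") from exc


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, named substream: seed sequence of (seed, crc32(stage))."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    )


def chromosome_group(chromosome: str) -> str:
    """Collapse a chromosome name to the AUTOSOME / X / Y comparison group."""
    if chromosome in ("chrX", "X"):
        return "X"
    if chromosome in ("chrY", "Y"):
        return "Y"
    if chromosome in ("UNASSIGNED", ""):
        return "UNASSIGNED"
    return "AUTOSOME"


# ---------------------------------------------------------------------------
# karyotype
# ---------------------------------------------------------------------------

def simulate_karyotype(config: SimulationConfig) -> pd.DataFrame:
    """Fragment each chromosome into scaffolds with lognormal sizes.

    Returns the truth table: ``scaffold_id, true_chromosome,
    scaffold_length, offset`` with scaffolds exactly tiling each
    chromosome (lengths sum to the chromosome length, offsets 0-based and
    non-overlapping).
    """
    rng = _stage_rng(config.seed, "karyotype")
    rows: list[tuple[str, str, int, int]] = []
    counter = 0
    for chrom, chrom_len in config.chrom_lengths.items():
        if chrom_len < config.min_scaffold_len:
            raise ConfigError(
                f"{chrom} ({chrom_len} bp) is shorter than "
                f"min_scaffold_len ({config.min_scaffold_len} bp)"
            )
        offset = 0
        while offset < chrom_len:
            draw = int(rng.lognormal(config.scaffold_len_logmean,
                                     config.scaffold_len_logsd))
            size = max(config.min_scaffold_len, draw)
            remaining = chrom_len - offset
            # Never leave a tail shorter than the minimum scaffold size.
            if size >= remaining or remaining - size < config.min_scaffold_len:
                size = remaining
            counter += 1
            rows.append((f"scaffold_{counter:05d}", chrom, size, offset))
            offset += size
    return pd.DataFrame(
        rows,
        columns=["scaffold_id", "true_chromosome", "scaffold_length", "offset"],
    )


# ---------------------------------------------------------------------------
# depths
# ---------------------------------------------------------------------------

def _gamma_depths(rng: np.random.Generator, means: np.ndarray,
                  cv: float) -> np.ndarray:
    """Gamma draws with the requested means and constant CV.

    shape k = 1/cv^2, scale = mean * cv^2; zero mean yields exactly zero.
    """
    out = np.asarray(means, dtype=float).copy()
    if cv <= 0:
        return out
    shape = 1.0 / (cv * cv)
    positive = means > 0
    out[positive] = rng.gamma(shape, means[positive] / shape)
    out[~positive] = 0.0
    return out


def simulate_depths(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scaffold mean depths for the male and female samples.

    Expected depths: male — autosomal mean on autosomes, half on X and Y
    (single copy each); female — autosomal mean on autosomes and X, and
    ``female_y_background`` times it on Y.

    Per-scaffold dispersion (total CV = ``depth_cv``) is split into a
    scaffold-intrinsic multiplicative bias shared by both samples
    (mappability/GC effects follow the sequence, not the library;
    variance share ``depth_shared_frac``) and an independent per-sample
    Gamma residual.  The shared component cancels in the female:male
    ratio, which is what makes per-scaffold depth ratios far tighter
    than per-scaffold depths — the regime in which AD-ratio
    classification operates on real data.
    """
    if truth.empty:
        raise InputError("truth table is empty")
    rng = _stage_rng(config.seed, "depths")
    group = truth["true_chromosome"].map(chromosome_group).to_numpy()
    male_mean = np.where(np.isin(group, ["X", "Y"]),
                         config.depth_male / 2.0, config.depth_male)
    female_mean = np.where(
        group == "Y",
        config.female_y_background * config.depth_female,
        config.depth_female,
    )
    cv_bias = config.depth_cv * math.sqrt(config.depth_shared_frac)
    cv_resid = config.depth_cv * math.sqrt(1.0 - config.depth_shared_frac)
    bias = _gamma_depths(rng, np.ones(len(truth)), cv_bias)
    male = pd.DataFrame({
        "scaffold_id": truth["scaffold_id"],
        "length": truth["scaffold_length"],
        "mean_depth": _gamma_depths(rng, male_mean * bias, cv_resid),
    })
    female = pd.DataFrame({
        "scaffold_id": truth["scaffold_id"],
        "length": truth["scaffold_length"],
        "mean_depth": _gamma_depths(rng, female_mean * bias, cv_resid),
    })
    return male, female


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def simulate_alignments(truth: pd.DataFrame,
                        config: SimulationConfig) -> pd.DataFrame:
    """Noisy scaffold-to-reference alignment blocks (0-based half-open).

    With probability 1 - aln_miss_prob a scaffold receives 1-3
    non-overlapping blocks on its true chromosome jointly covering at
    least 55% of its length; independently, with probability
    aln_chimera_prob it receives one spurious block (<=18% of its
    length) on a random wrong chromosome.
    """
    if truth.empty:
        raise InputError("truth table is empty")
    rng = _stage_rng(config.seed, "alignments")
    chroms = list(config.chrom_lengths)
    rows = []
    for rec in truth.itertuples(index=False):
        length = int(rec.scaffold_length)
        if rng.random() >= config.aln_miss_prob:
            n_blocks = int(rng.integers(1, 4))
            cov = rng.uniform(0.55, 0.95)
            seg = length / n_blocks
            for b in range(n_blocks):
                block_len = max(1, int(seg * cov))
                slack = max(0.0, seg - block_len)
                q_start = int(seg * b + rng.uniform(0.0, slack))
                q_end = min(q_start + block_len, length)
                rows.append((
                    rec.scaffold_id, q_start, q_end, rec.true_chromosome,
                    rec.offset + q_start, rec.offset + q_end,
                    q_end - q_start, rng.uniform(0.92, 0.995),
                ))
        if rng.random() < config.aln_chimera_prob and len(chroms) > 1:
            wrong = [c for c in chroms if c != rec.true_chromosome]
            target = wrong[int(rng.integers(len(wrong)))]
            t_len = config.chrom_lengths[target]
            block_len = max(1, int(length * rng.uniform(0.03, 0.18)))
            block_len = min(block_len, t_len)
            q_start = int(rng.uniform(0, length - block_len))
            t_start = int(rng.uniform(0, t_len - block_len))
            rows.append((
                rec.scaffold_id, q_start, q_start + block_len, target,
                t_start, t_start + block_len, block_len,
                rng.uniform(0.85, 0.95),
            ))
    return pd.DataFrame(
        rows,
        columns=["scaffold_id", "q_start", "q_end", "chromosome",
                 "t_start", "t_end", "aligned_len", "identity"],
    )


# ---------------------------------------------------------------------------
# marker genes
# ---------------------------------------------------------------------------

@dataclass
class MarkerSimulation:
    """Marker-gene homology evidence plus its generating truth."""

    hits: pd.DataFrame      # BLAST outfmt-6 style columns
    manifest: pd.DataFrame  # gene, gene_class, partner_gene
    gene_truth: pd.DataFrame  # gene, true_scaffold (empty string = ambiguous)


_BLAST6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def _blast_row(rng: np.random.Generator, gene: str, scaffold: str,
               scaffold_len: int, hit_len: int, bitscore: float,
               evalue: float) -> tuple:
    """One outfmt-6 row with 1-based inclusive coordinates."""
    hit_len = max(50, min(hit_len, scaffold_len))
    q_start = 1
    q_end = hit_len
    s_start = int(rng.integers(1, max(2, scaffold_len - hit_len + 1)))
    s_end = s_start + hit_len - 1
    pident = round(rng.uniform(75.0, 95.0), 2)
    mismatch = int(hit_len * (1 - pident / 100.0))
    return (gene, scaffold, pident, hit_len, mismatch, 0,
            q_start, q_end, s_start, s_end, evalue, round(bitscore, 1))


def simulate_marker_hits(truth: pd.DataFrame,
                         config: SimulationConfig) -> MarkerSimulation:
    """Homology hits for Y marker genes and their X/autosomal homologs.

    Unambiguous Y genes get one strong hit (e-value <= 1e-20) on a Y
    scaffold; with probability ``y_gene_ambiguous_frac`` a gene instead
    scatters several partial hits of near-equal bitscore (within 20%)
    across distinct scaffolds, reproducing multi-copy ATRY-like
    behaviour.  Homologs land on X scaffolds when X-borne, else on
    autosomal scaffolds.
    """
    rng = _stage_rng(config.seed, "markers")
    group = truth["true_chromosome"].map(chromosome_group)
    y_scaffolds = truth.loc[group == "Y"]
    if y_scaffolds.empty:
        raise InputError("truth table contains no Y scaffolds")
    x_scaffolds = truth.loc[group == "X"]
    auto_scaffolds = truth.loc[group == "AUTOSOME"]
    lengths = truth.set_index("scaffold_id")["scaffold_length"]

    pairs = list(Y_GENE_CATALOG)
    while len(pairs) < config.n_y_genes:
        i = len(pairs) + 1
        pairs.append((f"YG{i}", f"YG{i}_HOM"))
    pairs = pairs[: config.n_y_genes]

    hit_rows: list[tuple] = []
    manifest_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for y_gene, homolog in pairs:
        manifest_rows.append((y_gene, "Y_GENE", homolog))
        manifest_rows.append((homolog, "HOMOLOG", y_gene))
        gene_len = int(rng.integers(800, 3000))
        ambiguous = rng.random() < config.y_gene_ambiguous_frac
        if ambiguous:
            n_sites = int(rng.integers(2, 5))
            pool = pd.concat([y_scaffolds, auto_scaffolds])
            idx = rng.choice(len(pool), size=min(n_sites, len(pool)),
                             replace=False)
            base = rng.uniform(150.0, 400.0)
            factors = np.concatenate(
                [[1.0], rng.uniform(0.85, 0.999, size=len(idx) - 1)])
            for k, scaffold in enumerate(pool.iloc[idx]["scaffold_id"]):
                hit_rows.append(_blast_row(
                    rng, y_gene, scaffold, int(lengths[scaffold]),
                    gene_len // 3, base * factors[k],
                    10.0 ** -rng.uniform(21, 40)))
            truth_rows.append((y_gene, ""))
        else:
            scaffold = y_scaffolds.iloc[
                int(rng.integers(len(y_scaffolds)))]["scaffold_id"]
            hit_rows.append(_blast_row(
                rng, y_gene, scaffold, int(lengths[scaffold]), gene_len,
                rng.uniform(600.0, 1500.0), 10.0 ** -rng.uniform(40, 120)))
            truth_rows.append((y_gene, scaffold))
        # homolog: X-borne when an X scaffold exists and the pair is X/Y,
        # else autosomal
        on_x = homolog.endswith("X") and len(x_scaffolds) > 0
        source = x_scaffolds if on_x else auto_scaffolds
        if len(source) == 0:
            source = truth.loc[group != "Y"]
        hom_scaffold = source.iloc[
            int(rng.integers(len(source)))]["scaffold_id"]
        hit_rows.append(_blast_row(
            rng, homolog, hom_scaffold, int(lengths[hom_scaffold]),
            gene_len, rng.uniform(600.0, 1500.0),
            10.0 ** -rng.uniform(40, 120)))
        truth_rows.append((homolog, hom_scaffold))

    return MarkerSimulation(
        hits=pd.DataFrame(hit_rows, columns=_BLAST6_COLUMNS),
        manifest=pd.DataFrame(
            manifest_rows, columns=["gene", "gene_class", "partner_gene"]),
        gene_truth=pd.DataFrame(
            truth_rows, columns=["gene", "true_scaffold"]),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_mosdepth_summary(depths: pd.DataFrame, path: str | Path) -> None:
    """mosdepth summary dialect: chrom, length, bases, mean, min, max."""
    df = depths.copy()
    df["bases"] = (df["length"] * df["mean_depth"]).round().astype("int64")
    total = pd.DataFrame({
        "chrom": ["total"],
        "length": [int(df["length"].sum())],
        "bases": [int(df["bases"].sum())],
        "mean": [round(float(df["bases"].sum() / df["length"].sum()), 2)],
        "min": [0],
        "max": [0],
    })
    out = pd.DataFrame({
        "chrom": df["scaffold_id"],
        "length": df["length"],
        "bases": df["bases"],
        "mean": df["mean_depth"].round(2),
        "min": 0,
        "max": (df["mean_depth"] * 3).round().astype(int),
    })
    pd.concat([out, total]).to_csv(path, sep="\t", index=False)


def write_paf(hits: pd.DataFrame, scaffold_lengths: pd.Series,
              chrom_lengths: dict[str, int], path: str | Path) -> None:
    """Minimal 12-column PAF (0-based half-open, + strand)."""
    with open(path, "w") as fh:
        for rec in hits.itertuples(index=False):
            aln = int(rec.q_end - rec.q_start)
            matches = int(aln * float(rec.identity))
            fh.write("\t".join(map(str, [
                rec.scaffold_id, int(scaffold_lengths[rec.scaffold_id]),
                int(rec.q_start), int(rec.q_end), "+",
                rec.chromosome, int(chrom_lengths[rec.chromosome]),
                int(rec.t_start), int(rec.t_end),
                matches, aln, 60,
            ])) + "\n")


def write_blast6(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, header=False)


def write_fai(truth: pd.DataFrame, path: str | Path) -> None:
    """Two-column fai-style table: scaffold_id, length."""
    truth[["scaffold_id", "scaffold_length"]].to_csv(
        path, sep="\t", index=False, header=False)


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate the full labelled dataset and write every input file.

    Returns a manifest mapping logical names to paths (plus the in-memory
    truth tables for callers that want them).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_karyotype(config)
    male, female = simulate_depths(truth, config)
    alignments = simulate_alignments(truth, config)
    markers = simulate_marker_hits(truth, config)

    paths = {
        "truth": outdir / "truth.tsv",
        "male_depth": outdir / "male.mosdepth.summary.txt",
        "female_depth": outdir / "female.mosdepth.summary.txt",
        "alignments": outdir / "alignments.paf",
        "marker_hits": outdir / "ygenes.blast6",
        "gene_manifest": outdir / "genes.tsv",
        "gene_truth": outdir / "gene_truth.tsv",
        "lengths": outdir / "scaffolds.fai",
        "config": outdir / "sim_config.yaml",
    }
    write_truth(truth, paths["truth"])
    write_mosdepth_summary(male, paths["male_depth"])
    write_mosdepth_summary(female, paths["female_depth"])
    write_paf(alignments, truth.set_index("scaffold_id")["scaffold_length"],
              config.chrom_lengths, paths["alignments"])
    write_blast6(markers.hits, paths["marker_hits"])
    markers.manifest.to_csv(paths["gene_manifest"], sep="\t", index=False)
    markers.gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    write_fai(truth, paths["lengths"])
    config.to_yaml(paths["config"])
    return {k: str(v) for k, v in paths.items()}
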