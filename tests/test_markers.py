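"""Marker-gene placement, Y confirmation and the gene track."""

import numpy as np
import pandas as pd
import pytest

from sexscaff import (
    InputError,
    SimulationConfig,
    chromosome_group,
    classify_scaffolds,
    compute_ad_ratios,
    compute_normalization,
    confirm_y,
    gene_map_report,
    place_genes,
    simulate_depths,
    simulate_karyotype,
    simulate_marker_hits,
)


def _manifest(*pairs):
    rows = []
    for y_gene, homolog in pairs:
        rows.append((y_gene, "Y_GENE", homolog))
        rows.append((homolog, "HOMOLOG", y_gene))
    return pd.DataFrame(rows, columns=["gene", "gene_class", "partner_gene"])


def _hit(gene, scaffold, bitscore=500.0, evalue=1e-30, sstart=100, send=600):
    return (gene, scaffold, 90.0, 500, 10, 0, 1, 500, sstart, send,
            evalue, bitscore)


def _hits(*rows):
    return pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore"])


def _ad_table(entries):
    df = pd.DataFrame(entries, columns=["scaffold_id", "length", "ad_ratio"])
    df["male_depth"] = 27.0
    df["female_depth"] = df["ad_ratio"] * 27.0
    return df


class TestPlacement:
    def test_single_strong_hit_placed(self):
        out = place_genes(_hits(_hit("SRY", "sY")), _manifest(("SRY", "SOX3")))
        sry = out.set_index("gene").loc["SRY"]
        assert sry["status"] == "PLACED"
        assert sry["scaffold_id"] == "sY"
        # the partner with no hits is reported too, exactly once per gene
        assert out.set_index("gene").loc["SOX3", "status"] == "UNPLACED_NO_HIT"
        assert out["gene"].is_unique

    def test_weak_evalue_discarded(self):
        out = place_genes(_hits(_hit("SRY", "sY", evalue=1e-5)),
                          _manifest(("SRY", "SOX3")))
        assert out.set_index("gene").loc["SRY", "status"] == "UNPLACED_NO_HIT"

    def test_near_equal_scaffolds_ambiguous(self):
        out = place_genes(
            _hits(_hit("ATRY", "s1", bitscore=200),
                  _hit("ATRY", "s2", bitscore=190)),
            _manifest(("ATRY", "ATRX")))
        atry = out.set_index("gene").loc["ATRY"]
        assert atry["status"] == "UNPLACED_AMBIGUOUS"
        assert atry["best_bitscore"] == 200
        assert atry["runner_up_bitscore"] == 190

    def test_duplicate_gene_scaffold_rows_aggregated(self):
        out = place_genes(
            _hits(_hit("SRY", "s1", bitscore=150),
                  _hit("SRY", "s1", bitscore=150),
                  _hit("SRY", "s2", bitscore=200)),
            _manifest(("SRY", "SOX3")))
        sry = out.set_index("gene").loc["SRY"]
        assert sry["scaffold_id"] == "s1"  # 300 summed beats 200 by >1.2x
        assert sry["status"] == "PLACED"

    def test_evalue_monotonicity_and_margin_antitonicity(self):
        rng = np.random.default_rng(3)
        rows = [_hit(f"G{i}", f"s{rng.integers(5)}",
                     bitscore=float(rng.uniform(50, 400)),
                     evalue=float(10.0 ** -rng.uniform(5, 40)))
                for i in range(30)]
        manifest = _manifest(*[(f"G{i}", f"H{i}") for i in range(30)])
        placed = {}
        for emax in (1e-20, 1e-10, 1e-4):
            out = place_genes(_hits(*rows), manifest, evalue_max=emax)
            placed[emax] = set(out.loc[out["status"] == "PLACED", "gene"])
        assert placed[1e-20] <= placed[1e-10] <= placed[1e-4]
        by_margin = {}
        for margin in (1.0, 1.2, 2.0):
            out = place_genes(_hits(*rows), manifest,
                              ambiguity_margin=margin)
            by_margin[margin] = set(out.loc[out["status"] == "PLACED",
                                            "gene"])
        assert by_margin[2.0] <= by_margin[1.2] <= by_margin[1.0]


class TestConfirmY:
    def test_low_ratio_with_distinct_homolog_confirmed(self):
        placements = place_genes(
            _hits(_hit("SRY", "sY"), _hit("SOX3", "sX")),
            _manifest(("SRY", "SOX3")))
        ad = _ad_table([("sY", 70_000, 0.005), ("sX", 50_000, 2.0)])
        table, total_bp = confirm_y(placements, ad)
        row = table.set_index("scaffold_id").loc["sY"]
        assert bool(row["confirmed"])
        assert row["supporting_genes"] == "SRY"
        assert total_bp == 70_000

    def test_high_ratio_excluded(self):
        placements = place_genes(_hits(_hit("SRY", "s1")),
                                 _manifest(("SRY", "SOX3")))
        ad = _ad_table([("s1", 1000, 1.0)])
        table, total_bp = confirm_y(placements, ad)
        row = table.iloc[0]
        assert not row["confirmed"]
        assert row["excluded_reason"] == "AD_TOO_HIGH"
        assert total_bp == 0

    def test_homolog_on_same_scaffold_excluded(self):
        placements = place_genes(
            _hits(_hit("SRY", "s1"), _hit("SOX3", "s1", sstart=5000,
                                          send=5500)),
            _manifest(("SRY", "SOX3")))
        ad = _ad_table([("s1", 1000, 0.005)])
        table, _ = confirm_y(placements, ad)
        assert table.iloc[0]["excluded_reason"] == "HOMOLOG_SAME_SCAFFOLD"

    def test_coverage_y_scaffold_without_genes_reported(self):
        placements = place_genes(_hits(_hit("SRY", "s1")),
                                 _manifest(("SRY", "SOX3")))
        ad = _ad_table([("s1", 1000, 0.005), ("s2", 9000, 0.01)])
        ad = classify_scaffolds(ad)
        table, _ = confirm_y(placements, ad)
        s2 = table.set_index("scaffold_id").loc["s2"]
        assert not s2["confirmed"] and s2["excluded_reason"] == "NO_GENES"

    def test_missing_scaffold_in_ad_table_rejected(self):
        placements = place_genes(_hits(_hit("SRY", "ghost")),
                                 _manifest(("SRY", "SOX3")))
        with pytest.raises(InputError, match="ghost"):
            confirm_y(placements, _ad_table([("s1", 1000, 0.005)]))


class TestSyntheticRecovery:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_truth_y_confirmed_no_false_positives(self, seed):
        cfg = SimulationConfig(seed=seed, y_gene_ambiguous_frac=0.0)
        truth = simulate_karyotype(cfg)
        sim = simulate_marker_hits(truth, cfg)
        male, female = simulate_depths(truth, cfg)
        k = compute_normalization(male, female, "median")
        ad = classify_scaffolds(compute_ad_ratios(male, female, k))
        placements = place_genes(sim.hits, sim.manifest)
        table, _ = confirm_y(placements, ad)
        confirmed = set(table.loc[table["confirmed"], "scaffold_id"])
        y_truth = set(truth.loc[truth["true_chromosome"] == "chrY",
                                "scaffold_id"])
        marker_bearing = y_truth & set(sim.gene_truth["true_scaffold"])
        assert marker_bearing <= confirmed
        assert confirmed <= y_truth  # zero false confirmations

    def test_placements_match_generator_truth(self):
        cfg = SimulationConfig(seed=17, y_gene_ambiguous_frac=0.0)
        truth = simulate_karyotype(cfg)
        sim = simulate_marker_hits(truth, cfg)
        placements = place_genes(sim.hits, sim.manifest)
        merged = placements.merge(sim.gene_truth, on="gene")
        assert (merged["status"] == "PLACED").all()
        assert (merged["scaffold_id"] == merged["true_scaffold"]).all()


class TestGeneTrack:
    def test_genes_sorted_by_coordinate(self):
        hits = _hits(_hit("A", "s1", sstart=10_000, send=11_000),
                     _hit("B", "s1", sstart=5_000, send=6_000),
                     _hit("C", "s1", sstart=20_000, send=21_000))
        manifest = _manifest(("A", "Ah"), ("B", "Bh"), ("C", "Ch"))
        placements = place_genes(hits, manifest)
        track = gene_map_report(placements, hits)
        assert list(track["gene"]) == ["B", "A", "C"]
        assert list(track["start"]) == [5_000, 10_000, 20_000]

    def test_counts_on_synthetic_default(self):
        cfg = SimulationConfig(seed=21)
        truth = simulate_karyotype(cfg)
        sim = simulate_marker_hits(truth, cfg)
        placements = place_genes(sim.hits, sim.manifest)
        track = gene_map_report(placements, sim.hits)
        placed_y = placements[(placements["gene_class"] == "Y_GENE")
                              & (placements["status"] == "PLACED")]
        assert len(track) == len(placed_y)
        # every unambiguous Y gene from the generator is on the track
        y_truth = sim.gene_truth.merge(
            sim.manifest[sim.manifest["gene_class"] == "Y_GENE"], on="gene")
        unambiguous = y_truth[y_truth["true_scaffold"] != ""]
        assert set(unambiguous["gene"]) == set(track["gene"])

    def test_restricted_to_confirmed_scaffolds(self):
        hits = _hits(_hit("A", "s1"), _hit("B", "s2"))
        manifest = _manifest(("A", "Ah"), ("B", "Bh"))
        placements = place_genes(hits, manifest)
        confirmations = pd.DataFrame({
            "scaffold_id": ["s1", "s2"], "confirmed": [True, False]})
        track = gene_map_report(placements, hits, confirmations)
        assert list(track["gene"]) == ["A"]

    def test_empty_when_nothing_confirmed(self):
        hits = _hits(_hit("A", "s1"))
        placements = place_genes(hits, _manifest(("A", "Ah")))
        confirmations = pd.DataFrame({"scaffold_id": ["s1"],
                                      "confirmed": [False]})
        assert gene_map_report(placements, hits, confirmations).empty
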