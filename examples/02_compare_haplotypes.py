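"""Compare two haplotypes: duplication blocks, period, spacing, GC anomalies.

Simulates a pair of haplotypes that share flanks and ancestry but differ in
class-I gene copy number (four copies vs two), then runs the comparison
workflow and prints the block structure it recovers.
"""

from haploblock.pipeline import RunConfig, run_haplotype_comparison
from haploblock.simulate import SimConfig, simulate_haplotype_pair

cfg = SimConfig(seed=12, n_blocks=4, block_divergence=0.05)
hap_a, truth_a, hap_b, truth_b = simulate_haplotype_pair(cfg, n_blocks_b=2)

report = run_haplotype_comparison(
    hap_a, hap_b, RunConfig(out_dir="example_out/compare"),
    features_a=truth_a.features, features_b=truth_b.features,
)

print(f"{hap_a.id}: {len(report.self_blocks_a)} self duplication-block pairings")
print(f"{hap_b.id}: {len(report.self_blocks_b)} self duplication-block pairings")
if report.period:
    print(f"block period {report.period.period} bp, {report.period.n_copies} copies")
for (up, down), dist in report.gene_spacings:
    print(f"gene spacing {up} -> {down}: {dist} bp")
print("flank vs centre identity:", {k: round(v, 3) for k, v in report.flank_identity.items()})
# Four copies give C(4,2)=6 pairings and two copies give 1, so the
# copy-number difference is directly visible; conserved flanks sit near
# identity 1.0 while the diverged block region sits lower.
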