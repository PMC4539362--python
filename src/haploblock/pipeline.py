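"""Orchestration of the two analysis workflows.

``run_clone_validation`` checks that a set of overlapping clones represents
a single haplotype: all-pairs end overlaps, per-overlap variant tables,
restriction digest profiles (and matches against experimental size lists),
and optional contig scaffolding.

``run_haplotype_comparison`` compares two assembled haplotypes: cross- and
self-identity matrices, duplication blocks and period, gene spacing, GC
anomalies with boundary association, and the segment-partitioned
phylogenetic incongruence report.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import blockmap, gcscan, overlap, phylo, restriction
from .seq_core import Feature, SequenceRecord, write_variants_vcf


@dataclass
class RunConfig:
    """Stage parameters with defaults matching the published analysis:
    200-bp dot-matrix window, 100-bp GC window with a 2.5-SD cut-off,
    HindIII digests."""

    out_dir: str = "haploblock_out"
    # overlap stage
    min_overlap: int = 1000
    min_identity: float = 0.9
    # detection floor: same-haplotype clone overlaps stay above this even
    # with large indels and inversions (column identity ~0.97 for the
    # heaviest case), while mosaic alignments induced by the paralogous
    # tandem blocks (~90-95% unit identity) fall below it
    detect_identity: float = 0.95
    min_inversion: int = 100
    # restriction stage
    enzyme: str = "HindIII"
    rel_tol: float = 0.05
    abs_tol: int = 50
    min_fragment: int = 500
    # scaffold stage
    min_anchor: int = 500
    # blockmap stage
    dot_window: int = 200
    dot_step: int | None = None
    block_threshold: float = 0.7
    min_block: int = 5000
    # gcscan stage
    gc_window: int = 100
    gc_step: int = 1
    z_cutoff: float = 2.5
    boundary_max_dist: int = 200
    # phylo stage
    min_segment_columns: int = 50

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


@dataclass
class CloneValidationReport:
    pairs: list[dict]
    digests: dict[str, list[int]]
    profile_matches: dict[str, dict]
    scaffold: dict | None
    verdict: str
    exit_code: int


def run_clone_validation(
    clones: list[SequenceRecord],
    cfg: RunConfig,
    experimental_profiles: dict[str, restriction.FragmentProfile] | None = None,
    contigs: list[SequenceRecord] | None = None,
) -> CloneValidationReport:
    """Validate that overlapping clones represent one haplotype.

    The verdict is "single haplotype consistent" when every detected
    overlap reaches the identity threshold.  Exit code 2 signals a failed
    validation, 1 no qualifying overlaps.
    """
    if len(clones) < 2:
        raise ValueError("clone validation needs at least 2 clones")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pairs = []
    any_overlap = False
    all_consistent = True
    for i in range(len(clones)):
        for j in range(i + 1, len(clones)):
            a, b = clones[i], clones[j]
            ov = overlap.find_end_overlap(
                a, b, min_overlap=cfg.min_overlap, min_identity=cfg.detect_identity
            )
            if ov is None or ov.aligned_length < cfg.min_overlap:
                continue
            any_overlap = True
            variants = overlap.call_overlap_variants(ov, min_inversion=cfg.min_inversion)
            consistent = ov.identity >= cfg.min_identity
            all_consistent &= consistent
            counts = {
                "SNP": sum(v.kind == "SNP" for v in variants),
                "insertion": sum(v.kind == "insertion" for v in variants),
                "deletion": sum(v.kind == "deletion" for v in variants),
                "inversion": sum(v.kind == "inversion" for v in variants),
                "large_indel": sum(
                    v.kind in ("insertion", "deletion") and v.length >= 100 for v in variants
                ),
            }
            write_variants_vcf(variants, a.id, a.seq, out / f"{a.id}_{b.id}.vcf")
            pairs.append(
                {
                    "id_a": a.id,
                    "id_b": b.id,
                    "aligned_length": ov.aligned_length,
                    "identity": ov.identity,
                    "orientation": ov.orientation,
                    "variant_counts": counts,
                    "consistent": consistent,
                }
            )

    enzyme = restriction.ENZYMES[cfg.enzyme]
    digests = {}
    matches = {}
    for c in clones:
        prof = restriction.digest(c, enzyme)
        digests[c.id] = prof.fragments
        if experimental_profiles and c.id in experimental_profiles:
            m = restriction.match_profiles(
                prof,
                experimental_profiles[c.id],
                rel_tol=cfg.rel_tol,
                abs_tol=cfg.abs_tol,
                min_fragment=cfg.min_fragment,
            )
            restriction.write_match_tsv(m, out / f"{c.id}_profile_match.tsv")
            matches[c.id] = {
                "concordant": m.concordant,
                "n_matched": len(m.matched),
                "unmatched_in_silico": m.unmatched_a,
                "unmatched_experimental": m.unmatched_b,
            }

    scaffold_report = None
    if contigs:
        layout = overlap.scaffold_contigs(contigs, clones, min_anchor=cfg.min_anchor)
        overlap.write_scaffold_tsv(layout, out / "scaffold.tsv")
        scaffold_report = {
            "order": [p.contig_id for p in layout.placements],
            "orientations": [p.orientation for p in layout.placements],
            "gaps": layout.gaps,
            "unplaced": layout.unplaced,
        }

    if not any_overlap:
        verdict, code = "no qualifying overlaps", 1
    elif all_consistent:
        verdict, code = "single haplotype consistent", 0
    else:
        verdict, code = "overlap discordance detected", 2

    report = CloneValidationReport(
        pairs=pairs,
        digests=digests,
        profile_matches=matches,
        scaffold=scaffold_report,
        verdict=verdict,
        exit_code=code,
    )
    _write_clone_tsv(report, out / "clone_validation.tsv")
    return report


def _write_clone_tsv(report: CloneValidationReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("pair\taligned_length\tidentity\tSNPs\tinsertions\tdeletions\tinversions\tconsistent\n")
        for p in sorted(report.pairs, key=lambda p: (p["id_a"], p["id_b"])):
            c = p["variant_counts"]
            fh.write(
                f"{p['id_a']}~{p['id_b']}\t{p['aligned_length']}\t{p['identity']:.5f}\t"
                f"{c['SNP']}\t{c['insertion']}\t{c['deletion']}\t{c['inversion']}\t{p['consistent']}\n"
            )
        fh.write(f"# verdict: {report.verdict}\n")


@dataclass
class HaplotypeComparisonReport:
    cross_blocks: list
    self_blocks_a: list
    self_blocks_b: list
    period: blockmap.BlockPeriodEstimate | None
    gene_spacings: list
    gc_anomalies: dict[str, list]
    incongruence: phylo.IncongruenceReport | None
    flank_identity: dict[str, float]


def run_haplotype_comparison(
    hap_a: SequenceRecord,
    hap_b: SequenceRecord,
    cfg: RunConfig,
    features_a: list[Feature] | None = None,
    features_b: list[Feature] | None = None,
    alignment: tuple[list[str], list[str]] | None = None,
    partition: phylo.SegmentPartition | None = None,
) -> HaplotypeComparisonReport:
    """Compare two haplotypes: block structure, GC anomalies, incongruence."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    step = cfg.dot_step or max(1, cfg.dot_window // 4)
    # phase-max matrices: block offsets in real haplotypes are not
    # multiples of the grid step, and a plain subsampled grid cannot see
    # repeats whose offset misses the lattice
    cross = blockmap.identity_matrix(hap_a, hap_b, window=cfg.dot_window, step=step, phase_max=True)
    self_a = blockmap.identity_matrix(hap_a, hap_a, window=cfg.dot_window, step=step, phase_max=True)
    self_b = blockmap.identity_matrix(hap_b, hap_b, window=cfg.dot_window, step=step, phase_max=True)
    blockmap.write_dotplot(cross, tsv_path=out / "cross_dotplot.tsv", threshold=cfg.block_threshold)

    cross_blocks = blockmap.detect_blocks(cross, cfg.block_threshold, cfg.min_block)
    blocks_a = blockmap.detect_blocks(self_a, cfg.block_threshold, cfg.min_block)
    blocks_b = blockmap.detect_blocks(self_b, cfg.block_threshold, cfg.min_block)
    period = None
    for blocks in (blocks_a, blocks_b):
        if blocks:
            period = blockmap.estimate_period(blocks, step=step)
            break

    spacings = []
    for feats in (features_a, features_b):
        if feats:
            spacings.extend(blockmap.gene_spacing(feats))

    anomalies: dict[str, list] = {}
    for hap, feats in ((hap_a, features_a), (hap_b, features_b)):
        if not feats:
            print(f"warning: no annotation for {hap.id}; GC boundary association skipped",
                  file=sys.stderr)
            continue
        genes = [f for f in feats if f.kind in ("gene", "pseudogene")]
        hap_anoms = []
        for g in genes:
            lo = max(0, g.start - 500)
            hi = min(len(hap), g.end + 500)
            scan = gcscan.gc_profile(hap, (lo, hi), window=cfg.gc_window, step=cfg.gc_step)
            found = gcscan.flag_anomalies(scan, z_cutoff=cfg.z_cutoff)
            exons = [f for f in feats if f.kind == "exon" and g.start <= f.start < g.end]
            gcscan.associate_boundaries(found, exons, max_dist=cfg.boundary_max_dist)
            hap_anoms.extend(found)
        anomalies[hap.id] = hap_anoms
        gcscan.write_anomalies_bed(hap_anoms, hap.id, out / f"{hap.id}_gc_anomalies.bed")

    incongruence = None
    if alignment is not None and partition is not None:
        names, rows = alignment
        incongruence = phylo.congruence_scan(
            names, rows, partition, min_columns=cfg.min_segment_columns
        )
        with open(out / "segment_trees.nwk", "w") as fh:
            for label, tree in incongruence.segment_trees.items():
                fh.write(f"# {label}\n{tree.newick()}\n")

    # conserved-flank check: per-window best identity anywhere in the
    # partner (haplotypes differ in length, so the matrix diagonal does
    # not track homologous positions)
    import numpy as np

    row_best = np.nanmax(np.nan_to_num(cross.values), axis=1)
    k = max(1, min(10, row_best.size // 10))
    flank_identity = {}
    if row_best.size >= 2 * k + 1:
        flank_identity = {
            "left": float(row_best[:k].mean()),
            "right": float(row_best[-k:].mean()),
            "centre": float(row_best[k:-k].mean()),
        }

    report = HaplotypeComparisonReport(
        cross_blocks=cross_blocks,
        self_blocks_a=blocks_a,
        self_blocks_b=blocks_b,
        period=period,
        gene_spacings=spacings,
        gc_anomalies=anomalies,
        incongruence=incongruence,
        flank_identity=flank_identity,
    )
    _write_comparison_tsv(report, out / "haplotype_comparison.tsv")
    return report


def _write_comparison_tsv(report: HaplotypeComparisonReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("section\tkey\tvalue\n")
        for label, blocks in (
            ("self_blocks_a", report.self_blocks_a),
            ("self_blocks_b", report.self_blocks_b),
            ("cross_blocks", report.cross_blocks),
        ):
            for b in blocks:
                fh.write(
                    f"{label}\t{b.a_interval[0] + 1}-{b.a_interval[1]}~"
                    f"{b.b_interval[0] + 1}-{b.b_interval[1]}\t{b.mean_identity:.4f}\n"
                )
        if report.period:
            fh.write(f"period\tbp\t{report.period.period}\n")
            fh.write(f"period\tn_copies\t{report.period.n_copies}\n")
        for (pair, dist) in report.gene_spacings:
            fh.write(f"gene_spacing\t{pair[0]}~{pair[1]}\t{dist}\n")
        for hap_id, anoms in report.gc_anomalies.items():
            for a in anoms:
                bnd = a.nearest_boundary[0] if a.nearest_boundary else "."
                fh.write(
                    f"gc_anomaly\t{hap_id}:{a.interval[0] + 1}-{a.interval[1]}\t"
                    f"z={a.peak_z:.2f};boundary={bnd}\n"
                )
        if report.incongruence:
            for (s1, s2), rf in sorted(report.incongruence.rf.items()):
                fh.write(f"rf\t{s1}~{s2}\t{rf}\n")
            for s1, s2, col in report.incongruence.flagged:
                fh.write(f"breakpoint\t{s1}|{s2}\tcolumn {col}\n")
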