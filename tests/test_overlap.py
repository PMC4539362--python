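from collections import Counter

import pytest

from haploblock.overlap import (
    call_overlap_variants,
    classify_coding_effects,
    find_end_overlap,
    scaffold_contigs,
)
from haploblock.seq_core import Feature, SequenceRecord, VariantCall
from haploblock.simulate import (
    SimConfig,
    _rng,
    random_seq,
    simulate_clones,
    simulate_fragmented_clone,
    simulate_haplotype,
)


def _clone_pair(seed, **implants):
    cfg = SimConfig(seed=seed, n_blocks=2, block_length=8000, block_divergence=0.02)
    hap, _ = simulate_haplotype(cfg)
    layout = [(0, 12000), (7000, hap.length)]
    clones, truth = simulate_clones(hap, layout, seed=seed + 500, **implants)
    return clones, truth


class TestFindEndOverlap:
    def test_self_overlap_full_length(self):
        s = random_seq(_rng(1, 1), 50000, 0.45)
        a = SequenceRecord(id="a", seq=s)
        b = SequenceRecord(id="b", seq=s)
        ov = find_end_overlap(a, b, min_overlap=1000, min_identity=0.95)
        assert (ov.a_start, ov.a_end) == (0, 50000)
        assert (ov.b_start, ov.b_end) == (0, 50000)
        assert ov.identity == 1.0
        assert call_overlap_variants(ov) == []

    def test_constructed_suffix_prefix_overlap(self):
        rng = _rng(2, 1)
        a = SequenceRecord(id="a", seq=random_seq(rng, 30000, 0.45))
        b = SequenceRecord(id="b", seq=a.seq[-10000:] + random_seq(rng, 5000, 0.45))
        ov = find_end_overlap(a, b, min_overlap=1000, min_identity=0.95)
        assert ov.aligned_length == 10000
        assert ov.b_start == 0
        assert ov.a_start == 20000
        # direct string equality over the reported span
        assert a.seq[ov.a_start : ov.a_end] == b.seq[ov.b_start : ov.b_end]

    def test_reverse_orientation_found(self):
        from haploblock.seq_core import reverse_complement

        rng = _rng(3, 1)
        a = SequenceRecord(id="a", seq=random_seq(rng, 20000, 0.45))
        b_fwd = a.seq[-8000:] + random_seq(rng, 4000, 0.45)
        b = SequenceRecord(id="b", seq=reverse_complement(b_fwd))
        ov = find_end_overlap(a, b, min_overlap=1000, min_identity=0.95)
        assert ov.orientation == "reverse"
        assert ov.aligned_length == 8000

    def test_short_sequences_return_none(self):
        a = SequenceRecord(id="a", seq="ACGT" * 100)
        b = SequenceRecord(id="b", seq="ACGT" * 100)
        assert find_end_overlap(a, b, min_overlap=5000) is None

    def test_unrelated_sequences_return_none(self):
        a = SequenceRecord(id="a", seq=random_seq(_rng(4, 1), 10000, 0.45))
        b = SequenceRecord(id="b", seq=random_seq(_rng(4, 2), 10000, 0.45))
        assert find_end_overlap(a, b, min_overlap=1000, min_identity=0.9) is None


class TestCallOverlapVariants:
    def test_implanted_snps_and_indel_recovered(self):
        clones, truth = _clone_pair(
            7, snp_count=5, indel_spec=(("deletion", 10),)
        )
        ov = find_end_overlap(*clones, min_overlap=1000, min_identity=0.9)
        variants = call_overlap_variants(ov)
        got = Counter(v.kind for v in variants)
        assert got == Counter({"SNP": 5, "deletion": 1})
        (dele,) = [v for v in variants if v.kind == "deletion"]
        assert dele.length == 10
        # SNP positions exactly match the implant record
        assert sorted(v.pos_a for v in variants if v.kind == "SNP") == sorted(
            t.pos_a for t in truth.implanted_variants if t.kind == "SNP"
        )

    def test_inversion_relabelled_exactly(self):
        clones, truth = _clone_pair(8, inversion_spec=514)
        ov = find_end_overlap(*clones, min_overlap=1000, min_identity=0.7)
        variants = call_overlap_variants(ov, min_inversion=100)
        (inv,) = variants
        truth_inv = truth.implanted_variants[0]
        assert inv.kind == "inversion"
        assert inv.length == 514
        assert inv.pos_a == truth_inv.pos_a

    def test_variant_positions_increasing_and_inside_overlap(self):
        clones, _ = _clone_pair(
            9, snp_count=12, indel_spec=(("insertion", 40), ("deletion", 25))
        )
        ov = find_end_overlap(*clones, min_overlap=1000, min_identity=0.8)
        variants = call_overlap_variants(ov)
        positions = [v.pos_a for v in variants]
        assert positions == sorted(positions)
        assert all(ov.a_start <= p < ov.a_end for p in positions)

    def test_relabelling_conserves_aligned_length(self):
        clones, _ = _clone_pair(10, inversion_spec=300)
        ov = find_end_overlap(*clones, min_overlap=1000, min_identity=0.7)
        before = ov.aligned_length
        call_overlap_variants(ov, min_inversion=100)
        assert ov.aligned_length == before


class TestCodingEffects:
    def _gene(self):
        # CDS ATG GGA ATG at [10, 19)
        seq = SequenceRecord(id="g", seq="A" * 10 + "ATGGGAATG" + "T" * 10)
        cds = [Feature(seq_id="g", kind="CDS", start=10, end=19, name="g1")]
        return seq, cds

    def test_synonymous_third_position(self):
        seq, cds = self._gene()
        v = VariantCall("SNP", 15, 15, 1, "A", "G")  # GGA -> GGG (Gly)
        (e,) = classify_coding_effects([v], cds, seq)
        assert (e.region, e.effect) == ("CDS", "synonymous")

    def test_nonsynonymous_second_position(self):
        seq, cds = self._gene()
        v = VariantCall("SNP", 17, 17, 1, "T", "C")  # ATG -> ACG (Met -> Thr)
        (e,) = classify_coding_effects([v], cds, seq)
        assert (e.region, e.effect) == ("CDS", "nonsynonymous")

    def test_frameshift_and_inframe_indels(self):
        seq, cds = self._gene()
        fs = VariantCall("deletion", 12, 12, 2, "GG", "")
        inframe = VariantCall("deletion", 11, 11, 3, "TGG", "")
        e_fs, e_in = classify_coding_effects([fs, inframe], cds, seq)
        assert e_fs.effect == "frameshift"
        assert e_in.effect == "not_applicable"

    def test_intergenic_snp(self):
        seq, cds = self._gene()
        v = VariantCall("SNP", 3, 3, 1, "A", "C")
        (e,) = classify_coding_effects([v], cds, seq)
        assert e.region == "intergenic"

    def test_invalid_cds_length_errors(self):
        seq = SequenceRecord(id="g", seq="A" * 30)
        cds = [Feature(seq_id="g", kind="CDS", start=10, end=14, name="bad")]
        with pytest.raises(ValueError, match="bad"):
            classify_coding_effects([], cds, seq)

    def test_implanted_cds_snp_effects_match_truth(self):
        # implant SNPs with known codon effects into a random CDS
        rng = _rng(11, 3)
        from haploblock.simulate import _random_cds
        from haploblock.seq_core import translate_cds

        cds_seq = _random_cds(rng, 100)  # 300 bp
        seq = SequenceRecord(id="g", seq="A" * 50 + cds_seq + "T" * 50)
        cds = [Feature(seq_id="g", kind="CDS", start=50, end=350, name="g1")]
        variants, expected = [], []
        for codon_idx in range(2, 90, 5):
            within = int(rng.integers(0, 3))
            pos = 50 + codon_idx * 3 + within
            ref = seq.seq[pos]
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
            codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            alt_codon = codon[:within] + alt + codon[within + 1 :]
            expected.append(
                "synonymous" if translate_cds(codon) == translate_cds(alt_codon) else "nonsynonymous"
            )
            variants.append(VariantCall("SNP", pos, pos, 1, ref, alt))
        effects = classify_coding_effects(variants, cds, seq)
        assert [e.effect for e in effects] == expected


class TestScaffold:
    def test_single_contig_identical_to_reference(self):
        s = random_seq(_rng(12, 1), 20000, 0.45)
        ref = SequenceRecord(id="ref", seq=s)
        contig = SequenceRecord(id="c1", seq=s)
        layout = scaffold_contigs([contig], [ref])
        assert len(layout.placements) == 1
        assert layout.gaps == []
        assert layout.unplaced == []

    def test_fragmented_reference_recovers_order_and_gaps(self):
        cfg = SimConfig(seed=13, n_blocks=2, block_length=8000, block_divergence=0.03)
        hap, _ = simulate_haplotype(cfg)
        spacers = [1, 500, 4610]
        contigs, truth = simulate_fragmented_clone(
            hap, (500, hap.length - 500), spacers, seed=13
        )
        ref = SequenceRecord(id="ref", seq=hap.seq)
        layout = scaffold_contigs(contigs, [ref], min_anchor=500)
        expected_order = [
            d["id"] for d in sorted(truth.clone_layout, key=lambda d: d["start"])
        ]
        assert [p.contig_id for p in layout.placements] == expected_order
        assert layout.gaps == spacers
        truth_orient = {d["id"]: d["orientation"] for d in truth.clone_layout}
        assert all(p.orientation == truth_orient[p.contig_id] for p in layout.placements)

    def test_random_contig_goes_unplaced(self):
        s = random_seq(_rng(14, 1), 20000, 0.45)
        ref = SequenceRecord(id="ref", seq=s)
        good = SequenceRecord(id="good", seq=s[2000:8000])
        junk = SequenceRecord(id="junk", seq=random_seq(_rng(14, 2), 5000, 0.45))
        layout = scaffold_contigs([good, junk], [ref], min_anchor=500)
        assert layout.unplaced == ["junk"]
        assert [p.contig_id for p in layout.placements] == ["good"]

    def test_uncut_reference_zero_gap_total(self):
        # recovered gap total equals total deleted spacer length
        cfg = SimConfig(seed=15, n_blocks=2, block_length=8000, block_divergence=0.03)
        hap, _ = simulate_haplotype(cfg)
        spacers = [100, 900, 2000]
        contigs, _ = simulate_fragmented_clone(hap, (500, hap.length - 500), spacers, seed=15)
        ref = SequenceRecord(id="ref", seq=hap.seq)
        layout = scaffold_contigs(contigs, [ref])
        assert sum(layout.gaps) == sum(spacers)
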