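import numpy as np
import pytest

from haploblock.blockmap import (
    detect_blocks,
    detect_blocks_seeded,
    estimate_period,
    gene_spacing,
    gene_end_to_start_spacing,
    identity_matrix,
    DuplicationBlock,
)
from haploblock.seq_core import Feature, SequenceRecord
from haploblock.simulate import SimConfig, _rng, random_seq, simulate_haplotype


class TestIdentityMatrix:
    def test_self_main_diagonal_all_ones(self):
        s = SequenceRecord(id="s", seq=random_seq(_rng(1, 70), 5000, 0.45))
        m = identity_matrix(s, s, window=200, step=50)
        diag = np.array([m.values[i, i] for i in range(min(m.shape))])
        assert np.allclose(diag, 1.0)

    def test_self_symmetry(self):
        s = SequenceRecord(id="s", seq=random_seq(_rng(2, 70), 3000, 0.45))
        m = identity_matrix(s, s, window=200, step=100)
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_random_pair_values_near_chance(self):
        # window identity is Binomial(200, 0.25)/200; nearly all of the
        # ~10^4 cells lie in the central band and none approach 0.7
        a = SequenceRecord(id="a", seq=random_seq(_rng(3, 70), 10000, 0.5))
        b = SequenceRecord(id="b", seq=random_seq(_rng(3, 71), 10000, 0.5))
        m = identity_matrix(a, b, window=200, step=100)
        assert abs(float(np.mean(m.values)) - 0.25) < 0.01
        lo, hi = np.percentile(m.values, [0.5, 99.5])
        assert 0.15 <= lo and hi <= 0.35
        assert m.values.max() < 0.5

    def test_exact_copy_gives_off_diagonal_run(self):
        rng = _rng(4, 70)
        s = random_seq(rng, 12000, 0.45)
        s = s[:8000] + s[1000:3000] + s[8000:10000]  # copy of [1000,3000) at 8000
        rec = SequenceRecord(id="s", seq=s)
        m = identity_matrix(rec, rec, window=200, step=50)
        offset_cells = [
            (i, j)
            for i in range(m.shape[0])
            for j in range(m.shape[1])
            if j - i == (8000 - 1000) // 50 and m.values[i, j] >= 0.99
        ]
        run_len = len(offset_cells) * 50
        assert abs(run_len - 2000) <= 400

    def test_window_larger_than_sequence_errors(self):
        s = SequenceRecord(id="s", seq="ACGT" * 10)
        with pytest.raises(ValueError):
            identity_matrix(s, s, window=100)

    def test_phase_max_sees_off_lattice_offsets(self):
        # a repeat at an offset that is not a multiple of the step is
        # invisible to the plain grid but visible in phase-max mode
        rng = _rng(5, 70)
        s = random_seq(rng, 12000, 0.45)
        s = s[:8137] + s[1000:3000] + s[8137:9000]
        rec = SequenceRecord(id="s", seq=s)
        plain = identity_matrix(rec, rec, window=200, step=50)
        pm = identity_matrix(rec, rec, window=200, step=50, phase_max=True)
        off = (8137 - 1000) // 50
        plain_max = max(
            plain.values[i, i + off]
            for i in range(plain.shape[0] - off)
        )
        pm_max = max(pm.values[i, i + off] for i in range(pm.shape[0] - off))
        assert plain_max < 0.7 < pm_max


class TestDetectBlocks:
    def test_random_sequences_no_blocks(self):
        a = SequenceRecord(id="a", seq=random_seq(_rng(6, 70), 10000, 0.5))
        b = SequenceRecord(id="b", seq=random_seq(_rng(6, 71), 10000, 0.5))
        m = identity_matrix(a, b, window=200, step=50)
        assert detect_blocks(m, threshold=0.7, min_block=1000) == []

    def test_self_no_duplication_no_blocks(self):
        s = SequenceRecord(id="s", seq=random_seq(_rng(7, 70), 15000, 0.45))
        m = identity_matrix(s, s, window=200, step=50)
        assert detect_blocks(m, threshold=0.7, min_block=1000) == []

    def test_tandem_array_recovers_copies_and_offsets(self):
        cfg = SimConfig(
            seed=8, n_blocks=3, block_length=8000,
            gene_spacing_range=(8000, 8000), block_divergence=0.025,
        )
        hap, _ = simulate_haplotype(cfg)
        m = identity_matrix(hap, hap, window=200, step=50)
        blocks = detect_blocks(m, threshold=0.7, min_block=5000)
        offsets = sorted(abs(b.offset) for b in blocks)
        assert len(blocks) >= 2
        assert any(abs(o - 8000) <= 100 for o in offsets)
        assert any(abs(o - 16000) <= 100 for o in offsets)

    def test_threshold_monotonicity(self):
        cfg = SimConfig(
            seed=9, n_blocks=3, block_length=8000,
            gene_spacing_range=(8000, 8000), block_divergence=0.05,
        )
        hap, _ = simulate_haplotype(cfg)
        m = identity_matrix(hap, hap, window=200, step=50)
        totals = []
        for thr in (0.7, 0.8, 0.9, 0.97):
            blocks = detect_blocks(m, threshold=thr, min_block=1000)
            totals.append(sum(b.length for b in blocks))
        assert totals == sorted(totals, reverse=True)

    def test_self_blocks_exclude_main_diagonal_and_mirror(self):
        cfg = SimConfig(
            seed=10, n_blocks=2, block_length=8000,
            gene_spacing_range=(8000, 8000), block_divergence=0.03,
        )
        hap, _ = simulate_haplotype(cfg)
        m = identity_matrix(hap, hap, window=200, step=50)
        blocks = detect_blocks(m, threshold=0.7, min_block=3000)
        assert all(b.offset != 0 for b in blocks)
        assert all(b.a_interval[0] < b.b_interval[0] for b in blocks)


class TestEstimatePeriod:
    def _block(self, offset):
        return DuplicationBlock((0, 6000), (offset, offset + 6000), 0.95, offset, 6000)

    def test_hand_clustered_offsets(self):
        blocks = [self._block(8000), self._block(16050), self._block(7950)]
        est = estimate_period(blocks, tolerance=500)
        assert abs(est.period - 8000) <= 50
        assert est.n_copies == 3

    def test_single_block(self):
        est = estimate_period([self._block(80000)])
        assert est.period == 80000 and est.n_copies == 2

    def test_two_gene_haplotype(self):
        est = estimate_period([self._block(63000)])
        assert est.period == 63000

    def test_no_blocks_errors(self):
        with pytest.raises(ValueError, match="no duplication"):
            estimate_period([])


class TestGeneSpacing:
    def _genes(self, starts, length=1000):
        return [
            Feature(seq_id="h", kind="gene", start=s, end=s + length, name=f"g{i}")
            for i, s in enumerate(starts)
        ]

    def test_two_genes(self):
        (pair,) = gene_spacing(self._genes([0, 63000]))
        assert pair[1] == 63000

    def test_four_genes_arithmetic(self):
        spacings = gene_spacing(self._genes([0, 63000, 128000, 196000]))
        assert [d for _, d in spacings] == [63000, 65000, 68000]

    def test_fewer_than_two_is_empty(self):
        assert gene_spacing(self._genes([100])) == []

    def test_end_to_start_spacing(self):
        spacings = gene_end_to_start_spacing(self._genes([0, 63000], length=3000))
        assert [d for _, d in spacings] == [60000]

    def test_simulator_truth_recovered(self):
        cfg = SimConfig(seed=11, n_blocks=4, block_divergence=0.05)
        hap, truth = simulate_haplotype(cfg)
        spacings = [d for _, d in gene_spacing(truth.features)]
        expected = truth.extras["copy_lengths"][:-1]
        assert spacings == expected


class TestDetectBlocksSeeded:
    def test_matches_grid_detection_on_tandem_array(self):
        cfg = SimConfig(
            seed=21, n_blocks=3, block_length=8000,
            gene_spacing_range=(8000, 8000), block_divergence=0.03,
        )
        hap, _ = simulate_haplotype(cfg)
        blocks = detect_blocks_seeded(hap, min_block=5000)
        offsets = sorted(set(b.offset for b in blocks))
        assert any(abs(o - 8000) <= 200 for o in offsets)
        est = estimate_period(blocks, tolerance=500)
        assert abs(est.period - 8000) <= 100
        assert est.n_copies == 3

    def test_random_sequence_yields_nothing(self):
        rec = SequenceRecord(id="r", seq=random_seq(_rng(22, 70), 30000, 0.45))
        assert detect_blocks_seeded(rec, min_block=3000) == []

    def test_off_lattice_offset_detected(self):
        cfg = SimConfig(seed=23, n_blocks=3, block_length=8000, block_divergence=0.03)
        hap, truth = simulate_haplotype(cfg)  # spacing 6300-6800, not step-aligned
        blocks = detect_blocks_seeded(hap, min_block=4000)
        spacings = truth.extras["copy_lengths"][:-1]
        # close adjacent offsets cluster to one representative; a block at
        # one of the true inter-copy spacings must be reported
        assert any(
            any(abs(b.offset - sp) <= 200 for sp in spacings) for b in blocks
        )
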