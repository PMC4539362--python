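"""Sliding-window identity matrices, tandem duplication blocks and gene spacing.

A DOTTER-style dot matrix of ungapped window identities reveals the block
structure of the MHC class Ia region: each classical gene sits in a
tandemly duplicated unit, visible as parallel off-diagonal high-identity
runs whose offsets share a common period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .seq_core import Feature, SequenceRecord

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class IdentityMatrix:
    """Grid of ungapped window-identity fractions between two sequences."""

    id_a: str
    id_b: str
    window: int
    step: int
    values: np.ndarray  # (windows in a, windows in b), NaN where no valid bases
    self_comparison: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DuplicationBlock:
    """An off-diagonal high-identity run: one tandem-repeat unit pairing."""

    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    mean_identity: float
    offset: int  # b_start - a_start, bp
    length: int

    def __post_init__(self) -> None:
        self.length = self.a_interval[1] - self.a_interval[0]


@dataclass
class BlockPeriodEstimate:
    period: int
    n_copies: int
    support: list[DuplicationBlock] = field(default_factory=list)


def _window_starts(n: int, window: int, step: int, max_windows: int) -> np.ndarray:
    count = (n - window) // step + 1
    if count > max_windows:
        step = int(np.ceil((n - window) / (max_windows - 1)))
        count = (n - window) // step + 1
    return np.arange(count) * step, step


def identity_matrix(
    a: SequenceRecord,
    b: SequenceRecord,
    window: int = 200,
    step: int | None = None,
    max_windows: int = 2000,
    phase_max: bool = False,
) -> IdentityMatrix:
    """Ungapped window-identity grid between two sequences.

    value(i, j) is the exact-match fraction of the ungapped comparison of
    window i of ``a`` with window j of ``b``; positions where either window
    has N are excluded from both numerator and denominator.  The grid is
    computed in row chunks so memory stays bounded; very long inputs are
    subsampled to at most ``max_windows`` windows per axis.

    With ``phase_max`` the comparison runs at base-pair diagonal resolution
    and each grid cell stores the maximum windowed identity over the
    diagonals it covers (the way a zoomed-out dot plot renders).  The plain
    grid only registers repeats whose offset is a multiple of the step —
    a tandem unit of, say, 6,621 bp is invisible to a 50-bp-step grid of
    ungapped comparisons — so the phase-max mode is what block detection
    should consume when repeat offsets are not known in advance.
    """
    if window > len(a) or window > len(b):
        raise ValueError("window larger than a sequence")
    if step is None:
        step = max(1, window // 4)
    if phase_max:
        return _identity_matrix_diagonal(a, b, window, step, max_windows)
    ea, eb = _encode(a.seq), _encode(b.seq)
    starts_a, step_a = _window_starts(len(a), window, step, max_windows)
    starts_b, step_b = _window_starts(len(b), window, step, max_windows)
    step = max(step_a, step_b)
    if step_a != step_b:  # keep axes on a common step for offset arithmetic
        starts_a, _ = _window_starts(len(a), window, step, max_windows)
        starts_b, _ = _window_starts(len(b), window, step, max_windows)
    # window views (n_windows, window)
    wa = np.lib.stride_tricks.sliding_window_view(ea, window)[starts_a]
    wb = np.lib.stride_tricks.sliding_window_view(eb, window)[starts_b]
    na_, nb_ = len(starts_a), len(starts_b)
    values = np.empty((na_, nb_), dtype=np.float32)
    chunk = max(1, int(4e6 // (nb_ * window + 1)) or 1)
    valid_a = wa != 4
    valid_b = wb != 4
    for i0 in range(0, na_, chunk):
        i1 = min(i0 + chunk, na_)
        eq = wa[i0:i1, None, :] == wb[None, :, :]
        ok = valid_a[i0:i1, None, :] & valid_b[None, :, :]
        num = (eq & ok).sum(axis=2, dtype=np.int32)
        den = ok.sum(axis=2, dtype=np.int32)
        with np.errstate(invalid="ignore"):
            values[i0:i1] = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return IdentityMatrix(
        id_a=a.id,
        id_b=b.id,
        window=window,
        step=step,
        values=values,
        self_comparison=(a.id == b.id and a.seq == b.seq),
    )


def _identity_matrix_diagonal(
    a: SequenceRecord, b: SequenceRecord, window: int, step: int, max_windows: int
) -> IdentityMatrix:
    """Diagonal-resolution identity, max-pooled onto the window grid."""
    ea, eb = _encode(a.seq), _encode(b.seq)
    na, nb = len(ea), len(eb)
    starts_a, step = _window_starts(na, window, step, max_windows)
    starts_b, _ = _window_starts(nb, window, step, max_windows)
    gna, gnb = len(starts_a), len(starts_b)
    values = np.zeros((gna, gnb), dtype=np.float32)
    self_mode = a.id == b.id and a.seq == b.seq
    has_n = bool((ea == 4).any() or (eb == 4).any())
    # window start positions along a (multiples of step), and diagonal
    # bands of exactly `step` diagonals starting at multiples of step:
    # within one band every evaluated position maps to a single grid cell,
    # so the band max IS the cell max and no scatter is needed
    pos = np.arange(0, na - window + 1, step)
    d_lo = 1 if self_mode else -(na - window)
    d_hi = nb - window
    band0 = (d_lo // step) * step
    for b0 in range(band0, d_hi + 1, step):
        ds = np.arange(max(b0, d_lo), min(b0 + step, d_hi + 1))
        if ds.size == 0:
            continue
        lo = max(0, -int(ds.min()))
        hi = min(na, nb - int(ds.max()))
        if hi - lo < window:
            continue
        seg_a = ea[lo:hi]
        L = hi - lo
        rows = np.lib.stride_tricks.sliding_window_view(eb, L)[lo + ds]
        eq = seg_a[None, :] == rows
        if has_n:
            valid = (seg_a[None, :] != 4) & (rows != 4)
            eq &= valid
        cs = np.cumsum(eq, axis=1, dtype=np.int32)
        p = pos[(pos >= lo) & (pos + window <= hi)] - lo
        if p.size == 0:
            continue
        num = cs[:, p + window - 1] - np.where(p > 0, cs[:, p - 1], 0)
        if has_n:
            cv = np.cumsum(valid, axis=1, dtype=np.int32)
            den = cv[:, p + window - 1] - np.where(p > 0, cv[:, p - 1], 0)
        else:
            den = np.full_like(num, window)
        with np.errstate(invalid="ignore"):
            ident = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        band_max = ident.max(axis=0).astype(np.float32)
        gi = (p + lo) // step
        gj = gi + b0 // step
        ok = (gj >= 0) & (gj < gnb) & (gi < gna)
        values[gi[ok], gj[ok]] = np.maximum(values[gi[ok], gj[ok]], band_max[ok])
    # the banded pass truncates each band to a common span, which clips
    # cells near the matrix borders; recompute those exactly
    border: set[tuple[int, int]] = set()
    for i in list(range(min(2, gna))) + list(range(max(0, gna - 2), gna)):
        border.update((i, j) for j in range(gnb))
    for j in list(range(min(2, gnb))) + list(range(max(0, gnb - 2), gnb)):
        border.update((i, j) for i in range(gna))
    for i, j in border:
        if self_mode and i == j:
            continue
        p0 = i * step
        best = 0.0
        for d in range(j * step - p0, j * step - p0 + step):
            if self_mode and d == 0:
                continue
            q0 = p0 + d
            if q0 < 0 or q0 + window > nb or p0 + window > na:
                continue
            wa = ea[p0 : p0 + window]
            wb = eb[q0 : q0 + window]
            okm = (wa != 4) & (wb != 4)
            den = int(okm.sum())
            if den > 0:
                best = max(best, float(((wa == wb) & okm).sum() / den))
        values[i, j] = max(values[i, j], np.float32(best))
    if self_mode:
        values = np.maximum(values, values.T)
        np.fill_diagonal(values, 1.0)
    return IdentityMatrix(
        id_a=a.id, id_b=b.id, window=window, step=step, values=values,
        self_comparison=self_mode,
    )


def detect_blocks(
    m: IdentityMatrix,
    threshold: float = 0.7,
    min_block: int = 5000,
    diagonal_exclusion: int | None = None,
) -> list[DuplicationBlock]:
    """Group above-threshold cells into diagonal runs; return duplication blocks.

    Cells >= threshold are connected (8-connectivity, so diagonal runs with
    one-step offset jitter merge); components whose a-span is shorter than
    ``min_block`` are discarded.  In self-comparison mode the main diagonal
    is excluded and mirror-image blocks are reported once (a_start < b_start).
    """
    vals = np.nan_to_num(m.values, nan=0.0)
    mask = vals >= threshold
    if m.self_comparison:
        excl = diagonal_exclusion if diagonal_exclusion is not None else max(1, m.window // m.step)
        n = min(mask.shape)
        ii, jj = np.indices(mask.shape)
        mask &= np.abs(ii - jj) > excl
    labels, n_comp = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    blocks: list[DuplicationBlock] = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labels == comp)
        i_min, j_min = idx.min(axis=0)
        i_max, j_max = idx.max(axis=0)
        a_iv = (int(i_min) * m.step, int(i_max) * m.step + m.window)
        b_iv = (int(j_min) * m.step, int(j_max) * m.step + m.window)
        if a_iv[1] - a_iv[0] < min_block:
            continue
        mean_ident = float(vals[idx[:, 0], idx[:, 1]].mean())
        offset = b_iv[0] - a_iv[0]
        blocks.append(DuplicationBlock(a_iv, b_iv, mean_ident, offset, a_iv[1] - a_iv[0]))
    if m.self_comparison:
        # keep the upper-triangle copy of each mirror pair
        blocks = [b for b in blocks if b.a_interval[0] < b.b_interval[0]]
    blocks.sort(key=lambda b: (b.a_interval, b.b_interval))
    return blocks


def detect_blocks_seeded(
    seq: SequenceRecord,
    window: int = 200,
    step: int | None = None,
    threshold: float = 0.7,
    min_block: int = 5000,
    k: int = 31,
    max_offsets: int = 12,
    offset_band: int = 500,
) -> list[DuplicationBlock]:
    """Self-duplication blocks for long sequences via k-mer seeding.

    The dense dot matrix is quadratic in sequence length; at chromosome
    scale the candidate repeat offsets are instead read from a histogram
    of exact k-mer self-matches, and windowed ungapped identity is then
    evaluated only along those candidate diagonals.  Suitable when copies
    are colinear (no large indels between them).
    """
    from collections import Counter, defaultdict

    s = seq.seq
    n = len(s)
    if step is None:
        step = max(1, window // 4)
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(0, n - k + 1, k):
        index[s[i : i + k]].append(i)
    offsets: Counter[int] = Counter()
    for j in range(n - k + 1):
        for i in index.get(s[j : j + k], ()):
            if i - j >= window:
                offsets[i - j] += 1
    if not offsets:
        return []
    # greedy clustering of offset peaks
    remaining = dict(offsets)
    centres: list[int] = []
    while remaining and len(centres) < max_offsets:
        best = max(remaining, key=lambda d: (remaining[d], -d))
        band = [d for d in remaining if abs(d - best) <= offset_band]
        centres.append(best)
        for d in band:
            del remaining[d]
    ea = _encode(s)
    blocks: list[DuplicationBlock] = []
    for d in sorted(centres):
        L = n - d
        if L < min_block:
            continue
        eq = (ea[:L] == ea[d : d + L]) & (ea[:L] != 4) & (ea[d : d + L] != 4)
        cum = np.concatenate([[0], np.cumsum(eq, dtype=np.int64)])
        starts = np.arange(0, L - window + 1, step)
        ident = (cum[starts + window] - cum[starts]) / window
        hit = ident >= threshold
        # merge runs bridging up to two low windows
        i = 0
        while i < len(hit):
            if not hit[i]:
                i += 1
                continue
            j = i
            last = i
            while j < len(hit) and j - last <= 2:
                if hit[j]:
                    last = j
                j += 1
            a0 = int(starts[i])
            a1 = int(starts[last]) + window
            if a1 - a0 >= min_block:
                mean_ident = float(ident[i : last + 1].mean())
                blocks.append(
                    DuplicationBlock((a0, a1), (a0 + d, a1 + d), mean_ident, d, a1 - a0)
                )
            i = last + 1
    blocks.sort(key=lambda b: (b.a_interval, b.b_interval))
    return blocks


def estimate_period(blocks: list[DuplicationBlock], tolerance: int | None = None, step: int = 50) -> BlockPeriodEstimate:
    """Consensus tandem-repeat period from block offsets.

    Offsets are clustered with the given tolerance (default 2 * step); the
    best-supported cluster's mean is the period, and copy number is
    1 + round(max offset / period).
    """
    if not blocks:
        raise ValueError("no duplication detected")
    tol = tolerance if tolerance is not None else 2 * step
    offsets = sorted(abs(b.offset) for b in blocks)
    clusters: list[list[int]] = [[offsets[0]]]
    for off in offsets[1:]:
        if off - clusters[-1][-1] <= tol:
            clusters[-1].append(off)
        else:
            clusters.append([off])
    # mode cluster; ties broken toward the smallest period
    clusters.sort(key=lambda c: (-len(c), sum(c) / len(c)))
    best = clusters[0]
    period = int(round(sum(best) / len(best)))
    n_copies = 1 + int(round(max(offsets) / period))
    support = [b for b in blocks if any(abs(abs(b.offset) - o) <= tol for o in best)]
    return BlockPeriodEstimate(period=period, n_copies=n_copies, support=support)


def gene_spacing(
    features: list[Feature], kind_filter: tuple[str, ...] = ("gene",)
) -> list[tuple[tuple[str, str], int]]:
    """Start-to-start distances between consecutive genes on one sequence.

    Start-to-start distance equals the duplication period when the genes
    sit in tandem blocks, which is the comparison of interest here.
    """
    genes = sorted(
        (f for f in features if f.kind in kind_filter), key=lambda f: (f.seq_id, f.start)
    )
    out = []
    for up, down in zip(genes, genes[1:]):
        if up.seq_id != down.seq_id:
            continue
        out.append(((up.name, down.name), down.start - up.start))
    return out


def gene_end_to_start_spacing(
    features: list[Feature], kind_filter: tuple[str, ...] = ("gene",)
) -> list[tuple[tuple[str, str], int]]:
    """End-to-start (intergenic) distances, reported for transparency."""
    genes = sorted(
        (f for f in features if f.kind in kind_filter), key=lambda f: (f.seq_id, f.start)
    )
    out = []
    for up, down in zip(genes, genes[1:]):
        if up.seq_id != down.seq_id:
            continue
        out.append(((up.name, down.name), down.start - up.end))
    return out


def write_dotplot(m: IdentityMatrix, png_path=None, tsv_path=None, threshold: float = 0.7) -> None:
    """Export the identity matrix: greyscale PNG and/or TSV of cells >= threshold."""
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("a_start\tb_start\tidentity\n")
            idx = np.argwhere(np.nan_to_num(m.values) >= threshold)
            for i, j in idx:
                fh.write(f"{i * m.step}\t{j * m.step}\t{m.values[i, j]:.4f}\n")
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        ax.imshow(
            m.values.T, origin="lower", cmap="Greys", vmin=0.25, vmax=1.0, aspect="auto",
            extent=[0, m.values.shape[0] * m.step, 0, m.values.shape[1] * m.step],
        )
        ax.set_xlabel(f"{m.id_a} (bp)")
        ax.set_ylabel(f"{m.id_b} (bp)")
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
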