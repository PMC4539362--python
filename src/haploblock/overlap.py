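"""Clone end-overlap detection, variant calling and reference-guided scaffolding.

Overlapping BAC clones from a single haplotype should be near-identical in
their shared interval; this module finds the maximal end-to-end overlap
between two sequences, enumerates the SNPs, insertion/deletions and
inversions within it, classifies coding effects of overlap SNPs against a
gene model, and orders clone contigs along reference sequences with gap
estimation.

Overlap detection seeds on shared k-mers, chains colinear seeds to fix the
overlap configuration (which end of which partner, which orientation) and
then computes a global alignment of the chained span with edlib.
"""

from __future__ import annotations

import sys
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import edlib
from Bio import Align

from .seq_core import Feature, SequenceRecord, VariantCall, reverse_complement, translate_cds

# Alignment scoring used to rank candidate overlaps (edlib computes the
# alignment path; this rescoring picks between orientations/configurations).
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -4, -1


@dataclass
class OverlapAlignment:
    """A maximal end-to-end alignment between two sequences."""

    id_a: str
    id_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    orientation: str  # forward | reverse
    identity: float
    aligned_length: int
    variants: list[VariantCall] = field(default_factory=list)
    # private: aligned column strings (a row, b row) used by variant calling
    _columns: tuple[str, str] | None = None


@dataclass
class Placement:
    contig_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    orientation: str
    identity: float
    score: int


@dataclass
class ScaffoldLayout:
    """Ordered contig placements along reference sequences with gap estimates."""

    placements: list[Placement]
    gaps: list[int]
    unplaced: list[str]
    overlapping_joins: list[int] = field(default_factory=list)  # indices of gaps floored at 0


def _kmer_diagonals(a: str, b: str, k: int = 31, max_candidates: int = 5) -> list[int]:
    """Candidate seed diagonals between a and b, best-supported first.

    A diagonal offset d means a[i] pairs with b[i - d].  Diagonals within a
    small band are clustered; several candidates are returned because
    tandem repeats induce strong false diagonals one period away from the
    true overlap diagonal, and the caller scores each candidate alignment.
    """
    if len(a) < k or len(b) < k:
        return []
    # sparse index on a, dense scan of b: every diagonal stays reachable
    # (sampling both sides at a stride would hide diagonals not divisible
    # by the stride)
    index: dict[str, list[int]] = defaultdict(list)
    step = max(1, k // 2)
    for i in range(0, len(a) - k + 1, step):
        index[a[i : i + k]].append(i)
    diags: Counter[int] = Counter()
    for j in range(len(b) - k + 1):
        kmer = b[j : j + k]
        for i in index.get(kmer, ()):
            diags[i - j] += 1
    if not diags:
        return []
    # greedy band clustering: repeatedly take the best-supported diagonal and
    # absorb its neighbours
    remaining = dict(diags)
    out: list[int] = []
    while remaining and len(out) < max_candidates:
        best_d = max(remaining, key=lambda d: (remaining[d], -abs(d)))
        band = [d for d in remaining if abs(d - best_d) <= 400]
        centre = max(band, key=lambda d: remaining[d])
        out.append(centre)
        for d in band:
            del remaining[d]
    return out


def _affine_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN + GAP_EXTEND
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _align_columns(sub_a: str, sub_b: str) -> tuple[str, str]:
    """Global alignment of two near-identical spans; raw aligned rows.

    edlib's O(nd) edit-distance alignment provides the path.  Unit costs
    leave large-indel placement degenerate (a long gap can be fragmented at
    no cost), so variant calling later re-aligns dirty regions with affine
    gap scoring; the raw rows are kept here because inversion detection
    needs the unpolished mismatch storm.
    """
    res = edlib.align(sub_a, sub_b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, sub_a, sub_b)
    return nice["query_aligned"], nice["target_aligned"]


def _polish_columns(
    row_a: str,
    row_b: str,
    flank: int = 50,
    max_gap: int = 30,
    skip_spans: list[tuple[int, int]] | None = None,
) -> tuple[str, str]:
    """Re-align dirty column clusters with affine gap scoring.

    Clusters overlapping a span in ``skip_spans`` (column coordinates) are
    left untouched — used for confirmed inversions, whose columns must not
    be rearranged before masking."""
    bad = [
        (ca == "-" or cb == "-") or (ca != cb and ca != "N" and cb != "N")
        for ca, cb in zip(row_a, row_b)
    ]
    n = len(bad)
    clusters = []
    i = 0
    while i < n:
        if not bad[i]:
            i += 1
            continue
        last_bad = i
        j = i
        while j < n and j - last_bad <= max_gap:
            if bad[j]:
                last_bad = j
            j += 1
        if sum(bad[i : last_bad + 1]) >= 3:
            lo, hi = max(0, i - flank), min(n, last_bad + 1 + flank)
            if not any(lo < e and s0 < hi for s0, e in (skip_spans or ())):
                clusters.append((lo, hi))
        i = last_bad + 1
    if not clusters:
        return row_a, row_b
    aligner = _affine_aligner()
    out_a, out_b = [], []
    prev = 0
    for ci, cj in clusters:
        ci = max(ci, prev)
        out_a.append(row_a[prev:ci])
        out_b.append(row_b[prev:ci])
        sub_a = row_a[ci:cj].replace("-", "")
        sub_b = row_b[ci:cj].replace("-", "")
        if sub_a and sub_b:
            aln = aligner.align(sub_a, sub_b)[0]
            out_a.append(str(aln[0]))
            out_b.append(str(aln[1]))
        else:
            out_a.append(row_a[ci:cj])
            out_b.append(row_b[ci:cj])
        prev = cj
    out_a.append(row_a[prev:])
    out_b.append(row_b[prev:])
    return "".join(out_a), "".join(out_b)


def _realign_terminal(cols_a: str, cols_b: str, overhang: str, left: bool) -> tuple[str, str, int, int]:
    """Re-align a terminal column region with the overhang end free.

    ``overhang`` names the row whose unpaired terminal characters should be
    skipped at no cost (they hang over into the partner's non-overlapping
    region).  Returns the realigned columns with the free gap run stripped,
    plus the number of a/b characters removed from the overlap span.
    """
    pa = cols_a.replace("-", "")
    pb = cols_b.replace("-", "")
    if not pa or not pb:
        return cols_a, cols_b, 0, 0
    al = _affine_aligner()
    # extra target (a) chars appear as deletions; extra query (b) chars as insertions
    if left:
        if overhang == "a":
            al.open_left_deletion_score = 0
            al.extend_left_deletion_score = 0
        else:
            al.open_left_insertion_score = 0
            al.extend_left_insertion_score = 0
    else:
        if overhang == "a":
            al.open_right_deletion_score = 0
            al.extend_right_deletion_score = 0
        else:
            al.open_right_insertion_score = 0
            al.extend_right_insertion_score = 0
    aln = al.align(pa, pb)[0]
    ra, rb = str(aln[0]), str(aln[1])
    other = rb if overhang == "a" else ra
    if left:
        i = 0
        while i < len(ra) and other[i] == "-":
            i += 1
        skip_a = i - ra[:i].count("-")
        skip_b = i - rb[:i].count("-")
        return ra[i:], rb[i:], skip_a, skip_b
    j = len(ra)
    while j > 0 and other[j - 1] == "-":
        j -= 1
    drop_a = (len(ra) - j) - ra[j:].count("-")
    drop_b = (len(rb) - j) - rb[j:].count("-")
    return ra[:j], rb[:j], drop_a, drop_b


def _column_stats(row_a: str, row_b: str) -> tuple[int, int, int, int]:
    """(matches, mismatches, gap columns, valid columns); N columns excluded."""
    matches = mismatches = gaps = valid = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            gaps += 1
            valid += 1
            continue
        if ca == "N" or cb == "N":
            continue
        valid += 1
        if ca == cb:
            matches += 1
        else:
            mismatches += 1
    return matches, mismatches, gaps, valid


def _score_columns(row_a: str, row_b: str) -> int:
    score = 0
    in_gap = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            score += GAP_OPEN + GAP_EXTEND if not in_gap else GAP_EXTEND
            in_gap = True
        else:
            in_gap = False
            if ca == "N" or cb == "N":
                continue
            score += MATCH if ca == cb else MISMATCH
    return score


def find_end_overlap(
    a: SequenceRecord,
    b: SequenceRecord,
    min_overlap: int = 1000,
    min_identity: float = 0.9,
) -> OverlapAlignment | None:
    """Find the best end-to-end overlap between two sequences.

    Both orientations of ``b`` are tried.  Returns the highest-scoring
    overlap (suffix of one partner against prefix of the other) whose
    identity over aligned columns (N excluded) reaches ``min_identity``
    and whose aligned length reaches ``min_overlap``; None otherwise.
    Ties are broken by longer aligned length, then forward orientation.
    """
    if len(a) < min_overlap or len(b) < min_overlap:
        return None
    candidates: list[tuple[int, int, int, OverlapAlignment]] = []
    for orientation in ("forward", "reverse"):
        b_seq = b.seq if orientation == "forward" else reverse_complement(b.seq)
        for d in _kmer_diagonals(a.seq, b_seq):
            # overlap window implied by diagonal d (a[i] ~ b[i-d]); widen by a
            # margin so indels inside the overlap do not truncate it
            margin = 200
            a_start = max(0, d - margin)
            a_end = min(len(a.seq), d + len(b_seq) + margin)
            b_start = max(0, -d - margin)
            b_end = min(len(b_seq), len(a.seq) - d + margin)
            # snap to sequence ends: an end overlap reaches an end of each partner
            if a_start <= margin:
                a_start = 0
            if len(a.seq) - a_end <= margin:
                a_end = len(a.seq)
            if b_start <= margin:
                b_start = 0
            if len(b_seq) - b_end <= margin:
                b_end = len(b_seq)
            sub_a = a.seq[a_start:a_end]
            sub_b = b_seq[b_start:b_end]
            if min(len(sub_a), len(sub_b)) < min_overlap:
                continue
            row_a, row_b = _align_columns(sub_a, sub_b)
            # the windows carry margin overhang into the partners'
            # non-overlapping regions; realign each boundary region with
            # the overhang end free so the overlap boundary is exact.  The
            # overhang can be displaced by the net indel shift inside the
            # overlap, so the region size includes the observed gap load.
            gap_load = row_a.count("-") + row_b.count("-")
            K = min(
                margin + abs(len(sub_a) - len(sub_b)) + gap_load + 200,
                max(len(row_a) // 2, 1),
            )
            if d != 0:
                overhang = "a" if d > 0 else "b"
                cut = min(len(row_a), K)
                na, nb, skip_a, skip_b = _realign_terminal(
                    row_a[:cut], row_b[:cut], overhang, left=True
                )
                row_a, row_b = na + row_a[cut:], nb + row_b[cut:]
                a_start += skip_a
                b_start += skip_b
            tail_a = len(a.seq) - d  # where a's sequence would end on b
            if tail_a != len(b_seq):
                overhang = "b" if tail_a < len(b_seq) else "a"
                cut = max(0, len(row_a) - K)
                na, nb, drop_a, drop_b = _realign_terminal(
                    row_a[cut:], row_b[cut:], overhang, left=False
                )
                row_a, row_b = row_a[:cut] + na, row_b[:cut] + nb
                a_end -= drop_a
                b_end -= drop_b
            # an end overlap must reach a sequence end on each edge
            slack = 300
            left_anchored = a_start <= slack or b_start <= slack
            right_anchored = (
                a_end >= len(a.seq) - slack or b_end >= len(b_seq) - slack
            )
            if not (left_anchored and right_anchored):
                continue
            matches, _mm, _gaps, valid = _column_stats(row_a, row_b)
            if valid == 0:
                continue
            identity = matches / valid
            aligned_length = len(row_a)
            if aligned_length < min_overlap or identity < min_identity:
                continue
            score = _score_columns(row_a, row_b)
            ov = OverlapAlignment(
                id_a=a.id,
                id_b=b.id,
                a_start=a_start,
                a_end=a_end,
                b_start=b_start,
                b_end=b_end,
                orientation=orientation,
                identity=identity,
                aligned_length=aligned_length,
                _columns=(row_a, row_b),
            )
            candidates.append((score, aligned_length, 1 if orientation == "forward" else 0, ov))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1], t[2]), reverse=True)
    return candidates[0][3]


def _raw_variants(row_a: str, row_b: str, a_start: int, b_start: int) -> list[VariantCall]:
    """Column-by-column SNP and indel calls from aligned rows."""
    variants: list[VariantCall] = []
    pa, pb = a_start, b_start
    i = 0
    n = len(row_a)
    while i < n:
        ca, cb = row_a[i], row_b[i]
        if ca == "-" or cb == "-":
            # gap run: insertion (b has extra) or deletion (a has extra)
            j = i
            ins = dele = ""
            while j < n and (row_a[j] == "-" or row_b[j] == "-"):
                if row_a[j] == "-":
                    ins += row_b[j]
                else:
                    dele += row_a[j]
                j += 1
            if dele:
                variants.append(
                    VariantCall("deletion", pa, pb, len(dele), allele_a=dele, allele_b="")
                )
            if ins:
                variants.append(
                    VariantCall("insertion", pa, pb, len(ins), allele_a="", allele_b=ins)
                )
            pa += len(dele)
            pb += len(ins)
            i = j
            continue
        if ca != cb and ca != "N" and cb != "N":
            variants.append(VariantCall("SNP", pa, pb, 1, allele_a=ca, allele_b=cb))
        pa += 1
        pb += 1
        i += 1
    return variants


def _mismatch_clusters(ov: OverlapAlignment, min_span: int, win: int = 50):
    """Dense low-identity regions of the raw overlap (candidate inversions).

    Identity is assessed in ``win``-column windows; windows with >= 40% bad
    columns are merged (bridging one good window), boundaries are expanded
    to adjacent bad columns and snapped to the first/last bad column.
    Yields (col_lo, col_hi, a_start, a_len, b_start, b_len): column range
    plus sequence coordinates, the b position anchored on the clean flank
    entering the region.
    """
    row_a, row_b = ov._columns
    bad_cols = []
    pa, pb = ov.a_start, ov.b_start
    col_pos = []
    for ca, cb in zip(row_a, row_b):
        col_pos.append((pa, pb))
        is_bad = (ca == "-" or cb == "-") or (ca != cb and ca != "N" and cb != "N")
        bad_cols.append(is_bad)
        if ca != "-":
            pa += 1
        if cb != "-":
            pb += 1
    col_pos.append((pa, pb))
    n = len(bad_cols)
    n_win = (n + win - 1) // win
    win_bad = [
        sum(bad_cols[w * win : (w + 1) * win]) / max(1, len(bad_cols[w * win : (w + 1) * win]))
        >= 0.4
        for w in range(n_win)
    ]
    clusters = []
    w = 0
    while w < n_win:
        if not win_bad[w]:
            w += 1
            continue
        w2 = w
        while w2 + 1 < n_win and (win_bad[w2 + 1] or (w2 + 2 < n_win and win_bad[w2 + 2])):
            w2 += 1
        lo, hi = w * win, min(n, (w2 + 1) * win)
        # expand outward over any contiguous tail of bad columns (the last
        # window of a tract may fall below the density mark), then snap
        # inward to the actual bad-column extent
        while hi < n and any(bad_cols[hi : hi + 8]):
            hi = min(n, hi + 8)
        while lo > 0 and any(bad_cols[max(0, lo - 8) : lo]):
            lo = max(0, lo - 8)
        while lo < hi and not bad_cols[lo]:
            lo += 1
        while hi > lo and not bad_cols[hi - 1]:
            hi -= 1
        if hi - lo >= max(20, min_span // 2):
            a0, b0 = col_pos[lo]
            a1, b1 = col_pos[hi]
            clusters.append((lo, hi, a0, a1 - a0, b0, b1 - b0))
        w = w2 + 1
    return clusters


def _refine_inversion(
    seq_a: str,
    seq_b: str,
    a_lo: int,
    alen: int,
    b_lo: int,
    blen: int,
    pad: int = 80,
    k: int = 13,
) -> tuple[int, int, int, float] | None:
    """Locate the maximal inverted tract inside a low-identity region.

    The candidate window of ``b`` is reverse-complemented, which turns the
    anti-diagonal structure of an inversion into an ordinary diagonal;
    k-mer matches on the dominant diagonal delimit the tract, which is
    then extended outward base by base.  Returns (a_start, length,
    b_start, identity) in overlap-local coordinates, or None.
    """
    off = b_lo - a_lo
    lo = max(0, a_lo - pad)
    hi = min(len(seq_a), a_lo + max(alen, blen) + pad)
    b_win_lo = max(0, lo + off)
    b_win_hi = min(len(seq_b), hi + off)
    A = seq_a[lo:hi]
    Bwin = seq_b[b_win_lo:b_win_hi]
    if len(A) < k or len(Bwin) < k:
        return None
    B = reverse_complement(Bwin)
    index = defaultdict(list)
    for i in range(len(A) - k + 1):
        index[A[i : i + k]].append(i)
    diag_hits: dict[int, list[int]] = defaultdict(list)
    for j in range(len(B) - k + 1):
        for i in index.get(B[j : j + k], ()):
            diag_hits[i - j].append(i)
    if not diag_hits:
        return None
    diag = max(diag_hits, key=lambda d: len(diag_hits[d]))
    hits = diag_hits[diag]
    i0, i1 = min(hits), max(hits) + k
    j0 = i0 - diag
    # per-base outward extension on the diagonal
    while i0 > 0 and i0 - diag > 0 and A[i0 - 1] == B[i0 - 1 - diag] != "N":
        i0 -= 1
    while (
        i1 < len(A)
        and i1 - diag < len(B)
        and A[i1] == B[i1 - diag] != "N"
    ):
        i1 += 1
    L = i1 - i0
    if L < k:
        return None
    j0, j1 = i0 - diag, i1 - diag
    a_start = lo + i0
    # B index j maps to Bwin index len(Bwin) - 1 - j
    b_start = b_win_lo + len(Bwin) - j1
    tract_a = seq_a[a_start : a_start + L]
    tract_b_rc = reverse_complement(seq_b[b_start : b_start + L])
    m = sum(1 for x, y in zip(tract_a, tract_b_rc) if x == y and x != "N")
    return a_start, L, b_start, m / L


def call_overlap_variants(
    ov: OverlapAlignment, min_inversion: int = 100, min_inv_identity: float = 0.9
) -> list[VariantCall]:
    """Enumerate SNPs, indels and inversions within an overlap.

    Inversions are detected first, on the raw alignment columns: a dense
    low-identity segment whose reverse complement aligns back at
    >= ``min_inv_identity`` is re-labelled as a single inversion and its
    internal mismatches are not double-counted as SNPs.  The remaining
    dirty regions are then re-aligned with affine gap scoring (so each
    large indel is one contiguous event), mismatch columns become SNPs and
    gap runs become insertions/deletions.  Variants are sorted by pos_a.
    """
    if ov._columns is None:
        raise ValueError("overlap carries no alignment columns")
    row_a, row_b = ov._columns
    seq_a = _reconstruct(row_a)
    seq_b = _reconstruct(row_b)
    inversions: list[VariantCall] = []
    masked: list[tuple[int, int]] = []
    skip_cols: list[tuple[int, int]] = []
    for col_lo, col_hi, a0, alen, b0, blen in _mismatch_clusters(ov, min_span=min_inversion):
        refined = _refine_inversion(
            seq_a, seq_b, a0 - ov.a_start, alen, b0 - ov.b_start, blen
        )
        if refined is None:
            continue
        s, L, bs, ident = refined
        if ident < min_inv_identity or L < min_inversion:
            continue
        a_abs, b_abs = s + ov.a_start, bs + ov.b_start
        if any(v.pos_a == a_abs and v.length == L for v in inversions):
            # a shredded storm can split into two clusters that both
            # resolve to the same tract
            masked.append((a0 - 5, a0 + alen + 5))
            continue
        inversions.append(
            VariantCall(
                "inversion",
                a_abs,
                b_abs,
                L,
                allele_a=seq_a[s : s + L],
                allele_b=seq_b[bs : bs + L],
            )
        )
        # mask the full dirty region around the tract: alignment shredding
        # can smear calls tens of bp outside the inverted segment
        masked.append((min(a0, a_abs) - 16, max(a0 + alen, a_abs + L) + 16))
        skip_cols.append((col_lo, col_hi))
    prow_a, prow_b = _polish_columns(row_a, row_b, skip_spans=skip_cols)
    variants = _raw_variants(prow_a, prow_b, ov.a_start, ov.b_start)
    if masked:
        variants = [
            v for v in variants if not any(s <= v.pos_a < e for s, e in masked)
        ]
    variants.extend(inversions)
    variants.sort(key=lambda v: (v.pos_a, v.kind))
    return variants


def _reconstruct(row: str) -> str:
    return row.replace("-", "")


@dataclass
class CodingEffect:
    variant: VariantCall
    gene: str
    region: str  # CDS | intron | intergenic
    effect: str  # synonymous | nonsynonymous | frameshift | not_applicable


def _cds_map(cds_parts: list[Feature]) -> tuple[list[tuple[int, int]], str, str]:
    """Sorted CDS intervals, strand and gene name for one gene model."""
    parts = sorted(cds_parts, key=lambda f: f.start)
    strand = parts[0].strand
    name = parts[0].name or "CDS"
    return [(p.start, p.end) for p in parts], strand, name


def classify_coding_effects(
    variants: list[VariantCall],
    cds_features: list[Feature],
    seq: SequenceRecord,
    gene_features: list[Feature] | None = None,
) -> list[CodingEffect]:
    """Classify overlap variants by coding effect against CDS gene models.

    Positions are taken on the ``a`` partner, which must be the sequence the
    features annotate.  SNPs inside a CDS are translated in both alleles
    with the standard genetic code; indels with length % 3 != 0 inside a
    CDS are frameshifts.
    """
    by_gene: dict[str, list[Feature]] = defaultdict(list)
    for f in cds_features:
        if f.kind == "CDS":
            by_gene[f.name or "CDS"].append(f)
    models = {}
    for gene, parts in by_gene.items():
        intervals, strand, name = _cds_map(parts)
        total = sum(e - s for s, e in intervals)
        if total % 3 != 0:
            raise ValueError(f"CDS model for gene {name!r} has length {total}, not a multiple of 3")
        models[gene] = (intervals, strand)
    gene_spans = {}
    if gene_features:
        for f in gene_features:
            if f.kind in ("gene", "pseudogene"):
                gene_spans[f.name] = (f.start, f.end)

    effects = []
    for v in variants:
        region, effect, gene_name = "intergenic", "not_applicable", ""
        for gene, (intervals, strand) in models.items():
            inside = any(s <= v.pos_a < e for s, e in intervals)
            if inside:
                region, gene_name = "CDS", gene
                if v.kind == "SNP":
                    effect = _snp_effect(v, intervals, strand, seq.seq)
                elif v.kind in ("insertion", "deletion"):
                    effect = "frameshift" if v.length % 3 != 0 else "not_applicable"
                break
            span = gene_spans.get(gene)
            if span is None and intervals:
                span = (intervals[0][0], intervals[-1][1])
            if span and span[0] <= v.pos_a < span[1]:
                region, gene_name = "intron", gene
                break
        effects.append(CodingEffect(variant=v, gene=gene_name, region=region, effect=effect))
    return effects


def _snp_effect(v: VariantCall, intervals: list[tuple[int, int]], strand: str, seq: str) -> str:
    cds = "".join(seq[s:e] for s, e in intervals)
    # index of the SNP within the concatenated CDS
    idx = 0
    for s, e in intervals:
        if s <= v.pos_a < e:
            idx += v.pos_a - s
            break
        idx += e - s
    alt_cds = cds[:idx] + v.allele_b + cds[idx + 1 :]
    if strand == "-":
        cds = reverse_complement(cds)
        alt_cds = reverse_complement(alt_cds)
        idx = len(cds) - 1 - idx
    ci = idx // 3
    ref_codon = cds[ci * 3 : ci * 3 + 3]
    alt_codon = alt_cds[ci * 3 : ci * 3 + 3]
    return "synonymous" if translate_cds(ref_codon) == translate_cds(alt_codon) else "nonsynonymous"


def scaffold_contigs(
    contigs: list[SequenceRecord],
    references: list[SequenceRecord],
    min_anchor: int = 500,
    min_identity: float = 0.9,
) -> ScaffoldLayout:
    """Order and orient contigs along reference sequences; estimate gaps.

    Each contig is placed at its best semi-global (infix) alignment against
    any reference, in either orientation.  Contigs without an anchor of at
    least ``min_anchor`` bp at >= ``min_identity`` go to ``unplaced``.
    Gaps between consecutive placed contigs are reference-projected
    distances between their facing ends, floored at 0 (floored joins are
    recorded in ``overlapping_joins``).
    """
    placements: list[Placement] = []
    unplaced: list[str] = []
    for contig in contigs:
        best: Placement | None = None
        if len(contig) >= min_anchor:
            for ri, ref in enumerate(references):
                for orientation in ("forward", "reverse"):
                    q = contig.seq if orientation == "forward" else reverse_complement(contig.seq)
                    max_k = int(len(q) * (1 - min_identity)) + 1
                    res = edlib.align(q, ref.seq, mode="HW", task="locations", k=max_k)
                    if res["editDistance"] < 0:
                        continue
                    loc = res["locations"][0]
                    ident = 1 - res["editDistance"] / len(q)
                    if ident < min_identity:
                        continue
                    score = len(q) - res["editDistance"] * 3  # penalise errors
                    cand = Placement(
                        contig_id=contig.id,
                        ref_id=ref.id,
                        ref_start=loc[0] if loc[0] is not None else 0,
                        ref_end=loc[1] + 1,
                        orientation=orientation,
                        identity=ident,
                        score=score,
                    )
                    if best is None or (cand.score, cand.identity) > (best.score, best.identity):
                        best = cand
        if best is None:
            unplaced.append(contig.id)
        else:
            placements.append(best)

    # resolve conflicting placements: overlapping on the same reference
    ref_order = {r.id: i for i, r in enumerate(references)}
    placements.sort(key=lambda p: (ref_order[p.ref_id], p.ref_start))
    kept: list[Placement] = []
    for p in placements:
        if kept and kept[-1].ref_id == p.ref_id and p.ref_start < kept[-1].ref_end - 50:
            loser = p if p.score <= kept[-1].score else kept[-1]
            winner = p if loser is not p else kept[-1]
            print(
                f"warning: placements of {p.contig_id} and {kept[-1].contig_id} overlap on "
                f"{p.ref_id}; demoting {loser.contig_id}",
                file=sys.stderr,
            )
            unplaced.append(loser.contig_id)
            kept[-1] = winner
        else:
            kept.append(p)

    gaps: list[int] = []
    floored: list[int] = []
    for prev, nxt in zip(kept, kept[1:]):
        if prev.ref_id != nxt.ref_id:
            continue
        gap = nxt.ref_start - prev.ref_end
        if gap < 0:
            floored.append(len(gaps))
            gap = 0
        gaps.append(gap)
    return ScaffoldLayout(placements=kept, gaps=gaps, unplaced=unplaced, overlapping_joins=floored)


def write_scaffold_tsv(layout: ScaffoldLayout, path) -> None:
    """AGP-like TSV: contig, reference, 1-based start, end, orientation, gap-after."""
    with open(path, "w") as fh:
        fh.write("contig\treference\tref_start\tref_end\torientation\tidentity\tgap_after\n")
        for i, p in enumerate(layout.placements):
            gap = layout.gaps[i] if i < len(layout.gaps) else ""
            fh.write(
                f"{p.contig_id}\t{p.ref_id}\t{p.ref_start + 1}\t{p.ref_end}\t"
                f"{p.orientation}\t{p.identity:.4f}\t{gap}\n"
            )
        for cid in layout.unplaced:
            fh.write(f"{cid}\t.\t.\t.\t.\t.\t.\n")
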