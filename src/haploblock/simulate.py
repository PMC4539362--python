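"""Synthetic haplotypes, clone sets and alignments with machine-readable truth.

The generator emulates the structure of the cattle MHC class Ia region at a
1:10 default scale: a haplotype of tandemly duplicated blocks each carrying
one class I gene (3 exons / 2 introns and a 3' region), gene starts spaced
like the duplication period, conserved flanks, optional gene-conversion
tracts with GC bias, SNP/indel/inversion implants in clone overlaps, and
fragmentation of a clone into ordered contigs with gaps.  Every implant is
recorded in a TruthRecord so downstream stages can be scored exactly.

One integer seed governs all randomness; each stage derives its own
substream from a fixed offset, so the same seed gives byte-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .seq_core import Feature, SequenceRecord, VariantCall, reverse_complement

BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Parameters of the haplotype generator (defaults at 1:10 paper scale)."""

    seed: int = 0
    block_length: int = 8000
    n_blocks: int = 4
    block_divergence: float = 0.05
    flank_length: int = 5000
    flank_divergence: float = 0.005
    indel_rate: float = 0.0
    indel_length_geometric_p: float = 0.1
    gene_spacing_range: tuple[int, int] | None = (6300, 6800)
    transition_transversion_kappa: float = 2.0
    gc_content: float = 0.45
    inversion_spec: tuple[int, int] | None = None  # (position, length)
    conversion_spec: tuple[int, int, int, float] | None = None  # (donor, recipient, tract_length, gc_bias)


@dataclass
class TruthRecord:
    implanted_variants: list[VariantCall] = field(default_factory=list)
    block_layout: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    conversion_tracts: list[dict] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)
    clone_layout: list[dict] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "implanted_variants": [asdict(v) for v in self.implanted_variants],
                    "block_layout": self.block_layout,
                    "conversion_tracts": self.conversion_tracts,
                    "features": [asdict(f) for f in self.features],
                    "clone_layout": self.clone_layout,
                    "extras": self.extras,
                },
                fh,
                indent=1,
            )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG-initiated coding sequence without internal stops."""
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(BASES[rng.integers(0, 4, size=3)])
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def mutate_substitutions(
    seq: str, rate: float, kappa: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Per-site substitutions: mutate with prob ``rate``; a mutation is a
    transition with probability kappa/(kappa+2), else a uniform transversion.
    Returns the mutated sequence and the substituted positions."""
    if rate <= 0:
        return seq, []
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    p_ts = kappa / (kappa + 2.0)
    ts_draw = rng.random(len(hits)) < p_ts
    tv_draw = rng.integers(0, 2, size=len(hits))
    for k, pos in enumerate(hits):
        base = arr[pos]
        if base == "N":
            continue
        arr[pos] = _TRANSITION[base] if ts_draw[k] else _TRANSVERSIONS[base][tv_draw[k]]
    return "".join(arr), [int(h) for h in hits]


def _gene_model(rng: np.random.Generator, offset: int = 500) -> tuple[str, list[Feature], int]:
    """A class-I-like gene: exons of 270/270/276 bp with 200/250-bp introns.

    Returns (gene sequence, features with coordinates relative to the block
    start assuming the gene begins at ``offset``, gene length)."""
    exon_lens = (270, 270, 276)
    intron_lens = (200, 250)
    cds = _random_cds(rng, sum(exon_lens) // 3)
    exon_seqs = [cds[:270], cds[270:540], cds[540:]]
    intron_seqs = [random_seq(rng, L, gc=0.45) for L in intron_lens]
    parts = [exon_seqs[0], intron_seqs[0], exon_seqs[1], intron_seqs[1], exon_seqs[2]]
    gene_seq = "".join(parts)
    feats: list[Feature] = []
    pos = offset
    labels = ["exon1", "intron1", "exon2", "intron2", "exon3"]
    kinds = ["exon", "intron", "exon", "intron", "exon"]
    for label, kind, part in zip(labels, kinds, parts):
        feats.append(Feature(seq_id="", kind=kind, start=pos, end=pos + len(part), name=label))
        if kind == "exon":
            feats.append(Feature(seq_id="", kind="CDS", start=pos, end=pos + len(part), name="gene"))
        pos += len(part)
    feats.insert(0, Feature(seq_id="", kind="gene", start=offset, end=pos, name="gene"))
    return gene_seq, feats, pos - offset


def _draw_indels(
    rng: np.random.Generator,
    length: int,
    rate: float,
    geom_p: float,
    forbidden: list[tuple[int, int]],
) -> list[tuple[int, int, int]]:
    """Indel events as (position, signed length, unused); avoid forbidden intervals."""
    if rate <= 0:
        return []
    n = rng.binomial(length, rate)
    events = []
    guard = 0
    while len(events) < n and guard < 100 * (n + 1):
        guard += 1
        pos = int(rng.integers(50, length - 50))
        L = int(rng.geometric(geom_p))
        sign = 1 if rng.random() < 0.5 else -1
        span = (pos, pos + (L if sign < 0 else 1))
        if any(s < span[1] and span[0] < e for s, e in forbidden):
            continue
        if any(abs(pos - p) < 50 + L for p, sl, _ in events):
            continue
        if span[1] > length - 50:
            continue
        events.append((pos, sign * L, 0))
    return events


def _apply_indels(seq: str, events, rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """Apply indels right-to-left; returns new sequence and (pos, shift) list."""
    out = seq
    shifts = []
    for pos, sL, _ in sorted(events, reverse=True):
        if sL < 0:
            out = out[:pos] + out[pos - sL :]
        else:
            out = out[:pos] + random_seq(rng, sL, 0.45) + out[pos:]
        shifts.append((pos, sL))
    return out, shifts


def _shift_coord(x: int, shifts: list[tuple[int, int]]) -> int:
    for pos, sL in shifts:
        if x > pos:
            x += sL if sL > 0 else max(sL, pos - x)
    return x


def simulate_haplotype(cfg: SimConfig, _mut_stream: int = 2) -> tuple[SequenceRecord, TruthRecord]:
    """Simulate one haplotype of tandem gene-bearing blocks with flanks.

    The ancestral block (length ``block_length``) carries one gene model;
    copies are the ancestral template truncated to the drawn gene spacing
    (so gene start-to-start distance equals the block period), each copy
    independently mutated at ``block_divergence``.  Flanks are emitted
    unmutated; inter-haplotype flank divergence is applied by
    :func:`simulate_haplotype_pair`.
    """
    rng_anc = _rng(cfg.seed, 1)
    rng_mut = _rng(cfg.seed, _mut_stream)
    rng_ev = _rng(cfg.seed, 3)

    template = list(random_seq(rng_anc, cfg.block_length, cfg.gc_content))
    gene_offset = 500
    gene_seq, gene_feats, gene_len = _gene_model(rng_anc, gene_offset)
    template[gene_offset : gene_offset + gene_len] = gene_seq
    template = "".join(template)
    exon_ivs = [(f.start, f.end) for f in gene_feats if f.kind == "exon"]

    left = random_seq(rng_anc, cfg.flank_length, cfg.gc_content)
    right = random_seq(rng_anc, cfg.flank_length, cfg.gc_content)

    # per-copy lengths: spacing = start-to-start distance; last copy full length
    lengths = []
    for k in range(cfg.n_blocks):
        if cfg.gene_spacing_range is None or k == cfg.n_blocks - 1:
            lengths.append(cfg.block_length)
        else:
            lo, hi = cfg.gene_spacing_range
            lengths.append(int(rng_anc.integers(lo, hi + 1)))

    truth = TruthRecord()
    copies: list[str] = []
    copy_feats: list[list[Feature]] = []
    for k in range(cfg.n_blocks):
        unit = template[: lengths[k]]
        mutated, _subs = mutate_substitutions(
            unit, cfg.block_divergence, cfg.transition_transversion_kappa, rng_mut
        )
        events = _draw_indels(
            rng_mut, len(mutated), cfg.indel_rate, cfg.indel_length_geometric_p, exon_ivs
        )
        mutated, shifts = _apply_indels(mutated, events, rng_mut)
        feats = [
            Feature(
                seq_id="",
                kind=f.kind,
                start=_shift_coord(f.start, shifts),
                end=_shift_coord(f.end, shifts),
                name=f"{f.name}_copy{k + 1}" if f.kind in ("gene",) else f.name,
                strand=f.strand,
            )
            for f in gene_feats
        ]
        copies.append(mutated)
        copy_feats.append(feats)

    # optional conversion between copies (applied on copy-local coordinates)
    if cfg.conversion_spec is not None:
        donor, recipient, tract_len, gc_bias = cfg.conversion_spec
        if tract_len > min(len(copies[donor]), len(copies[recipient])):
            raise ValueError("conversion tract exceeds block length")
        start = int(rng_ev.integers(0, min(len(copies[donor]), len(copies[recipient])) - tract_len))
        rec = list(copies[recipient])
        don = copies[donor]
        for i in range(start, start + tract_len):
            if don[i] != rec[i]:
                if rng_ev.random() < gc_bias:
                    gc_allele = don[i] if don[i] in "GC" else (rec[i] if rec[i] in "GC" else don[i])
                    rec[i] = gc_allele
                else:
                    rec[i] = don[i]
        copies[recipient] = "".join(rec)
        truth.conversion_tracts.append(
            {"donor": donor, "recipient": recipient, "start": start, "end": start + tract_len}
        )

    # assemble haplotype
    parts = [left] + copies + [right]
    seq = "".join(parts)
    offset = len(left)
    feats_all: list[Feature] = []
    for k, (copy_seq, feats) in enumerate(zip(copies, copy_feats)):
        truth.block_layout.append((k, (offset, offset + len(copy_seq))))
        for f in feats:
            feats_all.append(
                Feature(
                    seq_id="hap",
                    kind=f.kind,
                    start=f.start + offset,
                    end=f.end + offset,
                    name=f.name if f.kind != "gene" else f.name,
                    strand=f.strand,
                )
            )
        offset += len(copy_seq)

    if cfg.inversion_spec is not None:
        pos, L = cfg.inversion_spec
        if pos + L > len(seq):
            raise ValueError("inversion outside sequence")
        seq = seq[:pos] + reverse_complement(seq[pos : pos + L]) + seq[pos + L :]
        truth.implanted_variants.append(
            VariantCall("inversion", pos, pos, L, allele_a=seq[pos : pos + L])
        )

    truth.features = feats_all
    truth.extras["copy_lengths"] = lengths
    truth.extras["flank_length"] = cfg.flank_length
    rec = SequenceRecord(id="hap", seq=seq, description=f"simulated haplotype seed={cfg.seed}")
    return rec, truth


def simulate_haplotype_pair(
    cfg: SimConfig, n_blocks_b: int | None = None
) -> tuple[SequenceRecord, TruthRecord, SequenceRecord, TruthRecord]:
    """Two haplotypes sharing ancestry: conserved flanks, diverged blocks.

    Haplotype B shares the ancestral template and flanks with A; its copies
    are mutated independently at ``block_divergence`` and its flanks at
    ``flank_divergence``, and it may carry a different block count
    (copy-number variation between haplotypes).
    """
    hap_a, truth_a = simulate_haplotype(cfg)
    cfg_b = SimConfig(**{**asdict_cfg(cfg), "n_blocks": n_blocks_b or cfg.n_blocks})
    # same ancestral stream (shared template and flanks), independent mutations
    hap_b, truth_b = simulate_haplotype(cfg_b, _mut_stream=12)
    # diverge B's flanks at flank_divergence
    rng_f = _rng(cfg.seed, 13)
    fl = cfg.flank_length
    left_b, _ = mutate_substitutions(hap_b.seq[:fl], cfg.flank_divergence, cfg.transition_transversion_kappa, rng_f)
    right_b, _ = mutate_substitutions(hap_b.seq[-fl:], cfg.flank_divergence, cfg.transition_transversion_kappa, rng_f)
    seq_b = left_b + hap_b.seq[fl:-fl] + right_b
    hap_b = SequenceRecord(id="hapB", seq=seq_b, description=hap_b.description)
    hap_a = SequenceRecord(id="hapA", seq=hap_a.seq, description=hap_a.description)
    for f in truth_a.features:
        f.seq_id = "hapA"
    for f in truth_b.features:
        f.seq_id = "hapB"
    return hap_a, truth_a, hap_b, truth_b


def asdict_cfg(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    return d


def _required_sep(min_separation: int, e1: int, e2: int) -> int:
    if e1 > 20 and e2 > 20:
        return max(min_separation, e1 + e2)
    return min_separation


def simulate_clones(
    hap: SequenceRecord,
    layout: list[tuple[int, int]],
    snp_count: int = 0,
    indel_spec: tuple[tuple[str, int], ...] = (),
    inversion_spec: int | None = None,
    seed: int = 0,
    min_separation: int = 50,
) -> tuple[list[SequenceRecord], TruthRecord]:
    """Cut a haplotype into overlapping clones and implant variants.

    ``layout`` gives clone intervals on the haplotype.  For each pair of
    consecutive overlapping clones, the requested variants are implanted
    into the *later* clone, confined to the overlap, with pairwise
    separation >= ``min_separation`` bp.  Truth positions are in the
    coordinates of the earlier clone (pos_a) and later clone (pos_b).
    """
    rng = _rng(seed, 21)
    clones = [
        SequenceRecord(id=f"clone{i + 1}", seq=hap.seq[s:e], description=f"{s}-{e}")
        for i, (s, e) in enumerate(layout)
    ]
    truth = TruthRecord()
    truth.clone_layout = [{"id": c.id, "start": s, "end": e} for c, (s, e) in zip(clones, layout)]

    for i in range(len(layout) - 1):
        (a_s, a_e), (b_s, b_e) = layout[i], layout[i + 1]
        ov_s, ov_e = max(a_s, b_s), min(a_e, b_e)
        if ov_e - ov_s <= 0:
            continue
        # reserve loci: (global_pos, extent)
        wanted: list[tuple[str, int]] = []
        if inversion_spec:
            wanted.append(("inversion", inversion_spec))
        for kind, L in indel_spec:
            wanted.append((kind, L))
        wanted.extend(("SNP", 1) for _ in range(snp_count))
        margin = 1000 if (ov_e - ov_s) >= 3000 else max(300, (ov_e - ov_s) // 10)
        placed: list[tuple[str, int, int]] = []  # kind, global pos, extent
        comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
        for kind, extent in wanted:
            ok = False
            for _ in range(100):
                pos = int(rng.integers(ov_s + margin, ov_e - margin - extent))
                if not all(
                    # two large events too close are not recoverable as
                    # implanted: an aligner can merge a nearby deletion and
                    # insertion into a cheaper mismatch run, so large pairs
                    # need separation comparable to their combined size
                    pos + extent + _required_sep(min_separation, extent, e2) <= p
                    or p + e2 + _required_sep(min_separation, extent, e2) <= pos
                    for _, p, e2 in placed
                ):
                    continue
                if kind == "inversion":
                    # an inverted tract whose flanks are complement-symmetric is
                    # indistinguishable from a longer inversion; forbid such flanks
                    # so the implanted boundaries are the unique maximal call
                    if hap.seq[pos - 1] == comp[hap.seq[pos + extent]]:
                        continue
                placed.append((kind, pos, extent))
                ok = True
                break
            if not ok:
                raise ValueError("could not place implants without collisions")
        # apply to clone i+1, right to left
        b_seq = clones[i + 1].seq
        variants: list[VariantCall] = []
        for kind, pos, extent in sorted(placed, key=lambda t: -t[1]):
            lb = pos - b_s  # local position in clone b
            la = pos - a_s  # position in clone a coordinates
            if kind == "SNP":
                ref = b_seq[lb]
                alt_choices = [c for c in "ACGT" if c != ref]
                alt = alt_choices[int(rng.integers(0, 3))]
                b_seq = b_seq[:lb] + alt + b_seq[lb + 1 :]
                variants.append(VariantCall("SNP", la, lb, 1, allele_a=ref, allele_b=alt))
            elif kind == "deletion":
                removed = b_seq[lb : lb + extent]
                b_seq = b_seq[:lb] + b_seq[lb + extent :]
                variants.append(VariantCall("deletion", la, lb, extent, allele_a=removed))
            elif kind == "insertion":
                ins = random_seq(rng, extent, 0.45)
                b_seq = b_seq[:lb] + ins + b_seq[lb:]
                variants.append(VariantCall("insertion", la, lb, extent, allele_b=ins))
            elif kind == "inversion":
                tract = b_seq[lb : lb + extent]
                b_seq = b_seq[:lb] + reverse_complement(tract) + b_seq[lb + extent :]
                variants.append(
                    VariantCall("inversion", la, lb, extent, allele_a=tract,
                                allele_b=reverse_complement(tract))
                )
        clones[i + 1] = SequenceRecord(id=clones[i + 1].id, seq=b_seq,
                                       description=clones[i + 1].description)
        variants.sort(key=lambda v: v.pos_a)
        truth.implanted_variants.extend(variants)
    return clones, truth


def simulate_fragmented_clone(
    hap: SequenceRecord,
    region: tuple[int, int],
    spacer_lengths: list[int],
    seed: int = 0,
    shuffle: bool = True,
    allow_reverse: bool = True,
    min_contig: int = 800,
) -> tuple[list[SequenceRecord], TruthRecord]:
    """Fragment a region into ordered contigs separated by deleted spacers.

    ``spacer_lengths`` has one entry per inter-contig gap, so the region is
    cut into len(spacer_lengths)+1 contigs.  Contigs are optionally shuffled
    and reverse-complemented (truth records order and orientation).
    """
    rng = _rng(seed, 31)
    start, end = region
    n_contigs = len(spacer_lengths) + 1
    total_spacer = sum(spacer_lengths)
    usable = end - start - total_spacer
    if usable < n_contigs * min_contig:
        raise ValueError("region too small for requested fragmentation")
    # contig lengths: random composition with a floor that keeps every
    # contig anchorable
    slack = usable - n_contigs * min_contig
    cuts = sorted(rng.choice(slack, size=n_contigs - 1, replace=False))
    lens = np.diff([0] + [int(c) for c in cuts] + [slack]) + min_contig
    contigs = []
    truth = TruthRecord()
    pos = start
    for i, L in enumerate(lens):
        seq = hap.seq[pos : pos + int(L)]
        contigs.append((i, pos, pos + int(L), seq))
        pos += int(L)
        if i < len(spacer_lengths):
            pos += spacer_lengths[i]
    order = list(range(n_contigs))
    if shuffle:
        rng.shuffle(order)
    records = []
    for rank, idx in enumerate(order):
        i, s, e, seq = contigs[idx]
        orientation = "forward"
        if allow_reverse and rng.random() < 0.5:
            seq = reverse_complement(seq)
            orientation = "reverse"
        rec = SequenceRecord(id=f"contig{i + 1}", seq=seq)
        records.append(rec)
        truth.clone_layout.append(
            {"id": rec.id, "start": s, "end": e, "orientation": orientation, "true_index": i}
        )
    truth.extras["spacer_lengths"] = list(spacer_lengths)
    truth.extras["region"] = list(region)
    return records, truth


def simulate_gc_gene(
    seed: int = 0,
    background_gc: float = 0.40,
    tract_gc: float = 0.80,
    tract_length: int = 300,
    gene_length: int = 10000,
    at_junctions: bool = True,
) -> tuple[SequenceRecord, list[Feature], list[tuple[int, int]]]:
    """A gene-sized sequence with high-GC tracts at 5' intron/exon junctions.

    Returns (sequence, exon/intron features, implanted tract intervals).
    With ``at_junctions`` the tracts sit at the starts of introns 1, 2 and 3
    (the pattern expected from GC-biased gene conversion near conversion
    breakpoints); otherwise a single tract is placed mid-sequence.
    """
    rng = _rng(seed, 41)
    seq = list(random_seq(rng, gene_length, background_gc))
    exon_lens = (270, 270, 276)
    intron_lens = (1200, 1500)
    feats: list[Feature] = []
    pos = 800
    labels = ["exon1", "intron1", "exon2", "intron2", "exon3", "intron3"]
    lens = [exon_lens[0], intron_lens[0], exon_lens[1], intron_lens[1], exon_lens[2], 2000]
    for label, L in zip(labels, lens):
        kind = "exon" if label.startswith("exon") else "intron"
        feats.append(Feature(seq_id="gene", kind=kind, start=pos, end=pos + L, name=label))
        pos += L
    tracts: list[tuple[int, int]] = []
    if at_junctions:
        for f in feats:
            if f.kind == "intron":
                tracts.append((f.start, f.start + tract_length))
    else:
        mid = gene_length // 2
        tracts.append((mid, mid + tract_length))
    for s, e in tracts:
        seq[s:e] = list(random_seq(rng, e - s, tract_gc))
    return SequenceRecord(id="gene", seq="".join(seq)), feats, tracts


def simulate_alignment(
    tree,
    length: int,
    seed: int = 0,
    theta: float = 0.5,
    kappa: float = 2.0,
    conversion: dict | None = None,
) -> tuple[list[str], list[str], TruthRecord]:
    """Evolve a gapless alignment down a tree column-independently.

    ``tree`` is a :class:`haploblock.phylo.Tree` (branch lengths in expected
    substitutions/site).  Sites substitute with probability 1 - exp(-t) per
    branch; a substitution is a transition with probability kappa/(kappa+2).
    The root sequence is drawn at GC fraction ``theta``.

    ``conversion`` = {donor, recipient, start, end, gc_bias} copies donor
    residues into the recipient over [start, end): at each differing site
    the GC-bearing allele is chosen with probability gc_bias, else the
    donor allele.
    """
    rng = _rng(seed, 51)
    root_seq = random_seq(rng, length, theta)
    rows: dict[str, str] = {}

    def evolve(node, seq: str) -> None:
        p = 1.0 - np.exp(-node.length)
        mutated, _ = mutate_substitutions(seq, p, kappa, rng)
        if node.is_leaf():
            rows[node.name] = mutated
        else:
            for c in node.children:
                evolve(c, mutated)

    for child in tree.root.children:
        evolve(child, root_seq)

    truth = TruthRecord()
    if conversion is not None:
        s, e = conversion["start"], conversion["end"]
        if not (0 <= s < e <= length):
            raise ValueError("conversion interval outside alignment")
        don = rows[conversion["donor"]]
        rec = list(rows[conversion["recipient"]])
        gc_bias = conversion.get("gc_bias", 0.0)
        for i in range(s, e):
            if don[i] != rec[i]:
                if rng.random() < gc_bias:
                    rec[i] = don[i] if don[i] in "GC" else (rec[i] if rec[i] in "GC" else don[i])
                else:
                    rec[i] = don[i]
        rows[conversion["recipient"]] = "".join(rec)
        truth.conversion_tracts.append(dict(conversion))

    names = sorted(rows)
    return names, [rows[n] for n in names], truth
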