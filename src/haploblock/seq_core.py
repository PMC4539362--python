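"""Core domain types and I/O for sequences, annotations and variant calls.

Coordinates are 0-based half-open everywhere inside the package; readers
convert from the 1-based inclusive conventions of GFF3/GenBank-style input,
and human-readable reports convert back on output.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("gene", "pseudogene", "exon", "intron", "CDS", "region")


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A, C, G, T, N}."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.seq = self.seq.upper().replace("U", "T")
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"record {self.id!r}: invalid character {self.seq[pos]!r} at position {pos + 1}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """An annotated interval on a sequence (0-based half-open)."""

    seq_id: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""
    phase: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class VariantCall:
    """A difference between two aligned sequences.

    ``pos_a``/``pos_b`` are 0-based positions on each partner.  For an
    insertion (sequence present in b only) ``allele_a`` is empty; for a
    deletion (present in a only) ``allele_b`` is empty.  Inversions carry
    the forward-strand alleles of both partners.
    """

    kind: str  # SNP | insertion | deletion | inversion
    pos_a: int
    pos_b: int
    length: int
    allele_a: str = ""
    allele_b: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "insertion", "deletion", "inversion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.kind == "SNP":
            if self.length != 1:
                raise ValueError("SNP must have length 1")
            if self.allele_a == self.allele_b:
                raise ValueError("SNP alleles must differ")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; N maps to N."""
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters for reverse complement: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased and U is mapped to T; any character outside
    {A, C, G, T, N, U} raises with the offending record and position.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=rec.description))
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA wrapped at ``wrap`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_features(path: str | Path, dialect: str = "gff3") -> list[Feature]:
    """Read features from GFF3 or a 5-column table (name, kind, start, end, strand).

    Input coordinates are 1-based inclusive; output features are 0-based
    half-open.  Unknown kinds are demoted to ``region`` with a warning.
    """
    if dialect not in ("gff3", "table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if dialect == "gff3":
                if len(cols) < 8:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
                seq_id, _src, kind, start_s, end_s, _score, strand, phase_s = cols[:8]
                attrs = _parse_gff3_attributes(cols[8]) if len(cols) > 8 else {}
                name = attrs.get("Name") or attrs.get("ID") or ""
                phase = int(phase_s) if phase_s.isdigit() else 0
            else:
                if len(cols) < 5:
                    cols = line.split()
                if len(cols) < 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns")
                name, kind, start_s, end_s, strand = cols[:5]
                seq_id, phase = "", 0
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            if kind not in FEATURE_KINDS:
                print(
                    f"warning: {path}:{lineno}: unknown kind {kind!r}, treating as region",
                    file=sys.stderr,
                )
                kind = "region"
            features.append(
                Feature(
                    seq_id=seq_id,
                    kind=kind,
                    start=start - 1,
                    end=end,
                    strand=strand if strand in "+-" else "+",
                    name=name,
                    phase=phase,
                )
            )
    return features


def write_features(features: Sequence[Feature], path: str | Path) -> None:
    """Write features as GFF3 (coordinates back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"Name={f.name}" if f.name else "."
            fh.write(
                "\t".join(
                    [
                        f.seq_id or ".",
                        "haploblock",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        str(f.phase) if f.kind == "CDS" else ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_variants_vcf(
    variants: Sequence[VariantCall],
    chrom: str,
    ref_seq: str,
    path: str | Path,
) -> None:
    """Write variant calls as a minimal VCF.

    SNPs and indels use REF/ALT with the usual left-anchor base convention;
    inversions are written as symbolic ``<INV>`` with END and SVLEN.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##ALT=<ID=INV,Description="Inversion">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: v.pos_a):
            if v.kind == "SNP":
                fh.write(
                    f"{chrom}\t{v.pos_a + 1}\t.\t{v.allele_a}\t{v.allele_b}\t.\t.\t.\n"
                )
            elif v.kind == "inversion":
                fh.write(
                    f"{chrom}\t{v.pos_a + 1}\t.\tN\t<INV>\t.\t.\t"
                    f"END={v.pos_a + v.length};SVLEN={v.length}\n"
                )
            else:
                # anchor on the base before the event
                anchor_pos = max(v.pos_a - 1, 0)
                anchor = ref_seq[anchor_pos] if ref_seq else "N"
                if v.kind == "deletion":
                    ref = anchor + v.allele_a
                    alt = anchor
                else:
                    ref = anchor
                    alt = anchor + v.allele_b
                fh.write(f"{chrom}\t{anchor_pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


def translate_cds(cds_seq: str) -> str:
    """Translate a coding sequence with the standard genetic code."""
    return str(Seq(cds_seq).translate())
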