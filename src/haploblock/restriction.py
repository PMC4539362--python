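"""In-silico restriction digestion and gel-profile matching.

Digesting an assembled BAC clone with HindIII in silico and matching the
fragment sizes against the gel-derived (Southern) profile validates that
the assembly represents the physical clone.  Fragment matching is
tolerance-based because gel sizing is imprecise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .seq_core import SequenceRecord


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError("cut_offset outside site")
        if set(self.site) - set("ACGT"):
            raise ValueError("site must contain only A, C, G, T")


# HindIII cuts A^AGCTT
ENZYMES = {
    "HindIII": Enzyme("HindIII", "AAGCTT", 1),
    "EcoRI": Enzyme("EcoRI", "GAATTC", 1),
    "BamHI": Enzyme("BamHI", "GGATCC", 1),
}


@dataclass
class FragmentProfile:
    """Multiset of restriction fragment lengths from one digest."""

    source: str
    fragments: list[int]
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.fragments = sorted(self.fragments)

    @property
    def total(self) -> int:
        return sum(self.fragments)


@dataclass
class ProfileMatch:
    matched: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]

    @property
    def concordant(self) -> bool:
        return not self.unmatched_a and not self.unmatched_b


def _site_positions(seq: str, site: str) -> list[int]:
    """All (possibly overlapping) occurrence starts of site in seq."""
    positions = []
    start = 0
    while True:
        i = seq.find(site, start)
        if i < 0:
            break
        positions.append(i)
        start = i + 1
    return positions


def digest(seq: SequenceRecord, enzyme: Enzyme, topology: str = "linear") -> FragmentProfile:
    """Digest a sequence; fragment lengths from sorted cut positions.

    A linear molecule with k cut sites yields k+1 fragments; a circular
    molecule yields max(k, 1).  Sites containing N are never called (exact
    string match, so this falls out naturally).
    """
    if topology not in ("linear", "circular"):
        raise ValueError(f"unknown topology {topology!r}")
    s = seq.seq
    n = len(s)
    site, off = enzyme.site, enzyme.cut_offset
    if topology == "linear":
        cuts = sorted(p + off for p in _site_positions(s, site))
        bounds = [0] + cuts + [n]
        frags = [b - a for a, b in zip(bounds, bounds[1:]) if b > a]
        if not frags:
            frags = [n]
    else:
        # scan across the origin by extending with a site-length-1 prefix
        extended = s + s[: len(site) - 1]
        cuts = sorted((p + off) % n for p in _site_positions(extended, site) if p < n)
        if not cuts:
            frags = [n]
        else:
            frags = [b - a for a, b in zip(cuts, cuts[1:])]
            frags.append(n - cuts[-1] + cuts[0])
    return FragmentProfile(source=seq.id, fragments=frags, topology=topology)


def read_profile(path: str | Path, source: str | None = None) -> FragmentProfile:
    """Read an experimental size list: one integer bp per line, '#' comments."""
    fragments = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if line:
                fragments.append(int(float(line)))
    return FragmentProfile(source=source or str(path), fragments=fragments)


def match_profiles(
    a: FragmentProfile,
    b: FragmentProfile,
    rel_tol: float = 0.05,
    abs_tol: int = 50,
    min_fragment: int = 500,
) -> ProfileMatch:
    """Tolerance-based greedy matching of two fragment profiles.

    Fragments x and y match when |x - y| <= max(abs_tol, rel_tol * max(x, y)).
    Matching is greedy on sorted sizes, largest first (deterministic).
    Fragments below ``min_fragment`` are excluded (unresolved on gels);
    set ``min_fragment=0`` to keep everything.
    """
    fa = sorted((f for f in a.fragments if f >= min_fragment), reverse=True)
    fb = sorted((f for f in b.fragments if f >= min_fragment), reverse=True)
    used_b = [False] * len(fb)
    matched: list[tuple[int, int]] = []
    unmatched_a: list[int] = []
    for x in fa:
        best_j = -1
        best_diff = None
        for j, y in enumerate(fb):
            if used_b[j]:
                continue
            diff = abs(x - y)
            if diff <= max(abs_tol, rel_tol * max(x, y)):
                if best_diff is None or diff < best_diff:
                    best_diff, best_j = diff, j
        if best_j >= 0:
            used_b[best_j] = True
            matched.append((x, fb[best_j]))
        else:
            unmatched_a.append(x)
    unmatched_b = [y for j, y in enumerate(fb) if not used_b[j]]
    return ProfileMatch(matched=matched, unmatched_a=sorted(unmatched_a), unmatched_b=sorted(unmatched_b))


def write_match_tsv(m: ProfileMatch, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("status\tsize_a\tsize_b\n")
        for x, y in m.matched:
            fh.write(f"matched\t{x}\t{y}\n")
        for x in m.unmatched_a:
            fh.write(f"unmatched_a\t{x}\t.\n")
        for y in m.unmatched_b:
            fh.write(f"unmatched_b\t.\t{y}\n")
        fh.write(f"# concordant: {m.concordant}\n")
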