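# Methods

## Scope and coordinate conventions

`haploblock` analyses assembled nucleotide sequences (BAC clones or whole
haplotypes) of an MHC-class-I-like locus: a region of tandemly duplicated
gene-bearing blocks flanked by conserved single-copy sequence. All internal
coordinates are 0-based half-open; GFF3/table readers convert from 1-based
inclusive input and report writers convert back. Lowercase input is
uppercased (soft-masking is discarded), U maps to T, and N is permitted but
never counts as a match in any identity or distance computation.

## Clone end-overlaps and variant calling

Two clones from one haplotype should tile: a suffix of one is near-identical
to a prefix of the other. Detection seeds on shared 31-mers (sparse index on
one sequence, dense scan of the other, so every diagonal is reachable),
clusters seed diagonals into candidate offsets — several candidates are kept
because tandem blocks induce strong false diagonals one period away — and
aligns the implied span globally with edlib. Because unit edit costs leave
large-indel placement degenerate (a long gap can be fragmented at no cost),
the boundary regions are re-aligned with affine gap scoring (match +1,
mismatch −2, gap open −4, extend −1) with the overhanging end free, which
pins the overlap boundary exactly; candidates that do not reach a sequence
end on both edges (repeat-induced internal alignments) are rejected, and the
best survivor by affine score wins, ties broken by longer alignment, then
forward orientation.

Variant calling works on the alignment columns. Inversions are found first,
on the raw columns: windows with ≥ 40% mismatch/gap columns merge into
low-identity candidate regions; each region's partner window is
reverse-complemented, which turns an inversion's anti-diagonal into an
ordinary diagonal, and k-mer seeding plus per-base extension delimits the
maximal inverted tract. A tract is accepted when its reverse complement
aligns back at ≥ 90% identity and it reaches the minimum inversion length
(default 100 bp); its interior mismatches are masked so they are not
double-counted as SNPs. An inversion whose flanking bases are
complement-symmetric is inherently ambiguous (a symmetric extension of an
inverted tract is still a perfect inversion); the caller reports the maximal
tract. Remaining dirty regions are then re-aligned with the affine scorer so
each large indel is one contiguous event; mismatch columns become SNPs
(adjacent mismatches are separate SNPs, not MNPs) and gap runs become
insertions/deletions. Reports flag indels ≥ 100 bp separately.

Coding effects: each SNP inside a CDS model (joined length must be divisible
by 3) is translated in both alleles with the standard code — identical amino
acid ⇒ synonymous; indels with length mod 3 ≠ 0 inside a CDS are
frameshifts. Strand-aware via reverse complement of the joined CDS.

## Scaffolding

Each contig is placed at its best semi-global (infix) alignment against any
reference, both orientations, using edlib; a placement needs ≥ 90% identity
and the contig must reach the minimum anchor length. Conflicting overlapping
placements keep the higher score and demote the loser to unplaced with a
warning. Gaps between consecutive placements are reference-projected
distances between facing ends, floored at zero (floored joins are recorded).

## Restriction fingerprints

Digestion finds every (possibly overlapping) occurrence of the recognition
site and cuts at the top-strand offset; linear molecules with k sites give
k+1 fragments, circular give max(k, 1), and fragment lengths always sum to
the sequence length. A site containing N is never called. Note that a
palindromic but staggered cutter (HindIII, A^AGCTT, offset 1) is *not*
exactly strand-invariant on linear molecules: the two terminal fragments
shift by site_len − 2·offset = 4 bp under reverse complement; interior
(site-to-site) fragments, and all circular fragments, are invariant.
Profile matching is greedy largest-first with tolerance
|x − y| ≤ max(50 bp, 5% of the larger) — gel sizing error — and fragments
below 500 bp are excluded by default as unresolvable on gels; tests check
the greedy matching against a brute-force assignment oracle on small
profiles.

## Identity matrices and duplication blocks

The dot-matrix comparison computes ungapped exact-match fractions of 200-bp
windows (default step window/4, subsampled to ≤ 2,000 windows per axis on
long inputs). A subtlety matters here: a plain window grid only registers
repeats whose offset is a multiple of the step — a tandem unit of 6,621 bp
is invisible to a 50-bp-step grid. `identity_matrix(..., phase_max=True)`
therefore evaluates identity at base-pair diagonal resolution and max-pools
onto the grid (what a zoomed-out dot plot renders); the comparison pipeline
uses this mode. For chromosome-scale inputs, `detect_blocks_seeded` skips
the quadratic matrix entirely: candidate repeat offsets come from a k-mer
self-match histogram and windowed identity is evaluated only along those
diagonals (assumes colinear copies, i.e. no large indels between them).

Blocks are connected runs of cells ≥ 0.7 identity (8-connectivity, so
one-step offset jitter merges), discarding runs shorter than the minimum
block length; in self-comparison the main diagonal is excluded and mirror
images are reported once (a_start < b_start). The period estimate clusters
block offsets with tolerance 2 × step, takes the best-supported cluster's
mean, and sets copy number to 1 + round(max offset / period). Gene spacing
is start-to-start (equal to the duplication period when blocks are tandem);
end-to-start distances are also reported for transparency.

## GC scan

GC fraction per 100-bp window at 1-bp step (a step parameter exists for
speed), N excluded from the denominator, all-N windows recorded as missing.
The mean/SD baseline is computed per scanned gene, not genome-wide, and on
unclipped values. Windows ≥ 2.5 SD above the mean (direction "high" by
default; "low"/"both" available) merge into maximal anomaly intervals;
nearby window runs whose 100-bp spans overlap are merged so intervals stay
disjoint. Anomalies associate with the closest exon boundary within 200 bp.

## Segment-partitioned phylogenetics

Pairwise T92 distances use pairwise deletion of gap/N columns and a per-pair
GC estimate θ (an alignment-wide θ is a flag); the distance is undefined at
saturation (log argument ≤ 0), which raises a dedicated error, and with
θ = 0.5 the formula reduces to Kimura's two-parameter distance. NJ is the
canonical Saitou–Nei algorithm; ties on the Q-criterion break toward the
lowest taxon-index pair (deterministic), negative branch lengths clamp to
zero, and the result is unrooted (trifurcating root). Robinson–Foulds is
the symmetric difference of non-trivial bipartitions; monophyly of a taxon
group means some bipartition equals the group. The congruence scan builds a
T92+NJ tree per partition segment (segments with < 50 valid columns or a
saturated pair are skipped with a warning), computes all pairwise RF
distances, and flags adjacent analysed segments with RF > 0 as candidate
gene-conversion breakpoints at their shared boundary. NJ on T92 distances
stands in for a maximum-likelihood search deliberately: the claims the
package makes are topology-level (monophyly, incongruence), it is exactly
reproducible, and it is fast enough to run per segment.

## The synthetic-data generator

The generator is first-class, tested code and the source of ground truth
for every stage. A haplotype is built from an ancestral block (default
8,000 bp — a 1:10-scale stand-in for the ~80-kb unit of the real locus)
carrying one class-I-like gene model (exons of 270/270/276 bp, ATG-initiated
stop-free CDS, 200/250-bp introns); copies are the template truncated to a
per-copy spacing drawn uniformly from 6,300–6,800 bp (1:10 scale of the
63–68-kb gene spacing), so gene start-to-start distance equals the block
period by construction; each copy is mutated independently at the block
divergence (default 0.05 per site) under a minimal κ-weighted scheme
(transition with probability κ/(κ+2), κ = 2 by default), with optional
geometric-length indels that never hit exons; conserved flanks (5,000 bp)
complete the sequence. A haplotype pair shares the ancestral template and
flanks, mutates copies independently, diverges flanks at 0.005 per site,
and may differ in copy number. Clone sets are substrings with variants
implanted only in designated overlaps; implant positions keep ≥ 50 bp
separation, large event pairs keep separation comparable to their combined
size (a nearby deletion/insertion pair is otherwise genuinely
unrecoverable: the optimal alignment merges them into a cheaper mismatch
run), and implanted inversions are placed so their flanks are not
complement-symmetric, making the implanted boundaries the unique maximal
call. Alignments evolve column-independently down a given tree (substitute
with probability 1 − e^(−t) per branch); a conversion event copies donor
residues into the recipient over an interval, taking the GC-bearing allele
with probability gc_bias (default 0.7 — chosen only to make the GC
footprint detectable; no quantitative bias strength is established for the
real locus) at differing sites.

One integer seed drives everything; per-stage substreams come from fixed
offsets, so equal seeds give byte-identical output. Full-scale generation
(80-kb blocks, 63–68-kb spacing) is supported and used by the acceptance
script; routine tests run at 1:10 scale so the suite finishes in well under
a minute.

What the generator does *not* emulate: sequencing error, assembly
collapse/expansion of repeats, interspersed repeat families (SINEs/LINEs),
CpG methylation structure, selection on coding sequence, and indel
accumulation between block copies at full scale. Passing tests therefore
demonstrate correctness of the analysis pipeline on clean, truth-known
structures, not robustness to raw-assembly artifacts.

## Numerical and design choices

- Alignment scoring (match +1, mismatch −2, open −4, extend −1) favours the
  near-identical overlaps this locus produces; edlib supplies the alignment
  path, affine re-scoring ranks candidates and polishes dirty regions.
- The clone-validation workflow only reports overlaps above a detection
  identity floor (0.95): genuine same-haplotype overlaps stay above it even
  with a large inversion and two large indels (~0.97 column identity),
  while mosaic alignments induced by the 90–95%-identical paralogous blocks
  fall below it. The concordance verdict then applies the stricter
  configured threshold to reported pairs.
- Greedy largest-first profile matching is deterministic and adequate at
  gel resolution; the brute-force optimum is used as a test oracle only.
- Degenerate inputs: zero-site digests return one fragment; sd = 0 GC scans
  warn and flag nothing; fewer than two genes give an empty spacing list;
  three-taxon congruence scans produce trees but can flag nothing.
- Reports iterate in sorted order everywhere, so outputs are byte-stable
  for fixed inputs and seeds.

## Known limitations

- Inversion calling assumes at most a few rearranged tracts per overlap and
  reports the maximal tract; nested or abutting rearrangements are out of
  scope.
- `detect_blocks_seeded` requires colinear copies; copies separated by
  large indels drift off a single diagonal and are better served by the
  phase-max matrix.
- The congruence scan flags breakpoints at segment granularity; it does not
  estimate the breakpoint position within a segment.
- Building multiple sequence alignments is out of scope; the phylogenetics
  stage accepts pre-aligned FASTA.
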