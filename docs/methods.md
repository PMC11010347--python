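# Methods

## Scope and model

`splitkit` studies one well-defined step of SPLiT-seq data processing: the
extraction and error correction of combinatorial cell barcodes from the
barcode read, isolated from alignment, normalization and downstream
analysis. The package contains a generative model of the barcode read, three
extraction algorithms representative of the families used by published
demultiplexers, a per-element whitelist corrector, the quantification steps
that turn corrected reads into a cells × features UMI matrix (random-hexamer
collapsing, exact-match UMI deduplication, a read-count cell filter), and an
evaluation layer that scores everything against simulated truth.

### Barcode-read geometry

The barcode read concatenates, in order: UMI (10 nt), BC3 (8 nt), LINKER2
(30 nt), BC2 (8 nt), LINKER1 (22 nt in v2 chemistry, 30 nt in v1), BC1
(8 nt). All internal coordinates are 0-based half-open; with the standard
lengths this places BC3 at [10, 18), BC2 at [48, 56) and BC1 at [78, 86)
(v2) or [86, 94) (v1), i.e. inclusive positions 10–17, 48–55 and 78–85 /
86–93, as tools configured by position use them. Linker lengths are derived
as the gaps between barcode positions and validated against the configured
linker sequences; a mismatch is a configuration error rather than a silent
shift. The actual linker base compositions are not meaningful for any
computation here (only their lengths and fixedness are), so the package
ships fixed arbitrary sequences of the correct lengths, overridable in the
chemistry config.

### Synthetic data generator

The generator is first-class, tested code, and its defaults are the study
conditions: 500 cells, 10,000 reads per cell, read 1 of 120 bases, eight
read categories in equal proportion. Each cell is a distinct (BC1, BC2, BC3)
whitelist-index triplet sampled without replacement; sampling is performed
in the hexamer-collapsed space and the polyA/hexamer alias of BC1 is fixed
per cell, so no two simulated cells can merge under collapsing and the truth
cell count is unambiguous.

The eight categories pin the correction boundary: perfect reads; reads with
exactly 2 substitutions in 1, 2 or 3 barcode elements (within the distance-2
correction budget); reads with exactly 3 substitutions in 1, 2 or 3 elements
(beyond it); and reads whose barcode read is replaced entirely by a uniform
random sequence. Substitutions hit distinct positions and always change the
base, so the realized per-element Hamming distance equals the nominal count
exactly; which elements are hit is uniform. The boundary values 2 and 3 are
configurable but deliberately default to the edges of the correction
distance. For the random category only read 2 is randomized; read 1 keeps
the category's feature sequence so the fate of those reads remains traceable
in the count matrix. Read 1 carries no errors: feature assignment is meant
to be trivial so that any loss observed downstream is attributable to
barcode handling. Quality strings are constant maximum quality, as no step
here is quality-aware.

Each read's UMI comes from a single code of `reads_per_cell` sequences with
pairwise Hamming distance ≥ 3, generated once and reused across cells (the
constraint matters only within a cell; it exists to defeat UMI-collapsing
heuristics, so that one read is one molecule). Truth — cell id, category,
barcode indices, UMI, feature — is encoded in the read name
(`SK:cell:category:bc1:bc2:bc3:umi:feature`), making the FASTQ pair
self-describing; a `truth.tsv` sidecar is also written.

Eight feature reference sequences (one per category) are drawn at random at
120 nt, audited to be mutually > 25% divergent, and written as
`features.fasta`.

### Minimum-distance codes and whitelist presets

Whitelists and the UMI code are generated greedily: candidates are visited
in a seeded random order (a full shuffled enumeration of the 4^L space for
the lengths used here) and accepted unless they fall in the rejection set,
the union of Hamming balls of radius `min_distance − 1` around accepted
members; acceptance is therefore a single set lookup. The result is audited
exhaustively (`min_pairwise_distance` is computed, never assumed) and is a
pure function of the seed; a deterministic retry escalation re-runs the
greedy with derived seeds when a request sits near the method's yield, and a
capacity error names the bound when the space genuinely cannot hold the
request.

Two presets ship:

* **realistic** — 96 barcodes per round at pairwise distance ≥ 3, hexamer
  split 48: the dimensions of a 96-well round with typical whitelist
  separation. The combinatorial space is 96³ = 884,736 raw triplets.
* **guarantee** — 12 barcodes per round at pairwise distance ≥ 6, hexamer
  split 6. With separation ≥ 6 and correction distance 2, outcomes are
  analytically forced: a 2-substitution mutant is within distance 2 of its
  origin and at distance ≥ 4 from every other entry (unique), while a
  3-substitution mutant is at distance ≥ 3 from every entry (never
  assigned). This makes end-to-end expectations exact rather than
  statistical. The size 12 is close to the largest set the greedy generator
  attains at distance 6 on 8-mers — distance 6 on length 8 over a 4-letter
  alphabet sits at the Plotkin boundary d = (1 − 1/q)·n, so large sets do
  not exist — and 12³ = 1,728 still dwarfs the cell counts used with this
  preset.

For the default UMI request (10,000 codewords of length 10 at distance ≥ 3)
the greedy yield is ≈ 1.1 × 10⁴ per seed, above the request and below the
radius-1 sphere-packing ceiling of ≈ 3.4 × 10⁴.

### Extraction strategies

* **fixed** slices each element at its theoretical span; a read shorter than
  the layout is `too_short`. It is exact on substitution-only data and
  breaks under any positional shift.
* **linker** finds the best Hamming placement of each linker within ± 3
  bases (default) of its theoretical position, ties resolved toward the
  theoretical position and then leftmost, and re-derives element positions:
  UMI and BC3 from the linker2 placement, BC2 from the end of linker2, BC1
  from the end of linker1. A linker whose best placement exceeds the
  mismatch budget (default 20% of its length) yields `not_found`; this is
  what rejects fully random reads, whose chance of matching a 30-mer at ≤ 6
  mismatches within a 7-position window is negligible.
* **bc_align** scores every whitelist barcode concatenated with a short
  anchor from the adjoining linker (default 5 nt; BC3 anchors on the start
  of linker2, BC2 on the start of linker1, BC1 on the end of linker1)
  against the read near the element's theoretical position. The best unique
  entry within the mismatch budget (default 2, matching the correction
  distance) determines the placement, and the observed bases at that
  placement are reported; equal best scores from different entries null the
  element as ambiguous.

The window ± 3, the 20% linker budget and the 5-nt anchor are package
choices — the published tools in these families do not document comparable
thresholds — and are exposed as flags.

### Whitelist correction

Correction is per element against the round's whitelist: the unique entry at
minimal distance ≤ 2 (the conventional `Edit_dist_2` budget) is assigned;
a tied minimum is rejected as ambiguous rather than arbitrarily resolved
(conservative: no silent miscorrection); no entry in range is
uncorrectable. The default metric is Hamming — the error model is
substitution-only, where Hamming and Levenshtein coincide — with Levenshtein
(via edlib's global alignment) available by flag. When elements fail for
mixed reasons the call status reports `uncorrectable` in preference to
`ambiguous`. Correction is per element, not on the concatenated barcode, so
a distance budget applies to each round independently.

Note one consequence of the ambiguity rule: on a read whose element carries
3 substitutions, fixed and linker extraction still report the mutated bases
(correction then rejects them), while bc_align rejects the placement
outright. The three strategies therefore agree at the level of assignment
decisions on all substitution-only reads, and byte-for-byte on element
sequences for reads within the correction budget; the equivalence tests
assert exactly that.

### Quantification

Random-hexamer collapsing maps round-1 index i > split to i − split (with
the standard 96/48 configuration: 49→1 … 96→48) and merges cells that
become identical by element-wise row sums; the operation conserves totals
and is idempotent. UMI counting is exact-match deduplication — the
simulator's distance-3 UMI code makes mismatch-tolerant merging pointless,
and this is a documented divergence from tools that collapse UMIs at 1
mismatch. Feature assignment is best-identity against the eight references
with a 0.9 identity threshold and a uniqueness requirement; it deliberately
replaces genome alignment, which is out of scope. The cell filter keeps
cells with strictly more than 100 assigned reads, reading the conventional
">100 reads per cell" rule literally; the filter counts reads, not UMIs.

### Evaluation

A read's outcome is `correct` (corrected triplet equals truth),
`miscorrected` (non-null but different) or `dropped`. Capture rate is the
fraction correct per category, with categories i–iv aggregated as
correctable, v–vii as uncorrectable, and random reported separately;
"captured" counts only correct assignments, and miscorrections are reported
as their own rate (recoverable by summation for comparison with conventions
that fold them together). Barcode recovery compares the post-filter matrix
cell set with the truth set — in the collapsed space when the matrix was
collapsed — as (found, missed, spurious). Strategy overlap uses exclusive
("upset") semantics: each barcode counts in exactly the one subset row of
strategies that contain it, so rows sum to the union. Per-cell summaries are
means and medians of genes (nonzero features) and UMIs per cell, with the
even-count median taken as the midpoint mean.

## Problem sizes in the test suite

The conformance suite runs the generator at its full default scale
(500 × 10,000 = 5 × 10⁶ reads, ≈ 1.5 min) and audits every read's
per-element substitution counts while streaming; the within-cell UMI audit
checks all pairwise distances of one full cell's 10,000 UMIs. The
end-to-end forced-outcome pipeline uses 50 cells × 400 reads under the
guarantee preset, where every expectation is exact: capture 1.0 for
categories i–iv and 0.0 for v–vii, recovery (50, 0, 0) with the filter
disabled and at its default (each cell retains 200 assigned reads > 100).
Strategy-equivalence and determinism checks run on toy batches where
exhaustive comparison is cheap. Corrector correctness is additionally
established against a brute-force oracle (an independent distance scan with
its own Hamming and dynamic-programming Levenshtein implementations) on 10⁴
random instances.

## Known limitations

* The error model is substitution-only; there are no indels, no
  quality-dependent errors, no PCR duplicates, no ambient RNA or doublets.
  Linker-based extraction is exercised on shifts only through constructed
  reads.
* Feature assignment by identity stands in for alignment; results say
  nothing about aligner-induced differences between pipelines.
* The guarantee preset's forced outcomes certify the correction logic, not
  performance on realistic whitelists, where distance-3 separation makes
  some 2-substitution mutants ambiguous; the realistic preset is used for
  the monotonicity (correctable ≥ uncorrectable capture) checks instead.
* Real barcode sets and linker sequences from commercial kits are not
  reproduced; all sequences here are generated.
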