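# splitkit

Simulation, demultiplexing and benchmarking of combinatorially barcoded
SPLiT-seq reads.

SPLiT-seq identifies each cell not by a single synthesized barcode but by
the *combination* of three barcodes (BC1, BC2, BC3) ligated in successive
split-pool rounds, giving `b^3` possible cell barcodes from `b` barcodes per
round (96³ = 884,736 for standard plates). The barcode read interleaves
these elements with fixed linker sequences:

```
UMI[10] · BC3[8] · LINKER2[30] · BC2[8] · LINKER1[22 or 30] · BC1[8]
```

Demultiplexing this read is where SPLiT-seq pipelines differ most: tools
extract the elements at **fixed positions**, by **aligning the linkers**, or
by **aligning whitelist barcodes anchored on linker fragments**, and then
correct each element to its round's whitelist within an edit distance of 2.
`splitkit` is for people who want to study that step in isolation: it
generates truth-labelled synthetic reads with a controlled substitution
model, implements all three extraction families plus whitelist correction,
builds UMI count matrices (including random-hexamer collapsing of round-1
barcodes and the >100-reads-per-cell filter), and scores every strategy
against the simulated truth — capture rates per error category, barcode
recovery, strategy overlap.

The error model pins the correction boundary exactly. Reads fall into eight
categories: perfect; 2 substitutions in 1, 2 or 3 barcode elements
(*correctable*, within the distance-2 budget); 3 substitutions in 1, 2 or 3
elements (*uncorrectable*); and a fully random barcode read. Every read's
truth (cell, category, barcode indices, UMI, feature) is encoded in its
read name, so the FASTQ pair is self-describing.

## Worked example

Simulate 4 cells × 80 reads under the "guarantee" whitelist preset
(12 barcodes per round at pairwise Hamming ≥ 6, which makes correction
outcomes analytically forced), demultiplex with two strategies, quantify
and benchmark:

```
splitkit -q run-all -o toy --cells 4 --reads-per-cell 80 --seed 3 \
    --preset guarantee --strategies fixed,linker --min-reads 0
```

`toy/benchmark_fixed/report.json` then contains:

```json
"capture_by_group": {
  "correctable": 1.0,
  "random": 0.0,
  "uncorrectable": 0.0
},
"recovery": { "found": 4, "missed": 0, "spurious": 0 },
"stats": {
  "mean_genes_per_cell": 4.0,
  "mean_umis_per_cell": 40.0,
  "median_genes_per_cell": 4.0,
  "median_umis_per_cell": 40.0,
  "n_cells": 4
}
```

Every read in the perfect and correctable categories (2 substitutions per
affected element) was assigned to its true cell barcode (capture 1.0); no
uncorrectable read (3 substitutions per element, at distance ≥ 3 from every
whitelist entry) was assigned anywhere (capture 0.0, and a miscorrection
rate of 0.0 confirms none was silently mis-assigned). All 4 simulated cells
were recovered with no spurious barcodes. Each cell's 40 assigned reads
(the 4 correctable categories × 10 reads) carry distinct UMIs and map to
the 4 correctable-category features — hence 40 UMIs and 4 genes per cell.
`toy/overlap.json` reports the upset-style intersection of the cell-barcode
sets from the two strategies (`"fixed+linker": 4` — full agreement).

The same machinery is available as a library:

```python
import splitkit as sk

chem = sk.guarantee_chemistry()
cfg = sk.SimConfig(n_cells=4, reads_per_cell=80, chemistry=chem, seed=3)
layout = sk.build_layout(chem)
for pair, truth in sk.iter_read_pairs(cfg):
    raw = sk.extract(pair.read2, chem, strategy="linker", layout=layout)
    call = sk.correct_call(raw, chem)   # .status, .indices, .distances
```

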