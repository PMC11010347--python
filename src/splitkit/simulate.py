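"""Truth-labelled synthetic SPLiT-seq read simulation.

The simulator emits paired reads for a configurable number of cells: read 1
carries a feature sequence (a fixed 120-base surrogate for a gene's cDNA) and
read 2 carries the barcode read composed as UMI, BC3, LINKER2, BC2, LINKER1,
BC1.  Every read belongs to one of eight error categories:

    i    perfect           no errors
    ii   correctable_1     2 substitutions in 1 barcode element
    iii  correctable_2     2 substitutions in each of 2 elements
    iv   correctable_3     2 substitutions in each of 3 elements
    v    uncorrectable_1   3 substitutions in 1 element
    vi   uncorrectable_2   3 substitutions in each of 2 elements
    vii  uncorrectable_3   3 substitutions in each of 3 elements
    viii random            read 2 replaced by a uniformly random sequence

With the default whitelist correction distance of 2, categories ii-iv are
within correction range ("correctable") and v-vii beyond it.  Substitution
counts are configurable but pinned to the boundary values 2 and 3 by default.

Each read receives a UMI from a single minimum-distance code (pairwise
Hamming >= 3) that is generated once and reused across cells: the distance
constraint only needs to hold within a cell, and it prevents UMI-collapsing
demultiplexers from merging distinct molecules.  The complete ground truth of
every read is encoded in its name, so no sidecar is needed to benchmark
(though one can be written).
"""

from __future__ import annotations

import gzip
import io
import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence, TextIO

from .chemistry import (
    BC_LENGTH,
    DNA_BASES,
    UMI_LENGTH,
    CapacityError,
    Chemistry,
    ConfigError,
    ReadLayout,
    build_layout,
    hamming_distance,
    min_distance_code,
    realistic_chemistry,
    write_whitelist,
)

CATEGORIES = (
    "perfect",
    "correctable_1",
    "correctable_2",
    "correctable_3",
    "uncorrectable_1",
    "uncorrectable_2",
    "uncorrectable_3",
    "random",
)
CORRECTABLE_CATEGORIES = CATEGORIES[0:4]
UNCORRECTABLE_CATEGORIES = CATEGORIES[4:7]
RANDOM_CATEGORY = "random"

_READ_NAME_TAG = "SK"
_N_FIELDS = 8


class ReadNameError(ValueError):
    """A read name does not encode a valid truth record."""


@dataclass(frozen=True)
class FeatureReference:
    """One of the eight per-category reference sequences carried on read 1."""

    feature_id: str
    sequence: str


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    cell_id: int
    category: str
    bc_indices: tuple[int, int, int]  # (bc1, bc2, bc3), 1-based whitelist indices
    umi: str
    feature_id: str


@dataclass(frozen=True)
class ReadPair:
    name: str
    read1: str
    read2: str


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-dataset configuration.

    Defaults reproduce the reference synthetic design: 500 cells, 10,000
    reads each, the eight categories in equal proportion, 120-base features,
    and substitution counts of 2 (correctable) / 3 (uncorrectable) per
    affected barcode element.
    """

    n_cells: int = 500
    reads_per_cell: int = 10_000
    chemistry: Chemistry | None = None  # None -> realistic v2 preset
    category_mix: tuple[float, ...] = tuple([1 / 8] * 8)
    subs_correctable: int = 2
    subs_uncorrectable: int = 3
    read1_length: int = 120
    seed: int = 0

    def resolved_chemistry(self) -> Chemistry:
        return self.chemistry if self.chemistry is not None else realistic_chemistry()

    def validate(self) -> None:
        if self.n_cells < 1 or self.reads_per_cell < 1:
            raise ConfigError("n_cells and reads_per_cell must be >= 1")
        if len(self.category_mix) != len(CATEGORIES):
            raise ConfigError(f"category_mix needs {len(CATEGORIES)} proportions")
        if any(p < 0 for p in self.category_mix):
            raise ConfigError("category proportions must be non-negative")
        if not math.isclose(sum(self.category_mix), 1.0, abs_tol=1e-9):
            raise ConfigError("category proportions must sum to 1")
        if not 0 <= self.subs_correctable <= 2:
            raise ConfigError("subs_correctable must be <= 2 (within correction range)")
        if self.subs_uncorrectable < 3:
            raise ConfigError("subs_uncorrectable must be >= 3 (beyond correction range)")
        chem = self.resolved_chemistry()
        if self.subs_uncorrectable > chem.bc_length:
            raise ConfigError("substitution count exceeds barcode length")
        if self.n_cells > chem.n_cell_barcodes:
            raise ConfigError(
                f"n_cells {self.n_cells} exceeds the collapsed combinatorial space "
                f"({chem.n_cell_barcodes})"
            )
        if self.read1_length < 1:
            raise ConfigError("read1_length must be >= 1")


# ---------------------------------------------------------------------------
# Read names


def encode_read_name(truth: TruthRecord) -> str:
    """Colon-delimited truth encoding: tag:cell:category:bc1:bc2:bc3:umi:feature."""
    fields = (
        _READ_NAME_TAG,
        str(truth.cell_id),
        truth.category,
        str(truth.bc_indices[0]),
        str(truth.bc_indices[1]),
        str(truth.bc_indices[2]),
        truth.umi,
        truth.feature_id,
    )
    for f in fields:
        if ":" in f:
            raise ValueError(f"read-name field contains the delimiter: {f!r}")
    return ":".join(fields)


def parse_read_name(name: str) -> TruthRecord:
    """Inverse of :func:`encode_read_name` (raises ReadNameError when malformed)."""
    parts = name.split(":")
    if len(parts) != _N_FIELDS:
        raise ReadNameError(f"expected {_N_FIELDS} colon-separated fields: {name!r}")
    tag, cell, category, b1, b2, b3, umi, feature_id = parts
    if tag != _READ_NAME_TAG:
        raise ReadNameError(f"unknown read-name tag {tag!r}")
    if category not in CATEGORIES:
        raise ReadNameError(f"unknown category {category!r}")
    try:
        cell_id = int(cell)
        indices = (int(b1), int(b2), int(b3))
    except ValueError:
        raise ReadNameError(f"non-integer cell/barcode field in {name!r}") from None
    if not umi or any(b not in DNA_BASES for b in umi):
        raise ReadNameError(f"invalid UMI {umi!r}")
    return TruthRecord(
        read_id=name,
        cell_id=cell_id,
        category=category,
        bc_indices=indices,
        umi=umi,
        feature_id=feature_id,
    )


# ---------------------------------------------------------------------------
# Building blocks


def generate_umi_code(
    n: int, length: int = UMI_LENGTH, min_distance: int = 3, seed: int = 0
) -> list[str]:
    """A UMI code: ``n`` sequences with pairwise Hamming >= min_distance.

    Built once per simulation and reused across cells (the distance
    constraint is within-cell only).
    """
    return min_distance_code(n, length, min_distance, seed)


def make_feature_references(
    read1_length: int = 120, seed: int = 0
) -> list[FeatureReference]:
    """Eight per-category reference sequences of ``read1_length`` bases.

    Random sequences of this length are mutually distant with overwhelming
    probability; the pairwise separation (> length/4) is verified anyway and
    the draw repeated in the astronomically unlikely case of a near-pair.
    """
    rng = random.Random(seed ^ 0x5EED)
    for _ in range(100):
        seqs = [
            "".join(rng.choice(DNA_BASES) for _ in range(read1_length))
            for _ in CATEGORIES
        ]
        min_d = min(
            hamming_distance(a, b)
            for i, a in enumerate(seqs)
            for b in seqs[i + 1:]
        )
        if min_d > read1_length / 4:
            return [
                FeatureReference(feature_id=cat, sequence=s)
                for cat, s in zip(CATEGORIES, seqs)
            ]
    raise CapacityError("could not draw mutually distinguishable feature sequences")


def partition_counts(total: int, proportions: Sequence[float]) -> list[int]:
    """Split ``total`` into integer counts per proportion.

    Each bin gets floor(total * p); the remainder is assigned one read at a
    time round-robin in bin order.
    """
    counts = [int(total * p) for p in proportions]
    remainder = total - sum(counts)
    i = 0
    while remainder > 0:
        counts[i % len(counts)] += 1
        remainder -= 1
        i += 1
    return counts


def _mutate(seq: str, n_subs: int, rng: random.Random) -> str:
    """Exactly n_subs substitutions at distinct positions, each to a different base."""
    positions = rng.sample(range(len(seq)), n_subs)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in DNA_BASES if b != out[p]])
    return "".join(out)


def inject_errors(
    elements: tuple[str, str, str],
    category: str,
    rng: random.Random,
    subs_correctable: int = 2,
    subs_uncorrectable: int = 3,
) -> tuple[tuple[str, str, str], tuple[int, int, int]] | None:
    """Apply the category's substitution pattern to (bc1, bc2, bc3).

    Returns the mutated elements and per-element substitution counts, or
    ``None`` for the ``random`` category, which signals whole-read
    randomization to the caller (no per-element errors apply).
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if category == RANDOM_CATEGORY:
        return None
    if category == "perfect":
        return elements, (0, 0, 0)
    group, k_str = category.rsplit("_", 1)
    n_hit = int(k_str)
    n_subs = subs_correctable if group == "correctable" else subs_uncorrectable
    for el in elements:
        if n_subs > len(el):
            raise ConfigError(
                f"{n_subs} substitutions exceed element length {len(el)}"
            )
    hit = rng.sample(range(3), n_hit)
    mutated = list(elements)
    counts = [0, 0, 0]
    for i in hit:
        mutated[i] = _mutate(mutated[i], n_subs, rng)
        counts[i] = n_subs
    return (mutated[0], mutated[1], mutated[2]), (counts[0], counts[1], counts[2])


def compose_read2(
    layout: ReadLayout,
    umi: str,
    bc3: str,
    bc2: str,
    bc1: str,
    linker1: str,
    linker2: str,
) -> str:
    """Concatenate the six elements in read order, validating each span length."""
    parts = {"umi": umi, "bc3": bc3, "linker2": linker2, "bc2": bc2,
             "linker1": linker1, "bc1": bc1}
    for name in ReadLayout.ELEMENT_ORDER:
        start, end = layout.span(name)
        if len(parts[name]) != end - start:
            raise ConfigError(
                f"element {name} has length {len(parts[name])}, layout expects "
                f"{end - start}"
            )
    return "".join(parts[name] for name in ReadLayout.ELEMENT_ORDER)


# ---------------------------------------------------------------------------
# Dataset generation


def _sample_cells(
    chem: Chemistry, n_cells: int, rng: random.Random
) -> list[tuple[int, int, int]]:
    """Sample distinct (bc1, bc2, bc3) triplets, distinct after hexamer collapse.

    The collapsed round-1 identity (the physical well) is sampled without
    replacement; each cell's raw bc1 is then fixed to either the polyA index
    or its paired hexamer index.  Two simulated cells therefore never merge
    under hexamer collapsing.
    """
    n1c = chem.n_collapsed_round1
    n2 = len(chem.whitelists[1])
    n3 = len(chem.whitelists[2])
    picks = rng.sample(range(n1c * n2 * n3), n_cells)
    split = chem.hexamer_split
    cells = []
    for p in picks:
        i1c = p // (n2 * n3) + 1
        rem = p % (n2 * n3)
        i2 = rem // n3 + 1
        i3 = rem % n3 + 1
        i1 = i1c
        # polyA wells have a hexamer alias i1c + split; pick one per cell
        if split and i1c <= split and rng.random() < 0.5:
            i1 = i1c + split
        cells.append((i1, i2, i3))
    return cells


def iter_read_pairs(
    config: SimConfig,
    features: Sequence[FeatureReference] | None = None,
) -> Iterator[tuple[ReadPair, TruthRecord]]:
    """Stream the simulated dataset as (ReadPair, TruthRecord) tuples.

    Deterministic for a fixed config: the same seed yields the identical
    stream. Reads are emitted cell by cell, category blocks in canonical
    category order within each cell.
    """
    config.validate()
    chem = config.resolved_chemistry()
    layout = build_layout(chem)
    rng = random.Random(config.seed)

    if features is None:
        features = make_feature_references(config.read1_length, config.seed)
    feature_seq = {f.feature_id: f.sequence for f in features}

    umi_code = generate_umi_code(
        config.reads_per_cell, chem.umi_length, 3, seed=config.seed + 101
    )
    cells = _sample_cells(chem, config.n_cells, rng)
    counts = partition_counts(config.reads_per_cell, config.category_mix)
    wl1, wl2, wl3 = chem.whitelists
    total_len = layout.total_length

    for cell_id, (i1, i2, i3) in enumerate(cells):
        true_elements = (wl1.sequence(i1), wl2.sequence(i2), wl3.sequence(i3))
        umi_iter = iter(umi_code)
        for category, n_reads in zip(CATEGORIES, counts):
            for _ in range(n_reads):
                umi = next(umi_iter)
                truth = TruthRecord(
                    read_id="",
                    cell_id=cell_id,
                    category=category,
                    bc_indices=(i1, i2, i3),
                    umi=umi,
                    feature_id=category,
                )
                name = encode_read_name(truth)
                truth = replace(truth, read_id=name)
                if category == RANDOM_CATEGORY:
                    read2 = "".join(rng.choices(DNA_BASES, k=total_len))
                else:
                    injected = inject_errors(
                        true_elements,
                        category,
                        rng,
                        config.subs_correctable,
                        config.subs_uncorrectable,
                    )
                    assert injected is not None
                    (e1, e2, e3), _ = injected
                    read2 = compose_read2(
                        layout, umi, e3, e2, e1, chem.linker1, chem.linker2
                    )
                yield ReadPair(name=name, read1=feature_seq[category], read2=read2), truth


def _open_out(path: Path) -> TextIO:
    if path.suffix == ".gz":
        # fixed mtime + no embedded filename: identical content -> identical bytes
        raw = gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"),
                            compresslevel=5, mtime=0)
        return io.TextIOWrapper(raw, encoding="ascii")
    return open(path, "w")


def simulate_dataset(
    config: SimConfig,
    outdir: str | Path,
    write_truth: bool = True,
    compress: bool = False,
) -> dict[str, Path]:
    """Simulate and write the dataset to ``outdir``.

    Writes ``R1.fastq[.gz]`` (cDNA), ``R2.fastq[.gz]`` (barcode read),
    ``features.fasta``, ``whitelist_round{1,2,3}.tsv`` and, by default,
    ``truth.tsv``.  Returns the paths keyed by artifact name.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chem = config.resolved_chemistry()
    features = make_feature_references(config.read1_length, config.seed)

    ext = ".fastq.gz" if compress else ".fastq"
    paths = {
        "r1": outdir / f"R1{ext}",
        "r2": outdir / f"R2{ext}",
        "features": outdir / "features.fasta",
    }
    for rnd in (1, 2, 3):
        p = outdir / f"whitelist_round{rnd}.tsv"
        write_whitelist(chem.whitelist(rnd), p)
        paths[f"whitelist{rnd}"] = p
    with open(paths["features"], "w") as fh:
        for f in features:
            fh.write(f">{f.feature_id}\n{f.sequence}\n")

    truth_fh = None
    if write_truth:
        paths["truth"] = outdir / "truth.tsv"
        truth_fh = open(paths["truth"], "w")
        truth_fh.write(
            "read_id\tcell_id\tcategory\tbc1\tbc2\tbc3\tumi\tfeature_id\n"
        )
    qual1 = "I" * config.read1_length
    layout = build_layout(chem)
    qual2 = "I" * layout.total_length
    with _open_out(paths["r1"]) as f1, _open_out(paths["r2"]) as f2:
        for pair, truth in iter_read_pairs(config, features=features):
            f1.write(f"@{pair.name}\n{pair.read1}\n+\n{qual1}\n")
            f2.write(f"@{pair.name}\n{pair.read2}\n+\n{qual2}\n")
            if truth_fh is not None:
                i1, i2, i3 = truth.bc_indices
                truth_fh.write(
                    f"{truth.read_id}\t{truth.cell_id}\t{truth.category}\t"
                    f"{i1}\t{i2}\t{i3}\t{truth.umi}\t{truth.feature_id}\n"
                )
    if truth_fh is not None:
        truth_fh.close()
    return paths
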