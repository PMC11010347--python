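"""Hexamer collapsing, feature assignment, UMI counting and cell filtering.

In the first barcoding round both oligo-dT (polyA) and random-hexamer
primers sit in the same wells: with 96 round-1 barcodes, index ``i`` (polyA)
and index ``i + 48`` (hexamer) label the same physical well.  Collapsing
subtracts 48 from every round-1 index larger than 48 and merges the counts of
cells that become identical.

Counting is UMI-based: a (cell, feature) entry counts the distinct UMIs
observed for it.  UMIs are deduplicated by exact match — no 1-mismatch
merging — which is lossless here because simulated UMIs within a cell are
pairwise Hamming >= 3 apart; tools that do collapse UMIs diverge on real
data, not on this input.  Cells are finally filtered by total assigned reads
(strictly more than ``min_reads``, default 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .extract import CorrectedCall, levenshtein
from .chemistry import hamming_distance
from .simulate import FeatureReference

DEFAULT_MIN_READS = 100
DEFAULT_MIN_IDENTITY = 0.9

Cell = tuple[int, int, int]


@dataclass(frozen=True)
class CountMatrix:
    """Sparse cells x features matrix of deduplicated UMI counts.

    ``read_totals[i]`` is the number of assigned reads that contributed to
    cell ``i`` (used by the read-count cell filter, which is defined on reads,
    not molecules).
    """

    cells: tuple[Cell, ...]
    features: tuple[str, ...]
    counts: sp.csr_matrix  # int64, shape (len(cells), len(features))
    read_totals: np.ndarray  # int64, per cell

    def __post_init__(self) -> None:
        n, m = self.counts.shape
        if n != len(self.cells) or m != len(self.features):
            raise ValueError("counts shape disagrees with cells/features")
        if len(self.read_totals) != len(self.cells):
            raise ValueError("read_totals length disagrees with cells")
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("duplicate cell triplet in matrix")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def total_umis(self) -> int:
        return int(self.counts.sum())

    def total_reads(self) -> int:
        return int(self.read_totals.sum())

    def cell_set(self) -> set[Cell]:
        return set(self.cells)


def empty_matrix(features: Sequence[str] = ()) -> CountMatrix:
    return CountMatrix(
        cells=(),
        features=tuple(features),
        counts=sp.csr_matrix((0, len(features)), dtype=np.int64),
        read_totals=np.zeros(0, dtype=np.int64),
    )


def matrix_from_counts(
    cell_counts: dict[Cell, dict[str, int]],
    features: Sequence[str],
    read_totals: dict[Cell, int] | None = None,
) -> CountMatrix:
    """Build a CountMatrix from nested dicts (cells sorted for determinism)."""
    cells = tuple(sorted(cell_counts))
    feat_index = {f: j for j, f in enumerate(features)}
    mat = sp.dok_matrix((len(cells), len(features)), dtype=np.int64)
    for i, cell in enumerate(cells):
        for feat, n in cell_counts[cell].items():
            mat[i, feat_index[feat]] = n
    totals = np.array(
        [
            (read_totals or {}).get(cell, sum(cell_counts[cell].values()))
            for cell in cells
        ],
        dtype=np.int64,
    )
    return CountMatrix(
        cells=cells, features=tuple(features),
        counts=mat.tocsr(), read_totals=totals,
    )


# ---------------------------------------------------------------------------
# Hexamer collapsing


def collapse_hexamer_index(
    bc1_index: int, whitelist_size: int = 96, split: int = 48
) -> int:
    """Map a hexamer round-1 index to its paired polyA index.

    Index ``i > split`` becomes ``i - split``; indices ``1..split`` are
    unchanged (index 49 pairs with index 1, and so on).
    """
    if not 1 <= bc1_index <= whitelist_size:
        raise ValueError(
            f"bc1 index {bc1_index} outside the round-1 whitelist 1..{whitelist_size}"
        )
    return bc1_index - split if bc1_index > split else bc1_index


def collapse_cells(
    cells: Iterable[Cell], whitelist_size: int = 96, split: int = 48
) -> set[Cell]:
    """Hexamer-collapse a set of cell triplets (for truth-set comparisons)."""
    return {
        (collapse_hexamer_index(c[0], whitelist_size, split), c[1], c[2])
        for c in cells
    }


def collapse_matrix(
    matrix: CountMatrix, whitelist_size: int = 96, split: int = 48
) -> CountMatrix:
    """Merge cells identical after round-1 hexamer collapsing (row sums)."""
    if matrix.n_cells == 0:
        return matrix
    collapsed_cells = [
        (collapse_hexamer_index(c[0], whitelist_size, split), c[1], c[2])
        for c in matrix.cells
    ]
    out_cells = tuple(sorted(set(collapsed_cells)))
    row_of = {cell: i for i, cell in enumerate(out_cells)}
    # indicator matrix S (out x in): summed rows implement the merge
    rows = [row_of[c] for c in collapsed_cells]
    cols = np.arange(matrix.n_cells)
    s = sp.csr_matrix(
        (np.ones(matrix.n_cells, dtype=np.int64), (rows, cols)),
        shape=(len(out_cells), matrix.n_cells),
    )
    totals = np.zeros(len(out_cells), dtype=np.int64)
    np.add.at(totals, rows, matrix.read_totals)
    return CountMatrix(
        cells=out_cells,
        features=matrix.features,
        counts=(s @ matrix.counts).tocsr(),
        read_totals=totals,
    )


# ---------------------------------------------------------------------------
# Feature assignment and counting


def assign_feature(
    read1: str,
    references: Sequence[FeatureReference],
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> str | None:
    """Best-identity reference for a cDNA read, or None.

    Identity is (length - distance) / length, Hamming for equal lengths and
    edit distance otherwise.  Requires a unique best hit at or above
    ``min_identity``.
    """
    best_id = -1.0
    best_feature: str | None = None
    tied = False
    for ref in references:
        n = max(len(read1), len(ref.sequence))
        if len(read1) == len(ref.sequence):
            d = hamming_distance(read1, ref.sequence)
        else:
            d = levenshtein(read1, ref.sequence)
        identity = (n - d) / n
        if identity > best_id:
            best_id, best_feature, tied = identity, ref.feature_id, False
        elif identity == best_id:
            tied = True
    if best_feature is None or tied or best_id < min_identity:
        return None
    return best_feature


def build_count_matrix(
    assignments: Iterable[tuple[CorrectedCall, str | None, str | None]],
    features: Sequence[str],
) -> CountMatrix:
    """UMI-count a stream of (corrected call, umi, feature_id).

    Only ``assigned`` calls contribute.  Every assigned read counts toward
    its cell's read total; only reads with an assigned feature and a UMI
    contribute to the UMI counts, where a (cell, feature) count is the number
    of distinct UMIs seen.
    """
    umis: dict[Cell, dict[str, set[str]]] = {}
    totals: dict[Cell, int] = {}
    for call, umi, feature_id in assignments:
        cell = call.cell
        if cell is None:
            continue
        totals[cell] = totals.get(cell, 0) + 1
        if feature_id is None or umi is None:
            continue
        umis.setdefault(cell, {}).setdefault(feature_id, set()).add(umi)
    cell_counts = {
        cell: {feat: len(u) for feat, u in feats.items()}
        for cell, feats in umis.items()
    }
    for cell in totals:
        cell_counts.setdefault(cell, {})
    return matrix_from_counts(cell_counts, features, read_totals=totals)


def filter_cells(matrix: CountMatrix, min_reads: int = DEFAULT_MIN_READS) -> CountMatrix:
    """Retain cells with strictly more than ``min_reads`` assigned reads."""
    keep = np.flatnonzero(matrix.read_totals > min_reads)
    return CountMatrix(
        cells=tuple(matrix.cells[i] for i in keep),
        features=matrix.features,
        counts=matrix.counts[keep].tocsr(),
        read_totals=matrix.read_totals[keep],
    )


# ---------------------------------------------------------------------------
# MatrixMarket triplet layout (features x cells, conventional orientation)


def write_matrix(matrix: CountMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write matrix.mtx + barcodes.tsv + features.tsv (+ read_totals.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "barcodes": outdir / "barcodes.tsv",
        "features": outdir / "features.tsv",
        "read_totals": outdir / "read_totals.tsv",
    }
    scipy.io.mmwrite(
        str(paths["matrix"]), matrix.counts.T.tocoo(), field="integer"
    )
    with open(paths["barcodes"], "w") as fh:
        for c in matrix.cells:
            fh.write(f"{c[0]}-{c[1]}-{c[2]}\n")
    with open(paths["features"], "w") as fh:
        for f in matrix.features:
            fh.write(f"{f}\n")
    with open(paths["read_totals"], "w") as fh:
        for c, t in zip(matrix.cells, matrix.read_totals):
            fh.write(f"{c[0]}-{c[1]}-{c[2]}\t{t}\n")
    return paths


def read_matrix(outdir: str | Path) -> CountMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    outdir = Path(outdir)
    counts = sp.csr_matrix(scipy.io.mmread(outdir / "matrix.mtx").T, dtype=np.int64)
    with open(outdir / "barcodes.tsv") as fh:
        cells = tuple(
            tuple(int(x) for x in line.strip().split("-")) for line in fh if line.strip()
        )
    with open(outdir / "features.tsv") as fh:
        features = tuple(line.strip() for line in fh if line.strip())
    totals_path = outdir / "read_totals.tsv"
    if totals_path.exists():
        totals_by_cell = {}
        with open(totals_path) as fh:
            for line in fh:
                token, t = line.split("\t")
                totals_by_cell[tuple(int(x) for x in token.split("-"))] = int(t)
        read_totals = np.array([totals_by_cell[c] for c in cells], dtype=np.int64)
    else:
        read_totals = np.asarray(counts.sum(axis=1)).ravel().astype(np.int64)
    return CountMatrix(
        cells=cells, features=features, counts=counts, read_totals=read_totals  # type: ignore[arg-type]
    )
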