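"""Evaluation of demultiplexing output against simulation ground truth.

Joins per-read corrected calls with the truth encoded in read names and
computes: capture rates per error category (fraction of reads whose corrected
cell barcode equals the simulated truth), the correctable (categories i-iv)
and uncorrectable (v-vii) group aggregates with the random category reported
separately, miscorrection rates (a non-null call that differs from truth,
reported separately from dropped reads and recoverable by summation),
barcode recovery of the final matrix against the truth cell set, exclusive
("upset") intersection counts between strategies, and per-cell summary
statistics (genes and UMIs per cell).
"""

from __future__ import annotations

import itertools
import json
import statistics
from dataclasses import dataclass, field, asdict

import numpy as np
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .extract import CorrectedCall
from .quantify import Cell, CountMatrix
from .simulate import (
    CATEGORIES,
    CORRECTABLE_CATEGORIES,
    RANDOM_CATEGORY,
    UNCORRECTABLE_CATEGORIES,
    TruthRecord,
    parse_read_name,
)


class TruthJoinError(ValueError):
    """A call's read id has no ground truth."""


@dataclass(frozen=True)
class EvalRecord:
    read_id: str
    category: str
    truth_cell: Cell
    called_cell: Cell | None
    outcome: str  # correct | miscorrected | dropped

    @staticmethod
    def classify(truth_cell: Cell, called_cell: Cell | None) -> str:
        if called_cell is None:
            return "dropped"
        return "correct" if called_cell == truth_cell else "miscorrected"


def join_truth(
    calls: Iterable[CorrectedCall],
    truth: Mapping[str, TruthRecord] | None = None,
) -> Iterator[EvalRecord]:
    """Join corrected calls with ground truth (read names, or a sidecar map)."""
    for call in calls:
        if truth is not None:
            rec = truth.get(call.read_id)
            if rec is None:
                raise TruthJoinError(f"read id missing from truth: {call.read_id!r}")
        else:
            try:
                rec = parse_read_name(call.read_id)
            except ValueError as err:
                raise TruthJoinError(
                    f"read id does not encode truth: {call.read_id!r} ({err})"
                ) from None
        called = call.cell
        yield EvalRecord(
            read_id=call.read_id,
            category=rec.category,
            truth_cell=rec.bc_indices,
            called_cell=called,
            outcome=EvalRecord.classify(rec.bc_indices, called),
        )


def _rate(records: Sequence[EvalRecord], outcome: str) -> float | None:
    if not records:
        return None
    return sum(r.outcome == outcome for r in records) / len(records)


def capture_rates(
    records: Iterable[EvalRecord], grouping: str = "category"
) -> dict[str, float | None]:
    """Fraction of reads with outcome ``correct``, per category or per group.

    ``grouping="group"`` aggregates categories i-iv as ``correctable`` and
    v-vii as ``uncorrectable``; the random category stays its own group.
    A group with no reads maps to None (rate undefined).
    """
    records = list(records)
    if grouping == "category":
        groups = {c: [r for r in records if r.category == c] for c in CATEGORIES}
    elif grouping == "group":
        groups = {
            "correctable": [r for r in records if r.category in CORRECTABLE_CATEGORIES],
            "uncorrectable": [
                r for r in records if r.category in UNCORRECTABLE_CATEGORIES
            ],
            RANDOM_CATEGORY: [r for r in records if r.category == RANDOM_CATEGORY],
        }
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return {name: _rate(rs, "correct") for name, rs in groups.items()}


def miscorrection_rates(
    records: Iterable[EvalRecord], grouping: str = "category"
) -> dict[str, float | None]:
    """Fraction of reads assigned to a wrong cell barcode, per category/group."""
    records = list(records)
    if grouping == "category":
        groups = {c: [r for r in records if r.category == c] for c in CATEGORIES}
    else:
        groups = {
            "correctable": [r for r in records if r.category in CORRECTABLE_CATEGORIES],
            "uncorrectable": [
                r for r in records if r.category in UNCORRECTABLE_CATEGORIES
            ],
            RANDOM_CATEGORY: [r for r in records if r.category == RANDOM_CATEGORY],
        }
    return {name: _rate(rs, "miscorrected") for name, rs in groups.items()}


def barcode_recovery(
    matrix: CountMatrix, truth_cells: Iterable[Cell]
) -> tuple[int, int, int]:
    """(found, missed, spurious) comparing matrix cells with the truth set."""
    truth_set = set(truth_cells)
    called = matrix.cell_set()
    found = len(called & truth_set)
    return found, len(truth_set) - found, len(called - truth_set)


def strategy_overlap(
    cb_sets: Mapping[str, set[Cell]]
) -> dict[tuple[str, ...], int]:
    """Exclusive intersection counts for every non-empty subset (upset semantics).

    Each cell barcode is counted in exactly one row: the subset of strategies
    that contain it.  Rows sum to the size of the union.
    """
    if len(cb_sets) < 2:
        raise ValueError("strategy overlap needs at least two sets")
    names = tuple(cb_sets)
    union: set[Cell] = set().union(*cb_sets.values())
    table: dict[tuple[str, ...], int] = {}
    for k in range(1, len(names) + 1):
        for subset in itertools.combinations(names, k):
            table[subset] = 0
    for cb in union:
        members = tuple(n for n in names if cb in cb_sets[n])
        table[members] += 1
    return table


def cell_stats(matrix: CountMatrix) -> dict[str, float | int | None]:
    """n cells; mean/median genes per cell (nonzero features) and UMIs per cell."""
    if matrix.n_cells == 0:
        return {
            "n_cells": 0,
            "mean_genes_per_cell": None, "median_genes_per_cell": None,
            "mean_umis_per_cell": None, "median_umis_per_cell": None,
        }
    genes = [int(g) for g in np.asarray((matrix.counts > 0).sum(axis=1)).ravel()]
    umis = [int(u) for u in np.asarray(matrix.counts.sum(axis=1)).ravel()]
    return {
        "n_cells": matrix.n_cells,
        "mean_genes_per_cell": statistics.fmean(genes),
        "median_genes_per_cell": statistics.median(genes),
        "mean_umis_per_cell": statistics.fmean(umis),
        "median_umis_per_cell": statistics.median(umis),
    }


@dataclass
class BenchmarkReport:
    """Bundled evaluation results, serializable to JSON and flat TSV."""

    n_reads: int
    capture_by_category: dict[str, float | None]
    capture_by_group: dict[str, float | None]
    miscorrection_by_group: dict[str, float | None]
    recovery: tuple[int, int, int] | None = None  # (found, missed, spurious)
    stats: dict[str, float | int | None] = field(default_factory=dict)
    overlap: dict[str, int] = field(default_factory=dict)  # "+".join(names) -> count

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        if payload["recovery"] is not None:
            payload["recovery"] = {
                "found": self.recovery[0],
                "missed": self.recovery[1],
                "spurious": self.recovery[2],
            }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path | None = None) -> str:
        rows: list[tuple[str, str]] = [("n_reads", str(self.n_reads))]
        for cat, v in self.capture_by_category.items():
            rows.append((f"capture.{cat}", "" if v is None else f"{v:.6f}"))
        for grp, v in self.capture_by_group.items():
            rows.append((f"capture_group.{grp}", "" if v is None else f"{v:.6f}"))
        for grp, v in self.miscorrection_by_group.items():
            rows.append((f"miscorrection.{grp}", "" if v is None else f"{v:.6f}"))
        if self.recovery is not None:
            for k, v in zip(("found", "missed", "spurious"), self.recovery):
                rows.append((f"recovery.{k}", str(v)))
        for k, v in self.stats.items():
            rows.append((f"cells.{k}", "" if v is None else str(v)))
        for k, v in self.overlap.items():
            rows.append((f"overlap.{k}", str(v)))
        text = "".join(f"{k}\t{v}\n" for k, v in rows)
        if path is not None:
            Path(path).write_text(text)
        return text


def evaluate(
    records: Iterable[EvalRecord],
    matrix: CountMatrix | None = None,
    truth_cells: Iterable[Cell] | None = None,
    cb_sets: Mapping[str, set[Cell]] | None = None,
) -> BenchmarkReport:
    """Compute the full report from eval records (+ optional matrix / sets)."""
    records = list(records)
    report = BenchmarkReport(
        n_reads=len(records),
        capture_by_category=capture_rates(records, "category"),
        capture_by_group=capture_rates(records, "group"),
        miscorrection_by_group=miscorrection_rates(records, "group"),
    )
    if matrix is not None and truth_cells is not None:
        report.recovery = barcode_recovery(matrix, truth_cells)
    if matrix is not None:
        report.stats = cell_stats(matrix)
    if cb_sets is not None and len(cb_sets) >= 2:
        report.overlap = {
            "+".join(subset): n for subset, n in strategy_overlap(cb_sets).items()
        }
    return report
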