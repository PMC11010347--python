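"""Barcode extraction strategies and whitelist error correction.

Demultiplexers in the field extract the three cell barcodes from the barcode
read in one of three ways, all implemented here:

``fixed``
    Slice each element at its theoretical position (position-based; the
    approach of STARsolo-like tools).  Fast, but any positional shift breaks
    every downstream element.
``linker``
    Locate the two linkers by best Hamming placement within a small window of
    their theoretical positions, then re-derive the element positions from
    the placements (linker-based; SCSit / LR-splitpipe style).
``bc_align``
    Score each whitelist barcode, concatenated with a short anchor fragment
    of the adjoining linker, against the read near the element's theoretical
    position and take the best unique hit (alignment-based;
    splitseq-demultiplex style).

Extraction is followed by per-element whitelist correction at a maximum
distance (default 2), with ties between whitelist entries rejected as
ambiguous rather than arbitrarily resolved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Literal

import edlib
import pysam

from .chemistry import BarcodeSet, Chemistry, ReadLayout, build_layout
from .chemistry import hamming_distance as hamming

STRATEGIES = ("fixed", "linker", "bc_align")
Metric = Literal["hamming", "levenshtein"]

#: default search window (bases either side of the theoretical position)
DEFAULT_MAX_SHIFT = 3
#: default linker mismatch budget, as a fraction of linker length
DEFAULT_MAX_MISMATCH_RATE = 0.2
#: default linker-anchor length for barcode-alignment extraction
DEFAULT_ANCHOR_LENGTH = 5
#: default whitelist correction distance (matches the conventional Edit_dist_2)
DEFAULT_MAX_DISTANCE = 2


class FastqPairingError(ValueError):
    """Paired FASTQ files disagree (truncated file or mismatched names)."""


@dataclass(frozen=True)
class RawBarcodeCall:
    """Extracted element sequences before whitelist correction.

    ``status`` is ``ok`` when all three barcode elements were extracted;
    ``too_short`` when the read cannot hold the layout; ``not_found`` when a
    linker or barcode placement failed its mismatch budget; ``ambiguous``
    when two whitelist entries tied for an element under bc_align.
    """

    read_id: str
    strategy: str
    umi: str | None
    bc3: str | None
    bc2: str | None
    bc1: str | None
    offsets: tuple[int | None, int | None, int | None]  # starts of bc1, bc2, bc3
    status: str  # ok | not_found | too_short | ambiguous

    @property
    def elements(self) -> tuple[str | None, str | None, str | None]:
        """(bc1, bc2, bc3)."""
        return (self.bc1, self.bc2, self.bc3)


@dataclass(frozen=True)
class CorrectedCall:
    """Whitelist-corrected barcode indices for one read.

    ``status``: ``assigned`` (all three elements corrected), ``uncorrectable``
    (an element beyond the correction distance), ``ambiguous`` (a tie), or
    ``not_found`` (extraction already failed).
    """

    read_id: str
    indices: tuple[int | None, int | None, int | None]  # (bc1, bc2, bc3)
    distances: tuple[int | None, int | None, int | None]
    status: str  # assigned | uncorrectable | ambiguous | not_found

    @property
    def cell(self) -> tuple[int, int, int] | None:
        if self.status != "assigned":
            return None
        i1, i2, i3 = self.indices
        assert i1 is not None and i2 is not None and i3 is not None
        return (i1, i2, i3)


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (global alignment)."""
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _hamming_capped(a: str, b: str, cap: int) -> int:
    """Hamming distance, early-exited once it exceeds ``cap`` (returns cap+1)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > cap:
                return d
    return d


# ---------------------------------------------------------------------------
# Extraction strategies


def extract_fixed(read2: str, layout: ReadLayout, read_id: str = "") -> RawBarcodeCall:
    """Slice every element at its theoretical layout span."""
    if len(read2) < layout.total_length:
        return RawBarcodeCall(
            read_id=read_id, strategy="fixed", umi=None, bc3=None, bc2=None,
            bc1=None, offsets=(None, None, None), status="too_short",
        )
    return RawBarcodeCall(
        read_id=read_id,
        strategy="fixed",
        umi=layout.slice(read2, "umi"),
        bc3=layout.slice(read2, "bc3"),
        bc2=layout.slice(read2, "bc2"),
        bc1=layout.slice(read2, "bc1"),
        offsets=(layout.bc1[0], layout.bc2[0], layout.bc3[0]),
        status="ok",
    )


def _best_placement(
    read: str, probe: str, theoretical_start: int, max_shift: int
) -> tuple[int, int] | None:
    """Best (start, mismatches) of ``probe`` within +-max_shift of its position.

    Ties go to the placement closest to the theoretical position, then to the
    leftmost.  Returns None when no placement fits inside the read.
    """
    best: tuple[int, int, int] | None = None  # (score, |shift|, start)
    for shift in range(-max_shift, max_shift + 1):
        start = theoretical_start + shift
        if start < 0 or start + len(probe) > len(read):
            continue
        score = hamming(probe, read[start:start + len(probe)])
        key = (score, abs(shift), start)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    return best[2], best[0]


def extract_linker_aligned(
    read2: str,
    layout: ReadLayout,
    linker1: str,
    linker2: str,
    max_shift: int = DEFAULT_MAX_SHIFT,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    read_id: str = "",
) -> RawBarcodeCall:
    """Re-derive element positions from the best Hamming placement of each linker.

    UMI and BC3 are anchored to the linker2 placement, BC2 to the end of
    linker2, and BC1 to the end of linker1.
    """
    fail = dict(read_id=read_id, strategy="linker", umi=None, bc3=None,
                bc2=None, bc1=None, offsets=(None, None, None))
    umi_len = layout.umi[1] - layout.umi[0]
    bc_len = layout.bc3[1] - layout.bc3[0]

    p2 = _best_placement(read2, linker2, layout.linker2[0], max_shift)
    p1 = _best_placement(read2, linker1, layout.linker1[0], max_shift)
    if p2 is None or p1 is None:
        return RawBarcodeCall(status="too_short", **fail)
    (l2_start, l2_mm), (l1_start, l1_mm) = p2, p1
    if l2_mm > max_mismatch_rate * len(linker2) or l1_mm > max_mismatch_rate * len(linker1):
        return RawBarcodeCall(status="not_found", **fail)

    bc3_start = l2_start - bc_len
    umi_start = bc3_start - umi_len
    bc2_start = l2_start + len(linker2)
    bc1_start = l1_start + len(linker1)
    if umi_start < 0 or bc1_start + bc_len > len(read2):
        return RawBarcodeCall(status="too_short", **fail)
    return RawBarcodeCall(
        read_id=read_id,
        strategy="linker",
        umi=read2[umi_start:umi_start + umi_len],
        bc3=read2[bc3_start:bc3_start + bc_len],
        bc2=read2[bc2_start:bc2_start + bc_len],
        bc1=read2[bc1_start:bc1_start + bc_len],
        offsets=(bc1_start, bc2_start, bc3_start),
        status="ok",
    )


def _align_element(
    read2: str,
    whitelist: BarcodeSet,
    theoretical_start: int,
    anchor: str,
    anchor_before: bool,
    max_mismatch: int,
    max_shift: int,
) -> tuple[str, int, int] | None | str:
    """Best unique whitelist placement for one element.

    The probe is ``barcode + anchor`` (or ``anchor + barcode`` when the
    anchor precedes the element); ``theoretical_start`` refers to the probe.
    Returns (observed element sequence, element start, score), the string
    ``"ambiguous"`` when distinct whitelist entries tie for the best score,
    or None when nothing scores within ``max_mismatch``.
    """
    bc_len = whitelist.bc_length
    best_score = max_mismatch + 1
    best: tuple[int, int, int] | None = None  # (|shift|, start, entry_idx)
    tie_entries: set[int] = set()
    for entry_idx, bc in enumerate(whitelist.sequences):
        probe = (anchor + bc) if anchor_before else (bc + anchor)
        for shift in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
            start = theoretical_start + shift
            if start < 0 or start + len(probe) > len(read2):
                continue
            score = _hamming_capped(probe, read2[start:start + len(probe)], best_score)
            if score < best_score:
                best_score = score
                best = (abs(shift), start, entry_idx)
                tie_entries = {entry_idx}
            elif score == best_score and best_score <= max_mismatch:
                tie_entries.add(entry_idx)
                if (abs(shift), start, entry_idx) < best and entry_idx == best[2]:
                    best = (abs(shift), start, entry_idx)
    if best_score > max_mismatch or best is None:
        return None
    if len(tie_entries) > 1:
        return "ambiguous"
    _, start, _ = best
    el_start = start + (len(anchor) if anchor_before else 0)
    return read2[el_start:el_start + bc_len], el_start, best_score


def extract_bc_aligned(
    read2: str,
    whitelists: tuple[BarcodeSet, BarcodeSet, BarcodeSet],
    layout: ReadLayout,
    linker1: str,
    linker2: str,
    anchor_length: int = DEFAULT_ANCHOR_LENGTH,
    max_mismatch: int = DEFAULT_MAX_DISTANCE,
    max_shift: int = DEFAULT_MAX_SHIFT,
    read_id: str = "",
) -> RawBarcodeCall:
    """Place each element by aligning whitelist barcodes plus a linker anchor.

    BC3 is anchored by the first ``anchor_length`` bases of linker2, BC2 by
    the first bases of linker1, and BC1 by the last bases of linker1 (its
    upstream neighbour, since BC1 ends the read).  The UMI is taken relative
    to the BC3 placement.
    """
    if anchor_length < 0 or anchor_length > min(len(linker1), len(linker2)):
        raise ValueError("anchor_length must be within the adjoining linker length")
    wl1, wl2, wl3 = whitelists
    umi_len = layout.umi[1] - layout.umi[0]
    fail = dict(read_id=read_id, strategy="bc_align", umi=None, bc3=None,
                bc2=None, bc1=None, offsets=(None, None, None))
    if len(read2) < layout.total_length:
        return RawBarcodeCall(status="too_short", **fail)

    specs = {
        "bc3": (wl3, layout.bc3[0], linker2[:anchor_length], False),
        "bc2": (wl2, layout.bc2[0], linker1[:anchor_length], False),
        "bc1": (
            wl1,
            layout.bc1[0] - anchor_length,
            linker1[len(linker1) - anchor_length:] if anchor_length else "",
            True,
        ),
    }
    results: dict[str, tuple[str, int, int]] = {}
    ambiguous = False
    for name, (wl, theo, anchor, before) in specs.items():
        res = _align_element(read2, wl, theo, anchor, before, max_mismatch, max_shift)
        if res == "ambiguous":
            ambiguous = True
        elif res is None:
            pass
        else:
            results[name] = res  # type: ignore[assignment]
    if len(results) < 3:
        return RawBarcodeCall(
            status="ambiguous" if ambiguous else "not_found",
            read_id=read_id, strategy="bc_align",
            umi=None,
            bc3=results.get("bc3", (None,))[0],
            bc2=results.get("bc2", (None,))[0],
            bc1=results.get("bc1", (None,))[0],
            offsets=(
                results["bc1"][1] if "bc1" in results else None,
                results["bc2"][1] if "bc2" in results else None,
                results["bc3"][1] if "bc3" in results else None,
            ),
        )
    bc_len = wl3.bc_length
    umi_start = results["bc3"][1] - umi_len
    umi = read2[max(umi_start, 0):results["bc3"][1]] if umi_start >= 0 else None
    return RawBarcodeCall(
        read_id=read_id,
        strategy="bc_align",
        umi=umi,
        bc3=results["bc3"][0],
        bc2=results["bc2"][0],
        bc1=results["bc1"][0],
        offsets=(results["bc1"][1], results["bc2"][1], results["bc3"][1]),
        status="ok",
    )


def extract(
    read2: str,
    chemistry: Chemistry,
    strategy: str = "fixed",
    layout: ReadLayout | None = None,
    read_id: str = "",
    **kwargs,
) -> RawBarcodeCall:
    """Dispatch to one of the three extraction strategies."""
    if layout is None:
        layout = build_layout(chemistry)
    if strategy == "fixed":
        return extract_fixed(read2, layout, read_id=read_id)
    if strategy == "linker":
        return extract_linker_aligned(
            read2, layout, chemistry.linker1, chemistry.linker2,
            read_id=read_id, **kwargs,
        )
    if strategy == "bc_align":
        return extract_bc_aligned(
            read2, chemistry.whitelists, layout, chemistry.linker1,
            chemistry.linker2, read_id=read_id, **kwargs,
        )
    raise ValueError(f"unknown strategy {strategy!r} (choose from {STRATEGIES})")


# ---------------------------------------------------------------------------
# Whitelist correction


def correct_element_detail(
    observed: str,
    whitelist: BarcodeSet,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    metric: Metric = "hamming",
) -> tuple[int | None, int | None, str]:
    """Correct one element: (index, distance, status).

    Status is ``assigned`` for a unique minimal-distance entry within
    ``max_distance``, ``ambiguous`` when >= 2 entries attain the minimum, and
    ``uncorrectable`` when no entry is within range.
    """
    if metric == "hamming":
        dist = lambda wl_seq: _hamming_capped(observed, wl_seq, max_distance)
    elif metric == "levenshtein":
        dist = lambda wl_seq: levenshtein(observed, wl_seq)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    best_d: int | None = None
    best_i: int | None = None
    n_best = 0
    for i, wl_seq in enumerate(whitelist.sequences, start=1):
        if metric == "hamming" and len(observed) != len(wl_seq):
            raise ValueError("hamming correction needs equal-length observed element")
        d = dist(wl_seq)
        if d > max_distance:
            continue
        if best_d is None or d < best_d:
            best_d, best_i, n_best = d, i, 1
        elif d == best_d:
            n_best += 1
    if best_d is None:
        return None, None, "uncorrectable"
    if n_best > 1:
        return None, None, "ambiguous"
    return best_i, best_d, "assigned"


def correct_element(
    observed: str,
    whitelist: BarcodeSet,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    metric: Metric = "hamming",
) -> tuple[int, int] | None:
    """The unique whitelist entry at minimal distance <= max_distance, or None."""
    index, distance, status = correct_element_detail(
        observed, whitelist, max_distance, metric
    )
    if status != "assigned":
        return None
    assert index is not None and distance is not None
    return index, distance


def correct_call(
    raw: RawBarcodeCall,
    chemistry: Chemistry,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    metric: Metric = "hamming",
) -> CorrectedCall:
    """Whitelist-correct a raw call, element by element against its round.

    A raw status other than ``ok`` propagates to ``not_found``.  When any
    element fails, ``uncorrectable`` takes precedence over ``ambiguous``.
    """
    if raw.status != "ok":
        return CorrectedCall(
            read_id=raw.read_id, indices=(None, None, None),
            distances=(None, None, None), status="not_found",
        )
    indices: list[int | None] = []
    distances: list[int | None] = []
    statuses: list[str] = []
    for observed, rnd in zip((raw.bc1, raw.bc2, raw.bc3), (1, 2, 3)):
        assert observed is not None
        idx, d, st = correct_element_detail(
            observed, chemistry.whitelist(rnd), max_distance, metric
        )
        indices.append(idx)
        distances.append(d)
        statuses.append(st)
    if all(st == "assigned" for st in statuses):
        status = "assigned"
    elif "uncorrectable" in statuses:
        status = "uncorrectable"
    else:
        status = "ambiguous"
    return CorrectedCall(
        read_id=raw.read_id,
        indices=(indices[0], indices[1], indices[2]),
        distances=(distances[0], distances[1], distances[2]),
        status=status,
    )


# ---------------------------------------------------------------------------
# Paired-FASTQ demultiplexing


@dataclass(frozen=True)
class DemuxRecord:
    read_id: str
    raw: RawBarcodeCall
    corrected: CorrectedCall
    read1: str


def iter_read_pairs_fastq(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[tuple[str, str, str]]:
    """Yield (name, read1, read2) from a FASTQ pair, validating pairing."""
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for i, (rec1, rec2) in enumerate(itertools.zip_longest(f1, f2), start=1):
            if rec1 is None or rec2 is None:
                short = r1_path if rec1 is None else r2_path
                raise FastqPairingError(
                    f"{short} ends at record {i} while its mate continues"
                )
            if rec1.name != rec2.name:
                raise FastqPairingError(
                    f"record {i}: read names differ ({rec1.name!r} vs {rec2.name!r})"
                )
            yield rec1.name, rec1.sequence, rec2.sequence


def demultiplex(
    r1_path: str | Path,
    r2_path: str | Path,
    chemistry: Chemistry,
    strategy: str = "fixed",
    metric: Metric = "hamming",
    max_distance: int = DEFAULT_MAX_DISTANCE,
    **extract_kwargs,
) -> Iterator[DemuxRecord]:
    """Extract and correct every read pair of a FASTQ pair (streaming)."""
    layout = build_layout(chemistry)
    for name, read1, read2 in iter_read_pairs_fastq(r1_path, r2_path):
        raw = extract(
            read2, chemistry, strategy=strategy, layout=layout, read_id=name,
            **extract_kwargs,
        )
        corrected = correct_call(raw, chemistry, max_distance=max_distance,
                                 metric=metric)
        yield DemuxRecord(read_id=name, raw=raw, corrected=corrected, read1=read1)


ASSIGNMENT_COLUMNS = (
    "read_id", "strategy", "status", "bc1", "bc2", "bc3",
    "dist1", "dist2", "dist3", "umi",
)


def write_assignments(records: Iterable[DemuxRecord], path: str | Path) -> int:
    """Write the per-read assignment TSV; returns the number of rows."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(ASSIGNMENT_COLUMNS) + "\n")
        for rec in records:
            c = rec.corrected
            fields = [
                rec.read_id, rec.raw.strategy, c.status,
                *("" if v is None else str(v) for v in c.indices),
                *("" if v is None else str(v) for v in c.distances),
                rec.raw.umi or "",
            ]
            fh.write("\t".join(fields) + "\n")
            n += 1
    return n
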