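"""Barcode-read geometry, whitelists and combinatorial-space arithmetic.

SPLiT-seq identifies each cell by a combination of three barcodes (BC1..BC3)
ligated in successive split-pool rounds and read out, together with the UMI,
on the barcode read (read 2).  The element order on that read is fixed:

    UMI | BC3 | LINKER2 | BC2 | LINKER1 | BC1

Two protocol versions circulate ("chemistries"): they share the 30 nt
LINKER2 but differ in LINKER1 (30 nt in v1, 22 nt in v2), which shifts the
position of BC1.  With the standard 10 nt UMI and 8 nt barcodes this puts
BC3 at positions 10-17, BC2 at 48-55 and BC1 at 86-93 (v1) or 78-85 (v2),
all 0-based inclusive.

This module also owns whitelist handling: generation of minimum-Hamming-
distance barcode sets, TSV round-trip, and the ``b ** rounds`` arithmetic of
the combinatorial barcode space.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DNA_BASES = "ACGT"

#: standard element lengths (bases)
UMI_LENGTH = 10
BC_LENGTH = 8
LINKER2_LENGTH = 30
LINKER1_LENGTH = {"v1": 30, "v2": 22}

# Default linker sequences.  The published protocol's linkers are not part of
# this package; these are fixed arbitrary sequences of the correct lengths and
# can be overridden in the Chemistry config.
DEFAULT_LINKER1 = {
    "v1": "AGGCGTGCATGCGAAGCACAATGAGTCATA",
    "v2": "ACCCTTAGACCAAAGATGAGAT",
}
DEFAULT_LINKER2 = "ATGCATGAACTTATCTTCGTCCATCAATCT"

VERSIONS = ("v1", "v2")


class ConfigError(ValueError):
    """Inconsistent chemistry / layout configuration."""


class CapacityError(ValueError):
    """A barcode-code request exceeds what the sequence space can hold."""


class WhitelistParseError(ValueError):
    """Malformed whitelist TSV."""


def _check_dna(seq: str, what: str) -> None:
    if not seq or any(b not in DNA_BASES for b in seq):
        raise ConfigError(f"{what} must be a non-empty ACGT string, got {seq!r}")


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance needs equal lengths ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Barcode sets


@dataclass(frozen=True)
class BarcodeSet:
    """An ordered whitelist of equal-length barcodes for one barcoding round.

    Entry *i* of round *r* is addressed by its 1-based index, matching plate
    well numbering.  ``min_pairwise_distance`` is computed exhaustively on
    construction, never trusted from input.
    """

    round: int
    sequences: tuple[str, ...]
    min_pairwise_distance: int = field(init=False)

    def __post_init__(self) -> None:
        if self.round not in (1, 2, 3):
            raise ConfigError(f"barcode round must be 1..3, got {self.round}")
        if not self.sequences:
            raise ConfigError("barcode set is empty")
        length = len(self.sequences[0])
        for s in self.sequences:
            _check_dna(s, "barcode")
            if len(s) != length:
                raise ConfigError(f"ragged barcode lengths: {len(s)} != {length}")
        if len(set(self.sequences)) != len(self.sequences):
            raise ConfigError("duplicate barcode sequence in set")
        object.__setattr__(
            self, "min_pairwise_distance", self._compute_min_distance()
        )

    def _compute_min_distance(self) -> int:
        if len(self.sequences) == 1:
            return len(self.sequences[0])
        return min(
            hamming_distance(a, b)
            for a, b in itertools.combinations(self.sequences, 2)
        )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def bc_length(self) -> int:
        return len(self.sequences[0])

    def sequence(self, index: int) -> str:
        """Barcode sequence for a 1-based whitelist index."""
        if not 1 <= index <= len(self.sequences):
            raise IndexError(f"barcode index {index} outside 1..{len(self.sequences)}")
        return self.sequences[index - 1]

    def index_of(self, seq: str) -> int | None:
        """1-based index of an exact whitelist member, or None."""
        try:
            return self.sequences.index(seq) + 1
        except ValueError:
            return None


# ---------------------------------------------------------------------------
# Minimum-distance code generation

_BASE_TO_BITS = {b: i for i, b in enumerate(DNA_BASES)}


def _seq_to_int(seq: str) -> int:
    code = 0
    for i, b in enumerate(seq):
        code |= _BASE_TO_BITS[b] << (2 * i)
    return code


def _int_to_seq(code: int, length: int) -> str:
    return "".join(DNA_BASES[(code >> (2 * i)) & 3] for i in range(length))


def _hamming_ball(code: int, length: int, radius: int) -> Iterable[int]:
    """All 2-bit packed sequences within Hamming distance <= radius of code."""
    yield code
    for r in range(1, radius + 1):
        for positions in itertools.combinations(range(length), r):
            for subs in itertools.product((1, 2, 3), repeat=r):
                c = code
                for p, s in zip(positions, subs):
                    c ^= s << (2 * p)
                yield c


# Above this space size a full shuffled enumeration is too large to hold;
# fall back to rejection sampling with a retry cap.
_ENUMERATION_LIMIT = 4**11
_SAMPLING_RETRY_CAP = 100_000


def greedy_min_distance_code(
    n: int, length: int, min_distance: int, seed: int
) -> list[str]:
    """Generate ``n`` DNA sequences with pairwise Hamming distance >= min_distance.

    Greedy acceptance over a seeded random candidate order, maintaining a
    rejection set of every sequence within ``min_distance - 1`` of an accepted
    member (so each new candidate is accepted with a single set lookup).
    Deterministic for a fixed seed.

    Raises
    ------
    CapacityError
        If ``n`` exceeds ``4**length``, the candidate space is exhausted, or
        the sampling retry cap is reached before ``n`` sequences are found.
    """
    if n < 1 or length < 1 or min_distance < 1:
        raise ValueError("n, length and min_distance must all be >= 1")
    space = 4**length
    if n > space:
        raise CapacityError(f"requested {n} sequences but 4^{length} = {space}")

    rng = random.Random(seed)
    rejected: set[int] = set()
    accepted: list[int] = []

    def accept(cand: int) -> None:
        accepted.append(cand)
        rejected.update(_hamming_ball(cand, length, min_distance - 1))

    if space <= _ENUMERATION_LIMIT:
        order = list(range(space))
        rng.shuffle(order)
        for cand in order:
            if cand in rejected:
                continue
            accept(cand)
            if len(accepted) == n:
                break
        else:
            raise CapacityError(
                f"candidate space 4^{length} exhausted after {len(accepted)} "
                f"of {n} sequences at min distance {min_distance}"
            )
    else:
        misses = 0
        while len(accepted) < n:
            cand = rng.randrange(space)
            if cand in rejected:
                misses += 1
                if misses > _SAMPLING_RETRY_CAP:
                    raise CapacityError(
                        f"retry cap {_SAMPLING_RETRY_CAP} reached after "
                        f"{len(accepted)} of {n} sequences at min distance "
                        f"{min_distance}"
                    )
                continue
            misses = 0
            accept(cand)

    return [_int_to_seq(c, length) for c in accepted]


def min_distance_code(
    n: int, length: int, min_distance: int, seed: int, retries: int = 8
) -> list[str]:
    """Greedy code generation with deterministic retry escalation.

    The greedy yield for a given (length, min_distance) varies slightly with
    the candidate order; when a request sits near that yield, a different
    seeded order may succeed where the first stalls.  Retries derive their
    seeds from ``seed``, so the result is still a pure function of the inputs.
    """
    last_err: CapacityError | None = None
    for attempt in range(retries):
        try:
            return greedy_min_distance_code(
                n, length, min_distance, seed + attempt * 1_000_003
            )
        except CapacityError as err:
            last_err = err
    assert last_err is not None
    raise last_err


def generate_whitelist(
    n: int, length: int = BC_LENGTH, min_distance: int = 3, seed: int = 0, round: int = 1
) -> BarcodeSet:
    """Generate a whitelist of ``n`` barcodes with pairwise Hamming >= min_distance."""
    return BarcodeSet(
        round=round, sequences=tuple(min_distance_code(n, length, min_distance, seed))
    )


# ---------------------------------------------------------------------------
# Whitelist TSV round-trip (index<TAB>sequence, 1-based contiguous indices)


def load_whitelist(path: str | Path, round: int = 1) -> BarcodeSet:
    """Read a whitelist TSV (``index<TAB>sequence`` per line, no header)."""
    path = Path(path)
    sequences: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise WhitelistParseError(
                    f"{path}:{lineno}: expected 'index<TAB>sequence', got {line!r}"
                )
            idx_str, seq = parts
            try:
                idx = int(idx_str)
            except ValueError:
                raise WhitelistParseError(
                    f"{path}:{lineno}: non-integer index {idx_str!r}"
                ) from None
            if idx != len(sequences) + 1:
                raise WhitelistParseError(
                    f"{path}:{lineno}: index {idx} breaks the contiguous 1..n order"
                )
            if not seq or any(b not in DNA_BASES for b in seq):
                raise WhitelistParseError(f"{path}:{lineno}: non-ACGT sequence {seq!r}")
            if sequences and len(seq) != len(sequences[0]):
                raise WhitelistParseError(
                    f"{path}:{lineno}: ragged sequence length {len(seq)}"
                )
            if seq in sequences:
                raise WhitelistParseError(f"{path}:{lineno}: duplicate sequence {seq}")
            sequences.append(seq)
    if not sequences:
        raise WhitelistParseError(f"{path}: empty whitelist")
    return BarcodeSet(round=round, sequences=tuple(sequences))


def write_whitelist(barcode_set: BarcodeSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(barcode_set.sequences, start=1):
            fh.write(f"{i}\t{seq}\n")


# ---------------------------------------------------------------------------
# Chemistry and read layout


@dataclass(frozen=True)
class Chemistry:
    """A SPLiT-seq chemistry: version, whitelists, linkers and hexamer mode.

    ``hexamer_split`` is the count of round-1 barcodes assigned to oligo-dT
    (polyA) primers; the same count of hexamer-primed barcodes follows them in
    the round-1 whitelist (index i pairs with index i + hexamer_split).
    0 disables hexamer mode.
    """

    version: str
    whitelists: tuple[BarcodeSet, BarcodeSet, BarcodeSet]
    linker1: str
    linker2: str
    umi_length: int = UMI_LENGTH
    bc_length: int = BC_LENGTH
    hexamer_split: int = 48

    def __post_init__(self) -> None:
        if self.version not in VERSIONS:
            raise ConfigError(f"unknown chemistry version {self.version!r}")
        if self.umi_length <= 0 or self.bc_length <= 0:
            raise ConfigError("umi_length and bc_length must be positive")
        _check_dna(self.linker1, "linker1")
        _check_dna(self.linker2, "linker2")
        if len(self.whitelists) != 3:
            raise ConfigError("exactly one whitelist per round (3 rounds) required")
        for expect_round, wl in enumerate(self.whitelists, start=1):
            if wl.round != expect_round:
                raise ConfigError(
                    f"whitelist at position {expect_round} is labelled round {wl.round}"
                )
            if wl.bc_length != self.bc_length:
                raise ConfigError(
                    f"round-{wl.round} barcode length {wl.bc_length} != "
                    f"bc_length {self.bc_length}"
                )
        if self.hexamer_split < 0:
            raise ConfigError("hexamer_split must be >= 0")
        if self.hexamer_split and len(self.whitelists[0]) < 2 * self.hexamer_split:
            raise ConfigError(
                f"round-1 whitelist has {len(self.whitelists[0])} entries; hexamer "
                f"mode needs >= 2 x hexamer_split = {2 * self.hexamer_split}"
            )

    def whitelist(self, round: int) -> BarcodeSet:
        return self.whitelists[round - 1]

    @property
    def n_collapsed_round1(self) -> int:
        """Distinct round-1 identities after hexamer collapsing."""
        n1 = len(self.whitelists[0])
        if not self.hexamer_split:
            return n1
        return max(self.hexamer_split, n1 - self.hexamer_split)

    @property
    def n_cell_barcodes(self) -> int:
        """Size of the collapsed combinatorial cell-barcode space."""
        return (
            self.n_collapsed_round1
            * len(self.whitelists[1])
            * len(self.whitelists[2])
        )


@dataclass(frozen=True)
class ReadLayout:
    """Spans of the six barcode-read elements, 0-based half-open intervals."""

    umi: tuple[int, int]
    bc3: tuple[int, int]
    linker2: tuple[int, int]
    bc2: tuple[int, int]
    linker1: tuple[int, int]
    bc1: tuple[int, int]

    #: element names in read order
    ELEMENT_ORDER = ("umi", "bc3", "linker2", "bc2", "linker1", "bc1")

    def __post_init__(self) -> None:
        pos = 0
        for name in self.ELEMENT_ORDER:
            start, end = getattr(self, name)
            if start != pos or end <= start:
                raise ConfigError(
                    f"layout element {name} span ({start},{end}) breaks contiguity "
                    f"at position {pos}"
                )
            pos = end

    @property
    def total_length(self) -> int:
        return self.bc1[1]

    def span(self, element: str) -> tuple[int, int]:
        return getattr(self, element)

    def slice(self, read: str, element: str) -> str:
        start, end = self.span(element)
        return read[start:end]


def build_layout(chemistry: Chemistry) -> ReadLayout:
    """Derive the read-2 element spans from a chemistry.

    Linker lengths are the gaps between the fixed barcode positions of the
    version (30 between BC3 and BC2 in both; 22/30 between BC2 and BC1 in
    v2/v1); a configured linker of any other length is a configuration error.
    """
    expect_l1 = LINKER1_LENGTH[chemistry.version]
    if len(chemistry.linker1) != expect_l1:
        raise ConfigError(
            f"linker1 length {len(chemistry.linker1)} inconsistent with "
            f"{chemistry.version} (expected {expect_l1})"
        )
    if len(chemistry.linker2) != LINKER2_LENGTH:
        raise ConfigError(
            f"linker2 length {len(chemistry.linker2)} inconsistent with the "
            f"protocol (expected {LINKER2_LENGTH})"
        )
    spans = {}
    pos = 0
    for name, length in (
        ("umi", chemistry.umi_length),
        ("bc3", chemistry.bc_length),
        ("linker2", len(chemistry.linker2)),
        ("bc2", chemistry.bc_length),
        ("linker1", len(chemistry.linker1)),
        ("bc1", chemistry.bc_length),
    ):
        spans[name] = (pos, pos + length)
        pos += length
    return ReadLayout(**spans)


def max_unique_barcodes(barcodes_per_round: int, rounds: int) -> int:
    """Size of the combinatorial cell-barcode space: barcodes_per_round ** rounds."""
    if barcodes_per_round < 1 or rounds < 1:
        raise ValueError("barcodes_per_round and rounds must be >= 1")
    return barcodes_per_round**rounds


# ---------------------------------------------------------------------------
# Chemistry config file (plain key = value; whitelist paths relative to it)


def write_chemistry_config(
    chemistry: Chemistry, path: str | Path, whitelist_paths: Sequence[str | Path]
) -> None:
    """Write a chemistry as a key-value config next to its whitelist TSVs."""
    path = Path(path)
    lines = [
        f"version = {chemistry.version}",
        f"umi_length = {chemistry.umi_length}",
        f"bc_length = {chemistry.bc_length}",
        f"linker1 = {chemistry.linker1}",
        f"linker2 = {chemistry.linker2}",
        f"hexamer_split = {chemistry.hexamer_split}",
    ]
    for rnd, wl_path in enumerate(whitelist_paths, start=1):
        rel = Path(wl_path)
        if rel.is_absolute():
            try:
                rel = rel.relative_to(path.parent.resolve())
            except ValueError:
                pass
        lines.append(f"whitelist{rnd} = {rel}")
    path.write_text("\n".join(lines) + "\n")


def load_chemistry_config(path: str | Path) -> Chemistry:
    """Load a chemistry from a key-value config written by write_chemistry_config."""
    path = Path(path)
    kv: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    missing = [
        k
        for k in ("version", "linker1", "linker2", "whitelist1", "whitelist2", "whitelist3")
        if k not in kv
    ]
    if missing:
        raise ConfigError(f"{path}: missing config keys: {', '.join(missing)}")
    whitelists = tuple(
        load_whitelist(path.parent / kv[f"whitelist{rnd}"], round=rnd)
        for rnd in (1, 2, 3)
    )
    return Chemistry(
        version=kv["version"],
        whitelists=whitelists,  # type: ignore[arg-type]
        linker1=kv["linker1"],
        linker2=kv["linker2"],
        umi_length=int(kv.get("umi_length", UMI_LENGTH)),
        bc_length=int(kv.get("bc_length", BC_LENGTH)),
        hexamer_split=int(kv.get("hexamer_split", 0)),
    )


# ---------------------------------------------------------------------------
# Presets

#: "realistic": 96 barcodes per round at pairwise Hamming >= 3, mirroring a
#: 96-well plate per round with typical whitelist separation.
REALISTIC_SIZE = 96
REALISTIC_MIN_DISTANCE = 3

#: "guarantee": a small whitelist at pairwise Hamming >= 6, where whitelist
#: correction outcomes are analytically forced: any 2-substitution mutant is
#: uniquely within distance 2 of its origin, and any 3-substitution mutant is
#: at distance >= 3 from every entry.  12 per round is close to the largest
#: set the greedy generator attains at distance 6 on 8-mers.
GUARANTEE_SIZE = 12
GUARANTEE_MIN_DISTANCE = 6


def _preset(
    version: str, size: int, min_distance: int, seed: int, hexamer_split: int
) -> Chemistry:
    whitelists = tuple(
        generate_whitelist(
            size, BC_LENGTH, min_distance, seed=seed * 7919 + rnd, round=rnd
        )
        for rnd in (1, 2, 3)
    )
    return Chemistry(
        version=version,
        whitelists=whitelists,  # type: ignore[arg-type]
        linker1=DEFAULT_LINKER1[version],
        linker2=DEFAULT_LINKER2,
        hexamer_split=hexamer_split,
    )


def realistic_chemistry(version: str = "v2", seed: int = 1) -> Chemistry:
    """96 barcodes per round, pairwise Hamming >= 3, hexamer split 48."""
    return _preset(version, REALISTIC_SIZE, REALISTIC_MIN_DISTANCE, seed, 48)


def guarantee_chemistry(version: str = "v2", seed: int = 1) -> Chemistry:
    """12 barcodes per round, pairwise Hamming >= 6, hexamer split 6.

    Designed for exact tests: with separation >= 6 and correction distance 2,
    elements carrying <= 2 substitutions always correct to their origin and
    elements carrying >= 3 substitutions are never assigned.
    """
    return _preset(version, GUARANTEE_SIZE, GUARANTEE_MIN_DISTANCE, seed, 6)
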