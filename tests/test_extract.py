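"""Extraction strategies, distance metrics and whitelist correction."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import splitkit as sk
from splitkit.chemistry import BarcodeSet
from splitkit.extract import (
    FastqPairingError,
    correct_element_detail,
    extract_bc_aligned,
    extract_linker_aligned,
    iter_read_pairs_fastq,
)
from splitkit.simulate import RANDOM_CATEGORY


# --- independent oracles -----------------------------------------------------


def oracle_hamming(a, b):
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y)


def oracle_levenshtein(a, b):
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


def oracle_correct(observed, whitelist, max_distance, metric):
    """Brute-force scan over every whitelist entry with the oracle metrics."""
    fn = oracle_hamming if metric == "hamming" else oracle_levenshtein
    dists = [fn(observed, s) for s in whitelist.sequences]
    best = min(dists)
    if best > max_distance or dists.count(best) > 1:
        return None
    return dists.index(best) + 1, best


# --- distance metrics --------------------------------------------------------


class TestMetrics:
    @pytest.mark.parametrize(
        "a,b,expected", [("AAAA", "AAAT", 1), ("ACGT", "ACGT", 0)]
    )
    def test_hamming(self, a, b, expected):
        assert sk.hamming(a, b) == expected

    def test_hamming_needs_equal_lengths(self):
        with pytest.raises(ValueError):
            sk.hamming("AA", "A")

    @pytest.mark.parametrize(
        "a,b,expected",
        [("kitten", "sitting", 3), ("ACGT", "ACGT", 0), ("", "AB", 2)],
    )
    def test_levenshtein_known_values(self, a, b, expected):
        assert sk.levenshtein(a, b) == expected
        assert oracle_levenshtein(a, b) == expected

    @given(
        a=st.text(alphabet="ACGT", min_size=1, max_size=12),
        b=st.text(alphabet="ACGT", min_size=1, max_size=12),
    )
    def test_levenshtein_agrees_with_dp_oracle(self, a, b):
        assert sk.levenshtein(a, b) == oracle_levenshtein(a, b)

    @given(
        a=st.text(alphabet="ACGT", min_size=8, max_size=8),
        b=st.text(alphabet="ACGT", min_size=8, max_size=8),
    )
    def test_hamming_upper_bounds_levenshtein(self, a, b):
        assert sk.hamming(a, b) >= sk.levenshtein(a, b)


# --- fixed-position extraction ----------------------------------------------


class TestExtractFixed:
    def test_too_short_read(self, layout_v2):
        raw = sk.extract_fixed("A" * (layout_v2.total_length - 1), layout_v2)
        assert raw.status == "too_short"

    def test_substitutions_do_not_move_spans(self, guarantee_chem, layout_v2):
        umi, bc3, bc2, bc1 = "A" * 10, "C" * 8, "G" * 8, "T" * 8
        read2 = sk.compose_read2(
            layout_v2, umi, bc3, bc2, bc1, guarantee_chem.linker1,
            guarantee_chem.linker2,
        )
        # two substitutions inside bc2
        s, _ = layout_v2.bc2
        mutated = read2[:s] + "TT" + read2[s + 2:]
        raw = sk.extract_fixed(mutated, layout_v2)
        assert raw.bc2 == "TT" + "G" * 6
        assert raw.bc1 == bc1 and raw.bc3 == bc3 and raw.umi == umi


# --- linker-based extraction --------------------------------------------------


class TestExtractLinkerAligned:
    def test_matches_fixed_on_substitution_only_reads(
        self, guarantee_chem, layout_v2, toy_pairs
    ):
        for pair, truth in toy_pairs:
            if truth.category == RANDOM_CATEGORY:
                continue
            fixed = sk.extract_fixed(pair.read2, layout_v2)
            linked = extract_linker_aligned(
                pair.read2, layout_v2, guarantee_chem.linker1,
                guarantee_chem.linker2,
            )
            assert linked.status == "ok"
            assert linked.elements == fixed.elements
            assert linked.umi == fixed.umi

    def test_recovers_from_one_base_shift(self, guarantee_chem, layout_v2):
        umi, bc3, bc2, bc1 = "ACGTACGTAC", "AATTCCGG", "GGCCAATT", "TACGTACG"
        read2 = sk.compose_read2(
            layout_v2, umi, bc3, bc2, bc1, guarantee_chem.linker1,
            guarantee_chem.linker2,
        )
        shifted = "G" + read2  # one base prepended: everything moves +1
        fixed = sk.extract_fixed(shifted, layout_v2)
        assert fixed.bc2 != bc2  # position-only slicing is off by one
        linked = extract_linker_aligned(
            shifted, layout_v2, guarantee_chem.linker1, guarantee_chem.linker2
        )
        assert linked.status == "ok"
        assert linked.elements == (bc1, bc2, bc3)
        assert linked.umi == umi

    def test_random_read_not_found(self, guarantee_chem, layout_v2, toy_pairs):
        n_random = 0
        for pair, truth in toy_pairs:
            if truth.category != RANDOM_CATEGORY:
                continue
            n_random += 1
            linked = extract_linker_aligned(
                pair.read2, layout_v2, guarantee_chem.linker1,
                guarantee_chem.linker2,
            )
            assert linked.status == "not_found"
        assert n_random > 0


# --- barcode-alignment extraction ---------------------------------------------


class TestExtractBcAligned:
    def test_error_free_read_yields_truth_indices(
        self, guarantee_chem, layout_v2
    ):
        wl1, wl2, wl3 = guarantee_chem.whitelists
        read2 = sk.compose_read2(
            layout_v2, "A" * 10, wl3.sequence(2), wl2.sequence(5), wl1.sequence(7),
            guarantee_chem.linker1, guarantee_chem.linker2,
        )
        raw = extract_bc_aligned(
            read2, guarantee_chem.whitelists, layout_v2,
            guarantee_chem.linker1, guarantee_chem.linker2,
        )
        assert raw.status == "ok"
        corrected = sk.correct_call(raw, guarantee_chem)
        assert corrected.status == "assigned"
        assert corrected.indices == (7, 5, 2)

    def test_tie_between_whitelist_entries_is_ambiguous(
        self, guarantee_chem, layout_v2
    ):
        # a bc2 observation equidistant from two custom whitelist entries
        wl2 = BarcodeSet(round=2, sequences=("AAAAAAAA", "AAAATTTT"))
        wl1 = guarantee_chem.whitelist(1)
        wl3 = guarantee_chem.whitelist(3)
        read2 = sk.compose_read2(
            layout_v2, "A" * 10, wl3.sequence(1), "AAAAAATT", wl1.sequence(1),
            guarantee_chem.linker1, guarantee_chem.linker2,
        )
        raw = extract_bc_aligned(
            read2, (wl1, wl2, wl3), layout_v2,
            guarantee_chem.linker1, guarantee_chem.linker2,
        )
        assert raw.status == "ambiguous"
        assert raw.bc2 is None

    def test_correctable_categories_recover_truth(
        self, guarantee_chem, layout_v2, toy_pairs
    ):
        for pair, truth in toy_pairs:
            if truth.category not in sk.CORRECTABLE_CATEGORIES:
                continue
            raw = extract_bc_aligned(
                pair.read2, guarantee_chem.whitelists, layout_v2,
                guarantee_chem.linker1, guarantee_chem.linker2,
            )
            corrected = sk.correct_call(raw, guarantee_chem)
            assert corrected.status == "assigned"
            assert corrected.indices == truth.bc_indices


# --- whitelist correction ------------------------------------------------------


HOMOPOLYMER_WL = BarcodeSet(
    round=1, sequences=("AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "TTTTTTTT")
)


class TestCorrectElement:
    def test_two_substitutions_within_range(self):
        assert sk.correct_element("AAAAAATT", HOMOPOLYMER_WL) == (1, 2)

    def test_three_substitutions_beyond_range(self):
        assert sk.correct_element("AAAAATTT", HOMOPOLYMER_WL) is None

    def test_equidistant_minimum_is_rejected(self):
        wl = BarcodeSet(round=1, sequences=("AAAACCCC", "AAAAGGGG"))
        # two mismatches to both entries
        assert sk.correct_element("AAAACCGG", wl) is None
        assert correct_element_detail("AAAACCGG", wl)[2] == "ambiguous"

    @pytest.mark.parametrize("metric", ["hamming", "levenshtein"])
    def test_agrees_with_brute_force_oracle(self, metric):
        rng = random.Random(2024)
        wl = BarcodeSet(
            round=1,
            sequences=tuple(
                sk.generate_whitelist(16, 8, 2, seed=6).sequences
            ),
        )
        for _ in range(5_000):
            observed = "".join(rng.choice("ACGT") for _ in range(8))
            assert sk.correct_element(observed, wl, 2, metric) == oracle_correct(
                observed, wl, 2, metric
            )


class TestCorrectCall:
    def test_perfect_read(self, guarantee_chem, layout_v2, toy_pairs):
        for pair, truth in toy_pairs:
            if truth.category != "perfect":
                continue
            cc = sk.correct_call(sk.extract_fixed(pair.read2, layout_v2,
                                                  read_id=pair.name),
                                 guarantee_chem)
            assert cc.status == "assigned"
            assert cc.distances == (0, 0, 0)
            assert cc.indices == truth.bc_indices

    def test_correctable_3_forced_to_truth_at_distance_2(
        self, guarantee_chem, layout_v2, toy_pairs
    ):
        seen = 0
        for pair, truth in toy_pairs:
            if truth.category != "correctable_3":
                continue
            seen += 1
            cc = sk.correct_call(
                sk.extract_fixed(pair.read2, layout_v2), guarantee_chem
            )
            assert cc.status == "assigned"
            assert cc.indices == truth.bc_indices
            assert cc.distances == (2, 2, 2)
        assert seen > 0

    def test_uncorrectable_rejected(self, guarantee_chem, layout_v2, toy_pairs):
        for pair, truth in toy_pairs:
            if truth.category not in sk.UNCORRECTABLE_CATEGORIES:
                continue
            cc = sk.correct_call(
                sk.extract_fixed(pair.read2, layout_v2), guarantee_chem
            )
            assert cc.status == "uncorrectable"
            assert cc.cell is None

    def test_raw_failure_propagates(self, guarantee_chem, layout_v2):
        raw = sk.extract_fixed("ACGT", layout_v2)
        cc = sk.correct_call(raw, guarantee_chem)
        assert cc.status == "not_found"


# --- strategy agreement --------------------------------------------------------


class TestStrategyAgreement:
    def test_assignment_agreement_on_substitution_only_reads(
        self, guarantee_chem, layout_v2, toy_pairs
    ):
        """All three strategies make identical assignment decisions."""
        for pair, truth in toy_pairs:
            if truth.category == RANDOM_CATEGORY:
                continue
            calls = {
                strat: sk.correct_call(
                    sk.extract(pair.read2, guarantee_chem, strategy=strat,
                               layout=layout_v2),
                    guarantee_chem,
                )
                for strat in ("fixed", "linker", "bc_align")
            }
            cells = {s: c.cell for s, c in calls.items()}
            assert len(set(cells.values())) == 1, cells
            if truth.category in sk.CORRECTABLE_CATEGORIES:
                # raw element sequences are also identical when correctable
                raws = {
                    strat: sk.extract(pair.read2, guarantee_chem, strategy=strat,
                                      layout=layout_v2).elements
                    for strat in ("fixed", "linker", "bc_align")
                }
                assert len(set(raws.values())) == 1, raws


# --- FASTQ pairing -------------------------------------------------------------


class TestFastqPairing:
    def test_truncated_mate_raises_with_record_number(self, guarantee_chem, tmp_path):
        cfg = sk.SimConfig(n_cells=1, reads_per_cell=8, chemistry=guarantee_chem,
                           seed=5)
        paths = sk.simulate_dataset(cfg, tmp_path)
        r2_lines = paths["r2"].read_text().splitlines(keepends=True)
        truncated = tmp_path / "R2_short.fastq"
        truncated.write_text("".join(r2_lines[:-4]))  # drop the last record
        with pytest.raises(FastqPairingError, match="record"):
            list(iter_read_pairs_fastq(paths["r1"], truncated))

    def test_demultiplex_stream(self, guarantee_chem, tmp_path):
        cfg = sk.SimConfig(n_cells=2, reads_per_cell=8, chemistry=guarantee_chem,
                           seed=5)
        paths = sk.simulate_dataset(cfg, tmp_path)
        records = list(sk.demultiplex(paths["r1"], paths["r2"], guarantee_chem))
        assert len(records) == 16
        assert all(r.read_id == r.corrected.read_id for r in records)
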