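"""Consensus-pattern parsing and block scanning."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsptools.architecture import assemble
from bsptools.blocks import (
    AMINO_ACIDS,
    DEFAULT_HYDROPHOBIC,
    BlockId,
    PatternError,
    SequenceError,
    format_pattern,
    load_block_definitions,
    match_at,
    parse_pattern,
    scan_blocks,
)

CANONICAL_STARTS = {
    "I": 1, "II": 15, "III": 22, "IV": 31, "V": 40,
    "VI": 46, "VII": 60, "VIII": 67, "IX": 78,
}
CANONICAL_LENGTHS = {
    "I": 7, "II": 6, "III": 7, "IV": 8, "V": 3,
    "VI": 7, "VII": 6, "VIII": 9, "IX": 10,
}


class TestParsePattern:
    def test_alternative_sets_and_wildcards(self):
        pat = parse_pattern("C[VA]FPFxY")
        assert len(pat) == 7
        assert pat.positions[0].kind == "fixed" and pat.positions[0].residues == {"C"}
        assert pat.positions[1].kind == "alt" and pat.positions[1].residues == {"V", "A"}
        assert pat.positions[5].kind == "wildcard"

    def test_mostly_unconstrained_linker_pattern(self):
        pat = parse_pattern("xxD")
        assert len(pat) == 3
        assert [p.kind for p in pat.positions] == ["wildcard", "wildcard", "fixed"]

    @pytest.mark.parametrize("bad", ["", "C[VA", "C[]F", "CZB!"])
    def test_malformed_input_raises(self, bad):
        with pytest.raises(PatternError):
            parse_pattern(bad)

    def test_error_names_offending_position(self):
        with pytest.raises(PatternError, match="position 3"):
            parse_pattern("CC?")

    @pytest.mark.parametrize(
        "text", ["C[VA]FPFxY", "xxD", "hxxxWCSL[ST]", "[FY][DN]xDxxW[KR][QY]C"]
    )
    def test_format_round_trips(self, text):
        normalized = format_pattern(parse_pattern(text))
        assert format_pattern(parse_pattern(normalized)) == normalized
        assert len(parse_pattern(normalized)) == len(parse_pattern(text))


class TestMatchAt:
    def test_exact_consensus_instance(self):
        pat = parse_pattern("C[VA]FPFxY")
        assert match_at(pat, "CVFPFEY", 1) == (True, 0)

    def test_hydrophobic_class_accepts_tryptophan(self):
        # the BSPH1 version of Block VI carries W at the hydrophobic slot
        pat = parse_pattern("CxFPFh[YF]")
        assert match_at(pat, "CHFPFWY", 1) == (True, 0)

    def test_single_fixed_violation(self):
        pat = parse_pattern("C[VA]FPFxY")
        matched, mism = match_at(pat, "AVFPFEY", 1, tolerance=0)
        assert not matched and mism == 1
        assert match_at(pat, "AVFPFEY", 1, tolerance=1) == (True, 1)

    def test_window_overrun_raises(self):
        pat = parse_pattern("C[VA]FPFxY")
        with pytest.raises(IndexError):
            match_at(pat, "CVFPF", 1)
        with pytest.raises(IndexError):
            match_at(pat, "CVFPFEYCVFPFEY", 9)


class TestScanBlocks:
    def test_canonical_core_yields_full_chain_at_canonical_starts(self, canonical_core):
        matches = scan_blocks(canonical_core, tolerance_per_block=0)
        arch = assemble(matches, canonical_core)
        assert arch.complete
        starts = {b.value: m.start for b, m in arch.block_matches.items()}
        assert starts == CANONICAL_STARTS
        assert all(m.mismatches == 0 for m in arch.block_matches.values())

    def test_poly_alanine_has_no_matches(self):
        assert scan_blocks("A" * 100, tolerance_per_block=0) == []

    def test_non_amino_acid_symbols_rejected(self):
        with pytest.raises(SequenceError, match="B.*Z|BZ"):
            scan_blocks("ACDB" * 30 + "Z")

    def test_determinism(self, canonical_core):
        a = scan_blocks(canonical_core, 1)
        b = scan_blocks(canonical_core, 1)
        assert a == b

    @given(
        seq=st.text(alphabet=sorted(AMINO_ACIDS), min_size=0, max_size=120),
        tol=st.integers(min_value=0, max_value=2),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_scanner_equals_brute_force_oracle(self, seq, tol, block_defs):
        """The scanner must equal exhaustive per-position matching."""
        got = {
            (m.block_id.value, m.start, m.mismatches)
            for m in scan_blocks(seq, tol, block_defs)
        }
        expected = set()
        for block in block_defs:
            allowed = []
            for spec in block.pattern.positions:
                if spec.kind == "wildcard":
                    allowed.append(AMINO_ACIDS)
                elif spec.kind == "hydrophobic":
                    allowed.append(DEFAULT_HYDROPHOBIC)
                else:
                    allowed.append(spec.residues)
            w = len(allowed)
            for start in range(len(seq) - w + 1):
                mism = sum(
                    seq[start + k] not in allowed[k] for k in range(w)
                )
                if mism <= tol:
                    expected.add((block.block_id.value, start + 1, mism))
        assert got == expected


class TestCanonicalGeometry:
    def test_block_lengths(self, block_defs):
        lengths = {d.block_id.value: d.canonical_length for d in block_defs}
        assert lengths == CANONICAL_LENGTHS
        assert lengths["VIII"] - lengths["III"] == 2
        assert lengths["IX"] - lengths["IV"] == 2

    def test_domain_span_asymmetry(self, block_defs):
        by_id = {d.block_id: d for d in block_defs}
        fn2_1 = by_id[BlockId.IV].canonical_end - by_id[BlockId.I].canonical_start + 1
        fn2_2 = by_id[BlockId.IX].canonical_end - by_id[BlockId.VI].canonical_start + 1
        assert (fn2_1, fn2_2) == (38, 42)
        assert fn2_2 - fn2_1 == 4

    def test_patterns_have_canonical_width(self, block_defs):
        for d in block_defs:
            assert len(d.pattern) == d.canonical_length

    def test_bsph1_variant_relaxes_block_ii_terminus(self):
        relaxed = {d.block_id: d for d in load_block_definitions(bsph1_mode=True)}
        pat = relaxed[BlockId.II].pattern
        assert pat.positions[-1].residues == {"S", "A", "G", "T"}
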