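"""Descriptor extraction, term enumeration and canonicalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duplexml.descriptors import (
    KINDS,
    DescriptorError,
    TermTable,
    UnknownTermError,
    canonicalize_stacking,
    enumerate_terms,
    extract_all,
    extract_dangling,
    extract_initiating,
    extract_looping,
    extract_stacking,
)
from duplexml.notation import parse_dna_string


def brute_force_quartets(s: str) -> list:
    """Independent oracle: slide a width-4 window over each "(...)" region."""
    out = []
    for seg in s.split(".")[:1]:
        start = 0
        while True:
            i = seg.find("(", start)
            if i < 0:
                break
            j = seg.find(")", i)
            region = seg[i : j + 1]
            out.extend(region[k : k + 4] for k in range(len(region) - 3))
            start = j + 1
    return out


class TestStacking:
    def test_worked_example_three_quartets(self):
        assert [d.token for d in extract_stacking("(CGCG)")] == ["(CGC", "CGCG", "GCG)"]

    def test_minimal_domain_single_quartet(self):
        assert [d.token for d in extract_stacking("(AT)")] == ["(AT)"]

    def test_five_base_domain_four_quartets(self):
        tokens = [d.token for d in extract_stacking("(AACGT)")]
        assert tokens == brute_force_quartets("(AACGT)")
        assert len(tokens) == 4

    def test_single_base_domain_rejected(self):
        with pytest.raises(DescriptorError):
            extract_stacking("(A)")

    @given(
        st.lists(
            st.text(alphabet="ACGT", min_size=2, max_size=8), min_size=1, max_size=3
        ),
        st.lists(st.text(alphabet="ACGT", min_size=1, max_size=3), min_size=4, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_quartet_count_matches_window_oracle(self, stacks, loops):
        s = loops[0] + "".join(
            f"({stack}){loop}" for stack, loop in zip(stacks, loops[1 : len(stacks)] + [""])
        ) + loops[3]
        tokens = [d.token for d in extract_stacking(s)]
        assert tokens == brute_force_quartets(s)
        assert len(tokens) == sum(len(stack) - 1 for stack in stacks)


class TestDangling:
    def test_worked_example_prefix(self):
        tokens = [d.token for d in extract_dangling("CT(CGCG)")]
        assert tokens == ["*C", "T(C"]

    def test_perfect_duplex_has_no_dangles(self):
        assert extract_dangling("(CGCG)") == []

    def test_three_prime_mirror_rule(self):
        tokens = [d.token for d in extract_dangling("(CGCG)TA")]
        assert tokens == ["G)T", "*A"]

    def test_unstructured_strand_is_all_starred(self):
        tokens = [d.token for d in extract_dangling("AAAA")]
        assert tokens == ["*A"] * 4

    def test_both_strands_contribute_dangles(self):
        tokens = [d.token for d in extract_dangling("CT(CGCG)A.AA(CGCG)")]
        assert tokens == ["*C", "T(C", "G)A", "*A", "A(C"]


class TestLoopingInitiating:
    def test_loop_between_domains(self):
        assert [d.token for d in extract_looping("(AT)CC(AT)")] == ["C", "C"]
        assert [d.token for d in extract_looping("(AT)A(AT)")] == ["A"]

    def test_no_loops_in_perfect_duplex(self):
        assert extract_looping("(CGCG)") == []

    def test_initiating_tokens_per_domain(self):
        assert [d.token for d in extract_initiating("(CGCG)")] == ["(C", "G)"]
        assert extract_initiating("AAAA") == []

    def test_dot_is_an_initiating_term(self):
        tokens = [d.token for d in extract_initiating("(CG)A.(CG)")]
        assert tokens.count(".") == 1


class TestCoverage:
    @pytest.mark.parametrize(
        "s", ["(CGCG)", "CT(CGCG)A", "(AT)CC(AT)", "AAAA", "TT(ACGT)GG"]
    )
    def test_every_nucleotide_contributes(self, s):
        descriptors = extract_all(s)
        covered = set()
        for d in descriptors:
            covered.update(d.positions)
        n_letters = sum(1 for c in s if c in "ACGT")
        assert covered == set(range(n_letters))
        # dangles and loops cover each of their nucleotides exactly once
        once = [p for d in descriptors if d.kind in ("dangling", "looping") for p in d.positions]
        assert len(once) == len(set(once))


class TestEnumeration:
    @pytest.mark.parametrize(
        "kind,count", [("stacking", 400), ("dangling", 36), ("looping", 4), ("initiating", 9)]
    )
    def test_alphabet_sizes(self, kind, count):
        tokens = enumerate_terms(kind)
        assert len(tokens) == len(set(tokens)) == count

    def test_stacking_split(self):
        tokens = enumerate_terms("stacking")
        middle = [t for t in tokens if t.isalpha()]
        double = [t for t in tokens if t[0] == "(" and t[-1] == ")"]
        end = [t for t in tokens if (t[0] == "(") ^ (t[-1] == ")")]
        assert (len(middle), len(end), len(double)) == (256, 128, 16)

    def test_dangling_split(self):
        tokens = enumerate_terms("dangling")
        starred = [t for t in tokens if t.startswith("*")]
        assert len(starred) == 4
        assert len([t for t in tokens if "(" in t]) == 16
        assert len([t for t in tokens if ")" in t]) == 16

    def test_extracted_tokens_are_always_in_alphabet(self):
        alphabet = {t for kind in KINDS for t in enumerate_terms(kind)}
        for s in ["CT(CGCG)A.AA(CGCG)", "(AT)CC(AT)", "AAAA", "GGC(ATCG)T"]:
            assert {d.token for d in extract_all(s)} <= alphabet


class TestCanonicalization:
    def test_opposite_strand_equivalence(self):
        # 5'-TGCT-3'/3'-ACGA-5' is the same physical stack as 5'-AGCA-3'/3'-TCGT-5'
        assert canonicalize_stacking("TGCT") == canonicalize_stacking("AGCA")

    def test_palindrome_is_its_own_class(self):
        assert canonicalize_stacking("ATAT") == "ATAT"

    def test_idempotent_and_image_stable(self):
        for token in enumerate_terms("stacking"):
            c = canonicalize_stacking(token)
            assert canonicalize_stacking(c) == c

    def test_unique_class_counts(self):
        tokens = enumerate_terms("stacking")
        middle = {canonicalize_stacking(t) for t in tokens if t.isalpha()}
        end = {
            canonicalize_stacking(t)
            for t in tokens
            if (t[0] == "(") ^ (t[-1] == ")")
        }
        assert len(middle) == 136  # (4^4 + 4^2) / 2
        assert len(end) == 64  # 128 / 2

    def test_illegal_token_rejected(self):
        with pytest.raises(DescriptorError):
            canonicalize_stacking("AXGT")


class TestTermTable:
    def test_dense_deterministic_identifiers(self, term_table):
        assert len(term_table) == 449
        ids = sorted(term_table.ids.values())
        assert ids == list(range(1, 450))
        assert TermTable.default().ids == term_table.ids

    def test_kind_major_blocks(self, term_table):
        for token, ident in term_table.ids.items():
            kind = term_table.kinds[token]
            lo, hi = {
                "stacking": (1, 400),
                "dangling": (401, 436),
                "looping": (437, 440),
                "initiating": (441, 449),
            }[kind]
            assert lo <= ident <= hi

    def test_unknown_token_raises(self, term_table):
        with pytest.raises(UnknownTermError):
            term_table.identifier("XXXX")

    def test_tsv_round_trip(self, term_table, tmp_path):
        path = tmp_path / "terms.tsv"
        term_table.to_tsv(path)
        assert TermTable.from_tsv(path).ids == term_table.ids


@given(st.text(alphabet="ACGT", min_size=2, max_size=12))
@settings(max_examples=50, deadline=None)
def test_stack_token_count_property(stack):
    s = f"({stack})"
    parse_dna_string(s)
    assert len(extract_stacking(s)) == len(stack) - 1
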