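"""Occurrence scanning, the parameter-A statistic, and candidate ranking."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepscreen import (
    FragmentLibrary,
    Occurrence,
    ValidationError,
    annotate_table,
    find_occurrences,
    format_a,
    format_occurrences,
    parameter_a,
    scan,
    select_candidates,
)
from pepscreen.survey_io import SurveyTable
from pepscreen.synthetic_data import naive_find_occurrences
from conftest import parse_printed_annotation


def as_tuples(occurrences):
    return sorted((o.fragment, o.start, o.end) for o in occurrences)


def test_overlapping_and_nested_matches_all_count(library):
    occ = as_tuples(find_occurrences("SFDIPPPPMD", library))
    assert occ == sorted(
        [("SF", 1, 2), ("IP", 4, 5), ("PP", 5, 6), ("PP", 6, 7), ("PPPP", 5, 8),
         ("PP", 7, 8), ("PM", 8, 9)]
    )


def test_headline_peptide_positions(library):
    occ = as_tuples(find_occurrences("WTIAVPGPPHS", library))
    assert occ == sorted(
        [("GP", 7, 8), ("PP", 8, 9), ("VP", 5, 6), ("IA", 3, 4), ("WT", 1, 2),
         ("AV", 4, 5), ("HS", 10, 11), ("PG", 6, 7), ("PH", 9, 10), ("TI", 2, 3)]
    )


def test_homopolymer_overlap_semantics():
    lib = FragmentLibrary("x", frozenset({"AA"}))
    occ = as_tuples(find_occurrences("AAAA", lib))
    assert occ == [("AA", 1, 2), ("AA", 2, 3), ("AA", 3, 4)]
    assert parameter_a("AAAA", lib) == Fraction(3, 4)


@pytest.mark.parametrize(
    "sequence, expected",
    [
        ("WTIAVPGPPHS", "0.9091"),
        ("FKRPPL", "0.8333"),
        ("SFDIPPPPMD", "0.7000"),
        ("GVDNPGHPF", "0.8889"),
        ("VPAPVEIPVTPPTLVSGLK", "0.8421"),
    ],
)
def test_parameter_a_headline_values(library, sequence, expected):
    assert format_a(parameter_a(sequence, library)) == expected


def test_parameter_a_no_matches_and_empty_library(library):
    assert parameter_a("GGGGG", FragmentLibrary("x", frozenset({"WW"}))) == 0
    assert parameter_a("WTIA", FragmentLibrary("x", frozenset())) == 0
    with pytest.raises(ValidationError):
        find_occurrences("WTIA", FragmentLibrary("x", frozenset()))


def test_invalid_residue_rejected(library):
    with pytest.raises(ValidationError):
        find_occurrences("WTIAX", library)


def test_occurrence_span_invariant():
    with pytest.raises(ValidationError):
        Occurrence(1, 3, "AB")


def test_batch_reproduction_of_printed_profiles(library, printed_annotations):
    """Full-library scan reproduces every printed occurrence list, and every
    printed A value except the documented SAPILNIPIV carry-over."""
    mismatched_a = []
    for _, row in printed_annotations.iterrows():
        result = scan(row["sequence"], library)
        assert as_tuples(result.occurrences) == sorted(
            parse_printed_annotation(row["fragments_printed"])
        ), row["sequence"]
        if format_a(result.A) != row["A_printed"]:
            mismatched_a.append(row["sequence"])
    assert mismatched_a == ["SAPILNIPIV"]


def test_scan_result_bookkeeping(library):
    result = scan("FKRPPL", library)
    assert result.N == 6
    assert result.a == 5
    assert result.A == Fraction(5, 6)
    assert result.unique_fragments == {"PP", "RP", "PL", "PPL", "KR"}


_SEQ = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30)
_LIB = st.sets(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=4),
    min_size=1,
    max_size=15,
)


@given(sequence=_SEQ, fragments=_LIB)
def test_position_soundness(sequence, fragments):
    lib = FragmentLibrary("x", frozenset(fragments))
    for occ in find_occurrences(sequence, lib):
        assert sequence[occ.start - 1 : occ.end] == occ.fragment


@given(sequence=_SEQ, fragments=_LIB, extra=_LIB)
def test_parameter_a_monotone_under_library_growth(sequence, fragments, extra):
    small = FragmentLibrary("x", frozenset(fragments))
    big = FragmentLibrary("x", frozenset(fragments | extra))
    assert parameter_a(sequence, small) <= parameter_a(sequence, big)


def test_scanner_agrees_with_naive_oracle_bulk(library):
    """Production scanner == per-fragment sliding-window oracle, >=1000 cases."""
    rng = np.random.default_rng(20240901)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    frag_pool = sorted(library.fragments)
    checked = 0
    for _ in range(1000):
        seq = "".join(rng.choice(letters, size=rng.integers(2, 26)))
        lib_frags = [frag_pool[i] for i in rng.choice(len(frag_pool), size=8)]
        lib = FragmentLibrary("x", frozenset(lib_frags))
        got = as_tuples(find_occurrences(seq, lib))
        assert got == sorted(naive_find_occurrences(seq, sorted(lib.fragments)))
        checked += 1
    assert checked == 1000


def test_annotate_table_layout(wsf_table, library):
    frame = annotate_table(wsf_table, library)
    assert list(frame.columns) == [
        "sequence", "fraction", "protein_name", "accession", "N", "a", "A",
        "fragments",
    ]
    row = frame.set_index("sequence").loc["WTIAVPGPPHS"]
    assert row["N"] == 11 and row["a"] == 10 and row["A"] == 0.9091
    assert "PP [8–9]" in row["fragments"]


def test_annotate_empty_table(library):
    frame = annotate_table(SurveyTable((), ("28",), 1), library)
    assert frame.empty


def test_format_occurrences_groups_repeats(library):
    text = format_occurrences(find_occurrences("SFDIPPPPMD", library))
    assert "PP [5–6] [6–7] [7–8]" in text
    assert "PPPP [5–8]" in text


def test_select_candidates_per_fraction(wsf_table, ssf_table, library):
    import pandas as pd

    annotated = pd.concat(
        [annotate_table(wsf_table, library), annotate_table(ssf_table, library)],
        ignore_index=True,
    )
    top = select_candidates(annotated, top_k=1, per="fraction")
    by_fraction = top.set_index("fraction")
    assert by_fraction.loc["WSF", "sequence"] == "WTIAVPGPPHS"
    assert by_fraction.loc["WSF", "A"] == 0.9091
    assert by_fraction.loc["SSF", "sequence"] == "FKRPPL"
    assert by_fraction.loc["SSF", "A"] == 0.8333


def test_select_candidates_tie_break_and_errors(wsf_table, library):
    import pandas as pd

    frame = pd.DataFrame(
        [
            {"sequence": "BBB", "fraction": "WSF", "N": 3, "a": 2, "A": 0.5, "fragments": ""},
            {"sequence": "AAAA", "fraction": "WSF", "N": 4, "a": 2, "A": 0.5, "fragments": ""},
            {"sequence": "CCCC", "fraction": "WSF", "N": 4, "a": 2, "A": 0.5, "fragments": ""},
        ]
    )
    top = select_candidates(frame, top_k=2, per="fraction")
    # longer sequences first, then lexicographic
    assert list(top["sequence"]) == ["AAAA", "CCCC"]
    with pytest.raises(ValidationError):
        select_candidates(frame, top_k=0)
    with pytest.raises(ValidationError):
        select_candidates(frame.iloc[0:0], top_k=1)
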