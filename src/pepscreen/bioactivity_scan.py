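"""Fragment-occurrence scanning and the parameter-A occurrence statistic.

The frequency of bioactive-fragment occurrence in a peptide of length N is

    A = a / N

where ``a`` counts *every* occurrence of *every* library fragment as a
substring of the peptide — overlapping matches, repeated matches of the same
fragment, and motifs nested inside longer motifs (each PP inside PPPP) all
count separately. A higher A means a denser packing of bioactive motifs and
is used to rank candidate peptides.

Positions are 1-based and inclusive, matching the ``FRAG [start-end]``
notation of published occurrence profiles. Exact rationals are kept
internally; display rounds half-up to four decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .fragment_library import FragmentLibrary
from .survey_io import SurveyTable, validate_sequence

#: En dash used in the position notation, e.g. ``GP [7–8]``.
_DASH = "–"


@dataclass(frozen=True, order=True)
class Occurrence:
    """One fragment match; ``start``/``end`` are 1-based inclusive."""

    start: int
    end: int
    fragment: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.fragment):
            raise ValidationError(
                f"span [{self.start}-{self.end}] does not fit {self.fragment!r}"
            )


@dataclass(frozen=True)
class ScanResult:
    """All occurrences of a library in one peptide, with a and A = a/N."""

    sequence: str
    occurrences: tuple[Occurrence, ...]

    @property
    def N(self) -> int:
        return len(self.sequence)

    @property
    def a(self) -> int:
        return len(self.occurrences)

    @property
    def A(self) -> Fraction:
        return Fraction(self.a, self.N)

    @property
    def unique_fragments(self) -> frozenset[str]:
        return frozenset(o.fragment for o in self.occurrences)


def round_half_up(value: Fraction | float | int, ndigits: int = 4) -> float:
    """Round half away from zero at ``ndigits`` decimals (display convention)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(str(value))
    quantum = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(quantum, rounding=ROUND_HALF_UP))


def format_a(value: Fraction | float, ndigits: int = 4) -> str:
    """Format A with a fixed number of decimals, e.g. ``0.9091``."""
    return f"{round_half_up(value, ndigits):.{ndigits}f}"


def find_occurrences(
    sequence: str, library: FragmentLibrary
) -> list[Occurrence]:
    """All occurrences of all library fragments in ``sequence``.

    Overlapping, repeated, and nested matches are reported independently.
    The result is ordered by start position, then by descending fragment
    length (longer motifs first at the same start).
    """
    seq = validate_sequence(sequence)
    if len(library) == 0:
        raise ValidationError("fragment library is empty")
    by_length: dict[int, frozenset[str]] = {}
    for frag in library.fragments:
        by_length.setdefault(len(frag), set()).add(frag)  # type: ignore[arg-type]
    lengths = sorted(by_length, reverse=True)
    found: list[Occurrence] = []
    for i in range(len(seq)):
        for L in lengths:
            if i + L > len(seq):
                continue
            if seq[i : i + L] in by_length[L]:
                found.append(Occurrence(i + 1, i + L, seq[i : i + L]))
    return found


def scan(sequence: str, library: FragmentLibrary) -> ScanResult:
    """Scan one peptide and package the occurrence list as a ScanResult."""
    return ScanResult(validate_sequence(sequence), tuple(find_occurrences(sequence, library)))


def parameter_a(sequence: str, library: FragmentLibrary) -> Fraction:
    """Exact A = a/N for one peptide (0 for an empty library)."""
    seq = validate_sequence(sequence)
    if len(library) == 0:
        return Fraction(0, 1)
    return Fraction(len(find_occurrences(seq, library)), len(seq))


def format_occurrences(occurrences: Sequence[Occurrence]) -> str:
    """Render occurrences as ``FRAG [s–e]`` groups, repeats sharing one label.

    Fragments are listed in order of first occurrence (longer fragment first
    on a tied start); repeated fragments contribute one label followed by
    all position spans, e.g. ``PP [5–6] [6–7] [7–8]``.
    """
    groups: dict[str, list[Occurrence]] = {}
    for occ in sorted(occurrences, key=lambda o: (o.start, -len(o.fragment))):
        groups.setdefault(occ.fragment, []).append(occ)
    parts = []
    for fragment, occs in groups.items():
        spans = " ".join(f"[{o.start}{_DASH}{o.end}]" for o in occs)
        parts.append(f"{fragment} {spans}")
    return ", ".join(parts)


def annotate_table(table: SurveyTable, library: FragmentLibrary) -> pd.DataFrame:
    """One row per record with N, a, A (4-decimal) and the occurrence profile."""
    rows = []
    for rec in table:
        result = scan(rec.sequence, library)
        rows.append(
            {
                "sequence": rec.sequence,
                "fraction": rec.fraction,
                "protein_name": rec.protein_name,
                "accession": rec.accession,
                "N": result.N,
                "a": result.a,
                "A": round_half_up(result.A),
                "fragments": format_occurrences(result.occurrences),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence",
            "fraction",
            "protein_name",
            "accession",
            "N",
            "a",
            "A",
            "fragments",
        ],
    )


def select_candidates(
    annotated: pd.DataFrame, top_k: int = 1, per: str | None = "fraction"
) -> pd.DataFrame:
    """Top ``top_k`` rows by A within each group (default: per fraction).

    Ties break toward the longer sequence, then lexicographically.
    """
    if top_k < 1:
        raise ValidationError(f"top_k must be >= 1, got {top_k}")
    if annotated.empty:
        raise ValidationError("annotated table is empty")
    ranked = annotated.sort_values(
        by=["A", "N", "sequence"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    if per is None:
        return ranked.head(top_k).reset_index(drop=True)
    return (
        ranked.groupby(per, sort=True, group_keys=False)
        .head(top_k)
        .sort_values(by=per, kind="mergesort")
        .reset_index(drop=True)
    )
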