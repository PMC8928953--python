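"""Peptide detection tables and the aging-stability filter.

A peptidomic survey of a dry-cured meat product records, for every detected
peptide, in which independent experimental trials and at which aging time
points (periods, e.g. days 28/90/180/270/360) the sequence was observed.
This module reads and writes those presence/absence tables and applies the
two-stage stability criterion used to shortlist aging-stable peptides:

1. a peptide counts as *present in a period* when it was detected there in
   at least ``min_trials`` trials (consensus across trials), and
2. a peptide is retained when it is present in at least ``min_periods``
   periods.

With a single consensus trial (the layout of published summary tables) the
criterion reduces to "detected in >= min_periods periods".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
FRACTIONS = ("WSF", "SSF")
#: Default aging periods, in days.
DEFAULT_PERIODS: tuple[str, ...] = ("28", "90", "180", "270", "360")

_PRESENT = {"+", "1", "true", "t", "yes"}
# U+2212 (minus sign) and U+2013 (en dash) occur in typeset tables.
_ABSENT = {"-", "−", "–", "0", "false", "f", "no", ""}


def _parse_flag(value: object, where: str) -> bool:
    text = str(value).strip().lower()
    if text in _PRESENT:
        return True
    if text in _ABSENT or text == "nan":
        return False
    raise FormatError(f"unrecognised presence flag {value!r} in {where}")


def validate_sequence(sequence: str, where: str = "sequence") -> str:
    """Upper-case and validate a one-letter amino-acid string."""
    seq = str(sequence).strip().upper()
    if not seq:
        raise ValidationError(f"empty peptide sequence in {where}")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValidationError(
            f"non-amino-acid character(s) {sorted(bad)} in {where}: {sequence!r}"
        )
    return seq


@dataclass(frozen=True)
class PeptideRecord:
    """One detected peptide and its trial x period detection matrix."""

    sequence: str
    fraction: str
    protein_name: str = ""
    accession: str = ""
    #: boolean matrix, shape (n_trials, n_periods)
    detection: np.ndarray = field(default_factory=lambda: np.ones((1, 1), bool))

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))
        fraction = str(self.fraction).strip().upper()
        if fraction not in FRACTIONS:
            raise ValidationError(
                f"fraction must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        object.__setattr__(self, "fraction", fraction)
        det = np.asarray(self.detection, dtype=bool)
        if det.ndim != 2 or det.shape[0] < 1 or det.shape[1] < 1:
            raise ValidationError(
                f"detection matrix must be 2-D and non-empty, got shape {det.shape}"
            )
        object.__setattr__(self, "detection", det)

    @property
    def n_trials(self) -> int:
        return self.detection.shape[0]

    @property
    def n_periods(self) -> int:
        return self.detection.shape[1]

    def periods_present(self, min_trials: int = 1) -> np.ndarray:
        """Boolean per-period consensus: detected in >= min_trials trials."""
        return self.detection.sum(axis=0) >= min_trials


@dataclass(frozen=True)
class SurveyTable:
    """An ordered collection of peptide records sharing trial/period axes."""

    records: tuple[PeptideRecord, ...]
    periods: tuple[str, ...] = DEFAULT_PERIODS
    n_trials: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "periods", tuple(str(p) for p in self.periods))
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.detection.shape != (self.n_trials, len(self.periods)):
                raise ValidationError(
                    f"record {rec.sequence}: detection shape {rec.detection.shape} "
                    f"does not match table ({self.n_trials}, {len(self.periods)})"
                )
            key = (rec.sequence, rec.fraction)
            if key in seen:
                raise ValidationError(f"duplicate (sequence, fraction) row: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the TSV column layout (one flag column per trial:period)."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "sequence": rec.sequence,
                "fraction": rec.fraction,
                "protein_name": rec.protein_name,
                "accession": rec.accession,
            }
            for t in range(self.n_trials):
                for j, period in enumerate(self.periods):
                    col = period if self.n_trials == 1 else f"t{t + 1}:{period}"
                    row[col] = "+" if rec.detection[t, j] else "-"
            rows.append(row)
        columns = ["sequence", "fraction", "protein_name", "accession"]
        if self.n_trials == 1:
            columns += list(self.periods)
        else:
            columns += [
                f"t{t + 1}:{p}" for t in range(self.n_trials) for p in self.periods
            ]
        return pd.DataFrame(rows, columns=columns)


_META_COLUMNS = ["sequence", "fraction", "protein_name", "accession"]


def read_survey_table(path: str | Path, n_trials: int | None = None) -> SurveyTable:
    """Read a detection table from TSV.

    Flag columns are either one per period (header = period label, single
    consensus trial) or one per trial:period pair (header ``t1:28``).
    ``n_trials``, when given, must agree with the header layout.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    missing = [c for c in _META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    flag_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    if not flag_cols:
        raise FormatError(f"{path}: no period columns found")

    if any(":" in c for c in flag_cols):
        pairs = []
        for col in flag_cols:
            trial, _, period = col.partition(":")
            if not (trial.startswith("t") and trial[1:].isdigit()):
                raise FormatError(f"{path}: malformed trial:period header {col!r}")
            pairs.append((int(trial[1:]), period))
        trials = sorted({t for t, _ in pairs})
        periods = list(dict.fromkeys(p for _, p in pairs))
        if trials != list(range(1, len(trials) + 1)):
            raise FormatError(f"{path}: trial indices must be t1..tT, got {trials}")
        expected = [(t, p) for t in trials for p in periods]
        if sorted(pairs) != sorted(expected):
            raise FormatError(f"{path}: trial/period grid is not rectangular")
        inferred_trials = len(trials)
        column_of = {tp: f"t{tp[0]}:{tp[1]}" for tp in pairs}
    else:
        periods = flag_cols
        inferred_trials = 1
        column_of = {(1, p): p for p in periods}

    if n_trials is not None and n_trials != inferred_trials:
        raise FormatError(
            f"{path}: header describes {inferred_trials} trial(s), "
            f"but n_trials={n_trials} was requested"
        )

    records = []
    for idx, row in frame.iterrows():
        where = f"{path} row {idx + 2}"  # 1-based, counting the header
        detection = np.zeros((inferred_trials, len(periods)), dtype=bool)
        for t in range(1, inferred_trials + 1):
            for j, period in enumerate(periods):
                detection[t - 1, j] = _parse_flag(
                    row[column_of[(t, period)]], where
                )
        try:
            records.append(
                PeptideRecord(
                    sequence=row["sequence"],
                    fraction=row["fraction"],
                    protein_name=row["protein_name"],
                    accession=row["accession"],
                    detection=detection,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{where}: {exc}") from exc
    try:
        return SurveyTable(tuple(records), tuple(periods), inferred_trials)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_survey_table(table: SurveyTable, path: str | Path) -> None:
    """Write a detection table as TSV (inverse of :func:`read_survey_table`)."""
    table.to_frame().to_csv(path, sep="\t", index=False)


def stability_filter(
    table: SurveyTable, min_trials: int = 1, min_periods: int = 3
) -> SurveyTable:
    """Keep the peptides that satisfy the two-stage stability criterion.

    A record survives when, in at least ``min_periods`` periods, it was
    detected in at least ``min_trials`` trials. Input order is preserved.
    """
    if not 1 <= min_trials <= table.n_trials:
        raise ValidationError(
            f"min_trials must be in [1, {table.n_trials}], got {min_trials}"
        )
    if not 1 <= min_periods <= len(table.periods):
        raise ValidationError(
            f"min_periods must be in [1, {len(table.periods)}], got {min_periods}"
        )
    kept = tuple(
        rec
        for rec in table.records
        if int(rec.periods_present(min_trials).sum()) >= min_periods
    )
    return replace(table, records=kept)
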