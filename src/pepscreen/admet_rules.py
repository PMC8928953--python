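"""Rule-based ADMET classification and target-probability ranking.

ADMET predictions (Caco-2 permeability, human intestinal absorption,
plasma-protein binding, blood-brain-barrier score, volume of distribution,
CYP450 2D6 status, half-life index, acute-toxicity LD50) and ligand-target
probabilities are produced by external predictors and *ingested* here as
data; this module applies fixed, configurable decision thresholds:

* Caco-2 optimal:      log permeability > -5.15 (log cm/s)
* HIA:                 binary flag (1 = HIA+, with a probability attached)
* PPB acceptable:      < 90 % bound (highly bound drugs need caution)
* BBB+:                brain/blood ratio score >= 0.1
* VD optimal:          0.04 - 20 L/kg
* T1/2 bands:          < 3 h low, 3-8 h moderate (endpoints inclusive),
                       > 8 h high
* CYP2D6:              categorical pass-through
                       (non-interactor / inhibitor / substrate)

The thresholds live in a flat JSON config so alternative rule sets can be
swapped in; the defaults above ship with the package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .survey_io import validate_sequence

CYP_CLASSES = ("non-interactor", "inhibitor", "substrate")


@dataclass(frozen=True)
class AdmetThresholds:
    """Decision thresholds for the rule-based ADMET classification."""

    caco2_optimal_gt: float = -5.15
    ppb_acceptable_lt: float = 90.0
    bbb_positive_ge: float = 0.1
    vd_optimal_min: float = 0.04
    vd_optimal_max: float = 20.0
    t_half_low_lt: float = 3.0
    t_half_high_gt: float = 8.0


def load_thresholds(path: str | Path | None = None) -> AdmetThresholds:
    """Load thresholds from a flat JSON file (package default when None)."""
    if path is None:
        ref = resources.files("pepscreen.data") / "admet_thresholds.json"
        raw = json.loads(ref.read_text(encoding="utf-8"))
    else:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    known = {f.name for f in fields(AdmetThresholds)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown threshold key(s): {sorted(unknown)}")
    return AdmetThresholds(**raw)


@dataclass(frozen=True)
class AdmetRecord:
    """One ligand's ADMET prediction row (values from an external predictor)."""

    parent: str
    fragment: str
    caco2: float  # log cm/s
    hia_flag: int  # 0 = HIA-, 1 = HIA+
    hia_prob: Optional[float]  # present iff hia_flag == 1
    ppb: float  # percent bound
    bbb: float  # brain/blood ratio score
    vd: float  # L/kg
    cyp2d6: str  # non-interactor / inhibitor / substrate
    t_half: float  # hours-scale index
    ld50: float  # -log mol/kg

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent", validate_sequence(self.parent, "parent"))
        object.__setattr__(
            self, "fragment", validate_sequence(self.fragment, "fragment")
        )
        for name in ("caco2", "ppb", "bbb", "vd", "t_half", "ld50"):
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValidationError(f"missing ADMET field {name!r} for {self.fragment}")
        if self.hia_flag not in (0, 1):
            raise ValidationError(f"hia_flag must be 0 or 1, got {self.hia_flag}")
        if (self.hia_prob is not None) != (self.hia_flag == 1):
            raise ValidationError(
                f"{self.fragment}: hia_prob must be present iff hia_flag == 1"
            )
        if self.hia_prob is not None and not 0.0 <= self.hia_prob <= 1.0:
            raise ValidationError(f"hia_prob outside [0, 1]: {self.hia_prob}")
        if not 0.0 <= self.ppb <= 100.0:
            raise ValidationError(f"PPB outside [0, 100] %: {self.ppb}")
        if self.cyp2d6 not in CYP_CLASSES:
            raise ValidationError(
                f"cyp2d6 must be one of {CYP_CLASSES}, got {self.cyp2d6!r}"
            )


@dataclass(frozen=True)
class AdmetVerdict:
    """Per-parameter categorical classification of one AdmetRecord."""

    parent: str
    fragment: str
    caco2_optimal: bool
    hia_class: str  # "HIA+" / "HIA-"
    ppb_class: str  # "acceptable" / "highly-bound"
    bbb_class: str  # "BBB+" / "BBB-"
    vd_optimal: bool
    cyp_class: str
    t_half_class: str  # "low" / "moderate" / "high"


def classify_admet(
    record: AdmetRecord, thresholds: AdmetThresholds | None = None
) -> AdmetVerdict:
    """Apply the decision thresholds to one record (pure function)."""
    th = thresholds or AdmetThresholds()
    if record.t_half < th.t_half_low_lt:
        t_half_class = "low"
    elif record.t_half > th.t_half_high_gt:
        t_half_class = "high"
    else:
        t_half_class = "moderate"  # band edges closed on the moderate side
    return AdmetVerdict(
        parent=record.parent,
        fragment=record.fragment,
        caco2_optimal=record.caco2 > th.caco2_optimal_gt,
        hia_class="HIA+" if record.hia_flag == 1 else "HIA-",
        ppb_class="acceptable" if record.ppb < th.ppb_acceptable_lt else "highly-bound",
        bbb_class="BBB+" if record.bbb >= th.bbb_positive_ge else "BBB-",
        vd_optimal=th.vd_optimal_min <= record.vd <= th.vd_optimal_max,
        cyp_class=record.cyp2d6,
        t_half_class=t_half_class,
    )


def classify_table(
    records: Sequence[AdmetRecord], thresholds: AdmetThresholds | None = None
) -> pd.DataFrame:
    """Verdicts for a list of records, as a DataFrame (one row per record)."""
    verdicts = [classify_admet(rec, thresholds) for rec in records]
    return pd.DataFrame([vars(v) for v in verdicts])


_NUMERIC_COLUMNS = ("caco2", "ppb", "bbb", "vd", "t_half", "ld50")


def summarize_admet(
    records: Sequence[AdmetRecord], exclude: Iterable[str] | None = None
) -> dict:
    """Per-column min / max / mean plus HIA+ and CYP-substrate tallies.

    ``exclude`` drops records by fragment sequence before computing the
    statistics (used e.g. to report a toxicity mean without an outlier).
    Means are reported to 3 decimals; min/max are exact.
    """
    if not records:
        raise ValidationError("no ADMET records to summarize")
    excluded = {validate_sequence(f, "exclude") for f in exclude} if exclude else set()
    kept = [r for r in records if r.fragment not in excluded]
    if not kept:
        raise ValidationError("exclusion removed every ADMET record")
    summary: dict = {"n": len(kept), "excluded": sorted(excluded)}
    for column in _NUMERIC_COLUMNS:
        values = [getattr(r, column) for r in kept]
        summary[column] = {
            "min": min(values),
            "max": max(values),
            "mean": round(sum(values) / len(values), 3),
        }
    hia_positive = sorted(r.fragment for r in kept if r.hia_flag == 1)
    summary["hia_positive"] = {"count": len(hia_positive), "fragments": hia_positive}
    substrates = sorted(r.fragment for r in kept if r.cyp2d6 == "substrate")
    summary["cyp2d6_substrates"] = substrates
    return summary


def _parse_hia(text: str, where: str) -> tuple[int, Optional[float]]:
    """Parse an HIA cell: ``0`` or ``1 (0.504)``."""
    text = str(text).strip()
    if text == "0":
        return 0, None
    if text.startswith("1"):
        inner = text[1:].strip().strip("()")
        if not inner:
            raise FormatError(f"{where}: HIA+ cell missing probability: {text!r}")
        return 1, float(inner)
    raise FormatError(f"{where}: unrecognised HIA cell {text!r}")


def _parse_cyp(text: str, where: str) -> str:
    """Parse a CYP2D6 cell: ``0``, ``1 (substrate)`` or ``1 (inhibitor)``."""
    text = str(text).strip()
    if text == "0":
        return "non-interactor"
    if text.startswith("1"):
        inner = text[1:].strip().strip("()").lower()
        if inner in ("substrate", "inhibitor"):
            return inner
    if text in CYP_CLASSES:
        return text
    raise FormatError(f"{where}: unrecognised CYP2D6 cell {text!r}")


def read_admet_table(path: str | Path | None = None) -> list[AdmetRecord]:
    """Read an ADMET prediction TSV (package fixture when path is None).

    Expected columns: parent, fragment, caco2, hia, ppb, bbb, vd, cyp2d6,
    t_half, ld50. The hia and cyp2d6 cells use the predictor's printed
    convention (``0`` / ``1 (0.504)`` and ``0`` / ``1 (substrate)``).
    """
    if path is None:
        ref = resources.files("pepscreen.data") / "admet_profile.tsv"
        with resources.as_file(ref) as p:
            return read_admet_table(p)
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [
        "parent", "fragment", "caco2", "hia", "ppb", "bbb", "vd",
        "cyp2d6", "t_half", "ld50",
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for idx, row in frame.iterrows():
        where = f"{path} row {idx + 2}"
        hia_flag, hia_prob = _parse_hia(row["hia"], where)
        records.append(
            AdmetRecord(
                parent=row["parent"],
                fragment=row["fragment"],
                caco2=float(row["caco2"]),
                hia_flag=hia_flag,
                hia_prob=hia_prob,
                ppb=float(row["ppb"]),
                bbb=float(row["bbb"]),
                vd=float(row["vd"]),
                cyp2d6=_parse_cyp(row["cyp2d6"], where),
                t_half=float(row["t_half"]),
                ld50=float(row["ld50"]),
            )
        )
    return records


@dataclass(frozen=True)
class TargetProbability:
    """Predicted probability that a ligand interacts with the target enzyme."""

    fragment: str
    smiles: str
    probability: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fragment", validate_sequence(self.fragment, "fragment")
        )
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"{self.fragment}: probability outside [0, 1]: {self.probability}"
            )


def read_probability_table(path: str | Path | None = None) -> list[TargetProbability]:
    """Read a ligand-probability TSV (package fixture when path is None).

    Expected columns: parent, fragment, smiles, probability. The parent
    column is carried for provenance but not part of the ranking key.
    """
    if path is None:
        ref = resources.files("pepscreen.data") / "dppiv_probabilities.tsv"
        with resources.as_file(ref) as p:
            return read_probability_table(p)
    frame = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("fragment", "smiles", "probability") if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        TargetProbability(row["fragment"], row["smiles"], float(row["probability"]))
        for _, row in frame.iterrows()
    ]


def rank_target_probabilities(
    rows: Sequence[TargetProbability],
) -> list[TargetProbability]:
    """Order ligands by descending probability (ties: alphabetical fragment).

    A fragment appearing more than once (e.g. shared by two parent peptides)
    collapses to a single row; conflicting probabilities are an error.
    """
    merged: dict[str, TargetProbability] = {}
    for row in rows:
        prior = merged.get(row.fragment)
        if prior is None:
            merged[row.fragment] = row
        elif prior.probability != row.probability:
            raise ValidationError(
                f"conflicting probabilities for {row.fragment}: "
                f"{prior.probability} vs {row.probability}"
            )
    return sorted(merged.values(), key=lambda r: (-r.probability, r.fragment))
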