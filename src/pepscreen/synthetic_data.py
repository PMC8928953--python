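"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the data shapes the screen consumes, without any
mass-spectrometry realism:

* detection matrices — independent Bernoulli presence flags per
  (peptide, trial, period), emulating a multi-trial, multi-period survey;
* planted-motif peptides — background residues chosen (when possible) from
  letters that occur in no library fragment, with library fragments planted
  at recorded positions, so expected occurrence counts are well defined;
* ADMET-like tables — uniform draws within configurable ranges per column.

Every generator returns a :class:`SyntheticLedger` from which each expected
value can be recomputed by an independent brute-force routine (the naive
scanner below, a direct matrix recount, or a direct threshold recount) —
never by trusting the generation plan.

All randomness flows through one ``numpy`` Generator seeded per call; the
same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Optional, Sequence

import numpy as np

from .admet_rules import AdmetRecord, AdmetThresholds
from .errors import ValidationError
from .fragment_library import FragmentLibrary
from .survey_io import AMINO_ACIDS, DEFAULT_PERIODS, PeptideRecord, SurveyTable


def naive_find_occurrences(sequence: str, fragments: Sequence[str]):
    """Brute-force occurrence list: (fragment, start, end), 1-based inclusive.

    Deliberately simple (per-fragment sliding window) so it can serve as an
    independent oracle for the production scanner.
    """
    found = []
    for fragment in fragments:
        span = len(fragment)
        for i in range(len(sequence) - span + 1):
            if sequence[i : i + span] == fragment:
                found.append((fragment, i + 1, i + span))
    return sorted(found, key=lambda t: (t[1], -len(t[0]), t[0]))


def naive_count(sequence: str, fragments: Sequence[str]) -> int:
    """Brute-force occurrence count (the ``a`` of A = a/N)."""
    return len(naive_find_occurrences(sequence, fragments))


@dataclass
class SyntheticLedger:
    """Ground truth accompanying a synthetic data set.

    Only the fields relevant to the generator that produced the ledger are
    populated. Every derived quantity is recomputed from the raw data by
    brute force, so the ledger stays valid however the data are consumed.
    """

    seed: int
    #: raw detection flags, shape (n_peptides, n_trials, n_periods)
    detection: Optional[np.ndarray] = None
    sequences: tuple[str, ...] = ()
    #: planting plan per sequence: list of (fragment, 1-based start)
    planted: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    #: brute-force occurrence count per sequence
    expected_counts: dict[str, int] = field(default_factory=dict)
    #: exact A = a/N per sequence
    expected_a: dict[str, Fraction] = field(default_factory=dict)

    def survivors(self, min_trials: int, min_periods: int) -> list[str]:
        """Recount the stability-filter survivor set directly from the flags."""
        if self.detection is None:
            raise ValidationError("this ledger carries no detection matrix")
        out = []
        for name, matrix in zip(self.sequences, self.detection):
            periods_ok = 0
            for j in range(matrix.shape[1]):
                if int(matrix[:, j].sum()) >= min_trials:
                    periods_ok += 1
            if periods_ok >= min_periods:
                out.append(name)
        return out


def _random_sequences(
    rng: np.random.Generator, n: int, length: int, alphabet: str = AMINO_ACIDS
) -> list[str]:
    letters = np.array(list(alphabet))
    return ["".join(rng.choice(letters, size=length)) for _ in range(n)]


def generate_detection_matrix(
    n_peptides: int,
    n_trials: int,
    n_periods: int,
    p_present: float,
    seed: int,
) -> tuple[SurveyTable, SyntheticLedger]:
    """Random survey table with independent Bernoulli(p_present) flags."""
    if not 0.0 <= p_present <= 1.0:
        raise ValidationError(f"p_present must be in [0, 1], got {p_present}")
    if min(n_peptides, n_trials, n_periods) < 1:
        raise ValidationError("n_peptides, n_trials and n_periods must be >= 1")
    rng = np.random.default_rng(seed)
    detection = rng.random((n_peptides, n_trials, n_periods)) < p_present
    # unique sequences: deterministic 10-mers, regenerated on collision
    sequences: list[str] = []
    seen: set[str] = set()
    while len(sequences) < n_peptides:
        for seq in _random_sequences(rng, n_peptides - len(sequences), 10):
            if seq not in seen:
                seen.add(seq)
                sequences.append(seq)
    periods = (
        DEFAULT_PERIODS
        if n_periods == len(DEFAULT_PERIODS)
        else tuple(f"p{i + 1}" for i in range(n_periods))
    )
    records = tuple(
        PeptideRecord(seq, "WSF", "synthetic", "SYN0000", detection[i])
        for i, seq in enumerate(sequences)
    )
    table = SurveyTable(records, periods, n_trials)
    ledger = SyntheticLedger(
        seed=seed, detection=detection, sequences=tuple(sequences)
    )
    return table, ledger


def generate_planted_peptides(
    n: int,
    length: int,
    library: FragmentLibrary,
    plant_rate: float,
    seed: int,
) -> tuple[list[str], SyntheticLedger]:
    """Random peptides with library fragments planted at recorded positions.

    Background residues are drawn from the letters that occur in no library
    fragment when any exist (making accidental matches impossible);
    otherwise the background is the full alphabet and the ledger's expected
    counts — always recomputed by the naive oracle on the final sequence —
    remain authoritative.
    """
    if not 0.0 <= plant_rate <= 1.0:
        raise ValidationError(f"plant_rate must be in [0, 1], got {plant_rate}")
    fragments = sorted(library.fragments, key=lambda f: (len(f), f))
    if not fragments:
        raise ValidationError("cannot plant from an empty library")
    if length < library.max_fragment_length:
        raise ValidationError(
            f"length {length} shorter than longest fragment "
            f"({library.max_fragment_length})"
        )
    background = sorted(set(AMINO_ACIDS) - set("".join(fragments)))
    if not background:
        background = list(AMINO_ACIDS)
    rng = np.random.default_rng(seed)
    bg = np.array(background)
    sequences: list[str] = []
    ledger = SyntheticLedger(seed=seed)
    for _ in range(n):
        chars: list[str] = []
        plan: list[tuple[str, int]] = []
        while len(chars) < length:
            remaining = length - len(chars)
            candidates = [f for f in fragments if len(f) <= remaining]
            if candidates and rng.random() < plant_rate:
                frag = candidates[rng.integers(len(candidates))]
                plan.append((frag, len(chars) + 1))
                chars.extend(frag)
            else:
                chars.append(str(rng.choice(bg)))
        seq = "".join(chars)
        sequences.append(seq)
        ledger.planted[seq] = plan
        count = naive_count(seq, fragments)
        ledger.expected_counts[seq] = count
        ledger.expected_a[seq] = Fraction(count, length)
    ledger.sequences = tuple(sequences)
    return sequences, ledger


#: Default sampling ranges for the synthetic ADMET generator; spans chosen to
#: straddle every decision threshold so all verdict classes are exercised.
DEFAULT_ADMET_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "caco2": (-7.0, -4.0),
    "ppb": (0.0, 100.0),
    "bbb": (-0.5, 1.2),
    "vd": (-1.0, 25.0),
    "t_half": (0.0, 12.0),
    "ld50": (1.0, 4.0),
}


def generate_admet_table(
    n: int,
    seed: int,
    distributions: Mapping[str, tuple[float, float]] | None = None,
    p_hia: float = 0.3,
    p_substrate: float = 0.1,
) -> tuple[list[AdmetRecord], dict]:
    """Random ADMET records plus expected verdict-class counts.

    Numeric columns are uniform draws within the configured (low, high)
    ranges; HIA and CYP-substrate status are Bernoulli. The expected counts
    are obtained by direct threshold application to the drawn values, not by
    tracking the draws.
    """
    dists = dict(DEFAULT_ADMET_DISTRIBUTIONS)
    if distributions:
        unknown = set(distributions) - set(dists)
        if unknown:
            raise ValidationError(f"unknown distribution key(s): {sorted(unknown)}")
        dists.update(distributions)
    for key, (low, high) in dists.items():
        if not low <= high:
            raise ValidationError(f"invalid range for {key}: ({low}, {high})")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sequences = _random_sequences(rng, n, 2)
    records = []
    for i, seq in enumerate(sequences):
        draw = {k: float(rng.uniform(*dists[k])) for k in sorted(dists)}
        hia_flag = int(rng.random() < p_hia)
        cyp = "substrate" if rng.random() < p_substrate else "non-interactor"
        records.append(
            AdmetRecord(
                parent=seq,
                fragment=seq,
                caco2=draw["caco2"],
                hia_flag=hia_flag,
                hia_prob=float(rng.uniform(0.5, 1.0)) if hia_flag else None,
                ppb=draw["ppb"],
                bbb=draw["bbb"],
                vd=draw["vd"],
                cyp2d6=cyp,
                t_half=draw["t_half"],
                ld50=draw["ld50"],
            )
        )
    th = AdmetThresholds()
    expected = {
        "caco2_optimal": sum(r.caco2 > th.caco2_optimal_gt for r in records),
        "hia_positive": sum(r.hia_flag == 1 for r in records),
        "ppb_acceptable": sum(r.ppb < th.ppb_acceptable_lt for r in records),
        "bbb_positive": sum(r.bbb >= th.bbb_positive_ge for r in records),
        "vd_optimal": sum(
            th.vd_optimal_min <= r.vd <= th.vd_optimal_max for r in records
        ),
        "cyp_substrate": sum(r.cyp2d6 == "substrate" for r in records),
        "t_half_low": sum(r.t_half < th.t_half_low_lt for r in records),
        "t_half_high": sum(r.t_half > th.t_half_high_gt for r in records),
    }
    expected["t_half_moderate"] = n - expected["t_half_low"] - expected["t_half_high"]
    return records, expected
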