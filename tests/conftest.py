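"""Shared fixtures: packaged tables, the DPP-IV library, printed oracles."""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

from pepscreen import builtin_library, read_survey_table

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

TESTS_DIR = Path(__file__).parent


def data_path(name: str) -> Path:
    """Path of a fixture packaged under pepscreen/data."""
    with resources.as_file(resources.files("pepscreen.data") / name) as p:
        return Path(p)


def parse_printed_annotation(text: str) -> list[tuple[str, int, int]]:
    """Parse 'FA [3-4], AG [1-2] [4-5]' into (fragment, start, end) tuples."""
    out = []
    for part in text.split(","):
        part = part.strip()
        match = re.match(r"^([A-Z]+)((?: \[\d+-\d+\])+)$", part)
        assert match, f"unparsable annotation chunk: {part!r}"
        fragment = match.group(1)
        for start, end in re.findall(r"\[(\d+)-(\d+)\]", match.group(2)):
            out.append((fragment, int(start), int(end)))
    return out


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture(scope="session")
def wsf_table():
    return read_survey_table(data_path("survey_wsf.tsv"))


@pytest.fixture(scope="session")
def ssf_table():
    return read_survey_table(data_path("survey_ssf.tsv"))


@pytest.fixture(scope="session")
def printed_annotations() -> pd.DataFrame:
    """Printed per-peptide A values and occurrence profiles (test oracle)."""
    return pd.read_csv(
        TESTS_DIR / "data" / "printed_annotations.tsv", sep="\t", dtype=str
    )
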