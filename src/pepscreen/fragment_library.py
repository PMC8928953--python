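"""Bioactive-fragment libraries.

A fragment library is a named activity class (here: DPP-IV inhibition)
together with a set of short amino-acid motifs (length >= 2) that carry that
activity. Peptides are screened by counting occurrences of these motifs.

The packaged ``dppiv_survey`` library is the union of every DPP-IV
inhibitory fragment annotated in the dry-cured pork loin survey tables
shipped with this package (105 motifs, mostly dipeptides plus PPL, IPI, IPM,
IIAP and PPPP).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import FormatError, ValidationError

_FRAGMENT_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]{2,}$")

#: Name of the packaged DPP-IV library.
DPPIV_SURVEY = "dppiv_survey"


def _validate_fragment(fragment: str) -> str:
    frag = str(fragment).strip().upper()
    if not _FRAGMENT_RE.match(frag):
        raise ValidationError(
            f"invalid fragment {fragment!r}: must be >= 2 standard one-letter "
            "amino-acid codes"
        )
    return frag


@dataclass(frozen=True)
class FragmentLibrary:
    """A named activity plus a set of amino-acid motifs (length >= 2)."""

    activity: str
    fragments: frozenset[str]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "fragments",
            frozenset(_validate_fragment(f) for f in self.fragments),
        )

    def __len__(self) -> int:
        return len(self.fragments)

    def __contains__(self, fragment: object) -> bool:
        return fragment in self.fragments

    def __iter__(self) -> Iterator[str]:
        """Iterate fragments in a stable order (length, then alphabetical)."""
        return iter(sorted(self.fragments, key=lambda f: (len(f), f)))

    @property
    def max_fragment_length(self) -> int:
        return max((len(f) for f in self.fragments), default=0)

    def residues(self) -> frozenset[str]:
        """All residues used by any fragment."""
        return frozenset("".join(self.fragments))


def build_library_from_annotations(
    rows: Iterable[tuple[str, Iterable[str]]],
    activity: str = "DPP-IV inhibitor",
) -> FragmentLibrary:
    """Union the per-peptide fragment annotations into one library.

    ``rows`` are (parent sequence, iterable of plain fragment strings with
    positions already stripped). The operation is order-independent and
    idempotent: duplicates collapse by set union.
    """
    fragments: set[str] = set()
    provenance: dict[str, str] = {}
    for sequence, frags in rows:
        for fragment in frags:
            frag = _validate_fragment(fragment)
            fragments.add(frag)
            provenance.setdefault(frag, f"annotated in {sequence}")
    return FragmentLibrary(activity, frozenset(fragments), provenance)


def load_library(path: str | Path) -> FragmentLibrary:
    """Load a plain-text library: one fragment per line, ``#`` comments.

    A comment of the form ``# activity: <label>`` sets the activity label.
    Blank (non-comment) lines are a format error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    activity = "unspecified"
    fragments: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("activity:"):
                activity = body[len("activity:"):].strip()
            continue
        if not line:
            raise FormatError(f"{path}:{lineno}: empty fragment line")
        try:
            fragments.add(_validate_fragment(line))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return FragmentLibrary(activity, frozenset(fragments))


def save_library(library: FragmentLibrary, path: str | Path) -> None:
    """Write a library so that ``load_library`` restores it exactly."""
    lines = [f"# activity: {library.activity}"]
    lines += list(library)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def builtin_library(name: str = DPPIV_SURVEY) -> FragmentLibrary:
    """Load a library shipped with the package by short name."""
    ref = resources.files("pepscreen.data") / f"{name}.txt"
    if not ref.is_file():
        raise FormatError(f"no packaged library named {name!r}")
    with resources.as_file(ref) as path:
        return load_library(path)
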