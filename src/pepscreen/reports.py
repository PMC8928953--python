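"""End-to-end screen orchestration and report rendering.

The screen runs in the order the underlying workflow prescribes: stability
filter -> occurrence scan and parameter-A annotation -> candidate selection
-> short-ligand enumeration -> SMILES construction -> target-probability
ranking -> ADMET verdicts and summary. ``run_pipeline`` executes the stages
and returns an in-memory :class:`ReportBundle`; ``render_report`` writes the
bundle as TSV tables, a JSON summary, or a markdown report. Rendering is
deterministic: the same bundle always produces identical bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import bioactivity_scan as scan_mod
from .admet_rules import (
    AdmetRecord,
    AdmetThresholds,
    TargetProbability,
    classify_table,
    rank_target_probabilities,
    summarize_admet,
)
from .errors import ValidationError
from .fragment_library import DPPIV_SURVEY, FragmentLibrary, builtin_library, load_library
from .peptide_chem import enumerate_bioactive_fragments, peptide_to_smiles
from .survey_io import SurveyTable, stability_filter


@dataclass(frozen=True)
class PipelineConfig:
    """Run-time parameters of the full screen (defaults = packaged study)."""

    library: str = DPPIV_SURVEY  # builtin name or path to a library file
    min_trials: int = 1
    min_periods: int = 3
    top_k: int = 1
    fragment_max_len: int = 3
    thresholds: Optional[str] = None  # path to a thresholds JSON, None = default
    ld50_exclude: tuple[str, ...] = ()  # fragments excluded from the summary

    def resolve_library(self) -> FragmentLibrary:
        if Path(self.library).exists():
            return load_library(self.library)
        return builtin_library(self.library)


@dataclass
class ReportBundle:
    """Everything one screen run produced, ready to render."""

    annotated: pd.DataFrame  # filtered survey rows with N, a, A, fragments
    candidates: pd.DataFrame  # top rows per fraction
    ligands: pd.DataFrame  # candidate fragments with SMILES
    probability_ranking: list[TargetProbability] = field(default_factory=list)
    verdicts: pd.DataFrame = field(default_factory=pd.DataFrame)
    admet_summary: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig,
    tables: Sequence[SurveyTable],
    admet_records: Sequence[AdmetRecord] = (),
    probability_rows: Sequence[TargetProbability] = (),
    thresholds: AdmetThresholds | None = None,
) -> ReportBundle:
    """Execute filter -> scan -> select -> ligands -> SMILES -> rank -> ADMET."""
    library = config.resolve_library()

    filtered = [
        stability_filter(t, config.min_trials, config.min_periods) for t in tables
    ]
    annotated_parts = [
        scan_mod.annotate_table(t, library) for t in filtered if len(t) > 0
    ]
    if annotated_parts:
        annotated = pd.concat(annotated_parts, ignore_index=True)
        candidates = scan_mod.select_candidates(
            annotated, top_k=config.top_k, per="fraction"
        )
    else:
        annotated = scan_mod.annotate_table(
            SurveyTable((), tables[0].periods if tables else (), 1), library
        )
        candidates = annotated.copy()

    ligand_rows = []
    for _, cand in candidates.iterrows():
        frags = enumerate_bioactive_fragments(
            cand["sequence"], library, config.fragment_max_len
        )
        for frag in sorted(frags, key=lambda f: (len(f), f)):
            ligand_rows.append(
                {
                    "parent": cand["sequence"],
                    "fraction": cand["fraction"],
                    "fragment": frag,
                    "smiles": peptide_to_smiles(frag),
                }
            )
    ligands = pd.DataFrame(
        ligand_rows, columns=["parent", "fraction", "fragment", "smiles"]
    )

    ranking = rank_target_probabilities(probability_rows) if probability_rows else []
    if admet_records:
        verdicts = classify_table(list(admet_records), thresholds)
        admet_summary = summarize_admet(list(admet_records))
        if config.ld50_exclude:
            admet_summary["ld50_excluding"] = {
                "excluded": sorted(config.ld50_exclude),
                "mean": summarize_admet(
                    list(admet_records), exclude=config.ld50_exclude
                )["ld50"]["mean"],
            }
    else:
        verdicts = pd.DataFrame()
        admet_summary = {}

    summary: dict = {"n_peptides": int(len(annotated)), "candidates": {}}
    for _, cand in candidates.iterrows():
        summary["candidates"][cand["fraction"]] = {
            "sequence": cand["sequence"],
            "A": float(cand["A"]),
            "a": int(cand["a"]),
            "N": int(cand["N"]),
        }
    if ranking:
        summary["top_ligand"] = {
            "fragment": ranking[0].fragment,
            "probability": ranking[0].probability,
        }
    if admet_summary:
        summary["hia_positive"] = admet_summary["hia_positive"]
        summary["cyp2d6_substrates"] = admet_summary["cyp2d6_substrates"]
    return ReportBundle(
        annotated=annotated,
        candidates=candidates,
        ligands=ligands,
        probability_ranking=ranking,
        verdicts=verdicts,
        admet_summary=admet_summary,
        summary=summary,
    )


_FORMATS = ("tsv", "json", "markdown")


def render_report(
    bundle: ReportBundle, outdir: str | Path, format: str = "tsv"
) -> list[Path]:
    """Write the bundle under ``outdir`` in one format; returns paths written."""
    if format not in _FORMATS:
        raise ValidationError(f"unknown report format {format!r}, expected {_FORMATS}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format == "tsv":
        for name, frame in (
            ("annotated.tsv", bundle.annotated),
            ("candidates.tsv", bundle.candidates),
            ("ligands.tsv", bundle.ligands),
            ("admet_verdicts.tsv", bundle.verdicts),
        ):
            if frame.empty and name == "admet_verdicts.tsv":
                continue
            path = outdir / name
            frame.to_csv(path, sep="\t", index=False)
            written.append(path)
        if bundle.probability_ranking:
            path = outdir / "probability_ranking.tsv"
            pd.DataFrame(
                [vars(r) for r in bundle.probability_ranking]
            ).to_csv(path, sep="\t", index=False)
            written.append(path)
    elif format == "json":
        payload = {
            "summary": bundle.summary,
            "admet_summary": bundle.admet_summary,
            "probability_ranking": [
                {"fragment": r.fragment, "probability": r.probability}
                for r in bundle.probability_ranking
            ],
        }
        path = outdir / "summary.json"
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        written.append(path)
    else:  # markdown
        lines = ["# Peptide screen report", "", "## Candidates", ""]
        for _, cand in bundle.candidates.iterrows():
            lines.append(
                f"- **{cand['sequence']}** ({cand['fraction']}): "
                f"A = {cand['A']:.4f} ({cand['a']}/{cand['N']}); "
                f"{cand['fragments']}"
            )
        if bundle.probability_ranking:
            lines += ["", "## Ligand probability ranking", ""]
            for r in bundle.probability_ranking:
                lines.append(f"- {r.fragment}: {r.probability:.4f}")
        if bundle.admet_summary:
            lines += ["", "## ADMET summary", ""]
            hia = bundle.admet_summary["hia_positive"]
            lines.append(
                f"- HIA+ ligands: {hia['count']} ({', '.join(hia['fragments'])})"
            )
            subs = bundle.admet_summary["cyp2d6_substrates"]
            lines.append(
                "- CYP2D6 substrates: " + (", ".join(subs) if subs else "none")
            )
        path = outdir / "report.md"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        written.append(path)
    return written
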