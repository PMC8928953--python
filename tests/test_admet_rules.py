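"""Rule-based ADMET classification, summaries, and ligand ranking."""

import json

import pytest

from pepscreen import (
    AdmetRecord,
    AdmetThresholds,
    TargetProbability,
    ValidationError,
    classify_admet,
    classify_table,
    load_thresholds,
    rank_target_probabilities,
    read_admet_table,
    read_probability_table,
    summarize_admet,
)
from pepscreen.errors import FormatError


@pytest.fixture(scope="module")
def admet_records():
    return read_admet_table()


def make_record(**overrides):
    base = dict(
        parent="FKRPPL", fragment="PL", caco2=-5.0, hia_flag=0, hia_prob=None,
        ppb=50.0, bbb=0.5, vd=1.0, cyp2d6="non-interactor", t_half=5.0, ld50=2.0,
    )
    base.update(overrides)
    return AdmetRecord(**base)


def test_classify_av_row(admet_records):
    av = next(r for r in admet_records if r.fragment == "AV")
    verdict = classify_admet(av)
    assert not verdict.caco2_optimal  # -5.540 below the -5.15 cut-off
    assert verdict.hia_class == "HIA+"
    assert verdict.ppb_class == "acceptable"
    assert verdict.bbb_class == "BBB+"
    assert verdict.t_half_class == "low"


@pytest.mark.parametrize(
    "t_half, expected",
    [(2.999, "low"), (3.0, "moderate"), (5.0, "moderate"), (8.0, "moderate"),
     (8.001, "high")],
)
def test_half_life_bands_closed_on_moderate(t_half, expected):
    assert classify_admet(make_record(t_half=t_half)).t_half_class == expected


def test_caco2_and_vd_rules():
    assert classify_admet(make_record(caco2=-5.14)).caco2_optimal
    assert not classify_admet(make_record(caco2=-5.15)).caco2_optimal
    assert classify_admet(make_record(vd=0.04)).vd_optimal
    assert not classify_admet(make_record(vd=0.039)).vd_optimal
    assert not classify_admet(make_record(vd=20.5)).vd_optimal


def test_profile_verdict_tallies(admet_records):
    """Exactly 4 HIA+ ligands (VP, IA, AV, PL) and one CYP2D6 substrate (RPL)."""
    frame = classify_table(admet_records)
    assert len(frame) == 15
    hia_positive = sorted(frame.loc[frame["hia_class"] == "HIA+", "fragment"])
    assert hia_positive == ["AV", "IA", "PL", "VP"]
    substrates = list(frame.loc[frame["cyp_class"] == "substrate", "fragment"])
    assert substrates == ["RPL"]
    # every printed VD value sits outside the 0.04-20 L/kg optimum
    assert not frame["vd_optimal"].any()


def test_classification_is_pure(admet_records):
    record = admet_records[0]
    assert classify_admet(record) == classify_admet(record)


def test_summary_ranges_and_toxicity_mean(admet_records):
    summary = summarize_admet(admet_records)
    # true column extremes; the WT ligand (53.96 %) tops the PPB column
    assert summary["ppb"]["min"] == 13.60
    assert summary["ppb"]["max"] == 53.96
    assert summary["t_half"]["max"] == 1.229
    assert summary["hia_positive"]["count"] == 4
    excl = summarize_admet(admet_records, exclude=["GP"])
    assert excl["ld50"]["mean"] == 2.336
    assert excl["n"] == 14


def test_summary_matches_direct_recomputation(admet_records):
    summary = summarize_admet(admet_records)
    for column in ("caco2", "ppb", "bbb", "vd", "t_half", "ld50"):
        values = [getattr(r, column) for r in admet_records]
        assert summary[column]["min"] == min(values)
        assert summary[column]["max"] == max(values)
        assert abs(summary[column]["mean"] - sum(values) / len(values)) < 5e-4


def test_summary_single_record_and_exhaustive_exclusion():
    record = make_record()
    summary = summarize_admet([record])
    assert summary["ld50"]["min"] == summary["ld50"]["max"] == summary["ld50"]["mean"] == 2.0
    with pytest.raises(ValidationError):
        summarize_admet([record], exclude=["PL"])
    with pytest.raises(ValidationError):
        summarize_admet([])


def test_record_validation():
    with pytest.raises(ValidationError, match="ppb|PPB"):
        make_record(ppb=120.0)
    with pytest.raises(ValidationError, match="hia_prob"):
        make_record(hia_flag=1, hia_prob=None)
    with pytest.raises(ValidationError, match="hia_prob"):
        make_record(hia_flag=0, hia_prob=0.5)
    with pytest.raises(ValidationError, match="t_half"):
        make_record(t_half=float("nan"))
    with pytest.raises(ValidationError, match="cyp2d6"):
        make_record(cyp2d6="unknown")


def test_probability_ranking_of_packaged_tables():
    ranking = rank_target_probabilities(read_probability_table())
    assert len(ranking) == 14  # PP collapses across the two parents
    assert (ranking[0].fragment, ranking[0].probability) == ("PL", 0.4592)
    assert (ranking[1].fragment, ranking[1].probability) == ("PP", 0.3095)
    tail = [r.fragment for r in ranking[-3:]]
    assert tail == sorted(["HS", "KR", "PH"])  # zeros last, alphabetical
    assert all(r.probability == 0.0 for r in ranking[-3:])


def test_probability_ranking_edge_cases():
    single = TargetProbability("PL", "x", 0.4)
    assert rank_target_probabilities([single]) == [single]
    with pytest.raises(ValidationError, match="conflicting"):
        rank_target_probabilities(
            [TargetProbability("PP", "x", 0.3), TargetProbability("PP", "x", 0.4)]
        )
    with pytest.raises(ValidationError, match="probability"):
        TargetProbability("PP", "x", 1.5)


def test_thresholds_config_round_trip(tmp_path):
    assert load_thresholds() == AdmetThresholds()
    path = tmp_path / "th.json"
    path.write_text(json.dumps({"ppb_acceptable_lt": 80.0}))
    assert load_thresholds(path).ppb_acceptable_lt == 80.0
    path.write_text(json.dumps({"bogus": 1}))
    with pytest.raises(FormatError):
        load_thresholds(path)
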