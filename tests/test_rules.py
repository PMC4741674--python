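import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycotype import (
    ProfileMatrix,
    SignalModel,
    ThresholdRule,
    TypingMethod,
    band,
    classify,
    combine_bands,
    load_method,
    predict_types,
    save_method,
    simulate_profiles,
)
from glycotype.rules import (
    FlowchartTyper,
    ThresholdTyper,
    averaged,
    build_flowchart_method,
    canonical_flowchart_targets,
    single,
)
from oracles import oracle_agree, oracle_band, oracle_combine, oracle_flowchart

RULE = single("X", "IgG", 8.0, 9.0)


@pytest.mark.parametrize(
    "signal, expected",
    [
        (9.5, "positive"),
        (7.9, "negative"),
        (8.5, "unclassified"),
        (8.0, "unclassified"),  # boundaries are unclassified
        (9.0, "unclassified"),
    ],
)
def test_band_worked_illustration(signal, expected):
    """A signal over 9.0 is positive, below 8.0 negative, in between
    (boundaries included) unclassified."""
    assert band(signal, RULE) == expected


def test_band_rejects_non_finite():
    with pytest.raises(ValueError):
        band(float("nan"), RULE)


def test_threshold_rule_validates():
    with pytest.raises(ValueError):
        ThresholdRule((("X", "IgG"),), 9.0, 8.0)
    with pytest.raises(ValueError):
        ThresholdRule((), 8.0, 9.0)


BANDS = ("negative", "unclassified", "positive")


def test_combine_bands_total_truth_table():
    """All 9 band pairs resolve per the rule table: (pos,pos)->O,
    (neg,pos)->A, (pos,neg)->B, (neg,neg)->AB, else unclassified."""
    expected = {
        ("positive", "positive"): "O",
        ("negative", "positive"): "A",
        ("positive", "negative"): "B",
        ("negative", "negative"): "AB",
    }
    for a, b in itertools.product(BANDS, repeat=2):
        assert combine_bands(a, b) == expected.get((a, b), "unclassified")
        assert combine_bands(a, b) == oracle_combine(a, b)


def _frame(rows: dict[str, dict[tuple[str, str], float]]) -> pd.DataFrame:
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = pd.MultiIndex.from_tuples(frame.columns)
    return frame


# signals realising each band for an 8-9 rule
SIGNAL_FOR = {"negative": 7.0, "unclassified": 8.5, "positive": 10.0}


def test_all_agree_truth_table_exhaustive():
    """All 3^4 band assignments to a 2+2-rule all-agree method match the
    independent truth-table oracle."""
    method = TypingMethod(
        a_rules=(single("A1", "IgG", 8, 9), single("A2", "IgM", 8, 9)),
        b_rules=(single("B1", "IgG", 8, 9), single("B2", "IgM", 8, 9)),
        combination="all_agree",
    )
    for combo in itertools.product(BANDS, repeat=4):
        a1, a2, b1, b2 = combo
        frame = _frame(
            {
                "s": {
                    ("A1", "IgG"): SIGNAL_FOR[a1],
                    ("A2", "IgM"): SIGNAL_FOR[a2],
                    ("B1", "IgG"): SIGNAL_FOR[b1],
                    ("B2", "IgM"): SIGNAL_FOR[b2],
                }
            }
        )
        got = predict_types(frame, method)["call"].iloc[0]
        want = oracle_combine(oracle_agree([a1, a2]), oracle_agree([b1, b2]))
        assert got == want, combo


def test_all_agree_isotype_disagreement_is_unclassified():
    """IgG saying anti-A-positive while IgM says anti-A-negative must
    leave the sample unclassified (all components must agree)."""
    method = TypingMethod(
        a_rules=(single("A1", "IgG", 8, 9), single("A1", "IgM", 8, 9)),
        b_rules=(single("B1", "IgG", 8, 9), single("B1", "IgM", 8, 9)),
        combination="all_agree",
    )
    frame = _frame(
        {
            "s": {
                ("A1", "IgG"): 10.0,
                ("A1", "IgM"): 7.0,
                ("B1", "IgG"): 10.0,
                ("B1", "IgM"): 10.0,
            }
        }
    )
    assert predict_types(frame, method)["call"].iloc[0] == "unclassified"


def _toy_flowchart(stringency=0.5) -> TypingMethod:
    return build_flowchart_method(
        a_igg_band=(8.0, 9.0),
        a_igm_band=(8.0, 9.0),
        b_igg_band=(8.0, 9.0),
        b_igm_band=(8.0, 9.0),
        stringency=stringency,
        targets=(("Ag1", "Ag2", "Ag3", "Ag4"), "Am", ("Bg1", "Bg2", "Bg3", "Bg4"), "Bm"),
    )


# IgG signal levels realising every consistent (stage1, stage2) band
# pair for an 8-9 band widened by 0.5 at stage 2
IGG_LEVELS = {
    ("negative", "negative"): 7.0,
    ("negative", "unclassified"): 7.8,
    ("unclassified", "unclassified"): 8.5,
    ("positive", "unclassified"): 9.2,
    ("positive", "positive"): 10.0,
}


def test_flowchart_truth_table_exhaustive():
    """Every reachable combination of stage-1/stage-2 bands matches an
    independently coded two-stage oracle (including the produced
    stage)."""
    method = _toy_flowchart(stringency=0.5)
    igm_levels = SIGNAL_FOR
    cases = 0
    for (a_g1, a_g2), a_m, (b_g1, b_g2), b_m in itertools.product(
        IGG_LEVELS, BANDS, IGG_LEVELS, BANDS
    ):
        sig_a = IGG_LEVELS[(a_g1, a_g2)]
        sig_b = IGG_LEVELS[(b_g1, b_g2)]
        row = {("Am", "IgM"): igm_levels[a_m], ("Bm", "IgM"): igm_levels[b_m]}
        for name in ("Ag1", "Ag2", "Ag3", "Ag4"):
            row[(name, "IgG")] = sig_a
        for name in ("Bg1", "Bg2", "Bg3", "Bg4"):
            row[(name, "IgG")] = sig_b
        frame = _frame({"s": row})
        result = predict_types(frame, method)
        want_call, want_stage = oracle_flowchart(
            [a_g1, a_m], [b_g1, b_m], [a_g2], [b_g2]
        )
        assert result["call"].iloc[0] == want_call
        assert int(result["stage"].iloc[0]) == want_stage
        cases += 1
    assert cases == 225


def test_flowchart_noise_free_type_o_called_at_stage_one():
    """A noise-free type-O profile (both foreign determinants far above
    threshold) is called O at stage 1."""
    model = SignalModel(sigma=1e-9, crossreact_epsilon=0.0)
    profiles, truth = simulate_profiles(
        8, model=model, seed=0, true_types=["O"] * 8
    )
    typer = FlowchartTyper().fit(profiles, truth)
    frame = typer.predict_frame(profiles)
    assert (frame["call"] == "O").all()
    assert (frame["stage"] == 1).all()


def test_classify_single_sample_keeps_evidence(tiny_profiles):
    method = TypingMethod(
        a_rules=(single("BG-A3-Oct-14", "IgG", 8, 9),),
        b_rules=(single("BG-B3-Oct-17", "IgG", 8, 9),),
    )
    call = classify(tiny_profiles, "s3", method)
    assert call.call == "O"
    assert call.stage == 1
    assert any("anti-A" in k for k in call.evidence)
    assert set(call.evidence.values()) <= {"negative", "unclassified", "positive"}


def test_classify_missing_component_names_target(tiny_profiles):
    method = TypingMethod(
        a_rules=(single("Globo A-09", "IgG", 8, 9),),
        b_rules=(single("BG-B3-Oct-17", "IgG", 8, 9),),
    )
    with pytest.raises(KeyError, match="Globo A-09"):
        classify(tiny_profiles, "s1", method)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    sig_a=st.floats(4, 14),
    sig_b=st.floats(4, 14),
    bump=st.floats(0.01, 8),
)
def test_monotonicity_in_anti_a_signal(sig_a, sig_b, bump):
    """Raising an anti-A signal can only move its band along
    negative -> unclassified -> positive, never backwards."""
    order = {"negative": 0, "unclassified": 1, "positive": 2}
    rule = single("A1", "IgG", 8.0, 9.0)
    before = band(sig_a, rule)
    after = band(sig_a + bump, rule)
    assert order[after] >= order[before]
    # and the resulting call's anti-A evidence is monotone too
    method = TypingMethod(
        a_rules=(rule,), b_rules=(single("B1", "IgG", 8.0, 9.0),)
    )
    for s in (sig_a, sig_a + bump):
        frame = _frame({"s": {("A1", "IgG"): s, ("B1", "IgG"): sig_b}})
        call = predict_types(frame, method)["call"].iloc[0]
        assert call in {"A", "B", "AB", "O", "unclassified"}


def test_calls_invariant_to_rule_and_sample_order():
    rng = np.random.default_rng(5)
    frame = _frame(
        {
            f"s{i}": {
                ("A1", "IgG"): rng.uniform(5, 13),
                ("A2", "IgM"): rng.uniform(5, 13),
                ("B1", "IgG"): rng.uniform(5, 13),
                ("B2", "IgM"): rng.uniform(5, 13),
            }
            for i in range(25)
        }
    )
    a_rules = (single("A1", "IgG", 8, 9), single("A2", "IgM", 7.5, 9.5))
    b_rules = (single("B1", "IgG", 8, 9), single("B2", "IgM", 7.5, 9.5))
    m1 = TypingMethod(a_rules, b_rules, "all_agree")
    m2 = TypingMethod(a_rules[::-1], b_rules[::-1], "all_agree")
    shuffled = frame.sample(frac=1, random_state=1)
    c1 = predict_types(frame, m1)["call"]
    c2 = predict_types(shuffled, m2)["call"].reindex(frame.index)
    assert (c1 == c2).all()


def test_stage1_calls_are_final():
    """A sample classified at stage 1 keeps its call whatever stage 2
    would say."""
    base = _toy_flowchart(stringency=0.5)
    wild_stage2 = TypingMethod(
        a_rules=base.a_rules,
        b_rules=base.b_rules,
        combination="flowchart",
        stage2_a_rules=(averaged(["Ag1", "Ag2", "Ag3", "Ag4"], "IgG", 0.0, 0.1),),
        stage2_b_rules=(averaged(["Bg1", "Bg2", "Bg3", "Bg4"], "IgG", 0.0, 0.1),),
    )
    row = {("Am", "IgM"): 10.0, ("Bm", "IgM"): 10.0}
    for name in ("Ag1", "Ag2", "Ag3", "Ag4", "Bg1", "Bg2", "Bg3", "Bg4"):
        row[(name, "IgG")] = 10.0
    frame = _frame({"s": row})
    r1 = predict_types(frame, base)
    r2 = predict_types(frame, wild_stage2)
    assert r1["call"].iloc[0] == r2["call"].iloc[0] == "O"
    assert int(r2["stage"].iloc[0]) == 1


def test_method_yaml_round_trip(tmp_path):
    method = _toy_flowchart()
    path = tmp_path / "method.yaml"
    save_method(method, path)
    assert load_method(path) == method


def test_naming_variant_warns_and_canonicalises():
    with pytest.warns(UserWarning, match="BG-A2-Oct-16"):
        a_igg, _, _, _ = canonical_flowchart_targets(
            ("BG-A2-Sp-17", "BG-A2-Oct-17", "BG-A3-Oct-14", "Globo A-09"),
            "BG-A2-Sp-17",
            ("BG-B2-Sp-20", "BG-B2-Oct-17", "BG-B3-Oct-17", "Globo B-12"),
            "BG-B2-Sp-05",
        )
    assert "BG-A2-Oct-16" in a_igg


def test_threshold_typer_requires_fit_and_validates(tiny_profiles):
    method = TypingMethod(
        a_rules=(single("BG-A3-Oct-14", "IgG", 8, 9),),
        b_rules=(single("BG-B3-Oct-17", "IgG", 8, 9),),
    )
    typer = ThresholdTyper(method)
    with pytest.raises(AttributeError):
        typer.predict(tiny_profiles)
    calls = typer.fit(tiny_profiles).predict(tiny_profiles)
    assert list(calls) == ["A", "B", "O"]
    assert typer.get_params()["method"] is method
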