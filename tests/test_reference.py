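"""Reference state: GPR scores, thresholds, fasted bounds, iMAT, L1 fit."""

from __future__ import annotations

import numpy as np
import pytest

from dynamoma.network import build_stoichiometric_matrix
from dynamoma.reference import (
    ExpressionProfile,
    ReactionScoreSet,
    ReferenceState,
    apply_fasted_state,
    build_reference_state,
    evaluate_gpr,
    imat_fit,
    minimize_intracellular_flux,
    reaction_scores,
    threshold_sets,
)


# --- GPR ------------------------------------------------------------------

def test_gpr_or_is_max_and_is_min():
    scores = {"a": 0.2, "b": 0.8, "c": 0.5}
    assert evaluate_gpr("a or b", scores)[0] == 0.8
    assert evaluate_gpr("a and b", scores)[0] == 0.2
    assert evaluate_gpr("(a and b) or c", scores)[0] == 0.5
    assert evaluate_gpr("a and (b or c)", scores)[0] == 0.2


def test_gpr_missing_genes_drop_out():
    val, missing = evaluate_gpr("a or ghost", {"a": 0.3})
    assert val == 0.3 and missing == {"ghost"}
    val, missing = evaluate_gpr("ghost1 and ghost2", {"a": 0.3})
    assert val is None and missing == {"ghost1", "ghost2"}


def test_gpr_syntax_errors():
    with pytest.raises(ValueError):
        evaluate_gpr("(a or b", {"a": 1.0, "b": 1.0})


def test_reaction_scores_normalized_to_peak(toy):
    scores = reaction_scores(toy.network, ExpressionProfile(toy.expression))
    assert max(scores.scores.values()) == 1.0
    assert scores.scores["GNG"] == 1.0  # g_gng carries the peak intensity
    # reactions without a GPR receive no score
    assert "BIOMASS" not in scores.scores
    assert "EX_lac" not in scores.scores


def test_expression_profile_rejects_bad_values():
    with pytest.raises(ValueError):
        ExpressionProfile({"g": -1.0})
    with pytest.raises(ValueError):
        ExpressionProfile({"g": float("nan")})
    with pytest.raises(ValueError):
        ExpressionProfile({})


def test_expression_from_tsv_averages_samples(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text("gene_id\ts1\ts2\ng1\t10\t30\ng2\t5\t5\n")
    prof = ExpressionProfile.from_tsv(str(path))
    assert prof.values == {"g1": 20.0, "g2": 5.0}


# --- thresholds -------------------------------------------------------------

def test_threshold_sets_percentile_oracle():
    # 10 scores; p75 and p25 computed by hand with linear interpolation
    vals = [0.05, 0.1, 0.12, 0.7, 0.75, 0.78, 0.8, 0.9, 0.95, 1.0]
    scores = {f"r{i}": v for i, v in enumerate(vals)}
    hi = np.percentile(vals, 75)  # 0.875
    lo = np.percentile(vals, 25)  # 0.265
    sets = threshold_sets(ReactionScoreSet(scores=scores))
    assert sets.active == {r for r, s in scores.items() if s >= hi}
    assert sets.inactive == {r for r, s in scores.items() if s <= lo}


def test_threshold_sets_zero_scores_are_inactive():
    scores = {"a": 0.0, "b": 0.5, "c": 0.9, "d": 1.0, "e": 0.4}
    sets = threshold_sets(ReactionScoreSet(scores=scores))
    assert "a" in sets.inactive


def test_threshold_sets_small_input_special_case():
    sets = threshold_sets(ReactionScoreSet(scores={"a": 0.5, "b": 0.0}))
    assert sets.active == {"a"} and sets.inactive == {"b"}


def test_threshold_sets_all_zero_raises():
    with pytest.raises(ValueError):
        threshold_sets(ReactionScoreSet(scores={"a": 0.0, "b": 0.0}))


# --- fasted state -----------------------------------------------------------

def test_apply_fasted_state_closes_unlisted_exchanges(toy):
    util = {"EX_lac": (-20.0, 0.0)}
    out = apply_fasted_state(toy.network, util)
    assert out.reaction("EX_lac").lower_bound == -20.0
    assert out.reaction("EX_o2").lower_bound == 0.0
    assert out.reaction("EX_o2").upper_bound == 0.0
    # intracellular bounds untouched
    assert out.reaction("LDH").upper_bound == 1000.0
    # the input network is not modified
    assert toy.network.reaction("EX_o2").lower_bound == -10.0


def test_apply_fasted_state_rejects_non_exchange_id(toy):
    with pytest.raises(ValueError, match="LDH"):
        apply_fasted_state(toy.network, {"LDH": (0.0, 1.0)})


def test_apply_fasted_state_rejects_inverted_bounds(toy):
    with pytest.raises(ValueError, match="EX_lac"):
        apply_fasted_state(toy.network, {"EX_lac": (1.0, -1.0)})


# --- iMAT + pruning ---------------------------------------------------------

@pytest.fixture(scope="module")
def imat_result(toy, extended_net):
    constrained = apply_fasted_state(extended_net, toy.utilization)
    sets = threshold_sets(
        reaction_scores(constrained, ExpressionProfile(toy.expression))
    )
    ctx, v, satisfied = imat_fit(constrained, sets)
    return constrained, sets, ctx, v, satisfied


def test_imat_satisfies_all_fixture_indicators(imat_result):
    _, sets, _, v, satisfied = imat_result
    assert satisfied == len(sets.active) + len(sets.inactive)
    for rid in sets.active:
        assert abs(v.values[rid]) >= 1e-5 - 1e-12, rid
    for rid in sets.inactive:
        if rid in v.values:  # pruned reactions carry no flux by definition
            assert abs(v.values[rid]) <= 1e-5 + 1e-12, rid


def test_imat_prunes_only_blocked_reactions(imat_result):
    _, _, ctx, _, _ = imat_result
    # the dead-end chain is stoichiometrically blocked -> pruned
    assert not ctx.has_reaction("DEAD") and not ctx.has_reaction("DEAD2")
    # GNG_ALT is idle but NOT blocked (it parallels GNG) -> kept
    assert ctx.has_reaction("GNG_ALT")
    # orphaned metabolites disappear with their reactions
    assert "dead_c" not in ctx.metabolite_ids


def test_imat_keeps_closed_xenobiotic_reactions(imat_result, extended_net):
    _, _, ctx, _, _ = imat_result
    xen = extended_net.reactions_with_role("xenobiotic")
    assert xen and all(ctx.has_reaction(rid) for rid in xen)


def test_imat_flux_is_steady_state(imat_result):
    _, _, ctx, v, _ = imat_result
    S = build_stoichiometric_matrix(ctx)
    assert np.max(np.abs(S @ v.as_array(ctx))) <= 1e-8


def test_imat_respects_biomass_minimum(imat_result):
    _, _, ctx, v, _ = imat_result
    assert v.values["BIOMASS"] >= 1e-4 - 1e-12


# --- flux-sum minimization / reference state --------------------------------

def test_minimize_flux_fixes_exchanges_and_directions(imat_result):
    _, _, ctx, v_imat, _ = imat_result
    ref = minimize_intracellular_flux(ctx, v_imat)
    for r in ctx.reactions:
        if r.role == "exchange":
            assert ref.v_ref.values[r.id] == pytest.approx(
                v_imat.values[r.id], abs=1e-7
            )
    for rid, sign in ref.fixed_directions.items():
        assert sign * ref.v_ref.values[rid] >= -1e-9
    # L1 objective does not exceed the iMAT solution's flux sum
    intr = [r.id for r in ctx.reactions if r.role != "exchange"]
    assert sum(abs(ref.v_ref.values[r]) for r in intr) <= (
        sum(abs(v_imat.values[r]) for r in intr) + 1e-6
    )


def test_reference_network_keeps_open_bounds(reference):
    """The stored reference network must NOT carry the direction-fixed
    bounds of the L1 step — the coupling loop leaves endogenous reactions
    unconstrained beyond the fasted-state bounds."""
    assert reference.network.reaction("LDH").upper_bound == 1000.0
    assert reference.network.reaction("GNG").upper_bound == 1000.0


def test_reference_state_round_trip(reference, tmp_path):
    outdir = str(tmp_path / "ref")
    reference.save(outdir)
    back = ReferenceState.load(outdir)
    assert back.network.reaction_ids == reference.network.reaction_ids
    assert back.epsilon == reference.epsilon
    assert back.biomass_min == reference.biomass_min
    assert back.fixed_directions == reference.fixed_directions
    a, b = reference.v_ref_array(), back.v_ref_array()
    assert np.max(np.abs(a - b)) <= 1e-12


def test_build_reference_state_end_to_end(toy, extended_net, reference):
    assert reference.v_ref.values["BIOMASS"] >= 1e-4 - 1e-12
    S = build_stoichiometric_matrix(reference.network)
    assert np.max(np.abs(S @ reference.v_ref_array())) <= 1e-8
    # active fixture reactions carry flux in the reference
    assert reference.v_ref.values["GNG"] > 1e-5
    assert reference.v_ref.values["RX"] > 1e-5
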