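"""Coupling loop: pinning, per-step QP, relax mode, Model/Results facade."""

from __future__ import annotations

import numpy as np
import pytest

from dynamoma.coupling import (
    DynamicMOMA,
    FluxMatrix,
    InfeasibleStepError,
    pin_xenobiotic,
    run_dmoma,
    solve_moma_step,
)
from dynamoma.network import build_stoichiometric_matrix
from dynamoma.pbpk import RateTimeSeries


def _series_for(reference, rate_fn, n=31, dt=1.0, ids=None):
    ids = ids or reference.network.reactions_with_role("xenobiotic")
    times = np.arange(n) * dt
    rates = np.zeros((n, len(ids)))
    for t in range(n):
        rates[t] = rate_fn(times[t])
    return RateTimeSeries(times=times, rates=rates, reaction_ids=ids)


def test_pin_sets_both_bounds(reference):
    net = pin_xenobiotic(reference.network, {"XEN_NAT2_INH": 2.5})
    r = net.reaction("XEN_NAT2_INH")
    assert r.lower_bound == r.upper_bound == 2.5
    # source network untouched
    assert reference.network.reaction("XEN_NAT2_INH").upper_bound == 0.0


def test_pin_rejects_unknown_and_non_xenobiotic(reference):
    with pytest.raises(KeyError):
        pin_xenobiotic(reference.network, {"NOPE": 1.0})
    with pytest.raises(ValueError, match="role"):
        pin_xenobiotic(reference.network, {"LDH": 1.0})


def test_null_pin_returns_reference(reference):
    xen = reference.network.reactions_with_role("xenobiotic")
    net = pin_xenobiotic(reference.network, {rid: 0.0 for rid in xen})
    v = solve_moma_step(net, reference)
    assert np.max(np.abs(v.as_array(net) - reference.v_ref_array())) <= 1e-9


def test_pinned_rates_exact_in_solution(reference):
    net = pin_xenobiotic(reference.network, {"XEN_NAT2_INH": 1.25})
    v = solve_moma_step(net, reference)
    assert v.values["XEN_NAT2_INH"] == pytest.approx(1.25, abs=1e-12)
    S = build_stoichiometric_matrix(net)
    assert np.max(np.abs(S @ v.as_array(net))) <= 1e-8


def test_run_rejects_foreign_series_columns(reference):
    series = _series_for(reference, lambda t: [1.0], ids=["LDH"])
    with pytest.raises(ValueError, match="LDH"):
        run_dmoma(reference, series, progress_every=0)


def test_unlisted_xenobiotics_held_at_zero(reference):
    series = _series_for(
        reference, lambda t: [0.5], ids=["XEN_NAT2_INH"], n=11
    )
    fm = run_dmoma(reference, series, progress_every=0)
    assert np.allclose(fm.row("XEN_NAT2_INH"), 0.5)
    assert np.allclose(fm.row("XEN_NOS2_HZ"), 0.0)


def test_fast_path_agrees_with_full_qp(reference):
    """Every column must solve the same QP the one-shot path solves."""
    series = _series_for(
        reference,
        lambda t: [0.8 * np.exp(-t / 10.0)],
        ids=["XEN_NAT2_INH"],
        n=6,
    )
    fm = run_dmoma(reference, series, progress_every=0)
    for t in range(series.n_timepoints):
        net = pin_xenobiotic(
            reference.network, {"XEN_NAT2_INH": float(series.rates[t, 0])}
        )
        v = solve_moma_step(net, reference).as_array(net)
        assert np.max(np.abs(fm.values[:, t] - v)) <= 1e-7, t


def test_infeasible_step_carries_partial_and_diagnosis(reference):
    # the NAT2 acetylation rate cannot exceed the AcCoA supply
    series = _series_for(
        reference, lambda t: [1e4 if t >= 2 else 0.0], ids=["XEN_NAT2_INH"], n=5
    )
    with pytest.raises(InfeasibleStepError) as err:
        run_dmoma(reference, series, progress_every=0)
    assert err.value.timepoint == 2
    assert isinstance(err.value.partial, FluxMatrix)
    assert err.value.partial.values.shape[1] == 2
    assert "metabolite" in str(err.value) or "bound" in str(err.value)


def test_relax_mode_scales_infeasible_rates(reference):
    series = _series_for(
        reference, lambda t: [1e4 if t >= 2 else 0.0], ids=["XEN_NAT2_INH"], n=5
    )
    fm = run_dmoma(reference, series, relax=True, progress_every=0)
    assert fm.alphas is not None
    assert np.all(fm.alphas[:2] == 1.0)
    assert np.all(fm.alphas[2:] < 1.0)
    # relaxed columns are still steady states
    S = build_stoichiometric_matrix(reference.network)
    assert np.max(np.abs(S @ fm.values)) <= 1e-8


def test_chained_mode_runs_and_differs(reference):
    series = _series_for(
        reference,
        lambda t: [1.0 if t < 5 else 0.0],
        ids=["XEN_NAT2_INH"],
        n=11,
    )
    plain = run_dmoma(reference, series, progress_every=0)
    chained = run_dmoma(reference, series, chained=True, progress_every=0)
    # after the pulse, the plain mode snaps back to v_ref; the chained
    # mode stays where the last perturbed step left it
    v_ref = reference.v_ref_array()
    assert np.max(np.abs(plain.values[:, -1] - v_ref)) <= 1e-9
    assert np.max(np.abs(chained.values[:, -1] - v_ref)) > 1e-6


def test_flux_matrix_save_and_sidecar(reference, tmp_path):
    series = _series_for(reference, lambda t: [0.1], ids=["XEN_NAT2_INH"], n=4)
    fm = run_dmoma(reference, series, progress_every=0)
    csv = str(tmp_path / "fm.csv")
    sidecar = str(tmp_path / "fm.json")
    fm.save(csv, sidecar)
    import json

    import pandas as pd

    df = pd.read_csv(csv, index_col=0)
    assert list(df.index) == fm.reaction_ids
    assert np.allclose(df.to_numpy(), fm.values)
    meta = json.load(open(sidecar))
    assert meta["n_timepoints"] == 4 and meta["dt_min"] == 1.0


def test_model_results_facade(reference):
    series = _series_for(reference, lambda t: [0.5], ids=["XEN_NAT2_INH"], n=11)
    res = DynamicMOMA(reference, series).fit()
    assert res.reference is reference
    assert res.delta().shape == res.flux_matrix.values.shape
    rep = res.perturbation()
    assert rep is res.perturbation()  # cached
    text = res.summary()
    assert "P_PBPK" in text and "pathway cluster" in text
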