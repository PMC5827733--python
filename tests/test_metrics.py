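"""Perturbation metrics against hand oracles, plus property tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dynamoma.metrics import (
    PathwayClustering,
    attenuation_curve,
    altered_fraction,
    compare_reports,
    exometabolome_pools,
    integrate_perturbation,
    pathway_perturbation,
    pathway_score,
    significance_mask,
)


# --- clustering ---------------------------------------------------------------

def test_clustering_validate_and_restrict(toy):
    cl = PathwayClustering({"LDH": "ccm", "GHOST": "ccm"})
    with pytest.raises(ValueError, match="GHOST"):
        cl.validate(toy.network)
    kept = cl.restrict_to(toy.network)
    assert kept.mapping == {"LDH": "ccm"}


def test_clustering_csv_round_trip(toy, tmp_path):
    cl = PathwayClustering.from_network(toy.network)
    path = str(tmp_path / "cl.csv")
    cl.to_csv(path)
    assert PathwayClustering.from_csv(path).mapping == cl.mapping


# --- integration oracles --------------------------------------------------------

def test_integrate_perturbation_left_rectangle_oracle():
    # |Δ| rows: [1, 2, 3] and [0, 1, 0]; dt = 2; last point carries no weight
    delta = np.array([[1.0, -2.0, 3.0], [0.0, 1.0, 0.0]])
    times = np.array([0.0, 2.0, 4.0])
    p = integrate_perturbation(delta, times, "rxn")
    assert p[0] == pytest.approx((1 + 2) * 2.0)
    assert p[1] == pytest.approx(1 * 2.0)
    # pbpk: sum across rows first
    assert integrate_perturbation(delta, times, "pbpk") == pytest.approx(
        (1 + 0) * 2 + (2 + 1) * 2
    )


def test_integrate_perturbation_trapezoid_option():
    delta = np.array([[1.0, 1.0, 1.0]])
    times = np.array([0.0, 1.0, 2.0])
    assert integrate_perturbation(delta, times, "rxn", "trapezoid")[0] == 2.0
    assert integrate_perturbation(delta, times, "rxn", "rectangle")[0] == 2.0


def test_integrate_rejects_nonuniform_grid():
    with pytest.raises(ValueError):
        integrate_perturbation(np.ones((1, 3)), np.array([0.0, 1.0, 3.0]))


# --- significance / pathway aggregation ------------------------------------------

def test_significance_is_strict():
    eps, t = 1e-5, 100.0
    p = {"at": eps * t, "above": eps * t * 1.001, "below": eps * t * 0.999}
    assert significance_mask(p, eps, t) == {"above"}


def test_pathway_perturbation_sums_only_significant():
    clusters = PathwayClustering({"r1": "A", "r2": "A", "r3": "B"})
    p_rxn = {"r1": 5.0, "r2": 7.0, "r3": 1.0}
    p_mp = pathway_perturbation(p_rxn, {"r1"}, clusters)
    assert p_mp == {"A": 5.0, "B": 0.0}


def test_pathway_score_semantics():
    assert pathway_score({"A": 5.0}, 10.0) == {"A": 0.5}
    assert pathway_score({"A": 0.0}, 0.0) == {"A": 0.0}
    with pytest.raises(ValueError):
        pathway_score({"A": 1.0}, 0.0)


def test_attenuation_curve_oracle():
    curve = attenuation_curve(np.array([1.0, 3.0, 0.0]), 4.0)
    assert np.allclose(curve, [0.25, 1.0, 1.0])
    assert attenuation_curve(np.array([]), 0.0).size == 0


def test_altered_fraction_oracle():
    delta = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 0.0], [1.0, 0.0]])
    assert np.allclose(altered_fraction(delta, 0.5), [0.25, 0.5])


# --- exometabolome pools -----------------------------------------------------------

def test_pools_signs_and_flag():
    times = np.array([0.0, 1.0, 2.0])
    delta = np.array([[60.0, 60.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0]])
    df = exometabolome_pools(delta, times, ["EX_up", "EX_mix", "EX_zero"])
    row = df.set_index("exchange_id")
    assert row.loc["EX_up", "signed_change_umol"] == 120.0
    assert row.loc["EX_up", "direction"] == "increased"
    assert bool(row.loc["EX_up", "flagged"])  # > 50 µmol
    assert row.loc["EX_mix", "signed_change_umol"] == 0.0
    assert row.loc["EX_mix", "p_ex_umol"] == 2.0
    assert row.loc["EX_mix", "direction"] == "unchanged"
    assert not bool(row.loc["EX_zero", "flagged"])
    assert row.loc["EX_up", "uptake_positive_umol"] == -120.0


# --- report-level checks -------------------------------------------------------------

def test_report_attenuation_total_equals_p_mp(report_dt10):
    for cl, curve in report_dt10.at_mp.items():
        if curve.size:
            assert curve[-1] * report_dt10.p_mp[cl] == pytest.approx(
                report_dt10.p_mp[cl], rel=1e-9
            )


def test_report_driver_cluster_scores_one(report_dt10):
    """P_PBPK sums exactly the xenobiotic reactions, so the xenobiotic
    cluster's score is 1 whenever all of its members are significant."""
    assert report_dt10.pathway_scores["xenobiotic metabolism"] == pytest.approx(
        1.0, rel=1e-9
    )


def test_compare_reports_explicit_zero_for_missing(report_dt10):
    import copy

    other = copy.copy(report_dt10)
    other.pathway_scores = dict(report_dt10.pathway_scores)
    other.pathway_scores["extra cluster"] = 0.25
    tables = compare_reports(report_dt10, other)
    ps = tables["pathway_scores"].set_index("cluster")
    assert ps.loc["extra cluster", "score_a"] == 0.0
    assert ps.loc["extra cluster", "score_diff_b_minus_a"] == 0.25


def test_compare_reports_self_is_zero(report_dt10):
    tables = compare_reports(report_dt10, report_dt10)
    assert (tables["pathway_scores"]["score_diff_b_minus_a"] == 0.0).all()
    assert (tables["pools"]["signed_diff_b_minus_a"] == 0.0).all()


# --- property tests ---------------------------------------------------------------

@given(
    series=hnp.arrays(
        float,
        st.integers(min_value=1, max_value=40),
        elements=st.floats(0.0, 1e3, allow_nan=False),
    )
)
def test_property_attenuation_monotone_and_normalized(series):
    total = float(series.sum())
    curve = attenuation_curve(series, total)
    if total <= 0:
        assert curve.size == 0
    else:
        assert np.all(np.diff(curve) >= -1e-12)
        assert curve[-1] == pytest.approx(1.0, abs=1e-9)


@given(
    delta=hnp.arrays(
        float, (3, 8), elements=st.floats(-1e3, 1e3, allow_nan=False)
    ),
    scale=st.floats(0.1, 10.0),
)
def test_property_integration_is_positively_homogeneous(delta, scale):
    times = np.arange(8.0)
    base = integrate_perturbation(delta, times, "rxn")
    scaled = integrate_perturbation(scale * delta, times, "rxn")
    assert np.allclose(scaled, scale * base, rtol=1e-9, atol=1e-9)
    assert np.all(base >= 0.0)


@given(
    delta=hnp.arrays(
        float, (2, 6), elements=st.floats(-1e3, 1e3, allow_nan=False)
    )
)
def test_property_pbpk_integral_bounded_by_row_sums(delta):
    times = np.arange(6.0)
    total = integrate_perturbation(delta, times, "pbpk")
    rows = integrate_perturbation(delta, times, "rxn")
    assert total == pytest.approx(float(rows.sum()), rel=1e-9, abs=1e-9)
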