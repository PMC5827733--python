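"""PBPK driver: rate tables, resampling, the toy simulator's ledgers."""

from __future__ import annotations

import numpy as np
import pytest

from dynamoma.pbpk import (
    DOSE_300MG_UMOL,
    PBPKModel,
    RateTableError,
    RateTimeSeries,
    acetylator_preset,
    multi_dose,
    read_rate_table,
    resample,
)


def _series(n=11, dt=1.0, k=2, seed=0):
    rng = np.random.default_rng(seed)
    return RateTimeSeries(
        times=np.arange(n) * dt,
        rates=rng.uniform(0, 2, size=(n, k)),
        reaction_ids=[f"R{i}" for i in range(k)],
    )


# --- RateTimeSeries validation ----------------------------------------------

def test_series_rejects_nonzero_start():
    with pytest.raises(RateTableError, match="start at 0"):
        RateTimeSeries(times=np.array([1.0, 2.0]), rates=np.zeros((2, 1)),
                       reaction_ids=["R"])


def test_series_rejects_nonuniform_grid():
    with pytest.raises(RateTableError, match="non-uniform"):
        RateTimeSeries(times=np.array([0.0, 1.0, 3.0]), rates=np.zeros((3, 1)),
                       reaction_ids=["R"])


def test_series_rejects_duplicate_ids():
    with pytest.raises(RateTableError, match="duplicate"):
        RateTimeSeries(times=np.array([0.0, 1.0]), rates=np.zeros((2, 2)),
                       reaction_ids=["R", "R"])


def test_series_rejects_nan():
    with pytest.raises(RateTableError, match="NaN"):
        RateTimeSeries(times=np.array([0.0, 1.0]),
                       rates=np.array([[0.0], [np.nan]]), reaction_ids=["R"])


def test_read_rate_table_names_bad_cell(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("time_min,R1\n0,1.0\n1,\n")
    with pytest.raises(RateTableError, match="R1"):
        read_rate_table(str(p))
    p.write_text("time_min,R1\n0,1.0\n1,-0.5\n")
    with pytest.raises(RateTableError, match="negative"):
        read_rate_table(str(p))


def test_rate_table_csv_round_trip(tmp_path):
    s = _series()
    path = str(tmp_path / "rates.csv")
    s.to_csv(path)
    back = read_rate_table(path)
    assert back.reaction_ids == s.reaction_ids
    assert np.allclose(back.rates, s.rates)
    assert np.array_equal(back.times, s.times)


# --- resampling ---------------------------------------------------------------

def test_resample_preserves_left_rectangle_integrals():
    s = _series(n=41, dt=1.0)
    r = resample(s, 5.0)
    assert r.dt == 5.0
    a, b = s.integrals(), r.integrals()
    for rid in s.reaction_ids:
        assert a[rid] == pytest.approx(b[rid], abs=1e-10)


def test_resample_rejects_non_divisible_factor():
    s = _series(n=11, dt=1.0)  # 10 steps, not divisible by 3
    with pytest.raises(ValueError):
        resample(s, 3.0)


# --- simulator ----------------------------------------------------------------

def test_mass_balance_and_washout(pk_fast):
    assert pk_fast.mass_balance_error() <= 1e-9
    assert pk_fast.body_residual() / pk_fast.total_dose <= 0.05


def test_urine_is_monotone(pk_fast):
    for sp in ("INH", "ACINH", "INA"):
        col = pk_fast.amounts[f"urine_{sp}"].to_numpy()
        assert np.all(np.diff(col) >= -1e-9), sp


def test_rate_series_matches_xenobiotic_ids(pk_fast):
    assert set(pk_fast.series.reaction_ids) == {
        "XEN_NAT2_INH", "XEN_NAT2_HZ", "XEN_NAT2_ACHZ", "XEN_AMIDASE_INH",
        "XEN_AMIDASE_ACINH", "XEN_CYP2E1_ACHZ", "XEN_GLYCONJ_INA", "XEN_NOS2_HZ",
    }
    assert np.all(pk_fast.series.rates >= 0.0)


def test_fast_acetylates_more_than_slow(pk_fast, pk_slow):
    f = pk_fast.urinary_fractions()
    s = pk_slow.urinary_fractions()
    assert f["ACINH"] > s["ACINH"]
    assert f["INH"] < s["INH"]


def test_excretion_ledger_totals(pk_fast):
    ledger = pk_fast.excretion_ledger().set_index("species")["fraction_of_dose"]
    assert ledger["total_isonicotinyl"] == pytest.approx(
        sum(ledger[s] for s in ("INH", "ACINH", "INA", "INGLY")), abs=1e-12
    )


def test_multi_dose_accumulates():
    m1 = acetylator_preset("fast")
    m3 = multi_dose(acetylator_preset("fast"), 3, 1440.0)
    assert len(m3.doses) == 3
    assert sum(d.amount for d in m3.doses) == pytest.approx(3 * DOSE_300MG_UMOL)
    r1 = m1.simulate(duration=4320.0, dt=10.0)
    r3 = m3.simulate(duration=5760.0, dt=10.0)
    assert r3.mass_balance_error() <= 1e-9
    assert sum(r3.urinary_amounts().values()) > sum(r1.urinary_amounts().values())


def test_model_json_round_trip(tmp_path):
    m = acetylator_preset("slow")
    path = str(tmp_path / "model.json")
    m.to_json(path)
    back = PBPKModel.from_json(path)
    assert back.nat2_vmax_scale == m.nat2_vmax_scale
    assert len(back.reactions) == len(m.reactions)
    assert back.renal_clearance == m.renal_clearance
    r_a = m.simulate(duration=60.0, dt=1.0)
    r_b = back.simulate(duration=60.0, dt=1.0)
    assert np.allclose(r_a.series.rates, r_b.series.rates)


def test_simulation_is_deterministic():
    a = acetylator_preset("fast").simulate(duration=240.0, dt=1.0)
    b = acetylator_preset("fast").simulate(duration=240.0, dt=1.0)
    assert np.array_equal(a.series.rates, b.series.rates)


def test_duration_must_cover_doses():
    m = multi_dose(acetylator_preset("fast"), 2, 1440.0)
    with pytest.raises(ValueError, match="duration"):
        m.simulate(duration=720.0, dt=1.0)
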