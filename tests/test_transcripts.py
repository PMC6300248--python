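"""1/E^Cq quantitation, pool composition, fold induction, RT- screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from psiirepair import NoiseModel, make_preset
from psiirepair.synth import generate_qpcr
from psiirepair.transcripts import (fold_induction, load_primer_table,
                                    pool_composition, relative_abundance,
                                    rt_minus_check, rt_minus_screen,
                                    triplicate_mean_cq)


def test_relative_abundance_worked_values():
    assert relative_abundance(10.0, 2.0) == pytest.approx(1 / 1024)
    assert relative_abundance(0.0, 2.0) == 1.0
    # delta-Cq of 3 cycles at E=2 is an 8-fold abundance ratio
    assert relative_abundance(20.0, 2.0) / relative_abundance(23.0, 2.0) \
        == pytest.approx(8.0)
    with pytest.raises(ValueError):
        relative_abundance(10.0, 1.0)
    with pytest.raises(ValueError):
        relative_abundance(10.0, 2.5)


@given(cq=st.floats(0.1, 40.0), dcq=st.floats(0.1, 5.0),
       e=st.floats(1.1, 2.0), de=st.floats(0.001, 0.4))
def test_abundance_monotone_in_cq_and_efficiency(cq, dcq, e, de):
    assert relative_abundance(cq + dcq, e) < relative_abundance(cq, e)
    e2 = min(e + de, 2.0)
    if e2 > e:
        assert relative_abundance(cq, e2) < relative_abundance(cq, e)


def test_triplicate_outlier_drop():
    mean, kept = triplicate_mean_cq([20.0, 20.2, 23.0])
    assert kept == 2
    assert mean == pytest.approx(20.1)
    mean_all, kept_all = triplicate_mean_cq([20.0, 20.2, 20.4])
    assert kept_all == 3
    assert triplicate_mean_cq([np.nan] * 3) == (pytest.approx(np.nan, nan_ok=True), 0)


def _records(rows):
    return pd.DataFrame(rows, columns=["strain_id", "isoform", "condition",
                                       "rt", "biological_replicate_id",
                                       "cq1", "cq2", "cq3", "efficiency"])


def test_equal_cq_gives_equal_fractions():
    rows = [("X", iso, "GL", "plus", "rep1", 20.0, 20.0, 20.0, 2.0)
            for iso in ("FtsH1", "FtsH2", "FtsH3", "FtsH4")]
    pool = pool_composition(_records(rows), "X", "GL")
    assert all(f == pytest.approx(0.25) for f in pool.fractions.values())
    assert sum(pool.fractions.values()) == pytest.approx(1.0, abs=1e-9)


def test_two_cycles_lower_means_fourfold_abundance():
    rows = [("X", "FtsH1", "GL", "plus", "rep1", 18.0, 18.0, 18.0, 2.0)] + [
        ("X", iso, "GL", "plus", "rep1", 20.0, 20.0, 20.0, 2.0)
        for iso in ("FtsH2", "FtsH3", "FtsH4")]
    pool = pool_composition(_records(rows), "X", "GL")
    assert pool.abundances["FtsH1"] == pytest.approx(
        4 * pool.abundances["FtsH2"])


def test_missing_isoform_recorded_zero_with_flag():
    rows = [("X", iso, "GL", "plus", "rep1", 20.0, 20.0, 20.0, 2.0)
            for iso in ("FtsH1", "FtsH2", "FtsH3")]
    pool = pool_composition(_records(rows), "X", "GL")
    assert pool.abundances["FtsH4"] == 0.0
    assert any("FtsH4" in f for f in pool.flags)


def test_fold_induction_identity_and_zero_pool_error():
    rows = [("X", iso, c, "plus", "rep1", 20.0, 20.0, 20.0, 2.0)
            for iso in ("FtsH1", "FtsH2", "FtsH3", "FtsH4")
            for c in ("GL", "HL")]
    df = _records(rows)
    gl = pool_composition(df, "X", "GL")
    hl = pool_composition(df, "X", "HL")
    assert fold_induction(gl, hl) == pytest.approx(1.0)
    empty = pool_composition(df[df["condition"] == "none"], "X", "GL")
    with pytest.raises(ValueError):
        fold_induction(empty, hl)


def test_fold_induction_invariant_to_common_rescaling():
    p = make_preset("MED4_30")
    scaled_gl = {k: 3.7 * v for k, v in p.transcript_pool_gl.items()}
    scaled_hl = {k: 3.7 * v for k, v in p.transcript_pool_hl.items()}
    base = sum(p.transcript_pool_hl.values()) / sum(p.transcript_pool_gl.values())
    assert sum(scaled_hl.values()) / sum(scaled_gl.values()) == pytest.approx(base)


def test_med4_zero_noise_pools_reproduce_preset_composition():
    p = make_preset("MED4_30")
    rng = np.random.default_rng(4)
    qpcr = generate_qpcr(p, NoiseModel.zero(), 3, rng)
    gl = pool_composition(qpcr, "MED4", "GL")
    hl = pool_composition(qpcr, "MED4", "HL")
    for iso, ab in p.transcript_pool_gl.items():
        assert gl.abundances[iso] == pytest.approx(ab, rel=1e-9)
    assert fold_induction(gl, hl) == pytest.approx(8.0, rel=1e-9)
    # high-light pool dominated by isoforms 1 and 2
    fr = hl.fractions
    assert fr["FtsH1"] + fr["FtsH2"] > 0.8


def test_mit9313_pool_does_not_increase_under_high_light():
    p = make_preset("MIT9313_30")
    rng = np.random.default_rng(4)
    qpcr = generate_qpcr(p, NoiseModel.zero(), 3, rng)
    gl = pool_composition(qpcr, "MIT9313", "GL")
    hl = pool_composition(qpcr, "MIT9313", "HL")
    assert fold_induction(gl, hl) <= 1.0
    assert max(gl.fractions, key=gl.fractions.get) == "FtsH3"


def test_rt_minus_rules_and_boundary():
    plus = [20.0, 20.1, 19.9]
    assert rt_minus_check(plus, [np.nan] * 3) == "pass"  # RT- undetected
    assert rt_minus_check(plus, [22.0, 22.0, 22.0]) == "fail"
    assert rt_minus_check(plus, [25.0, 25.0, 25.0]) == "pass"  # == 5 cycles


def test_rt_minus_screen_flags_missing_partner():
    rows = [("X", "FtsH1", "GL", "plus", "rep1", 20.0, 20.0, 20.0, 2.0)]
    screen = rt_minus_screen(_records(rows))
    assert screen["outcome"].iloc[0] == "pass"
    assert screen["flag"].iloc[0] == "missing_rt_minus_partner"


def test_primer_fixture_table_matches_assay_design():
    primers = load_primer_table()
    assert set(primers["strain_id"]) == {"MIT9313", "MED4"}
    assert primers["amplicon_size_bp"].between(157, 226).all()
    assert len(primers) == 16  # 2 strains x 4 isoforms x F/R
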