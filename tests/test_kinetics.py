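import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oxidimer.kinetics import (TSRecord, rate_pair, rates_from_fixtures, tst_rate,
                               wigner_factor)
from oxidimer.thermo import CONSTANTS, Compound, Constants, Phase


class TestWigner:
    def test_no_imaginary_frequency_no_tunneling(self):
        assert wigner_factor(0.0) == 1.0

    @pytest.mark.parametrize("nu,expected", [
        (1702.2, 3.816), (1426.7, 2.978),
    ])
    def test_printed_frequencies(self, nu, expected):
        assert wigner_factor(nu) == pytest.approx(expected, abs=5e-4)

    @given(nu=st.floats(min_value=0, max_value=5000, allow_nan=False))
    def test_always_at_least_one(self, nu):
        assert wigner_factor(nu) >= 1.0

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            wigner_factor(-1.0)
        with pytest.raises(ValueError):
            wigner_factor(100.0, T=0.0)


class TestTstRate:
    # printed-table cells recomputed from their printed barrier/frequency;
    # agreement limit is 1% (one unit in the third significant digit): the
    # printed inputs are rounded to 3 decimals, so digit-exact reproduction
    # of the printed rates is not attainable
    @pytest.mark.parametrize("dG,nu,printed", [
        (21.684, 1702.2, 7.33e-2),   # 2AP-D1' forward, gas
        (9.478, 1426.7, 5.07e7),     # 2AP-D2' reverse, gas
        (13.665, 1385.9, 4.16e4),    # L-3HOK-D2' forward, water
        (19.932, 1706.1, 1.42e0),    # 3HAAi-D1' forward, water
    ])
    def test_printed_cells(self, dG, nu, printed):
        assert tst_rate(dG, nu) == pytest.approx(printed, rel=1e-2)

    def test_huge_barrier_gives_vanishing_rate(self):
        assert tst_rate(200.0, 1500.0) < 1e-100

    def test_negative_barrier_allowed_but_logged(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="oxidimer"):
            k = tst_rate(-1.0, 1500.0)
        assert k > 0
        assert any("barrierless" in r.message for r in caplog.records)

    @given(d=st.floats(min_value=1.0, max_value=40.0),
           step=st.floats(min_value=0.1, max_value=10.0))
    def test_log_k_decreasing_in_barrier(self, d, step):
        assert tst_rate(d + step, 1500.0) < tst_rate(d, 1500.0)

    @given(nu=st.floats(min_value=0.0, max_value=4000.0),
           step=st.floats(min_value=1.0, max_value=500.0))
    def test_k_increasing_in_frequency(self, nu, step):
        assert tst_rate(20.0, nu + step) > tst_rate(20.0, nu)

    def test_degeneracy_scales_linearly(self):
        assert tst_rate(20.0, 1500.0, degeneracy=2) == pytest.approx(
            2 * tst_rate(20.0, 1500.0), rel=1e-12)

    def test_exact_constants_shift_rates_slightly(self):
        exact = Constants(wigner_coeff=1.43877, std_state_factor=24.465)
        ratio = tst_rate(20.0, 1500.0, constants=exact) / tst_rate(20.0, 1500.0)
        assert 0.99 < ratio < 1.01 and ratio != 1.0


class TestRatePair:
    def make(self, dgr, dgp, nu=1500.0):
        return TSRecord(label="t", compound=Compound.AP2, phase=Phase.GAS,
                        dG_TS_R=dgr, dG_TS_P=dgp, nu_i=nu)

    def test_direction_from_reaction_free_energy(self):
        # L-3HOK-D2' in gas is the one downhill O-H abstraction
        res = rate_pair(self.make(15.373, 16.224, 1385.9))
        assert res.record.dG_P_R == pytest.approx(-0.851, abs=1e-9)
        assert res.K_eq_direction == "products_favored"

    def test_symmetric_barriers_equal_rates(self):
        res = rate_pair(self.make(20.0, 20.0))
        assert res.k_forward == res.k_reverse

    def test_spin_forbidden_stage_reverse_dominates(self):
        # 2AP-D5' gas: reverse faster by many orders of magnitude
        res = rate_pair(self.make(33.439, 21.308, 2297.8))
        assert res.k_reverse / res.k_forward > 1e8
        assert res.K_eq_direction == "reactants_favored"

    @given(dgr=st.floats(min_value=5, max_value=40),
           dgp=st.floats(min_value=5, max_value=40),
           nu=st.floats(min_value=0, max_value=4000))
    def test_detailed_balance_exact(self, dgr, dgp, nu):
        """k_f/k_r = exp(-ΔG_P-R/RT): degeneracy, standard-state and Wigner
        factors cancel exactly."""
        res = rate_pair(self.make(dgr, dgp, nu))
        expected = math.exp(-(dgr - dgp) * 1000.0 / (CONSTANTS.R_cal * CONSTANTS.T))
        assert res.k_forward / res.k_reverse == pytest.approx(expected, rel=1e-9)

    def test_raw_g_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            TSRecord(label="t", compound=Compound.AP2, phase=Phase.GAS,
                     dG_TS_R=10.0, dG_TS_P=5.0, nu_i=1500.0,
                     G_TS=0.0, G_R=-11.0, G_P=-5.0)


def test_full_printed_table_reproduced(fixtures):
    """All 60 printed rate cells recomputed from printed barriers and
    frequencies agree within the printed-precision limit (1%)."""
    df = rates_from_fixtures(fixtures)
    assert len(df) == 30
    rel_f = np.abs(df.k_forward / df.k_fwd_printed - 1)
    rel_r = np.abs(df.k_reverse / df.k_rev_printed - 1)
    assert rel_f.max() < 1e-2 and rel_r.max() < 1e-2


def test_3haai_has_only_d1p_row(fixtures):
    # no stable TS was found for 3HAAi D2'/D5': the rows are absent, not zero
    sub = fixtures.ts[fixtures.ts.compound == "3HAAi"]
    assert set(sub["form"]) == {"D1p"}
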