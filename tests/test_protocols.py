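"""Protocol suite: APD measurement, restitution, alternans, Ca metrics."""

import numpy as np
import pandas as pd
import pytest

from ordsim.integrator import PacingProtocol, Trace, run, steady_state_pace
from ordsim.model import State, make_params
from ordsim.protocols import (APDSet, RepolarizationFailure,
                              alternans_metrics, apd_set,
                              ca_transient_metrics, detect_eads,
                              measure_apd, s1s2_restitution)


def synthetic_triangle_trace(rest=-100.0, peak=0.0, fall_ms=100.0,
                             dt=0.05):
    """Instantaneous rise to ``peak`` then linear return to ``rest``."""
    t_pre = np.arange(0.0, 5.0, dt)
    v_pre = np.full_like(t_pre, rest)
    t_fall = np.arange(5.0 + dt, 5.0 + fall_ms + dt, dt)
    v_fall = peak + (rest - peak) * (t_fall - (5.0 + dt)) / fall_ms
    t = np.concatenate([t_pre, [5.0 + dt / 2], t_fall])
    v = np.concatenate([v_pre, [peak], v_fall])
    return Trace(t=t, v=v, beats=pd.DataFrame(), stim_times=np.zeros(0))


class TestMeasureApd:
    def test_linear_repolarization_geometry(self):
        tr = synthetic_triangle_trace()
        assert measure_apd(tr, 90.0) == pytest.approx(90.0, abs=0.2)
        assert measure_apd(tr, 30.0) == pytest.approx(30.0, abs=0.2)

    def test_level_ordering_holds(self):
        tr = synthetic_triangle_trace()
        vals = [measure_apd(tr, lv) for lv in (30, 50, 70, 90)]
        assert np.all(np.diff(vals) > 0)
        APDSet(*vals)  # ordering invariant accepted

    def test_apdset_rejects_misordered_values(self):
        with pytest.raises(ValueError):
            APDSet(100.0, 90.0, 120.0, 130.0)

    def test_unrepolarized_trace_flagged(self):
        t = np.arange(0.0, 50.0, 0.1)
        v = np.where(t < 5, -90.0, 10.0)  # depolarizes, never returns
        tr = Trace(t=t, v=v, beats=pd.DataFrame(), stim_times=np.zeros(0))
        with pytest.raises(RepolarizationFailure):
            measure_apd(tr, 90.0)

    def test_matches_kernel_apd_on_real_beat(self, accept_ss1000,
                                             endo_params):
        tr, _ = run(accept_ss1000.state,
                    PacingProtocol(cl=1000.0, n_beats=1), endo_params,
                    record="v", rec_start=0.0, rec_dt=0.05)
        for lv, col in ((30, "apd30"), (90, "apd90")):
            assert measure_apd(tr, lv) == pytest.approx(
                tr.beats[col].iloc[0], abs=0.2)

    def test_per_beat_ordering_invariant(self, accept_ss1000):
        b = accept_ss1000.beats.iloc[-1]
        s = apd_set(b)
        assert s.apd30 <= s.apd50 <= s.apd70 <= s.apd90 <= s.apd95


class TestAlternansMetrics:
    def test_slow_rate_has_no_alternans(self, accept_ss1000):
        m = alternans_metrics(accept_ss1000)
        assert not m["block_2to1"]
        assert m["delta_apd90"] < 0.5
        assert m["delta_ca_peak"] < 1e-5


class TestS1S2:
    def test_restitution_monotone_and_full_recovery(self, accept_ss1000,
                                                    endo_params):
        """S2 APD90 grows with DI; an S2 falling exactly on the S1 rhythm
        (DI = CL - APD90) reproduces the steady APD90."""
        apd_ss = accept_ss1000.beats.apd90.iloc[-1]
        di_match = 1000.0 - apd_ss
        curve = s1s2_restitution(s1_state=accept_ss1000.state,
                                 params=endo_params,
                                 dis=(5, 20, 70, 200, di_match))
        a = curve.table.apd90.to_numpy()
        assert np.all(np.diff(a) > 0)
        assert curve.table.captured.all()
        assert a[-1] == pytest.approx(apd_ss, abs=1.0)

    def test_negative_di_outside_protocol_domain(self, accept_ss1000,
                                                 endo_params):
        """DI is defined from APD90 completion; a negative DI would land
        the S2 on the plateau and is rejected."""
        with pytest.raises(ValueError, match="diastolic interval"):
            s1s2_restitution(s1_state=accept_ss1000.state,
                             params=endo_params, dis=(-150.0,))


class TestCaTransient:
    def test_metrics_well_formed(self, accept_ss1000, endo_params):
        tr, _ = run(accept_ss1000.state,
                    PacingProtocol(cl=1000.0, n_beats=1), endo_params,
                    record="states", rec_start=0.0, rec_dt=0.5)
        m = ca_transient_metrics(tr.t, tr.states["cai"].to_numpy())
        assert m.peak > m.diastolic > 0
        assert 10.0 < m.tau < 1000.0

    def test_decay_accelerates_with_rate(self, accept_ss1000, endo_params,
                                         accept_ss2000):
        """Frequency-dependent acceleration of relaxation: Ca decay tau at
        2 Hz is smaller than at 0.5 Hz."""
        p = endo_params
        fast = steady_state_pace(p, 500.0, start_state=accept_ss1000.state,
                                 max_beats=300)
        taus = {}
        for tag, res, cl in (("fast", fast, 500.0),
                             ("slow", accept_ss2000, 2000.0)):
            tr, _ = run(res.state, PacingProtocol(cl=cl, n_beats=1), p,
                        record="states", rec_start=0.0, rec_dt=0.5)
            taus[tag] = ca_transient_metrics(
                tr.t, tr.states["cai"].to_numpy()).tau
        assert taus["fast"] < taus["slow"]

    def test_camk_removal_blunts_ca_cycling(self, accept_ss1000):
        """Without CaMK: smaller Ca transient, higher diastolic Ca."""
        p_off = make_params("endo", camk=False)
        off = steady_state_pace(p_off, 1000.0, max_beats=400,
                                start_state=accept_ss1000.state)
        b_on = accept_ss1000.beats.iloc[-1]
        b_off = off.beats.iloc[-1]
        amp_on = b_on.cai_max - b_on.cai_min
        amp_off = b_off.cai_max - b_off.cai_min
        assert amp_off < amp_on
        assert b_off.cai_min > b_on.cai_min


class TestEADDetection:
    def test_no_eads_on_normal_beat(self, accept_ss1000, endo_params):
        tr, _ = run(accept_ss1000.state,
                    PacingProtocol(cl=1000.0, n_beats=1), endo_params,
                    record="v", rec_start=0.0, rec_dt=0.2)
        assert detect_eads(tr).count == 0


class TestMechanismExperiments:
    def test_na_clamp_flattens_rate_dependence(self, accept_ss1000,
                                               accept_ss2000, endo_params):
        """Clamping [Na+]i/[Na+]ss to slow-rate values keeps the APD long
        at fast rates: the Na+/INaK axis carries most of the steady-state
        APD rate dependence."""
        from ordsim.integrator import Intervention
        from ordsim.protocols import mechanism_experiment
        iv = Intervention(clamps={"nai": accept_ss2000.state["nai"],
                                  "nass": accept_ss2000.state["nass"]})
        df = mechanism_experiment(iv, "rate", cls=(2000, 500),
                                  max_beats=300)
        d_ctrl = (df.set_index("cl").control[2000]
                  - df.set_index("cl").control[500])
        d_clmp = (df.set_index("cl").intervention[2000]
                  - df.set_index("cl").intervention[500])
        assert d_clmp < 0.65 * d_ctrl           # residual dependence remains
        assert df.set_index("cl").intervention[500] \
            > df.set_index("cl").control[500] + 10.0

    def test_gate_reset_at_s2_flattens_restitution(self, accept_ss1000,
                                                   endo_params):
        """Resetting late-INa and ICaL inactivation gates to their S1
        values at S2 delivery keeps the APD long at all DIs: restitution
        is carried by recovery-from-inactivation kinetics."""
        from ordsim.integrator import Intervention
        from ordsim.protocols import mechanism_experiment, \
            prestimulus_values
        resets = prestimulus_values(accept_ss1000.state,
                                    ("hL", "hLp", "ff", "fs", "fcaf",
                                     "fcas", "jca"))
        df = mechanism_experiment(Intervention(gate_resets=resets), "s1s2",
                                  dis=(5, 70, 1000), max_beats=300)
        spread_ctrl = df.control.max() - df.control.min()
        spread_rst = df.intervention.max() - df.intervention.min()
        assert spread_rst < 0.5 * spread_ctrl
        assert df.intervention.iloc[0] > df.control.iloc[0] + 20.0


class TestIonRateDependence:
    def test_sodium_accumulates_and_relaxation_accelerates(self):
        """[Na+]i rises monotonically with pacing frequency (normalized to
        the slowest rate) and the Ca2+ decay tau shortens (FDAR); peak
        Ca2+ at ~Schmidt protocol length is below its true steady state."""
        from ordsim.protocols import ion_rate_dependence
        df = ion_rate_dependence(frequencies=(0.5, 1.0, 2.0),
                                 max_beats=300, schmidt_beats=50)
        assert df.nai_norm.iloc[0] == 1.0
        assert np.all(np.diff(df.nai.to_numpy()) > 0)
        assert np.all(np.diff(df.ca_tau.to_numpy()) < 0)
        tail = df.iloc[1:]
        assert np.all(tail.ca_peak_100.to_numpy()
                      < tail.ca_peak_ss.to_numpy())
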