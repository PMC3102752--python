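"""Time integration: pacing protocols, interventions, trace recording.

Gates advance with the exponential (Rush-Larsen) update, everything else
with forward Euler, on a hybrid time step: ``dt_fast`` during the stimulus
and upstroke (|dVm/dt| > ``thr_fast``), ``dt_mid`` through plateau and
repolarization, ``dt_slow`` in diastole.  The scheme is deterministic —
identical configuration gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import constants as C
from . import _kernel as K
from .model import ModelParameters, State

__all__ = ["PacingProtocol", "Intervention", "Trace", "IntegratorSettings",
           "step", "run", "steady_state_pace", "PacingResult"]

APD_LEVELS = np.array([30.0, 50.0, 70.0, 90.0, 95.0])

_EMPTY_I = np.zeros(0, dtype=np.int64)
_EMPTY_F = np.zeros(0, dtype=np.float64)


@dataclass
class IntegratorSettings:
    """Hybrid time-step scheme (ms and mV/ms)."""
    dt_fast: float = C.DT_FAST
    dt_mid: float = C.DT_MID
    dt_slow: float = C.DT_SLOW
    thr_fast: float = C.THR_FAST
    thr_mid: float = C.THR_MID

    def scaled(self, factor: float) -> "IntegratorSettings":
        return IntegratorSettings(self.dt_fast * factor, self.dt_mid * factor,
                                  self.dt_slow * factor,
                                  self.thr_fast, self.thr_mid)


@dataclass
class PacingProtocol:
    """Stimulus schedule: fixed CL, optional multi-segment CL schedule.

    ``schedule`` is a list of (cycle length ms, beat count) segments; when
    given it overrides ``cl``/``n_beats``.  ``extra_time`` extends the run
    past the final cycle (e.g. for slow-repolarization recording).
    """
    cl: float = 1000.0
    n_beats: int = 1
    stim_amp: float = C.STIM_AMP
    stim_dur: float = C.STIM_DUR
    schedule: Optional[Sequence[Tuple[float, int]]] = None
    extra_time: float = 0.0

    def __post_init__(self):
        segs = self.segments()
        for cl, n in segs:
            if cl <= self.stim_dur:
                raise ValueError("cycle length must exceed stimulus duration")
            if n < 0:
                raise ValueError("beat count must be >= 0")

    def segments(self) -> List[Tuple[float, int]]:
        if self.schedule is not None:
            return [(float(cl), int(n)) for cl, n in self.schedule]
        return [(float(self.cl), int(self.n_beats))]

    def stim_times(self) -> np.ndarray:
        times = []
        t = 0.0
        for cl, n in self.segments():
            for _ in range(n):
                times.append(t)
                t += cl
        return np.array(times)

    def t_end(self) -> float:
        t = 0.0
        for cl, n in self.segments():
            t += cl * n
        return t + self.extra_time


@dataclass
class Intervention:
    """Declarative clamp/reset rules applied during a run.

    clamps            : state name -> constant value (held every step)
    waveform          : (state name, times ms, values) sampled clamp
    gate_resets       : state name -> value, applied at each stimulus onset
                        from beat index ``reset_from_beat`` on
    monotonic_gates   : gates allowed only to decrease (recovery prevented)
    camk_off          : disable CaMK signalling for the run
    """
    clamps: Dict[str, float] = field(default_factory=dict)
    waveform: Optional[Tuple[str, np.ndarray, np.ndarray]] = None
    gate_resets: Dict[str, float] = field(default_factory=dict)
    reset_from_beat: int = 0
    monotonic_gates: Sequence[str] = ()
    camk_off: bool = False

    def validate(self) -> None:
        for name in list(self.clamps) + list(self.gate_resets) \
                + list(self.monotonic_gates):
            if name not in C.STATE_INDEX:
                raise KeyError(f"unknown state variable {name!r}")
        if self.waveform is not None:
            name, t, v = self.waveform
            if name not in C.STATE_INDEX:
                raise KeyError(f"unknown state variable {name!r}")
            t = np.asarray(t, float)
            v = np.asarray(v, float)
            if t.ndim != 1 or t.shape != v.shape or t.size < 2:
                raise ValueError("waveform needs matching 1D times/values")
            if np.any(np.diff(t) <= 0):
                raise ValueError("waveform times must increase")

    def _kernel_args(self):
        self.validate()
        ci = np.array([C.STATE_INDEX[n] for n in self.clamps], dtype=np.int64)
        cv = np.array(list(self.clamps.values()), dtype=float)
        if self.waveform is not None:
            wname, wt, wv = self.waveform
            widx = C.STATE_INDEX[wname]
            wt = np.asarray(wt, float)
            wv = np.asarray(wv, float)
        else:
            widx, wt, wv = 0, _EMPTY_F, _EMPTY_F
        ri = np.array([C.STATE_INDEX[n] for n in self.gate_resets],
                      dtype=np.int64)
        rv = np.array(list(self.gate_resets.values()), dtype=float)
        mi = np.array([C.STATE_INDEX[n] for n in self.monotonic_gates],
                      dtype=np.int64)
        return ci, cv, widx, wt, wv, ri, rv, int(self.reset_from_beat), mi


@dataclass
class Trace:
    """Recorded time series plus per-beat summaries."""
    t: np.ndarray                    # ms, strictly increasing
    v: np.ndarray                    # mV
    beats: pd.DataFrame              # one row per stimulus
    stim_times: np.ndarray
    currents: Optional[pd.DataFrame] = None
    states: Optional[pd.DataFrame] = None
    prestates: Optional[np.ndarray] = None   # (n_beats, 41) pre-stimulus states

    def beat_frame(self) -> pd.DataFrame:
        return self.beats

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.t, "v": self.v})
        if self.currents is not None:
            df = pd.concat([df, self.currents.reset_index(drop=True)], axis=1)
        return df


_BEAT_COLS = ["t_stim", "v_rest", "v_max", "dvdt_max", "t_dvdt_max",
              "apd30", "apd50", "apd70", "apd90", "apd95",
              "repolarized", "cai_max", "cai_min", "inal_min", "camka_avg"]


def step(state: State, dt: float, params: ModelParameters,
         i_stim: float = 0.0) -> State:
    """Advance one hybrid step (RL gates + Euler otherwise); returns new state."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    cur = np.zeros(K.N_CUR)
    ginf = np.zeros(31)
    gtau = np.zeros(31)
    dy = np.zeros(C.N_STATE)
    y = state.values.copy()
    K.compute_rhs(y, params.array, params.celltype_code,
                  params.camk and state.camk, float(i_stim),
                  cur, ginf, gtau, dy)
    K._rl_step(y, float(dt), ginf, gtau, dy)
    if not np.isfinite(y[0]):
        raise FloatingPointError("non-finite state after step")
    return State(y, state.camk)


def run(state: State, protocol: PacingProtocol, params: ModelParameters,
        intervention: Optional[Intervention] = None,
        record: str = "v", rec_start: Optional[float] = None,
        rec_dt: float = 0.1,
        settings: Optional[IntegratorSettings] = None,
        ) -> Tuple[Trace, State]:
    """Run a pacing protocol from ``state``; returns (Trace, final state).

    ``record``: "none", "v", "currents", or "states" (each level includes the
    previous).  ``rec_start`` defaults to the onset of the final beat.
    """
    iv = intervention or Intervention()
    iv.validate()
    st = settings or IntegratorSettings()
    stim_times = protocol.stim_times()
    t_end = protocol.t_end()
    camk_on = params.camk and state.camk and not iv.camk_off

    if record == "none":
        rstart = t_end + 1.0
    elif rec_start is not None:
        rstart = float(rec_start)
    elif stim_times.size:
        rstart = float(stim_times[-1])
    else:
        rstart = 0.0
    rec_currents = record in ("currents", "states")
    rec_states = record == "states"

    ci, cv, widx, wt, wv, ri, rv, rfrom, mi = iv._kernel_args()
    y = state.values.copy()
    try:
        out = K.run_cell(y, params.array, params.celltype_code, camk_on,
                         stim_times, protocol.stim_amp, protocol.stim_dur,
                         t_end, st.dt_fast, st.dt_mid, st.dt_slow,
                         st.thr_fast, st.thr_mid,
                         ci, cv, widx, wt, wv, ri, rv, rfrom, mi,
                         rstart, rec_dt, rec_currents, rec_states,
                         APD_LEVELS)
    except (ZeroDivisionError, OverflowError) as exc:
        raise FloatingPointError(
            f"non-finite state during integration step: {exc}") from exc
    (status, fail_step, prestate, vrest, vmax, dvdtmax, t_dvdtmax, apd,
     cai_max, cai_min, inal_min, camka_avg,
     rec_t, rec_v, rec_cur, rec_y) = out
    if status != 0:
        raise FloatingPointError(
            f"non-finite state during integration at step {fail_step}")

    nb = stim_times.size
    beats = pd.DataFrame({
        "t_stim": stim_times,
        "v_rest": vrest, "v_max": vmax,
        "dvdt_max": dvdtmax, "t_dvdt_max": t_dvdtmax,
        "apd30": apd[:, 0], "apd50": apd[:, 1], "apd70": apd[:, 2],
        "apd90": apd[:, 3], "apd95": apd[:, 4],
        "repolarized": ~np.isnan(apd[:, 3]),
        "cai_max": cai_max, "cai_min": cai_min,
        "inal_min": inal_min, "camka_avg": camka_avg,
    }, columns=_BEAT_COLS) if nb else pd.DataFrame(columns=_BEAT_COLS)

    currents = None
    if rec_currents and rec_cur.size:
        currents = pd.DataFrame(rec_cur, columns=list(_KCUR_NAMES))
    states_df = None
    if rec_states and rec_y.size:
        states_df = pd.DataFrame(rec_y, columns=list(C.STATE_NAMES))
    trace = Trace(t=rec_t, v=rec_v, beats=beats, stim_times=stim_times,
                  currents=currents, states=states_df, prestates=prestate)
    return trace, State(y, state.camk)


_KCUR_NAMES = ("INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs",
               "IK1", "INaCa_i", "INaCa_ss", "INaK", "INab", "ICab", "IKb",
               "IpCa", "Istim", "Jrel", "Jup", "Jtr", "Jdiff_Na", "Jdiff_Ca",
               "Jdiff_K", "Jleak", "CaMKa")


@dataclass
class PacingResult:
    """Outcome of pacing toward a periodic (1:1 or period-2) orbit."""
    state: State                     # pre-stimulus state, final beat
    converged: bool
    alternans: bool
    capture_failure: bool            # some stimuli failed to elicit an AP
    n_beats: int
    beats: pd.DataFrame              # summaries of the final chunk of beats
    state2: Optional[State] = None   # second phase of a period-2 orbit
    apd90_pair: Optional[Tuple[float, float]] = None

    @property
    def delta_apd90(self) -> float:
        if self.apd90_pair is None:
            return 0.0
        return abs(self.apd90_pair[0] - self.apd90_pair[1])


# characteristic magnitude per state variable, used as an absolute floor in
# the convergence norm (1e-3 of a typical peak value), so that physically
# meaningless diastolic tails (e.g. the release flux, ~1e-7 mM/ms between
# beats) do not dominate a relative criterion
_STATE_SCALE = np.ones(C.N_STATE)
_STATE_SCALE[0] = 100.0                       # Vm, mV
_STATE_SCALE[[1, 2]] = 10.0                   # Na, mM
_STATE_SCALE[[3, 4]] = 150.0                  # K, mM
_STATE_SCALE[[5, 6]] = 1.0e-3                 # Ca myo/ss, mM
_STATE_SCALE[[7, 8]] = 2.0                    # Ca SR, mM
_STATE_SCALE[[C.STATE_INDEX["Jrelnp"], C.STATE_INDEX["Jrelp"]]] = 1.0e-2


def _rel_linf(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.max(np.abs(a - b) / (np.abs(a) + 1.0e-3 * _STATE_SCALE)))


def steady_state_pace(params: ModelParameters, cl: float,
                      start_state: Optional[State] = None,
                      tol: float = 1.0e-6, max_beats: int = 1000,
                      chunk: int = 64,
                      stim_amp: float = C.STIM_AMP,
                      stim_dur: float = C.STIM_DUR,
                      intervention: Optional[Intervention] = None,
                      settings: Optional[IntegratorSettings] = None,
                      ) -> PacingResult:
    """Pace until the beat-to-beat pre-stimulus state change falls below tol.

    Convergence is the relative L-inf norm between consecutive pre-stimulus
    states (or between beats n and n-2 for a period-2/alternans orbit,
    which is then reported with both phases).
    """
    if cl <= stim_dur:
        raise ValueError("cycle length out of range")
    state = start_state.copy() if start_state is not None \
        else State(C.INITIAL_STATE, camk=params.camk)
    total = 0
    last_prestate = None   # prestate of final beat of previous chunk
    prev_prestate2 = None
    trace = None
    while total < max_beats:
        n = min(chunk, max_beats - total)
        proto = PacingProtocol(cl=cl, n_beats=n, stim_amp=stim_amp,
                               stim_dur=stim_dur)
        trace, state = run(state, proto, params, intervention=intervention,
                           record="none", settings=settings)
        total += n
        ps = trace.prestates
        allp = ps if last_prestate is None else np.vstack([last_prestate, ps])
        # consecutive-beat and beat-(n-2) differences
        for k in range(1, allp.shape[0]):
            d1 = _rel_linf(allp[k], allp[k - 1])
            d2 = _rel_linf(allp[k], allp[k - 2]) if k >= 2 else np.inf
            if d1 < tol or d2 < tol:
                alternans = d1 >= tol
                return _finish(params, cl, state, trace, total, True,
                               alternans, stim_amp, stim_dur, intervention,
                               settings)
        last_prestate = ps[-2:] if ps.shape[0] >= 2 else ps
        prev_prestate2 = allp[-2:]
    return _finish(params, cl, state, trace, total, False,
                   _is_alternating(trace), stim_amp, stim_dur, intervention,
                   settings)


def _is_alternating(trace: Trace) -> bool:
    a = trace.beats["apd90"].to_numpy()
    if a.size < 3 or np.any(np.isnan(a[-3:])):
        return False
    return (abs(a[-1] - a[-2]) > 1.0 and abs(a[-1] - a[-3]) < 1.0)


def _finish(params, cl, state, trace, total, converged, alternans,
            stim_amp, stim_dur, intervention, settings) -> PacingResult:
    # run two more measured beats to characterize the final orbit
    proto = PacingProtocol(cl=cl, n_beats=2, stim_amp=stim_amp,
                           stim_dur=stim_dur)
    mtrace, final = run(state, proto, params, intervention=intervention,
                        record="none", settings=settings)
    beats = mtrace.beats
    capture_failure = bool((~beats["repolarized"]).any()
                           or (beats["v_max"] < 0).any())
    a = beats["apd90"].to_numpy()
    apd_pair = (float(a[0]), float(a[1])) if not np.any(np.isnan(a)) else None
    alternans = bool(alternans and apd_pair is not None
                     and abs(a[0] - a[1]) > 1.0)
    state2 = State(mtrace.prestates[1], state.camk) if alternans else None
    return PacingResult(state=State(mtrace.prestates[0], state.camk),
                        converged=converged, alternans=alternans,
                        capture_failure=capture_failure,
                        n_beats=total, beats=beats, state2=state2,
                        apd90_pair=apd_pair)
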