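"""Cell-level experimental protocols and summary metrics.

Every protocol here mirrors a wet-lab pacing experiment: steady-state rate
dependence, S1S2 and dynamic restitution, accommodation after abrupt rate
changes, EAD induction by IKr block at slow rate, alternans at fast rate,
and the mechanistic clamp/reset experiments that dissect which currents
carry rate dependence and restitution.

APD convention: an AP starts at the time of maximum dVm/dt; APDX ends when
Vm has returned to X% of the resting (pre-stimulus) voltage, with linear
interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import constants as C
from .integrator import (Intervention, PacingProtocol, PacingResult,
                         Trace, run, steady_state_pace)
from .model import ModelParameters, State, make_params

__all__ = [
    "APDSet", "RestitutionCurve", "CaTransientMetrics", "EADReport",
    "RepolarizationFailure", "measure_apd", "apd_set",
    "rate_dependence", "s1s2_restitution", "dynamic_restitution",
    "accommodation", "ead_protocol", "alternans_metrics",
    "ion_rate_dependence", "mechanism_experiment", "ca_transient_metrics",
]


class RepolarizationFailure(RuntimeError):
    """The AP never reached the repolarization threshold (e.g. 2:1 block)."""


@dataclass(frozen=True)
class APDSet:
    """APD at 30/50/70/90(/95)% repolarization for one beat, ms."""
    apd30: float
    apd50: float
    apd70: float
    apd90: float
    apd95: Optional[float] = None

    def __post_init__(self):
        vals = [self.apd30, self.apd50, self.apd70, self.apd90]
        if self.apd95 is not None:
            vals.append(self.apd95)
        arr = np.array(vals, dtype=float)
        if np.any(np.diff(arr[~np.isnan(arr)]) < -1e-9):
            raise ValueError("APD ordering violated (APD30<=...<=APD95)")


@dataclass
class RestitutionCurve:
    """(DI, APD) pairs; ``protocol`` is 's1s2' or 'dynamic'."""
    table: pd.DataFrame
    protocol: str


@dataclass(frozen=True)
class CaTransientMetrics:
    """Systolic/diastolic [Ca2+]i (mM) and single-exponential decay tau (ms)."""
    peak: float
    diastolic: float
    tau: float

    def __post_init__(self):
        if not (self.peak > self.diastolic):
            raise ValueError("Ca transient peak must exceed diastolic level")
        if not self.tau > 0:
            raise ValueError("decay time constant must be positive")


@dataclass
class EADReport:
    count: int
    takeoff_vm: List[float]
    amplitude: List[float]
    apd90: float


# ---------------------------------------------------------------------------
# APD measurement on a recorded trace
# ---------------------------------------------------------------------------

def measure_apd(trace: Trace, level: float, beat: int = -1) -> float:
    """APD at ``level``% repolarization for one recorded AP.

    Uses the trace's Vm samples: start at max dVm/dt, end where Vm falls
    below (level/100)*resting Vm (resting = first sample, assumed
    pre-stimulus).  Raises RepolarizationFailure if the threshold is never
    reached.
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100) percent")
    t = np.asarray(trace.t, float)
    v = np.asarray(trace.v, float)
    if t.size < 4:
        raise ValueError("trace too short")
    if np.any(np.diff(t) <= 0):
        raise ValueError("trace time must be strictly increasing")
    v_rest = v[0]
    dv = np.diff(v) / np.diff(t)
    iup = int(np.argmax(dv))
    t_up = 0.5 * (t[iup] + t[iup + 1])
    thr = level * 0.01 * v_rest
    for i in range(iup + 1, v.size - 1):
        if v[i] > thr >= v[i + 1]:
            tc = t[i] + (t[i + 1] - t[i]) * (v[i] - thr) / (v[i] - v[i + 1])
            return tc - t_up
    raise RepolarizationFailure(
        f"Vm never repolarized to {level}% of resting value")


def apd_set(beats_row: pd.Series) -> APDSet:
    """Bundle a per-beat summary row into an APDSet."""
    return APDSet(beats_row["apd30"], beats_row["apd50"], beats_row["apd70"],
                  beats_row["apd90"], beats_row.get("apd95"))


# ---------------------------------------------------------------------------
# Steady-state rate dependence
# ---------------------------------------------------------------------------

def rate_dependence(cell_type: str = "endo",
                    cls: Sequence[float] = (2000, 1500, 1000, 700, 500, 400, 300),
                    block: Optional[Mapping[str, float]] = None,
                    camk: bool = True, max_beats: int = 1000,
                    params: Optional[ModelParameters] = None) -> pd.DataFrame:
    """Steady-state APD30-90 (and Ca/Na summaries) per pacing cycle length.

    CLs are paced in the given order, each continuing from the previous
    steady state (descending order converges fastest).
    """
    p = params if params is not None else make_params(cell_type, camk=camk,
                                                      block=block)
    state = None
    rows = []
    for cl in cls:
        res = steady_state_pace(p, float(cl), start_state=state,
                                max_beats=max_beats)
        state = res.state
        b = res.beats.iloc[-1]
        rows.append({
            "cl": float(cl), "apd30": b.apd30, "apd50": b.apd50,
            "apd70": b.apd70, "apd90": b.apd90, "apd95": b.apd95,
            "dvdt_max": b.dvdt_max, "v_max": b.v_max, "v_rest": b.v_rest,
            "cai_max": b.cai_max, "cai_min": b.cai_min,
            "nai": res.state["nai"], "camka_avg": b.camka_avg,
            "alternans": res.alternans, "delta_apd90": res.delta_apd90,
            "capture_failure": res.capture_failure,
            "converged": res.converged, "n_beats": res.n_beats,
        })
    return pd.DataFrame(rows).sort_values("cl", ignore_index=True)


# ---------------------------------------------------------------------------
# Restitution
# ---------------------------------------------------------------------------

def s1s2_restitution(cell_type: str = "endo", s1_cl: float = 1000.0,
                     dis: Sequence[float] = (5, 10, 20, 40, 70, 100, 150,
                                             200, 300, 500, 1000),
                     block: Optional[Mapping[str, float]] = None,
                     max_beats: int = 1000,
                     params: Optional[ModelParameters] = None,
                     s1_state: Optional[State] = None,
                     intervention: Optional[Intervention] = None,
                     ) -> RestitutionCurve:
    """S2 APD after steady S1 pacing; DI measured relative to S1 APD90."""
    p = params if params is not None else make_params(cell_type, block=block)
    if s1_state is None:
        s1_state = steady_state_pace(p, s1_cl, max_beats=max_beats).state
    # reference S1 beat timing
    ref, _ = run(s1_state, PacingProtocol(cl=s1_cl, n_beats=1), p,
                 record="none")
    b1 = ref.beats.iloc[0]
    if np.isnan(b1.apd90):
        raise RepolarizationFailure("S1 beat does not repolarize")
    t90 = b1.t_dvdt_max + b1.apd90
    rows = []
    for di in dis:
        if di < 0:
            raise ValueError("diastolic interval must be >= 0 (DI is "
                             "measured from APD90 completion)")
        t_s2 = t90 + float(di)
        # two-stimulus schedule: S1 at t=0, S2 at t90 + DI
        proto = PacingProtocol(schedule=[(t_s2, 1), (1500.0, 1)])
        tr, _ = run(s1_state, proto, p, record="none",
                    intervention=intervention)
        b2 = tr.beats.iloc[1]
        rows.append({"di": float(di), "apd30": b2.apd30, "apd50": b2.apd50,
                     "apd70": b2.apd70, "apd90": b2.apd90,
                     "v_max": b2.v_max,
                     "captured": bool(b2.v_max > 0.0
                                      and not np.isnan(b2.apd90))})
    return RestitutionCurve(pd.DataFrame(rows), protocol="s1s2")


def dynamic_restitution(cell_type: str = "endo",
                        cls: Sequence[float] = (1000, 900, 800, 700, 600,
                                                550, 500, 450, 400, 375, 350,
                                                325, 300, 290, 280, 270, 260,
                                                250, 240, 230),
                        seconds_per_cl: float = 30.0,
                        params: Optional[ModelParameters] = None,
                        start_state: Optional[State] = None,
                        alternans_threshold: float = 1.0,
                        ) -> RestitutionCurve:
    """Dynamic (Koller) restitution: 30 s pacing per CL, APD95 vs DI.

    The final beats of each segment contribute one point per alternans
    phase (DI = CL - APD95 of the preceding beat), so one DI may map to two
    APDs.  The bifurcation report flags CLs whose consecutive-beat APD95
    differ by more than ``alternans_threshold`` ms.
    """
    p = params if params is not None else make_params(cell_type)
    state = start_state.copy() if start_state is not None \
        else State(C.INITIAL_STATE, camk=p.camk)
    rows = []
    for cl in cls:
        n = max(int(round(seconds_per_cl * 1000.0 / cl)), 4)
        tr, state = run(state, PacingProtocol(cl=float(cl), n_beats=n), p,
                        record="none")
        a95 = tr.beats["apd95"].to_numpy()
        ok = ~np.isnan(a95[-3:])
        bif = (ok.all()
               and abs(a95[-1] - a95[-2]) > alternans_threshold
               and abs(a95[-1] - a95[-3]) <= alternans_threshold)
        for k in (-2, -1):
            if not np.isnan(a95[k]) and not np.isnan(a95[k - 1]):
                rows.append({"cl": float(cl), "apd95": a95[k],
                             "di": float(cl) - a95[k - 1],
                             "alternans": bool(bif),
                             "delta_apd95": abs(a95[-1] - a95[-2])})
    return RestitutionCurve(pd.DataFrame(rows), protocol="dynamic")


# ---------------------------------------------------------------------------
# Accommodation
# ---------------------------------------------------------------------------

def accommodation(cell_type: str = "endo", cl_a: float = 750.0,
                  cl_b: float = 480.0, duration_each: float = 900.0,
                  params: Optional[ModelParameters] = None,
                  start_state: Optional[State] = None,
                  max_beats: int = 1000) -> Tuple[pd.DataFrame, float, State]:
    """APD90 time course after an abrupt CL change, with exponential fit.

    Paces to steady state at ``cl_a`` (unless ``start_state`` given), then
    switches abruptly to ``cl_b`` for ``duration_each`` seconds.  A single
    exponential with offset, A + B*exp(-t/tau), is fit to APD90 versus wall
    time from the first post-switch beat on (the switch beat itself carries
    the instantaneous restitution step, not accommodation).  Returns
    (course, tau_seconds, final state); tau is NaN if the fit fails.
    """
    p = params if params is not None else make_params(cell_type)
    ss = start_state if start_state is not None else \
        steady_state_pace(p, cl_a, max_beats=max_beats).state
    n = int(duration_each * 1000.0 / cl_b)
    tr, final = run(ss, PacingProtocol(cl=cl_b, n_beats=n), p, record="none")
    b = tr.beats
    course = pd.DataFrame({"t_s": b.t_stim / 1000.0, "apd90": b.apd90,
                           "nai": tr.prestates[:, 1]})
    tt = course.t_s.to_numpy()[1:]
    aa = course.apd90.to_numpy()[1:]
    ok = ~np.isnan(aa)
    tau = np.nan
    if ok.sum() > 10:

        def f(t, a0, b0, tau0):
            return a0 + b0 * np.exp(-t / tau0)

        try:
            popt, _ = curve_fit(
                f, tt[ok] - tt[0], aa[ok],
                p0=(aa[ok][-1], aa[ok][0] - aa[ok][-1], 150.0),
                maxfev=20000)
            tau = float(popt[2])
        except RuntimeError:
            tau = np.nan
    return course, tau, final


# ---------------------------------------------------------------------------
# EADs
# ---------------------------------------------------------------------------

def detect_eads(trace: Trace, v_floor: float = -40.0,
                min_rise: float = 1.0) -> EADReport:
    """Count EADs on the recorded beat: dVm/dt turning positive above
    ``v_floor`` after the AP peak, followed by a rise of >= ``min_rise`` mV."""
    t = trace.t
    v = trace.v
    dv = np.diff(v) / np.diff(t)
    ipk = int(np.argmax(v))
    takeoffs, amps = [], []
    i = ipk + 2
    while i < dv.size - 1:
        if v[i] > v_floor and dv[i - 1] < 0.0 and dv[i] >= 0.0:
            seg = v[i:]
            j = int(np.argmax(seg))
            rise = seg[j] - v[i]
            if rise >= min_rise:
                takeoffs.append(float(v[i]))
                amps.append(float(rise))
                i += j + 1
                continue
        i += 1
    apd90 = np.nan
    if len(trace.beats):
        apd90 = float(trace.beats.iloc[-1]["apd90"])
    return EADReport(count=len(takeoffs), takeoff_vm=takeoffs,
                     amplitude=amps, apd90=apd90)


def ead_protocol(cell_type: str = "endo", cl: float = 4000.0,
                 ikr_block: float = 0.85, max_beats: int = 300,
                 freeze_ical_recovery: bool = False,
                 start_state: Optional[State] = None) -> EADReport:
    """Slow pacing with IKr block (Guo protocol): EAD count and morphology.

    ``freeze_ical_recovery`` prevents the L-type VDI gates from recovering
    during the AP (they may only inactivate), the in-silico analogue of the
    recovery-clamp used to prove the reactivation mechanism.
    """
    p = make_params(cell_type, block={"IKr": ikr_block} if ikr_block else None)
    res = steady_state_pace(p, cl, start_state=start_state,
                            max_beats=max_beats)
    # the recovery freeze acts on the measured beat only; the conditioning
    # pacing itself is unperturbed
    iv = None
    if freeze_ical_recovery:
        iv = Intervention(monotonic_gates=("ff", "fs", "fcaf", "fcas",
                                           "ffp", "fcafp", "jca"))
    tr, _ = run(res.state, PacingProtocol(cl=cl, n_beats=1), p,
                intervention=iv, record="v", rec_start=0.0, rec_dt=0.2)
    return detect_eads(tr)


# ---------------------------------------------------------------------------
# Alternans
# ---------------------------------------------------------------------------

def alternans_metrics(result: PacingResult) -> Dict[str, float]:
    """Beat-to-beat APD90 and peak-[Ca2+]i differences at steady state.

    For a 1:1 rhythm both deltas are ~0; a capture failure is reported as
    2:1 block instead of alternans.
    """
    b = result.beats
    if len(b) < 2:
        raise ValueError("need at least two consecutive beats")
    if result.capture_failure:
        return {"delta_apd90": np.nan, "delta_ca_peak": np.nan,
                "block_2to1": True}
    a = b["apd90"].to_numpy()[-2:]
    ca = b["cai_max"].to_numpy()[-2:]
    return {"delta_apd90": float(abs(a[1] - a[0])),
            "delta_ca_peak": float(abs(ca[1] - ca[0])),
            "block_2to1": False}


# ---------------------------------------------------------------------------
# Na+/Ca2+ rate dependence
# ---------------------------------------------------------------------------

def ca_transient_metrics(t: np.ndarray, cai: np.ndarray) -> CaTransientMetrics:
    """Peak/diastolic [Ca2+]i and single-exponential decay tau for one beat.

    The fit window runs from the Ca2+ peak to 90% completion of decay.
    """
    ipk = int(np.argmax(cai))
    peak = float(cai[ipk])
    dia = float(np.min(cai))
    target = peak - 0.9 * (peak - dia)
    seg = cai[ipk:]
    ts = t[ipk:] - t[ipk]
    below = np.nonzero(seg <= target)[0]
    iend = below[0] if below.size else seg.size - 1

    def f(x, a0, b0, tau0):
        return a0 + b0 * np.exp(-x / tau0)

    popt, _ = curve_fit(f, ts[:iend + 1], seg[:iend + 1],
                        p0=(dia, peak - dia, 50.0), maxfev=20000)
    return CaTransientMetrics(peak=peak, diastolic=dia, tau=float(popt[2]))


def ion_rate_dependence(cell_type: str = "endo",
                        frequencies: Sequence[float] = (0.25, 0.5, 1.0,
                                                        1.5, 2.0, 2.5),
                        max_beats: int = 1000,
                        schmidt_beats: int = 100) -> pd.DataFrame:
    """[Na+]i and peak-Ca2+ versus pacing frequency, plus Ca decay tau.

    [Na+]i is normalized to the 0.25 Hz value.  Peak [Ca2+]i is reported
    both after ~100 beats from the previous rate (the Schmidt fluorescence
    protocol) and at true steady state.  The decay tau per rate measures
    frequency-dependent acceleration of relaxation.
    """
    p = make_params(cell_type)
    state = None
    rows = []
    for f_hz in frequencies:
        cl = 1000.0 / f_hz
        # Schmidt protocol: ~100 beats from the preceding rate's steady state
        if state is not None:
            tr100, _ = run(state, PacingProtocol(cl=cl, n_beats=schmidt_beats),
                           p, record="none")
            ca_100 = float(tr100.beats.iloc[-1]["cai_max"])
        else:
            ca_100 = np.nan
        res = steady_state_pace(p, cl, start_state=state, max_beats=max_beats)
        state = res.state
        tr, _ = run(state, PacingProtocol(cl=cl, n_beats=1), p,
                    record="states", rec_start=0.0, rec_dt=0.5)
        cam = ca_transient_metrics(tr.t, tr.states["cai"].to_numpy())
        rows.append({"freq_hz": f_hz, "cl": cl, "nai": state["nai"],
                     "ca_peak_ss": cam.peak, "ca_peak_100": ca_100,
                     "ca_dia": cam.diastolic, "ca_tau": cam.tau})
    df = pd.DataFrame(rows)
    df["nai_norm"] = df["nai"] / df["nai"].iloc[0]
    return df


# ---------------------------------------------------------------------------
# Mechanism (clamp/reset) experiments
# ---------------------------------------------------------------------------

def prestimulus_values(state: State, names: Iterable[str]) -> Dict[str, float]:
    """Capture reference values (e.g. slow-rate gates) for reset rules."""
    return {n: state[n] for n in names}


def mechanism_experiment(intervention: Intervention,
                         protocol_kind: str = "rate",
                         cell_type: str = "endo",
                         cls: Sequence[float] = (2000, 1000, 700, 500, 300),
                         dis: Sequence[float] = (5, 20, 70, 200, 1000),
                         max_beats: int = 1000,
                         params: Optional[ModelParameters] = None,
                         ) -> pd.DataFrame:
    """Control vs intervention APD curves for the named clamp experiments.

    ``protocol_kind`` 'rate': steady-state APD90 vs CL with the
    intervention active throughout; 's1s2': restitution where the
    intervention acts from the S2 beat on (gate resets at S2 delivery).
    """
    p = params if params is not None else make_params(cell_type)
    if protocol_kind == "rate":
        rows = []
        for label, iv in (("control", None), ("intervention", intervention)):
            state = None
            for cl in cls:
                res = steady_state_pace(p, float(cl), start_state=state,
                                        max_beats=max_beats, intervention=iv)
                state = res.state
                rows.append({"arm": label, "cl": float(cl),
                             "apd90": float(res.beats.iloc[-1]["apd90"])})
        return (pd.DataFrame(rows)
                .pivot(index="cl", columns="arm", values="apd90")
                .reset_index())
    if protocol_kind == "s1s2":
        iv2 = Intervention(clamps=dict(intervention.clamps),
                           waveform=intervention.waveform,
                           gate_resets=dict(intervention.gate_resets),
                           reset_from_beat=1,
                           monotonic_gates=tuple(intervention.monotonic_gates))
        ctrl = s1s2_restitution(cell_type, dis=dis, params=p,
                                max_beats=max_beats)
        ss = steady_state_pace(p, 1000.0, max_beats=max_beats).state
        test = s1s2_restitution(cell_type, dis=dis, params=p, s1_state=ss,
                                intervention=iv2, max_beats=max_beats)
        out = ctrl.table[["di", "apd90"]].rename(columns={"apd90": "control"})
        out["intervention"] = test.table["apd90"].to_numpy()
        return out
    raise ValueError("protocol_kind must be 'rate' or 's1s2'")
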