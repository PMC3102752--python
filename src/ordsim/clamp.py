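"""Virtual voltage-clamp workbench for channel-kinetics protocols.

Vm is imposed; bath/pipette concentrations are held at configured values so
channel kinetics are isolated.  For the L-type current the subspace Ca2+
pool is dynamic by default, because calcium-dependent inactivation (CDI)
requires Ca2+ entry; ``freeze_n`` pins the CDI-mode fraction at zero, the
in-silico analogue of replacing Ca2+ with Ba2+ as charge carrier.

Protocols are piecewise-constant step families with placeholders: a
segment voltage ``"X"`` or duration ``"T"`` is filled per sweep from the
sweep list.  CaMK signalling is off by default (isolated-channel kinetics).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import constants as C
from . import _kernel as K
from .model import ModelParameters, make_params

__all__ = ["ClampProtocol", "SweepSet", "run_clamp", "frc",
           "steady_state_curves", "tail_iv", "recovery_double_pulse",
           "ap_clamp", "CLAMP_CURRENTS"]

CLAMP_CURRENTS = {
    "INa": K.C_INA, "INaL": K.C_INAL, "Ito": K.C_ITO, "ICaL": K.C_ICAL,
    "ICaNa": K.C_ICANA, "ICaK": K.C_ICAK, "IKr": K.C_IKR, "IKs": K.C_IKS,
    "IK1": K.C_IK1, "INaK": K.C_INAK, "INaCa_i": K.C_INACA_I,
}
# current -> conductance slot for difference-current (drug-subtraction) mode
_CUR_PARAM = {
    "INa": C.P_GNA, "INaL": C.P_GNAL, "Ito": C.P_GTO, "ICaL": C.P_PCA,
    "IKr": C.P_GKR, "IKs": C.P_GKS, "IK1": C.P_GK1,
}

_DEFAULT_CONC = {"nai": 7.0, "nass": 7.0, "ki": 145.0, "kss": 145.0,
                 "cai": 1.0e-4, "cass": 1.0e-4, "cansr": 1.2, "cajsr": 1.2}

Seg = Tuple[Union[float, str], Union[float, str]]


@dataclass
class ClampProtocol:
    """Step-protocol family: holding, ordered segments, sweep values.

    ``segments`` are (voltage mV | "X", duration ms | "T") pairs; each sweep
    substitutes its value for the placeholder.  ``equilibrate`` ms at the
    holding potential precede the segments (stands in for the interpulse
    interval of the wet protocol).
    """
    holding: float
    segments: Sequence[Seg]
    sweeps: Sequence[float]
    equilibrate: float = 5000.0

    def __post_init__(self):
        for v, d in self.segments:
            if not isinstance(d, str) and d <= 0:
                raise ValueError("segment durations must be positive")
        if self.equilibrate < 0:
            raise ValueError("equilibration time must be >= 0")

    def realize(self, sweep: float) -> Tuple[np.ndarray, np.ndarray]:
        """Segment (durations, voltages) arrays for one sweep value."""
        dur = [self.equilibrate]
        vv = [self.holding]
        for v, d in self.segments:
            vv.append(sweep if isinstance(v, str) else float(v))
            dur.append(sweep if isinstance(d, str) else float(d))
        return np.array(dur), np.array(vv)

    def to_json(self) -> str:
        return json.dumps({"holding": self.holding,
                           "segments": list(map(list, self.segments)),
                           "sweeps": list(self.sweeps),
                           "equilibrate": self.equilibrate})

    @classmethod
    def from_json(cls, s: str) -> "ClampProtocol":
        d = json.loads(s)
        return cls(d["holding"], [tuple(x) for x in d["segments"]],
                   d["sweeps"], d.get("equilibrate", 5000.0))


@dataclass
class SweepSet:
    """Per-sweep traces of one named current under a clamp protocol."""
    current: str
    sweeps: List[float]
    traces: List[pd.DataFrame]          # columns: t, v, i  (t=0 at protocol start)
    measure_start: List[float]          # onset time of the first placeholder/test segment
    protocol: Optional[ClampProtocol] = None

    def long(self) -> pd.DataFrame:
        out = []
        for s, tr in zip(self.sweeps, self.traces):
            d = tr.copy()
            d.insert(0, "sweep", s)
            out.append(d)
        return pd.concat(out, ignore_index=True)


def _clamp_state(concentrations: Optional[Mapping[str, float]]) -> np.ndarray:
    y = C.INITIAL_STATE.copy()
    conc = dict(_DEFAULT_CONC)
    if concentrations:
        conc.update(concentrations)
    for k, v in conc.items():
        y[C.STATE_INDEX[k]] = v
    return y


def run_clamp(current: str, protocol: ClampProtocol,
              params: Optional[ModelParameters] = None,
              freeze_n: bool = False, camk: bool = False,
              cass_dynamic: Optional[bool] = None,
              concentrations: Optional[Mapping[str, float]] = None,
              dt: float = 0.02, rec_dt: float = 0.1) -> SweepSet:
    """Run a step-protocol family, recording one named current per sweep."""
    if current not in CLAMP_CURRENTS:
        raise KeyError(f"unknown current {current!r}; "
                       f"expected one of {sorted(CLAMP_CURRENTS)}")
    p = params if params is not None else make_params("endo")
    if cass_dynamic is None:
        cass_dynamic = current in ("ICaL", "ICaNa", "ICaK")
    if cass_dynamic:
        dt = min(dt, 0.005)
    cidx = CLAMP_CURRENTS[current]
    traces, mstarts = [], []
    for sweep in protocol.sweeps:
        seg_dur, seg_v = protocol.realize(float(sweep))
        y = _clamp_state(concentrations)
        rt, rv, rc = K.run_vclamp(y, p.array, p.celltype_code, camk,
                                  seg_dur, seg_v, np.zeros(0), np.zeros(0),
                                  dt, rec_dt, cass_dynamic, freeze_n)
        traces.append(pd.DataFrame({"t": rt, "v": rv, "i": rc[:, cidx]}))
        mstarts.append(float(seg_dur[0]))
    return SweepSet(current=current, sweeps=[float(s) for s in protocol.sweeps],
                    traces=traces, measure_start=mstarts, protocol=protocol)


def _peak(tr: pd.DataFrame, t0: float, t1: Optional[float] = None
          ) -> Tuple[float, float]:
    """Signed extremum of the current in [t0, t1] and its time."""
    m = tr.t >= t0
    if t1 is not None:
        m &= tr.t <= t1
    seg = tr[m]
    if not len(seg):
        raise ValueError("empty measurement window")
    k = int(np.argmax(np.abs(seg.i.to_numpy())))
    return float(seg.i.iloc[k]), float(seg.t.iloc[k])


def frc(sweeps: SweepSet, times_after_peak: Sequence[float] = (5, 10, 15, 20,
                                                               25, 30, 35, 40,
                                                               45, 50, 55),
        ) -> pd.DataFrame:
    """Fractional remaining current FRC(t, V) = I(t_peak + t)/I_peak.

    Rows are sweep voltages, columns the offsets (ms) after peak current.
    Sweeps without a detectable peak are excluded with a warning.
    """
    rows = {}
    for s, tr, t0 in zip(sweeps.sweeps, sweeps.traces, sweeps.measure_start):
        ipk, tpk = _peak(tr, t0)
        if abs(ipk) < 1e-6:
            warnings.warn(f"sweep {s} mV has no measurable peak; excluded")
            continue
        t = tr.t.to_numpy()
        i = tr.i.to_numpy()
        rows[s] = [float(np.interp(tpk + dt_, t, i) / ipk)
                   for dt_ in times_after_peak]
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=list(times_after_peak))
    out.index.name = "v_mV"
    return out


# default kinetics-validation protocols per current
_ACT_PROTOCOLS: Dict[str, ClampProtocol] = {
    "ICaL": ClampProtocol(-60.0, [("X", 75.0)], np.arange(-40.0, 51.0, 10.0)),
    "Ito": ClampProtocol(-90.0, [("X", 300.0)], np.arange(-30.0, 61.0, 10.0)),
    "INa": ClampProtocol(-120.0, [("X", 40.0)], np.arange(-75.0, 21.0, 5.0)),
    "INaL": ClampProtocol(-120.0, [("X", 500.0)], np.arange(-70.0, 31.0, 10.0)),
}
_INACT_PROTOCOLS: Dict[str, ClampProtocol] = {
    "Ito": ClampProtocol(-90.0, [("X", 500.0), (50.0, 300.0)],
                         np.arange(-110.0, 1.0, 10.0)),
    "INa": ClampProtocol(-120.0, [("X", 1000.0), (-20.0, 40.0)],
                         np.arange(-140.0, -39.0, 5.0)),
    "INaL": ClampProtocol(-120.0, [("X", 1000.0), (-30.0, 500.0)],
                          np.arange(-140.0, -29.0, 10.0)),
    "ICaL": ClampProtocol(-60.0, [("X", 1000.0), (10.0, 75.0)],
                          np.arange(-80.0, 11.0, 10.0)),
}


def steady_state_curves(current: str, kind: str = "activation",
                        protocol: Optional[ClampProtocol] = None,
                        reversal: Optional[float] = None,
                        **clamp_kw) -> pd.DataFrame:
    """Protocol-extracted normalized activation/inactivation curve.

    Activation: peak test current divided by driving force (when a
    reversal potential applies), normalized to its maximum.  Inactivation:
    normalized peak current of a fixed test pulse after conditioning steps.
    """
    if kind == "activation":
        proto = protocol or _ACT_PROTOCOLS[current]
        ss = run_clamp(current, proto, **clamp_kw)
        vals = []
        for s, tr, t0 in zip(ss.sweeps, ss.traces, ss.measure_start):
            ipk, _ = _peak(tr, t0)
            if reversal is not None:
                drive = s - reversal
                vals.append(ipk / drive if abs(drive) > 1e-9 else np.nan)
            else:
                vals.append(abs(ipk))
        vals = np.array(vals, float)
        vals = vals / np.nanmax(np.abs(vals))
        return pd.DataFrame({"v": ss.sweeps, "norm": np.abs(vals)})
    if kind == "inactivation":
        proto = protocol or _INACT_PROTOCOLS[current]
        ss = run_clamp(current, proto, **clamp_kw)
        vals = []
        for s, tr, t0 in zip(ss.sweeps, ss.traces, ss.measure_start):
            # peak during the fixed test pulse (after the conditioning step)
            test_start = t0 + (proto.realize(s)[0][1])
            ipk, _ = _peak(tr, test_start)
            vals.append(abs(ipk))
        vals = np.array(vals, float)
        return pd.DataFrame({"v": ss.sweeps, "norm": vals / np.nanmax(vals)})
    raise ValueError("kind must be 'activation' or 'inactivation'")


def tail_iv(current: str,
            protocol: Optional[ClampProtocol] = None,
            **clamp_kw) -> pd.DataFrame:
    """Normalized peak tail current per conditioning voltage.

    Default protocol is the IKr family: 1000 ms conditioning steps from
    -40 mV holding, tail at -40 mV.
    """
    proto = protocol or ClampProtocol(
        -40.0, [("X", 1000.0), (-40.0, 3000.0)],
        np.arange(-40.0, 41.0, 10.0))
    ss = run_clamp(current, proto, **clamp_kw)
    vals = []
    for s, tr, t0 in zip(ss.sweeps, ss.traces, ss.measure_start):
        cond_dur = proto.realize(s)[0][1]
        ipk, _ = _peak(tr, t0 + cond_dur)   # tail segment
        vals.append(abs(ipk))
    vals = np.array(vals, float)
    mx = np.nanmax(vals)
    return pd.DataFrame({"v": ss.sweeps,
                         "tail_norm": vals / (mx if mx > 0 else 1.0)})


def recovery_double_pulse(current: str,
                          intervals: Sequence[float] = (1, 2, 5, 10, 20, 50,
                                                        100, 200, 500, 1000,
                                                        2000, 5000),
                          holding: float = -90.0, pulse_v: float = 50.0,
                          pulse_dur: float = 200.0,
                          **clamp_kw) -> pd.DataFrame:
    """P2/P1 peak ratio versus interpulse interval (recovery from
    inactivation); defaults follow the Ito double-pulse protocol."""
    proto = ClampProtocol(
        holding, [(pulse_v, pulse_dur), (holding, "T"),
                  (pulse_v, pulse_dur)], list(intervals))
    ss = run_clamp(current, proto, **clamp_kw)
    rows = []
    for s, tr, t0 in zip(ss.sweeps, ss.traces, ss.measure_start):
        p1, _ = _peak(tr, t0, t0 + pulse_dur)
        t2 = t0 + pulse_dur + s
        p2, _ = _peak(tr, t2, t2 + pulse_dur)
        rows.append({"interval": s, "ratio": p2 / p1 if p1 != 0 else np.nan})
    return pd.DataFrame(rows)


def ap_clamp(current: str, waveform: Tuple[np.ndarray, np.ndarray],
             block_fraction: float = 1.0,
             params: Optional[ModelParameters] = None,
             camk: bool = False,
             concentrations: Optional[Mapping[str, float]] = None,
             dt: float = 0.01, rec_dt: float = 0.1) -> pd.DataFrame:
    """Current elicited by an imposed AP waveform (difference-current form).

    Returns the named current under the waveform minus the same run with
    the channel's conductance scaled by (1 - block_fraction); with the
    default full block this is simply the clean simulated current, matching
    the drug-subtraction convention of the wet experiments.
    """
    if current not in CLAMP_CURRENTS:
        raise KeyError(f"unknown current {current!r}")
    t, v = (np.asarray(waveform[0], float), np.asarray(waveform[1], float))
    if t.ndim != 1 or t.shape != v.shape or t.size < 2:
        raise ValueError("waveform needs matching 1D time/voltage arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("waveform time must be strictly increasing")
    p = params if params is not None else make_params("endo")
    if not 0.0 <= block_fraction <= 1.0:
        raise ValueError("block fraction must be in [0,1]")
    cidx = CLAMP_CURRENTS[current]
    cass_dyn = current in ("ICaL", "ICaNa", "ICaK")

    def _one(par):
        y = _clamp_state(concentrations)
        y[0] = v[0]
        rt, rv, rc = K.run_vclamp(y, par.array, par.celltype_code, camk,
                                  np.zeros(1) + 1.0, np.zeros(1) + v[0],
                                  t, v, dt, rec_dt, cass_dyn, False)
        return rt, rv, rc[:, cidx]

    rt, rv, i_full = _one(p)
    if block_fraction >= 1.0:
        i_blk = np.zeros_like(i_full)
    else:
        pb = p.copy()
        if current not in _CUR_PARAM:
            raise KeyError(f"no conductance mapping for {current!r}")
        pb.array[_CUR_PARAM[current]] *= (1.0 - block_fraction)
        _, _, i_blk = _one(pb)
    return pd.DataFrame({"t": rt, "v": rv, "i": i_full - i_blk})
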