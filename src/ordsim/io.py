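"""Configuration schema, artifact serialization, and reference fixtures.

A RunConfig (YAML/JSON, schema-validated with unknown keys rejected) names
a protocol and its parameters; ``run_from_config`` executes it and writes
tidy CSV outputs plus a JSON summary stamped with the config hash, so any
run is reproducible from its emitted config copy.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import constants as C
from .integrator import PacingProtocol, Trace, run, steady_state_pace
from .model import State, make_params
from . import protocols as P
from .fiber import Cable, conduction_velocity, pseudo_ecg, simulate_cable, \
    transmural_wedge

log = logging.getLogger("ordsim")

__all__ = ["RunConfig", "run_from_config", "load_config", "config_hash",
           "write_trace_csv", "regenerate_fixtures", "verify_fixtures",
           "fixtures_path", "load_fixtures"]

_PROTOCOLS = ("simulate", "rate-dependence", "restitution",
              "dynamic-restitution", "accommodation", "ead", "alternans",
              "fiber-cv", "ecg")


class RunConfig(BaseModel):
    """Schema-validated run description (unknown keys rejected)."""
    model_config = ConfigDict(extra="forbid")

    protocol: Literal["simulate", "rate-dependence", "restitution",
                      "dynamic-restitution", "accommodation", "ead",
                      "alternans", "fiber-cv", "ecg"]
    cell_type: Literal["endo", "epi", "M"] = "endo"
    camk: bool = True
    cl: float = 1000.0
    n_beats: int = 10
    cls: Optional[List[float]] = None
    dis: Optional[List[float]] = None
    cl_from: float = 750.0
    cl_to: float = 480.0
    duration_s: float = 900.0
    ikr_block: float = 0.85
    max_beats: int = 1000
    block: Dict[str, float] = Field(default_factory=dict)
    overrides: Dict[str, Dict[str, float]] = Field(default_factory=dict)
    stim_amplitude: float = C.STIM_AMP
    stim_duration: float = C.STIM_DUR
    record: Literal["none", "v", "currents", "states"] = "v"
    n_cells: int = 100
    out_dir: str = "."


def load_config(path: str | Path) -> RunConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_trace_csv(trace: Trace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.10g")


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_from_config(config: RunConfig) -> Dict[str, object]:
    """Execute the named protocol; write CSV/JSON artifacts; return summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config_hash(config)
    params = make_params(config.cell_type, camk=config.camk,
                         block=config.block or None,
                         overrides=config.overrides or None)
    summary: Dict[str, object] = {"protocol": config.protocol,
                                  "config_hash": h}

    if config.protocol == "simulate":
        proto = PacingProtocol(cl=config.cl, n_beats=config.n_beats,
                               stim_amp=config.stim_amplitude,
                               stim_dur=config.stim_duration)
        trace, final = run(State(C.INITIAL_STATE, camk=config.camk), proto,
                           params, record=config.record)
        write_trace_csv(trace, out / "trace.csv")
        _write(trace.beats, out / "beats.csv")
        b = trace.beats.iloc[-1]
        summary.update(apd90=float(b.apd90), v_rest=float(b.v_rest),
                       dvdt_max=float(b.dvdt_max), nai=final["nai"])
        for i, row in trace.beats.iterrows():
            log.info("beat %3d  APD90=%7.2f ms  Vmax=%6.1f mV",
                     i, row.apd90, row.v_max)
    elif config.protocol == "rate-dependence":
        cls = config.cls or [2000, 1500, 1000, 700, 500, 400, 300]
        df = P.rate_dependence(config.cell_type, cls, block=config.block or
                               None, camk=config.camk,
                               max_beats=config.max_beats)
        _write(df, out / "rate_dependence.csv")
        summary["apd90_by_cl"] = dict(zip(df.cl, df.apd90))
    elif config.protocol == "restitution":
        curve = P.s1s2_restitution(config.cell_type, s1_cl=config.cl,
                                   dis=config.dis or (5, 10, 20, 40, 70, 100,
                                                      150, 200, 300, 500,
                                                      1000),
                                   block=config.block or None,
                                   max_beats=config.max_beats)
        _write(curve.table, out / "s1s2_restitution.csv")
        summary["apd90_by_di"] = dict(zip(curve.table.di, curve.table.apd90))
    elif config.protocol == "dynamic-restitution":
        kw = {"cls": config.cls} if config.cls else {}
        curve = P.dynamic_restitution(config.cell_type, **kw)
        _write(curve.table, out / "dynamic_restitution.csv")
        bif = curve.table[curve.table.alternans]
        summary["max_bifurcation_di"] = (float(bif.di.max())
                                         if len(bif) else None)
    elif config.protocol == "accommodation":
        course, tau, _ = P.accommodation(config.cell_type, config.cl_from,
                                         config.cl_to, config.duration_s,
                                         max_beats=config.max_beats)
        _write(course, out / "accommodation.csv")
        summary["tau_s"] = float(tau)
    elif config.protocol == "ead":
        rep = P.ead_protocol(config.cell_type, cl=config.cl or 4000.0,
                             ikr_block=config.ikr_block,
                             max_beats=config.max_beats)
        summary.update(ead_count=rep.count, takeoff_vm=rep.takeoff_vm,
                       amplitude=rep.amplitude, apd90=rep.apd90)
    elif config.protocol == "alternans":
        res = steady_state_pace(params, config.cl,
                                max_beats=config.max_beats)
        m = P.alternans_metrics(res)
        _write(res.beats, out / "beats.csv")
        summary.update(m)
    elif config.protocol in ("fiber-cv", "ecg"):
        if config.protocol == "fiber-cv":
            cable = Cable(["endo"] * config.n_cells)
        else:
            cable = transmural_wedge()
        proto = PacingProtocol(cl=config.cl, n_beats=config.n_beats,
                               stim_dur=C.FIBER_STIM_DUR)
        res = simulate_cable(cable, proto, rec_dt=1.0)
        np.savetxt(out / "vm_space_time.csv.gz",
                   np.column_stack([res.t, res.vm]), delimiter=",")
        if config.protocol == "fiber-cv":
            n = cable.n
            summary["cv_cm_s"] = conduction_velocity(
                res, (int(0.3 * n), int(0.7 * n)))
        else:
            ecg = pseudo_ecg(res)
            _write(pd.DataFrame({"t": ecg.t, "phi": ecg.phi}),
                   out / "pseudo_ecg.csv")
            summary["t_wave_amplitude"] = ecg.t_wave_amplitude
            summary["t_wave_upright"] = ecg.t_wave_upright

    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=float))
    (out / "config.json").write_text(
        json.dumps(config.model_dump(), indent=2))
    return summary


# ---------------------------------------------------------------------------
# Reference fixtures
# ---------------------------------------------------------------------------

def fixtures_path() -> Path:
    return Path(__file__).parent / "data" / "fixtures.json"


def load_fixtures() -> Dict[str, dict]:
    return json.loads(fixtures_path().read_text())


def regenerate_fixtures(max_beats: int = 1000) -> Dict[str, dict]:
    """Recompute the stored reference steady states and headline metrics."""
    fx: Dict[str, dict] = {}
    p = make_params("endo")
    res = steady_state_pace(p, 1000.0, max_beats=max_beats)
    b = res.beats.iloc[-1]
    fx["endo_ss_cl1000"] = {
        "state": list(res.state.values),
        "metrics": {"apd90": float(b.apd90), "nai": res.state["nai"],
                    "dvdt_max": float(b.dvdt_max)},
        "meta": {"max_beats": max_beats, "tol": 1e-6,
                 "dt": [C.DT_FAST, C.DT_MID, C.DT_SLOW]},
    }
    off = make_params("endo", camk=False)
    res_off = steady_state_pace(off, 1000.0, max_beats=max_beats)
    st_off = res_off.state
    st_off.camk = False
    fx["endo_ss_cl1000_camk_off"] = {
        "state": list(st_off.values),
        "metrics": {"apd90": float(res_off.beats.iloc[-1].apd90),
                    "n_state_vars": len(st_off)},
        "meta": {"max_beats": max_beats},
    }
    return fx


def verify_fixtures(tol: float = 1e-6) -> List[str]:
    """Recompute fixtures and report names drifting beyond tolerance."""
    stored = load_fixtures()
    fresh = regenerate_fixtures()
    bad = []
    for name, ref in stored.items():
        if name not in fresh:
            bad.append(name)
            continue
        a = np.array(ref["state"])
        b = np.array(fresh[name]["state"])
        if np.max(np.abs(a - b) / (np.abs(a) + 1e-8)) > tol:
            bad.append(name)
    return bad
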