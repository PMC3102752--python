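"""Public surface of the single-cell model: state, parameters, currents.

The model is the ORd undiseased human ventricular myocyte: 41 ODE state
variables (31 with CaMK signalling disabled) describing membrane voltage,
Hodgkin-Huxley gates for nine reformulated currents, four-compartment ion
concentrations, CaMK trapping, and ryanodine-receptor release flux states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np

from . import constants as C
from . import _kernel as K

__all__ = [
    "CELL_TYPES", "State", "ModelParameters", "CurrentsSnapshot",
    "initial_state", "compute_currents", "derivatives", "camk_active",
    "phospho_mix", "gate_weighted", "apply_cell_type", "apply_drug",
    "gate_kinetics",
]

CELL_TYPES = ("endo", "epi", "M")
_CELLTYPE_CODE = {"endo": C.CELLTYPE_ENDO, "epi": C.CELLTYPE_EPI,
                  "M": C.CELLTYPE_M}

# drug-block targets -> parameter slot
_BLOCK_TARGETS = {
    "IKr": C.P_GKR, "IKs": C.P_GKS, "ICaL": C.P_PCA,
    "IK1": C.P_GK1, "Jrel": C.P_JREL, "INaL": C.P_GNAL,
}

# symbol-name overrides accepted from configuration files
_SYMBOLS = {
    "GNa": C.P_GNA, "GNaL": C.P_GNAL, "Gto": C.P_GTO, "PCa": C.P_PCA,
    "GKr": C.P_GKR, "GKs": C.P_GKS, "GK1": C.P_GK1, "Gncx": C.P_GNCX,
    "Pnak": C.P_PNAK, "GKb": C.P_GKB, "PNab": C.P_PNAB, "PCab": C.P_PCAB,
    "GpCa": C.P_GPCA, "Jrel": C.P_JREL, "Jup": C.P_JUP,
    "cmdnmax": C.P_CMDN, "nao": C.P_NAO, "cao": C.P_CAO, "ko": C.P_KO,
}

_CAMK_IDX = np.array(sorted(C.STATE_INDEX[n] for n in C.CAMK_STATE_NAMES))
_NON_CAMK_NAMES = tuple(n for n in C.STATE_NAMES
                        if n not in C.CAMK_STATE_NAMES)


def _check_cell_type(cell_type: str) -> int:
    if cell_type not in _CELLTYPE_CODE:
        raise ValueError(
            f"unknown cell type {cell_type!r}; expected one of {CELL_TYPES}")
    return _CELLTYPE_CODE[cell_type]


class State:
    """Model state: Vm, gates, concentrations, CaMK and release states.

    Internally always stores the full 41-vector; with ``camk=False`` the
    public view (names/len/as_dict) is the 31-variable system and the
    phosphorylated-pathway entries are inert.
    """

    __slots__ = ("values", "camk")

    def __init__(self, values: np.ndarray, camk: bool = True):
        values = np.asarray(values, dtype=float)
        if values.shape != (C.N_STATE,):
            raise ValueError(f"state must have {C.N_STATE} entries")
        self.values = values.copy()
        self.camk = bool(camk)

    @property
    def names(self):
        return C.STATE_NAMES if self.camk else _NON_CAMK_NAMES

    def __len__(self):
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[C.STATE_INDEX[name]])

    def __setitem__(self, name: str, value: float) -> None:
        self.values[C.STATE_INDEX[name]] = value

    @property
    def v(self) -> float:
        return float(self.values[0])

    def copy(self) -> "State":
        return State(self.values, self.camk)

    def as_dict(self) -> Dict[str, float]:
        return {n: self[n] for n in self.names}

    def validate(self) -> None:
        """Raise if gates leave [0,1] or concentrations are not positive."""
        vals = self.values
        gates = vals[C.GATE_SLICE.start:C.STATE_INDEX["Jrelnp"]]
        if np.any(gates < -1e-12) or np.any(gates > 1.0 + 1e-12):
            bad = np.argmax((gates < -1e-12) | (gates > 1 + 1e-12))
            name = C.STATE_NAMES[C.GATE_SLICE.start + int(bad)]
            raise ValueError(f"gate {name} outside [0,1]: {gates[bad]}")
        conc = vals[1:9]
        if np.any(conc <= 0):
            name = C.STATE_NAMES[1 + int(np.argmax(conc <= 0))]
            raise ValueError(f"concentration {name} not positive")
        jrel = vals[C.STATE_INDEX["Jrelnp"]:C.STATE_INDEX["Jrelp"] + 1]
        if np.any(jrel < -1e-12):
            raise ValueError("release flux state negative")
        camkt = vals[C.STATE_INDEX["CaMKt"]]
        if not (-1e-12 <= camkt <= 1 + 1e-12):
            raise ValueError("CaMKt outside [0,1]")


@dataclass
class ModelParameters:
    """Maximal conductances/permeabilities plus flux and buffer scales.

    ``array`` is the flat parameter vector consumed by the kernel (see
    ``constants`` for slot names); ``cell_type`` records which transmural
    scaling has been applied; ``camk`` toggles CaMK signalling.
    """

    array: np.ndarray = field(
        default_factory=lambda: C.BASE_PARAMS.copy())
    cell_type: str = "endo"
    camk: bool = True

    def __post_init__(self):
        self.array = np.asarray(self.array, dtype=float).copy()
        if self.array.shape != (C.N_PARAM,):
            raise ValueError("bad parameter vector length")
        if np.any(self.array[:C.P_JREL] < 0):
            raise ValueError("conductances must be non-negative")
        _check_cell_type(self.cell_type)

    @property
    def celltype_code(self) -> int:
        return _CELLTYPE_CODE[self.cell_type]

    def copy(self) -> "ModelParameters":
        return ModelParameters(self.array, self.cell_type, self.camk)

    def get(self, symbol: str) -> float:
        return float(self.array[_SYMBOLS[symbol]])

    def with_overrides(self, overrides: Mapping[str, Mapping[str, float]]
                       ) -> "ModelParameters":
        """Apply config-style overrides: symbol -> {scale: x} or {value: x}."""
        out = self.copy()
        for sym, spec in overrides.items():
            if sym not in _SYMBOLS:
                raise KeyError(f"unknown parameter symbol {sym!r}")
            if "scale" in spec:
                out.array[_SYMBOLS[sym]] *= float(spec["scale"])
            elif "value" in spec:
                out.array[_SYMBOLS[sym]] = float(spec["value"])
            else:
                raise ValueError(f"override for {sym!r} needs scale or value")
        return out


_CUR_FIELDS = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "INab", "ICab", "IKb", "IpCa", "Istim",
    "Jrel", "Jup", "Jtr", "Jdiff_Na", "Jdiff_Ca", "Jdiff_K", "Jleak",
    "CaMKa",
)


@dataclass(frozen=True)
class CurrentsSnapshot:
    """Instantaneous membrane currents (uA/uF) and SR/diffusion fluxes (mM/ms)."""
    INa: float
    INaL: float
    Ito: float
    ICaL: float
    ICaNa: float
    ICaK: float
    IKr: float
    IKs: float
    IK1: float
    INaCa_i: float
    INaCa_ss: float
    INaK: float
    INab: float
    ICab: float
    IKb: float
    IpCa: float
    Istim: float
    Jrel: float
    Jup: float
    Jtr: float
    Jdiff_Na: float
    Jdiff_Ca: float
    Jdiff_K: float
    Jleak: float
    CaMKa: float

    def total_membrane_current(self) -> float:
        return (self.INa + self.INaL + self.Ito + self.ICaL + self.ICaNa
                + self.ICaK + self.IKr + self.IKs + self.IK1 + self.INaCa_i
                + self.INaCa_ss + self.INaK + self.INab + self.ICab
                + self.IKb + self.IpCa + self.Istim)

    def as_dict(self) -> Dict[str, float]:
        return {f: getattr(self, f) for f in _CUR_FIELDS}


def initial_state(cell_type: str, camk: bool = True) -> State:
    """Documented resting initial conditions (identical across cell types)."""
    _check_cell_type(cell_type)
    return State(C.INITIAL_STATE, camk=camk)


def _eval(state: State, params: ModelParameters, i_stim: float = 0.0):
    cur = np.zeros(K.N_CUR)
    ginf = np.zeros(31)
    gtau = np.zeros(31)
    dy = np.zeros(C.N_STATE)
    K.compute_rhs(state.values, params.array, params.celltype_code,
                  params.camk and state.camk, float(i_stim),
                  cur, ginf, gtau, dy)
    return cur, ginf, gtau, dy


def compute_currents(state: State, params: ModelParameters,
                     i_stim: float = 0.0) -> CurrentsSnapshot:
    """Evaluate all membrane currents and intracellular fluxes."""
    cur, _, _, _ = _eval(state, params, i_stim)
    if not np.all(np.isfinite(cur)):
        bad = _CUR_FIELDS[int(np.argmax(~np.isfinite(cur)))]
        raise FloatingPointError(f"non-finite current: {bad}")
    return CurrentsSnapshot(*cur)


def derivatives(state: State, params: ModelParameters,
                i_stim: float = 0.0) -> np.ndarray:
    """Full time derivative of the 41-vector (phospho entries inert w/o CaMK)."""
    cur, _, _, dy = _eval(state, params, i_stim)
    if not np.all(np.isfinite(cur)):
        bad = _CUR_FIELDS[int(np.argmax(~np.isfinite(cur)))]
        raise FloatingPointError(f"non-finite current: {bad}")
    if not params.camk or not state.camk:
        dy[_CAMK_IDX] = 0.0
    return dy


def gate_kinetics(state: State, params: ModelParameters):
    """Gate steady states and time constants at the state's voltage.

    Returns (names, g_inf, tau) for the 31 first-order gate-type variables.
    """
    _, ginf, gtau, _ = _eval(state, params)
    names = C.STATE_NAMES[C.GATE_SLICE]
    return names, ginf, gtau


@dataclass(frozen=True)
class CaMKState:
    """Trapped CaMK fraction (CaMKt); active fraction is derived."""
    camkt: float


def camk_active(camk: CaMKState, ca_ss: float,
                params: Optional[ModelParameters] = None) -> float:
    """Active CaMK fraction: Ca2+/CaM-bound plus trapped subunits.

    CaMKa = CaMKo*(1-CaMKt)/(1+KmCaM/[Ca2+]ss) + CaMKt; monotone in Ca2+.
    """
    if ca_ss <= 0:
        raise ValueError("subspace Ca2+ must be positive")
    camkt = camk.camkt if isinstance(camk, CaMKState) else float(camk)
    if not 0.0 <= camkt <= 1.0:
        raise ValueError("CaMKt must lie in [0,1]")
    bound = C.CAMK_O * (1.0 - camkt) / (1.0 + C.KM_CAM / ca_ss)
    return bound + camkt


def phospho_mix(value_nonphos: float, value_phos: float,
                phos_fraction: float) -> float:
    """Population mix of fully phosphorylated and unaffected channels."""
    if not 0.0 <= phos_fraction <= 1.0:
        raise ValueError("phosphorylated fraction must lie in [0,1]")
    return phos_fraction * value_phos + (1.0 - phos_fraction) * value_nonphos


def gate_weighted(fast_gate: float, slow_gate: float,
                  weight_fast: float) -> float:
    """Weighted sum (never a product) of fast and slow gating processes."""
    for name, x in (("fast gate", fast_gate), ("slow gate", slow_gate),
                    ("fast weight", weight_fast)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {x}")
    return weight_fast * fast_gate + (1.0 - weight_fast) * slow_gate


def apply_cell_type(params: ModelParameters, cell_type: str) -> ModelParameters:
    """Derive epi/M parameters from the endo baseline (endo is identity)."""
    code = _check_cell_type(cell_type)
    if params.cell_type != "endo":
        raise ValueError("cell-type scaling starts from the endo baseline")
    out = params.copy()
    out.cell_type = cell_type
    for idx, scale in C.CELLTYPE_SCALING.get(code, {}).items():
        out.array[idx] *= scale
    return out


def apply_drug(params: ModelParameters,
               block: Optional[Mapping[str, float]]) -> ModelParameters:
    """Scale targeted conductances/fluxes by (1 - blocked fraction)."""
    out = params.copy()
    if not block:
        return out
    for target, frac in block.items():
        if target not in _BLOCK_TARGETS:
            raise KeyError(f"unknown drug-block target {target!r}; "
                           f"expected one of {sorted(_BLOCK_TARGETS)}")
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"blocked fraction for {target} must be in [0,1]")
        out.array[_BLOCK_TARGETS[target]] *= (1.0 - frac)
    return out


def make_params(cell_type: str = "endo", camk: bool = True,
                block: Optional[Mapping[str, float]] = None,
                overrides: Optional[Mapping[str, Mapping[str, float]]] = None,
                ) -> ModelParameters:
    """Convenience constructor: baseline -> cell type -> drug block -> overrides."""
    p = ModelParameters(camk=camk)
    p = apply_cell_type(p, cell_type)
    p = apply_drug(p, block)
    if overrides:
        p = p.with_overrides(overrides)
    p.camk = camk
    return p
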