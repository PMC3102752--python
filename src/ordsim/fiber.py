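"""1D multicellular strand: conduction velocity and transmural pseudo-ECG.

Monodomain cable with one grid node per cell (dx = cell length, 0.01 cm),
no-flux boundaries, explicit operator splitting: the full single-cell
reaction step followed by a diffusion step on Vm.  The diffusion
coefficient was tuned once so that a homogeneous endocardial strand
conducts at 45 cm/s during steady 1 Hz pacing, then frozen.

The transmural wedge follows the published layout: cells 1-60 endo,
61-105 M, 106-165 epi, stimulated at the endo end; the unipolar
pseudo-ECG is the distance-weighted integral of the spatial voltage
gradient evaluated 2 cm beyond the epi end, with 15 cells at each end
excluded from the gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from . import constants as C
from . import _kernel as K
from .integrator import PacingProtocol
from .model import ModelParameters

__all__ = ["Cable", "EcgTrace", "transmural_wedge", "simulate_cable",
           "conduction_velocity", "pseudo_ecg"]

_CT_CODE = {"endo": 0, "epi": 1, "M": 2}


@dataclass
class Cable:
    """Strand geometry: per-cell types, coupling, stimulus site."""
    cell_types: Sequence[str]
    diffusion: float = C.FIBER_DIFF       # cm^2/ms
    dx: float = C.FIBER_DX                # cm
    stim_cells: Sequence[int] = (0, 1, 2)

    def __post_init__(self):
        if len(self.cell_types) < 2:
            raise ValueError("cable needs at least 2 cells")
        if self.diffusion <= 0 or self.dx <= 0:
            raise ValueError("coupling and spatial step must be positive")
        for ct in self.cell_types:
            if ct not in _CT_CODE:
                raise ValueError(f"unknown cell type {ct!r}")
        for i in self.stim_cells:
            if not 0 <= i < len(self.cell_types):
                raise ValueError("stimulated cell outside the cable")

    @property
    def n(self) -> int:
        return len(self.cell_types)

    def type_codes(self) -> np.ndarray:
        return np.array([_CT_CODE[c] for c in self.cell_types], dtype=np.int64)


def transmural_wedge(n_endo: int = 60, n_m: int = 45, n_epi: int = 60,
                     **kw) -> Cable:
    """Published wedge layout (endo 1-60, M 61-105, epi 106-165)."""
    return Cable(["endo"] * n_endo + ["M"] * n_m + ["epi"] * n_epi, **kw)


@dataclass
class FiberResult:
    t: np.ndarray                 # ms
    vm: np.ndarray                # (n_samples, n_cells)
    act_time: np.ndarray          # per-cell time of max dVm/dt in window, ms
    act_dvdt: np.ndarray          # per-cell max dVm/dt, mV/ms
    cable: Cable = None
    stim_times: np.ndarray = None


def simulate_cable(cable: Cable, protocol: PacingProtocol,
                   params: Optional[ModelParameters] = None,
                   initial_states: Optional[np.ndarray] = None,
                   rec_dt: float = 0.5,
                   act_window: Optional[Tuple[float, float]] = None,
                   camk: bool = True) -> FiberResult:
    """Run the monodomain strand; returns the space-time Vm array.

    ``initial_states`` is an (n_cells, 41) array (e.g. single-cell steady
    states at the pacing CL); by default all cells start from the resting
    initial conditions.  ``act_window`` restricts the per-cell activation
    measurement (defaults to the final beat).
    """
    n = cable.n
    base = params if params is not None else ModelParameters()
    if base.cell_type != "endo":
        raise ValueError("pass the endo baseline; cell types scale per cell")
    P3 = np.vstack([_scaled(base, ct) for ct in ("endo", "epi", "M")])
    if initial_states is None:
        Y = np.tile(C.INITIAL_STATE, (n, 1))
    else:
        Y = np.asarray(initial_states, float).copy()
        if Y.shape != (n, C.N_STATE):
            raise ValueError("initial_states must be (n_cells, 41)")
    stim_times = protocol.stim_times()
    t_end = protocol.t_end()
    if act_window is None:
        act_window = (float(stim_times[-1]) if stim_times.size else 0.0,
                      t_end)
    status, rec_t, rec_V, act_dvdt, act_time = K.run_fiber(
        Y, P3, cable.type_codes(), camk, cable.diffusion, cable.dx,
        np.asarray(cable.stim_cells, dtype=np.int64), stim_times,
        protocol.stim_amp, protocol.stim_dur, t_end,
        C.DT_FAST, C.DT_MID, C.DT_SLOW, C.THR_FAST,
        rec_dt, act_window[0], act_window[1])
    if status != 0:
        raise FloatingPointError(
            f"fiber simulation became non-finite (dt={C.DT_FAST}, "
            f"dx={cable.dx}); refine the discretization")
    return FiberResult(t=rec_t, vm=rec_V, act_time=act_time,
                       act_dvdt=act_dvdt, cable=cable, stim_times=stim_times)


def _scaled(base: ModelParameters, ct: str) -> np.ndarray:
    arr = base.array.copy()
    for idx, s in C.CELLTYPE_SCALING.get(_CT_CODE[ct], {}).items():
        arr[idx] *= s
    return arr


def conduction_velocity(result: FiberResult, cells: Tuple[int, int]) -> float:
    """CV (cm/s) from activation-time difference between two interior cells."""
    i, j = cells
    if i == j:
        raise ValueError("need two distinct cells")
    for k in (i, j):
        if result.act_dvdt[k] < 10.0:
            raise ValueError(f"cell {k} did not activate")
    dt_ms = result.act_time[j] - result.act_time[i]
    if dt_ms == 0:
        raise ValueError("zero activation-time difference")
    dist_cm = abs(j - i) * result.cable.dx
    return abs(dist_cm / dt_ms) * 1000.0


@dataclass
class EcgTrace:
    """Unipolar pseudo-ECG at an axial electrode beyond the epi end."""
    t: np.ndarray
    phi: np.ndarray
    t_wave_amplitude: float = np.nan   # signed; >0 means upright

    @property
    def t_wave_upright(self) -> bool:
        return self.t_wave_amplitude > 0


def pseudo_ecg(result: FiberResult, electrode_distance: float = 2.0,
               edge_exclusion: int = 15,
               t_wave_window: Optional[Tuple[float, float]] = None,
               ) -> EcgTrace:
    """Distance-weighted integral of the Vm gradient at an axial electrode.

    phi(t) ~ -sum dV/dx * d(1/r)/dx * dx over interior cells, electrode on
    the fiber axis ``electrode_distance`` cm beyond the last (epi) cell.
    The T wave is the dominant deflection of the late (repolarization)
    portion of the final beat.
    """
    vm = result.vm
    n = vm.shape[1]
    dx = result.cable.dx
    lo = edge_exclusion
    hi = n - edge_exclusion
    if hi - lo < 2:
        raise ValueError("edge exclusion leaves too few cells")
    # positions of cell centres; electrode beyond the last cell
    x = (np.arange(n) + 0.5) * dx
    xe = n * dx + electrode_distance
    # gradient between adjacent cells, weighted by d(1/r)/dx
    xm = 0.5 * (x[lo:hi - 1] + x[lo + 1:hi])
    w = np.diff(1.0 / (xe - x[lo:hi])) / np.diff(x[lo:hi])
    dv = np.diff(vm[:, lo:hi], axis=1) / dx
    phi = -(dv * w).sum(axis=1) * dx
    t = result.t
    if t_wave_window is None:
        # repolarization portion of the final beat (past QRS and ST onset)
        t0 = float(result.stim_times[-1]) if result.stim_times is not None \
            and len(result.stim_times) else float(result.t[0])
        t_wave_window = (t0 + 150.0, float(result.t[-1]))
    m = (t >= t_wave_window[0]) & (t <= t_wave_window[1])
    amp = np.nan
    if m.any():
        seg = phi[m]
        amp = seg[np.argmax(np.abs(seg))]
    return EcgTrace(t=t, phi=phi, t_wave_amplitude=float(amp))
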