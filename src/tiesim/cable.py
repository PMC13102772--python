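"""Extracellularly driven Hodgkin-Huxley cable model.

Each mechanoreceptive fiber is a continuous unmyelinated cable with
classic squid-axon Hodgkin-Huxley membrane dynamics, driven through the
activating function: the axial term couples the second spatial
derivative of the extracellular potential into the membrane equation,

    c_m dV_m/dt = (d g_i / 4) d2(V_m + V_e)/dr2 - I_ion(V_m, m, h, n)

in classic HH units (mV, ms, cm, uF/cm2, mS/cm2).  The printed cable
parameters give the axial coupling coefficient d*g_i/4 with
g_i = 0.0282 S/cm (axial resistivity 1/g_i = 35.46 Ohm cm) and fiber
diameter d = 8.7 um.

Time integration is operator-split: gating variables advance by an
exponential (Rush-Larsen) update, then a Crank-Nicolson step handles
axial diffusion and the (frozen-conductance) membrane currents with a
tridiagonal solve.  Axon tips are sealed (zero axial current), realised
by mirror ghost nodes for the intracellular potential.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from tiesim.field import AxonPotentialSeries


@dataclass(frozen=True)
class CableParams:
    """Membrane and cable parameters (classic HH units)."""

    g_na: float = 120.0  # mS/cm2 (0.12 S/cm2)
    g_k: float = 36.0  # mS/cm2
    g_l: float = 0.3  # mS/cm2
    e_na: float = 50.0  # mV
    e_k: float = -77.0  # mV
    e_l: float = -54.3  # mV
    c_m: float = 1.0  # uF/cm2
    g_i: float = 28.2  # mS/cm (intracellular conductance, 0.0282 S/cm)
    diameter: float = 8.7e-4  # cm (8.7 um)
    m0: float = 0.00804
    h0: float = 0.931
    n0: float = 0.129
    v_rest: float = -65.0  # mV

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_l", "g_i", "c_m", "diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("m0", "h0", "n0"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def axial_coupling(self) -> float:
        """d * g_i / 4, the axial coupling coefficient in mS."""
        return self.diameter * self.g_i / 4.0


@dataclass(frozen=True)
class SimConfig:
    """Timing, guard and detection configuration of a run."""

    dt: float = 10e-6  # s (10 us)
    t_window: float = 0.100  # s, evaluation window T_w
    t_guard: float = 0.020  # s, temporal guard on each side
    l_guard: float = 1.0  # mm, spatial guard at each axon end
    v_thr: float = -20.0  # mV, AP detection threshold
    wrapping: bool = True

    @property
    def t_total(self) -> float:
        """Total simulated time 2 T_guard + T_w, s."""
        return 2.0 * self.t_guard + self.t_window

    @property
    def n_window(self) -> int:
        return round(self.t_window / self.dt)

    @property
    def n_guard(self) -> int:
        return round(self.t_guard / self.dt)

    def times_window(self) -> np.ndarray:
        """Sample times (s) of the evaluation window, [0, T_w)."""
        return np.arange(self.n_window) * self.dt

    def times_total(self) -> np.ndarray:
        """Sample times (s) of the full run, [0, T_total]."""
        return np.arange(2 * self.n_guard + self.n_window + 1) * self.dt

    def guard_nodes(self, n_nodes: int, dr_mm: float) -> int:
        """Number of nodes inside one spatial guard region."""
        ng = self.l_guard / dr_mm
        if abs(ng - round(ng)) > 1e-9:
            raise ValueError("L_guard must be an integer multiple of dr")
        return round(ng)


@dataclass(frozen=True)
class MembraneTrace:
    """Membrane potential per axon node per time step."""

    axon_id: int
    times: np.ndarray  # ms
    vm: np.ndarray  # mV, (n_nodes, n_times)
    node_positions: np.ndarray  # (n_nodes, 3), mm
    node_spacing: float  # mm


class CableInstabilityError(RuntimeError):
    """Raised when the integration produces NaNs or runaway potentials."""


def gate_rates(v):
    """Classic HH opening/closing rates (1/ms) at membrane voltage v (mV).

    Returns (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n) in the
    -65 mV resting convention.  The removable singularities of alpha_m
    and alpha_n are evaluated by their limits.
    """
    v = np.asarray(v, dtype=float)

    def _f(u):
        # u / (1 - exp(-u)) with the limit 1 at u = 0
        out = np.where(np.abs(u) < 1e-7, 1.0 + u / 2.0,
                       u / (-np.expm1(-np.where(np.abs(u) < 1e-7, 1.0, u))))
        return out

    a_m = _f((v + 40.0) / 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.1 * _f((v + 55.0) / 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def activating_drive(ve: np.ndarray, dr: float) -> np.ndarray:
    """Second spatial difference of V_e along the axon, mV/mm2.

    ``ve`` holds the per-node extracellular potential at one instant
    (mV) and ``dr`` the node spacing (mm).  End nodes use the sealed-end
    mirror treatment (ghost node equal to the inner neighbour).  The
    cable equation multiplies this by the axial coupling coefficient
    d g_i / 4 to obtain a membrane current density.
    """
    ve = np.asarray(ve, dtype=float)
    if ve.shape[-1] < 3:
        raise ValueError("need at least 3 nodes for a second difference")
    d2 = np.empty_like(ve)
    d2[..., 1:-1] = ve[..., :-2] - 2.0 * ve[..., 1:-1] + ve[..., 2:]
    d2[..., 0] = 2.0 * (ve[..., 1] - ve[..., 0])
    d2[..., -1] = 2.0 * (ve[..., -2] - ve[..., -1])
    return d2 / dr**2


@njit(cache=True)
def _integrate_kernel(ve, dt, lam_half, cm_dt, g_na, g_k, g_l, e_na, e_k,
                      e_l, v0, m0, h0, n0):  # pragma: no cover - numba
    """Crank-Nicolson / Rush-Larsen cable integration.

    ve: (n_nodes, n_t) extracellular potential, mV.  lam_half is
    theta * k_ax / dr^2 with theta = 1/2 (mS/cm2); cm_dt is c_m/dt.
    Returns (vm trace, ok flag).
    """
    n_nodes, n_t = ve.shape
    vm = np.empty((n_nodes, n_t))
    v = np.empty(n_nodes)
    m = np.empty(n_nodes)
    h = np.empty(n_nodes)
    n = np.empty(n_nodes)
    for i in range(n_nodes):
        v[i] = v0
        m[i] = m0
        h[i] = h0
        n[i] = n0
        vm[i, 0] = v0

    lo = np.empty(n_nodes)
    di = np.empty(n_nodes)
    up = np.empty(n_nodes)
    rhs = np.empty(n_nodes)
    cp = np.empty(n_nodes)

    two_lam = 2.0 * lam_half

    for it in range(1, n_t):
        # Rush-Larsen gate update at the current voltage.  The rate
        # functions are evaluated on a clamped voltage so that strongly
        # forced (supra-physiological) potentials during gain searches
        # cannot overflow the exponentials; the gates saturate there
        # anyway.
        for i in range(n_nodes):
            vv = v[i]
            if vv < -200.0:
                vv = -200.0
            elif vv > 300.0:
                vv = 300.0
            u = (vv + 40.0) / 10.0
            if abs(u) < 1e-7:
                a_m = 1.0 + 0.5 * u
            else:
                a_m = u / (1.0 - math.exp(-u))
            b_m = 4.0 * math.exp(-(vv + 65.0) / 18.0)
            a_h = 0.07 * math.exp(-(vv + 65.0) / 20.0)
            b_h = 1.0 / (1.0 + math.exp(-(vv + 35.0) / 10.0))
            u = (vv + 55.0) / 10.0
            if abs(u) < 1e-7:
                a_n = 0.1 * (1.0 + 0.5 * u)
            else:
                a_n = 0.1 * u / (1.0 - math.exp(-u))
            b_n = 0.125 * math.exp(-(vv + 65.0) / 80.0)

            s = a_m + b_m
            m[i] = a_m / s + (m[i] - a_m / s) * math.exp(-dt * s)
            s = a_h + b_h
            h[i] = a_h / s + (h[i] - a_h / s) * math.exp(-dt * s)
            s = a_n + b_n
            n[i] = a_n / s + (n[i] - a_n / s) * math.exp(-dt * s)

        # frozen-conductance membrane currents and the CN right-hand side
        for i in range(n_nodes):
            gna = g_na * m[i] * m[i] * m[i] * h[i]
            gk = g_k * n[i] * n[i] * n[i] * n[i]
            gt = gna + gk + g_l
            ed = gna * e_na + gk * e_k + g_l * e_l

            # mirror-ghost second differences of v and the mid-step ve
            if i == 0:
                d2v = 2.0 * (v[1] - v[0])
                d2e = (ve[1, it - 1] - ve[0, it - 1]
                       + ve[1, it] - ve[0, it])
            elif i == n_nodes - 1:
                d2v = 2.0 * (v[i - 1] - v[i])
                d2e = (ve[i - 1, it - 1] - ve[i, it - 1]
                       + ve[i - 1, it] - ve[i, it])
            else:
                d2v = v[i - 1] - 2.0 * v[i] + v[i + 1]
                d2e = 0.5 * (ve[i - 1, it - 1] - 2.0 * ve[i, it - 1]
                             + ve[i + 1, it - 1]
                             + ve[i - 1, it] - 2.0 * ve[i, it]
                             + ve[i + 1, it])

            rhs[i] = (cm_dt * v[i] + lam_half * d2v - 0.5 * gt * v[i] + ed
                      + two_lam * d2e)
            di[i] = cm_dt + 0.5 * gt + two_lam
            lo[i] = -lam_half
            up[i] = -lam_half
        # sealed ends couple with weight 2 to the single neighbour
        up[0] = -two_lam
        lo[n_nodes - 1] = -two_lam

        # Thomas algorithm
        cp[0] = up[0] / di[0]
        rhs[0] = rhs[0] / di[0]
        for i in range(1, n_nodes):
            denom = di[i] - lo[i] * cp[i - 1]
            cp[i] = up[i] / denom
            rhs[i] = (rhs[i] - lo[i] * rhs[i - 1]) / denom
        v[n_nodes - 1] = rhs[n_nodes - 1]
        for i in range(n_nodes - 2, -1, -1):
            v[i] = rhs[i] - cp[i] * v[i + 1]

        for i in range(n_nodes):
            vm[i, it] = v[i]
            if not np.isfinite(v[i]):
                return vm, False
    return vm, True


def wrap_drive(drive: AxonPotentialSeries,
               config: SimConfig) -> AxonPotentialSeries:
    """Extend a T_w drive to T_total by periodic wrapping of the guards.

    The pre-guard is filled with the last T_guard of the window and the
    post-guard with its first T_guard, giving a continuous periodic
    drive when T_w is an integer number of stimulus periods.  A window
    that is visibly non-periodic (seam jump far above the within-window
    sample-to-sample variation) falls back to zero-padded guards with a
    warning.
    """
    n_w = config.n_window
    n_g = config.n_guard
    if drive.ve.shape[1] != n_w:
        raise ValueError(
            f"drive must cover exactly the {n_w}-sample evaluation window")
    ve = drive.ve
    seam = np.abs(ve[:, 0] - ve[:, -1]).max()
    interior = np.abs(np.diff(ve, axis=1)).max()
    scale = np.abs(ve).max()
    periodic = scale == 0 or seam <= max(3.0 * interior, 1e-12 * scale)
    out = np.empty((ve.shape[0], 2 * n_g + n_w + 1))
    if periodic:
        out[:, :n_g] = ve[:, n_w - n_g:]
        out[:, n_g:n_g + n_w] = ve
        out[:, n_g + n_w:] = ve[:, :n_g + 1]
    else:
        warnings.warn("drive window is not periodic; using zero-padded "
                      "temporal guards", stacklevel=2)
        out[:] = 0.0
        out[:, n_g:n_g + n_w] = ve
    return AxonPotentialSeries(axon_id=drive.axon_id,
                               node_positions=drive.node_positions,
                               times=config.times_total(), ve=out)


def simulate_axon(drive: AxonPotentialSeries,
                  params: CableParams | None = None,
                  config: SimConfig | None = None) -> MembraneTrace:
    """Integrate the cable equation for one axon over T_total.

    ``drive`` must cover the full run (use :func:`wrap_drive` on a
    window-only series first).  The axon starts at rest with the
    configured initial gate values; the pre-guard serves as the
    equilibration period.
    """
    params = params or CableParams()
    config = config or SimConfig()
    n_total = 2 * config.n_guard + config.n_window + 1
    if drive.ve.shape[1] != n_total:
        raise ValueError(
            f"drive has {drive.ve.shape[1]} samples; expected {n_total} "
            "covering T_total (wrap the window first)")
    dt_ms = config.dt * 1e3
    spacing_mm = float(np.linalg.norm(
        drive.node_positions[1] - drive.node_positions[0]))
    dr = spacing_mm * 0.1  # mm -> cm
    lam = params.axial_coupling / dr**2  # mS/cm2
    vm, ok = _integrate_kernel(
        np.ascontiguousarray(drive.ve), dt_ms, 0.5 * lam, params.c_m / dt_ms,
        params.g_na, params.g_k, params.g_l, params.e_na, params.e_k,
        params.e_l, params.v_rest, params.m0, params.h0, params.n0)
    if not ok or not np.isfinite(vm).all():
        raise CableInstabilityError(
            f"axon {drive.axon_id}: membrane potential left the stable "
            "range (numerical blow-up); reduce the time step or gain")
    return MembraneTrace(axon_id=drive.axon_id, times=drive.times * 1e3,
                         vm=vm, node_positions=drive.node_positions,
                         node_spacing=spacing_mm)


def simulate_axons(drives: list[AxonPotentialSeries],
                   params: CableParams | None = None,
                   config: SimConfig | None = None) -> list[MembraneTrace]:
    """Integrate a batch of axons (convenience loop)."""
    return [simulate_axon(d, params, config) for d in drives]
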