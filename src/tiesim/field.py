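"""Quasi-static volume-conductor field solver.

The potential in the layered tissue obeys div(sigma grad V + d/dt(eps
grad V)) = 0.  Because the tissue is linear and time-invariant at fixed
material properties, a sinusoidal drive at frequency f is solved once as
a complex-admittance Laplace problem div(sigma* grad Vhat) = 0 with
sigma* = sigma + j 2 pi f eps, and the two stimulus components are
composed in the time domain by superposition.  A brute-force implicit
time stepper of the full equation is kept as a small-grid oracle.

Discretisation: structured rectilinear grid with node-centred unknowns
and a 7-point finite-volume stencil.  Edge conductances are the series
(harmonic) combination of the admittances the edge traverses, so layer
interfaces that fall between node planes are handled exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tiesim.stimulus import StimulusSpec
from tiesim.tissue import (
    AxonPath,
    TissueModel,
    complex_admittance,
    material_properties,
)


class SolverConvergenceError(RuntimeError):
    """Raised when the iterative phasor solve does not reach tolerance."""


@dataclass(frozen=True)
class AdmittanceGrid:
    """Rectilinear grid with per-edge complex admittance at one frequency.

    Nodes sit at integer multiples of the spacing h covering the full
    tissue box.  ``edge_sigma`` holds, per axis, the series-combined
    sigma* (S/m) along each edge between neighbouring nodes.
    """

    spacing: float  # h, mm
    dims: tuple[int, int, int]  # node counts (nx, ny, nz)
    frequency: float  # Hz, drive frequency (omega in the capacitive term)
    edge_sigma: tuple[np.ndarray, np.ndarray, np.ndarray]
    model: TissueModel
    material_frequency: float = None  # Hz at which sigma/eps were read

    def __post_init__(self) -> None:
        if self.material_frequency is None:
            object.__setattr__(self, "material_frequency", self.frequency)

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def node_index(self, i: int, j: int, k: int) -> int:
        nx, ny, nz = self.dims
        return (i * ny + j) * nz + k

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Node coordinate vectors (x, y, z) in mm."""
        nx, ny, nz = self.dims
        h = self.spacing
        return (np.arange(nx) * h, np.arange(ny) * h, np.arange(nz) * h)

    def voxel_sigma(self) -> np.ndarray:
        """Per-voxel sigma* sampled at voxel centres, shape dims-1."""
        nx, ny, nz = self.dims
        h = self.spacing
        zc = (np.arange(nz - 1) + 0.5) * h
        sig_z = np.array([
            complex_admittance(
                material_properties(self.model.tissue_at(z),
                                    self.material_frequency, self.model),
                self.frequency)
            for z in zc])
        return np.broadcast_to(sig_z, (nx - 1, ny - 1, nz - 1)).copy()


@dataclass(frozen=True)
class BoundaryAssignment:
    """Dirichlet ground nodes and per-electrode injection node weights."""

    dirichlet_nodes: np.ndarray  # flat node indices with V = 0
    flux_patches: dict  # role -> (flat node indices, weights summing to 1)


@dataclass(frozen=True)
class PhasorField:
    """Complex potential per grid node for 1 A injected at one electrode."""

    potentials: np.ndarray  # complex, V per A, shape dims
    frequency: float  # Hz
    source: str  # electrode role
    grid: AdmittanceGrid

    def sample(self, points: np.ndarray, interpolate: bool = False,
               method: str = "cubic") -> np.ndarray:
        """Complex potential at points (n, 3) in mm.

        By default points must coincide with grid nodes (the sampling
        rule used for axon drives on the production grid); with
        ``interpolate=True`` off-node points are interpolated.  The
        default cubic spline has continuous second derivatives, so the
        activating function computed from interpolated samples is free
        of the cell-boundary curvature spikes a trilinear interpolant
        would inject; ``method="linear"`` is available for comparison.
        """
        points = np.asarray(points, dtype=float)
        h = self.grid.spacing
        idx = points / h
        on_node = np.allclose(idx, np.round(idx), atol=1e-9)
        if on_node:
            ii = np.round(idx).astype(int)
            return self.potentials[ii[:, 0], ii[:, 1], ii[:, 2]]
        if not interpolate:
            raise ValueError(
                "points are not co-located with grid nodes; pass "
                "interpolate=True to enable interpolation")
        if np.any(idx < 0) or np.any(idx > np.array(self.grid.dims) - 1):
            raise ValueError("sample points outside the grid")
        if method == "linear":
            from scipy.interpolate import RegularGridInterpolator

            itp = RegularGridInterpolator(self.grid.coordinates(),
                                          self.potentials, method="linear",
                                          bounds_error=True)
            return itp(points)
        if method != "cubic":
            raise ValueError(f"unknown interpolation method {method!r}")
        from scipy.ndimage import map_coordinates

        re = map_coordinates(self.potentials.real, idx.T, order=3,
                             mode="nearest")
        im = map_coordinates(self.potentials.imag, idx.T, order=3,
                             mode="nearest")
        return re + 1j * im


@dataclass(frozen=True)
class AxonPotentialSeries:
    """Extracellular potential time series at each node of one axon."""

    axon_id: int
    node_positions: np.ndarray  # (n_nodes, 3), mm
    times: np.ndarray  # s, uniform grid
    ve: np.ndarray  # mV, (n_nodes, n_times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def _series_sigma(model: TissueModel, f: float, f_mat: float, z0: float,
                  z1: float) -> complex:
    """Series (harmonic) combination of sigma* along a z-interval.

    The interval may cross layer interfaces; each sub-interval
    contributes its thickness over its admittance.
    """
    cuts = sorted({z0, z1} | {
        b for _, (lo, hi) in model.layer_boundaries for b in (lo, hi)
        if z0 < b < z1})
    total = z1 - z0
    resistance = 0.0 + 0.0j
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        zc = 0.5 * (lo + hi)
        sig = complex_admittance(
            material_properties(model.tissue_at(zc), f_mat, model), f)
        resistance += (hi - lo) / sig
    return total / resistance


def assemble_grid(model: TissueModel, f: float, h: float,
                  f_material: float | None = None) -> AdmittanceGrid:
    """Build the admittance grid for drive frequency f (Hz).

    h (mm) must divide all domain extents and be at most 0.5 mm.
    sigma and eps are interpolated at ``f_material`` (the carrier; by
    default f itself) while the capacitive term of sigma* uses the
    component's own omega = 2 pi f.  Each edge's sigma* is the series
    combination over the tissue it traverses.
    """
    f_mat = f if f_material is None else f_material
    ex, ey, ez = model.domain_extent
    for extent in (ex, ey, ez):
        n = extent / h
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"spacing {h} mm does not divide extent {extent} mm")
    if h > 0.5 + 1e-12:
        raise ValueError("grid spacing must be <= 0.5 mm")
    nx, ny, nz = (round(ex / h) + 1, round(ey / h) + 1, round(ez / h) + 1)

    z_nodes = np.arange(nz) * h
    # sigma* at constant-z levels (for x/y edges) and across z-intervals
    # (for z edges).  Nodes exactly on an interface take the mean of the
    # two adjacent layers for their lateral edges.
    sig_level = np.empty(nz, dtype=complex)
    for k, z in enumerate(z_nodes):
        below = material_properties(model.tissue_at(max(z - 1e-9, 0.0)),
                                    f_mat, model)
        above = material_properties(model.tissue_at(min(z + 1e-9, ez)),
                                    f_mat, model)
        sig_level[k] = 0.5 * (complex_admittance(below, f)
                              + complex_admittance(above, f))
    sig_zedge = np.array([
        _series_sigma(model, f, f_mat, z_nodes[k], z_nodes[k + 1])
        for k in range(nz - 1)])

    edge_x = np.broadcast_to(sig_level, (nx - 1, ny, nz)).copy()
    edge_y = np.broadcast_to(sig_level, (nx, ny - 1, nz)).copy()
    edge_z = np.broadcast_to(sig_zedge, (nx, ny, nz - 1)).copy()
    return AdmittanceGrid(spacing=h, dims=(nx, ny, nz), frequency=f,
                          edge_sigma=(edge_x, edge_y, edge_z), model=model,
                          material_frequency=f_mat)


def _surface_patch(grid: AdmittanceGrid, center: tuple[float, float],
                   diameter: float) -> tuple[np.ndarray, np.ndarray]:
    """Top-surface node indices under a disc and their area weights.

    Weights are proportional to each node's surface-cell overlap with
    the disc, estimated by 4 x 4 subsampling of the cell.
    """
    nx, ny, nz = grid.dims
    h = grid.spacing
    r = diameter / 2.0
    cx, cy = center
    xs = np.arange(nx) * h
    ys = np.arange(ny) * h
    # candidate nodes within one cell of the disc
    ii = np.where(np.abs(xs - cx) <= r + h)[0]
    jj = np.where(np.abs(ys - cy) <= r + h)[0]
    sub = (np.arange(4) + 0.5) / 4.0 - 0.5  # subsample offsets in cell units
    ox, oy = np.meshgrid(sub * h, sub * h, indexing="ij")
    nodes, weights = [], []
    for i in ii:
        for j in jj:
            px = xs[i] + ox
            py = ys[j] + oy
            frac = np.mean((px - cx) ** 2 + (py - cy) ** 2 <= r * r)
            if frac > 0:
                nodes.append(grid.node_index(i, j, nz - 1))
                weights.append(frac)
    nodes = np.asarray(nodes, dtype=np.int64)
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()
    return nodes, weights


def default_boundaries(grid: AdmittanceGrid) -> BoundaryAssignment:
    """Ground-disc Dirichlet nodes and stimulation flux patches."""
    model = grid.model
    gnd_nodes, _ = _surface_patch(grid, model.ground_electrode.center,
                                  model.ground_electrode.diameter)
    patches = {}
    for e in model.electrode_set:
        if e.role == "ground":
            continue
        nodes, w = _surface_patch(grid, e.center, e.diameter)
        patches[e.role] = (nodes, w)
    for role, (nodes, _) in patches.items():
        if np.intersect1d(nodes, gnd_nodes).size:
            raise ValueError(f"electrode {role} overlaps the ground disc")
    return BoundaryAssignment(dirichlet_nodes=gnd_nodes, flux_patches=patches)


def _edge_conductances(grid: AdmittanceGrid) -> list[np.ndarray]:
    """Per-edge conductances g = sigma* A/h (S) for each axis.

    Interior edges carry face area h^2; the control faces of edges on a
    domain boundary are halved per transverse boundary (finite-volume
    consistency: surface cells are half cells, edge cells quarter
    cells).
    """
    h_m = grid.spacing * 1e-3
    out = []
    for axis, sig in enumerate(grid.edge_sigma):
        g = sig * h_m
        for t_axis in range(3):
            if t_axis == axis:
                continue
            w = np.ones(grid.dims[t_axis])
            w[0] = 0.5
            w[-1] = 0.5
            shape = [1, 1, 1]
            shape[t_axis] = -1
            g = g * w.reshape(shape)
        out.append(g)
    return out


def _system_matrix(grid: AdmittanceGrid) -> sp.csr_matrix:
    """7-point finite-volume Laplacian with per-edge admittances.

    External faces carry no flux (insulating boundaries) simply by
    omission of edges.
    """
    nx, ny, nz = grid.dims
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    rows, cols, vals = [], [], []
    for axis, g in enumerate(_edge_conductances(grid)):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        a = idx[tuple(sl_lo)].ravel()
        b = idx[tuple(sl_hi)].ravel()
        gg = g.ravel()
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [-gg, -gg, gg, gg]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _apply_dirichlet(A: sp.csr_matrix, b: np.ndarray,
                     nodes: np.ndarray) -> sp.csr_matrix:
    """Zero-potential Dirichlet rows/columns (value 0 keeps b simple)."""
    n = A.shape[0]
    keep = np.ones(n)
    keep[nodes] = 0.0
    P = sp.diags(keep)
    A = (P @ A @ P + sp.diags(1.0 - keep)).tocsr()
    b[nodes] = 0.0
    return A


def solve_phasor(grid: AdmittanceGrid, boundaries: BoundaryAssignment,
                 source: str, rtol: float = 1e-8,
                 maxiter: int = 10_000) -> PhasorField:
    """Solve the complex-admittance Laplace problem for one electrode.

    1 A is injected through the source electrode's flux patch with the
    ground disc held at V = 0; all other boundary faces are insulating.
    The sparse system is solved directly (LU) with the relative residual
    checked against ``rtol``.
    """
    if source not in boundaries.flux_patches:
        raise KeyError(f"no flux patch for source electrode {source!r}")
    if boundaries.dirichlet_nodes.size == 0:
        raise ValueError("singular system: no Dirichlet (ground) nodes")
    A = _system_matrix(grid)
    b = np.zeros(grid.n_nodes, dtype=complex)
    nodes, w = boundaries.flux_patches[source]
    b[nodes] = w  # 1 A total, area-weighted
    A = _apply_dirichlet(A, b, boundaries.dirichlet_nodes)
    # incomplete-LU preconditioned BiCGStab; deterministic and far
    # cheaper than a full factorisation on production grids
    ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=30)
    M = spla.LinearOperator(A.shape, ilu.solve, dtype=complex)
    x, info = spla.bicgstab(A, b, rtol=rtol * 1e-2, atol=0.0, M=M,
                            maxiter=maxiter)
    res = np.linalg.norm(A @ x - b) / np.linalg.norm(b)
    if info != 0 or not np.isfinite(res) or res > rtol:
        raise SolverConvergenceError(
            f"phasor solve residual {res:.3e} exceeds {rtol:.0e} "
            f"(bicgstab info {info})")
    return PhasorField(potentials=x.reshape(grid.dims), frequency=grid.frequency,
                       source=source, grid=grid)


def current_balance(field: PhasorField,
                    boundaries: BoundaryAssignment) -> float:
    """|injected - returned| current as a fraction of injected (1 A).

    The return current is the flux into the ground disc computed from
    the discrete solution; discrete conservation makes this match the
    injected current to solver precision.
    """
    grid = field.grid
    V = field.potentials
    flux = np.zeros(grid.dims, dtype=complex)
    for axis, g in enumerate(_edge_conductances(grid)):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        dV = V[tuple(sl_hi)] - V[tuple(sl_lo)]
        lo = np.zeros(grid.dims, dtype=complex)
        hi = np.zeros(grid.dims, dtype=complex)
        lo[tuple(sl_lo)] = g * dV      # current flowing into lo node
        hi[tuple(sl_hi)] = -g * dV
        flux += lo + hi
    returned = flux.ravel()[boundaries.dirichlet_nodes].sum()
    return abs(1.0 - returned.real) + abs(returned.imag)


def analytic_halfspace(current: float, sigma: float, source: np.ndarray,
                       point: np.ndarray) -> float:
    """Surface point-source potential in a homogeneous half-space, V.

    V = I / (2 pi sigma r) for a source on the surface.
    """
    r = float(np.linalg.norm(np.asarray(point, float) - np.asarray(source, float)))
    if r == 0.0:
        raise ValueError("field point coincides with the source")
    return current / (2.0 * np.pi * sigma * r)


def time_domain_reference(grid: AdmittanceGrid,
                          boundaries: BoundaryAssignment,
                          stim: StimulusSpec,
                          times: np.ndarray) -> np.ndarray:
    """Implicit time-stepped solution of the full transient equation.

    Solves div(sigma grad V) + d/dt div(eps grad V) = 0 with the
    two-tone electrode currents as boundary drive, by backward Euler on
    G V + C dV/dt = b(t) where G and C are the conductive and capacitive
    edge-Laplacians.  Intended for tiny grids (<= ~11^3 nodes) as an
    oracle for the phasor composition; returns V (volts) with shape
    (n_nodes, n_times).  Currents in ``stim`` are interpreted in mA.
    """
    nx, ny, nz = grid.dims
    if grid.n_nodes > 2500:
        raise ValueError("time-domain reference is restricted to tiny grids")
    model = grid.model
    h = grid.spacing
    f = grid.frequency

    def laplacian(part: str) -> sp.csr_matrix:
        edges = []
        for axis, sig in enumerate(grid.edge_sigma):
            if part == "sigma":
                edges.append(sig.real)
            else:  # eps grad: sigma* imaginary part is 2 pi f eps
                edges.append(sig.imag / (2.0 * np.pi * f))
        g2 = AdmittanceGrid(spacing=h, dims=grid.dims, frequency=f,
                            edge_sigma=tuple(edges), model=model)
        return _system_matrix(g2)

    G = laplacian("sigma").astype(float)
    C = laplacian("eps").astype(float)

    times = np.asarray(times, dtype=float)
    dt = float(times[1] - times[0])
    if not np.allclose(np.diff(times), dt):
        raise ValueError("time grid must be uniform")

    b_pattern = {}
    for role, (nodes, w) in boundaries.flux_patches.items():
        b_pattern[role] = (nodes, w)
    dn = boundaries.dirichlet_nodes

    b0 = np.zeros(grid.n_nodes)
    A = _apply_dirichlet((G + C / dt).tocsr(), b0, dn)
    lu = spla.splu(A.tocsc())
    Cd = C / dt

    from tiesim.stimulus import ties_waveforms

    out = np.zeros((grid.n_nodes, times.size))
    v = np.zeros(grid.n_nodes)
    i1, i2 = ties_waveforms(stim, times)
    for n_t in range(1, times.size):
        b = Cd @ v
        for role, amp in (("stim1", i1[n_t]), ("stim2", i2[n_t])):
            if role in b_pattern:
                nodes, w = b_pattern[role]
                b[nodes] += amp * 1e-3 * w  # mA -> A
        b[dn] = 0.0
        v = lu.solve(b)
        out[:, n_t] = v
    return out


def compose_axon_drive(field1: PhasorField, field2: PhasorField,
                       stim: StimulusSpec, axon: AxonPath,
                       times: np.ndarray,
                       interpolate: bool = False) -> AxonPotentialSeries:
    """Compose the time-domain extracellular drive along an axon.

    V_e(r, t) = A1 Im[Vhat1(r) e^{j(2 pi f1 t + phi1)}]
              + A2 Im[Vhat2(r) e^{j(2 pi f2 t + phi2)}]
    i.e. each unit-current phasor is driven by its electrode's sinusoid.
    Fields are per 1 A injected and amplitudes are in mA, so the result
    is directly in mV.
    """
    if not np.isclose(field1.frequency, stim.f1):
        raise ValueError("field1 was not solved at the stimulus f1")
    if not np.isclose(field2.frequency, stim.f2):
        raise ValueError("field2 was not solved at the stimulus f2")
    times = np.asarray(times, dtype=float)
    v1 = field1.sample(axon.node_positions, interpolate=interpolate)
    v2 = field2.sample(axon.node_positions, interpolate=interpolate)
    ph1 = 2.0 * np.pi * stim.f1 * times + stim.phi1
    ph2 = 2.0 * np.pi * stim.f2 * times + stim.phi2
    # Im[Vhat e^{j ph}] = Re(Vhat) sin(ph) + Im(Vhat) cos(ph)
    ve = (stim.a1 * (np.outer(v1.real, np.sin(ph1))
                     + np.outer(v1.imag, np.cos(ph1)))
          + stim.a2 * (np.outer(v2.real, np.sin(ph2))
                       + np.outer(v2.imag, np.cos(ph2))))
    return AxonPotentialSeries(axon_id=axon.axon_id,
                               node_positions=axon.node_positions,
                               times=times, ve=ve)
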