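"""Scalar-potential finite-difference (SPFD) forward solver.

Quasi-static EEG forward problem: div(sigma grad(phi)) = -div(j) on a
regular voxel grid with heterogeneous conductivity.  Unknown potentials sit
on voxel *nodes* (corners); each grid edge carries a conductance
g = h * mean(sigma) over the up-to-4 voxels sharing the edge, which is the
classical SPFD stencil.  Air (sigma = 0) contributes zero conductance, so
the insulating head boundary is a natural Neumann condition and needs no
explicit boundary rows.

The resulting symmetric system is solved with geometric multigrid V-cycles
using red-black successive over-relaxation (SOR) smoothing; coarse grids are
re-assembled from 2x2x2 box-averaged conductivity.  Iterations stop when the
relative residual ||b - A phi|| / ||b|| drops below the configured tolerance
(default 1e-6, the pipeline's stopping rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import ConductivityVolume

__all__ = [
    "SpfdSystem",
    "SourceConfiguration",
    "PotentialField",
    "CurrentDensityField",
    "SolverConfig",
    "ConvergenceError",
    "assemble_spfd",
    "electrode_injection_rhs",
    "dipole_rhs",
    "solve_potential",
    "current_density",
    "voxel_gradient",
]


class ConvergenceError(RuntimeError):
    """Raised when the multigrid solver fails to reach tolerance."""

    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass
class SolverConfig:
    """Multigrid/SOR parameters.

    Only the level count (6) and the stopping tolerance (1e-6) are pinned by
    the method; relaxation factor, sweep counts and cycle limits are solver
    implementation choices.
    """

    tolerance: float = 1e-6
    levels: int = 6
    omega: float = 1.5
    pre_sweeps: int = 2
    post_sweeps: int = 2
    max_cycles: int = 100
    coarse_sweeps: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.omega < 2):
            raise ValueError("SOR relaxation factor must lie in (0, 2)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class SpfdSystem:
    """Edge-conductance representation of the discretized operator.

    ``gx/gy/gz`` hold edge conductances (S) for edges along each axis on the
    node grid; ``diag`` is the per-node sum of incident conductances.  Rows
    sum to zero (pure Neumann); nodes with ``diag == 0`` lie entirely in air
    and are excluded from the solve.
    """

    gx: np.ndarray
    gy: np.ndarray
    gz: np.ndarray
    spacing_mm: float
    sigma: np.ndarray | None = None  # voxel conductivity, kept for coarsening
    diag: np.ndarray = field(init=False)
    active: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for g in (self.gx, self.gy, self.gz):
            if np.any(g < 0):
                raise ValueError("edge conductances must be non-negative")
        nx = self.gx.shape[0] + 1
        ny = self.gy.shape[1] + 1
        nz = self.gz.shape[2] + 1
        expect = {
            "gx": (nx - 1, ny, nz),
            "gy": (nx, ny - 1, nz),
            "gz": (nx, ny, nz - 1),
        }
        for name, shape in expect.items():
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")
        d = np.zeros((nx, ny, nz))
        d[:-1] += self.gx
        d[1:] += self.gx
        d[:, :-1] += self.gy
        d[:, 1:] += self.gy
        d[:, :, :-1] += self.gz
        d[:, :, 1:] += self.gz
        self.diag = d
        self.active = d > 0
        self._hierarchy: list["_Level"] | None = None

    @property
    def node_shape(self) -> tuple[int, int, int]:
        return self.diag.shape

    def neighbor_sum(self, phi: np.ndarray) -> np.ndarray:
        """Sum of g_ij * phi_j over the neighbors of every node."""
        s = np.zeros_like(phi)
        s[:-1] += self.gx * phi[1:]
        s[1:] += self.gx * phi[:-1]
        s[:, :-1] += self.gy * phi[:, 1:]
        s[:, 1:] += self.gy * phi[:, :-1]
        s[:, :, :-1] += self.gz * phi[:, :, 1:]
        s[:, :, 1:] += self.gz * phi[:, :, :-1]
        return s

    def apply(self, phi: np.ndarray) -> np.ndarray:
        """Matrix-vector product A phi (A = diag - adjacency)."""
        return self.diag * phi - self.neighbor_sum(phi)


@dataclass
class SourceConfiguration:
    """Sparse nodal current injections b (A); total current must vanish."""

    nodes: np.ndarray  # (k, 3) node indices
    values: np.ndarray  # (k,) currents in A
    kind: str = "dipole"  # or "electrode_injection"

    def __post_init__(self) -> None:
        self.nodes = np.atleast_2d(np.asarray(self.nodes, dtype=int))
        self.values = np.asarray(self.values, dtype=float)
        if self.nodes.shape[0] != self.values.shape[0]:
            raise ValueError("one value per node required")
        total = float(self.values.sum())
        scale = float(np.abs(self.values).sum()) or 1.0
        if abs(total) > 1e-12 * scale:
            raise ValueError("injected currents must sum to zero (charge conservation)")

    def dense(self, node_shape: tuple[int, int, int]) -> np.ndarray:
        b = np.zeros(node_shape)
        np.add.at(b, tuple(self.nodes.T), self.values)
        return b


@dataclass
class PotentialField:
    """Nodal potential (V); zero at the reference node when one is given."""

    phi: np.ndarray
    spacing_mm: float
    reference_node: tuple[int, int, int] | None = None
    cycles: int = 0
    residual_history: list[float] = field(default_factory=list)

    @property
    def relative_residual(self) -> float:
        return self.residual_history[-1] if self.residual_history else 0.0


@dataclass
class CurrentDensityField:
    """Per-voxel current density vectors (A/m^2), zero outside the head."""

    j: np.ndarray  # (nx, ny, nz, 3)
    spacing_mm: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.j, axis=-1)


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------


def _edge_conductances(sigma: np.ndarray, spacing_mm: float):
    """g = h * mean(sigma over existing adjacent voxels) for all three axes."""
    h_m = spacing_mm * 1e-3

    def per_axis(axis: int) -> np.ndarray:
        # pad the two transverse axes by one (zero sigma, zero count)
        pad = [(0, 0)] * 3
        t1, t2 = [a for a in range(3) if a != axis]
        pad[t1] = (1, 1)
        pad[t2] = (1, 1)
        sp = np.pad(sigma, pad)
        cp = np.pad(np.ones_like(sigma), pad)
        n = sigma.shape
        out_shape = [n[0], n[1], n[2]]
        out_shape[t1] += 1
        out_shape[t2] += 1
        ssum = np.zeros(out_shape)
        csum = np.zeros(out_shape)
        for d1 in (0, 1):
            for d2 in (0, 1):
                sl = [slice(None)] * 3
                sl[t1] = slice(d1, d1 + out_shape[t1])
                sl[t2] = slice(d2, d2 + out_shape[t2])
                ssum += sp[tuple(sl)]
                csum += cp[tuple(sl)]
        return h_m * ssum / np.maximum(csum, 1.0)

    return per_axis(0), per_axis(1), per_axis(2)


def assemble_spfd(vol: ConductivityVolume) -> SpfdSystem:
    """Build the SPFD edge-conductance system from a conductivity volume."""
    if not np.any(vol.sigma > 0):
        raise ValueError("volume is entirely air: no conductor to solve on")
    gx, gy, gz = _edge_conductances(vol.sigma, vol.spacing_mm)
    return SpfdSystem(gx, gy, gz, vol.spacing_mm, sigma=vol.sigma)


# --------------------------------------------------------------------------
# right-hand sides
# --------------------------------------------------------------------------


def electrode_injection_rhs(
    system: SpfdSystem, electrodes, inject_label: str, current_amps: float = 1.0
) -> SourceConfiguration:
    """Unit-current injection between one electrode and the reference."""
    if inject_label == electrodes.reference_label:
        raise ValueError("injection electrode must differ from the reference")
    inj = electrodes.electrodes[electrodes.index_of(inject_label)].node_index
    ref = electrodes.electrodes[electrodes.index_of(electrodes.reference_label)].node_index
    for node, lab in ((inj, inject_label), (ref, electrodes.reference_label)):
        if not system.active[node]:
            raise ValueError(f"electrode {lab} node lies in air")
    return SourceConfiguration(
        nodes=np.array([inj, ref]),
        values=np.array([current_amps, -current_amps]),
        kind="electrode_injection",
    )


def dipole_rhs(
    system: SpfdSystem,
    voxel: tuple[int, int, int],
    axis: int,
    moment: float = 1.0,
    distributed: bool = True,
) -> SourceConfiguration:
    """Elementary dipole at a voxel: monopole pair(s) +/- I with I = moment/h.

    ``distributed=True`` (default) splits the pair over the voxel's four
    parallel edges (+/- I/4 per node), which centers the dipole on the voxel
    and makes it the exact discrete adjoint of voxel-center field sampling -
    reciprocity then holds to solver tolerance.  ``distributed=False`` puts
    the full pair on the voxel's corner edge.
    """
    h_m = system.spacing_mm * 1e-3
    current = moment / h_m
    i, j, k = (int(v) for v in voxel)
    if system.sigma is not None:
        nb = list(voxel)
        nb[axis] += 1
        inside = system.sigma[i, j, k] > 0
        nb_ok = nb[axis] < system.sigma.shape[axis] and system.sigma[tuple(nb)] > 0
        if not (inside and nb_ok):
            raise ValueError(f"dipole voxel {voxel} (axis {axis}) has no conducting neighbor")
    offs = [(0, 0), (0, 1), (1, 0), (1, 1)] if distributed else [(0, 0)]
    t1, t2 = [a for a in range(3) if a != axis]
    nodes, values = [], []
    for d1, d2 in offs:
        lo = [i, j, k]
        lo[t1] += d1
        lo[t2] += d2
        hi = list(lo)
        hi[axis] += 1
        nodes += [hi, lo]
        values += [current / len(offs), -current / len(offs)]
    sc = SourceConfiguration(np.array(nodes), np.array(values), kind="dipole")
    if not np.all(system.active[tuple(sc.nodes.T)]):
        raise ValueError(f"dipole at voxel {voxel} touches inactive (air) nodes")
    return sc


# --------------------------------------------------------------------------
# multigrid solver
# --------------------------------------------------------------------------


@dataclass
class _Level:
    system: SpfdSystem
    red: np.ndarray
    black: np.ndarray
    inv_diag: np.ndarray


def _make_level(system: SpfdSystem) -> _Level:
    shape = system.node_shape
    ii, jj, kk = np.indices(shape, sparse=True)
    parity = (ii + jj + kk) % 2 == 0
    red = parity & system.active
    black = (~parity) & system.active
    inv = np.zeros(shape)
    inv[system.active] = 1.0 / system.diag[system.active]
    return _Level(system, red, black, inv)


def _box_average(sigma: np.ndarray) -> np.ndarray:
    n = sigma.shape
    return sigma.reshape(n[0] // 2, 2, n[1] // 2, 2, n[2] // 2, 2).mean(axis=(1, 3, 5))


def _build_hierarchy(system: SpfdSystem, config: SolverConfig) -> list[_Level]:
    levels = [_make_level(system)]
    sigma = system.sigma
    spacing = system.spacing_mm
    while sigma is not None and len(levels) < config.levels:
        dims = sigma.shape
        if any(d % 2 or d < 4 for d in dims):
            break
        sigma = _box_average(sigma)
        spacing *= 2.0
        gx, gy, gz = _edge_conductances(sigma, spacing)
        levels.append(_make_level(SpfdSystem(gx, gy, gz, spacing, sigma=sigma)))
    return levels


def _sor_sweeps(level: _Level, phi: np.ndarray, b: np.ndarray, omega: float, n: int) -> None:
    sysm = level.system
    for _ in range(n):
        for mask in (level.red, level.black):
            s = sysm.neighbor_sum(phi)
            upd = (b + s) * level.inv_diag
            phi[mask] += omega * (upd[mask] - phi[mask])


def _restrict(r: np.ndarray) -> np.ndarray:
    """Transpose of trilinear prolongation (weights sum to 8): collects the
    residual currents of the fine neighborhood into each coarse node."""
    rp = np.pad(r, 1)
    nf = r.shape
    nc = tuple((d - 1) // 2 + 1 for d in nf)
    out = np.zeros(nc)
    for dx in (-1, 0, 1):
        wx = 1.0 if dx == 0 else 0.5
        for dy in (-1, 0, 1):
            wy = 1.0 if dy == 0 else 0.5
            for dz in (-1, 0, 1):
                wz = 1.0 if dz == 0 else 0.5
                sl = tuple(
                    slice(1 + d, 1 + d + 2 * (n - 1) + 1, 2) for d, n in zip((dx, dy, dz), nc)
                )
                out += (wx * wy * wz) * rp[sl]
    return out


def _prolong(ec: np.ndarray, fine_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear interpolation from the coarse node grid to the fine one."""
    a = np.zeros((fine_shape[0], ec.shape[1], ec.shape[2]))
    a[::2] = ec
    a[1::2] = 0.5 * (ec[:-1] + ec[1:])
    bqq = np.zeros((fine_shape[0], fine_shape[1], ec.shape[2]))
    bqq[:, ::2] = a
    bqq[:, 1::2] = 0.5 * (a[:, :-1] + a[:, 1:])
    c = np.zeros(fine_shape)
    c[:, :, ::2] = bqq
    c[:, :, 1::2] = 0.5 * (bqq[:, :, :-1] + bqq[:, :, 1:])
    return c


def _v_cycle(levels: list[_Level], li: int, phi: np.ndarray, b: np.ndarray, cfg: SolverConfig):
    level = levels[li]
    if li == len(levels) - 1:
        _sor_sweeps(level, phi, b, cfg.omega, cfg.coarse_sweeps)
        return
    _sor_sweeps(level, phi, b, cfg.omega, cfg.pre_sweeps)
    r = b - level.system.apply(phi)
    r[~level.system.active] = 0.0
    rc = _restrict(r)
    coarse = levels[li + 1]
    rc[~coarse.system.active] = 0.0
    act = coarse.system.active
    if act.any():
        rc[act] -= rc[act].mean()  # keep the singular Neumann system consistent
    ec = np.zeros_like(rc)
    _v_cycle(levels, li + 1, ec, rc, cfg)
    corr = _prolong(ec, level.system.node_shape)
    corr[~level.system.active] = 0.0
    phi += corr
    _sor_sweeps(level, phi, b, cfg.omega, cfg.post_sweeps)


def solve_potential(
    system: SpfdSystem,
    rhs: SourceConfiguration,
    config: SolverConfig | None = None,
    reference_node: tuple[int, int, int] | None = None,
) -> PotentialField:
    """Solve A phi = b to the configured relative residual.

    The pure-Neumann system is solved in its natural gauge (zero mean over
    conducting nodes); the potential is then shifted so phi = 0 exactly at
    ``reference_node`` when one is given.  Raises :class:`ConvergenceError`
    (carrying the residual history) if ``max_cycles`` is exceeded.
    """
    cfg = config or SolverConfig()
    b = rhs.dense(system.node_shape)
    if not np.all(system.active[tuple(rhs.nodes.T)]):
        raise ValueError("rhs injects current at air nodes")
    bnorm = float(np.linalg.norm(b))
    phi = np.zeros(system.node_shape)
    if bnorm == 0.0:
        return PotentialField(phi, system.spacing_mm, reference_node, 0, [])

    if system._hierarchy is None or getattr(system, "_hierarchy_levels", None) != cfg.levels:
        system._hierarchy = _build_hierarchy(system, cfg)
        system._hierarchy_levels = cfg.levels
    levels = system._hierarchy

    history: list[float] = []
    act = system.active
    for cycle in range(1, cfg.max_cycles + 1):
        _v_cycle(levels, 0, phi, b, cfg)
        phi[act] -= phi[act].mean()
        rel = float(np.linalg.norm(b - system.apply(phi)) / bnorm)
        history.append(rel)
        if rel <= cfg.tolerance:
            if reference_node is not None:
                phi = phi - phi[tuple(reference_node)]
                phi[~act] = 0.0
            return PotentialField(phi, system.spacing_mm, reference_node, cycle, history)
    raise ConvergenceError(
        f"multigrid did not reach {cfg.tolerance:g} in {cfg.max_cycles} cycles "
        f"(last relative residual {history[-1]:.3e})",
        history,
    )


# --------------------------------------------------------------------------
# derived fields
# --------------------------------------------------------------------------


def voxel_gradient(phi: np.ndarray, spacing_mm: float) -> np.ndarray:
    """Gradient of a nodal potential at voxel centers (V/m).

    The derivative along each axis is the mean of the forward differences on
    the voxel's four parallel edges, i.e. the central difference at the voxel
    center.  Returns an (nx, ny, nz, 3) array for an (nx+1, ny+1, nz+1) grid.
    """
    h_m = spacing_mm * 1e-3
    out_shape = tuple(d - 1 for d in phi.shape)
    g = np.empty(out_shape + (3,))
    dx = np.diff(phi, axis=0)
    g[..., 0] = 0.25 * (dx[:, :-1, :-1] + dx[:, 1:, :-1] + dx[:, :-1, 1:] + dx[:, 1:, 1:])
    dy = np.diff(phi, axis=1)
    g[..., 1] = 0.25 * (dy[:-1, :, :-1] + dy[1:, :, :-1] + dy[:-1, :, 1:] + dy[1:, :, 1:])
    dz = np.diff(phi, axis=2)
    g[..., 2] = 0.25 * (dz[:-1, :-1] + dz[1:, :-1] + dz[:-1, 1:] + dz[1:, 1:])
    return g / h_m


def current_density(vol: ConductivityVolume, field: PotentialField) -> CurrentDensityField:
    """Ohmic current density j = sigma E = -sigma grad(phi), per voxel."""
    expect = tuple(d + 1 for d in vol.sigma.shape)
    if field.phi.shape != expect:
        raise ValueError(f"potential grid {field.phi.shape} does not match volume {expect}")
    grad = voxel_gradient(field.phi, vol.spacing_mm)
    return CurrentDensityField(-vol.sigma[..., None] * grad, vol.spacing_mm)
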