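"""Lead-field matrix construction by reciprocity and by direct dipole solves.

The lead field L is the M x 3N gain matrix mapping the 3-component dipole
moment vector at each of N gray-matter voxels to the M electrode potentials,
phi = L j (V per A*m), with the reference electrode's row identically zero.

Reciprocity construction: injecting a unit current I between electrode m and
the reference and solving the SPFD once yields the electric field E_m inside
the head; row m of L is -E_m / I sampled at the source voxels.  Only M - 1
solves are needed, versus one solve per dipole component (3N) for the direct
construction - the latter is retained at small scale as a validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .forward import (
    SolverConfig,
    SpfdSystem,
    assemble_spfd,
    dipole_rhs,
    electrode_injection_rhs,
    solve_potential,
    voxel_gradient,
)
from .phantom import ConductivityVolume, ElectrodeSet

__all__ = [
    "LeadFieldMatrix",
    "build_leadfield_reciprocity",
    "build_leadfield_direct",
    "forward_project",
]

_DIRECT_COLUMN_GUARD = 10_000


@dataclass
class LeadFieldMatrix:
    """Gain matrix with its electrode and source-voxel bookkeeping.

    ``gain`` has shape (M, 3N); columns are voxel-major, component-minor
    (x, y, z), so column 3 v + a is component ``a`` of voxel ``voxel_indices[v]``.
    """

    gain: np.ndarray
    electrode_labels: list[str]
    reference_label: str
    voxel_indices: np.ndarray  # (N, 3)
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    current_amps: float = 1.0
    solve_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=int)
        if self.gain.shape != (len(self.electrode_labels), 3 * len(self.voxel_indices)):
            raise ValueError("gain shape does not match electrodes x 3 voxels")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain matrix contains non-finite entries")

    @property
    def n_electrodes(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return len(self.voxel_indices)

    def column_voxel_axis(self, col: int) -> tuple[np.ndarray, int]:
        return self.voxel_indices[col // 3], col % 3

    def column_coordinate_mm(self, col: int) -> np.ndarray:
        vox = self.voxel_indices[col // 3]
        return self.origin_mm + (vox + 0.5) * self.spacing_mm

    def source_coordinates_mm(self) -> np.ndarray:
        return self.origin_mm + (self.voxel_indices + 0.5) * self.spacing_mm

    def voxel_column_block(self, v: int) -> np.ndarray:
        return self.gain[:, 3 * v : 3 * v + 3]

    def project_dipole(self, voxel, moment: np.ndarray) -> np.ndarray:
        """Scalp potentials (V) of one dipole with ``moment`` (A*m) at ``voxel``."""
        voxel = np.asarray(voxel, dtype=int)
        hits = np.flatnonzero((self.voxel_indices == voxel).all(axis=1))
        if hits.size == 0:
            raise ValueError(f"voxel {tuple(voxel)} is not in the source space")
        return self.voxel_column_block(int(hits[0])) @ np.asarray(moment, dtype=float)

    # ---- persistence -----------------------------------------------------
    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("gain", data=self.gain, chunks=(1, self.gain.shape[1]))
            f.create_dataset("voxel_index", data=self.voxel_indices)
            f.attrs["spacing_mm"] = self.spacing_mm
            f.attrs["origin_mm"] = self.origin_mm
            f.attrs["reference"] = self.reference_label
            f.attrs["current_amps"] = self.current_amps
            f.create_dataset(
                "electrodes", data=np.array(self.electrode_labels, dtype=h5py.string_dtype())
            )

    @classmethod
    def load(cls, path: str) -> "LeadFieldMatrix":
        with h5py.File(path, "r") as f:
            return cls(
                gain=f["gain"][()],
                electrode_labels=[s.decode() for s in f["electrodes"][()]],
                reference_label=f.attrs["reference"],
                voxel_indices=f["voxel_index"][()],
                spacing_mm=float(f.attrs["spacing_mm"]),
                origin_mm=np.asarray(f.attrs["origin_mm"], dtype=float),
                current_amps=float(f.attrs["current_amps"]),
            )

    @staticmethod
    def load_row(path: str, row: int) -> np.ndarray:
        """Fetch a single electrode row without loading the whole gain."""
        with h5py.File(path, "r") as f:
            return f["gain"][row, :]


def _mask_voxels(vol: ConductivityVolume, voxel_subset) -> np.ndarray:
    if voxel_subset is None:
        vox = np.argwhere(vol.gray_matter_mask)
        if vox.size == 0:
            raise ValueError("volume has an empty gray-matter mask")
        return vox
    return np.atleast_2d(np.asarray(voxel_subset, dtype=int))


def build_leadfield_reciprocity(
    vol: ConductivityVolume,
    electrodes: ElectrodeSet,
    voxel_subset=None,
    config: SolverConfig | None = None,
    current_amps: float = 1.0,
    system: SpfdSystem | None = None,
) -> LeadFieldMatrix:
    """Build L with one SPFD injection solve per non-reference electrode.

    For each electrode m, a current ``current_amps`` is injected between m
    and the reference; row m is -E_m / I at the source voxels (E sampled at
    voxel centers by central differences of the nodal potential).  The
    reference row is identically zero.
    """
    sysm = system if system is not None else assemble_spfd(vol)
    vox = _mask_voxels(vol, voxel_subset)
    vidx = tuple(vox.T)
    gain = np.zeros((len(electrodes), 3 * len(vox)))
    log: list[dict] = []
    for m, lab in enumerate(electrodes.labels):
        if lab == electrodes.reference_label:
            continue
        rhs = electrode_injection_rhs(sysm, electrodes, lab, current_amps)
        try:
            pf = solve_potential(sysm, rhs, config)
        except Exception as exc:
            raise RuntimeError(f"forward solve failed for electrode {lab}") from exc
        grad = voxel_gradient(pf.phi, vol.spacing_mm)  # = -E
        gain[m] = (grad[vidx] / current_amps).ravel()
        log.append({"electrode": lab, "cycles": pf.cycles, "residual": pf.relative_residual})
    return LeadFieldMatrix(
        gain,
        electrodes.labels,
        electrodes.reference_label,
        vox,
        vol.spacing_mm,
        vol.origin_mm.copy(),
        current_amps,
        log,
    )


def build_leadfield_direct(
    vol: ConductivityVolume,
    electrodes: ElectrodeSet,
    voxel_subset=None,
    config: SolverConfig | None = None,
    system: SpfdSystem | None = None,
) -> LeadFieldMatrix:
    """Brute-force L: one SPFD solve per (voxel, axis) elementary dipole.

    Row m of each column is the potential at electrode m minus the potential
    at the reference.  Computationally prohibitive at full scale; guarded to
    small source subsets and used as the validation oracle for the
    reciprocity construction.
    """
    sysm = system if system is not None else assemble_spfd(vol)
    vox = _mask_voxels(vol, voxel_subset)
    if 3 * len(vox) > _DIRECT_COLUMN_GUARD:
        raise ValueError(
            f"{3 * len(vox)} columns exceed the direct-construction guard "
            f"({_DIRECT_COLUMN_GUARD}); use build_leadfield_reciprocity"
        )
    nodes = electrodes.node_indices
    ref_node = tuple(nodes[electrodes.index_of(electrodes.reference_label)])
    gain = np.zeros((len(electrodes), 3 * len(vox)))
    log: list[dict] = []
    for v, voxel in enumerate(vox):
        for axis in range(3):
            rhs = dipole_rhs(sysm, tuple(voxel), axis, moment=1.0)
            pf = solve_potential(sysm, rhs, config)
            phi_e = pf.phi[tuple(nodes.T)] - pf.phi[ref_node]
            gain[:, 3 * v + axis] = phi_e
            log.append({"voxel": tuple(int(x) for x in voxel), "axis": axis, "cycles": pf.cycles})
    return LeadFieldMatrix(
        gain,
        electrodes.labels,
        electrodes.reference_label,
        vox,
        vol.spacing_mm,
        vol.origin_mm.copy(),
        1.0,
        log,
    )


def forward_project(L: LeadFieldMatrix, source_vector: np.ndarray) -> np.ndarray:
    """Scalp potentials phi = L j for a full 3N source vector (A*m)."""
    j = np.asarray(source_vector, dtype=float)
    if j.shape != (L.gain.shape[1],):
        raise ValueError(f"source vector length {j.shape} does not match 3N={L.gain.shape[1]}")
    return L.gain @ j
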