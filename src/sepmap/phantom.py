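"""Synthetic spherical head phantoms, electrode layouts and SEP simulation.

Every downstream stage (forward solver, lead fields, inverse solvers,
evaluation) is exercised on phantoms built here, so no human MRI or EEG data
are needed.  Two model classes are supported, mirroring the two head-model
families the pipeline is designed to compare:

* *piecewise (segmented-style)* models: concentric spherical layers, each with
  a homogeneous conductivity (e.g. brain / skull / scalp);
* *smoothly varying (segmentation-free-style)* models: the same phantom after
  Gaussian smoothing of the conductivity restricted to the head support,
  emulating voxel-wise conductivity maps without hard tissue boundaries.

Conductivities are in S/m on an isotropic voxel grid (spacing in mm); air is
exactly 0 S/m and acts as a natural insulating boundary for the solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .preprocess import EpochSet

__all__ = [
    "PhantomSpec",
    "ConductivityVolume",
    "ElectrodeSet",
    "Electrode",
    "ColeColeParams",
    "PlantedSource",
    "build_layered_sphere",
    "smooth_conductivity",
    "cole_cole_conductivity",
    "place_electrodes",
    "ten_ten_layout",
    "fibonacci_layout",
    "simulate_sep_dataset",
    "gaussian_bump",
    "noise_sd_for_snr",
]

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m

# Default skin conductivity (S/m); chosen to avoid overestimating the
# contribution of the stratum corneum.
SKIN_CONDUCTIVITY = 0.1


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Concentric-sphere phantom description.

    ``layer_radii`` are listed inner -> outer in mm and must be strictly
    increasing; ``layer_conductivities`` follow the same order.  The gray
    matter source shell is the part of the innermost layer whose radius lies
    in ``gm_shell_frac`` times the innermost radius.
    """

    layer_radii: tuple[float, ...]
    layer_conductivities: tuple[float, ...]
    grid_shape: tuple[int, int, int]
    spacing_mm: float
    center_mm: tuple[float, float, float] | None = None
    gm_shell_frac: tuple[float, float] = (0.45, 0.85)

    def __post_init__(self) -> None:
        radii = np.asarray(self.layer_radii, dtype=float)
        cond = np.asarray(self.layer_conductivities, dtype=float)
        if radii.ndim != 1 or radii.size == 0:
            raise ValueError("need at least one layer radius")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("layer radii must be strictly increasing (inner -> outer)")
        if cond.shape != radii.shape:
            raise ValueError("one conductivity per layer required")
        if np.any(cond < 0):
            raise ValueError("conductivities must be >= 0")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.center_mm is None:
            self.center_mm = tuple(0.5 * self.spacing_mm * n for n in self.grid_shape)

    @property
    def outer_radius_mm(self) -> float:
        return float(self.layer_radii[-1])


@dataclass
class ConductivityVolume:
    """Voxel-wise conductivity field (S/m) plus the gray-matter source mask."""

    sigma: np.ndarray
    spacing_mm: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gray_matter_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 3:
            raise ValueError("sigma must be a 3-D array")
        if np.any(self.sigma < 0):
            raise ValueError("conductivity must be non-negative")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.gray_matter_mask is None:
            self.gray_matter_mask = np.zeros(self.sigma.shape, dtype=bool)
        self.gray_matter_mask = np.asarray(self.gray_matter_mask, dtype=bool)
        if self.gray_matter_mask.shape != self.sigma.shape:
            raise ValueError("mask and sigma shapes differ")
        if np.any(self.gray_matter_mask & (self.sigma == 0)):
            raise ValueError("gray-matter mask must lie inside the conducting head")

    @property
    def head_mask(self) -> np.ndarray:
        return self.sigma > 0

    def voxel_centers_mm(self, indices: np.ndarray) -> np.ndarray:
        """mm coordinates of voxel centers for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin_mm + (idx + 0.5) * self.spacing_mm

    def node_coords_mm(self, indices: np.ndarray) -> np.ndarray:
        """mm coordinates of grid nodes (voxel corners) for an (n, 3) index array."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin_mm + idx * self.spacing_mm

    # ---- NIfTI round trip ------------------------------------------------
    def to_nifti(self, path: str, mask_path: str | None = None) -> None:
        affine = np.diag([self.spacing_mm] * 3 + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.sigma.astype(np.float32), affine), path)
        if mask_path is not None:
            nib.save(
                nib.Nifti1Image(self.gray_matter_mask.astype(np.uint8), affine), mask_path
            )

    @classmethod
    def from_nifti(cls, path: str, mask_path: str | None = None) -> "ConductivityVolume":
        img = nib.load(path)
        spacing = float(img.header.get_zooms()[0])
        sigma = np.asarray(img.dataobj, dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        mask = None
        if mask_path is not None:
            mask = np.asarray(nib.load(mask_path).dataobj) > 0
        return cls(sigma, spacing, origin, mask)


@dataclass
class Electrode:
    label: str
    position_mm: np.ndarray
    node_index: tuple[int, int, int]
    role: str = "eeg"


@dataclass
class ElectrodeSet:
    """Labeled scalp electrodes snapped to outer-surface grid nodes."""

    electrodes: list[Electrode]
    reference_label: str

    def __post_init__(self) -> None:
        labels = [e.label for e in self.electrodes]
        if len(set(labels)) != len(labels):
            raise ValueError("electrode labels must be unique")
        if labels.count(self.reference_label) != 1 or self.reference_label not in labels:
            raise ValueError("exactly one reference electrode required")

    def __len__(self) -> int:
        return len(self.electrodes)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.electrodes]

    @property
    def positions_mm(self) -> np.ndarray:
        return np.array([e.position_mm for e in self.electrodes])

    @property
    def node_indices(self) -> np.ndarray:
        return np.array([e.node_index for e in self.electrodes], dtype=int)

    def node_flat(self, node_shape: tuple[int, int, int]) -> np.ndarray:
        return np.ravel_multi_index(self.node_indices.T, node_shape)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def to_tsv(self, path: str) -> None:
        rows = [
            {
                "label": e.label,
                "x_mm": e.position_mm[0],
                "y_mm": e.position_mm[1],
                "z_mm": e.position_mm[2],
                "role": "ref" if e.label == self.reference_label else "eeg",
            }
            for e in self.electrodes
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ColeColeParams:
    """Parameters of the 4-term Cole-Cole dispersive tissue model.

    ``terms`` is a sequence of (delta_eps, tau_s, alpha) dispersion terms
    (at most four); ``ionic_conductivity`` is the static ionic term in S/m.
    """

    eps_inf: float
    terms: tuple[tuple[float, float, float], ...]
    ionic_conductivity: float

    def __post_init__(self) -> None:
        if len(self.terms) > 4:
            raise ValueError("at most four dispersion terms supported")
        for _, tau, alpha in self.terms:
            if tau <= 0:
                raise ValueError("relaxation time tau must be positive")
            if not (0 <= alpha < 1):
                raise ValueError("alpha must lie in [0, 1)")
        if self.ionic_conductivity < 0:
            raise ValueError("ionic conductivity must be >= 0")


@dataclass
class PlantedSource:
    """A focal dipolar source planted in the gray-matter shell."""

    voxel: tuple[int, int, int]
    moment: np.ndarray  # A*m, 3 components
    target_label: str = "source"
    time_course: "object | None" = None  # callable t_ms -> amplitude; default P20 bump

    def __post_init__(self) -> None:
        self.moment = np.asarray(self.moment, dtype=float)
        if self.moment.shape != (3,):
            raise ValueError("moment must have 3 components")
        if np.linalg.norm(self.moment) == 0:
            raise ValueError("moment must be non-zero")


def gaussian_bump(peak_ms: float = 20.0, sigma_ms: float = 2.0):
    """Unit-amplitude Gaussian time course peaking in the P20/N20 window."""

    def course(t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        return np.exp(-0.5 * ((t - peak_ms) / sigma_ms) ** 2)

    return course


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------


def build_layered_sphere(spec: PhantomSpec) -> ConductivityVolume:
    """Assign each voxel the conductivity of the innermost layer containing
    its center (no partial-volume averaging); air voxels stay exactly 0.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    spacing = float(spec.spacing_mm)
    center = np.asarray(spec.center_mm, dtype=float)
    outer = spec.outer_radius_mm
    box = np.asarray(shape) * spacing
    lo = center - (outer + spacing)
    hi = center + (outer + spacing)
    if np.any(lo < 0) or np.any(hi > box):
        raise ValueError(
            f"outer sphere radius {outer} mm (plus one voxel margin) does not fit "
            f"in the {shape} grid at {spacing} mm spacing"
        )

    idx = [np.arange(n) + 0.5 for n in shape]
    xx = idx[0][:, None, None] * spacing - center[0]
    yy = idx[1][None, :, None] * spacing - center[1]
    zz = idx[2][None, None, :] * spacing - center[2]
    r = np.sqrt(xx**2 + yy**2 + zz**2)

    radii = np.asarray(spec.layer_radii, dtype=float)
    cond = np.asarray(spec.layer_conductivities, dtype=float)
    layer = np.searchsorted(radii, r)  # innermost layer whose radius >= r
    sigma = np.where(layer < radii.size, cond[np.minimum(layer, radii.size - 1)], 0.0)

    r_in = radii[0]
    lof, hif = spec.gm_shell_frac
    mask = (r >= lof * r_in) & (r <= hif * r_in) & (sigma > 0) & (layer == 0)
    return ConductivityVolume(sigma, spacing, np.zeros(3), mask)


def smooth_conductivity(vol: ConductivityVolume, fwhm_mm: float) -> ConductivityVolume:
    """Gaussian-smoothed conductivity restricted to the head support.

    The kernel is renormalized at the head boundary (division by the smoothed
    support indicator) so conductivity never leaks into air and air voxels
    stay exactly 0.  This emulates a smoothly varying, segmentation-free
    conductivity map from a piecewise phantom.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return ConductivityVolume(
            vol.sigma.copy(), vol.spacing_mm, vol.origin_mm.copy(), vol.gray_matter_mask.copy()
        )
    sigma_vox = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / vol.spacing_mm
    support = vol.head_mask.astype(float)
    num = ndimage.gaussian_filter(vol.sigma, sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(support, sigma_vox, mode="constant")
    out = np.zeros_like(vol.sigma)
    inside = vol.head_mask
    out[inside] = num[inside] / den[inside]
    out = np.maximum(out, 0.0)
    return ConductivityVolume(out, vol.spacing_mm, vol.origin_mm.copy(), vol.gray_matter_mask.copy())


def cole_cole_conductivity(params: ColeColeParams, freq_hz: float = 10.0) -> float:
    """Effective (real) conductivity of the Cole-Cole model at ``freq_hz``.

    The complex conductivity is sigma*(w) = sigma_i + j w eps0 eps*(w) with
    eps*(w) = eps_inf + sum_k d_eps_k / (1 + (j w tau_k)^(1-alpha_k)); the
    returned value is Re(sigma*), i.e. the ionic term plus the dispersive
    loss.  The pipeline default evaluation frequency is 10 Hz.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    w = 2.0 * math.pi * freq_hz
    eps = complex(params.eps_inf)
    for d_eps, tau, alpha in params.terms:
        eps += d_eps / (1.0 + (1j * w * tau) ** (1.0 - alpha))
    sigma_star = params.ionic_conductivity + 1j * w * EPS0 * eps
    return float(sigma_star.real)


# --------------------------------------------------------------------------
# electrode layouts
# --------------------------------------------------------------------------


def _sph(inc_deg: float, az_deg: float) -> np.ndarray:
    """Unit vector at inclination from vertex (+z) and azimuth from anterior (+y),
    positive toward the right (+x)."""
    inc = math.radians(inc_deg)
    az = math.radians(az_deg)
    return np.array([math.sin(inc) * math.sin(az), math.sin(inc) * math.cos(az), math.cos(inc)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    ang = math.acos(np.clip(float(a @ b), -1.0, 1.0))
    if ang < 1e-12:
        return a.copy()
    return (math.sin((1 - t) * ang) * a + math.sin(t * ang) * b) / math.sin(ang)


def ten_ten_layout() -> list[tuple[str, np.ndarray]]:
    """Deterministic 65-label layout approximating the International 10/10
    system on a sphere (vertex = Cz at +z, anterior = +y, right = +x).

    The outer ring (20 electrodes) sits 72 deg from the vertex at 18 deg
    azimuth steps; interior rows are placed by great-circle interpolation
    between the ring electrodes and the corresponding midline electrode.
    Four inferior temporal electrodes (FT9/FT10/TP9/TP10) complete 65.
    No fiducial-based scalp geometry is implied - only count and topology.
    """
    pts: dict[str, np.ndarray] = {}
    ring = [
        "Fpz", "Fp2", "AF8", "F8", "FT8", "T8", "TP8", "P8", "PO8", "O2",
        "Oz", "O1", "PO7", "P7", "TP7", "T7", "FT7", "F7", "AF7", "Fp1",
    ]
    for k, lab in enumerate(ring):
        pts[lab] = _sph(72.0, 18.0 * k)
    midline = {"AFz": 54.0, "Fz": 36.0, "FCz": 18.0, "Cz": 0.0}
    for lab, inc in midline.items():
        pts[lab] = _sph(inc, 0.0)
    for lab, inc in {"CPz": 18.0, "Pz": 36.0, "POz": 54.0}.items():
        pts[lab] = _sph(inc, 180.0)

    def row(left: str, mid: str, right: str, names_left: list[str], names_right: list[str]):
        nL = len(names_left)
        for i, lab in enumerate(names_left):
            pts[lab] = _slerp(pts[mid], pts[left], (i + 1) / (nL + 1))
        for i, lab in enumerate(names_right):
            pts[lab] = _slerp(pts[mid], pts[right], (i + 1) / (len(names_right) + 1))

    row("AF7", "AFz", "AF8", ["AF3"], ["AF4"])
    row("F7", "Fz", "F8", ["F1", "F3", "F5"], ["F2", "F4", "F6"])
    row("FT7", "FCz", "FT8", ["FC1", "FC3", "FC5"], ["FC2", "FC4", "FC6"])
    row("T7", "Cz", "T8", ["C1", "C3", "C5"], ["C2", "C4", "C6"])
    row("TP7", "CPz", "TP8", ["CP1", "CP3", "CP5"], ["CP2", "CP4", "CP6"])
    row("P7", "Pz", "P8", ["P1", "P3", "P5"], ["P2", "P4", "P6"])
    row("PO7", "POz", "PO8", ["PO3"], ["PO4"])
    for lab, az in {"FT9": -54.0, "FT10": 54.0, "TP9": -126.0, "TP10": 126.0}.items():
        pts[lab] = _sph(90.0, az)
    assert len(pts) == 65
    return [(lab, v) for lab, v in pts.items()]


def fibonacci_layout(n: int, cap_deg: float = 100.0) -> list[tuple[str, np.ndarray]]:
    """n electrodes on a golden-angle spiral over the upper spherical cap."""
    golden = math.pi * (3.0 - math.sqrt(5.0))
    zmin = math.cos(math.radians(cap_deg))
    out = []
    for k in range(n):
        z = 1.0 - (k + 0.5) / n * (1.0 - zmin)
        r = math.sqrt(max(0.0, 1.0 - z * z))
        th = golden * k
        out.append((f"E{k + 1:02d}", np.array([r * math.cos(th), r * math.sin(th), z])))
    return out


def _surface_nodes(vol: ConductivityVolume) -> np.ndarray:
    """Node indices on the outer conductor surface: nodes touching at least one
    conducting voxel and at least one air voxel (grid boundary counts as air)."""
    cond = vol.head_mask
    padded_c = np.pad(cond, 1, constant_values=False)
    padded_a = np.pad(~cond, 1, constant_values=True)
    nx, ny, nz = cond.shape
    has_c = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    has_a = np.zeros((nx + 1, ny + 1, nz + 1), dtype=bool)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                sl = (slice(dx, dx + nx + 1), slice(dy, dy + ny + 1), slice(dz, dz + nz + 1))
                has_c |= padded_c[sl]
                has_a |= padded_a[sl]
    return np.argwhere(has_c & has_a)


def place_electrodes(
    vol: ConductivityVolume,
    layout: "str | list[tuple[str, np.ndarray]]" = "10-10",
    n_electrodes: int | None = None,
    reference: str | None = None,
    center_mm: np.ndarray | None = None,
    radius_mm: float | None = None,
) -> ElectrodeSet:
    """Place a labeled electrode layout on the phantom's outer surface.

    Ideal positions on the sphere of ``radius_mm`` around ``center_mm``
    (defaults: head centroid and maximal head radius) are snapped to the
    nearest outer-surface grid node.  Errors if two electrodes snap to the
    same node or an electrode ends up farther than one voxel diagonal from
    its ideal position's surface projection.
    """
    if isinstance(layout, str):
        if layout == "10-10":
            entries = ten_ten_layout()
            if n_electrodes is not None and n_electrodes != 65:
                raise ValueError("the 10-10 layout has exactly 65 electrodes")
            ref = reference or "Cz"
        elif layout == "fibonacci":
            if n_electrodes is None:
                raise ValueError("n_electrodes required for the fibonacci layout")
            entries = fibonacci_layout(n_electrodes)
            ref = reference or entries[0][0]
        else:
            raise ValueError(f"unknown layout {layout!r}")
    else:
        entries = layout
        ref = reference or entries[0][0]

    labels = [lab for lab, _ in entries]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate electrode labels in layout")

    head = vol.head_mask
    if not head.any():
        raise ValueError("volume contains no conductor")
    vox = np.argwhere(head)
    centers = vol.voxel_centers_mm(vox)
    if center_mm is None:
        center_mm = centers.mean(axis=0)
    if radius_mm is None:
        radius_mm = float(np.linalg.norm(centers - center_mm, axis=1).max())

    surf = _surface_nodes(vol)
    tree = cKDTree(vol.node_coords_mm(surf))
    max_snap = math.sqrt(3.0) * vol.spacing_mm + 1e-9

    electrodes: list[Electrode] = []
    taken: dict[int, str] = {}
    for lab, u in entries:
        ideal = center_mm + radius_mm * np.asarray(u, dtype=float)
        dist, j = tree.query(ideal)
        if dist > max_snap + vol.spacing_mm:
            raise ValueError(f"electrode {lab} is {dist:.1f} mm from the head surface")
        if int(j) in taken:
            raise ValueError(
                f"electrodes {taken[int(j)]} and {lab} snap to the same surface node"
            )
        taken[int(j)] = lab
        node = tuple(int(v) for v in surf[j])
        electrodes.append(
            Electrode(lab, vol.node_coords_mm([node])[0], node, "ref" if lab == ref else "eeg")
        )
    return ElectrodeSet(electrodes, ref)


# --------------------------------------------------------------------------
# SEP simulation
# --------------------------------------------------------------------------


def noise_sd_for_snr(
    clean_window_vec: np.ndarray, snr_db: float, n_trials: int, n_window_samples: int
) -> float:
    """Per-sample sensor-noise SD giving the requested evoked SNR.

    The evoked SNR is defined on the trial-averaged, window-averaged scalp
    vector: SNR_dB = 20 log10(rms(clean) / sd(noise after averaging)); the
    averaging over ``n_trials`` trials and ``n_window_samples`` samples
    reduces the per-sample SD by sqrt(n_trials * n_window_samples).
    """
    rms = float(np.sqrt(np.mean(np.square(clean_window_vec))))
    return rms * math.sqrt(n_trials * n_window_samples) / (10.0 ** (snr_db / 20.0))


def simulate_sep_dataset(
    vol: ConductivityVolume,
    electrodes: ElectrodeSet,
    sources: list[PlantedSource],
    leadfield,
    noise_sd: float,
    n_trials: int,
    seed: int,
    fs_hz: float = 2000.0,
    epoch_ms: float = 500.0,
    prestim_ms: float = 100.0,
) -> EpochSet:
    """Simulate trial-wise SEP epochs: lead-field projection of the planted
    sources' time courses plus i.i.d. Gaussian sensor noise.

    Defaults follow the SEP recording protocol: 2 kHz sampling, 500 ms
    epochs with a 100 ms pre-stimulus baseline (noise only).  Output is in
    uV.  Fixed ``seed`` gives bit-identical output.
    """
    n_samp = int(round(epoch_ms * fs_hz / 1000.0))
    n_pre = int(round(prestim_ms * fs_hz / 1000.0))
    t_ms = (np.arange(n_samp) - n_pre) * 1000.0 / fs_hz

    clean = np.zeros((len(electrodes), n_samp))
    for src in sources:
        if not vol.gray_matter_mask[src.voxel]:
            raise ValueError(f"source at voxel {src.voxel} is outside the gray-matter mask")
        topo = leadfield.project_dipole(src.voxel, src.moment) * 1e6  # V -> uV
        course = src.time_course or gaussian_bump()
        amp = np.where(t_ms >= 0, course(t_ms), 0.0)
        clean += topo[:, None] * amp[None, :]

    rng = np.random.default_rng(seed)
    data = clean[None, :, :] + rng.normal(0.0, noise_sd, size=(n_trials, clean.shape[0], n_samp))
    return EpochSet(
        data=data,
        fs_hz=fs_hz,
        t0_ms=prestim_ms,
        channels=electrodes.labels,
        meta={"seed": seed, "noise_sd": noise_sd, "n_sources": len(sources)},
    )
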