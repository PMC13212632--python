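"""Analytic dipole potentials in multi-layer concentric spheres.

Ground truth for the SPFD forward solver: the quasi-static potential of a
current dipole inside concentric spherical shells of piecewise-constant
conductivity, evaluated on the outer surface as a Legendre series.  Per
harmonic degree n the radial solution in every layer is a_n rho^n +
b_n rho^-(n+1); the coefficients follow from continuity of potential and
radial current at each interface and the insulating outer boundary, solved
as a small linear system per degree.  Also provides the standard
forward-model discrepancy metrics RDM (topography mismatch) and MAG
(magnitude ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphereModel", "analytic_sphere_potential", "rdm_mag"]


@dataclass
class SphereModel:
    """Concentric-sphere conductor: radii mm (innermost first, strictly
    increasing) and the conductivity of each shell in S/m."""

    radii_mm: tuple[float, ...]
    conductivities: tuple[float, ...]
    n_max: int = 60
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_mm, dtype=float)
        s = np.asarray(self.conductivities, dtype=float)
        if r.size == 0 or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing, innermost first")
        if s.shape != r.shape or np.any(s <= 0):
            raise ValueError("each layer needs a positive conductivity")
        if self.n_max < 1:
            raise ValueError("series needs at least one term")


def _surface_response(model: SphereModel, n: int) -> float:
    """Outer-surface potential per unit source harmonic of degree n.

    Works in radii normalized by the outer radius.  The primary (source)
    term in layer 1 is scaled to (u1/u)^(n+1) so all matrix entries are
    O(1); the returned factor is the surface value per unit of the raw
    u^-(n+1) source harmonic, i.e. includes the u1^-(n+1) rescaling.
    """
    u = np.asarray(model.radii_mm, dtype=float) / model.radii_mm[-1]
    sig = np.asarray(model.conductivities, dtype=float)
    L = len(u)
    if L == 1:
        return (2 * n + 1) / n
    # unknowns: a_1, then (a_i, b_i) for i = 2..L  -> 2L - 1
    # layer i potential: a_i (rho/u_i)^n + b_i (u_{i-1}/rho)^(n+1)  (b_1 = 0)
    m = 2 * L - 1
    A = np.zeros((m, m))
    rhs = np.zeros(m)

    def col_a(i):  # layer index 1-based
        return 0 if i == 1 else 2 * i - 3

    def col_b(i):
        return 2 * i - 2

    row = 0
    for i in range(1, L):  # interface between layer i and i+1 at u[i-1]
        ui = u[i - 1]
        lo_prev = u[i - 2] if i >= 2 else 0.0
        # potential continuity
        A[row, col_a(i)] += (ui / u[i - 1]) ** n  # = 1
        if i >= 2:
            A[row, col_b(i)] += (lo_prev / ui) ** (n + 1)
        A[row, col_a(i + 1)] -= (ui / u[i]) ** n
        A[row, col_b(i + 1)] -= 1.0  # (u_i / u_i)^(n+1) at its inner radius
        if i == 1:
            rhs[row] = -1.0  # scaled source value (u1/u1)^(n+1)
        row += 1
        # radial current continuity: sigma * d(phi)/d(rho)
        A[row, col_a(i)] += sig[i - 1] * n / ui
        if i >= 2:
            A[row, col_b(i)] -= sig[i - 1] * (n + 1) * (lo_prev / ui) ** (n + 1) / ui
        A[row, col_a(i + 1)] -= sig[i] * n * (ui / u[i]) ** n / ui
        A[row, col_b(i + 1)] += sig[i] * (n + 1) / ui
        if i == 1:
            rhs[row] = sig[0] * (n + 1) / ui  # -sigma1 * d/drho[(u1/rho)^(n+1)]
        row += 1
    # insulating outer boundary at u = 1
    A[row, col_a(L)] += n
    A[row, col_b(L)] -= (n + 1) * (u[L - 2] if L >= 2 else 0.0) ** (n + 1)
    coef = np.linalg.solve(A, rhs)
    surface = coef[col_a(L)] + coef[col_b(L)] * u[L - 2] ** (n + 1)
    return float(surface) * u[0] ** -(n + 1)


def analytic_sphere_potential(
    model: SphereModel,
    dipole_position_mm: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_positions_mm: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Surface potentials (V) of a dipole (A*m) inside the sphere model.

    Electrode positions are projected radially onto the outer surface.
    Returns ``(potentials, truncation_error_estimate)``; the estimate is the
    geometric-tail bound of the first neglected term.  The dipole must lie
    strictly inside the innermost shell.
    """
    r0 = np.asarray(dipole_position_mm, dtype=float)
    p = np.asarray(dipole_moment, dtype=float)
    elec = np.atleast_2d(np.asarray(electrode_positions_mm, dtype=float))
    R = float(model.radii_mm[-1])
    r1 = float(model.radii_mm[0])
    b = float(np.linalg.norm(r0))
    if b >= r1:
        raise ValueError(f"dipole at radius {b:.2f} mm is not inside the innermost shell ({r1} mm)")
    sig1 = float(model.conductivities[0])
    e_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)

    if b < 1e-12 * R:
        # center dipole: only n = 1 survives; phi = t1 * (p . e_hat) / (4 pi sig1 R^2)
        t1 = _surface_response(model, 1)
        pots = t1 * (e_hat @ p) / (4.0 * np.pi * sig1 * (R * 1e-3) ** 2)
        return pots, 0.0

    r0_hat = r0 / b
    cosg = np.clip(e_hat @ r0_hat, -1.0, 1.0)
    sing = np.sqrt(np.maximum(0.0, 1.0 - cosg**2))
    # tangential unit vector in each electrode's meridian plane
    t_vec = e_hat - cosg[:, None] * r0_hat[None, :]
    t_norm = np.linalg.norm(t_vec, axis=1)
    ok = t_norm > 1e-12
    t_hat = np.zeros_like(t_vec)
    t_hat[ok] = t_vec[ok] / t_norm[ok, None]
    p_r = float(p @ r0_hat)
    p_t = t_hat @ p

    f = b / R
    u1 = r1 / R
    ratio = f / u1  # per-term geometric decay of the source seen at interface 1

    # Legendre recurrences on cos(gamma)
    P_nm1 = np.ones_like(cosg)  # P_0
    P_n = cosg.copy()  # P_1
    dP_n = np.ones_like(cosg)  # P_1'
    total = np.zeros(len(e_hat))
    scale = 1.0 / (4.0 * np.pi * sig1 * (R * 1e-3) ** 2)
    tail = np.inf
    last_term_norm = 0.0
    for n in range(1, model.n_max + 1):
        v_n = _surface_response(model, n) * u1 ** (n + 1)  # O(1) response
        geom = ratio ** (n - 1) * u1 ** -2
        term = v_n * geom * (n * p_r * P_n + p_t * sing * dP_n)
        total += term
        last_term_norm = float(np.linalg.norm(term))
        if last_term_norm <= model.tolerance * max(np.linalg.norm(total), 1e-300) and n >= 5:
            tail = last_term_norm * ratio / max(1e-12, 1.0 - ratio)
            break
        # advance recurrences to degree n+1
        P_np1 = ((2 * n + 1) * cosg * P_n - n * P_nm1) / (n + 1)
        dP_np1 = (n + 1) * P_n + cosg * dP_n
        P_nm1, P_n, dP_n = P_n, P_np1, dP_np1
    else:
        tail = last_term_norm * ratio / max(1e-12, 1.0 - ratio)
    return total * scale, float(tail * scale)


def rdm_mag(reference_potentials: np.ndarray, test_potentials: np.ndarray) -> tuple[float, float]:
    """Relative difference measure and magnitude ratio between two forward
    solutions: RDM = ||a/||a|| - b/||b|| ||, MAG = ||b|| / ||a||."""
    a = np.asarray(reference_potentials, dtype=float)
    bv = np.asarray(test_potentials, dtype=float)
    if a.shape != bv.shape:
        raise ValueError("potential vectors must have equal length")
    na = np.linalg.norm(a)
    if na == 0:
        raise ValueError("reference potentials are identically zero")
    nb = np.linalg.norm(bv)
    if nb == 0:
        return float(np.sqrt(2.0)), 0.0
    return float(np.linalg.norm(a / na - bv / nb)), float(nb / na)
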