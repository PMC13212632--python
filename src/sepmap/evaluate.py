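"""Localization accuracy and somatotopic-ordering statistics.

Accuracy is the Euclidean distance (mm) between each estimated source
coordinate and its reference coordinate, summarized per stimulation target
as mean +/- sample SD, with per-axis SDs exported as ellipsoid radii.
Somatotopic ordering across the five fingers is tested by ordinary
least-squares regression of the per-finger mean coordinate against the
finger index (1 = thumb ... 5 = little) on the lateral-medial and
superior-inferior axes, with Pearson R and a two-tailed p value from the
exact t distribution (n - 2 df).  No multiple-comparison correction is
applied: only two predefined anatomical axes are tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LocalizationResult",
    "SomatotopyFit",
    "TARGET_ORDER",
    "FINGER_ORDER",
    "localization_error",
    "read_reference_coordinates",
    "summarize_by_target",
    "somatotopy_regression",
]

TARGET_ORDER = ["Median", "Ulnar", "Thumb", "Index", "Middle", "Ring", "Little"]
FINGER_ORDER = ["Thumb", "Index", "Middle", "Ring", "Little"]
_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class LocalizationResult:
    """One subject x target x method localization outcome."""

    subject: str
    target: str
    method: str
    estimated_mm: np.ndarray
    reference_mm: np.ndarray

    def __post_init__(self) -> None:
        self.estimated_mm = np.asarray(self.estimated_mm, dtype=float)
        self.reference_mm = np.asarray(self.reference_mm, dtype=float)

    @property
    def distance_mm(self) -> float:
        return localization_error(self.estimated_mm, self.reference_mm)


def localization_error(estimated_mm, reference_mm) -> float:
    """Euclidean distance (mm) between estimated and reference coordinates."""
    a = np.asarray(estimated_mm, dtype=float)
    b = np.asarray(reference_mm, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("coordinates must be 3-vectors")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - b))


def read_reference_coordinates(path: str) -> dict[str, np.ndarray]:
    """Read per-target reference coordinates from a CSV with columns
    ``target, x_mm, y_mm, z_mm``.  References are inputs, not constants:
    literature coordinates only apply to the space they were reported in."""
    df = pd.read_csv(path)
    missing = {"target", "x_mm", "y_mm", "z_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV lacks columns: {sorted(missing)}")
    return {
        str(row.target): np.array([row.x_mm, row.y_mm, row.z_mm], dtype=float)
        for row in df.itertuples()
    }


def _sd(x: np.ndarray) -> float:
    # sample (n-1) SD; a single observation reports SD 0 by convention
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def summarize_by_target(
    results: list[LocalizationResult], targets: list[str] | None = None
) -> pd.DataFrame:
    """Per (target, method) distance and coordinate summary.

    Rows follow the canonical target order (Median, Ulnar, Thumb ... Little)
    with unknown targets appended.  Requested targets with no results are
    omitted with a warning.
    """
    if not results:
        raise ValueError("no localization results to summarize")
    rows = []
    seen = {(r.target, r.method) for r in results}
    if targets is not None:
        for t in targets:
            if not any(t == tt for tt, _ in seen):
                warnings.warn(f"no results for target {t!r}; omitted", RuntimeWarning)
    order = {t: i for i, t in enumerate(TARGET_ORDER)}
    keys = sorted(seen, key=lambda tm: (order.get(tm[0], len(order)), tm[0], tm[1]))
    for target, method in keys:
        grp = [r for r in results if r.target == target and r.method == method]
        d = np.array([g.distance_mm for g in grp])
        est = np.array([g.estimated_mm for g in grp])
        row = {
            "target": target,
            "method": method,
            "n": len(grp),
            "mean_distance_mm": float(d.mean()),
            "sd_distance_mm": _sd(d),
        }
        for ax, name in enumerate("xyz"):
            row[f"mean_{name}_mm"] = float(est[:, ax].mean())
            row[f"sd_{name}_mm"] = _sd(est[:, ax])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SomatotopyFit:
    """Linear trend of one coordinate axis against the finger index."""

    axis: str
    slope: float  # mm per finger step
    intercept: float
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def somatotopy_regression(
    mean_coords_mm: np.ndarray,
    order: np.ndarray | None = None,
    axes: tuple[str, ...] = ("x", "z"),
) -> dict[str, SomatotopyFit]:
    """OLS fit of per-finger mean coordinates versus finger identity.

    ``mean_coords_mm`` is (n_fingers, 3) ordered thumb -> little unless an
    explicit ``order`` (e.g. 1..5) is given.  Returns one fit per requested
    axis.  A coordinate axis with zero variance has an undefined correlation
    and raises ``ValueError``.
    """
    coords = np.atleast_2d(np.asarray(mean_coords_mm, dtype=float))
    n = coords.shape[0]
    if n < 3:
        raise ValueError("need at least three fingers for a regression")
    x = np.arange(1, n + 1, dtype=float) if order is None else np.asarray(order, dtype=float)
    if x.shape != (n,):
        raise ValueError("order must give one index per finger")
    fits: dict[str, SomatotopyFit] = {}
    for ax in axes:
        y = coords[:, _AXIS_INDEX[ax]]
        if np.ptp(y) == 0:
            raise ValueError(f"coordinates on axis {ax!r} are constant: R is undefined")
        res = stats.linregress(x, y)
        fits[ax] = SomatotopyFit(
            axis=ax,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r=float(res.rvalue),
            p=float(res.pvalue),
            n=n,
        )
    return fits
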