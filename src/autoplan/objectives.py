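"""Dose-volume objective functions, gradients and the objective-dose solver.

Every objective is a weighted, volume-normalized quadratic penalty on the
relative dose deviation from the objective dose ``d_j``:

    F_j = w_j * sum_{i in V} ((d_i - d_j) / d_j)^2 * dv_i

with ``dv_i`` the voxel volume normalized by the total structure volume, and
``V`` the set of structure voxels violating the objective (for an overdose
objective: voxels with ``d_i > d_j``). All voxels above the objective dose
are penalized; the fractional volume attached to a DVH-point objective is
bookkeeping for the controller (it identifies which DVH point seeded
``d_j``), not a cap on the penalized set.

Variants:

- ``max_dose`` / ``dvh_point`` — penalize voxels above ``d_j``;
- ``min_dose`` — penalize voxels below ``d_j``;
- ``uniform_dose`` — penalize all structure voxels (both directions);
- ``mean_dose`` — one-sided penalty on the structure mean exceeding ``d_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .phantoms import StructureMask

__all__ = [
    "Objective",
    "ObjectiveValue",
    "evaluate",
    "gradient",
    "composite",
    "composite_gradient",
    "solve_objective_dose",
    "OBJECTIVE_KINDS",
]

OBJECTIVE_KINDS = ("max_dose", "min_dose", "uniform_dose", "mean_dose", "dvh_point")

#: Floor (Gy) below which an objective dose is never pushed by the solver.
DOSE_FLOOR = 0.01


@dataclass
class Objective:
    """One dose-volume objective bound to a structure.

    ``dose`` is the objective dose d_j in Gy (> 0, since the penalty is
    relative to it); ``weight`` the user-assigned importance w_j;
    ``fractional_volume`` (percent, DVH-point objectives only) records which
    cumulative-DVH point the objective dose was sampled from.
    """

    kind: str
    structure: StructureMask
    dose: float
    weight: float
    fractional_volume: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ValueError(f"unknown objective kind {self.kind!r}; valid: {OBJECTIVE_KINDS}")
        if self.dose <= 0:
            raise ValueError(f"objective dose must be > 0 Gy, got {self.dose}")
        if self.weight < 0:
            raise ValueError(f"objective weight must be >= 0, got {self.weight}")
        if self.structure.voxel_count == 0:
            raise ValueError(f"structure {self.structure.name!r} has no voxels")
        if self.fractional_volume is not None and not (0.0 < self.fractional_volume <= 100.0):
            raise ValueError(f"fractional_volume must be in (0, 100], got {self.fractional_volume}")

    @property
    def label(self) -> str:
        fv = f"@{self.fractional_volume:g}%" if self.fractional_volume is not None else ""
        return f"{self.structure.name}:{self.kind}{fv}"

    def with_dose(self, dose: float) -> "Objective":
        return replace(self, dose=dose)

    def to_dict(self) -> dict:
        """Plan-config representation (structure referenced by name)."""
        d = {"kind": self.kind, "structure": self.structure.name,
             "dose_gy": self.dose, "weight": self.weight}
        if self.fractional_volume is not None:
            d["fractional_volume_pct"] = self.fractional_volume
        return d

    @classmethod
    def from_dict(cls, d: dict, structures) -> "Objective":
        return cls(kind=d["kind"], structure=structures[d["structure"]],
                   dose=float(d["dose_gy"]), weight=float(d["weight"]),
                   fractional_volume=d.get("fractional_volume_pct"))


@dataclass
class ObjectiveValue:
    """Composite objective value with a per-objective breakdown."""

    value: float
    breakdown: dict[str, float] = field(default_factory=dict)


def _structure_dose(obj: Objective, dose: np.ndarray) -> np.ndarray:
    return np.asarray(dose, dtype=float).ravel()[obj.structure.indices]


def evaluate(obj: Objective, dose: np.ndarray) -> float:
    """Objective value F_j for a voxel dose vector (Gy, full grid)."""
    d = _structure_dose(obj, dose)
    dj, w = obj.dose, obj.weight
    dv = 1.0 / d.size  # uniform grid: dv_i = voxel volume / structure volume
    if obj.kind in ("max_dose", "dvh_point"):
        r = d[d > dj] - dj
    elif obj.kind == "min_dose":
        r = d[d < dj] - dj
    elif obj.kind == "uniform_dose":
        r = d - dj
    else:  # mean_dose
        m = d.mean()
        return float(w * ((m - dj) / dj) ** 2) if m > dj else 0.0
    return float(w * np.sum((r / dj) ** 2) * dv)


def gradient(obj: Objective, dose: np.ndarray) -> np.ndarray:
    """Exact gradient dF_j/dd_i as a dense vector over all grid voxels."""
    dose = np.asarray(dose, dtype=float).ravel()
    g = np.zeros_like(dose)
    idx = obj.structure.indices
    d = dose[idx]
    dj, w = obj.dose, obj.weight
    dv = 1.0 / d.size
    if obj.kind in ("max_dose", "dvh_point"):
        m = d > dj
        g[idx[m]] = 2.0 * w * (d[m] - dj) / dj ** 2 * dv
    elif obj.kind == "min_dose":
        m = d < dj
        g[idx[m]] = 2.0 * w * (d[m] - dj) / dj ** 2 * dv
    elif obj.kind == "uniform_dose":
        g[idx] = 2.0 * w * (d - dj) / dj ** 2 * dv
    else:  # mean_dose
        m = d.mean()
        if m > dj:
            g[idx] = 2.0 * w * (m - dj) / dj ** 2 / d.size
    return g


def composite(objectives: list[Objective], dose: np.ndarray) -> ObjectiveValue:
    """Sum of all objective values, keeping the per-objective breakdown."""
    if not objectives:
        raise ValueError("objective list is empty")
    breakdown: dict[str, float] = {}
    for obj in objectives:  # duplicated objectives accumulate under one label
        breakdown[obj.label] = breakdown.get(obj.label, 0.0) + evaluate(obj, dose)
    return ObjectiveValue(value=float(sum(breakdown.values())), breakdown=breakdown)


def composite_gradient(objectives: list[Objective], dose: np.ndarray) -> np.ndarray:
    g = np.zeros(np.asarray(dose).size)
    for obj in objectives:
        g += gradient(obj, dose)
    return g


def solve_objective_dose(obj: Objective, dose: np.ndarray, target_value: float,
                         rel_tol: float = 1e-6, max_bisections: int = 200
                         ) -> tuple[float, str]:
    """Find the objective dose d* with F(d*; dose) = target_value.

    For overdose objectives F is continuous and strictly decreasing in d_j
    wherever F > 0, so the root on (DOSE_FLOOR, max structure dose] is unique
    when it exists; it is located by bisection to an absolute F-tolerance of
    ``rel_tol * target_value``.

    Returns ``(d*, flag)`` with flag one of ``"ok"``, ``"floor"`` (even the
    floor dose cannot raise F to the target — near-zero structure dose) or
    ``"zero_dose"`` (structure receives no dose at all; sentinel, no root
    finding).
    """
    if target_value <= 0:
        raise ValueError(f"target_value must be > 0, got {target_value}")
    d = _structure_dose(obj, dose)
    dmax = float(d.max()) if d.size else 0.0
    if dmax <= DOSE_FLOOR:
        return DOSE_FLOOR, "zero_dose"

    def f(dj: float) -> float:
        return evaluate(obj.with_dose(dj), dose)

    lo, hi = DOSE_FLOOR, dmax
    if f(lo) < target_value:
        return lo, "floor"
    tol = rel_tol * target_value
    for _ in range(max_bisections):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm - target_value) <= tol:
            return mid, "ok"
        if fm > target_value:  # F decreasing in d: root lies at larger d
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), "ok"
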