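"""Inner-loop fluence optimization: projected gradient with Armijo backtracking.

Minimizes the composite objective over non-negative beamlet fluence. The
gradient in fluence space is ``D^T g`` with ``g`` the voxel-space composite
gradient. Accepted iterates are monotone non-increasing in objective value;
the loop stops after ``max_iterations`` (default 100) or when the absolute
change of the composite objective between accepted iterates falls below
``objective_change_tolerance`` (default 1e-4). Step sizes are seeded by a
safeguarded Barzilai-Borwein rule and backtracked to satisfy the Armijo
sufficient-decrease condition. Fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_engine import BeamletBasis, DoseInfluenceMatrix
from .objectives import Objective, composite, composite_gradient

__all__ = ["OptimizerSettings", "OptimizationResult", "reset_fluence", "optimize_fluence"]


class OptimizationError(RuntimeError):
    pass


@dataclass(frozen=True)
class OptimizerSettings:
    """Inner-loop settings.

    ``tolerance_mode`` selects how the stopping change in the composite
    objective is measured: ``"relative"`` (default) compares the change
    against the current objective value, ``"absolute"`` against 1.
    """

    max_iterations: int = 100
    objective_change_tolerance: float = 1e-4
    tolerance_mode: str = "relative"
    armijo_c: float = 1e-4
    backtrack_factor: float = 0.5
    max_backtracks: int = 50
    step_growth: float = 2.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.objective_change_tolerance <= 0:
            raise ValueError("objective_change_tolerance must be > 0")
        if self.tolerance_mode not in ("absolute", "relative"):
            raise ValueError("tolerance_mode must be 'absolute' or 'relative'")


@dataclass
class OptimizationResult:
    fluence: np.ndarray
    dose: np.ndarray
    trace: list[float]
    reason: str

    @property
    def objective(self) -> float:
        return self.trace[-1]

    def scaled(self, factor: float) -> "OptimizationResult":
        """Linearly rescale fluence and dose (the model is linear)."""
        return OptimizationResult(fluence=self.fluence * factor, dose=self.dose * factor,
                                  trace=list(self.trace), reason=self.reason)


def reset_fluence(basis: BeamletBasis) -> np.ndarray:
    """Uniform unit fluence on every beamlet (the open-field starting plan)."""
    return np.ones(basis.n_beamlets)


def optimize_fluence(dim: DoseInfluenceMatrix, objectives: list[Objective],
                     x0: np.ndarray, settings: OptimizerSettings | None = None
                     ) -> OptimizationResult:
    """Run one optimization cycle from fluence ``x0``."""
    settings = settings or OptimizerSettings()
    D = dim.matrix
    x = np.asarray(x0, dtype=float).copy()
    if x.shape != (dim.n_beamlets,):
        raise ValueError(f"x0 shape {x.shape} != ({dim.n_beamlets},)")
    if np.any(x < 0):
        raise ValueError("initial fluence must be non-negative")

    def f_g(xv: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        dose = D @ xv
        val = composite(objectives, dose).value
        grad = D.T @ composite_gradient(objectives, dose)
        return val, grad, dose

    f, g, dose = f_g(x)
    if not np.isfinite(f) or not np.all(np.isfinite(g)):
        raise OptimizationError("non-finite objective or gradient at the starting fluence")
    trace = [f]
    gnorm = float(np.max(np.abs(g)))
    t = max(x.max(), 1.0) / gnorm if gnorm > 0 else 1.0
    reason = "max_iterations"

    for _ in range(settings.max_iterations):
        accepted = False
        for _bt in range(settings.max_backtracks):
            x_new = np.maximum(x - t * g, 0.0)
            f_new, g_new, dose_new = f_g(x_new)
            if not np.isfinite(f_new):
                t *= settings.backtrack_factor
                continue
            # Armijo sufficient decrease along the projected step
            if f_new <= f + settings.armijo_c * float(g @ (x_new - x)):
                accepted = True
                break
            t *= settings.backtrack_factor
        if not accepted:
            reason = "line_search_failure"
            break
        if not np.all(np.isfinite(g_new)):
            bad = [o.label for o in objectives
                   if not np.isfinite(composite([o], dose_new).value)]
            raise OptimizationError(f"non-finite gradient; offending objectives: {bad}")

        df = f - f_new
        s = x_new - x
        y = g_new - g
        x, f, g, dose = x_new, f_new, g_new, dose_new
        trace.append(f)
        scale = max(abs(f), np.finfo(float).tiny) if settings.tolerance_mode == "relative" else 1.0
        if df < settings.objective_change_tolerance * scale:
            reason = "tolerance"
            break
        sy = float(s @ y)
        if sy > 0:  # safeguarded Barzilai-Borwein step seed
            t = float(s @ s) / sy
        else:
            t *= settings.step_growth

    return OptimizationResult(fluence=x, dose=dose, trace=trace, reason=reason)
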