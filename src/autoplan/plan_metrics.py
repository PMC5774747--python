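"""Cumulative DVHs, dose indices (D95/D5/D2%/Dmean) and paired plan comparison.

Conventions: cumulative DVH volume at a dose bin is the percentage of
structure voxels receiving at least that dose; D_v is the dose received by
the hottest v% of the structure volume; standard deviations use the
population (1/n) convention; dose indices are in total plan dose (Gy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phantoms import StructureMask, StructureSet

__all__ = [
    "DvhCurve",
    "PlanMetrics",
    "cumulative_dvh",
    "dose_at_volume",
    "dose_at_volume_exact",
    "volume_at_dose",
    "relative_dose_sigma",
    "compare_plans",
    "signed_rank_test",
]

DEFAULT_BIN_WIDTH = 0.05  # Gy


@dataclass
class DvhCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    dose_bins: np.ndarray   # Gy, uniform bin edges starting at 0
    volume_pct: np.ndarray  # % of structure volume with dose >= bin edge

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"structure": self.structure, "dose_gy": self.dose_bins,
                             "volume_pct": self.volume_pct})


def _masked_dose(dose: np.ndarray, mask: StructureMask | np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=float).ravel()
    if isinstance(mask, StructureMask):
        return dose[mask.indices]
    return dose[np.flatnonzero(np.asarray(mask, dtype=bool).ravel())]


def cumulative_dvh(dose: np.ndarray, mask: StructureMask | np.ndarray,
                   bin_width: float = DEFAULT_BIN_WIDTH, name: str = "") -> DvhCurve:
    """Exact voxel-counting cumulative DVH on uniform dose bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = _masked_dose(dose, mask)
    if isinstance(mask, StructureMask) and not name:
        name = mask.name
    if d.size == 0:
        raise ValueError(f"empty structure mask{f' {name!r}' if name else ''}")
    n_bins = int(np.ceil(d.max() / bin_width)) + 2
    edges = np.arange(n_bins) * bin_width
    vol = (d[None, :] >= edges[:, None]).mean(axis=1) * 100.0
    return DvhCurve(structure=name, dose_bins=edges, volume_pct=vol)


def dose_at_volume(dvh: DvhCurve, v: float) -> float:
    """Dose D_v (Gy): the dose received by the hottest v percent of the
    structure volume — the largest dose whose cumulative volume is still >= v,
    linearly interpolated toward the next bin. Agrees with the sort-based
    quantile to within one bin width."""
    if not (0.0 < v <= 100.0):
        raise ValueError(f"v must be in (0, 100], got {v}")
    vol = dvh.volume_pct
    edges = dvh.dose_bins
    k = int(np.flatnonzero(vol >= v)[-1])  # vol[0] = 100 guarantees a hit
    if k == vol.size - 1:
        return float(edges[k])
    # vol[k] >= v > vol[k+1]: interpolate on that segment
    v0, v1 = vol[k], vol[k + 1]
    d0, d1 = edges[k], edges[k + 1]
    return float(d0 + (d1 - d0) * (v0 - v) / (v0 - v1))


def volume_at_dose(dvh: DvhCurve, d: float) -> float:
    """Cumulative volume (%) at dose d, linearly interpolated."""
    return float(np.interp(d, dvh.dose_bins, dvh.volume_pct))


def dose_at_volume_exact(dose: np.ndarray, mask: StructureMask | np.ndarray,
                         v: float) -> float:
    """Exact (unbinned) D_v: the coolest voxel among the hottest v% of voxels.

    Used where exactness matters (prescription normalization); agrees with
    the binned DVH version to within one bin width.
    """
    d = np.sort(_masked_dose(dose, mask))[::-1]
    if d.size == 0:
        raise ValueError("empty structure mask")
    k = int(np.ceil(v / 100.0 * d.size))
    k = min(max(k, 1), d.size)
    return float(d[k - 1])


def relative_dose_sigma(dose: np.ndarray, mask: StructureMask | np.ndarray,
                        prescription: float) -> float:
    """Population standard deviation of structure dose as a fraction of the
    prescription dose. Shared by the controller's termination check and the
    reported metrics."""
    d = _masked_dose(dose, mask)
    if d.size == 0:
        raise ValueError("empty structure mask")
    return float(np.std(d) / prescription)


@dataclass
class PlanMetrics:
    """Dose indices per structure, in Gy (sigma also as % of prescription)."""

    prescription: float
    table: pd.DataFrame  # index: structure; columns: D95, D5, D2, Dmean, Dmax, sigma_gy, sigma_pct

    INDICES = ("D95", "D5", "D2", "Dmean", "Dmax")

    @classmethod
    def from_dose(cls, dose: np.ndarray, structures: StructureSet, prescription: float,
                  names: list[str] | None = None) -> "PlanMetrics":
        rows = {}
        for s in structures.structures:
            if names is not None and s.name not in names:
                continue
            if s.voxel_count == 0:
                continue
            d = _masked_dose(dose, s)
            sig = relative_dose_sigma(dose, s, prescription)
            # exact quantiles so D95 <= D5 <= Dmax holds for any structure size
            rows[s.name] = {
                "D95": dose_at_volume_exact(dose, s, 95.0),
                "D5": dose_at_volume_exact(dose, s, 5.0),
                "D2": dose_at_volume_exact(dose, s, 2.0),
                "Dmean": float(d.mean()),
                "Dmax": float(d.max()),
                "sigma_gy": sig * prescription,
                "sigma_pct": sig * 100.0,
            }
        return cls(prescription=prescription, table=pd.DataFrame(rows).T)

    def value(self, structure: str, index: str) -> float:
        return float(self.table.loc[structure, index])


def dose_at_absolute_volume(dose: np.ndarray, mask: StructureMask | np.ndarray,
                            volume_cc: float, voxel_volume_mm3: float) -> float:
    """Dose to the hottest ``volume_cc`` cm^3 (e.g. D_2cc), voxel count
    rounded half-up."""
    d = np.sort(_masked_dose(dose, mask))[::-1]
    n = int(np.floor(volume_cc * 1000.0 / voxel_volume_mm3 + 0.5))
    n = min(max(n, 1), d.size)
    return float(d[n - 1])


def signed_rank_test(values_a, values_b) -> tuple[float, float]:
    """Related-samples Wilcoxon signed-rank test (two-sided).

    Returns (statistic, p-value); uses the exact null distribution for small
    samples without ties. Pairs with zero difference are discarded; if all
    differences are zero the test is degenerate and p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    method = "exact" if (a.size <= 20) else "auto"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_plans(metrics_ref: PlanMetrics, metrics_auto: PlanMetrics,
                  indices: list[tuple[str, str]] | None = None
                  ) -> tuple[pd.DataFrame, float]:
    """Per-index comparison of two plans, normalized to the reference plan.

    ``indices`` is a list of (structure, index) pairs; by default every
    structure/index present in both plans. Returns a table with reference and
    auto values, their ratio (auto/reference; > 1 means more dose in the auto
    plan) and difference (Gy), plus the Wilcoxon signed-rank p-value over the
    paired index values.
    """
    if indices is None:
        common = [s for s in metrics_ref.table.index if s in metrics_auto.table.index]
        indices = [(s, ix) for s in common for ix in PlanMetrics.INDICES]
    missing = [(s, ix) for s, ix in indices
               if s not in metrics_ref.table.index or s not in metrics_auto.table.index]
    if missing:
        raise ValueError(f"structures missing from one of the plans: {sorted({s for s, _ in missing})}")
    rows = []
    for s, ix in indices:
        vr = metrics_ref.value(s, ix)
        va = metrics_auto.value(s, ix)
        rows.append({"structure": s, "index": ix, "value_reference_gy": vr,
                     "value_auto_gy": va,
                     "ratio": va / vr if vr > 0 else np.nan,
                     "difference_gy": va - vr})
    frame = pd.DataFrame(rows)
    _, p = signed_rank_test(frame["value_auto_gy"].to_numpy(),
                            frame["value_reference_gy"].to_numpy())
    return frame, p


def plot_dvhs(curves_reference: list[DvhCurve], curves_auto: list[DvhCurve] | None = None,
              ax=None):
    """Overlay DVH curves (reference solid, auto-plan dashed)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves_reference:
        ax.plot(c.dose_bins, c.volume_pct, "-", label=c.structure)
    for c in (curves_auto or []):
        ax.plot(c.dose_bins, c.volume_pct, "--", label=f"{c.structure} (auto)")
    ax.set_xlabel("Dose [Gy]")
    ax.set_ylabel("Volume [%]")
    ax.set_ylim(0, 105)
    ax.legend(fontsize="small")
    return ax
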