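"""Automated planning controller: stepwise reduction of OAR DVH objectives.

The controller automates inverse planning in eight steps:

1. generate auxiliary ring structures around the target and set the target
   (min/max/uniform dose) and ring (max/mean dose) objectives;
2. optimize with target and ring objectives only, then normalize so the
   prescription dose covers the prescribed fraction of the PTV;
3. sample each OAR's cumulative DVH at a handful of fractional volumes
   (default: 5 equispaced points from 1% to 70%) to seed DVH objectives;
4. lower the OAR objective doses until every OAR objective value sits
   slightly (default 5%) above the largest target objective value;
5. re-optimize from a reset fluence with all objectives;
6. check the termination criterion: the standard deviation of PTV dose,
   relative to the prescription dose, reaching its limit (default 5%);
7. if not terminated, lower the OAR objective doses again (as in step 4)
   against the new dose distribution — objective doses never increase;
8. stop, returning the last plan that still satisfied the homogeneity limit.

Each pass through steps 5-7 is one outer cycle; every cycle trades target
dose homogeneity for OAR sparing, so the PTV sigma grows monotonically
toward the limit while the OAR objective doses ratchet downward.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import objectives as obj_mod
from .dose_engine import DoseInfluenceMatrix, compute_dose_influence, make_beams
from .fluence_optimizer import (OptimizationResult, OptimizerSettings, optimize_fluence,
                                reset_fluence)
from .objectives import DOSE_FLOOR, Objective, composite, solve_objective_dose
from .phantoms import StructureMask, StructureSet, generate_rings
from .plan_metrics import dose_at_volume, cumulative_dvh, dose_at_volume_exact, relative_dose_sigma

__all__ = [
    "AutoPlanConfig",
    "AutoPlanTrace",
    "CycleRecord",
    "AutoPlanResult",
    "setup_target_and_ring_objectives",
    "initial_optimize",
    "sample_initial_oar_doses",
    "build_oar_objectives",
    "scale_oar_objectives",
    "normalize_to_prescription",
    "check_termination",
    "run_autoplan",
]


class PlanConfigError(ValueError):
    pass


def equispaced_fractional_volumes(n: int = 5, lo: float = 1.0, hi: float = 70.0) -> tuple[float, ...]:
    """Equispaced cumulative-DVH sampling points (percent), default 1%..70%."""
    return tuple(np.linspace(lo, hi, n).tolist())


@dataclass(frozen=True)
class AutoPlanConfig:
    """Controller parameters. Doses in Gy, lengths in mm.

    Defaults follow the published pancreatic SBRT recipe: 35 Gy prescribed
    to 95% of the PTV in five fractions; three 10 mm rings at 5/35/55 mm
    from the target; objective weights 100 (target), 80 (rings), 1 (OARs);
    five DVH objectives per OAR at fractional volumes equispaced from 1% to
    70%; OAR objective values pinned 5% above the largest target objective
    value each cycle; termination once the PTV dose standard deviation
    reaches 5% of the prescription.
    """

    prescription: float = 35.0
    coverage: float = 95.0           # % of PTV receiving the prescription
    fractions: int = 5               # metadata; all doses are total plan dose
    ring_offsets: tuple[float, ...] = (5.0, 35.0, 55.0)
    ring_width: float = 10.0
    target_weight: float = 100.0
    ring_weight: float = 80.0
    oar_weight: float = 1.0
    target_max_factor: float = 1.07      # max-dose objective, x prescription
    target_uniform_factor: float = 1.02  # uniform-dose objective, x prescription
    ring_max_factors: tuple[float, ...] = (0.95, 0.70, 0.45)
    ring_mean_factors: tuple[float, ...] = (0.60, 0.35, 0.15)
    dvh_fractional_volumes: tuple[float, ...] = equispaced_fractional_volumes()
    oar_scaling_factor: float = 1.05
    sigma_termination: float = 0.05      # fraction of prescription
    max_outer_cycles: int = 20
    priorities: dict = field(default_factory=dict)  # structure -> multiplier (default 1)
    n_beams: int = 36
    beamlet_width: float = 4.0
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma_termination < 1.0):
            raise PlanConfigError("sigma_termination must be in (0, 1)")
        if self.oar_scaling_factor <= 1.0:
            raise PlanConfigError("oar_scaling_factor must be > 1")
        fv = self.dvh_fractional_volumes
        if any(not (0.0 < v <= 100.0) for v in fv) or any(b <= a for a, b in zip(fv, fv[1:])):
            raise PlanConfigError("dvh_fractional_volumes must be strictly increasing in (0, 100]")
        if self.prescription <= 0:
            raise PlanConfigError("prescription must be > 0 Gy")

    def priority(self, structure_name: str) -> float:
        return float(self.priorities.get(structure_name, 1.0))

    @classmethod
    def reference(cls, **overrides) -> "AutoPlanConfig":
        """The packaged reference configuration: defaults plus a doubled
        priority on duodenum sparing (the abutting serial organ)."""
        overrides.setdefault("priorities", {"duodenum": 2.0})
        return cls(**overrides)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["optimizer"] = asdict(self.optimizer)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AutoPlanConfig":
        d = dict(d)
        if "optimizer" in d and isinstance(d["optimizer"], dict):
            d["optimizer"] = OptimizerSettings(**d["optimizer"])
        for key in ("ring_offsets", "ring_mean_factors", "ring_max_factors",
                    "dvh_fractional_volumes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AutoPlanConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def setup_target_and_ring_objectives(structures: StructureSet,
                                     cfg: AutoPlanConfig) -> list[Objective]:
    """Step-1 objectives; never altered in later steps.

    Target: min dose at the prescription, max dose at 1.07x and uniform dose
    at 1.02x the prescription, each at the target weight. Rings: max and mean
    dose objectives at fixed fractions of the prescription that decrease with
    ring distance, at the ring weight.
    """
    rings = structures.rings
    if not rings:
        raise PlanConfigError("no ring structures; run generate_rings first")
    rx, w_t = cfg.prescription, cfg.target_weight
    objs: list[Objective] = []
    for t in structures.targets:
        objs += [
            Objective("min_dose", t, rx, w_t),
            Objective("max_dose", t, cfg.target_max_factor * rx, w_t),
            Objective("uniform_dose", t, cfg.target_uniform_factor * rx, w_t),
        ]
    for k, ring in enumerate(rings):
        fmax = cfg.ring_max_factors[min(k, len(cfg.ring_max_factors) - 1)]
        fmean = cfg.ring_mean_factors[min(k, len(cfg.ring_mean_factors) - 1)]
        objs += [
            Objective("max_dose", ring, fmax * rx, cfg.ring_weight),
            Objective("mean_dose", ring, fmean * rx, cfg.ring_weight),
        ]
    return objs


def normalize_to_prescription(result: OptimizationResult, ptv: StructureMask,
                              cfg: AutoPlanConfig) -> OptimizationResult:
    """Scale fluence and dose so that D_coverage(PTV) equals the prescription.

    The dose model is linear, so the rescaling is exact.
    """
    dcov = dose_at_volume_exact(result.dose, ptv, cfg.coverage)
    if dcov <= 0:
        raise RuntimeError("PTV coverage dose is zero; optimization failed")
    return result.scaled(cfg.prescription / dcov)


def initial_optimize(dim: DoseInfluenceMatrix, target_ring_objs: list[Objective],
                     ptv: StructureMask, cfg: AutoPlanConfig) -> OptimizationResult:
    """Step 2: optimize with target and ring objectives only, from reset
    fluence, then normalize to the prescription."""
    oar_kinds = {"dvh_point"}
    if any(o.kind in oar_kinds for o in target_ring_objs):
        raise PlanConfigError("initial optimization must not include OAR DVH objectives")
    x0 = reset_fluence(dim.basis)
    res = optimize_fluence(dim, target_ring_objs, x0, cfg.optimizer)
    return normalize_to_prescription(res, ptv, cfg)


def sample_initial_oar_doses(dose: np.ndarray, oars: list[StructureMask],
                             cfg: AutoPlanConfig) -> dict[tuple[str, float], float]:
    """Step 3: read the seed objective doses off each OAR's cumulative DVH.

    Returns a map (structure name, fractional volume %) -> dose-at-volume Gy.
    """
    out: dict[tuple[str, float], float] = {}
    for oar in oars:
        if oar.voxel_count == 0:
            warnings.warn(f"OAR {oar.name!r} has no voxels; skipped", stacklevel=2)
            continue
        dvh = cumulative_dvh(dose, oar)
        for v in cfg.dvh_fractional_volumes:
            out[(oar.name, v)] = dose_at_volume(dvh, v)
    return out


def build_oar_objectives(seed_doses: dict[tuple[str, float], float],
                         structures: StructureSet, cfg: AutoPlanConfig) -> list[Objective]:
    """Turn the sampled DVH points into DVH-point objectives at the OAR weight."""
    objs = []
    for (name, v), d in seed_doses.items():
        objs.append(Objective("dvh_point", structures[name], max(d, DOSE_FLOOR),
                              cfg.oar_weight, fractional_volume=v))
    return objs


def scale_oar_objectives(dose: np.ndarray, oar_objs: list[Objective],
                         target_objs: list[Objective], cfg: AutoPlanConfig
                         ) -> tuple[list[Objective], dict[str, str]]:
    """Steps 4 and 7: lower the OAR objective doses against the current dose.

    Each OAR objective dose is re-solved so its objective value equals
    ``oar_scaling_factor`` times the largest target objective value
    (multiplied by the structure's priority: a higher priority pins the
    objective further into violation, i.e. pushes its dose lower), then
    clamped so objective doses never increase across cycles. Returns the
    updated objectives and a flag per objective label: "scaled", "clamped",
    "floor" or "zero_dose" ("no_pressure" for all if the target plan is
    perfect).
    """
    target_ref = max(obj_mod.evaluate(o, dose) for o in target_objs)
    if target_ref <= 0.0:
        return list(oar_objs), {o.label: "no_pressure" for o in oar_objs}
    updated, flags = [], {}
    for o in oar_objs:
        target_value = cfg.oar_scaling_factor * target_ref * cfg.priority(o.structure.name)
        d_star, flag = solve_objective_dose(o, dose, target_value)
        if flag == "ok":
            if d_star > o.dose:
                d_star, flag = o.dose, "clamped"
            else:
                flag = "scaled"
        updated.append(o.with_dose(max(d_star, DOSE_FLOOR)))
        flags[o.label] = flag
    return updated, flags


def check_termination(dose: np.ndarray, ptv: StructureMask,
                      cfg: AutoPlanConfig) -> tuple[bool, float]:
    """Step 6: has PTV dose heterogeneity reached its limit?

    Returns (terminated, sigma_rel) where sigma_rel is the population
    standard deviation of PTV dose divided by the prescription; the loop
    stops once sigma_rel has grown to (or past) the limit.
    """
    sigma_rel = relative_dose_sigma(dose, ptv, cfg.prescription)
    return sigma_rel >= cfg.sigma_termination, sigma_rel


@dataclass
class CycleRecord:
    """Audit record of one outer cycle (cycle 0 is the initial plan)."""

    cycle: int
    sigma_pct: float                      # PTV sigma, % of prescription
    composite_value: float
    objective_values: dict[str, float]    # per-objective F on the normalized dose
    oar_objective_doses: dict[str, float]  # label -> d_j Gy entering this cycle
    scaling_flags: dict[str, str]
    optimizer_reason: str
    optimizer_iterations: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AutoPlanTrace:
    cycles: list[CycleRecord] = field(default_factory=list)
    termination_reason: str = ""

    @property
    def n_cycles(self) -> int:
        """Number of outer optimization cycles run (excluding the initial plan)."""
        return max(c.cycle for c in self.cycles) if self.cycles else 0

    @property
    def sigmas_pct(self) -> list[float]:
        return [c.sigma_pct for c in self.cycles]


@dataclass
class AutoPlanResult:
    """Final plan returned by the controller."""

    fluence: np.ndarray
    dose: np.ndarray
    structures: StructureSet           # with rings
    objectives: list[Objective]        # final objective set (target+ring+OAR)
    trace: AutoPlanTrace
    config: AutoPlanConfig
    initial_result: OptimizationResult  # the normalized step-2 plan
    dose_influence: DoseInfluenceMatrix


def run_autoplan(structures: StructureSet, cfg: AutoPlanConfig | None = None,
                 dim: DoseInfluenceMatrix | None = None) -> AutoPlanResult:
    """Execute the full automated planning loop on a structure set.

    A dose-influence matrix is computed from the configured beam geometry
    unless one is supplied. Returns the last plan whose PTV heterogeneity
    still satisfied the limit (keep-best-feasible), with the full per-cycle
    trace.
    """
    cfg = cfg or AutoPlanConfig()
    structures.validate()
    if not structures.rings:
        structures = generate_rings(structures, cfg.ring_offsets, cfg.ring_width)
    ptv = structures.targets[0]

    if dim is None:
        basis = make_beams(cfg.n_beams, structures, beamlet_width=cfg.beamlet_width)
        dim = compute_dose_influence(basis, structures)

    # Steps 1-2: target + ring objectives, initial plan
    tr_objs = setup_target_and_ring_objectives(structures, cfg)
    target_objs = [o for o in tr_objs if o.structure.role == "target"]
    init = initial_optimize(dim, tr_objs, ptv, cfg)
    _, sigma0 = check_termination(init.dose, ptv, cfg)
    trace = AutoPlanTrace()
    comp0 = composite(tr_objs, init.dose)
    trace.cycles.append(CycleRecord(
        cycle=0, sigma_pct=sigma0 * 100.0, composite_value=comp0.value,
        objective_values=comp0.breakdown, oar_objective_doses={}, scaling_flags={},
        optimizer_reason=init.reason, optimizer_iterations=len(init.trace) - 1))

    # Step 3: seed OAR objectives off the initial DVHs
    seeds = sample_initial_oar_doses(init.dose, structures.oars, cfg)
    oar_objs = build_oar_objectives(seeds, structures, cfg)
    # Step 4: first adjustment against the initial dose
    oar_objs, flags = scale_oar_objectives(init.dose, oar_objs, target_objs, cfg)

    best = init
    best_objs = list(tr_objs)
    reason = "cycle_cap"
    for cycle in range(1, cfg.max_outer_cycles + 1):
        all_objs = tr_objs + oar_objs
        # Step 5: reset beams and optimize with all objectives
        res = optimize_fluence(dim, all_objs, reset_fluence(dim.basis), cfg.optimizer)
        res = normalize_to_prescription(res, ptv, cfg)
        terminated, sigma = check_termination(res.dose, ptv, cfg)
        comp = composite(all_objs, res.dose)
        trace.cycles.append(CycleRecord(
            cycle=cycle, sigma_pct=sigma * 100.0, composite_value=comp.value,
            objective_values=comp.breakdown,
            oar_objective_doses={o.label: o.dose for o in oar_objs},
            scaling_flags=dict(flags),
            optimizer_reason=res.reason, optimizer_iterations=len(res.trace) - 1))
        if terminated:
            # Step 8: heterogeneity limit reached; keep the last feasible plan.
            reason = "sigma_limit"
            break
        best, best_objs = res, list(all_objs)
        # Step 7: ratchet the OAR objective doses down for the next cycle
        oar_objs, flags = scale_oar_objectives(res.dose, oar_objs, target_objs, cfg)
    trace.termination_reason = reason

    return AutoPlanResult(fluence=best.fluence, dose=best.dose, structures=structures,
                          objectives=best_objs, trace=trace, config=cfg,
                          initial_result=init, dose_influence=dim)
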