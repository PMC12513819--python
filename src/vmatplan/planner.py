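"""Iterative weight-adaptation planning loop.

The planner translates predicted planning goals into weighted dose
objectives, runs a preliminary optimization, and then alternates between
two adaptation phases until every goal is met or the iteration budget is
exhausted:

* **Organ-at-risk phase** -- every OAR objective weight is updated from
  the previous iteration's normalized value gap ``Δ = T - A`` and the
  relative contribution ``F_tot / F_obj`` by the piecewise rule::

      w <- w * 0.001                 if Δ <= -0.999
      w <- w * (1 + Δ)               if -0.999 < Δ < -0.05
      w <- w                         if -0.05 <= Δ <= 0   (dead band)
      w <- w * (1 + 0.1 * ratio)     if Δ > 0 and ratio < 100
      w <- w * 11                    if Δ > 0 and ratio >= 100

  The rule is continuous at both interior boundaries: (1 + Δ) -> 0.001 as
  Δ -> -0.999 and 1 + 0.1*100 = 11 at the ratio cap.

* **Target phase** -- the PTV minimum- and maximum-dose weights grow by
  ``w * (1 + 0.1 * ratio)`` for a small positive gap (< 0.1) and
  ``w * (1 + 0.2 * ratio)`` for a large one (>= 0.1), while a high-dose
  suppression structure (everything at >= 95% of the prescription outside
  the PTV) is regenerated from the current dose each pass and penalized
  with weight ``100 * i`` at the i-th suppression.

Every post-preliminary engine call counts against one shared budget of
40 iterations; hitting the cap returns status ``iteration_cap`` with the
full trace, signalling that the goals should be revised.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .dosimetry import DoseGrid, MetricSpec, cumulative_dvh, dvh_metric, quality_indices
from .engine import (
    BeamConfig,
    EngineResult,
    InfluenceMatrix,
    Objective,
    build_influence,
    inner_optimize,
)
from .geometry import ROIMask, StructureSet
from .prediction import PlanningGoal, normalize_metric

logger = logging.getLogger(__name__)

HIGHDOSE_ROI_NAME = "_highdose_suppress"


@dataclass(frozen=True)
class PlannerConfig:
    """Planner defaults.

    ``mu_cap_per_arc`` records the clinical monitor-unit cap per arc for
    fidelity of the configuration surface; the desk-scale engine has no
    MU concept, so it is never enforced.
    """

    default_oar_weight: float = 10.0
    default_ptv_weight: float = 100.0
    goal_margin: float = 0.10  # objectives sit 10% below the planning goals
    max_total_iterations: int = 40
    highdose_isodose_fraction: float = 0.95
    oar_deadband: tuple[float, float] = (-0.05, 0.0)
    ratio_cap: float = 100.0
    ptv_coverage_goal: float = 0.95
    ptv_max_fraction: float = 1.05
    ptv_min_fraction: float = 0.95
    mu_cap_per_arc: float = 350.0

    def __post_init__(self):
        if not (0.0 < self.goal_margin < 1.0):
            raise ValueError("goal_margin must be in (0, 1)")
        if self.max_total_iterations < 1 or self.ratio_cap <= 0:
            raise ValueError("iteration cap and ratio cap must be positive")


@dataclass
class ObjectiveState:
    """Per-objective snapshot stored in an iteration record."""

    roi: str
    kind: str
    weight: float
    raw: float
    f_obj: float
    gap: float | None = None


@dataclass
class IterationRecord:
    """One planner iteration: weights, objective values, gaps, F_tot."""

    index: int
    phase: str  # preliminary | oar | target
    f_tot: float
    objectives: list[ObjectiveState]
    gaps: dict[str, float]
    achieved: dict[str, float]
    suppression_count: int = 0


@dataclass
class PlanResult:
    """Final dose with its trace; status 'satisfied' or 'iteration_cap'."""

    dose: DoseGrid
    dvhs: dict[str, object]
    metrics: dict[str, float]
    indices: object
    status: str
    trace: list[IterationRecord]

    @property
    def n_iterations(self) -> int:
        """Post-preliminary engine calls consumed."""
        return len(self.trace) - 1


# ---------------------------------------------------------------------------
# Weight-update rules
# ---------------------------------------------------------------------------

def value_gap(goal_norm: float, achieved_norm: float) -> float:
    """Normalized value gap Δ = T - A; positive while the goal is unmet."""
    return goal_norm - achieved_norm


def update_oar_weight(
    w_prev: float,
    gap_prev: float,
    ratio: float,
    deadband: tuple[float, float] = (-0.05, 0.0),
    ratio_cap: float = 100.0,
) -> float:
    """Piecewise OAR weight update (see module docstring).

    ``ratio`` is F_tot/F_obj of the prior iteration and is treated as
    +inf when F_obj was exactly zero, which lands in the capped branch.
    """
    if w_prev <= 0:
        raise ValueError("weight must be positive")
    if gap_prev <= -0.999:
        return w_prev * 0.001
    if gap_prev < deadband[0]:
        return w_prev * (1.0 + gap_prev)
    if gap_prev <= deadband[1]:
        return w_prev
    # gap > 0: goal unmet, escalate
    if ratio >= ratio_cap or math.isinf(ratio):
        return w_prev * (1.0 + 0.1 * ratio_cap)
    return w_prev * (1.0 + 0.1 * ratio)


def update_ptv_weight(
    w_prev: float, gap_prev: float, ratio: float, ratio_cap: float = 100.0
) -> float:
    """Target weight update: unchanged for met goals, escalating otherwise.

    The contribution ratio is capped at ``ratio_cap`` (as in the OAR rule)
    so that a near-zero objective value cannot blow the weight up in one
    step.
    """
    if w_prev <= 0:
        raise ValueError("weight must be positive")
    ratio = min(ratio, ratio_cap)
    if gap_prev <= 0:
        return w_prev
    if gap_prev < 0.1:
        return w_prev * (1.0 + 0.1 * ratio)
    return w_prev * (1.0 + 0.2 * ratio)


def highdose_weight(suppression_count: int) -> float:
    """Weight of the i-th high-dose suppression objective: 100 * i."""
    if suppression_count < 1:
        raise ValueError("suppression count starts at 1")
    return 100.0 * suppression_count


def build_highdose_roi(
    dose: DoseGrid,
    ptv: ROIMask,
    prescription: float,
    fraction: float = 0.95,
) -> ROIMask:
    """Volume at >= ``fraction`` of the prescription outside the PTV.

    May be empty; regenerated from the current dose each target-phase pass.
    """
    if prescription <= 0:
        raise ValueError("prescription dose must be positive")
    hot = (dose.dose >= fraction * prescription) & ~ptv.voxels
    return ROIMask(dose.grid, hot, HIGHDOSE_ROI_NAME, "auxiliary")


# ---------------------------------------------------------------------------
# Goal -> objective translation
# ---------------------------------------------------------------------------

@dataclass
class _Slot:
    """An objective plus the planner-side bookkeeping attached to it."""

    objective: Objective
    tag: str  # oar | ptv_min | ptv_uniform | ptv_max | highdose
    goal: PlanningGoal | None = None

    @property
    def key(self) -> str:
        if self.goal is not None:
            return self.goal.metric.key
        return f"{self.objective.roi}.{self.objective.kind}"


def _oar_objective(goal: PlanningGoal, weight: float, margin: float) -> Objective:
    metric = goal.metric
    level_scale = 1.0 - margin
    if metric.kind == "mean":
        return Objective(metric.organ, "mean_below", max(level_scale * goal.goal, 0.05), weight)
    if metric.kind == "v_dose":
        return Objective(
            metric.organ,
            "vdose_below",
            metric.parameter,
            weight,
            volume_param=max(level_scale * goal.goal / 100.0, 0.0),
        )
    if metric.kind == "d_cc":
        return Objective(
            metric.organ,
            "dcc_below",
            max(level_scale * goal.goal, 0.05),
            weight,
            volume_param=metric.parameter,
        )
    raise ValueError(f"no objective translation for metric kind {metric.kind!r}")


def goals_to_objectives(
    goals: list[PlanningGoal],
    structures: StructureSet,
    config: PlannerConfig | None = None,
) -> list[Objective]:
    """Objectives for the engine: OAR goals at 90% of T, the PTV trio.

    OAR objective levels sit ``goal_margin`` (default 10%) below the
    planning goals so the optimizer has headroom to actually reach them.
    The PTV receives minimum / uniform / maximum dose objectives at 95% /
    100% / 105% of the prescription.  Goals for structures absent from
    the case are skipped with a warning.
    """
    cfg = config or PlannerConfig()
    if not goals:
        raise ValueError("no planning goals supplied")
    return [s.objective for s in _build_slots(goals, structures, cfg)]


def _build_slots(
    goals: list[PlanningGoal], structures: StructureSet, cfg: PlannerConfig
) -> list[_Slot]:
    slots: list[_Slot] = []
    for goal in goals:
        organ = goal.metric.organ
        roi = structures.rois.get(organ)
        if roi is None or roi.is_empty():
            logger.warning("goal for absent structure %r skipped", organ)
            continue
        slots.append(
            _Slot(_oar_objective(goal, cfg.default_oar_weight, cfg.goal_margin), "oar", goal)
        )
    dp = structures.prescription_dose
    w = cfg.default_ptv_weight
    slots.append(_Slot(Objective("ptv", "min_dose", cfg.ptv_min_fraction * dp, w), "ptv_min"))
    slots.append(_Slot(Objective("ptv", "uniform_dose", dp, w), "ptv_uniform"))
    slots.append(_Slot(Objective("ptv", "max_dose", cfg.ptv_max_fraction * dp, w), "ptv_max"))
    return slots


# ---------------------------------------------------------------------------
# The control loop
# ---------------------------------------------------------------------------

def _ratio(f_tot: float, f_obj: float) -> float:
    return math.inf if f_obj == 0.0 else f_tot / f_obj


def _gaps(
    dose: DoseGrid,
    structures: StructureSet,
    slots: list[_Slot],
    cfg: PlannerConfig,
) -> tuple[dict[str, float], dict[str, float]]:
    """Normalized value gaps and raw achieved metrics for all slots.

    OAR gaps live on the interval-normalized scale: Δ = (A_raw - T_raw) /
    (hi - lo).  PTV gaps live on raw fractional scales: coverage shortfall
    for the minimum-dose objective and the fractional D2% excess over the
    maximum-dose level for the maximum-dose objective.
    """
    gaps: dict[str, float] = {}
    achieved: dict[str, float] = {}
    dp = structures.prescription_dose
    for slot in slots:
        if slot.tag == "oar":
            goal = slot.goal
            roi = structures[goal.metric.organ]
            a_raw = dvh_metric(dose, roi, goal.metric)
            achieved[slot.key] = a_raw
            t_norm = normalize_metric(goal.goal, goal.lo, goal.hi)
            a_norm = normalize_metric(a_raw, goal.lo, goal.hi)
            gaps[slot.key] = value_gap(t_norm, a_norm)
        elif slot.tag == "ptv_min":
            d = dose.dose[structures.ptv.voxels]
            cov = float(
                np.count_nonzero(d >= cfg.highdose_isodose_fraction * dp) / d.size
            )
            achieved[slot.key] = cov
            gaps[slot.key] = cfg.ptv_coverage_goal - cov
        elif slot.tag == "ptv_max":
            d2 = dvh_metric(dose, structures.ptv, MetricSpec("ptv", "d_pct", 2.0))
            achieved[slot.key] = d2
            gaps[slot.key] = d2 / dp - cfg.ptv_max_fraction
    return gaps, achieved


def _record(
    index: int,
    phase: str,
    result: EngineResult,
    slots: list[_Slot],
    gaps: dict[str, float],
    achieved: dict[str, float],
    suppression_count: int,
) -> IterationRecord:
    states = [
        ObjectiveState(
            roi=s.objective.roi,
            kind=s.objective.kind,
            weight=s.objective.weight,
            raw=float(result.raw_values[i]),
            f_obj=float(result.f_obj[i]),
            gap=gaps.get(s.key),
        )
        for i, s in enumerate(slots)
    ]
    return IterationRecord(
        index, phase, result.f_tot, states, dict(gaps), dict(achieved), suppression_count
    )


def run_planner(
    case: StructureSet,
    goals: list[PlanningGoal],
    influence: InfluenceMatrix | None = None,
    beam_config: BeamConfig | None = None,
    config: PlannerConfig | None = None,
) -> PlanResult:
    """Full three-phase optimization of one case.

    Phase I runs once with the default weights.  Afterwards each loop
    pass spends one engine call: an OAR pass while any OAR gap is
    positive (all OAR weights updated simultaneously), otherwise a target
    pass (PTV min/max weight escalation plus high-dose suppression).
    Terminates with status ``satisfied`` when every gap is <= 0, or
    ``iteration_cap`` after 40 post-preliminary calls.
    """
    cfg = config or PlannerConfig()
    if influence is None:
        influence = build_influence(case, beam_config)

    slots = _build_slots(goals, case, cfg)
    if not any(s.tag == "oar" for s in slots):
        logger.warning("no OAR goals translate to objectives; target-only plan")

    rois = dict(case.rois)

    def engine_call(x0):
        objs = [s.objective for s in slots]
        return inner_optimize(influence, objs, rois, init_intensities=x0)

    result = engine_call(None)
    gaps, achieved = _gaps(result.dose, case, slots, cfg)
    trace = [_record(0, "preliminary", result, slots, gaps, achieved, 0)]
    logger.info("preliminary: F_tot=%.4g gaps=%s", result.f_tot, _fmt(gaps))

    suppressions = 0
    n_calls = 0
    status = "iteration_cap"
    while True:
        oar_unmet = any(gaps[s.key] > 0 for s in slots if s.tag == "oar")
        ptv_unmet = any(gaps[s.key] > 0 for s in slots if s.tag in ("ptv_min", "ptv_max"))
        if not oar_unmet and not ptv_unmet:
            status = "satisfied"
            break
        if n_calls >= cfg.max_total_iterations:
            logger.warning(
                "iteration cap (%d) reached with unmet goals; revise the planning goals",
                cfg.max_total_iterations,
            )
            break

        prev = trace[-1]
        if oar_unmet:
            phase = "oar"
            for i, s in enumerate(slots):
                if s.tag != "oar":
                    continue
                st = prev.objectives[i]
                ratio = _ratio(prev.f_tot, st.f_obj)
                gap_prev = prev.gaps[s.key]
                if gap_prev > 0 and st.f_obj == 0.0:
                    logger.warning(
                        "%s: positive gap with zero objective value "
                        "(metric/objective mismatch); capped escalation applied",
                        s.key,
                    )
                w_new = update_oar_weight(
                    st.weight, gap_prev, ratio, cfg.oar_deadband, cfg.ratio_cap
                )
                s.objective = replace(s.objective, weight=w_new)
        else:
            phase = "target"
            suppressions += 1
            for i, s in enumerate(slots):
                if s.tag not in ("ptv_min", "ptv_max"):
                    continue
                st = prev.objectives[i]
                gap_prev = prev.gaps[s.key]
                ratio = _ratio(prev.f_tot, st.f_obj)
                w_new = update_ptv_weight(st.weight, gap_prev, ratio, cfg.ratio_cap)
                s.objective = replace(s.objective, weight=w_new)
            # drop the previous suppression structure, regenerate from the
            # current dose, and penalize it with weight 100 * i
            slots = [s for s in slots if s.tag != "highdose"]
            hot = build_highdose_roi(
                result.dose, case.ptv, case.prescription_dose, cfg.highdose_isodose_fraction
            )
            rois.pop(HIGHDOSE_ROI_NAME, None)
            if not hot.is_empty():
                rois[HIGHDOSE_ROI_NAME] = hot
                slots.append(
                    _Slot(
                        Objective(
                            HIGHDOSE_ROI_NAME,
                            "max_dose",
                            case.prescription_dose,
                            highdose_weight(suppressions),
                        ),
                        "highdose",
                    )
                )

        result = engine_call(result.intensities)
        n_calls += 1
        gaps, achieved = _gaps(result.dose, case, slots, cfg)
        trace.append(_record(n_calls, phase, result, slots, gaps, achieved, suppressions))
        logger.info(
            "iteration %d (%s): F_tot=%.4g gaps=%s",
            n_calls, phase, result.f_tot, _fmt(gaps),
        )

    dvhs = {
        name: cumulative_dvh(result.dose, roi)
        for name, roi in case.rois.items()
        if not roi.is_empty()
    }
    metrics = dict(trace[-1].achieved)
    indices = quality_indices(result.dose, case.ptv, case.prescription_dose)
    return PlanResult(result.dose, dvhs, metrics, indices, status, trace)


def _fmt(gaps: dict[str, float]) -> str:
    return "{" + ", ".join(f"{k}: {v:+.3f}" for k, v in gaps.items()) + "}"
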