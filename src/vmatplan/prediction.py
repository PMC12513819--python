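"""Knowledge-based DVH-metric prediction from OVH/OZH geometry.

Two complementary predictors feed the planner:

* **Point prediction** -- the query case's per-organ OVH/OZH curves are
  compared (L2) against every library case; the metric values of the five
  best-matching cases are averaged.
* **Interval prediction** -- for each metric an ordinary-least-squares
  model on the normalized AUC features is fitted over the whole library
  (a plane on (AUC_OVH, AUC_OZH), a line on AUC_OVH alone, or a constant,
  depending on the metric), and the prediction interval is the fitted
  surface shifted up and down by three residual standard deviations
  (99.73% coverage under Gaussian residuals).

The interval bounds double as the normalization frame of the weight
adaptation loop: an achieved metric is mapped to (hi - value)/(hi - lo),
so 1 means optimal sparing (lower bound) and 0 the worst expected outcome.
The map is deliberately not clipped -- values far better than the lower
bound exceed 1, which is what drives the weight-release branch of the
organ-at-risk update rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dosimetry import MetricSpec
from .geometry import GeometrySignature

DEFAULT_NEIGHBORS = 5  # matched cases averaged by the point prediction

# The fixed metric set predicted for the critical thoracic structures.
TABLE_METRICS: tuple[MetricSpec, ...] = (
    MetricSpec("total_lung", "mean"),
    MetricSpec("total_lung", "v_dose", 20.0),
    MetricSpec("heart", "mean"),
    MetricSpec("spinal_cord", "d_cc", 0.01),
    MetricSpec("esophagus", "d_cc", 0.5),
    MetricSpec("skin", "d_cc", 0.5),
    MetricSpec("breast_l", "mean"),
    MetricSpec("breast_r", "mean"),
)

# Regression form per metric: lung/heart/breast metrics correlate with both
# AUC features (plane); esophagus and skin near-maximum doses track AUC_OVH
# only (line); the spinal-cord near-maximum dose is geometry-independent
# (constant: mean +/- 3 sample SD).
MODEL_FORMS: dict[str, str] = {
    "total_lung.mean": "plane",
    "total_lung.v_dose.20": "plane",
    "heart.mean": "plane",
    "breast_l.mean": "plane",
    "breast_r.mean": "plane",
    "esophagus.d_cc.0.5": "line",
    "skin.d_cc.0.5": "line",
    "spinal_cord.d_cc.0.01": "constant",
}

_MIN_CASES = {"plane": 4, "line": 3, "constant": 2}
MIN_KB_CASES = 6  # k=5 neighbors + one held-out query


class InsufficientCasesError(ValueError):
    """The knowledge base has too few cases for the requested prediction."""


@dataclass
class KBCase:
    """One prior case: geometry signature plus its achieved metric values."""

    case_id: str
    signature: GeometrySignature
    achieved: dict[str, float]  # MetricSpec.key -> value (Gy or %)

    def __post_init__(self):
        for key, val in self.achieved.items():
            if val < 0:
                raise ValueError(f"case {self.case_id}: metric {key} negative")


@dataclass
class KnowledgeBase:
    """Library of prior cases sharing one OVH/OZH sampling window."""

    cases: list[KBCase] = field(default_factory=list)
    window: tuple[float, float, float] = (-50.0, 100.0, 1.0)

    def __post_init__(self):
        for case in self.cases:
            if tuple(case.signature.window) != tuple(self.window):
                raise ValueError(
                    f"case {case.case_id}: signature window {case.signature.window} "
                    f"!= KB window {self.window}"
                )

    def __len__(self) -> int:
        return len(self.cases)


@dataclass(frozen=True)
class IntervalModel:
    """Fitted AUC->metric regression with its residual SD.

    ``coefficients`` are (intercept,), (intercept, slope_ovh) or
    (intercept, slope_ovh, slope_ozh) depending on ``form``.
    """

    metric: MetricSpec
    form: str  # plane | line | constant
    coefficients: tuple[float, ...]
    sigma_res: float
    n_fit: int

    def __post_init__(self):
        if self.sigma_res < 0:
            raise ValueError("sigma_res must be >= 0")
        n_coef = {"constant": 1, "line": 2, "plane": 3}[self.form]
        if len(self.coefficients) != n_coef:
            raise ValueError(f"{self.form} model needs {n_coef} coefficients")

    def center(self, auc_ovh: float, auc_ozh: float) -> float:
        c = self.coefficients
        if self.form == "constant":
            return c[0]
        if self.form == "line":
            return c[0] + c[1] * auc_ovh
        return c[0] + c[1] * auc_ovh + c[2] * auc_ozh


@dataclass(frozen=True)
class PlanningGoal:
    """Point + interval prediction for one metric and the chosen goal T."""

    metric: MetricSpec
    point: float
    lo: float
    hi: float
    goal: float

    def __post_init__(self):
        if not (self.lo <= self.hi):
            raise ValueError("interval bounds out of order")
        if not (self.lo - 1e-9 <= self.goal <= self.hi + 1e-9):
            raise ValueError("goal must lie inside the prediction interval")


# ---------------------------------------------------------------------------
# Point prediction
# ---------------------------------------------------------------------------

def signature_distance(a: GeometrySignature, b: GeometrySignature, organ: str) -> float:
    """Combined OVH-OZH dissimilarity of one organ between two cases.

    Unweighted sum of the L2 norms between the sampled OVH curves and
    between the sampled OZH curves; zero iff both pairs are identical.
    """
    if tuple(a.window) != tuple(b.window):
        raise ValueError(f"signature windows differ: {a.window} vs {b.window}")
    ga, gb = a[organ], b[organ]
    d_ovh = float(np.linalg.norm(ga.ovh.values - gb.ovh.values))
    d_ozh = float(np.linalg.norm(ga.ozh.values - gb.ozh.values))
    return d_ovh + d_ozh


def point_predict(
    kb: KnowledgeBase,
    query: GeometrySignature,
    metric: MetricSpec,
    k: int = DEFAULT_NEIGHBORS,
) -> float:
    """Average the metric over the ``k`` library cases most similar in geometry.

    Similarity is evaluated on the metric's own organ, so different organs
    of one query may be informed by different neighbors.  Ties in distance
    are broken by library order (stable sort), which makes the prediction
    deterministic.
    """
    candidates = [
        c for c in kb.cases
        if metric.key in c.achieved and metric.organ in c.signature
    ]
    if len(candidates) < k:
        raise InsufficientCasesError(
            f"{len(candidates)} cases record {metric.key}; k={k} required"
        )
    dists = np.array([signature_distance(query, c.signature, metric.organ) for c in candidates])
    order = np.argsort(dists, kind="stable")[:k]
    return float(np.mean([candidates[i].achieved[metric.key] for i in order]))


# ---------------------------------------------------------------------------
# Interval prediction
# ---------------------------------------------------------------------------

def _design(form: str, auc_ovh: np.ndarray, auc_ozh: np.ndarray) -> np.ndarray:
    if form == "constant":
        return np.ones((auc_ovh.size, 1))
    if form == "line":
        return np.column_stack([np.ones_like(auc_ovh), auc_ovh])
    return np.column_stack([np.ones_like(auc_ovh), auc_ovh, auc_ozh])


def fit_interval_model(kb: KnowledgeBase, metric: MetricSpec, form: str | None = None) -> IntervalModel:
    """Least-squares fit of one metric on the library AUC features.

    The residual standard deviation uses the unbiased n - p denominator,
    with p the number of fitted coefficients.
    """
    if form is None:
        form = MODEL_FORMS.get(metric.key, "plane")
    rows = [
        (c.signature[metric.organ].auc_ovh, c.signature[metric.organ].auc_ozh, c.achieved[metric.key])
        for c in kb.cases
        if metric.key in c.achieved and metric.organ in c.signature
    ]
    if len(rows) < _MIN_CASES[form]:
        raise InsufficientCasesError(
            f"{len(rows)} cases record {metric.key}; {_MIN_CASES[form]} needed for a {form} fit"
        )
    x, z, y = (np.array(v, dtype=float) for v in zip(*rows))
    X = _design(form, x, z)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {metric.key}: AUC features carry no variation"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return IntervalModel(metric, form, tuple(float(b) for b in beta), sigma, len(y))


def predict_interval(model: IntervalModel, auc_ovh: float, auc_ozh: float) -> tuple[float, float]:
    """+/- 3 sigma_res prediction interval; lower bound floored at zero.

    The floor reflects that doses and volume fractions cannot be negative.
    """
    center = model.center(auc_ovh, auc_ozh)
    lo = max(0.0, center - 3.0 * model.sigma_res)
    hi = center + 3.0 * model.sigma_res
    return lo, hi


def normalize_metric(value: float, lo: float, hi: float) -> float:
    """Map an achieved metric onto the interval scale: 1 at lo, 0 at hi.

    Intentionally unclipped: values better than the lower bound map above
    1 and values worse than the upper bound map below 0, which the weight
    update rules rely on.
    """
    if hi <= lo:
        raise ValueError(f"degenerate interval [{lo}, {hi}]")
    return (hi - value) / (hi - lo)


def derive_goals(
    kb: KnowledgeBase,
    query: GeometrySignature,
    metrics: tuple[MetricSpec, ...] = TABLE_METRICS,
    sliders: dict[str, float] | None = None,
    k: int = DEFAULT_NEIGHBORS,
) -> list[PlanningGoal]:
    """Planning goals: interval bounds plus a goal value T per metric.

    The point prediction is clamped into the interval.  A slider setting
    s in [0, 1] (keyed by ``MetricSpec.key``) places T = lo + s*(hi - lo);
    without a slider T is the clamped point prediction.  Metrics whose
    organ is absent from the query signature are skipped.
    """
    sliders = sliders or {}
    goals: list[PlanningGoal] = []
    for metric in metrics:
        if metric.organ not in query:
            continue
        model = fit_interval_model(kb, metric)
        g = query[metric.organ]
        lo, hi = predict_interval(model, g.auc_ovh, g.auc_ozh)
        point = point_predict(kb, query, metric, k=k)
        clamped = min(max(point, lo), hi)
        s = sliders.get(metric.key)
        if s is not None:
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"slider for {metric.key} must be in [0, 1]")
            goal = lo + s * (hi - lo)
        else:
            goal = clamped
        goals.append(PlanningGoal(metric, point, lo, hi, goal))
    return goals
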