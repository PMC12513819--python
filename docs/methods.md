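# Methods

This note documents the models, parameter choices and numerical
conventions behind `vmatplan`, and what the synthetic test bed does and
does not establish about the method on real data.

## Geometry descriptors

All structures are boolean voxel masks on one regular grid whose third
index is the cranio-caudal axis. Distances are signed Euclidean
distances between voxel centers under the physical spacing (exact
distance transform), negative inside a mask. The overlap volume
histogram of an organ with respect to the target,

    OVH(t) = |{v in OAR : dist(v, PTV) <= t}| / |OAR|,

and its 1-D cranio-caudal analog

    OZH(t) = |{v in OAR : z_v in [z_min(PTV) - t, z_max(PTV) + t]}| / |OAR|

are sampled on one fixed global window, t in [-50, +100] mm in 1 mm
steps. The window is a package constant recorded in every knowledge
base and validated at query time: the area-under-curve features
(trapezoid integral divided by window length, hence in [0, 1]) are only
comparable across cases when every case uses the same window. The OZH
is defined here as the minimal 1-D analog of the OVH — a z-interval
expansion/contraction — because only the construction's intent (capture
cranio-caudal relations the rotation-symmetric OVH misses) is fixed by
the method; alternative weightings of the two descriptors would slot in
at `signature_distance`, which currently sums the two L2 curve
distances with equal weight, per organ. Per-organ matching was chosen
so different organs of a query can be informed by different neighbors.

Threshold conventions: all `<= t` and `>= dose` comparisons are
inclusive, which makes behavior on integer-valued synthetic fixtures
deterministic. `expand(t)` keeps every voxel with signed distance
<= t; `contract(t)` is its morphological dual (complement, expand,
complement), i.e. strict, so a 1-voxel rind peels exactly the boundary
layer — the skin structure of the preparation phase depends on this.

Auxiliary-structure margins (skin rind 5 mm, esophagus z-extension
10 mm, anterior-avoid margin 20 mm around the PTV) are configurable
defaults; the method names these structures but their margins are
institutional choices. "Anterior" is the low-y half of the external
contour, split at its centroid.

## Prediction

**Point prediction.** The metric values of the five library cases with
the smallest combined OVH+OZH curve distance (on the metric's organ)
are averaged. Ties are broken by library order, making the prediction
deterministic. A knowledge base must hold at least 6 cases so that
leave-one-out evaluation leaves 5 neighbors.

**Interval prediction.** Per metric, ordinary least squares of the
achieved value on the AUC features over the whole library:

- plane on (AUC_OVH, AUC_OZH): lung mean, lung V20Gy, heart mean,
  breast means;
- line on AUC_OVH alone: esophagus D0.5cc, skin D0.5cc;
- constant (mean ± 3 sample SD): spinal cord D0.01cc.

The residual standard deviation uses the unbiased n − p denominator.
The prediction interval is the fitted surface shifted by ±3 σ_res
(99.73% under Gaussian residuals); the lower bound is floored at zero
because negative doses and volume fractions are unphysical. A plain
±3 σ̂ interval ignores coefficient-estimation error, so its true
coverage at n = 103 sits a tenth of a percentage point or two below
the nominal 99.73% — visible in the Monte-Carlo experiment below and
inherent to the construction, not a defect of the fit.

The interval doubles as the normalization frame of the planner: an
achieved value A maps to (hi − A)/(hi − lo), so 1 is optimal sparing
and 0 the worst expected outcome. The map is deliberately unclipped;
values far better than the lower bound exceed 1, which is what lets
the OAR weight-release branch (Δ ≤ −0.999) fire.

The spinal-cord/esophagus metric pair is taken as D0.01cc/D0.5cc
throughout (the declared prediction target set). The point prediction
is clamped into the interval before becoming a goal; without a slider
the goal is the clamped point prediction, with a slider s it is
lo + s·(hi − lo).

## Dose engine

The bundled engine is a transparent stand-in for a clinical optimizer;
the planner observes only dose, per-objective values F_obj = w·f and
their sum F_tot, so any smooth convex engine with that interface could
replace it.

- **Influence matrix**: parallel pencil beamlets at 36 equispaced
  coplanar angles by default, 4 mm beamlet width, traced exactly
  through the voxel grid in the axial plane (Amanatides–Woo traversal)
  and replicated per slice. Deposition per voxel is intersection
  length × exp(−μ·radiological depth) with μ = 0.005/mm, depth
  accumulated only inside the external contour.
- **Objectives**: normalized one-sided quadratics — e.g. min-dose
  penalty mean(max(0, L − d))²/L², a mean-dose excess penalty, a
  hot-volume-fraction excess penalty, and a hottest-x-cc variant whose
  subvolume is recomputed every gradient step. f = 0 exactly when the
  objective is met.
- **Solver**: projected gradient on the non-negative beamlet
  intensities, Armijo backtracking (halving), relative F_tot tolerance
  1e-6, at most 500 inner iterations, warm-started from the previous
  adaptation iteration (emulating "continue optimization" in a TPS).
  The initial step per iteration is a Barzilai–Borwein estimate: the
  adaptation loop produces weight spreads of four to six orders of
  magnitude, under which a fixed-scale step crawls; BB initialization
  handles that conditioning while backtracking preserves the
  monotone-descent guarantee. Everything is deterministic for a fixed
  initial point.

The clinical 350 MU-per-arc cap is carried in the configuration for
fidelity but not enforced: the engine has no monitor-unit concept.

## Planner loop

Phase I runs one optimization with default weights (10 OAR / 100 PTV,
OAR objective levels 10% below the goals, PTV min/uniform/max at
95%/100%/105% of the prescription). Each subsequent pass spends one
engine call from a shared budget of 40: an OAR pass while any OAR gap
is positive (all OAR weights updated simultaneously from the previous
iteration's Δ and ratio), otherwise a target pass. The piecewise OAR
rule is continuous at both interior boundaries: (1 + Δ) → 0.001 as
Δ → −0.999⁺, and 1 + 0.1·100 = 11 at the ratio cap. Δ in [−0.05, 0]
leaves the weight untouched (a goal met within tolerance needs no
action); this dead band is the one region the printed rule does not
enumerate.

PTV gaps live on raw fractional scales: the coverage shortfall
0.95 − C for the minimum-dose objective and the fractional D2% excess
over 1.05·D_p for the maximum-dose objective, so the 0.1 branch
threshold reads as an absolute fraction. The contribution ratio in the
PTV update is capped at 100 like the OAR rule: with normalized
quadratic penalties a hairline violation has F_obj ≈ 1e−7, the raw
ratio is ~1e5, and an uncapped update blows the weight up
double-exponentially (observed 1e11 within five passes), freezing the
solver; in a clinical TPS the objective magnitudes make this academic.
Each target pass deletes and regenerates the high-dose suppression
structure from the current dose ({dose ≥ 0.95·D_p} minus PTV) and, if
non-empty, attaches a maximum-dose objective at D_p with weight 100·i.

The preliminary call does not count against the 40-iteration budget
("40 in total" is read as the adaptation budget), so a trace holds at
most 41 records. `status == "satisfied"` is equivalent to every final
gap ≤ 0; on `iteration_cap` the CLI prompts the user to revise the
planning goals.

If an objective reports F_obj = 0 while its metric gap is positive
(possible only when objective and metric disagree about what they
measure), the ratio is treated as +∞ — the capped branch — and a
warning is logged.

## Synthetic test bed

**Phantoms.** Deterministic per seed. Default grid 96×96×48 at 4 mm
(full 3-D), with a 64×64 single-slice variant for planner-loop studies
and a 32×32×16 at 8 mm variant for library-scale generation — sizes
chosen so a full planner run stays interactive on one CPU. Organ
templates (external ellipse, two lung ellipsoids, heart blob, 1-voxel
spinal-cord column, esophagus tube) are placed as fractions of the
grid extent; the PTV is an ellipsoid jittered around one lung with
volumes spanning roughly 90–1400 cc under the default radius range,
inside the observed clinical spread (85–1672 cc). Mediastinal
placements penetrate heart and esophagus, as real target volumes do.

**Libraries.** Fast mode draws each achieved metric from
a + b·AUC_OVH + c·AUC_OZH + N(0, σ), truncated at zero, with the AUC
features computed from actual phantoms. The default per-metric
coefficients are order-of-magnitude choices that land the metrics in
clinically plausible ranges (lung mean ≈ 10–15 Gy, V20 ≈ 15–25%,
cord ≈ 28 Gy, …); the real library's residual magnitudes are unknown,
so σ defaults are config-exposed and never asserted. Planned mode
instead measures metrics from a dose actually optimized on each
phantom with default objectives — full goal-driven planning per
library case would be circular, since goals require a library.

**Coverage experiment.** The 99.73% claim is checked by Monte Carlo:
20 independently generated 103-case libraries are fitted and 500 fresh
cases per library (10,000 total) are drawn from the same generating
model and scored against their ±3 σ̂_res intervals. Averaging over
replicate libraries estimates the coverage probability of the
procedure itself; a single library's empirical coverage varies by a
few tenths of a percentage point with the draw of σ̂. Fresh-case
features are bootstrap-resampled from the library's feature pairs,
which preserves the strongly correlated (r ≈ 0.8) OVH/OZH feature
distribution; drawing features uniformly over the feature bounding box
instead inflates leverage at off-data corners and biases coverage low.
With heavy-tailed residuals in the generator the same experiment drops
visibly below 99.73% — the band is a Gaussian statement.

**What passing tests do and do not show.** The phantoms reproduce
topology, not anatomy: no CT densities, no heterogeneity corrections,
no breathing motion, and the fast-mode metric model is linear by
construction — so recovery and coverage results validate the
statistical machinery, not the linearity assumption on clinical data.
The dose engine is convex and parallel-beam; it exercises the
adaptation loop's control logic faithfully but says nothing about
deliverability, MLC sequencing or plan complexity.

## Numerical conventions

- DVH metrics come from raw sorted voxel doses, never binned curves
  (binned curves exist for display/serialization only). D at volume x
  is the minimum dose of the hottest ceil(x / voxel volume) voxels.
- CI is defined as 0 with a warning when no voxel reaches the
  reference isodose.
- A ray lying exactly on the upper grid boundary belongs to no voxel
  row (half-open membership), keeping opposed beams symmetric.
- The interval lower bound, synthetic metrics, and beamlet intensities
  are all floored at zero.
- OAR objective levels are floored at 0.05 Gy so a zero goal cannot
  produce a degenerate objective.

## Known limitations

- DICOM-RT import is a documented stub; cases live in a simple
  directory format (grid.json + one NIfTI volume per mask).
- The planner updates all OAR weights simultaneously per pass;
  per-organ sequential updates are a plausible alternative reading and
  would change iteration counts, not fixed points.
- Single-slice phantoms have no OZH variation, so plane-form metrics
  cannot be fitted on a purely planar library (the fit correctly
  raises); use the 3-D library family.
- d_pct goals have no objective translation (none of the supported
  prediction metrics needs one).
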