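# Methods

## Study design encoded by the pipeline

Participants are enrolled for 16 weeks. Symptom questionnaires are
scheduled at baseline and every 3 weeks (weeks 4, 7, 10, 13, 16); the
PHQ-8 has one extra check-in at week 1. Change pairs are built over the
post-baseline check-ins only — six PHQ-8 check-ins (weeks 1–16) give five
pairs per participant, five GAD-7/SPIN check-ins give four — because the
baseline questionnaire precedes any sensing and has no preceding sensor
window. Baseline scores still enter the within-person mean used to fill a
single missing member of a pair, and the item-level baseline is the input
to symptom-profile clustering.

Each check-in at study day d = 7·week anchors two 14-day sensor windows:
*preceding* = days [d−14, d−1] and *proceeding* = [d, d+13]. With 3-week
spacing the preceding windows of a pair always end strictly before the
symptom scores they predict (enumerated in the tests), which is the point
of the lag design: concurrent sensing never overlaps the outcome.
Consecutive check-ins' preceding and proceeding windows can share days
with *each other* (14 + 14 > 21); that is inherent to the design, not an
error. A window is treated as missing when fewer than `min_valid_days`
(default 7, half the window) days carry sensor data.

Day boundaries are local midnight: timestamps are stored UTC and shifted
by a per-participant `tz_offset_hours` before bucketing.

## Sensor features

**GPS.** Per-fix speed is haversine distance (R = 6371 km) over elapsed
time; fixes faster than 1 km/h are *transition*, the rest *stationary*;
the first fix inherits the second's state. Sampling gaps longer than
30 min break transition segments — no distance is imputed across a gap.
Stationary fixes are clustered by k-means with k grown from 1 until every
member lies within 500 m of its centroid (both thresholds configurable;
they follow the mobility-sensing literature this feature set comes from).
Window-level features: log location variance log(var lat + var lon + ε);
cluster count; dwell-time entropy and its ln k normalisation (defined 0 at
k = 1); circadian movement as log Lomb–Scargle energy of the latitude and
longitude series summed over periods 23.5–24.5 h (the band edges are a
package decision — no standard value exists — and are configurable);
total transition distance; and distance-weighted mean transition speed.
ε = 1e−10 guards the logs because single-location traces are legitimate.
GPS features are computed over the whole window, not daily-then-averaged:
cluster counts and 24-hour periodicity are window-level constructs.

**Semantic locations.** Labels collected during assessment weeks map
centroids to {home, work, shopping, social, religious, exercise}. Each
window's clusters take the category of the nearest labelled centroid
within 200 m (ties: distance, then lexicographic category), else "other".
A stationary fix credits 5 min to its cluster's category, but only within
dwell episodes of ≥3 consecutive fixes (≥15 min) — a deliberately
conservative reading of a "more than 10 minutes" visit rule given the
5-min cadence.

**Communication and apps.** Daily sums of incoming/outgoing call counts
and durations and SMS counts and lengths; each foreground-app sample
credits 5 min to its category (active / information / social via an
editable app-id map; unmapped apps fall to "other" and are excluded from
the feature groups). Daily values are averaged over the window's sensed
days; a sensed day without events counts as zero, not missing. Averaging
(rather than summing) makes window values robust to missing days.

## Standardisation and grouping

All base features are z-scored (n−1 denominator) across the full sample
of participant-windows jointly — not per participant — and averaged with
unit weights into 14 groups: Locations {clusters, location variance},
Time {entropy, normalised entropy, circadian movement}, Transitions
{distance, velocity}, the six semantic durations, Calls, Text Messages,
and the three app categories. A group is missing only when all members
are missing; otherwise it is the mean of the present members.
Zero-variance features standardise to zeros with a warning rather than
NaN, so degenerate cohorts still aggregate.

## Clustering

k-means on the raw 32 baseline items (items are already on comparable
0–3/0–4 scales; a config switch enables scaling), n_init = 50, k scanned
over 1–8. The elbow is operationalised as the maximum second difference
of the inertia curve, since the visual heuristic cannot be coded
verbatim. Cluster indices are relabelled by ascending mean baseline PHQ-8
so labels are reproducible; all downstream analysis is keyed by cluster
content, never raw k-means index.

## Inference

The repeated-measures correlation is computed by within-participant
centering (equivalent to ANCOVA with participant intercepts and one
shared slope): r_rm = Σx̃ỹ/√(Σx̃²Σỹ²) over the centred series, two-sided
t-test on N_obs − n − 1 df. Participants with fewer than two complete
pairs are excluded. The table also reports n·(k̄−1), a df convention some
reports use; it is displayed for comparability, never used for inference.
Benjamini–Hochberg adjustment (via statsmodels) is applied within each
measure × cluster × direction family of 14 feature groups — the family
definition matches how such tables are presented per measure and cluster,
and is config-exposed. The running-minimum step can make adjacent
adjusted p-values identical; that is a property of the procedure.

The power helper returns n = trunc(((z₁₋α/₂ + z_power)/atanh ρ)²); a flag
adds the +3 Fisher small-sample correction and ceils instead. The
truncating convention is the one whose output (255 at ρ = 0.2, α = .05,
power .90; raw value 255.66) matches the standard reference value, and a
Monte-Carlo test confirms empirical power 0.90 ± 0.02 at that n.

## Synthetic cohort

The generator encodes exactly the structure the analysis assumes, so the
pipeline can be validated by parameter recovery.

* Four latent symptom profiles with weights (0.312, 0.252, 0.245, 0.191)
  and group-mean totals chosen to echo the qualitative profiles (minimal:
  PHQ-8 3/GAD-7 3/SPIN 10; depression+social-anxiety: 12/5/35;
  depression+anxiety: 15/12/12; multiple comorbidities: 18/15/45).
  Baseline items are binomial draws whose expected sum is the group mean.
* A daily behavioural-activation state B per participant, stationary
  AR(1) (coefficient 0.9, marginal variance 1), drives the number of
  outings, travel, communication volume, and app use.
* Symptom totals at check-in j:
  Sx = μ_group + u_i + a_j + λ·z(B̄_pre(j)), with person intercept u_i
  (SD 2 on the PHQ-8 scale, scaled per instrument), AR(1) person process
  a_j (coefficient 0.5, innovation SD 3, scaled per instrument), and a
  coupling term on the standardised latent mean of the *preceding*
  window. λ is calibrated numerically from the cohort's own empirical
  second moments so that corr(ΔSn, ΔSx) equals `coupling_rho` — the knob
  is stated directly in the units the analysis estimates. Totals are
  rounded and clipped to instrument ranges (a small, accepted
  attenuation). Reverse coupling (default 0, enabling the specificity
  test) shifts the coupled features of the proceeding windows by κ·z(Sx),
  with κ solved by root finding.

Two tiers share this latent model. The **event tier** emits raw streams:
288 five-minute GPS fixes per day built from per-participant anchor
locations (home plus 0.8–3 km satellites) with Poisson outings whose mean
increases in B, ≥30-min dwells, straight-line travel at ~30 km/h, and
configurable GPS jitter; Poisson call/SMS events and app samples whose
rates increase in B; semantic labels for the anchors. The **feature
tier** emits window-level base features directly: the coupled group's
members load on z(B̄) with loading 0.95, all others are unit noise. The
feature tier exists because Monte-Carlo validation of the inference chain
(hundreds of seeded cohorts) does not need thousands of GPS-trace
extractions to inform the statistics under study; the event tier is
exercised end-to-end at smaller cohort sizes.

Missingness: post-baseline assessments are removed with probability
expit(logit(rate) + slope·z(baseline PHQ-8)) — missing-not-at-random when
the slope is positive — and whole sensor days are removed uniformly,
jointly across streams.

What the generator does **not** emulate: street-network trajectories,
app-level content, weekday/weekend structure, seasonal trends,
device-specific sampling irregularity, or informative *sensor* (as
opposed to assessment) missingness. Passing recovery tests therefore
demonstrate that the pipeline estimates what it claims under the model's
assumptions; they do not certify performance on real cohorts, where
feature noise and confounding are richer. Consistent with that, the
end-to-end event-tier estimate is attenuated relative to the injected
latent coupling (extracted features track the latent state imperfectly),
while the feature-tier estimate recovers the target almost exactly —
the gap is measurement attenuation, which real studies face too.

## Problem sizes and numerical choices

Monte-Carlo suites use 200-participant feature-tier cohorts for recovery
(100 seeds in the tests, 30 in the acceptance script) and 100-participant
cohorts for the 200-run null-FDR study; the Monte-Carlo power check uses
5000 replicates; the event tier runs end-to-end at 6–24 participants.
These sizes give stable estimates (recovery SE ≈ 0.03) at desk scale.
All randomness flows from a single `numpy.random.default_rng` seed per
generator call; identical seeds give byte-identical cohorts. Haversine
uses R = 6371 km throughout. CSV floats are written at 17 significant
digits and parsed with round-trip precision so save/load cycles are
bit-exact.

## Known limitations

* The adaptive k-means cluster count can depend on the k-means seed for
  ambiguous geometries; the seed is fixed in config.
* The proceeding window of the final (week-16) check-in has no sensor
  data in a 16-week study, so the reverse direction has one fewer pair.
* rmcorr assumes a common within-person slope; heterogeneous slopes are
  averaged, not modelled.
* No causal claims: the lag design establishes temporal precedence only,
  and nothing beyond the 2-week window is analysed.
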