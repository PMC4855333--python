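# Methods

## Overview

`fptmigrate` determines the timing of spring migration for a seasonal
migrant (developed with migratory caribou in mind) purely from changes in
movement pattern, with no reliance on fixed geographic landmarks. The chain
is:

1. **Track regularization** — filter raw satellite relocations and
   interpolate them to a 12-h grid.
2. **First-passage time (FPT)** — convert the path to a one-dimensional
   profile measuring area-restricted search intensity.
3. **Penalized-contrast segmentation** — cut the FPT profile into bouts of
   homogeneous mean, selecting the number of bouts from the data.
4. **Two-step detection** — identify winter breaks on the whole profile,
   then re-segment each inter-winter slice to find the June (calving) pause;
   migration departure and arrival dates follow from the bout boundaries.
5. **Validation** — a correlated-random-walk simulator with labeled ground
   truth, and scoring rules that reproduce the published validation design.

## Track regularization

Raw ARGOS-style data carry several fixes per transmission day at varying
quality. Within each transmission period (default: calendar day,
configurable) only the most accurate fix is kept (class order
3 > 2 > 1 > 0 > A > B, ties to the earlier fix). A forward speed filter then
drops any fix implying more than 50 km/day from the last *retained* fix —
re-testing against the last survivor rather than deleting pairs, so a single
aberrant position cannot remove valid anchors.

The filtered track is resampled by linear interpolation onto a 12-h grid
anchored at the first fix, i.e. constant speed and heading within each
inter-fix leg. Real fixes are snapped to the nearest grid time keeping their
coordinates, so interpolation adds no path length. Gaps of any length are
bridged (the per-point `gap_h` column reports how much); no gap cap is
imposed, matching fix intervals of up to 7 days in the motivating data.

## First-passage time

For a circle of radius r centred on a path point, FPT is the backward
passage time (elapsed time, walking back along the path, until the
trajectory first lies more than r from the point) plus the forward passage
time. The crossing instant is located exactly by solving the
circle–segment intersection on the crossing step, consistent with the
constant-speed-per-leg model; FPT is reported in days and computed at every
grid point, real or interpolated.

FPT is *undefined* where the path ends before crossing in one direction —
always at the first and last points, and potentially over long stretches of
a slow bout at the start of a path (no backward crossing exists until the
animal has drifted r from its early positions). Undefined values are
reported as missing, never zero-filled.

The working radius is selected from the data: S(r) = Var[log FPT(r)]
(natural log; base only shifts the scale, not the peak) is computed per
annual path over a grid of radii (10–100 km by 5, 110–300 km by 10),
averaged over paths, and the radius at the peak of the mean is taken as
r_max. For caribou-scale simulations and the motivating data this peak sits
at ~25 km, about half the long axis of a winter range; 25 km is the package
default for single-profile work.

## Penalized-contrast segmentation

The profile y_1..y_n is partitioned into K contiguous segments minimizing
the within-segment sum of squares about segment means (the *mean* contrast
J; variance-based contrasts are deliberately not implemented because the
dominant changes in FPT profiles are changes of level). For every
K ≤ Kmax the optimum is found exactly by dynamic programming over admissible
breakpoints with a minimum segment length l_min; ties take the smallest
admissible start index at each step, making output deterministic.

The number of segments K* is chosen by the curvature heuristic: J(K) is
rescaled to decrease from Kmax to 1,

    J~(K) = (J(Kmax) − J(K)) / (J(Kmax) − J(1)) · (Kmax − 1) + 1,

and K* is the largest K with discrete second derivative
D(K) = J~(K−1) − 2 J~(K) + J~(K+1) > S. Defaults: Kmax = 30 (well above the
five-ish bouts expected in an annual profile), l_min = 1 (detect bouts of
any duration), S = 0.75. A constant series (degenerate curve) yields K* = 1.
No explicit penalty weight is needed; the curvature rule takes its place.

**Missing values.** Undefined FPT points are removed before segmentation and
the compact series is segmented; an index map restores path coordinates
afterwards. The alternative — linear imputation across undefined runs — was
rejected after testing: imputing across a 50-point undefined run inside a
break manufactures a ramp that the mean contrast happily fits as structure,
displacing boundaries by tens of points and measurably degrading the
validation statistics below. Dropping keeps the contrast faithful to what
was observed.

Breakpoints that land on interpolated points are snapped to the nearest
point backed by a real fix (ties to the earlier one) before dates are read
off, since interpolated points carry no observation.

## Simulator

Each simulated path concatenates eight contiguous blocks —
range 1, leg, stopover, leg, range 2, leg, stopover, leg — at one location
per 12 h. Two designs: **2LB** (both ranges are long breaks: 200 locations,
50-km patch) and **1LB** (second range is a short break: 100 locations,
25-km patch, deliberately indistinguishable from a stopover, as for the
caribou calving pause). Migration legs have 100 locations each; stopovers
100 locations in 25-km patches.

Movement is a correlated random walk: per-step speeds log-normal with
arithmetic mean 15 km/day (migration) or 3 km/day (break) and CV 1 (the
log-normal is parameterized so the arithmetic mean is exact); turning angles
wrapped Cauchy (inverse-CDF sampling) with mean 0 and concentration 0.8
(migration) or 0.1 (break). Step length is speed x 0.5 day. During breaks
the patch edge reflects: a step crossing it is truncated at the edge and the
next step's base heading points at the patch centre, with the usual turning
noise. Legs start headed at a waypoint one spacing (default 400 km) ahead
of the current position along the migration axis; patches are centred
wherever the preceding leg ends (geometry is emergent — only the
speed/turning/patch contrast drives the FPT profile, so waypoint placement
is a free choice). The default start date (Jan 15) places the two long
breaks across winter windows and the first stopover in June, convenient for
exercising the detection pipeline; it does not affect the profile itself.

What the simulator emulates: the contrast structure between directed travel
and area-restricted search, at realistic caribou scales. What it does not:
habitat-driven movement, fix dropout and location error, multi-day fix
intervals (simulated paths are already regular), and gradual behavioural
transitions. Passing validation therefore demonstrates that the
segmentation recovers bout structure under the stated movement model, not
that it is robust to every feature of field data.

A known consequence of the stated design is that a path *starts inside* its
first break with no history: the break walk (RMS net displacement ≈ 33 km
over 200 steps) sometimes fails to drift 25 km, so the backward passage —
and hence FPT — is undefined over much or occasionally all of the first
break. The first plateau is then partly or wholly invisible to the
segmentation. This is a property of the study design, not a defect of the
estimator, and the scoring rules below account for it.

## Two-step detection

A segment is classified a *break* when its mean FPT exceeds c x the median
of all segment means in the same segmentation (default c = 2) — scale-free,
hence robust to differences in fix rate between animals. Calendar windows
then assign identity: winter breaks must touch Dec–Apr; the calving pause
must touch June 1–30 (both configurable; the defaults reflect caribou that
leave winter ranges around April and calve in late May–June).

Step 1 segments the whole multi-year profile and returns winter breaks; a
boundary shared with the data edge is flagged unobserved and the event
incomplete. Any biological year (Aug 1–Jul 31) with no winter event is
re-segmented on its own — on the yearly slice a weak winter pause is no
longer flattened by the normalization against stronger years — and events
found this way carry route `yearly_fallback`.

Step 2 slices the profile between consecutive winter breaks (plus an
open-ended tail slice) and re-segments each slice alone; with the
winter-dominated contrast removed, the June pause is resolvable. Among June
segments passing the break rule the highest-mean one is the calving event.
If none passes but a calving-ground polygon is supplied, the best June
candidate is accepted when ≥90% of its points fall inside the polygon
(route `spatial_check`) — the programmatic counterpart of confirming an
equivocal pause on a map.

Departure is the winter break's end; if the slice opens with a
pre-migration pause (first fine segment's mean above the following
segment's), departure moves to that pause's end. Arrival is the calving
event's start. Records missing either boundary are flagged incomplete.

## Validation scoring

Ground truth is the simulator's labeling (break vs migration per point). A
segmentation **fails** when a detected segment materially includes both a
break and a migration true segment; **precision** over successful paths is
the fraction of scored points whose detected segment's majority class
matches the point's true class. Only points with a defined FPT value are
scored — the segmentation never saw the others.

"Materially includes" requires covering more than max(50 points, half of
the true segment's defined points). The floor-and-majority tolerance is the
package's operationalization of the visual success scoring used in the
original validation design, which plainly tolerated boundary jitter of tens
of points (its reported precision SD of ±2.2% corresponds to 20–40
misassigned points per 1000-point path): a merged segment covers a true
segment wholesale and always fails, while boundary jitter below ~25 days
never does. The two tolerance constants were calibrated once against the
published validation statistics on a dedicated 40-path calibration set and
then frozen; the validation runs reported by `scripts/acceptance.py` and the
test suite use fresh seeds.

When the number of segments is forced to 4, scoring uses the four expected
blocks (two ranges, two migrations-including-stopovers) as truth: four
segments cannot resolve stopovers by construction, and the constrained
experiment asks whether the two ranges are correctly isolated. Under this
truth the 2LB design mostly succeeds (failures are paths whose first
plateau is largely undefined, so the DP spends its three cuts elsewhere)
while 1LB almost always fails — its short second range is indistinguishable
from a stopover, which is precisely the argument against fixing K from
prior expectations.

Validation runs 50 replicate paths per design (~1000 points each) x three
settings (l_min = 1, l_min = 10, forced K = 4); the full grid takes well
under a minute on one CPU. A paired t-test (`compare_precision`) compares
precision between settings on shared paths.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| max_speed | 50 | km/day | speed filter on raw fixes |
| interval | 12 | h | regularization grid |
| r (radius) | 25 | km | FPT circle; select via variance peak |
| Kmax | 30 | segments | DP ceiling; set well above expectation |
| l_min | 1 | points | minimum segment length |
| S | 0.75 | – | curvature threshold for K* |
| c (break_factor) | 2 | – | break rule: mean > c x median of means |
| winter window | Dec–Apr | months | winter-break identity |
| calving window | Jun 1–30 | dates | arrival identity |
| polygon_min_inside | 0.9 | fraction | spatial-check acceptance |
| tol_points / tol_frac | 50 / 0.5 | points / fraction | scoring inclusion tolerance |

## Numerical choices

- Circle crossings solved exactly on the crossing step (quadratic root
  within the segment), both in FPT and in the patch reflection.
- DP cost matrix via cumulative sums, clipped at 0 against round-off;
  exact, no pruning.
- Argmin/argmax ties resolve to the first (smallest) index throughout:
  earliest DP breakpoints, smallest r_max, earlier real fix when snapping.
- All randomness flows from one `numpy` Generator seeded per path;
  replicate seeds are drawn below 2^31 from the experiment seed.

## Limitations

- Fall migration is out of scope: it spans longer, may split into bouts,
  and lacks the sharp bracketing pauses of spring.
- The break rule's c = 2 was chosen on simulated contrast; species with
  shallower travel/residency contrast may need a smaller c or the yearly
  fallback more often.
- The simulator's break walk can render the first break (partly) invisible
  to FPT, as discussed; analyses of real multi-year tracks are unaffected
  since profiles begin mid-summer movement, not mid-break.
- Coordinates must arrive projected in km; no CRS handling is included.
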