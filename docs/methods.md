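# Methods

This note documents the models and procedures implemented in `lifespace`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic validation does and does not show.

## Trajectory extraction

The segmentation model assumes a person alternates between *stays* (dwells
at a geolocation) and *moves* (travel between geolocations), observed
through irregular, noisy GPS fixes.

**Stay/move labelling.** For each fix at time *t*, all fixes in
[*t*, *t* + `window_s`) are bounded by a latitude/longitude rectangle. If
the geodesic diagonal of that rectangle is at most `diag_threshold_m`, the
window is stationary and *every* fix in it is labelled stay; a fix claimed
by any stay window stays a stay. Otherwise the anchor fix is a move point.
This combines time and distance in one test and needs no resampling of the
irregular stream.

- `window_s` = 300 s: matches the ~5-min modal sampling period of
  power-constrained location logging.
- `diag_threshold_m` = 100 m: ~0.33 m/s sustained displacement over the
  window — above the jitter of 25 m-accuracy GPS, below slow walking. The
  value is a package default (configurable); any value in roughly
  50–200 m behaves similarly at these noise levels.

One boundary effect is intrinsic to the look-ahead rule: the final fix of a
stream (and any fix whose look-ahead window is a singleton) has a
zero-diagonal window and degenerates to "stay". Such isolated stay fixes
are subsequently reclassified by density clustering, so the pipeline-level
output is unaffected.

**Place clustering.** Stay fixes are clustered with DBSCAN under the
haversine metric (`eps` = 25 m, matched to the accuracy ceiling;
`min_pts` = 5, one ~25-min dwell at 5-min sampling). Clusters are numbered
1..K by first visit. Noise fixes — stay-labelled fixes that never
accumulate density, e.g. the lone mid-trip fix of a sparse move — are
reclassified as move points.

**Events.** Maximal runs of fixes sharing (state, place) become events.
Runs are broken at fix-free gaps longer than `max_gap_minutes` = 60; such
gaps remain unclassified time (typically indoor signal loss). Events are
split at local midnight (per-subject IANA timezone) so that per-day metrics
partition lived time; a split necessarily leaves two same-kind neighbours
abutting at the boundary, which is intended, and the merge stage rejoins
them internally before re-splitting.

**Short-event merging.** Events shorter than `min_event_minutes` = 5 whose
two neighbours are compatible (both moves, or both stays at one place)
dissolve, and the neighbours merge across the gap; this iterates to a fixed
point, then still-short events at segment edges are dropped. This removes
GPS-noise flicker at event boundaries without a separate smoothing pass.

**Gap-midpoint boundary assignment.** Event spans anchored strictly to
first/last fix times systematically censor the fix-free interval around
every true transition: under mean-Δ exponential sampling the interval
containing a transition has expected length 2Δ (length-biased sampling), so
each boundary loses ~10 min at Δ = 5 min and a day with four trips
undercounts away-time by over an hour. With `assign_gap_midpoints` (default
on), each sub-hour inter-event gap is split at its midpoint between the two
neighbouring events — an allocation with zero expected error under either
hypothesis about when the transition occurred. Setting it off restores
strict first/last-fix anchoring.

**Home.** A preliminary home is the most populous ~11 m grid cell
(`grid_decimals` = 4) over all fixes — the statistical mode of the
coordinate cloud, robust because sleep hours dominate the fix count. Every
place whose centroid lies within `home_radius_m` = 100 of it is flagged
home (several flagged places model e.g. a house and its garden), and the
final home coordinate is the centroid of all stay fixes at home places.
With no stay fixes at all (all-day travel), home is undefined and
home-dependent metrics are reported missing, never zero.

## Daily metrics

Notable estimator choices:

- **MCP quantile.** The 99% centroid-distance quantile uses ceil
  (`method="higher"`) semantics: on a day with ≤ 100 fixes the cut equals
  the maximum and every fix is retained, which is the conventional
  behaviour of hull-based home-range estimators at small n.
- **Distance covered** sums great-circle legs between *consecutive stay
  centroids*, not raw path length. It deliberately measures place-to-place
  displacement and undercounts wandering (a looping walk from home back to
  home contributes zero); interpret it jointly with time-moving.
- **Hull areas** are computed in a local equirectangular projection about
  the day centroid (distance distortion < 0.5% at ≤ 50 km span).
  Haversine distances use the IUGG mean radius 6 371 008.8 m; ellipsoidal
  corrections are below 0.5% at these scales.
- Events split at midnight contribute their within-day portion to each
  day's time sums, so daily totals can reach but never exceed 1440 min.

## Activity bouts and steps

Bout extraction follows the recognition stream's own granularity: labels
of interest (still, on-foot, bicycle, vehicle; walking/running folded into
on-foot), per-timestamp maximum confidence with ties kept as genuinely
multi-label instants, a 10-min same-activity grouping gap, and removal of
single-reading bouts. The gap is measured between consecutive readings of
one activity type. Bouts crossing midnight belong to their start day (they
are short). Move annotation picks the transport mode with the largest
total bout overlap; ties break to the earlier-starting bout.

Daily step totals treat any negative count difference as a reboot and take
the post-reboot reading itself as the increment — a deterministic lower
bound on steps walked while the register was down. Steps before a day's
first reading are uncounted (no extrapolation), and watch and phone series
are never fused, because inter-device step disparity is large and device
provenance is itself informative.

## Synthetic free-living generator

The generator draws, per subject, a home and up to 5 fixed places within
0.5–10 km, then tiles each day as home-stay → (move → stay)⁎ → home-stay
with 2–6 trips/day, stays ≥ 30 min (interior stays 30–180 min), trips
≥ 10 min, and a day starting between 08:00 and 11:00. Trip mode is drawn
uniformly from the modes that can complete the leg within 90 min at their
speed (on-foot 1.4, bicycle 4.5, vehicle 12 m/s) — so walking is chosen
only for nearby places, as in real errand-running — and trip duration is
distance over speed, floored at 10 min.

Rendered degradations mirror free-living phone data: exponential
inter-fix times (mean 300 s), isotropic 10 m Gaussian position noise,
accuracy values under the 25 m ceiling, 10% of stay fixes dropped
(indoors), activity readings every ~300 s with whole-move bicycle↔vehicle
label confusion at 0.15 per move, step counters fed by 100 steps/min
cadence plus 60 steps/h ambient with reboots on 20% of days, and log
sheets rounded to 15-min resolution with ±15-min boundary jitter (events
whose rounded span collapses vanish, as a diarist omits a brief stop).

What the generator does **not** model: road networks (moves are straight
lines, so distance metrics are exact rather than route-length), multi-day
behavioural routine, urban-canyon noise correlation, device wear-time
gaps longer than an hour, and per-reading (rather than per-move) activity
misclassification. Passing validation here therefore demonstrates
correctness of the algorithms under realistic sampling and noise, not
performance on any particular real cohort.

## Evaluation statistics

Move matching is greedy one-to-one on start times: candidate pairs within
the ±30-min window are taken closest-first, so one detected move can never
absorb several reference moves. Residuals are algorithm − reference per
paired subject-day; the summary reports RMSD, mean and sample SD (ddof 1).
The transport confusion matrix counts moves whose reference *and* detected
modes both lie in the requested subset (canonically {bicycle, vehicle});
moves with no overlapping transport bout annotate as `unknown` and drop
out of the subset.

## Problem sizes and determinism

The validation studies run at 5 subjects × 7 days (mobility; ~100
reference moves, 35 subject-days) and 10 subjects × 10 days restricted to
bicycle/vehicle (confusion; ~400 moves), sizes at which the binomial
standard error on the confusion accuracy is ≈ 1.8 percentage points and
a single run completes in seconds. All randomness flows from a single
seed through `numpy.random.SeedSequence` spawning, so every table is
byte-reproducible; the extraction pipeline itself is fully deterministic.

## Known limitations

- Stays shorter than ~25 min sampled at 5-min intervals may fail the
  DBSCAN density requirement on first visit and be absorbed into the
  surrounding move.
- A trip whose entire duration falls between two fixes (probability
  e^(−T/300 s), ~13% at the 10-min minimum) is undetectable in principle;
  this bounds move sensitivity at these sampling rates.
- Mobility below the spatial resolution of consumer GPS — room-to-room
  movement indoors — is out of scope.
- Antimeridian-crossing and polar data are rejected rather than handled.
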