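# Methods

## The Digital Arthritis Index

`daindex` scores disease in the rat collagen-induced arthritis (CIA)
model from continuous home-cage activity. Rats are nocturnal; joint
inflammation suppresses their dark-cycle locomotion, and in particular
the fastest movements disappear first. The pipeline therefore:

1. attributes every speed sample (mm/s) to a study day and a light or
   dark phase. The dark period that starts at lights-off on the
   calendar date of study day *d* belongs entirely to day *d*,
   including the post-midnight hours — each dosing day is paired with
   the following night's behavior;
2. extracts one *salient feature* per animal per day from the
   dark-cycle samples. The default is the 99th percentile
   (nearest-rank rule: the ceil(0.99·n)-th smallest of the per-minute
   speeds), a robust version of "maximum speed of motion" that resists
   single-sample outliers; `max` and `mean` are available
   alternatives. A day with less than `min_coverage` (default 50%) of
   its expected dark-cycle minutes is marked missing and never enters
   any downstream quantity;
3. aggregates the feature over a baseline window (study days −2..5,
   always excluding induction day 0) as an arithmetic mean over
   non-missing days, requiring at least 3 usable days (animals below
   the floor are excluded and logged);
4. scores each day as

   DAI_d = max(0, K · (1 − feature_d / baseline)),  K = 20.

   DAI is 0 at (or above) baseline activity and grows as activity
   falls; K = 20 puts the disease-calling threshold of 5 at a 25%
   activity reduction and severe endpoint disease (≈45% reduction)
   near DAI 9. A plain activity ratio would *fall* with disease; the
   reversed, scaled form keeps "higher = sicker", matching how the
   index is used for thresholding and severity.

## Disease calling

For any per-day metric (DAI, ankle joint size, total arthritis score):

* **incidence** — the metric is *strictly* greater than its threshold
  (0.25 in joint size, 4 arthritis score, 5 DAI) on any observed day;
* **onset** — the earliest day the metric is consistently above
  threshold, operationalized as above-threshold on day d *and* d+1, or
  d being the last observed day. One-day persistence would admit
  noise blips; longer runs would make onsets near the end of a 17-day
  study uncallable. The rule is forward-looking over two days only;
  later gaps do not revoke an onset;
* **severity** — the value on day 17 or at humane endpoint (for joint
  size, the change from induction day 0); if the end day itself is
  unobserved the last prior observation is used;
* **cumulative burden** — Σ_d max(0, value_d − threshold) over
  observed days;
* **censoring** — humane endpoint at the earliest of: ankle joint
  ≥ 0.4 in (inclusive, unlike the strict disease thresholds); any hind
  paw at the maximal score 4 on three consecutive daily observations
  (two observations span at most 48 h, so ">48 h" needs three); body
  weight below 80% of baseline. Series are truncated at the censor day
  before any calling.

Joint size per animal is the maximum of the left/right ankle, giving a
single series to threshold. Arthritis scores are per-hind-paw ordinals
0–4 summed to 0–8; front paws are not scored. Histopathology is five
0–5 subscores (inflammation, pannus formation, cartilage damage, bone
resorption, periosteal bone formation) per side, summed to ≤25 and
averaged over sides; a one-sided animal falls back to the measured
side with a logged warning rather than failing, since early-euthanized
animals can have partial data.

## Screening statistics

Group summaries report incidence as a half-up-rounded percentage,
onset mean ± SD over arthritic animals only, and severity mean ± SD
over *all* animals (healthy controls contribute their small nonzero
DAI values, matching how control rows are reported). Cross-metric
agreement uses Pearson correlation and simple least-squares regression
(scipy); undefined cases (zero variance, n < 3) are reported missing,
not zero. Compound ranking uses competition ranks on per-method
severity means: ascending mean, ties share the minimal rank and the
next rank is skipped (1, 2, 2, 4). Dose-effect orderings sort doses
by reduction versus vehicle and render ties with "=", tie-broken in
canonical Low < Medium < High order. Inferential machinery (ANOVA,
post-hoc tests) is deliberately out of scope; the pipeline exports
tidy CSVs for external statistics packages.

## The synthetic cohort generator

No public dataset of this kind exists, so the generator is first-class
code: it emulates the statistical structure the pipeline assumes, with
one latent severity trajectory per animal driving every modality.

* **Latent trajectory** s(d): 0 before a per-animal ramp start, linear
  to the animal's endpoint severity over `ramp_days` (default 4, the
  span over which swelling and scores climb in CIA), then flat.
  Endpoint severity is truncated-normal (mean 0.95, SD 0.05, clipped
  to [0, 1]); a group-level `treatment_effect` in [0, 1] multiplies it
  (0 = full protection, identical in law to a control).
* **Onset parameterization.** `onset_day_mean` (13) and `onset_day_sd`
  (1) describe the day disease becomes *detectable*: the ramp start is
  back-computed so the noise-free DAI crosses the detection threshold
  mid-way through the drawn onset day. Published onset days are
  detected onsets, so this is the scale on which the defaults are
  calibrated, and it makes onset-recovery error a measure of noise
  rather than of a fixed model offset.
* **Activity.** Dark-cycle mean speed on day d is
  `baseline · (1 − max_activity_reduction · s(d))` with baseline drawn
  per animal (22.0 ± 2.4 mm/s between animals — the published nightly
  means vary between animals on exactly this scale) and
  `max_activity_reduction` = 0.45, bracketing the observed ≈43%
  endpoint decline. Light-cycle mean is a fixed fraction (0.3) of the
  same day's dark mean. One sample per minute is generated (video-rate
  data are out of scope; per-minute aggregation suffices for daily
  features). Per-minute noise is Gaussian with SD proportional to the
  current mean (CV 0.3), clipped at 0: locomotor variability scales
  with activity level, and proportional noise keeps the q99 feature
  ratio — hence the expected DAI — analytic (DAI ≈ K·R·s(d)).
* **Clinical measures** on induction day, booster day, and daily
  during dosing: joint size per side = 0.22 + 0.12·s(d) in ± 0.005 in
  caliper noise (clamped to 0.1–0.6 in; the noise scale matches the
  dispersion of healthy-control Δ sizes); paw score =
  round(3.8·s + noise) clamped to 0..4 (endpoint totals then center
  near 7 of 8, as observed in vehicle cohorts); body weight declines
  by up to 8% of a per-animal baseline (≈190 g female Lewis rats).
* **Histopathology** scales each subscore with s(17) using weights
  (0.95, 0.30, 0.35, 0.30, 0.30)·5 — inflammation dominates, totals
  land near 10–11 of 25 for untreated disease — plus rounding noise,
  clamped to 0..5 per subscore.
* **Determinism.** Per-animal RNG streams are spawned from the seed in
  a fixed order; identical (config, groups, seed) reproduce the
  dataset byte-for-byte.

### What the generator does and does not emulate

It reproduces: circadian dark/light activity structure, between-animal
baseline variation, disease-linked activity suppression, correlated
joint/score/weight/histopathology measurements, humane-endpoint
censoring, treated groups with graded protection. It does **not**
model: day-to-day within-animal autocorrelation beyond the latent
trajectory (days are conditionally independent given s(d)), the mild
nonspecific late-study activity decline seen in healthy controls,
pharmacokinetics of specific compounds, or video-level artifacts.
Passing recovery tests therefore shows the pipeline is correct and
well-calibrated under the assumed generative structure — not that the
DAI would achieve the same sensitivity on real cohorts with correlated
day-to-day behavior or sensor dropout.

## Numerical and design choices

* Nearest-rank percentiles (reproducible across implementations; no
  interpolation ambiguity).
* Strict ">" for disease thresholds, "≥" for the 0.4 in humane limit —
  the two rules are worded differently in standard protocols and are
  kept distinct.
* Percentages round half-up (91% from 29/32, 78% from 7/9).
* Missing values propagate: a low-coverage day yields a missing DAI,
  never 0; zero-variance correlations are missing, not 0.
* Baseline division is guarded: non-positive baselines and animals
  with <3 usable baseline days raise a baseline error and are excluded
  with a log record, not silently scored.
* Timestamps are naive local study time; the light schedule interprets
  wall-clock times directly (no timezone arithmetic).
* Default problem sizes: tests use cohorts of 4–20 animals per group
  and ten-seed sweeps for recovery properties, which characterize the
  estimator distributions well at per-minute resolution while keeping
  the suite quick to run.

## Known limitations

The salient-feature family is a single configurable feature, not a
learned combination; K = 20 is a calibration constant, not a measured
quantity. Onset calling assumes near-daily observation; sparse
schedules (gaps > 1 day) can only call onset on a final observed day.
The generator's measurement model is piecewise-linear in the latent
severity — adequate for threshold logic and rank statistics, not for
modeling dose–response curve shapes.
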