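# Methods

## Measurement model

A recording is a sequence of pressure frames from a rectangular sensor
grid. The device of reference has 32 × 32 capacitive sensors of 10 × 10 mm
sampled at 10 Hz with a sensitive range of 3–240 kPa; all of these are
configurable (`GridSpec`). Readings are stored sparsely (zeros implicit),
indices are 0-based, row 0/col 0 is the top-left sensor viewed from above,
and time is `frame / frame_rate_hz` — the device clock is fixed, so no
per-frame timestamps exist. Sub-threshold readings may appear in files
(sensor noise) and are kept by I/O; thresholding is segmentation's job.
Readings above the device maximum are invalid input, because a saturated
sensor clips there and the true pressure is unknowable.

## Contact segmentation

Where the original workflow relied on hand-drawn regions of interest in
vendor software, `hopmat` substitutes a deterministic procedure:

1. **Binarize** at the activation threshold (default: the device's
   sensitive minimum, 3 kPa; inclusive).
2. **Label** maximal connected components in the (frame, row, col)
   lattice. Default connectivity is 26 (Chebyshev ≤ 1): at 10 Hz a rolling
   paw can shift a full sensor between frames, and face-wise 6-connectivity
   would split such stances. Both are available; labeling is verified
   against a brute-force BFS oracle in the tests.
3. **Orient**: travel direction is the sign of the regression slope of
   contact-centroid track coordinate on contact mid-frame (the fore prints
   land earlier and behind the hind prints, so a single hop suffices);
   with a single temporal cluster, the within-stance drift of the pooled
   pressure centroid is used. Below a slope tolerance of 0.05 sensors per
   frame the direction is declared ambiguous and a metadata override
   (`direction_override = ±1`) is required. An override always wins.
4. **Pair**: the hind pair is the two contacts with temporal overlap ≥ 0.5
   (relative to the shorter stance), cross-track centroid separation ≥ 1
   sensor, and the largest combined area; ties break toward the earliest
   pair, and one run yields one evaluated pair (the mat fits about one
   hop). With row 0 at the top and travel toward increasing columns, the
   smaller row centroid is the animal's left hind paw; the assignment
   mirrors for the opposite direction. Remaining contacts are fore paws if
   smaller than both hinds and temporally clear of the hind stance,
   otherwise unknown. How simultaneous non-overlapping fore prints should
   be attributed is not prescribed anywhere; this geometric rule is the
   package's own choice.

### Run quality control

A run is accepted iff none of the following fire:

| reason | rule | default |
|---|---|---|
| `edge_clipped` | a hind contact reaches the outermost sensor ring | — |
| `cross_paw_overlap` | any component's single-frame footprint exceeds `max_single_paw_area`, or a fore contact shares a sensor-frame with a hind | 40 sensors |
| `no_hind_pair` | no simultaneous hind pair found | — |
| `hesitation` | a hind stance exceeds `max_stance_frames` | 6 frames (0.6 s at 10 Hz) |
| `saturation` | a hind reading at the device ceiling | — |

The hesitation rule is a proxy: in the original protocol steadiness was
judged from video, which this package does not ingest. The limit is
expressed in frames, so at other frame rates it must be rescaled to keep
the 0.6 s meaning. Note that paws sharing an actual sensor-frame merge
into a single connected component, so the operative overlap detector in
practice is the per-frame footprint threshold; the fore/hind shared-cell
clause is retained for completeness. A run whose offloaded paw leaves no
print at all (nothing above 3 kPa) is rejected as `no_hind_pair`: without
the contralateral reference the lone print cannot be attributed to a side,
even though by convention a truly unloaded right limb corresponds to a
ratio of −1.

## Load metrics

Per hind contact: **peak pressure** is the maximum over all sensors and
frames of the contact; **TFI** is the rectangle-rule integral of the
per-frame summed force, force being pressure × sensor area. The rectangle
rule (not trapezoid) is deliberate: stances span 2–3 frames at 10 Hz, and
since both paws are sampled on the same clock the discretisation bias
largely cancels in the ratio — at 100 Hz the per-limb TFI converges to the
analytic half-sine impulse within 1% (tested). The symmetry index
`I = (R − L)/(R + L)` requires non-negative loads not both zero; it is
antisymmetric under limb swap, invariant under common scaling, and
reflecting a run across the track axis negates both ratios (tested
properties). Left/right are anatomical throughout; which side is
"affected" is a reporting convention.

## Cohort statistics

* **Quantiles** use linear interpolation between order statistics
  (position `(n−1)·q/100`); other methods exist but this one is the
  package default and the one the reference interval is defined with.
* **Physiological range**: Q2.5–Q97.5 of pooled preoperative single-run
  ratios, all animals and days. No range is defined from per-day animal
  means — too few values would make it arbitrarily strict. Below 40
  pooled values a warning marks the range as unstable. The in-range test
  uses the **closed** interval; boundary hits have probability ~0 for
  continuous data, but the choice is documented and tested.
* **Wilcoxon signed-rank** (two-sided) on paired per-animal day means.
  Zero differences are dropped; tied absolute differences get average
  ranks. The exact null distribution is built by convolution over doubled
  ranks (integer-exact with midranks) and is the default for m ≤ 25; the
  large-sample fallback uses the tie-corrected variance with a continuity
  correction, which keeps |Δp| ≤ 0.02 against exact at m = 12. The exact
  path is verified against full 2^m enumeration and against an independent
  library implementation. No multiplicity correction is applied across the
  timepoint comparisons — matching the small-sample practice this mirrors;
  users making many comparisons should correct externally.
* **Score agreement** reports both Spearman's ρ (tie-corrected, undefined
  rather than zero for constant input) and the R² of a linear fit, so a
  rank-based and a linear reading are both covered, plus the min/max band
  of mean ratios at each score. Points are pooled over the postoperative
  sessions present; pooling is under caller control.
* Session summaries flag SD as undefined (NaN) for single-run sessions.
  The pooled preoperative row of the cohort tables averages each animal
  across days *before* taking range/SD, which is why its mean-value range
  is narrower than any single day's.

## Synthetic cohorts

The simulator emulates the features of real data the analysis depends on:

* **Stance force**: per-limb half-sine, `F(t) = F0 sin(πt/T)`, stance
  T = 0.25 s, peak `load_factor` = 1.5 × bodyweight across both hind limbs
  (body mass default 4.08 kg). These give per-sensor pressures of a few
  tens of kPa, inside the 3–240 kPa window. The load factor is a plausible
  default for rabbit hopping, not an empirical claim.
* **Lameness**: multiplicative offload of the right limb by (1 − λ),
  leaving footprint shape unchanged — the simplest model consistent with
  negative observed ratios. Peak pressure and TFI then carry the same λ,
  so `ratio_pressure ≈ ratio_force` in simulation; on real data the two
  ratios differ, which the simulator deliberately does not reproduce.
* **Variability**: independent lognormal noise per limb per run
  (`noise_sd_log` = 0.20), giving a single-run ratio SD of
  0.20/√2 ≈ 0.14 — the preoperative spread reported for real cohorts —
  plus a per-animal baseline asymmetry drawn once per animal
  (`baseline_sd` = 0.03 on the ratio scale). The run-level ratio is
  `tanh((ln(1−λ) + 2b + ε_R − ε_L)/2)` with median `−λ/(2−λ)`;
  `recover_lambda` inverts that median relation. A ratio-level sampler
  (`sample_run_ratio`) draws from exactly this law and is used for
  large replicate studies (type-I error calibration), where rendering
  every frame would add nothing; a test ties the sampler to the rendered
  pipeline distribution.
* **Study shape**: 12 animals, three preoperative days (λ = 0) and two
  follow-ups (λ ~ N(0.88, 0.08) and N(0.50, 0.10), truncated to [0, 1],
  chosen to reproduce the reported week-1/week-12 mean ratios), five runs
  per day with the first two guaranteed clean, both travel directions at
  random. Observer scores are `λ + N(0, 0.08)` graded through increasing
  thresholds (0.15, 0.40, 0.70, 0.92) onto 0–4, so λ ≈ 0.3 maps to score
  1–2. This is a monotone stand-in enabling the agreement analysis; it
  does not model the systematic underestimation real observers show.
* **Defects**: per-run probabilities (edge-clip 0.08, overlap 0.15,
  hesitation 0.05 — roughly the rejection burden real studies report).
  `inject_defect` closes the loop: each kind must be rejected by QC with
  its own reason. The overlap defect paints a merged fore+hind smear
  wider than `max_single_paw_area` across the hind stance, because that
  is the form in which unresolvable overlap manifests to a
  connected-component labeler.

What passing tests on simulated data do **not** show: robustness to paw
roll and pressure redistribution within a stance, fore/hind prints that
genuinely touch without merging, cornering, variable hop speed, or the
divergence between the two ratios seen in vivo.

## Numerical choices and degenerate inputs

Pressures round-trip text I/O bit-identically (shortest round-trip
decimal). Contact ordering is deterministic (first frame, then centroid
column, then row). Both-zero loads raise rather than return 0; constant
inputs to ρ/R² raise rather than return 0; an all-zero-difference Wilcoxon
returns p = 1 with a warning. Exact Wilcoxon counts fit float64 exactly up
to m = 25 (2^25 < 2^53). The acceptance script and tests use these problem
sizes: 160 baseline runs for range coverage, 50 runs per λ for offload
recovery, 2000 replicates for test calibration, 150 random lattices
against the BFS oracle.

## Limitations

No fore-limb metrics, gait-cycle kinematics, centre-of-pressure
trajectories, per-toe subdivision or bodyweight-normalised forces; no
video ingestion or vendor-format parsing (PMAT-CSV is this package's own
canonical format, as no public device format specification exists). One
ratio is emitted per run (the earliest complete hind pair), so studies
averaging multiple hops per traversal need longer mats and their own
pooling.
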