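# Methods

This note documents the models and procedures `mazenet` implements, the
choices made where the underlying definitions were open, and what the
synthetic-data generator does and does not emulate.

## Maze geometry and scoring regions

A maze is a circular arena of radius `R` with `n` holes (default 12)
equally spaced on a ring of radius `r_ring`, one of which (the target)
leads to an escape box.  Two scales are built in:

| parameter            | BM1 (1-m maze) | BM3 (3-m maze) |
|----------------------|----------------|----------------|
| arena radius         | 490 mm         | 1500 mm        |
| hole ring radius     | 400 mm         | 1350 mm*       |
| hole scoring radius  | 80 mm          | 270 mm         |
| start-area radius    | 80 mm          | 270 mm         |
| sampling rate        | 20 Hz          | 20 Hz          |

*The 3-m maze's holes are slots in the rim and no ring radius is
published for it; the default (rim minus roughly half a slot length)
keeps the scoring circles essentially inside the arena and approximately
triples the small-maze layout.  It is configurable, as is everything else
via a YAML maze config.

All lengths are millimeters internally; configs may declare `unit: cm`.
A point is inside a hole's region when its distance to that hole center is
below the scoring radius (ties to the nearest center); the central start
area takes precedence.  Trajectories are rigidly rotated so every mouse's
target sits at 90° ("north") before any scoring — a pure isometry, so
distances are untouched.

Quadrants are the four 90° sectors anchored with the target ray bisecting
sector 0.  The original description leaves the anchoring unstated; anchoring
to the target makes the serial-strategy crossing rule invariant to where a
given mouse's goal happened to be.

## Conventional features

* **Errors** — number of visits (maximal sample runs) to nontarget hole
  regions; re-entries recount.  Training trials count until the first
  target entry; probe trials count over the scoring window.  No minimum
  visit duration is imposed by default (configurable for noisy tracking).
* **Latency / travel distance** — time and cumulative path length from the
  first sample to the first entry into the target region; trials are
  capped at 600 s.  "Entry" is entry into the scoring circle, not arrival
  at the hole center, so a straight 400-mm approach registers at ~320 mm.
* **Daily averages** — arithmetic mean over the (up to three) trials per
  day, with a logged warning when trials are missing.
* **Learning curves** — per-mouse series across trials of days 1–6 are fit
  with `y = α e^(−β t)` by nonlinear least squares, `t` being the global
  trial index (1–18 by default; the index convention is configurable since
  the original is unstated).  Latency and travel distance are first
  normalized to unit sum within a mouse so curves are unitless and
  comparable across maze scales; error counts are fitted raw.  The fit is
  deterministic: α starts at the first observation, β runs over a fixed
  five-point multistart {0.01, 0.05, 0.1, 0.3, 0.7} with |β| bounded by 10,
  and the lowest-cost solution wins.  A smaller β means slower convergence
  of performance.
* **Probe scoring** — dwell time inside each hole's region over the first
  150 s of the 300-s probe (the window is a parameter, so the 90-s vs
  150-s error-matched comparison needs no separate code path), keyed by
  the signed 30°-step angular offset from the target.  Probe latency is
  the start of the first stay in the target region longer than 10 s in a
  row; with no such stay it is undefined rather than capped.

## Strategy classification

Each training trial is labeled by rule order after discarding the initial
segment inside the start area (only the stay since field entry; later
center passages are kept):

1. **spatial** — fewer than 3 nontarget visits *and* path efficiency
   ≥ 0.75;
2. **serial** — target reached, adjacent-visit consistency ≥ 0.8, fewer
   than 3 quadrant crossings;
3. **random** — everything else (including trials that never leave the
   start area, which are flagged).

Path efficiency operationalizes "moved directly toward the target": the
straight-line distance from the first post-strip point to the target hole
center divided by the traveled length to the target (path to first entry
plus the remaining straight leg to the center — the extra leg keeps the
ratio in (0, 1] and makes a perfectly straight approach score exactly 1).

Serial consistency operationalizes "sequentially approached neighboring
holes": the fraction of consecutive visit pairs stepping to the adjacent
hole in one dominant direction.  Any adjacent step *against* the dominant
direction (ping-ponging between two holes) voids seriality and scores 0 —
a serial scan never reverses.

The 0.75 and 0.8 cutoffs are this package's operationalizations of the
verbal rules (the original quantitative definitions are in an unpublished
companion codebase); both are exposed in `StrategyThresholds` and echoed
into every call, so sensitivity analyses are one parameter away.

## Exploration networks

* **Stops** — a stop is a maximal run of ≥ 20 successive frames (1 s)
  whose traveled distance within the trailing 20-frame window stays below
  40 mm (≈ half a mouse body length).  Sliding-window semantics: runs of
  consecutive qualifying windows merge, and one non-qualifying window
  separates stops.  The rule uses cumulative path length, not net
  displacement (configurable), and the threshold is absolute — it
  deliberately does not scale with the arena, which is exactly why larger
  arenas produce larger networks.
* **City Clustering Algorithm** — stops are processed in temporal order
  (deterministic; the original order is unstated): each stop joins the
  nearest node closer than 40 mm or founds a new node, then node centroids
  are recomputed as member-stop centroids, and the pass repeats with
  cleared assignments until the partition stops changing (cap 100
  iterations with a diagnostic).  At convergence the partition is a fixed
  point and every centroid is exactly its members' mean.
* **Graph** — consecutive stops on distinct nodes add an undirected link;
  no self-links; duplicates collapse.
* **Measures** — order, mean degree, density `2L/(k(k−1))`, mean
  clustering coefficient, mean shortest path, mean betweenness (fraction
  of shortest s–t paths through a node, averaged over the unordered pairs
  excluding it) and mean closeness, defined as the *unnormalized* inverse
  summed path length `1/Σd` (so a 4-leaf star has center closeness 1/4 and
  leaf closeness 1/7).  Degree, clustering, betweenness and shortest paths
  delegate to networkx; closeness is computed in-package because networkx
  normalizes by `(k−1)`.  Disconnected graphs (which empty-link trials
  produce) average shortest path and closeness over reachable pairs only,
  drop fully isolated nodes from those node averages, and keep the
  betweenness normalization over all pairs excluding the node.

## Statistics

Per-day comparisons of strategy usage and network measures use the
Wilcoxon rank-sum test (two groups) or Kruskal–Wallis (three or more, with
rank-sum post hoc gated on the corrected Kruskal–Wallis), Bonferroni
corrected.  The correction family is the set of days within one measure;
the post hoc family is days × pairs — the original reporting does not
state the family, so both choices are documented here and visible in the
output.  The rank-sum `z` is the tie-corrected normal deviate with
continuity correction; `p` is exact (Mann–Whitney null distribution) when
both samples have ≤ 10 observations and no ties.  Effect size is
`r = |z|/√N`.

Conventional features and probe dwell profiles use a mixed-design two-way
ANOVA (between: group; within: day or hole) via pingouin, reporting
`η_p² = SS_effect/(SS_effect + SS_error)` (verified against a hand
split-plot decomposition), with Tukey's HSD on the groups gated on a
significant between effect or interaction.

## Synthetic data

The generator emulates the *contracts* the analyses depend on, not mouse
biomechanics:

* 20-Hz sampling from the arena center, all points inside the arena,
  byte-identical output for identical seeds (streams keyed on
  seed/day/trial).
* **Spatial** trials run near-straight to the target (heading noise
  0.12 rad/step); **serial** trials walk to a hole 3–5 positions from the
  target and scan hole-to-hole in one direction; **random** trials wander
  between interior waypoints (heading noise 0.6 rad/step) and visit
  `Poisson(α e^(−β t))` nontarget holes before the target, so the
  programmed learning curve is exactly the expected error curve.
* Pauses are inserted at waypoints by Poisson thinning (probability 0.5,
  log-normal durations, median 2 s — above the 1-s stop window so they
  register as stops); position jitter during pauses is 0.5 mm.
* Optional home-base mode replaces the goal run with roundtrips arriving
  and departing on one preferred site, reproducing the persistent
  high-betweenness node signature of early exploration.
* Probe mode concentrates dwell near the (absent) target with brief
  excursions to neighboring holes.
* Speeds (150 ± 30 mm/s) do not scale with the arena, so large-arena
  trials are naturally longer and stop-richer.
* Cohort presets: the small-arena profile shifts its strategy mix from
  random-dominated to 80% spatial over six days with error curve
  α = 10, β = 0.25; the large-arena profile stays random-heavy
  (50% on day 6) with α = 18, β = 0.06.  These are the package's chosen
  study conditions for the qualitative small-vs-large contrast: higher
  error intercept and markedly slower decay in the large arena, with the
  strategy-mix gap mirroring the reported day-by-day differences.

What it does not emulate: thigmotaxis, wall-following, realistic speed
autocorrelation, visual-cue use, inter-individual variability beyond the
seed, or tracking noise/dropouts.  Passing tests therefore demonstrate
that the analysis machinery is correct and sensitive under controlled
conditions — not that it would be robust to every artifact of real video
tracking (the IO validation rules handle the common ones explicitly).

## Numerical choices and degenerate inputs

* Region ties (a point equidistant from two hole centers) break to the
  lower hole index; points beyond the arena plus tolerance classify as
  open field with a data-quality warning.
* The quadrant of a sample exactly at the origin is undefined and carries
  the previous sample's quadrant forward.
* Trajectory files must be uniform within 1% of the nominal rate; internal
  gaps ≤ 0.5 s are linearly interpolated, longer gaps or > 5% missing or
  > 10% off-arena samples are hard errors naming the rule.
* Learning-curve fits require ≥ 4 finite points; constant series fit to
  β ≈ 0, α ≈ the constant.
* Empty networks report NaN measures; single-node networks have degree 0
  and NaN density/shortest-path/closeness.
* All thresholds are echoed into output headers together with a config
  hash.

## Problem sizes used in the checks

The test suite and acceptance script run on synthetic cohorts of up to 20
mice per arm with 6 training days × 3 trials (18 trials per mouse), 200
strategy-pure trials per class, 200-replicate Monte-Carlo parameter
recovery, 100 random graphs (≤ 8 nodes) against the exhaustive
path-enumeration oracle, 50 seeded stop sets for the clustering fixed
point, and 1000 replicates for the type-I-error calibration — sizes chosen
to make the Monte-Carlo bounds tight while keeping a full run a
few-minutes affair on one CPU.
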