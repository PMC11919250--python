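# Methods

This note documents the models, estimators and numerical choices behind
`islandseg`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## The capture null

The central statistic is the number of *captured* relay cells — cells whose
retinal input comes entirely from one bouton class (island or non-island).
The null hypothesis is indifference: each innervated primary dendrite of a
cell independently connects to the island class with probability *p*
(default 0.5, both classes equally available) or to the field otherwise. A
cell with *k* innervated primary dendrites is captured exactly when all *k*
dendrites agree:

    q(k) = p^k + (1 - p)^k.

Across a cohort with dendrite counts (k₁, …, kₙ) the captured count is a
sum of independent, non-identical Bernoulli variables — Poisson-binomial
with success probabilities q(kᵢ).

Two routes to this distribution are implemented and cross-checked:

- **Monte Carlo** (`run_monte_carlo`): each trial draws a class for every
  dendrite and counts unanimous cells; 100,000 trials by default. The
  generator is `numpy.random.Generator(PCG64)`; seed and generator identity
  are recorded in the result so runs are bit-for-bit reproducible.
- **Exact dynamic programming** (`exact_capture_distribution`): sequential
  convolution of the Bernoulli(q(kᵢ)) indicators, O(n²), exact to floating
  precision (PMF sums to 1 within 1e-12). The exact route is the default
  for reported thresholds; Monte Carlo is retained because it mirrors the
  original procedure and generalizes to nulls without a closed form.

The 99% threshold is the smallest count c with CDF(c) ≥ level ("this many
or fewer in 99% of trials"). On the reference cohort (2,2,3,4,4,4,5,5,7)
with p = 0.5 the exact CDF is 0.9429 at 3 and 0.9916 at 4, so the
threshold is 4 whether computed on the exact or the empirical CDF; the
statement "99% of trials produce 4 or fewer" is the empirical CDF at 4,
which slightly exceeds the rounded 99%. The upper-tail p-value for an
observed count is P(X ≥ observed) under the exact PMF; for a fully
captured cohort it reduces to ∏ q(kᵢ) = p^(Σkᵢ − n) at p = 0.5.

The null deliberately has no spatial structure and no correlation between
dendrites beyond the all-or-independent mixture used by the generator: it
is a model of indifferent wiring, not of dendritic geometry.

## Bouton labeling and the separation axis

Bouton classes can be assigned three ways, all deterministic given their
options:

- `region_mask` — a ball (`center`, `radius`, optional `outer_radius`) or a
  polygon prism in micrometer space. Boutons inside the inner radius are
  island; boutons in the shell between `radius` and `outer_radius` (the
  exclusion-zone annulus) are labeled ambiguous, mirroring the treatment of
  inputs found mid-zone.
- `two_class_split` — k-means with k = 2 on bouton positions, fixed seed,
  10 restarts, best inertia; the spatially compact cluster (smaller RMS
  radius about its centroid) is the island. Determinism is favored over
  elegance: the seed is recorded in the labeling.
- `manual` — per-bouton labels from a delimited file.

The direction of clearest separation — found by eye in interactive 3-D
rotation in the original workflow — is made reproducible as an exhaustive
search over a deterministic unit-sphere grid (θ, φ in multiples of the
angular step, default 2°). For each direction the score is the 1-D
projection gap, min(proj of class b) − max(proj of class a); the reported
axis maximizes it, oriented so projections increase toward the island, with
ties broken by the lexicographically smallest axis vector. The grid is
nested under halving, so refining the step can only increase the reported
maximum gap. A gap ≤ 0 means the classes overlap along every tested
direction. After the initial assignment, any bouton projecting strictly
inside the open gap interval is relabeled ambiguous (for points that
already define the class edges this is vacuous; it matters for mask- or
manually-pre-labeled candidates).

Exclusion-zone metrics report the projection gap, the minimum and median
nearest cross-class neighbor distance (pooled over both classes, k-d tree),
and the ambiguous count. The zone's width is reported, never thresholded
against a reference value, because no numeric ground truth exists for it.

## Capture classification

Per cell, retinal inputs are counted by label. The classification rule:

- total inputs below `min_inputs` (default 1) → `no_input`;
- both decided classes present → `mixed` (ambiguous inputs cannot rescue a
  cell that already mixes classes);
- otherwise any ambiguous input → `ambiguous` (cells with exclusion-zone
  inputs are set aside rather than forced onto a side);
- otherwise the single decided class → `island_only` / `non_island_only`.

The cohort capture fraction excludes `no_input` and `ambiguous` cells from
its default denominator, matching the bookkeeping in which the cell without
retinal input and the cell with mid-zone input are reported separately from
the exclusive cells.

The dendrite count *k* fed to the null is the number of root-children of
the skeleton whose subtree receives ≥ 1 retinal bouton. Synapses are tied
to skeleton nodes through their `post_node` reference when present;
otherwise nearest-node assignment within a configurable radius (default
2 µm, soma node excluded) is used, and unresolvable synapses raise an
error listing their ids rather than being silently dropped.

## Synthetic circuits

The generator produces the statistical structure the analysis assumes, with
ground truth for every bouton, dendrite and cell:

| parameter | default | meaning |
|---|---|---|
| `n_tc` | 9 | number of relay cells |
| `dendrite_count_sampler` | resample (2,2,3,4,4,4,5,5,7) | innervated primary dendrites per cell |
| `island_radius` | 15 µm | island ball radius |
| `gap_width` g | 5 µm | exclusion-zone width; no bouton at radius (R, R+g] |
| `background_extent` | 60 µm | outer radius of the bouton field |
| `boutons_per_dendrite` | uniform 3–15 | boutons per dendrite |
| `segregation` s | 0 | all-same vs independent dendrite mixture |
| `class_prob` p | 0.5 | island probability per assignment |
| `one_sided_field` | true | field restricted to a shell sector on one side |

Dendrite class assignment is a mixture: with probability *s* all of a
cell's dendrites take one class (island with probability *p*); with
probability 1 − *s* each dendrite draws independently. This makes s = 0
*exactly* the capture null and s = 1 exactly the fully segregated
observation, which is why s is a mixture weight rather than a correlation
coefficient. Expected captured cells at s = 0 with the default counts is
Σ 0.5^(k−1) = 1.765625.

Geometric choices: the island is a ball and the field a spherical-shell
sector beyond the gap on one side of the island (`field_direction`),
reflecting an island near the edge of the nucleus with the bouton field to
one side. The one-sided field gives the two classes a genuine linear
separation, so the projection gap along the field axis is at least g by
construction and the axis-search machinery has ground truth to recover;
with `one_sided_field=False` the field surrounds the island and no
separating direction exists (gap ≤ 0), which the `overlap` fixture uses.
Somata are placed mid-gap within a 30° cone of the field direction, so
island-captured cells have arbors pointing toward the island and
field-captured cells away from it. Arbors are minimal: one primary branch
per dendrite, boutons chained by distance from the soma. Boutons-per-
dendrite defaults are a placeholder (per-dendrite counts are not published
for the reference data); per-cell totals then span roughly 6–100,
consistent with the broad published per-cell range.

Randomness is split into independent PCG64 streams (dendrite counts,
dendrite classes, bouton counts, bouton placement, somata) spawned from the
master seed, so changing one entity class's parameters does not perturb the
others.

What the generator does **not** emulate: blob-shaped islands, dendrite
geometry beyond straight chains, bouton density gradients, multi-synaptic
boutons, tracing errors or partial reconstructions. Passing tests on
synthetic circuits therefore validate the estimators and their statistical
calibration, not robustness to annotation noise in real exports.

## Pipeline and reproducibility

A run is configured by a YAML/JSON file (paths, labeling method and
options, null options, seed); the effective config, package version and
seed are echoed into the JSON report, and identical config + inputs + seed
yield a byte-identical report. Stage progress is logged to stderr; every
reported number lives in the report file, never only in logs. SWC files in
the skeleton directory become relay-cell records (soma at the root node);
presynaptic partners named in the synapse table are added as axon records.

Problem sizes in the shipped tests and acceptance script are chosen to keep
full runs fast while leaving the estimators at their study conditions: the
null uses the full 100,000 trials; exact-vs-enumeration checks cover every
dendrite-count multiset summing to ≤ 16; capture-fraction recovery uses 20
seeds at s = 1 (200 cells each) and a 10,000-seed goodness-of-fit at s = 0
on the nine-cell reference cohort; the s = 0 loop uses a coarse (30°) axis
grid because class labels come from the region mask and are independent of
the axis resolution.

## Known limitations and open choices

- The reference bookkeeping lists 6 + 8 exclusive cells plus one mid-zone
  and one no-input cell (16) against 15 traced cells; the overlap is not
  stated. The `paper_like` fixture uses 16 cells and documents the choice
  here rather than resolving it.
- Whether "captured" requires ≥ 1 input per cell or per dendrite is
  settled as per cell (dendrites enter only through *k*, which counts only
  innervated dendrites); `min_inputs` exposes a stricter cell-level floor.
- The 2-cluster split assumes two roughly balanced, linearly separable
  point clouds; boutons lying mid-gap will be absorbed into a cluster and
  narrow the reported gap. Use a mask or manual labels when mid-gap
  boutons matter.
- The asymmetry index (|soma → mean input| / mean soma-to-input distance)
  is a defined operationalization of published soma-to-input plots, not a
  reproduction of any published normalization.
- Column naming in real exports varies; the synapse-table reader's
  `column_map` plus per-row reject reporting is the hedge, and unknown
  presynaptic kinds degrade to `OTHER` rather than failing the read.
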