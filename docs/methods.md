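# Methods

This note documents the models and numerical choices behind `gmgait`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the limits of what passing
tests demonstrate.

## Envelope preprocessing

Raw surface EMG is reduced to a gait-cycle envelope by: 4th-order
Butterworth band-pass at 20–350 Hz, full-wave rectification, 4th-order
Butterworth low-pass at 9 Hz, stride segmentation, resampling of each
stride onto 101 points (0–100 % of cycle at 1 % steps, the gait-analysis
convention), pointwise averaging across strides, and scaling so the
cycle mean is exactly 100. Both filters are applied forward–backward
(`sosfiltfilt`), doubling the effective order and removing phase lag —
important because four of the twelve per-phase statistics are *temporal
positions* of extrema, which a causal filter would shift. The band-pass
requires `fs > 700 Hz`; lower rates are rejected rather than silently
narrowed.

A *valid* stride is a foot-strike-to-foot-strike interval with exactly
one interior foot-off and a duration within 3 SD of the median stride
duration (the outlier screen engages only when at least three strides
are available). Resampling uses linear interpolation: at typical
sampling rates every 1 %-of-cycle bin spans many raw samples, so
higher-order interpolation would change nothing measurable.
Normalization is to the *signal mean*, not to a maximum voluntary
contraction; amplitudes are therefore percent-of-mean and a flat curve
reads 100 everywhere.

## Features and norm distances

Ten phases are used per cycle: stride [0, 100], stance [0, foot-off),
swing [foot-off, 100], and the seven Perry subphases at canonical bounds
LR [0, 10), MSt [10, 30), TSt [30, 50), PSw [50, foot-off),
ISw [foot-off, 73), MSw [73, 87), TSw [87, 100]. Windows are half-open
on the right (the cycle-closing ones include 100) so the subphases tile
the grid without double-counting; with foot-off at the canonical 60 %
the swing-related window PSw∪ISw∪MSw is exactly 50–87 % of the cycle.
A foot-off at or below 50 % (empty PSw) or at or above 73 % (empty ISw)
is a phase-degeneracy error rather than a silent empty window.

Per phase, six statistics are taken: max, min, cycle-percent of the
first maximal and first minimal sample (earliest-index tie-break, for
determinism), range = max − min, and mean — 60 features in a fixed
order (phases as listed above; stats max, min, tmax, tmin, range, mean)
so label matrices are comparable across runs.

Standardization is the norm distance `ND = |F − F̄_TD| / SD_TD` with the
TD sample mean and SD (n − 1 denominator). ND is nonnegative, zero
exactly at the TD mean, and invariant under any common affine rescaling
of patients and reference. Features with zero TD variance (possible for
temporal positions in small TD groups, where every smooth envelope peaks
at the same sample) are flagged and excluded rather than imputed — the
ratio is undefined there. Note that the absolute value *folds* the
deviation axis: a patient above and a patient below the TD mean by the
same amount are indistinguishable in ND space. This is intentional
(the statistic measures abnormality, not direction) but it reduces
separability between groups that straddle the TD mean; see
"Separability of the default archetypes" below.

## Stage 1: per-feature hybrid PSO/K-means

Each ND column is clustered independently in one dimension. A particle
swarm (swarm 30, 100 iterations, inertia 0.72, cognitive = social =
1.49, velocities clamped to the data range — standard constriction-style
settings) searches over candidate centroid k-tuples with
within-cluster sum of squares (WCSS) as fitness; Lloyd's algorithm then
refines the swarm's best candidates (the global best, the top
personal bests, and a few fresh data-point seeds) and the lowest-WCSS
result wins. WCSS evaluation exploits the 1-D structure: clusters of
nearest-centroid assignments are contiguous segments of the sorted
column, so each evaluation is a prefix-sum lookup rather than a full
distance matrix. All swarm state derives from the sorted column and a
per-column seed (`master_seed + column_index`), making results invariant
to subject order.

The cluster count is selected per column by minimizing the
Davies–Bouldin index, `DB = (1/k) Σ_i max_{j≠i} (s_i + s_j)/d_ij` with
`s_i` the mean absolute member–centroid distance and `d_ij` the centroid
separation, over k = 2…6 (ties to the smaller k; coincident centroids
score +inf). The range is deliberately narrow: the downstream analysis
expects a handful of ordinal activation levels per feature. Labels are
re-encoded by ascending centroid, so a larger label always means
"further from TD", and a column with fewer than two distinct values is
flagged and dropped.

## Stage 2: PCA + Ward + dendrogram gap

The ordinal label matrix is mean-centered but *not* rescaled — the
columns already share a small-integer scale, and unit-variance scaling
would inflate near-constant columns — and decomposed by full-rank PCA.
The smallest leading set of components explaining strictly more than
96 % of the variance is retained. Agglomerative clustering with Ward
linkage and Euclidean distance on the retained scores produces the merge
tree; the final cluster count is the cut with the largest *relative* gap
`(h_above − h_below)/h_below` between consecutive merge heights among
cuts yielding 2…10 clusters, a deterministic analog of reading the
dendrogram by eye. Ties, or an all-equal gap profile, fall back to two
clusters. Final labels are renumbered by decreasing cluster size; the
partition (though not necessarily the numbering) is invariant to subject
order. Linkage method, variance threshold and the cut search bound are
all exposed as configuration.

## Responder sub-clustering

For patients with paired examinations the change matrix
`ΔE = E2 − E1` spans seven columns: trunk- and pelvic-obliquity RoM,
peak hip abduction angle and moment in mid-stance, and the mean/min/max
EMG summaries. Because these mix degrees, Nm/kg and percent-of-mean,
columns are standardized to unit variance before PCA by default
(`scale=False` is available for sensitivity checks, and is the right
choice when all columns already share a scale — standardization
deliberately flattens any single column's dominance, which helps with
mixed units but hides a lone-column effect). The first component's sign
is fixed so that the trunk-obliquity loading is negative — improvement
scores positive — and subjects are labelled SUB_1 (score > 0), SUB_2
(score < 0), or left unassigned at an exact zero. Group statistics use
a two-sample Kruskal–Wallis H with tie correction against a chi-square
with 1 df; an all-tied pooled sample returns p = 1 by convention. The
E1-vs-E2 comparisons are run unpaired, matching the named test.

## The synthetic cohort generator

The generator stands in for the non-redistributable clinical database.
Four archetypes (three CP activation patterns and TD) are defined by
per-subphase envelope means and between-subject SDs plus clinical-exam
scalars (hip abduction passive RoM at 0°/90° hip flexion, abductor
strength on the continuous-valued MRC 0–5 scale), shipped as a
versioned YAML (`src/gmgait/data/archetypes.yaml`). One envelope is
drawn by sampling a target level per subphase from its Normal, fitting a
periodic shape-preserving cubic (PCHIP) through the subphase midpoints
whose knot values are adjusted by a damped fixed-point iteration
(12 rounds) until the within-window sample averages match the drawn
targets, clipping at zero, and scaling to mean 100. Because each
archetype's duration-weighted activation average sits at 97–99 rather
than 100, that final scaling inflates all subphase levels by a common
~1–3 %; this is the only systematic deviation of cohort subphase means
from their targets and is visible in the calibration outputs (e.g. a
loading-response target of 170.1 measures ≈ 173–175).

Choices worth knowing:

* **Between-subject variation only.** The published per-phase SDs
  conflate between-subject and between-stride variability without
  decomposing them; the generator attributes all of it to
  between-subject variation and each subject's curve is smooth and
  noise-free. Temporal-position features consequently vary much less
  than in real EMG.
* **Foot-off fixed at 60 %** for synthetic subjects (per-subject
  foot-off is not part of the published statistics).
* **Clinical scalars** are truncated Normals (RoM at 0, MRC to [0, 5]),
  kept continuous to match fractional published means. Zero SDs are
  allowed and produce constants (the TD strength entries).
* **Paired outcomes** are drawn independently at E1 and E2 from the
  stated group Normals. The post-treatment swing-window EMG of the
  responder group, which is not tabulated anywhere, is set to the
  non-responder pre-treatment profile (prolonged swing activity
  resolved) with its own E1 SDs; non-responders are modelled as
  unchanged between examinations.
* **Determinism.** Same seed, same call → bit-identical output. Batched
  and one-at-a-time generation agree only to ~1e-13 (vectorized spline
  evaluation), so reproducibility contracts are per-call.

## Separability of the default archetypes, honestly

The default calibration makes the three CP archetypes overlap
substantially: in the 7-dimensional drawn-target space the medium- and
high-activity archetypes sit about one within-cluster SD apart, and a
*supervised* quadratic classifier given the true labels only reaches an
adjusted Rand index of ≈ 0.39 against them; ND folding (both straddle
the TD loading-response mean from opposite sides) erodes the margin
further. No unsupervised method can beat that ceiling, and the pipeline
accordingly resolves two clusters, not three, on default draws
(ARI ≈ 0.0–0.1 over ten seeds; doubling the between-archetype mean
separation raises ARI only to ≈ 0.03–0.58). The pipeline mechanics are
validated separately: with the CP within-archetype SDs shrunk to a tenth
(TD reference untouched) the identical code selects three clusters and
recovers the planted labels with ARI = 1.000. The same applies to the
responder split: with independent E1/E2 draws the ΔE noise is
√(sd₁² + sd₂²) ≈ 8–9° against a ≈ 4.9° trunk effect, a supervised LDA
tops out near 0.73 accuracy, and the unsupervised PC1-sign rule reaches
a median ≈ 0.55 at n = 12 + 19. Passing the calibration tests therefore
shows the generator reproduces the published *marginal* statistics; it
does not show — and with these margins cannot show — that the published
cluster structure is recoverable from those marginals alone. Real
cohorts, whose structure the published tables summarize only partially,
may well be more separable.

## Problem sizes

The recovery simulations in the test suite use the full published cohort
mixture (84/654/107 CP + 65 TD) over ten seeds per condition, and
50 seeds at n = 12 + 19 for the responder analysis; the calibration
script uses the published group sizes (84, 65, 12). A complete pipeline
run on the 910-subject cohort takes a few seconds on one CPU.

## Known limitations

* Single muscle, single side-record semantics; left/right records are
  treated independently and never merged.
* The raw-EMG helper emits band-limited noise bursts for exercising the
  preprocessing chain — it is not a physiological EMG model (no
  motor-unit statistics, no realistic spectra).
* No kinematic/kinetic curve computation: frontal-plane parameters enter
  only as precomputed scalars.
* The 70 %-EMG / 30°-RoM responder flag is a labelled heuristic, not a
  validated classifier.
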