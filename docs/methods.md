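# Methods

This note documents the model behind `temposeq`, the choices made where the
procedure was genuinely open, the synthetic data the tests rest on, and what
those tests do and do not establish.

## The temporal pivot

Standard functional-connectivity analysis correlates time courses between
spatially defined nodes. Here the axes are swapped: nodes are *moments*
(acquired volumes), and the similarity measure runs across space — two
moments are associated when their whole-brain activation patterns are
similar, however far apart in time they occur. Temporal communities
("themes") may therefore be non-contiguous and interleaved, and the theme
label sequence (thematic profile) is a symbolic, heavily compressed
re-description of the scan from which recurrence statistics can be read.

## Association: partial correlation against the mean image

The association between moments i and j is the Pearson correlation of
their feature vectors after each is residualized (ordinary least squares,
with intercept) on the across-time mean image m, m[v] = mean_t X[t, v].

Why the mean *image* and not a per-volume scalar mean: correlating two rows
across features already centers each row, so partialling out a scalar would
change nothing. The meaningful nuisance shared by all moments is the
time-invariant spatial pattern, and that is what is removed. A row exactly
affine in m has zero residual variance; such rows are rejected (or zeroed
under an explicit allow-degenerate flag) since their association is
undefined.

Numerical notes: the residualization is a single rank-2 least-squares solve
for all rows; the matrix is symmetrized and clipped to [−1, 1] to absorb
~1e−16 floating-point asymmetry; the diagonal is fixed at 0 and excluded
everywhere (self-similarity of a moment carries no information).

## Thresholding

Exactly k = ⌊fraction · T(T−1)/2⌋ upper-triangle values become edges,
ranked signed (most positive first; an absolute-value option exists for
data where anticorrelation should count). Ties at the cutoff are broken
toward the pair with smaller (i, j) — the quota is exact and the graph is a
deterministic function of the matrix. Default fraction 0.05.

## Themes and modularity

Newman–Girvan modularity Q = Σ_c (e_cc − a_c²) is maximized with the
Louvain algorithm (networkx implementation). Louvain is stochastic, so it
is restarted (default 100×) with child seeds derived from the run seed, and
the best-Q partition is kept; labels are renumbered 1..K by first
appearance in time so outputs are canonical and diffable. Resolution γ is
1.0 by default and exposed in the config. The Q statistic itself is an
independent ~10-line implementation of the e_cc − a_c² formula, cross-
checked against networkx's modularity in the tests, so partition quality
and the reported statistic cannot silently drift apart.

## Null model

Surrogates are Maslov–Sneppen double-edge swaps on the binarized adjacency:
10 swap attempts per edge, rejecting any swap that would create a self-loop
or multi-edge. Degree is preserved exactly, per node. Graphs admitting no
valid swap (e.g. a triangle) return unchanged. Each surrogate is then
pushed through the full downstream chain — community detection, motif
extraction, interval histograms, summed spectra — with settings identical
to the observed chain, so every downstream null distribution reflects
"same connectivity budget, random pairings".

## Repetition, rhythm, harmony

**Repetition.** All T−n+1 sliding windows of length n (default n = 4..11)
are grouped by exact label equality. "Repeats" is Σ_motifs (count − 1):
with T≈900-scale profiles this occurrence-based count matches the scale of
repeats-per-length values near 1–2 at n = 4, whereas all-pairs counting
(Σ C(count, 2), available behind a `pairs` flag) grows quadratically.

**Rhythm.** Only motifs with ≥ 3 occurrences contribute intervals —
"recurring rhythmically" requires at least two intervals to compare.
Intervals are between consecutive starts. The histogram support is fixed to
1..(T−n) with zeros included before the SD is taken; the SD of counts is
support-dependent, and fixing the support makes profiles comparable. The
primary statistic is the SD over all bins; a per-bin surrogate screen
(Bonferroni across bins) and the SD over surviving bins are also reported,
since dispersion-over-all-bins and dispersion-over-significant-bins answer
slightly different questions and reasonable readers may want either.

**Harmony.** The spectrum stays on the integer interval grid (index i ↔
period i·TR) rather than being rebinned onto a linear frequency axis:
intervals arrive on that grid exactly, and decimation by k then aligns
period p with period k·p — precisely the integer (harmonic) relation the
method targets — without an arbitrary binning step. Decimation is 1-based
(component_k[i] = amplitude[k·i]) so each harmonic lands on its
fundamental; decimations are zero-padded to the original length and summed.
The summed peak index is reported but deliberately not assigned a physical
frequency: after summation every point mixes several periods. Per-point
surrogate tests are Bonferroni-corrected across the L = T−n points. The
harmonicity ratio averages observed/surrogate-mean amplitude over
significant points; points whose surrogate mean is zero are excluded (the
ratio is undefined there) and counted in the report, and the all-points
ratio is emitted alongside.

**Statistical machinery.** Comparing one observed value to an ensemble of
N surrogate values uses t = (x − μ̂)/σ̂ referred to Student's t with N−1
degrees of freedom, upper tail — the standard surrogate-testing form (a
two-sample test is impossible with one observed value). Zero surrogate SD
degrades to p ∈ {0, ½, 1} by sign, flagged. Bonferroni families are the 8
motif lengths for repetition and rhythm, and the L spectrum points within
each length for harmony, applied per subject and per measure.

## Seed policy

One master seed per run. Every consumer of randomness receives a child
seed derived via `numpy.random.SeedSequence(master, spawn_key=path)` with a
fixed integer path: (1,) observed Louvain, (2,) the rewiring ensemble,
(3, k) Louvain on surrogate k. Ensembles are therefore reproducible
element-wise — surrogate k is the same graph regardless of ensemble size —
and full runs are byte-identical given (input, config, seed).

## Synthetic data: what it emulates and what it does not

`generate_image_series` draws K mutually orthogonal prototype patterns of
equal norm (QR of a Gaussian matrix) and emits each timepoint as its
theme's prototype plus i.i.d. Gaussian noise, with block, periodic, or
sticky-Markov theme schedules. Equal prototype norms matter: with unequal
within-theme association strengths, a global top-fraction threshold admits
whole themes before others and can leave weak themes edgeless, which is a
property of the generator, not of the method. The defaults — T = 300,
V = 500, K = 5, σ = 0.5 — keep a full 100-surrogate chain around half a
minute on one CPU while preserving T ≫ K; at these settings the detected
partition recovers the planted themes with median adjusted Rand index
≈ 0.98 over 20 seeds (asserted ≥ 0.9 in the tests).

`generate_profile` plants exact periodic motif recurrences (optionally at
integer-ratio periods) in a random background; `generate_harmonic_spectrum`
places unit partials at integer multiples of a fundamental. Both give the
downstream stages known ground truth.

None of this emulates real fMRI: no hemodynamic response, no temporal
autocorrelation, no 1/f noise, no spatial covariance structure, no
scanner drift. Passing tests establish that the implementation recovers
planted structure and that its null calibration is correct — they say
nothing about how much repetition, rhythm, or harmony real scans contain.

## Problem sizes in the test suite

The end-to-end fixture runs T = 300 with 100 surrogates and 5 Louvain
restarts; the modularity-direction sweep runs 20 seeds at T = 90 with 20
surrogates and 3 restarts. These sizes make the whole suite and the
reproduction script each run in about a minute while leaving the study
conditions that define the method (top-5% threshold, 100 surrogates in the
main chain, lengths 4..11, factors 2..7, Bonferroni) at their reference
values. The restart count is the one deliberate reduction from the
reference setting of 100: on graphs this size, Louvain's restart-to-restart
variability is far below the observed-vs-surrogate contrasts being tested.

## Known limitations

- Exact-match motifs only: one relabeled timepoint breaks a repeat. The
  statistics are conservative for noisy profiles.
- The occurrence-vs-pairs reading of "repeats" is not fully determined by
  the method's verbal description; both are implemented, occurrence-based
  is the default.
- The harmonicity ratio is undefined at points where surrogates have zero
  power; with sparse surrogate spectra (short series, long motifs) the
  significant-points ratio can be undefined even when significance is
  overwhelming. The per-point counts and the all-points ratio remain.
- Thresholding keeps the most *positive* associations by default; strongly
  anticorrelated moment pairs are invisible unless the absolute-value
  option is used.
- Subjects are analyzed independently; there is no group model beyond the
  cohort summary grid.
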