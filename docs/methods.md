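# Methods

## The analysis in one paragraph

A functional connectome is a symmetric matrix of Pearson correlations
between regional brain signals.  We compare a control and a disease group
three ways: (1) subject-level graph quantifiers under nonparametric group
tests; (2) percolation — removing nodes one at a time from the
group-average networks under several targeting rules and tracking how the
global quantifiers collapse; and (3) progression — asking after how many
removals the attacked *healthy* network first reaches the *unattacked
diseased* network's value of a quantifier.  A targeting rule that reaches
the diseased baseline in very few removals is a candidate mechanistic
model of the disease's network effect, and the removed/disconnected nodes
are candidate biomarker regions.

## Processing model

Matrices move through an explicit state machine
`raw → normalized → thresholded → binarized`, validated at each step:

* **raw** — signed correlations in [−1, 1], zero diagonal, symmetric to
  1e−9 (asymmetric files are symmetrized by averaging; asymmetry beyond
  1e−6 is logged).
* **normalized** — negatives clipped to zero, remaining weights divided by
  the maximum.  The proportional threshold that follows is invariant to
  any strictly monotone rescaling, so this choice only fixes the *scale*
  of downstream weighted quantifiers, not the retained topology.
* **thresholded** — keep the top *E* = round(*d*·*n*(*n*−1)/2) weights.
  Rounding is half-away-from-zero: at *n* = 90, *d* = 0.10 the target
  400.5 rounds to 401, giving density 0.1001 and mean degree 8.911;
  banker's rounding would give 400 and neither printed value.  Ties at the
  cut weight break by ascending (*i*, *j*) index for cross-platform
  determinism.
* **binarized** — surviving weights become 1.  Binarized group averages
  are subtracted (entries in {−1, 0, +1}) for edge-difference maps.

Group averaging happens on raw signed matrices *before* normalization and
thresholding; subject-level statistics instead threshold each subject
individually at the same density.

## Quantifier conventions

* Edge length for shortest paths is 1/weight (strong correlation = short).
* CPL, global efficiency, radius and diameter average over **finite**
  off-diagonal distances only.  Thresholded and attacked networks are
  fragmented, and unreachable pairs are omitted rather than scored as
  infinite — note this differs from the common convention that scores
  unreachable pairs as zero efficiency, and it makes efficiency
  *conditional on connectedness*: a fragmented network with a tight core
  can score higher than a sparse connected one.
* Betweenness is weighted Brandes on the length matrix, endpoints
  excluded, **unnormalized** (raw path counts, so values scale like *n*²).
* Clustering is the Onnela geometric-mean triangle formula with weights
  rescaled by the network maximum; transitivity is the matching
  triangle-intensity-to-triples ratio.  Both reduce to the usual binary
  definitions on 0/1 matrices.  The Barrat variant would be a defensible
  alternative; Onnela was chosen and is asserted against a brute-force
  oracle.
* Local efficiency of node *i* is the finite-pair efficiency of the
  subgraph induced by *i*'s neighbors, with unreachable neighbor pairs
  scoring zero (so the value is always defined and bounded in [0, 1] for
  unit-max weights).
* Eigenvector centrality is the absolute leading eigenvector of the
  weight matrix at unit Euclidean norm; on disconnected graphs the full
  matrix is used and mass concentrates on the dominant component.
* Assortativity is the Pearson correlation of endpoint strengths over
  edges (both orientations), which equals degree assortativity on binary
  graphs.
* Communities come from Louvain at resolution 1, best modularity over
  seeded restarts (default 100); the participation coefficient
  *p*<sub>*i*</sub> = 1 − Σ<sub>c</sub>(*s*<sub>*ic*</sub>/*s*<sub>*i*</sub>)²
  always uses that best partition.  Isolated nodes get *p* = 0.
* Small-worldness σ = (C/C<sub>rand</sub>)/(L/L<sub>rand</sub>) is computed
  on the binary skeleton (C = mean clustering, L = finite-pair CPL),
  against degree-preserving double-edge-swap nulls (10 successful swaps
  per edge, default 20 nulls, seeded).  Calibration: σ ≈ 1 on
  Erdős–Rényi graphs, σ ≫ 1 on Watts–Strogatz rings.
* Collective influence CI<sub>ℓ</sub> uses hop distances on the binary
  topology even for weighted networks — the score is combinatorial by
  construction.  Default ball radius ℓ = 2; nodes of degree ≤ 1 always
  score 0.

## Attack engine

Node removal zeroes a row/column rather than shrinking the matrix, so node
indices are stable across the whole trajectory and removed nodes persist
as isolates.  Basis attacks rank once on the intact network and may
therefore "remove" already-disconnected nodes — a known limitation of
basis/random schemes that is reproduced deliberately rather than patched,
since it is part of the scheme's definition.  Iterative attacks re-rank on
the current network each step; ties break to the lowest node index.
Iterative collective influence is refused (basis-only scheme).  Random
attacks are seeded uniform permutations; ensemble curves are per-step
NaN-aware means (default 100 replicates).

Snapshots default to the degradation-curve metric set (largest cluster,
edges, mean degree, density, CPL, efficiency, diameter, transitivity, and
mean BC/LE/ST/CC) rather than the full battery: re-running Louvain with
full restarts and σ at all *n*+1 steps of every trajectory buys nothing
for the degradation curves and multiplies runtime several-fold.  The full
set (including modularity and participation) is available per snapshot via
`metrics=None`, with σ opt-in at step 0.

## Progression

Δ<sub>*t*</sub> = *q*<sub>disease</sub>(0) − *q*<sub>control</sub>(*t*).
The crossing step is the first *t* at which Δ reaches zero or changes sign
relative to its starting side, linearly interpolated between the flanking
steps (so "between attacks 5 and 6" is reported as e.g. 5.4); a curve that
never crosses reports +∞.  Strict sign change is used rather than closest
approach, and undefined (NaN) snapshots are skipped — crossings are only
declared between finite values.  In `disconnected_after`, the reference
giant component is chosen among *surviving* nodes (a removed node's
singleton must not win the tie), with ties broken by the lowest surviving
node index.

## Group statistics

Two-sided Wilcoxon rank-sum with tie-corrected variance and 0.5 continuity
correction; signed *z* (positive = first group ranks higher), effect size
*r* = |*z*|/√(*n*₁+*n*₂).  Exact enumeration is available for small
tie-free samples.  At *n* = 4 vs 4 the corrected normal approximation is
within 0.031 of exact enumeration in the worst case (verified
exhaustively) and within 0.02 typically.  P-values are **uncorrected**
across quantifiers, mirroring common practice in this analysis style; with
~15 global and several hundred nodal tests this inflates family-wise error
substantially, so isolated nodal hits should be treated as screening
leads, not confirmations.

## Synthetic cohort generator

The generator exists so the full pipeline is testable end-to-end with
known ground truth.  Defaults encode the emulated study conditions: 90
bilaterally mirrored regions, 17 subjects per group, 180 timepoints.

Region *i* in module *m*(*i*) gets the series
*x*<sub>*i*</sub>(*t*) = *a*<sub>*i*</sub> *L*<sub>*m*(*i*)</sub>(*t*) + ε,
with iid Gaussian noise (sd 1.0) and module latents *L* drawn with a
fixed correlation structure: adjacent modules along the anterior–posterior
axis correlate at 0.55 and the posterior "core" module correlates with
every module at 0.8·0.55 (kept positive-semidefinite; verified).  Loadings
*a*<sub>*i*</sub> = (base coupling 1.0) × lognormal pair gain (σ = 0.8,
shared by both hemispheres and by all subjects — hub identity is
population structure, not noise).  Six modules partition the 45 bilateral
pairs contiguously along the y axis; module 0 is the anterior/prefrontal
set, module 5 the posterior core.

Disease effect: the anterior module's latent correlations to all other
modules are multiplied by `anterior_attenuation` (default 0.3 — 70%
weaker anterior–posterior communication) and the core module's loadings by
`core_boost` (default 1.4).  These defaults were chosen so that the
thresholded group averages sit in the fragmented-but-cored regime (largest
cluster ≈ 60–85 of 90 on average, heavy-tailed degrees with tail fraction
≈ 0.12) and the designed CPL/efficiency group difference is detectable by
the subject-level pipeline in ≈ 88% of cohorts, while disabling both
levers restores nominal ~5% false positives.

What the generator does **not** emulate: BOLD hemodynamics, spatial
autocorrelation/smoothing, scanner noise spectra, motion artifacts, or
subject-level anatomical variability.  Passing tests therefore demonstrate
that the *pipeline* recovers designed effects from valid correlation
matrices with realistic network structure — not that it would behave
identically on real fMRI-derived matrices.

Reproducibility: per-subject seeds are hashed from
(cohort seed, group, subject index) via `numpy.random.SeedSequence`, so
cohorts are bitwise reproducible and subjects independent.

## Numerical choices and degenerate inputs

* Quantifiers on edgeless/fragmented inputs return NaN ("flagged
  undefined") rather than raising: CPL family with no finite pairs,
  modularity without edges, transitivity without connected triples,
  assortativity with constant endpoint values, σ with a degenerate null.
* Largest cluster of an empty *n*-node graph is 1 (an isolated node is a
  component), 0 only for *n* = 0.
* The long/short connection cutoff defaults to the median pairwise atlas
  distance — an arbitrary but reproducible midpoint, exposed as a
  parameter.
* BrainNet `.node` color defaults to 1 (or a supplied partition id); size
  is degree rescaled to [1, 10]; `.edge` files round-trip at 6 decimals.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run on 90-node networks
throughout; oracle sweeps use 200 random graphs at *n* ≤ 7 (path
enumeration) and *n* ≤ 30 (collective influence); power/calibration
experiments use 50 effect cohorts and 200 null cohorts; attack-ordering
and monotonicity sweeps use 20 cohort seeds with 10–20-replicate random
ensembles; σ calibration uses 100-node graphs with 20 nulls each.

## Known limitations

* The finite-pair efficiency convention (above) is non-standard; compare
  across packages with care.
* Louvain is stochastic; modularity and participation are "best of
  restarts" and seeded, not globally optimal.
* The weighted local-efficiency and transitivity variants are one of
  several defensible conventions (Onnela-style chosen).
* The crossing detector reports the *first* sign change; quantifiers that
  plateau near the baseline and cross late may be better summarized by
  closest approach, which is not implemented.
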