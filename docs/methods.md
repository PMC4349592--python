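# Methods

This note documents the models, numerical choices, and limitations behind
`lineascope`. Units throughout: minutes and µm.

## Lineage naming and the template

Cell names follow the Sulston convention: a founder prefix (P0-P4, AB,
EMS, MS, E, C, D, Z2, Z3) plus one letter per division from
{a, p, l, r, d, v}. The name determines the full ancestor chain, so tree
navigation is string manipulation plus a fixed founder table; no graph
library is needed. `x` is reserved as a wildcard for l/r in patterns
(`ABpxp` = ABplp ∪ ABprp sublineages) and rejected in concrete names.
Contralateral homology is purely syntactic — swap the first l/r letter —
which covers name-mirrored pairs only; anatomical homologs that violate
the naming mirror are out of scope.

The packaged lineage template (`data/lineage_template.tsv`, regenerable
with `scripts/make_template.py`) is a **synthetic** Sulston-shaped tree:
354 leaves (AB to 8 division rounds, MS/C to 5, E/D to 4; l/r divisions
at the second round of AB and C), 22 programmed deaths placed by
deterministic name rules (including MSpaapp and the ABx...ppap leaves),
cycle lengths growing geometrically per round with a mild
anterior/posterior asymmetry, and positions built from founder base
points plus depth-decaying per-letter steps and a deterministic per-name
jitter that keeps the cloud three-dimensional. Deaths occur 20 min after
birth (apoptotic corpses clear quickly — and late enough an endpoint
would otherwise censor survival of a death-skipping cell). The analysis
endpoint is 400 min on the template clock, after the last division
(~348 min). None of this is a claim about real *C. elegans* coordinates;
it is a fixture with realistic structure.

## Synthetic embryo generation

Per cell, the cycle length is Normal(template mean, cv·mean) truncated at
0.2·mean, with cv = 0.03 by default so the cohort reproduces the <5%
wild-type stereotypy. A cell's path is the straight line from its birth
position (mother's division position) to its template end position, plus
(i) an Ornstein-Uhlenbeck wobble (stationary SD 0.5 µm, correlation time
9 min) emulating slow biological drift and (ii) white measurement noise
(SD 1.0 µm per sample). The whole embryo is placed by a uniform random
rotation and a translation in [−30, 30]³ µm, then sampled every 1.5 min.
Features of real recordings the generator does **not** emulate: tracking
errors (mis-assignments, dropped nuclei), nucleus-size-dependent
localization error, optical anisotropy in z, embryo-to-embryo size/shape
variation (uniform scale is off by default in alignment for the same
reason), and fate changes that preserve timing and position. Passing
closure tests therefore demonstrates the statistical machinery, not
robustness to tracking artifacts.

Defect injections (`delay`/`advance`, `skip_death`, `extra_division`,
`displace`, `mirror_cross`) edit a generated embryo in the template frame
(the recorded placement is temporarily undone) and return a ground-truth
table. Timing shifts propagate to all descendant tracks; the exact
shifted division time is kept as a track sample so daughter births stay
contiguous through CSV round trips.

## Reference model construction

Build: initialize from the first embryo; iterate { temporally align every
embryo to the current model, gauge-fix, spatially align, re-average
canonical positions } until the maximum canonical movement is < 0.01 µm
(or 10 iterations, with a warning). Numerical choices that matter:

* **Temporal map.** t_ref = rate·(t_obs − offset) fit by least squares
  over shared division times (≥ 10 required; rate outside (0.5, 2) only
  warns). The joint align-average iteration has a free affine gauge on
  the reference clock, and regression attenuation makes it drift
  (~0.2 min/iteration) if unpinned; after each round the maps are
  renormalized so their cohort mean is the identity.
* **Averaging.** Canonical positions are the across-embryo mean of each
  track clamp-interpolated at every grid point of the cell's mean
  lifetime. Clamping (rather than masking by coverage) keeps the average
  continuous in the alignment parameters; coverage-set flips at track
  edges otherwise oscillate at ~0.5 µm and block convergence.
* **Spatial map.** Kabsch SVD over all matched (cell, timepoint) pairs;
  reflections are rejected (det forced to +1, with a warning); rank-
  deficient point clouds raise. Uniform scale is available but off by
  default.
* **Canonical frame.** The converged model is re-expressed in the
  principal-axis frame of the pooled cell cloud, signs fixed by
  anatomical landmarks (AB anterior of C on +x; C above E on +z; y by
  right-handedness). This makes the model invariant (≤ 1e-6 µm) to the
  arbitrary rigid placement of every input embryo, including the one
  that seeds the iteration.
* **Variance floors.** cycle SD ≥ 0.5 min, positional-deviation and
  neighbor-score SDs ≥ 0.3 µm. Zero-variance cells (identical synthetic
  embryos, or n too small) would otherwise turn measurement noise into
  defect calls; the calling thresholds presume nonzero wild-type
  variability. Death-time mean/SD are estimated per death cell the same
  way.
* **Neighbor map.** Each cell's 10 nearest wild-type neighbors are taken
  from canonical positions at the midpoint of its reference lifetime
  (single snapshot; ties broken lexicographically). The wild-type
  neighbor-score baseline (mean/SD across embryos) is stored per cell.
  k-NN is asymmetric by nature; every listed neighbor is alive at the
  query time (asserted in tests).
* Mean and maximum positional deviation keep **separate** baselines; the
  position rule takes the OR of the two standardized scores.

## Defect calling

Thresholds (config defaults): 3 SD **and** 5 min for cycle lengths;
3.5 SD for position **and** 3.5 SD for the neighbor score. Missed
divisions/deaths use a grace period of 5 min + 3·SD past the expected
event before calling, which prevents endpoint-truncation artifacts.
Divisions of reference-terminal cells are `extra_division` in the cycle
caller; death-skipping survivors that divide get `missed_death` +
`extra_division` from the death caller (the split avoids double
counting). Cells descending from a missed/extra division are "shadowed"
— their reference identity is ambiguous — and excluded from position
calling. A cell with fewer than 5 of its 10 mapped neighbors present has
an undefined neighbor score and is exempt from the neighbor criterion
(logged). Group-mean cycle comparison is a per-cell Welch t test with
Benjamini-Hochberg correction — deliberately plain.

## Statistics

The sister-pair bootstrap draws |defective| cells uniformly without
replacement from the subgroup and counts name-sister pairs, 100,000
iterations by default; p is the inclusive exceedance fraction, reported
as 1/n_iter when no iteration reaches the observed count (the minimum
reportable value). Chi-squared tests (2×2 and 1-df goodness of fit) use
no continuity correction; the 1-df upper tail is computed as
log 2 + log Φ(−√χ²) via `scipy.special.log_ndtr`, since the plain
survival function underflows to zero near χ² ≈ 1420 while published
defect-rate tables reach χ² ≈ 1000 and beyond; the log-space route stays
finite past χ² = 2000 (p ~ 10⁻⁴⁴⁰).

## Closure experiments and chosen problem sizes

`lineascope.experiments` measures the pipeline end to end on synthetic
cohorts: specificity on 8-22 held-out wild-type embryos (<1% of cells
called; observed ~0.25%), sensitivity to a standard injection program
over 20 seeded embryos (two delays, one advance, two 15-µm
displacements, one midline cross, one skipped death, one extra division,
and one mother+daughters "trio"; observed 100%), rigid recovery on a
noiseless embryo (residual ~1e-13 µm), per-cell timing-SD recovery at
n = 10 (median relative error ~0.17, asserted < 0.30 — the median is the
right summary because a single cell's sample SD at n = 10 carries ~24%
relative sampling error, so a per-cell bound near 30% cannot hold
uniformly), and bootstrap-vs-enumeration agreement within
3·√(p(1−p)/n_iter) on all subgroups of ≤ 8 cells. Injected timing shifts
are max(12 min, 8 SD) and displacements 15 µm — comfortably above the
calling thresholds, because an injection sitting exactly at threshold is
recovered only ~50-85% of the time by construction (the observed
magnitude carries one SD of cycle noise and the threshold itself uses an
estimated SD). Midline-cross targets are lateral AB-derived cells: in
sparse, near-symmetric neighborhoods (the synthetic C lineage) a mirror
image keeps nearly the same neighbor distances and the crossing is
genuinely undetectable by the neighbor-confirmed rule.

The analysis drivers use 18 reference embryos, 22 held-out controls and
8 mutants — the study's cohort sizes — and run in about two minutes
total; the test suite uses a 10-embryo reference fixture.

## Known limitations

* The reference's temporal gauge is pinned to the cohort-mean clock, not
  to absolute developmental time; only relative timing is meaningful.
* Neighbor sets from a single mid-life snapshot can misrepresent cells
  whose neighborhoods change quickly; the score inherits this by
  construction.
* The nuclei-file reader accepts the documented 10-field dialect only
  and rejects others loudly; track curation/editing is upstream's job.
* Division-orientation deviation is computed and reported (angle between
  observed and canonical daughter-separation axes, from lifetime-mean
  daughter positions since the at-birth separation is below the noise
  floor) but is never a calling criterion — no published deviation rule
  exists to implement. In the synthetic template deep daughters barely
  separate (< 1 µm), so reported angles are only meaningful for the
  first ~5 division rounds.
* Syntactic sisterhood misses founder-era sister pairs whose names are
  unrelated (handled by the founder table) and any anatomical
  re-identification of cells after fate transformation.
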