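# Methods

## The corpus and its encoding

The unit of observation is the study: a cohort of `n_treated` lesioned OCD
patients with one or more statistically significant imaging findings, each
finding citing one or more atlas parcels (ROIs). Findings are encoded at
lateralized-parcel granularity: a reported "bilateral caudate" becomes two
rows (L and R caudate), an unlateralized structure mention is expanded to
both hemispheres, and medial/lateral orbitofrontal mentions are collapsed
to one OFC parcel per hemisphere. This granularity choice is the main
judgement call in transcription; it changes per-ROI citation counts (and
therefore which ROIs rank "most cited") but not study-level descriptives.

Direction labels (+1 increase, −1 decrease) exist only for postoperative
volume and glucose-metabolism findings; all other measures (perfusion,
connectivity, FA, task activation, band power) and all preoperative
predictor findings carry no direction. These constraints are schema
invariants: violating rows fail loudly at read time with the offending
finding named.

A study appearing with both predictor and postoperative findings is a
single record with findings in both phases; descriptive counts are over
unique studies. The synthesis filter removes studies whose cohorts mix OCD
with other diagnoses and studies whose imaging is entirely EEG/MEG; it is
idempotent, and a study with EEG plus any tomographic modality survives.

The packaged corpus's `ybocs_pre_mean`/`ybocs_post_mean` columns are
**synthetic** plausible cohort means (pre ≈ 30–35, reductions ≈ 11–16,
present for the 14 synthesis-eligible studies that reported scores): the
transcription source does not print cohort Y-BOCS values. Outcome maps and
Kruskal–Wallis statistics computed from the fixture are therefore
demonstrations of the machinery, not replications of published outcome
figures; no test asserts a published outcome range.

## Composite maps

- Frequency: `F(r) = Σ n_s` over studies citing `r` at least once in the
  phase; the once-per-study rule keeps multi-finding studies from
  dominating.
- Directionality: distinct (study, ROI, direction) terms, each weighted
  `n_s`, averaged; a study reporting both directions for the same ROI
  contributes both terms and partially cancels itself. `D ∈ [−1, 1]` by
  construction with `|D| = 1` iff all terms share a sign. Defined only for
  volume and glucose metabolism; purely descriptive — no test is attached.
- Outcome: `n`-weighted mean of cohort Y-BOCS reductions over
  score-reporting studies with a *postoperative* finding citing the ROI.
  Predictor-only citations do not contribute, and scoreless studies are
  excluded from numerator and denominator alike. Reductions may be
  negative (worsening is representable; nothing clamps).

Rendering paints each ROI's voxels with its statistic on the atlas grid
(NIfTI out, background configurable) and exports a per-ROI table with the
value, the number of contributing studies and the total patient weight.

## Inference

Fisher tests compare two ROIs' citation proportions as independent binomial
rows of a 2×2 table over a common study denominator — by default the
procedure-specific subset of the synthesis corpus (configurable; the
alternative is the full synthesis set). Two-sided p sums the probabilities
of all fixed-margin tables no more probable than the observed one
(scipy's probability-mass rule; tests verify equality with an exhaustive
hypergeometric enumeration for every table with total ≤ 30). No
multiple-testing correction is applied across the pairwise matrix; the
reported quantity is the raw pairwise p. An empty study scope degenerates
to p = 1 with a warning rather than an error.

Kruskal–Wallis groups are ROIs cited postoperatively by at least
`min_studies` (default 3) score-reporting studies; each study contributes
its cohort reduction to every ROI it cites. Groups therefore overlap — the
chi-squared reference (df = groups − 1) assumes independence the data do
not have. The statistic is a descriptive screen and is documented as such,
not "corrected". Tie-corrected H; fewer than two eligible groups is an
error, not a silent p.

## Normative connectivity

Seed series = spatial mean BOLD over the ROI's voxels; voxelwise Pearson r
per subject; zero-variance voxels are NaN and stay excluded downstream.
Group maps average Fisher-z transformed r over subjects and back-transform
(plain r averaging available). Group t-maps are one-sample t on the subject
z values, df = n − 1, minimum three subjects; voxels with zero variance
across subjects — including constant nonzero z — are undefined and are
never declared significant (the variance carries the test; a 0/0 or x/0
statistic is not evidence).

Bonferroni control: V = in-mask voxels with a defined t (background voxels
carry no test); significance is strict, p < α/V, one-sided on positive t
("connected" means correlated, not anticorrelated; a two-sided flag
exists). The external network counts significant masks per voxel across
seeds and thresholds at τ = ⌈fraction × n_rois⌉ (fraction 0.5 by default).

Internal network: similarity(i, j) is the Pearson correlation of the two
group seed maps over in-mask voxels defined in both, excluding the seed
voxels of either ROI (their trivial self-correlation would inflate
similarity; configurable in principle by passing empty masks). Hierarchical
clustering (average linkage by default) on distance 1 − similarity, cut at
a user-chosen k — the analysis reports no canonical k, so none is baked in.
The centrality graph keeps positive-similarity edges with path length
1 − similarity, the simplest monotone map from similarity to distance;
betweenness is normalized shortest-path betweenness, closeness the inverse
mean shortest-path length, with the harmonic variant (flagged) for
disconnected graphs.

## Synthetic data

The generators are pure functions of (spec, seed).

- Atlas: disjoint spheres on a lattice with spacing 2r + 2, seeded shuffle
  of candidate centers, hemisphere by world-x sign on a centered affine
  (2 mm voxels by default).
- BOLD sample: module latents are unit-variance Gaussians with pairwise
  correlation `across_module_corr` (Cholesky mixing). A voxel of a
  module-m ROI is `α·latent_m + noise_sd·ε` with
  `α = noise_sd·ρ/√(1−ρ²)`, so the population voxel–latent correlation is
  exactly `ρ = within_module_corr` for any noise scale, and two voxels
  sharing a latent correlate at `ρ²` (0.64 at the default 0.8). Hub voxels
  — a seeded fixed subset (`hub_fraction`, default 2 %) of non-ROI brain
  voxels — load with the same α on the unit-variance equal mix of all
  latents, giving the external network a planted ground truth: hubs must
  enter the ≥ 50 % overlap map, pure-noise voxels must not. Defaults
  (2 modules × 3 ROIs, within 0.8, across 0.0, 10 subjects, T = 500)
  are the planted-recovery study conditions.
- Corpus: per study, each pool ROI is cited independently with its
  citation probability; directions ±1 by a Bernoulli draw; Y-BOCS pre
  fixed at 30 with reductions from a truncated normal on [0, 30] (mean 14,
  sd 3 — the scale of reported cohort improvements), missing completely at
  random with the configured probability. The generator can return its
  internal citation ledger for self-consistency checks against the
  frequency map.

What the generator does not emulate: hemodynamic autocorrelation, spatial
smoothness, subject-level anatomical variability, motion/physiological
artefacts. Passing recovery tests show the estimators do the algebra right
at realistic SNR; they do not certify behaviour on real fMRI.

## Numerical choices and problem sizes

- Fisher-z values are clipped at |r| = 1 − 1e-7 before `arctanh`.
- Coordinate lookup: background coordinates map to the nearest labeled
  voxel by Euclidean world distance, exact ties to the smallest label id;
  coordinates outside the grid are errors.
- Name resolution is exact (case-insensitive) against a curated lexicon;
  unknown names raise — never a nearest-string guess.
- Median over an even number of studies is the mean of the two central
  order statistics.
- Test problem sizes: oracle-equality checks run per-voxel Python loops on
  16³ grids (5 subjects, T = 120); planted-recovery runs use 24³ grids,
  6 ROIs, 10 subjects, T = 500 over ten seeds, with float32 BOLD storage.
  These sizes were chosen so every check runs as an exhaustive or
  full-resolution comparison at desk scale.

## Limitations

- ROI transcription granularity is a modelling choice; citation ranks and
  pairwise Fisher p-values shift under coarser or finer parcel vocabularies.
- Overlapping Kruskal–Wallis groups (above) make the p-value optimistic.
- The normative-connectome stage characterizes pre-lesion architecture; it
  does not model postoperative network reorganization.
- Probabilistic atlases must be reduced to maximum-probability label images
  upstream; the package takes no position on the threshold.
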