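# Methods

`tpenet` implements a noninvasive brain-network workflow for separating
temporal-plus epilepsy (TPE — seizure onset in the temporal lobe *plus*
adjacent structures, typically the insula) from classical temporal lobe
epilepsy (TLE). The workflow combines four ingredients: individual FDG-PET
metabolic networks summarized by graph theory, recurrence quantification
analysis (RQA) of scalp EEG, propensity-matched paired statistics, and a
cross-validated classifier bench. Because no patient data ship with the
package, a synthetic-cohort generator defines the study conditions under
which everything is tested.

## Individual metabolic networks

Regional glucose uptake is modeled on a 56-region single-hemisphere
gray-matter parcellation (`tpenet.atlas`), cerebellum-normalized. From a
normal-control (NC) cohort we take region means `mu`, SDs `sigma`, and the
Pearson correlation matrix `R` (the group connectivity prior). A subject
with uptake `x` has regional deviations

    e_i = (x_i - mu_i) / sigma_i            (NC z-scores)

and an individual network

    W_ij = w(|e_i - e_j|) * R_ij,           w(d) = exp(-d).

The kernel maps concordant deviation (both regions shifted alike, as in
diffuse hypometabolism) to full preservation of the NC edge and discordant
deviation to attenuation; hence `|W_ij| <= |R_ij|` always, with equality iff
`e_i = e_j`, and a subject at the NC mean reproduces `R` exactly. The
kernel is pluggable (`build_individual_network(..., kernel=...)`): the
published lineage of this construction does not print a closed form, so the
bounded, smooth exponential kernel is this package's documented choice.

## Graph features

Each `W` is thresholded on |weight| at sparsity values 0.20–0.65 (step
0.05), keeping the `round(s * 1540)` strongest of the 1540 possible edges
and binarizing (ties broken lexicographically). Per sparsity we compute:

* gamma, lambda, sigma — clustering and path-length ratios against
  degree-preserving random references (Maslov–Sneppen double-edge swaps,
  10·|E| attempted trials, default 100 references; 10 at desk scale), and
  their ratio sigma = gamma / lambda (small-worldness);
* global efficiency (mean 1/d over ordered pairs, 1/inf = 0) and local
  efficiency (mean over nodes of the neighbor-subgraph's global
  efficiency);
* degree centrality (Dc) and nodal clustering coefficient (Ncf) at the
  anterior and posterior insula, resolved by atlas label.

The per-subject scalar for each metric is the trapezoid area under its
metric-vs-sparsity curve divided by the grid span — the standard
area-under-curve summary for sparsity-thresholded analyses. Characteristic
path length averages over connected pairs only, so low-sparsity
disconnection never produces infinities.

## EEG recurrence quantification

Preprocessing follows the clinical recipe: downsample to 500 Hz, zero-phase
band-pass 1–80 Hz, 50 Hz notch, average reference (all via `mne.filter`).
Recordings sampled below 500 Hz keep their rate; below 160 Hz (twice the
band edge) they are rejected.

Per 10-s segment: the embedding delay `tau` is the first local minimum of
average mutual information (equal-width histograms with ceil(sqrt(N)) bins,
maximum lag 200). Because the histogram estimator produces shallow spurious
dips, a lag only counts as the first minimum when it is minimal within a
±3-lag window; signals whose AMI is already below AMI(0)/e at lag 1
(uncorrelated noise) get `tau = 1` with a warning, as do signals with no
minimum within the lag range (1/e fallback). The dimension `m` is the
smallest whose Kennel false-nearest-neighbor fraction falls below 1%
(rtol = 10, atol = 2, temporal neighbors within `tau` excluded as candidate
neighbors — necessary for oversampled flows); if the threshold is never
reached the argmin dimension is used with a warning. These defaults recover
the canonical results: `m = 2` for the Hénon map, `m = 3` for a
Lorenz-derived flow, and a quarter-period delay for sinusoids.

The recurrence plot marks pairs of embedded points within Euclidean
distance epsilon, excluding a Theiler band of half-width `tau` around the
diagonal. Epsilon is solved so the achieved recurrence rate equals a fixed
target (default 0.05, within ±0.005) — computed as the corresponding
quantile of the admissible distance distribution, the fixed point an
iterative threshold search would converge to; a fixed-epsilon mode is also
available, and the per-window epsilon variability is reported so RR-style
information is not lost. Thirteen measures are extracted with fixed
conventions (mirrored exactly by the brute-force oracle in the test suite):

* diagonal lines (both triangles, lmin = 2): DET, L, Lmax, ENTR (Shannon
  entropy, natural log, of the lengths ≥ lmin);
* vertical lines (vmin = 2), computed on the two admissible column segments
  either side of the Theiler band: LAM, TT, Vmax;
* white vertical gaps (interior zero-runs strictly between recurrences of
  one segment): RTmax = longest gap, T2 = mean gap + 1 (recurrence times of
  the second type after sojourn removal), RTE = Shannon entropy of the gap
  lengths;
* the Theiler-masked plot read as a recurrence network: Clust (mean local
  clustering, nodes with degree < 2 contributing 0) and Trans
  (3·triangles / connected triples).

Empty histograms yield 0 by convention. The per-recording protocol trims
4 s head and 10 s tail, draws `n_iter` uniformly placed 10-s windows
(default 1000; 20 at desk scale), analyzes each window in full (embedding
re-selected per window by default; once per channel in the desk-scale
configuration), and averages features over windows and then channels.

## Matching and statistics

Propensity scores come from a logistic model of TPE membership on gender,
seizure-onset-zone side, age of onset and epilepsy duration. Matching is
1:1 greedy nearest-neighbor on the probability scale, without replacement,
caliper 0.1 (absolute, on the score scale; the logit-SD variant is a
parameter), case order randomized under the seed. Balance is reported as
standardized mean differences before/after matching.

Per feature, each group passes through a Monte-Carlo Lilliefors normality
test (KS statistic against a normal with estimated moments; p from a seeded
null table, shared across features of equal sample size). If either group
rejects at alpha = 0.05 the paired comparison is the Wilcoxon signed-rank
test (zeros dropped), otherwise the paired t-test; two-sided p-values, no
correction across the 22 features. Benjamini–Hochberg FDR (statsmodels) is
used for the 56-region uptake screen.

## Classifier bench and interpretation

The feature matrix is subjects × 22 (9 graph + 13 RQA columns, fixed
order), TPE positive. Five classifiers — XGBoost (exact greedy splits:
at n≈50 the histogram approximation places thresholds on data points
rather than gap midpoints), logistic regression, RBF SVM (Platt
probabilities), random forest, Gaussian naive Bayes — otherwise at library
defaults, each inside a per-fold standardization pipeline, are evaluated by
stratified 10-fold cross-validation. Out-of-fold probability scores are
pooled, hard labels taken at 0.5, and accuracy, sensitivity, specificity,
precision and F1 computed from the confusion counts; ROC/AUC on the pooled
scores. AUCs are compared pairwise with the paired DeLong test (placement
values / structural components; implemented here, cross-checked against an
exhaustive oracle). SHAP attributions use XGBoost's native TreeSHAP
(`pred_contribs`, `pred_interactions`; exact path-dependent values summing
to the margin output); non-tree models get a seeded permutation-sampling
Shapley approximation, flagged as such.

## Synthetic cohorts

The generator emulates, under one cohort seed split into per-draw streams:

* **NC uptake** — multivariate normal with fixed per-region means
  (1.05–1.6) and SDs (0.08–0.15), correlation from a
  block-diagonal-plus-baseline prior (7 lobe blocks at r = 0.5 over a 0.15
  baseline; positive semi-definite by construction). Values are floored at
  a small positive intensity.
* **Patients** — NC-like draws plus a focal hypometabolic shift (default
  −1.5 z in 12 temporal/insular/subcortical regions, both groups equally,
  matching the observation that the two phenotypes share the same mean
  hypometabolic topography) and a group-graded insular connectivity
  effect: a fraction `s` of the decorrelated regions' variance is replaced
  by an *independent focal-disease component* of scale `kappa` z-units
  (`EffectSpec.disease_scale`). This attenuates the regions' correlations
  and, for `kappa > 1`, adds patient-to-patient heterogeneity of insular
  involvement — the mechanism by which the exp(-|Δe|) kernel actually
  attenuates insular edges; variance-preserving decorrelation alone moves
  only the spread of |Δe| and leaves nodal degree essentially unchanged.
  Defaults: TLE s = 0.25 (insula only), TPE s = 0.6 (insula + opercula),
  kappa = 2. The "fully expressed phenotype" used in sensitivity analyses
  (`strong_effect_specs`) is s_TLE = 0, s_TPE = 1, kappa = 6.
* **EEG** — each channel is `d·(shared chaotic source) + (1-d)·(band-limited
  noise)`, both unit-variance, scaled to ~20 µV. The source is a
  time-rescaled Lorenz system (lobe oscillation near 8 Hz) mixed into the
  montage through a random matrix, so the deterministic component is shared
  but not identical across channels; a continuous-time flow keeps the
  AMI/FNN selection nondegenerate. The determinism level `d` is drawn per
  subject from N(group mean, 0.1) clipped to [0, 1] (defaults 0.55 TLE /
  0.45 TPE), giving the RQA features realistic between-subject overlap.
* **Covariates** — gender ~ Bern(0.5), right-lateralized SOZ side
  ~ Bern(0.7), onset age ~ N(10, 7.5²) and duration ~ N(11, 7²) truncated
  positive; configurable additive shifts on the TLE group give the matcher
  genuine imbalance to correct.

What the generator does **not** emulate: voxel-level PET images, EEG
artifacts (blinks, EMG, electrode pops), sleep staging, volume conduction,
or any real spatial covariance structure beyond the lobe blocks. Passing
tests therefore demonstrate the pipeline's internal correctness and its
sensitivity/calibration under a controlled generative model — not clinical
performance on real patients.

## Problem sizes and numerical choices

Default study conditions mirror the modeled clinical protocol (52 NC
subjects, 25+25 patients, 19-channel / 500 Hz EEG, 1000 RQA iterations,
100 random graph references). Tests and the acceptance script run a
documented desk-scale configuration — 2 EEG channels at 128 Hz for 40 s,
20 RQA iterations, embedding once per channel, 10 random references —
chosen so a full cohort analysis completes in minutes on one core while
every algorithmic path stays identical.

Other fixed choices: threshold ties broken lexicographically; epsilon by
exact quantile (achieved RR asserted within ±0.005); Lilliefors p-values
from a 10⁴-sample null table with the add-one correction
(#{D_null ≥ D} + 1)/(n_mc + 1); degenerate inputs (constant signals,
zero-variance regions, perfect separation in the propensity model,
too-short recordings) rejected with named diagnostics; all randomness
flows from explicit integer seeds through `numpy.random.default_rng`.

## Known limitations

* The edge-weight kernel is a documented surrogate for the unpublished
  original; all downstream results inherit this choice.
* Lilliefors rejection rates, like any Monte-Carlo calibration, carry
  ±0.5% simulation error at 2000 replicates.
* The recurrence-network measures (Clust, Trans) treat the Theiler-masked
  plot as an undirected graph including its banded structure; values are
  therefore comparable within this package, not across tools with other
  masking conventions.
* Greedy caliper matching is order-dependent by construction; the seeded
  random order makes runs reproducible but not optimal (network-flow
  matching is out of scope).
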