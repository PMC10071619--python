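# Methods

`netmig` implements a connectome-based case–control analysis pipeline on
a fixed 379-region whole-brain parcellation: functional-connectivity
(FC) classification with directional feature importance, robust
control-referenced anomaly counting, and structural hub-shift detection.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic cohorts do and do not emulate.

## Parcellation and networks

The coordinate system is a registry of 379 regions: 180 cortical
parcels per hemisphere using multimodal-parcellation short codes
(`L_45`, `R_LO3`, ...), 9 subcortical structures per hemisphere
(thalamus, caudate, putamen, pallidum, hippocampus, amygdala,
accumbens, ventral diencephalon, cerebellum), and the brainstem as one
midline parcel. Every region carries exactly one of 14 large-scale
network labels; `Unassigned` is permitted.

The packaged default table pins the memberships that the source network
scheme states explicitly — a 15-region left-lateralised Language
network (left 55b, 8C, 44, 45, 8BM, IFJa, AIP, PFm, SFL, SCEF, PBelt,
STSdp, STSvp, TE1p, PHT), a 4-region left Accessory Language network
(left STSda, TE1a, TGv, STSva), area 23c in the Salience network, and
the stated default-mode and central-executive memberships — and fills
the remaining parcels with a conventional Yeo-style assignment. One
deliberate design choice: the four largest systems (Visual,
Sensorimotor, DMN, CEN) are exactly equal in size (48 regions each).
Raw per-network anomaly tallies scale with the number of incident
region pairs, which is a function of network size alone, so recovery of
a planted within-network effect is only a falsifiable comparison among
networks of equal extent; the equal sizing makes the largest systems
directly comparable while leaving the raw-count semantics untouched.
Any analysis accepts a user-supplied affiliation CSV instead.

A note on area 45: the literature variously places left area 45 in the
default-mode and in the language system. The packaged table follows the
explicit language-membership list and assigns it to Language.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 31
patients vs 17 controls by default, TR 2.0 s, 240 timepoints, a sex
imbalance of 26/31 vs 8/17 female, ages uniform on 20–35 years, and
structural connectomes of exactly 300,000 streamlines.

**Time series.** Each network carries a latent Gaussian AR(1) factor
(lag-1 coefficient 0.3, unit stationary variance). A region observes
`latent_coupling` (default 0.8) times its network's factor plus iid
noise of SD `noise_sd` (default 1.0); `Unassigned` regions are pure
noise. The defaults give a within-network Pearson correlation of
0.8²/(0.8²+1) ≈ 0.39 and zero expected cross-network correlation —
block structure of realistic magnitude with two interpretable knobs.

**Planted FC effects.** An effect `(a, b, delta)` adds a shared AR(1)
component `z` to patients only, as `x_a += w·z`, `x_b += sign(delta)·w·z`
with `w = √|delta|`, shifting the pair covariance by `delta` before
normalisation. Because the planting happens in the time series, it
passes through the genuine Pearson pipeline, and the induced population
correlation has a closed form (`expected_pair_correlation`) that the
tests use as an oracle. A side effect worth knowing: planting inflates
the variance of the two endpoint regions, which attenuates all their
other correlations — so a heavily perturbed region disturbs its whole
row of the FC matrix, as a genuine regional pathology would.

**Structural connectomes.** Edge weights are log-normal (μ=2, σ=1)
subject-level noise multiplied by a fixed per-region log-normal
propensity (σ=0.5, one draw per cohort, shared by both groups). The
propensity term gives the graph persistent hubs, so centrality rank
order is reproducible across subjects — without it every region has
the same expected strength and a control-median rank ordering is
meaningless noise. Patient-side hub effects multiply a region's row
and column by a factor before the matrix is rescaled; largest-remainder
rounding then makes the unique-pair streamline total exactly equal to
`total_streamlines`.

**Reproducibility.** All randomness flows from one config seed through
named `SeedSequence` substreams keyed by (stream, group, subject index),
so enlarging one group never changes the other group's draws.

**What is not emulated.** No raw BOLD volumes, head motion,
physiological noise, scanner drift, spatial autocorrelation between
neighbouring parcels, age effects, or streamline geometry. Passing
recovery tests on these cohorts demonstrates that the pipeline detects
the class of effect it is built for at the study's sample size; it says
nothing about effect sizes in real migraine cohorts.

## Functional connectivity features

Pearson correlation over the full provided series, computed per subject
on the T×379 matrix; the self-inclusive correlation set has
379² = 143,641 entries. The classifier consumes each unordered
off-diagonal pair once (71,631 features, row-major upper triangle) plus
one binary sex covariate; the redundant full-matrix flattening is
available behind a flag for fidelity experiments. No Fisher
z-transform. A constant (zero-variance) regional series is an error
naming the region, not a silent NaN.

## Classification

XGBoost (`binary:logistic`) with stratified 5-fold cross-validation;
the reported metric is the mean held-out AUC-ROC. The tuned
hyperparameters are the learning rate, the maximum tree depth and the
seed (stock grid {0.05, 0.1, 0.3} × {2, 3, 4} × {0, 1, 2}, 100 trees).
"Tree depth" here is the conventional maximum-depth control of boosted
trees. Two tuning protocols are implemented: selection on the same CV
that produces the reported score (the optimistic protocol,
`tune_hyperparameters`, reported side by side with the untuned
default), and a nested outer 5-fold wrapper (`nested_crossval_tune`)
where tuning sees only training folds — the honest generalisation
estimate. Nested tuning multiplies cost by the outer fold count and is
therefore opt-in in the pipeline config.

**Directional importance.** The fitted model's per-subject additive
TreeSHAP attributions (computed by XGBoost's own `pred_contribs`)
summarise feature influence: magnitude is the mean absolute attribution
across subjects, direction is the sign of the correlation between
feature value and attribution, so a coupling that is low in patients
and drives patient-class predictions comes out negative. The top-20
listing is the conventional view. Network aggregation credits each
pair feature's magnitude to both endpoint regions in full and averages
region scores within each network. The sex covariate participates in
the model but has no region pair; its magnitude is reported separately.
This signed-SHAP construction is this package's own summary; it is not
an implementation of the proprietary hollow-tree linearisation
described elsewhere in the literature.

**Numerical choices.** Histograms use 16 quantile bins per feature
(`tree_method="hist"`): cohorts here are tens of subjects, so 16 bins
per 71k features lose essentially nothing for depth-≤4 trees while
keeping single-CPU fits in seconds. Training is single-threaded and
seeded, so every result is bit-reproducible. The permutation-null
calibration uses a deliberately small spec (10 trees, depth 2): the
AUC ≈ 0.5 null property holds for any spec, and 500 refits of the
default spec would be needlessly slow.

## MAD anomaly counting

Per pair feature, the control cohort supplies a median and a raw MAD
(no 1.4826 consistency constant; a flag enables the scaled variant). A
patient's feature is an anomaly when its absolute deviation from the
control median reaches 3 MAD or more; the threshold is inclusive, with
a 1e-12 relative slack so that decimal inputs like 0.15/0.05 = 3 do not
fall out through floating-point round-off. Features with zero control
MAD (ties are likely at n = 17) are excluded rather than treated as
automatically anomalous. A within-network anomalous pair adds one to
that network; a cross-network pair adds one to each endpoint network
(a half-credit variant is available). Counts are reported per patient
and as per-network means over patients. No inferential testing is
attached to the counts; they are descriptive.

## PageRank hub shifts

Weighted PageRank on the streamline matrix, treating each undirected
edge as two directed edges of equal weight: transition probabilities
proportional to edge weight, dangling regions teleporting uniformly,
damping 0.85 by default (the conventional value; the source analysis
does not state one), power iteration to an L1 tolerance of 1e-10
(maximum 1000 iterations, error on non-convergence). A dense
linear-solve of the same stationary equations serves as the oracle in
tests. Scores become ranks 1 (most central) to 379 (least), ties
broken by ascending region id so ranks are a deterministic permutation.
The per-region median rank in controls defines the listing order; a
region is flagged when the patient-vs-control median-rank shift is at
least 20 positions (a package decision replacing visual heatmap
inspection; configurable), with direction "higher" when the patient
median rank is numerically smaller. Subjects whose whole rank vector
is unusually discordant with the control ordering (Spearman ρ an
outlier on the 3-MAD rule) are listed descriptively.

## Demographics and pipeline

Sex is compared by a Chi-squared test on the 2×2 group-by-sex table,
reported both uncorrected and Yates-corrected because the two disagree
noticeably at n = 48 and the convention is often unstated; age by a
two-sided Mann–Whitney U with medians and IQRs. Variables constant in
both groups are skipped with a notice.

`run_pipeline` chains synthesis (or cohort loading), demographics,
classification (untuned, tuned, optionally nested), importance and
network aggregation, MAD counting, and hub-shift detection, writing
CSV/JSON outputs plus a manifest with the seed, package versions and
SHA-256 checksums of every file. The manifest carries no timestamps;
two runs with the same config and seed are byte-identical.

## Problem sizes in the shipped experiments

The test suite and the acceptance script run recovery experiments at
the default cohort scale (31/17 subjects, 240 timepoints) over modest
seed counts (4–10 seeds, 30–100 label permutations) and verify solver
oracles on 50 random graphs of ≤ 20 nodes — sizes chosen so a complete
run finishes in minutes on one CPU while keeping every comparison at
the study's own sample size.

## Known limitations

- The default affiliation table is a reasonable reconstruction, not a
  published lookup; analyses meant to mirror a specific scheme should
  supply their own CSV.
- Recovery rates are properties of the synthetic generative model;
  they bound nothing about real cohorts.
- The optimistic tuning protocol overstates generalisation by design;
  nested CV is the number to trust, and at 48 subjects even that has
  wide folds.
- Functional and structural channels are analysed separately; no
  multimodal fusion.
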