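# Methods

## Feature geometry

All plane geometry uses pixel coordinates with **y increasing upward**; the
vertical of the ground is the +y axis, so "angle to vertical" is the arccos
of a unit vector's y component. Image-row (y-down) conventions are
converted at I/O boundaries only. Angles are unsigned magnitudes in
[0, 180]°: the severity scale does not distinguish left from right lateral
flexion, and the body-chain angles (F4, F5, F6, F8) use cranially directed
segments so a perfectly straight posture measures 0° on every feature.

Numerics: angles are evaluated as `atan2(|cross|, dot)` rather than
`acos(clamped dot)`. The two are mathematically identical, but arccos of a
clamped dot product loses up to ~1e−4 degrees near 0°/180°, whereas the
atan2 form is accurate to the last double-precision digit everywhere (the
test suite checks 1e−9° agreement against an 80-bit extended-precision
oracle).

F7, the camptocormia convexity index, is the perpendicular distance of the
vertebral fulcrum FC from the C7–L5 chord, normalized by body height and
scaled to percent. "Body height" is taken as the vertical pixel extent
MH.y − LM.y (head midpoint to ankle) — the closest literal reading of
height normalization; alternatives (trunk length, measured stature) would
rescale F7 by a subject-specific constant without changing its ordinal
behaviour. All features are invariant to translation and positive uniform
scaling of the landmarks; F7 in addition is a pure length ratio.

Degenerate geometry (coincident landmarks, zero body extent) raises typed
exceptions rather than returning 0: a silent zero would flow into the
classifier as a plausible healthy measurement.

Depth-map segmentation marks a pixel as body iff |d(x, y) − d_c| < thr
(strict inequality), with d_c the body-centre depth and thr > 0 in mm. The
mask convention is body = 1/True, background = 0/False.

## Synthetic cohort

Only per-class marginal summaries (mean ± SD per feature, group sizes
13/12/33/6/6 for severities 0–4) are available for the reference cohort, so
the generator draws each feature **independently within class** from a
normal truncated below at 0 (every feature is a non-negative magnitude);
rejection sampling keeps the exact truncated-normal law. Truncation
noticeably shifts the mean only where mean/SD is small (e.g. the class-0
lateral trunk flexion F2 = 0.7 ± 0.9°); well-separated classes
(mean/SD > 3) are indistinguishable from normal. A Gaussian-copula hook
accepts an 8×8 rank-correlation matrix for sensitivity analyses; the
default is the identity because the true inter-feature correlations are
unknown.

What the surrogate does **not** emulate — and hence what passing tests do
and do not show: real posture features are strongly correlated within a
subject (a camptocormic patient is flexed on F3, F4, F5 *and* F7 at once),
which concentrates each class on a low-dimensional manifold and makes the
classes far more separable than independent marginals with the same means
and SDs. Under independence the Bayes-optimal classifier on the six optimal
features attains only ≈ 0.89 ICC and ≈ 72% macro one-vs-rest sensitivity
(computable from the generative model), so the grader's surrogate
performance (ICC ≈ 0.64, sensitivity ≈ 49%, accuracy ≈ 82%, specificity
≈ 87%, averaged over 50 cohorts) is an information-theoretic property of
the surrogate, not of the method: the same tree code applied to data with
realistic feature coupling can reach the much higher agreement reported on
real cohorts. The pipeline-level checks therefore validate mechanics
(determinism, CV hygiene, metric definitions) and the feature–severity
correlation structure (mean Spearman r_s of F7/F3/F4 with severity
reproduces the reported 0.603/0.591/0.561 within 0.08), while the absolute
agreement ceiling is surrogate-limited. A cross-check against an
independently implemented CART (identical folds) yields the same surrogate
numbers, ruling out an implementation artefact.

Landmark synthesis inverts the feature map for testing: with the leg axis
vertical, L5 at the origin, C7 placed at inclination F4, MN above C7, MH at
inclination F3, and FC on the ray at inclination F5 from L5 at the distance
realizing F7, the designated subset {F1, F2, F3, F4, F5, F7} is reproduced
exactly (to 1e−6); F6 and F8 are over-determined and emerge. Feasibility
requires F1–F5 < 90°, F7 < 50% of body height, and — a geometric
consequence, not a convention — F4 ≠ F5 whenever F7 > 0 (FC off the chord
cannot sit on a ray through L5 parallel to it) and F4 = F5 when F7 = 0.

The second-rater surrogate flips each score by ±1 (clipped to 0–4) with
probability q; `calibrate_rater_noise` bisects q so the mean ICC(2,1)
against the original scores matches a target inter-rater agreement
(default 0.814), enabling human–human consistency experiments.

## Grading model

The tree is plain binary CART with Gini impurity 1 − Σp², grown greedily to
`max_depth`, a pure node, or no improving split. The 'best' splitter scans
midpoints between consecutive sorted unique values per feature; the
'random' splitter draws one uniform threshold per feature inside the node's
range (extremely-randomized style) and keeps the best feature. All
tie-breaks are deterministic — lowest feature index, lowest threshold,
leaf ties predict the lowest class — so fixed seeds give byte-identical
serialized models.

Model selection minimizes f = mean(|doc − machine|) + λ·#{|doc − machine| > 1}
over the grid of feature subsets × depths (1–10) × splitters. λ defaults to
1.0 (one gross error costs one extra mean-absolute-error point); it is a
config parameter. f is evaluated on **pooled** out-of-fold predictions from
stratified 5-fold CV (per-fold evaluation would weight small folds
unevenly and the objective's count term speaks of whole-cohort case
numbers). Fold assignment is stratified by class and seeded; the smallest
classes (n = 6) spread one subject per fold with one fold receiving two.
Grid ties break toward smaller depth, then 'best' before 'random', then
earlier subset order.

Agreement metrics: macro one-vs-rest accuracy, sensitivity TP/(TP+FN) and
specificity TN/(TN+FP), unweighted means over the classes present in the
truth (absent classes are skipped; a specificity term with an empty
denominator — all subjects truly in that class — is likewise skipped). The
ICC is ICC(2,1): two-way random effects, absolute agreement, single
measures, from the two-way ANOVA mean squares, with the 95% CI from the
F-distribution method (Satterthwaite df). Absolute agreement is the
clinically relevant form — a grader with a systematic one-class offset is
not "consistent" however well it correlates. With perfect agreement
(MSE = MSC = 0) the CI degenerates to the estimate.

## Statistics layer

Per feature: Kolmogorov–Smirnov normality screen per group (the plain KS
with sample mean/SD, as is conventional in clinical reporting; it is
conservative when parameters are estimated — the Lilliefors issue — so a
corrected variant is exposed via `lilliefors=True`); one-way ANOVA when all
groups pass at 0.05, otherwise tie-corrected Kruskal–Wallis; pairwise post
hocs matching the omnibus branch (two-sample t / Mann–Whitney) over all
C(5,2) = 10 group pairs at Bonferroni-corrected α' = 0.05/10 = 0.005
(correction within feature, across the 10 pairs); Spearman rank correlation
(mid-ranks, t-approximation) between each feature and severity. Under the
null the omnibus type-I rate at the reference group sizes is verified to
lie in [0.03, 0.07] over 2,000 replicates.

## Problem sizes and defaults

| parameter | default | rationale |
| --- | --- | --- |
| group sizes | 13/12/33/6/6 (×multiplier) | the reference cohort's distribution |
| tree max depth | 7, splitter 'random' | the selected optimal configuration |
| λ | 1.0 | unit gross-error penalty; unstated upstream |
| CV | stratified 5-fold, seeded | matches the evaluation protocol |
| surrogate replicates | 50 (grading), 200 (correlation) | Monte-Carlo SE < 0.01 on ICC, < 0.005 on r_s |
| landmark scale | 400 px | typical depth-camera body extent; features are scale-free |

## Known limitations

- Features are computed per landmark set; no temporal aggregation over a
  recording window is provided (how multi-frame features should be pooled
  is unspecified upstream).
- Landmark extraction from depth point clouds (deriving MH/C7/L5/FC from a
  segmented body) is out of scope; landmarks are supplied or synthesized.
- The synthetic cohort's independence assumption bounds achievable
  multiclass agreement (see above); conclusions about absolute clinical
  performance require real, correlated feature data.
- No probability calibration, pruning beyond the depth limit, or class
  weighting; the 0–4 scale is treated as nominal by the tree and ordinal
  only through the objective's |doc − machine| terms.
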