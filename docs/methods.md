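# Methods

This note documents the statistical procedures implemented in `cpgsig`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

β values are methylation fractions in [0, 1]; values outside that range
are hard errors, never clamped — silent clamping would mask upstream
normalisation faults. Pyrosequencing methylation percentages live on a
separate 0–100 scale; conversion between the two is always explicit
(×100). Sample sheets are keyed by sample id, and any mismatch between
a matrix's samples and its sheet is a hard error: label/matrix
misalignment is the most dangerous silent failure in a pipeline like
this. Missing β values are handled by one explicit policy,
`drop_incomplete_probes`, applied before ranking or distance
computation; probes lost from one cohort's platform export are removed
everywhere by `intersect_probes`.

## Probe ranking: one-way ANOVA F-ratio

For each probe, F = (SS_between / df_between) / (SS_within / df_within)
across the sample classes. With two classes this equals the squared
pooled-variance t statistic (property-tested against scipy). Probes are
ordered by F descending, ties broken by probe id for determinism.

Near-constant probes need a degenerate-case rule: when the within-group
sum of squares is numerically zero but the group means differ, F is the
+∞ sentinel and such probes rank above all finite scores, ordered among
themselves by the spread of their group means and then probe id. Zero
between-group variation gives F = 0 regardless of the within term. The
zero tests use a relative tolerance of 1e−12 on the total sum of
squares, so floating-point dust from constant groups does not produce
spurious huge finite F values.

## KNN prediction

Euclidean distance over the selected probes; majority vote among the k
nearest reference samples. Tie rules (all deterministic, chosen because
the classical description leaves them open):

- exact distance tie at the k-th position: every tied neighbour joins
  the vote;
- voting tie: the class of the single nearest neighbour wins;
- residual tie (equidistant nearest neighbours of different classes):
  the reference with the smallest sample id decides.

`k` is restricted to odd values by default (grid {1, 3, 5}) to avoid
most two-class voting ties in the first place.

## Nested cross-validation

Folds are stratified by class: each class is shuffled with the run's
seeded generator and dealt round-robin, so per-class fold sizes differ
by at most one. When the smallest class has fewer members than the
requested fold count, the effective fold count shrinks to that size
(with a logged warning) — a 5-vs-7 discovery cohort cannot fill ten
stratified folds.

**Inner selection.** For each inner fold, probes are re-ranked on the
in-fold training portion only; predictors are built at every candidate
size (default grid 1, 2, 3, 5, 10, 20, 35, 50, 100, 200, capped at the
probe count) and every candidate k, and the held-out portion is
predicted. The (size, k) pair minimising the pooled inner-CV error
wins; ties go to the smaller size, then the smaller k. Size and k are
selected jointly in one pass. Re-ranking per inner fold is the
stricter, leakage-safe reading of the classical procedure.

**Outer loop.** Each outer fold's held-out samples are excluded from
ranking, selection and fitting; they are predicted once, and the pooled
out-of-bag misclassification rate is the reported error. The
`fold_callback` hook exposes fold membership and the in-bag ranking so
tests can audit that corrupting held-out columns cannot change any
in-bag ranking.

**Final fit.** Selection and ranking are rerun on the complete series;
the signature is the top `size` probes with Δβ = mean β(positive) −
mean β(reference). Error rates are reported rounded to 3 decimals in
summaries; JSON artifacts keep full precision.

A consequence worth stating plainly: on cleanly separable data the
smallest-error/smallest-size rule selects one or two probes, because a
single strong probe already attains zero inner-CV error. Recovering a
*specific* larger signature size therefore requires fixing the size
grid (e.g. `size_grid=(35,)`), which is how the demo and the recovery
tests request an array-scale signature; ranking fidelity, not the
selection rule, is what those checks measure.

## UPGMA cluster validation

Distances are plain Euclidean over β values of the signature probes
(untransformed β is used; the alternative M-value transform is out of
scope). UPGMA merges the two clusters with the smallest average
cross-pair leaf distance, at a height equal to that distance; the
incremental update d(new, o) = (n_i·d(i,o) + n_j·d(j,o)) / (n_i+n_j) is
exactly the unweighted (leaf-count-weighted) arithmetic mean. Exact
distance ties merge the pair whose combined sorted member-id tuple is
lexicographically smallest — an arbitrary but deterministic rule.
Heights are monotone non-decreasing toward the root, and on ultrametric
input the cophenetic distances reproduce the input exactly (both
tested; heights are also cross-checked against scipy's average
linkage).

Class prediction is defined only for the two-cluster root cut: each
child cluster takes the majority class of its labelled members,
unlabelled samples inherit their cluster's class, and a cluster without
labels takes the one remaining class when that is unambiguous. Two
clusters sharing a majority class is a non-segregation error, not a
silent prediction. k-cluster cuts for k > 2 are reported descriptively
(per-cluster label composition) and never scored.

## Biomarker evaluation

**Mann–Whitney U** uses midranks; U is reported for the first sample
(0 ≤ U ≤ n₁n₂). With n₁+n₂ ≤ 12 and no ties the two-sided p is exact by
complete enumeration of the C(n₁+n₂, n₁) group assignments, counting
those whose U deviates from n₁n₂/2 at least as much as observed;
otherwise the normal approximation with tie correction and a 0.5
continuity correction is used. Tests are two-sided throughout, and no
multiple-testing correction is applied anywhere; every test output
carries `multiplicity_adjustment: none` so downstream consumers cannot
miss it.

**ROC cut-off by LR+.** Candidate cut-offs are the midpoints between
consecutive distinct observed values plus ±∞ sentinels. Under the
hypomethylation convention a sample is positive when its value is
strictly *below* the cut-off. Among candidates with specificity < 1 the
LR+ = sensitivity/(1 − specificity) maximiser wins; any candidate with
specificity = 1 and sensitivity > 0 has LR+ = +∞ (kept as a sentinel
rather than excluded, since perfect-specificity operating points are
legitimate outcomes) and the one with the largest sensitivity wins;
remaining ties go to the lower cut-off. All values identical is an
error — no informative threshold exists.

**Simultaneous-hypomethylation rule.** A sample is called tumour-like
iff its percent value is strictly below the cut-off for *every*
selected probe; equality is negative. The rule is monotone: lowering
any value never flips a positive call to negative.

**Stage-wise comparison** reports per-group medians, each stage versus
the reference group, and consecutive-stage contrasts, in the canonical
stage order I, IIA, IIB, IIIA, IIIC.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any
specific array cohort:

- per-probe background means drawn from a tri-modal mixture (0.1, 0.5,
  0.9 with weights 0.4/0.2/0.4), reflecting the strongly bimodal β
  landscape of 450K arrays with a minor intermediate mode;
- β values Beta-distributed with mean = class-specific probe mean and
  concentration c (α = mean·c, β = (1−mean)·c); the default c = 50
  gives a per-probe SD of ≈ 0.05–0.07 at intermediate means, a
  realistic within-class scatter for array data;
- planted DMPs shift the positive class's mean by Δβ (default −0.35,
  hypomethylation in the tumour class), drawn only from background
  modes whose shifted mean stays inside [0.02, 0.98];
- dropout operates per (probe, dataset): a dropped probe is missing for
  *all* samples of that dataset, mirroring a platform export that lacks
  the probe entirely;
- pyrosequencing tables are truncated-normal draws (clipped to
  [0, 100]) around group means, default SD 8 percent points — the
  scatter visible in typical pyrosequencing series;
- cfDNA draws attenuate the tumour shift by a factor 0.5, modelling
  dilution of tumour-derived fragments in plasma.

One integer seed governs all randomness; identical configuration and
seed give bit-identical output. What the generator does **not**
emulate: probe cross-reactivity, SNP-affected probes, cell-type
composition, batch intensity effects beyond dropout, and spatial/array
artefacts. Passing tests therefore demonstrate the correctness and
statistical behaviour of the *procedures* under a clean bounded-noise
model, not performance on real 450K data.

## Demo and problem sizes

The demo simulates one cohort of 10,000 probes and 163 samples sharing
a single planted truth (12 discovery: 5 controls vs 7 tumours; 151
extension: 58 controls vs 93 tumours split over four dataset batches),
fixes the discovery size grid at the planted DMP count (35) so the
probe-loss and multi-probe-rule stages operate on an array-scale
signature, drops the weakest-|Δβ| signature probe from the extension
cohorts (34 retained), clusters all 163 samples, and evaluates the
top-3 |Δβ| probes on simulated pyrosequencing series (16 controls, 46
staged tumours, 57 other-subtype tumours; cfDNA 15 vs 6). With the
default effect −0.35 the extension two-cluster error is ≈ 0. Test and
acceptance simulations use 1,035-probe, 20-vs-20 cohorts — large enough
for stable rates, small enough to keep the full suite fast. A
zero-effect demo is supported: discovery reports a chance-level
out-of-bag error and the clustering stage records its non-segregation
outcome in the summary instead of aborting.

## Known limitations

- The Beta noise model is a stand-in; its parameters are exposed, not
  asserted to match any GEO series.
- Class prediction from clustering is defined only for the two-cluster
  cut; multi-cohort structure is descriptive output.
- The exact-p Mann–Whitney path enumerates combinations and is
  restricted to n₁+n₂ ≤ 12 by design.
- Probe-to-gene annotation is a pass-through label; no genomic
  coordinates, normalisation or IDAT parsing is provided.
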