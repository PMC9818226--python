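# Methods

## Scope and data model

The pipeline starts at the integrated peak table — compounds × samples raw
peak areas with compound metadata and a two-level group factor — and ends at
aroma-type profiles. Chromatogram parsing, peak detection/integration, and
spectral-library matching are out of scope; the library match quality enters
only as a per-compound score column.

A missing peak ("not detected") is stored as area 0 with a `detected=False`
flag, not NaN. The multivariate stages need a complete matrix and zero is the
natural "not present" abundance; detection counts use the flag, never the
value, so an explicit zero measurement and an absence are never conflated.

Group labels are free strings, but every differential operation demands
exactly two non-empty groups and fails loudly otherwise; the supported design
is a two-condition contrast with biological replicates.

## Retention indexing

`RI = 100·[n + (Rt_x − Rt_n)/(Rt_{n+1} − Rt_n)]` with the bracketing
n-alkanes n and n+1. Two numerical choices:

* **No extrapolation.** The index is defined only between the first and last
  ladder alkanes; queries outside the span are errors, not guesses.
* **Exact rung hits.** A query equal to a ladder retention time returns
  exactly 100·n, bypassing the division, so alkane self-indices carry no
  floating-point residue.
* Ladders with gaps in the carbon series interpolate linearly on the carbon
  scale between the bracketing entries, which reduces to the classical
  formula for consecutive carbons.

The match filter retains compounds with score strictly greater than the
cutoff (default 80). A missing score is retained with a warning — curated
tables built from published compound lists carry no scores — and a strict
mode turns that into an error.

## Relative quantification

Relative content is `100·area/Σarea` per sample; group summaries are the
mean and (n−1) SD of the per-sample percentages — mean of percentages, not
percentage of mean areas, matching the conventional "mean ± SD" tables.

`relative_content(..., renormalize=False)` passes areas through unchanged.
This mode exists for curated tables whose "areas" are already published
percentages: published per-compound means carry 2-decimal rounding, so their
column sums deviate from 100 by ~0.01, and re-normalizing would shift every
value by that rounding residue and break agreement with the published class
totals at the second decimal. All rOAV quantities are content *ratios* and
are identical under either mode.

## Chemometrics

* **Z-scoring** is per compound across all samples, (n−1) SD, constant rows
  mapping to zeros (they carry no contrast).
* **Cluster ordering** delegates to SciPy's average-linkage/Euclidean
  agglomeration; the leaf order is the standard recursive dendrogram
  traversal and is deterministic for tie-free data (the test suite checks
  the merge sequence against a naive O(n³) agglomeration oracle).
* **PCA** is the SVD of the column-centered sample × variable matrix;
  explained fractions are squared singular values over the total.
* **OPLS-DA** is written in-house (it is the analytical core, not a
  commodity step). Orthogonal components are extracted iteratively
  (w ∝ X'y; the orthogonal weight is the X-loading minus its projection on
  w), each deflating X, then one predictive PLS component is fit on the
  filtered matrix. R²X is the variance captured by all components; R²Y the
  fitted y-variance; Q² = 1 − PRESS/SS from stratified k-fold CV with
  centering/scaling re-estimated inside each training fold. Default 7 folds
  (the common software convention), automatically reduced to leave-one-out
  when n < folds — at the design size of 3+3 replicates this makes LOO the
  de-facto behavior. `k_ortho="auto"` adds orthogonal components while CV-Q²
  improves by > 0.01, capped at min(n−3, 5) to prevent degenerate fits at
  n = 6. Inputs are unit-variance scaled by default; the pipeline passes
  `scale=False` because its X is already Z-scored.
* **VIP** uses the standard weighted formula
  `VIP_j = √(p·Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a)`, whose mean square is 1
  by identity. The default covers predictive + orthogonal components
  jointly; since orthogonal scores explain essentially no y-variance, this
  coincides numerically with the predictive-only flavor, which is also
  available (`vip_mode="predictive"`).
* **Permutation validation** refits under random label permutations with
  identical hyperparameters, recording (|Pearson corr with the original
  dummy-coded y|, R²Y, Q²); intercepts at zero correlation come from
  least-squares lines over the permuted triples plus the unpermuted
  reference point, as in standard validation plots.
* **t-tests** default to the pooled-variance two-sided variant (Welch
  available), applied to raw per-group areas. Degenerate inputs follow the
  conventional limits: two identical constant groups give (0, 1); constant
  groups with different means give (±∞, 0) with a warning. An informational
  Benjamini–Hochberg column is emitted, but the screening path uses raw
  p < 0.05 — the screen is a published two-criterion rule (VIP > 1 ∧
  p < 0.05, both strict), not an FDR-controlled discovery procedure.

## rOAV

`rOAV_i = 100·(C_i/C_ref)·(T_ref/T_i)`. The reference (whose score is 100
exactly) is the compound with the largest content/threshold ratio — i.e. the
largest plain odor-activity value. `T_ref` is therefore the *reference
compound's* threshold, not the largest threshold in the table: only this
reading makes the reference score 100 and reproduces the published per-group
values (with the reference differing between groups, the same compound can
legitimately score 0.27 in one group and 1.69 in the other). Category
boundaries: critical at rOAV ≥ 1 (inclusive), modifying on 0.1 < rOAV < 1,
negligible at ≤ 0.1. Compounds without a threshold are excluded from scoring
with an explicit report, never silently.

rOAV defaults to group-mean contents (the only data curated tables provide).
With replicate-level contents the per-sample rOAVs can be computed and
averaged instead; published "± SD" rOAV columns come from that replicate
path, which is why mean-based recomputation of large rOAVs can differ from
published means by a few tenths while small ones agree to 2 decimals.

Aroma profiles add each critical or modifying compound's full rOAV to every
descriptor term it carries. The curated descriptor lists normalize free-text
odor phrases to single canonical terms ("floral rosy" → floral + rosy,
"cedar aroma, woody mahogany aroma" → cedar + woody + mahogany) so that
terms, not phrases, aggregate.

## Synthetic data

The generator emulates the target study design: 42 compounds, 2 groups × 3
biological replicates, log-normal areas (peak areas are positive and
right-skewed) with natural-log-scale σ = 0.3 — giving coefficients of
variation comparable to tight replicate SDs — per-compound log-means drawn
uniformly over a ~e⁶-fold abundance range, 23 differential compounds at fold
change 4 in group 2, and 6 compounds fully dropped out of group 1
(reproducing 36 vs. 42 detection counts). Thresholds are log-uniform over
[10⁻⁴, 10] mg/kg; descriptors are drawn from a 14-term vocabulary. Everything
derives from one seed; identical configs are bit-identical.

What it does **not** emulate: correlated compound families (biosynthetic
pathways co-regulate volatiles), heteroscedastic instrument noise,
retention-time drift, co-elution, or censoring near the detection limit.
Passing recovery tests therefore demonstrate the screen's behavior under
independent log-normal variation at the study's n, not performance on any
particular real instrument run.

Simulation-based checks use deliberately modest problem sizes — 6-sample
models, 10–50 refits per property, 20 seeds for recovery rates — chosen as
the smallest sizes at which the asserted properties are stable.

## Pipeline

Stages run read → RI → match filter → relative content → Z-score → cluster
order → PCA → OPLS-DA (+ permutation) → t-tests → screen → rOAV per group →
aroma profiles; every stage writes a CSV stamped with a hash of the analysis
configuration (output directory excluded), and runs are pure functions of
(inputs, config, seed). When the contrasted groups lack replicates — as with
the curated mean-only dataset — the multivariate refit is refused and the
screen instead consumes externally supplied VIP/p columns; the bundled
dataset ships the published ones for exactly that path.

## Known limitations

* Two-group designs only; no 3+ class discriminant analysis or kernel
  variants.
* OPLS-DA at n = 6 is an illustration-scale model; Q² from LOO at that size
  is noisy, which is why model validity is asserted through permutation
  behavior rather than absolute Q² values.
* rOAV assumes thresholds on a common matrix/medium scale; mixing threshold
  compilations across media changes ratios.
* The descriptor vocabulary is unharmonized free text from threshold
  compilations; profiles are only as comparable as the curation of those
  terms.
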