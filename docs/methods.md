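# Methods

## Inference model

The network model is correlational: over the samples of a stress time
course (time points × replicates, log2 expression), a gene pair (x, y)
is *co-expressed* when the sample Pearson correlation satisfies
r_xy ≥ 0.8 with two-sided p < 0.001 (p from t = r·√((n−2)/(1−r²)) on
n−2 degrees of freedom), and a transcription factor z *explains* the
pair when the first-order partial correlation
r_xy|z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) satisfies
|r_xy|z| ≤ 0.3. Each passing triple materializes both edges z→x and z→y,
and a pair may be explained by several TFs — all are retained; the
method makes no attempt to pick a best regulator, so inferred networks
are dense wherever regulators are mutually correlated.

The hierarchy is assembled in two passes. PASS A screens pairs among
candidate structural genes and attributes them to any candidate TF; TFs
that acquire at least one structural target form layer 2, and structural
genes with at least one incoming edge form layer 3. PASS B screens
pairs among the layer-2 TFs and attributes them to the TFs not already
in layer 2; explaining TFs form layer 1. A TF placed in neither layer
is dropped (logged); a layer-2 TF without an upstream regulator is
retained (logged). When fewer than two TFs reach layer 2, PASS B is
impossible and the result is flagged two-layer.

Defaults follow the screening rule literally: the pair screen is signed
(r_xy ≥ 0.8). `use_absolute_r=True` switches to |r_xy| ≥ 0.8 for
repression-aware screening; the attribution gate always uses |r_xy|z|.
Correlations are computed across all samples by default, maximizing n
for the p-gate; `collapse_replicates=True` averages replicates first.
Pair-screen p-values are deliberately not multiplicity-adjusted (the
gate is a raw p threshold). Thresholds are validated up front
(0 < r_min ≤ 1, 0 < p_max < 1, 0 ≤ partial_max < r_min). The r_min
comparison is inclusive within 1e-12 so a correlation exactly at the cut
is never lost to rounding; conditioners with |r| within 1e-12 of 1 are
skipped as degenerate with a logged warning rather than failing the run.

### Known construction limit of the top layer

A top-layer TF is only placeable through a *pair* of layer-2 TFs, so a
TF regulating a single middle-layer TF is invisible to PASS B. Worse,
the two screens pull against each other: PASS B needs a layer-2 pair
correlated ≥ 0.8, but any two regulators that correlated would also let
each explain the other's targets in PASS A, degrading edge precision.
At study scale (11/19/158) the package therefore typically reports an
empty or very small top layer, and top-layer recovery is demonstrated on
small constructed hierarchies whose noise regime separates the two
screens (structural-gene correlations attenuated below the screen for
cross-parent pairs while middle-TF pairs stay above it).

## Differential expression

Each non-control time point is compared with the 0 h control on log2
values: log2 fold change is the difference of group means, the default
test is a two-sided Welch t (n ≥ 2 replicates per group required;
externally computed p-values can be injected for count-based designs,
which this package intentionally does not model), and BH adjustment is
applied within each time point across genes. A gene is a DEG at a time
point when FDR < 0.05 and fold change > 1.5 or < 0.66, all strict; the
union over time points is the gene universe entering the network.
All-zero genes are dropped before testing with a logged count. Whether
fold changes derive from normalized means or model coefficients is a
convention; this package documents its own (difference of log2 means).

## GO enrichment

Flat gene → term-set annotation (no DAG propagation; terms are used as
bins). The default test is the central hypergeometric upper tail
P[X ≥ k] for k DEGs among K term members, n DEGs, N universe genes,
with BH across terms. The Wallenius non-central mode reweights sampling
odds per term as (mean bias weight inside the term)/(mean outside) and
evaluates the non-central tail; equal weights reduce it exactly to the
central test. The bias-weighting spline machinery of length-aware
enrichment tools is out of scope — in a synthetic setting there is no
length bias to fit. The enrichment universe is always explicit (caller
supplied); DEGs outside the universe are an error, not silently dropped.

## Validation bookkeeping

A tested TF→target interaction is *direct* when any of the four 500 bp
promoter quarters (−2000..0 bp) is ChIP-PCR positive — band calling is
manual upstream, so fragments arrive as booleans, and multiple bound
fragments are equivalent to one. It is *indirect* when no fragment is
bound but overexpression changes the target's expression (qRT-PCR fold
change > 2 and p < 0.05, both strict; fold change exactly 2 is not
indirect). With qRT data present and failing those gates it is *none*;
with no binding and no qRT data it is *untested* and cannot be
summarized. Percentages are rounded half-up to one decimal;
pct_true = direct + indirect. Relative expression follows the
comparative-CT method: ΔCt = Ct(target) − Ct(reference) per condition,
ΔΔCt = ΔCt(treated) − ΔCt(control), relative expression 2^−ΔΔCt, with
replicate Ct vectors averaged first and a convenience Welch test on
replicate ΔCt values.

## Synthetic data generator

The generator plants a three-layer hierarchy and simulates the time
course the inference assumes, so that recovery can be scored against a
known truth.

**Topology.** Layer sizes (n1, n2, n3) and a mean out-degree over all
n1+n2 regulators. Every layer-2 TF receives two distinct upstream
parents when n1 ≥ 2 (distinct parent *pairs* while they last), every
layer-3 gene one parent; childless regulators are repaired; extra edges
are then added regulator-centrically (a uniformly chosen regulator with
spare capacity gains one unused downstream target) until the requested
edge total. Weight magnitudes are uniform on [0.5, 1.5]; signs are
positive with probability 0.8, reflecting the predominantly coherent
activation of acute stress regulons — and in the signed default screen a
symmetric sign distribution would hide half of all co-regulated sibling
pairs by construction rather than by the method's merits.

**Expression.** The defaults emulate a 7-point stress design
(0/1/3/5/9/12/24 h, 0 h control) with 3 replicates. Top-layer driver
profiles are smooth random curves: sums of `driver_smoothness` pairs of
orthonormal discrete-cosine modes on the sampling-order grid. The modes
are exactly orthogonal over the time points, so random drivers are
isotropic in their span; evaluating sinusoids on the raw-hours grid
instead collapses them onto a ~3-dimensional family in which "distinct"
drivers frequently correlate above the pair screen, making any planted
truth unidentifiable before the method even runs. Drivers are
additionally rejection-sampled under a pairwise coherence cap
(|corr| ≤ 0.45, relaxed progressively when the grid cannot hold more
separated profiles).

Each downstream gene is the weighted sum of its parents' *observed*
expression, rescaled to unit variance, plus i.i.d. Gaussian noise per
sample (`noise_sd`, log2 scale). Propagating observed rather than
noise-free parent profiles is load-bearing: if children mixed noise-free
profiles, two siblings and their parent would all equal signal + i.i.d.
noise, and the sample partial correlation of the siblings given the
parent converges to r/(1+r) ≈ 0.5 — above the 0.3 gate no matter how
small the noise, so the method would be inconsistent under its own test
data. With propagation through the observed parent, conditioning on the
parent removes everything the siblings share and the partial correlation
is ≈ 0. At `noise_sd = 0` (and `intrinsic_sd = 0`) the two formulations
coincide and every target is an exact signed linear combination of its
parents.

Middle-layer TFs additionally carry gene-intrinsic smooth variation
(`intrinsic_sd`, default 1.0 — half a regulator's variance from inputs
outside the modeled hierarchy), realized independently per biological
replicate. This is what keeps regulator profiles pairwise separated:
with only 7 time points all smooth profiles live in a 6-dimensional
space, where mixtures of even well-separated drivers can align almost
perfectly; per-replicate intrinsic variation raises the effective
dimension roughly threefold and caps regulator–regulator correlations
well below the pair screen. Children inherit it through their parent's
observed expression, replicate-matched, so attribution to the true
parent is unaffected. Bottom-layer genes are faithful outputs of their
planted regulator up to `noise_sd` — the planted truth is meant to be
identifiable, and their unexplained variation is the white-noise term.
An optional integer `lag` (time-point units, default 0) delays
propagation; the default is instantaneous because the inference
correlates contemporaneous samples. A `patterns` profile mode replaces
random drivers with three archetypes (up-early/down-late,
down-early/up-late, oscillating).

**What the simulation does and does not emulate.** It reproduces the
statistical structure the inference assumes — co-regulated genes share a
common driver, distinct regulators are distinguishable — with additive
Gaussian noise on the log scale. It does not model read counts,
library-size or GC artifacts, mean–variance relationships of counts,
nonlinear or saturating regulation, or regulator-specific response lags.
Passing recovery tests therefore demonstrate correctness of the
inference pipeline under its own assumptions, not performance on real
RNA-seq; in particular, the per-replicate intrinsic variation that makes
regulators separable also makes middle-layer TFs hard to call as DEGs at
n = 3, which is faithful to real biological replicate variability but
means demonstration pipelines are best run with the DEG filter relaxed
or bypassed.

**Recovery scoring.** Precision = |inferred ∩ planted|/|inferred| and
recall = |inferred ∩ planted|/|planted| per layer pair, ignoring weights
and signs; an empty inferred set reports NaN precision and zero recall
rather than failing. At the study scale (11/19/158, mean out-degree 8,
noise 0.05) the acceptance suite checks mean bottom-layer recall ≥ 0.6
and precision ≥ 0.7 over 20 seeds and that recall is non-increasing in
noise over {0.05, 0.3, 1.0}; the suite computes the actual values at run
time.

## Numerical and I/O conventions

Tabular files are tab-separated UTF-8 without quoting; expression
matrices use `t<hours>h_r<replicate>` sample IDs, are written with
`%.17g` floats and read with round-trip float parsing, so write → read →
write is byte-identical. All writers iterate in sorted order and the
pipeline is a pure function of its config file, so repeated runs produce
byte-identical artifacts (checked in the test suite). Percentages are
rounded half away from zero to one decimal. BH adjustment, Welch tests,
Pearson p-values and the hypergeometric/Wallenius tails are delegated to
scipy and verified in the test suite against independent brute-force
oracles (step-up definition, closed-form correlation formulas,
least-squares residual correlations, exhaustive subset enumeration).
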