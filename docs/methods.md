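# Methods

This note records the models, conventions and design choices behind
`plinet`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where genuine choices were made.

## Signal model and preprocessing

Recordings are channels × samples matrices with 10-20 labels and a
sampling rate (500 Hz reference design). Analysis always runs on the
fixed 16-channel montage F3 F4 F7 F8 T3 T4 T5 T6 C3 C4 P3 P4 O1 O2 Fz
Pz, in that canonical order; Cz (reference), Fp1/Fp2 (ocular and
frontalis artifacts) and A1/A2 (no cortical signal) are excluded.
Re-referencing subtracts the instantaneous 16-channel mean; this is
idempotent and preserves all pairwise channel differences exactly.

Epoching takes five contiguous, non-overlapping 4096-sample windows
from the start of the recording (8.192 s at 500 Hz). A nominal 8.19 s
window would be 4095 samples; 4096 samples is treated as the defining
quantity. Artifact-free segment selection is assumed to have happened
upstream (manual selection in clinical practice); explicit epoch start
offsets can be supplied in the run config, but automatic artifact
rejection is out of scope.

Band restriction is per-epoch FFT masking: Fourier coefficients outside
[low, high] Hz are zeroed. This filter is deterministic, has exactly
zero phase distortion and no order parameter; its cost is edge ringing,
so a configurable fraction of samples (default 5%) at each epoch edge is
excluded from PLI averaging. Whether filtering should precede or follow
epoch segmentation is a convention; per-epoch filtering matches the
per-segment processing of the rest of the pipeline. Instantaneous phase
is the angle of the analytic signal (Hilbert transform) per epoch and
channel, hence invariant to positive amplitude scaling.

## PLI

For two phase series, PLI = |mean over time of sign(sin(φᵢ − φⱼ))|.
The sine gives the sign of the principal wrapped phase difference and
assigns zero evidence both to exact in-phase (Δφ = 0, the
volume-conduction case) and to exact anti-phase (Δφ = ±π), where the
lead/lag direction is undefined. This makes PLI(i, j) = PLI(j, i) an
exact identity; under a (−π, π] wrap convention, symmetry fails on the
measure-zero set Δφ = ±π. Values lie in [0, 1]; matrices are symmetric
with a zero diagonal.

Scalar metrics are computed per epoch and then averaged across the five
epochs (the mean of per-segment metric values). The entry-wise mean PLI
matrix across epochs is exported for diagnostics but never feeds the
statistics.

## Weighted network measures

With weights w = PLI over the complete 16-node graph:

* Clustering (triple-product form): per node,
  `C_i = Σ_{k≠l} w_ik·w_il·w_kl / Σ_{k≠l} w_ik·w_il` over ordered
  neighbor pairs k ≠ l ≠ i; a node with fewer than two nonzero weights
  gets C_i = 0; C is the node average. With all weights equal to w the
  expression collapses to w. The formula choice is a convention of the
  weighted-graph lineage used in EEG network work and is recorded in
  output metadata.
* Path length: edge length 1/w (infinite for w = 0), Dijkstra
  all-pairs, L = mean over the 120 unordered pairs. Any unreachable
  pair makes L infinite and flags the subject — for PLI matrices this
  only signals pathological input; nothing is silently dropped.
* Surrogate normalization: a surrogate redistributes the 120
  upper-triangle weights uniformly at random over edge slots
  (re-symmetrized). For complete weighted graphs this is the reading of
  "random networks of identical density" that preserves both density
  and the weight distribution exactly. rC = C/⟨C_surr⟩,
  rL = L/⟨L_surr⟩ over 50 surrogates (default), seeded and recorded.
  An all-equal-weight matrix is a fixed point: every surrogate equals
  the input and rC = rL = 1 exactly. rC and rL are invariant to global
  rescaling of the weights; SWI = rC/rL holds to machine precision on
  every output.

## MST measures

Kruskal on costs 1/PLI (zero-weight edges carry infinite cost and are
considered last). Cost ties are broken lexicographically on the sorted
label pair, making the tree reproducible when PLI values collide —
common in short epochs; the tie-break is recorded in output metadata.
With n = 16 nodes and m = 15 edges:

* degree fraction = degree/m; Degr is the maximum;
* eccentricity per node = (max hop distance)/m; Ecc is the node mean;
* betweenness per node = (number of the n(n−1)/2 = 120 unique tree
  paths with that node strictly interior)/120, computed from the
  component sizes left by removing the node; BC is the maximum. Path
  endpoints do not count: otherwise every leaf would lie on 15 paths
  and a path graph could not have near-zero hierarchy;
* Leaf = (#degree-1 nodes)/n; Diam = (max hop distance)/m;
* TH = leaf_number/(2·m·BC), asserted exactly against its definition.

Hop counts (not weighted distances) are used inside the tree, since the
measures count connections. Both Ecc and Diam are normalized by the
same divisor m, preserving per-node eccentricity ≤ diameter. Top-node
extraction returns *all* maximizers of degree fraction and of
betweenness — ties are included, never broken — and hub-frequency
tables count a subject toward every tied node, so columns may exceed
100%.

Per-subject hub identification averages the per-node degree and
betweenness fractions over the five epoch trees before taking the
maximum, consistent with metric-level epoch averaging.

## Language scoring

z = (raw − mean)/SD against healthy norms (SD > 0 enforced); a domain
score is the mean of its available member tests. Missing tests leave a
domain missing — absent, never imputed as zero. Impairment is min
domain z ≤ −1.5; the boundary itself counts as impaired, the reading
under which the canonical impaired/unimpaired subgroup sizes are
defined. The eight-domain map (word retrieval, phonology, semantics,
grammar, auditory comprehension, visual comprehension, reading,
writing) is configurable; every test must belong to exactly one domain.

## Statistics

* Kendall tau-b with tie correction; p exact by enumeration for n ≤ 8
  without ties, else tie-adjusted normal approximation. Two-sided by
  default (one-sided available); correlations with fewer than 3
  complete pairs, or a constant margin, are reported as not estimable
  rather than dropped from the output schema.
* Mann–Whitney U with midrank ties; exact p for n1 + n2 ≤ 20 without
  ties, else tie-corrected normal approximation; U_min is reported.
* One-sample Wilcoxon signed-rank vs a reference; zeros dropped; exact
  p for n ≤ 15 (no tied absolute differences), else normal
  approximation with continuity correction; the standardized Z
  (tie-corrected variance) is reported alongside. Language-vs-norm
  comparisons are one-sided (deficit direction).
* Missing data: pairwise deletion per analysis cell, never listwise;
  cell n is reported. No multiple-testing correction by default
  (exploratory design); Benjamini–Hochberg is available behind a flag
  and reports both raw and adjusted p.

## Synthetic generators

**EEG.** Each connected component of the planted coupling graph shares
one band-limited Gaussian-process carrier (complex spectrum confined to
band_center ± band_width/2, default 2 Hz wide); each member channel
carries the carrier's analytic signal rotated by its cumulative phase
lag, propagated over a spanning tree of the component. Pair lags must
be nonzero — PLI is blind to zero lag — and two non-adjacent channels
with equal cumulative lags (e.g. the leaves of an equal-lag star) are
deliberately zero-lag copies, mimicking a volume-conducted common
source. `coupling_strength` is the fraction of a coupled channel's
oscillatory power from the shared carrier; the rest is an independent
same-band private process. Channels in no pair carry only noise, so
uncoupled pairs share nothing but noise. Noise is independent
1/f-shaped Gaussian per channel (flat below 1 Hz), default SD 0.5
relative to unit oscillatory power — background comparable to, but not
overwhelming, the rhythm. With strength 1 and no noise a coupled pair
is an exact constant-lag copy and its downstream PLI equals 1 to within
1e−9, including after average re-referencing (the reference is then
proportional to the same carrier).

One caveat found during validation and worth stating: for a planted
*star* the 16-channel average is essentially the carrier itself, so
average re-referencing cancels the shared signal from the leaves and
destroys the planted structure — the textbook behaviour of an average
reference in the presence of a dominant global source. Structure-
recovery checks (planted edge set, star-hub recovery) therefore
evaluate PLI on the band-limited phases of the generated recording
directly; the patient pipeline keeps the average reference, which is
appropriate when no single source dominates all channels.

**Cohorts.** Network metrics (10 measures × 2 bands, mapped onto
plausible scales) and 8 language-domain z-scores are drawn from a
Gaussian copula; a planted Kendall tau becomes a latent Pearson
correlation rho = sin(π·tau/2), exact for the bivariate normal, so
sample tau converges to the target (|bias| < 0.05 by n = 2000 in the
suite). Infeasible tau combinations (non-positive-semi-definite latent
correlation) raise an error; tau = ±1 (singular but PSD) is handled
exactly via eigendecomposition sampling. After sampling, one constant
is added to all patients' domain scores so that exactly
round(impairment_fraction · n) patients are impaired — an affine shift
that provably leaves every metric–domain rank correlation unchanged.
Controls are drawn without planted associations; an optional per-metric
location shift (in SD units) plants group differences for power checks.

All randomness flows from a single integer seed per spec or run config;
per-stage and per-subject seeds are derived via SeedSequence with a
CRC32 stage tag, so a whole study is reproducible byte for byte from
one integer (asserted by the end-to-end rerun test).

**What the generators do not emulate:** volume-conduction head models
beyond the zero-lag construction, nonstationarity and drowsiness,
artifacts (EOG/ECG channels are read but unused), tumor or lesion
geometry, and realistic cross-metric dependence (metric columns are
independent unless planted). Passing recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
clinical validity on real EEG.

## Problem sizes and numerical choices

The default study size is 15 patients + 15 controls with two follow-up
dropouts, five 4096-sample epochs at 500 Hz, 50 surrogates, and 100
seeds for Monte-Carlo recovery and calibration checks (the validation
driver uses 30 seeds for a quick desk run). Tolerances: exact PLI
identities at 1e−9; surrogate calibration within ±0.05 of 1; copula
bias below 0.05 at n = 2000; recovery rates at the 90–95% level stated
per check. Ties in Kruskal are resolved lexicographically; ties in
top-node rankings are kept. Degenerate inputs (all-equal weights,
zero-weight pairs, constant statistical margins, empty subgroups) are
either well-defined fixed points (rC = rL = 1), flags (infinite L,
not-estimable cells), or explicit errors (empty groups, all values at
the reference) — never silent.

## Known limitations

Epoch selection trusts the input ordering (first five windows); the
weighted clustering/path-length formulas are one defensible convention
among several and are therefore stamped into output metadata; exact
Wilcoxon p-values switch to the normal approximation in the presence of
tied absolute differences regardless of n; and the EDF writer covers
the common fixed-layout 16-bit case (integer sampling rates, one-second
records), not the full format zoo.
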