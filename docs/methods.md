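# Methods

## The emission model

Per-window ChIP-seq counts are overdispersed (windows differ in copy
number, mappability and PCR propensity) and carry excess zeros from
unmappable regions. The univariate baseline model is therefore the
zero-inflated negative binomial: a point mass at zero with weight π
mixed with NB(α, p). The multivariate model for r replicates is the
zero-inflated negative multinomial, derived as a Gamma-Poisson
construction: a mappable window draws a single intensity
λ ~ Gamma(α, 1), and replicate j draws Poisson(λ·p_j/p₀) counts. The
shared λ induces the positive across-replicate correlation seen in real
data; the correlation vanishes as α → ∞ and the model degenerates to
independent Poissons. Biases are *not* modeled from genomic covariates
(G+C, mappability tracks); they enter only through the variance via α.

Zero inflation is joint across profiles: an unmappable window is zero
in every replicate and in the controls. π is interpreted as the
proportion of unmappable windows.

## Fitting the ZINB (`zinm_model.fit_zinb`)

Maximum likelihood via EM over the structural-zero indicator:

* E-step: the posterior probability that a zero window is structural is
  π / (π + (1−π)·p₀^α).
* M-step: π is the weighted zero fraction; (α, p) solve the weighted NB
  likelihood with p profiled out (p = m/(α+m), m the weighted mean) and
  the remaining one-dimensional score in α solved by a damped Newton
  iteration inside a maintained sign bracket, falling back to bisection
  whenever a Newton step leaves the bracket.

Initialization is the NB moment fit with π set to the excess-zero
fraction over that fit (floored at 0). Boundary fits are legitimate
outputs: π = 0 on uninflated data, and α = ∞ (the Poisson limit,
represented explicitly with the mean as the carrier parameter) on
underdispersed data. Returning the boundary rather than a large capped
α keeps the nested-model likelihood ordering
Poisson ≤ NB ≤ ZINB exact on every dataset.

Convergence is declared at a relative log-likelihood change below
1e-11 (at most 500 iterations). The tolerance is deliberately tight:
EM approaches the optimum geometrically, and a looser cut-off (1e-8)
leaves a ~1e-4 gap to the true maximum, which is the same order as the
agreement we guarantee against an independent optimizer.

Two numerical points matter at large α. `gammaln(α+k) − gammaln(α)`
and the corresponding digamma difference cancel catastrophically above
α ≈ 1e4; the pmf is then computed as a Poisson correction
(k·log m − log k! − α·log1p(m/α) + Σ_{i<k} log1p((i−m)/(α+m))) and the
score via the exact harmonic sums ψ(α+k) − ψ(α) = Σ_{i<k} 1/(α+i).

## The HMM (`hmm_engine`)

Three states (low/medium/high abundance) with ZINM emissions sharing
(π, α); two states absorb the large-scale, low-amplitude baseline
variation so that the high state tracks targets. Chromosomes are
independent chains sharing all parameters — each block restarts from ν
— which avoids fictitious transitions across chromosome junctions.

* (π, α) are fitted once from the pooled control columns and pinned;
  estimating them inside EM is known to destabilize the fit, and the
  controls are exactly a draw from the baseline. If the control fit
  sits at the Poisson boundary, α is capped at 1e5 with a warning so
  the ZINM stays defined.
* E-step: scaled (per-position normalized) forward-backward; each
  emission row is max-shifted in log space before exponentiation so no
  underflow is reachable. Exactness is tested against brute-force path
  enumeration, not against a second recursion.
* M-step: ν from the posterior at block starts, Q from pairwise
  transition expectations, and each state's probability vector from the
  posterior-weighted ZINM likelihood equations. Profiling p₁…p_r out
  (they are proportional to the weighted column totals) leaves a
  one-dimensional score in p₀ solved by the same damped-Newton/bisection
  scheme. A state whose total responsibility falls below 1e-8 keeps its
  emission parameters for that iteration (with a warning).
* Decoding: Viterbi, ties broken toward the lower state index at each
  backtracking step. The posterior probability of the called state is
  reported as the per-window confidence. Posterior decoding is
  deliberately not the primary caller.

EM stops at a relative log-likelihood change below 1e-6 (default, at
most 100 iterations); the trace is non-decreasing up to 1e-6 slack.

**Initialization.** Seeding is deterministic: windows are rank-split by
total ChIP count and each group's emission vector fitted directly; ν is
uniform and Q sticky (0.95 diagonal). A single split can start EM in a
local optimum where two states share the baseline and the high state
swallows medium windows — on small inputs this optimum is sticky. The
fit is therefore restarted from three rank splits, (50, 90), (75, 95)
and (90, 99) percent, and the highest final log-likelihood wins. This
keeps the procedure free of random seeds while escaping the dominant
local optimum.

**State roles.** After fitting, states are ranked by the implied total
mean ChIP signal per mappable window (Σ_j α·p_j/p₀), ascending, to get
low/medium/high; ties fall back to raw index order with a warning.
Role identification makes the output invariant to label switching at
initialization.

**Parameter count.** The conventional count of estimated parameters is
3r + 9: 2 free in ν, 6 free in Q, α, and r free emission probabilities
per state. π is excluded because it is pinned to the controls'
structural-zero excess rather than estimated with the HMM; counting it
would give 3r + 10.

**Windows that are zero in every profile** stay in the chain — the
zero-inflation component absorbs them — but are never reported as
targets, whatever the Viterbi call around them.

## Quality control (`qc_classifier`)

Five features summarize a discretization: Q[high→low] (how short-lived
targets are), the minimum over replicates of the high/medium
emission-rate ratio (signal-to-noise), the target fraction, the
between-state over total sum of squares of the per-window mean ChIP
count (variance explained), and the mean pairwise Pearson correlation
of the raw ChIP columns (sentinel 1.0, with a warning, when r = 1).
Variance explained is computed on pooled counts, and correlation on
untransformed counts — the simplest reading of both quantities; they
are knobs, not laws.

The classifier is an RBF-kernel SVM (two hyperparameters, C and the
kernel width, grid-searched under stratified 10-fold cross-validation),
with features standardized by the training scaler at train and predict
time. The verdict is all-or-none at the SVM's natural zero margin — no
probability calibration. The model is persisted as JSON (scaler
constants, support vectors, dual coefficients, intercept), and the
decision function is evaluated directly from those arrays, which keeps
the artifact text-only and byte-stable across library versions.

**Training corpus.** Real corpora for this task are partly subjective
(success is judged by inspection). The package instead ships the
training *pipeline* plus a corpus generated by its own simulator:
positives are replicated two-sample profiles with genuine enrichment
(high state 7–14× baseline, medium 2–3.5×, randomized per case);
negatives alternate between (a) profiles with no enrichment treated as
ChIP and (b) pairs of profiles enriched at unrelated target sets
treated as replicates. Each case is one chromosome of 1000 windows at
300 bp — large enough for stable features, small enough that a 400-case
corpus builds in a few minutes. The bundled `qc_model.json` is trained
on exactly this corpus (seed 0) and is labeled as synthetic; it is not
a classifier trained on experimental data, and the cross-validated
accuracy on the synthetic corpus says nothing quantitative about
performance on real profiles — only that the five features separate
the failure modes the simulator encodes.

## Simulator (`simulator`)

The generator draws the hidden chain from (ν, Q), marks windows
unmappable with probability π (zero everywhere), and emits counts
through the shared Gamma-Poisson construction; controls draw from the
baseline rate at every window and share λ with the ChIP columns.
Defaults describe a routine mammalian experiment at 300 bp windows:
π = 0.1, α = 3, control mean 4 reads/window, two replicates with state
means (2, 6, 20), a sticky chain spending ~86% of its time in the low
state. Everything is determined by a single integer seed.

What it does *not* emulate: fragment-length and strand-shift structure,
G+C and mappability covariates along the genome, copy-number segments,
and real inter-laboratory batch effects. Tests passing on simulated
data therefore demonstrate correctness of the inference machinery under
the model's own assumptions, not robustness to everything real data do.

BED emission writes each count as a 36 bp read at a distinct midpoint
(alternating strand when an offset is exhausted) so that re-binning
reproduces the count matrix exactly and duplicate removal is a no-op
unless duplicates are injected deliberately.

## Evaluation (`evaluation`)

The Pareto front is the cumulative count of windows sorted by
decreasing reads; a discretization is the point (targets, reads
captured) and can never dominate the front. Motif benchmarking counts
≥1 bp overlaps on half-open intervals (optionally after re-centering
peaks to a fixed width, off by default); precision = peaks with a
motif / peaks, recall = motifs covered / motifs, F1 their harmonic mean
(0 when both vanish; precision is NaN with no peaks). Variance
explained of an external response is the one-way between/total sum of
squares; it takes pre-joined (response, group) pairs — assigning
windows to genes is out of scope.

## Problem sizes and defaults

Defaults are chosen so a complete verification pass is desk-scale: the
parameter-recovery study uses 2 chromosomes × 25 000 windows (r = 2),
the QC benchmark 200 positive + 200 negative cases of 1000 windows, the
EM-monotonicity sweep 50 runs of 300 windows, and the brute-force HMM
cross-checks sequences of ≤10 windows where 3^n enumeration is exact.

## Known limitations

* Exactly three states; no per-peak p-values or FDR — confidence is the
  state posterior.
* Paired-end mates are treated as two reads; no fragment
  reconstruction.
* The GEM mapper's output format is not read (BED/SAM/BAM only).
* The QC feature "replicate correlation" is computed on raw counts and
  is depth-sensitive in principle; on simulated data the verdict is
  robust to a 3× depth change, but extreme depth imbalance between
  replicates is not modeled.
* Control columns are used only to pin (π, α); they are not part of
  the emission vector during EM.
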