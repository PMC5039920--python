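# chipseg

Joint discretization of replicated ChIP-seq profiles with built-in
quality control.

ChIP-seq experiments measure where a transcription factor binds or a
histone modification sits, but read-count profiles from different
replicates — often produced by different laboratories — disagree, vary
in quality, and are hard to combine. `chipseg` turns any number of
replicate profiles (plus at least one input/mock control) into a single
per-window track with three states, *low*, *medium* and *high*
abundance, where the *high* windows are the called targets. It then
judges its own output: an SVM over five summary statistics of the
discretization accepts or rejects the profile as a whole, which is the
safe behavior for large automated pipelines (a swapped sample or failed
immunoprecipitation should fail loudly, not silently contribute peaks).

## Model

Read counts are binned by midpoint into fixed 300 bp windows. The count
vector y_i = (y_{i,1}, …, y_{i,r}) of window *i* over *r* replicates is
modeled with a **zero-inflated negative multinomial (ZINM)**
distribution

    g(y | π, α, p₀…p_r) = π + (1−π)·p₀^α                     if y = 0
    g(y | π, α, p₀…p_r) = (1−π) · Γ(α+Σy_j)/(Γ(α)·Π y_j!) ·
                           p₀^α · Π p_j^{y_j}                 otherwise

with p₀ + p₁ + … + p_r = 1. π is the fraction of unmappable
(structurally zero) windows, α the shape of a shared Gamma intensity
that captures window-to-window bias (copy number, mappability, PCR),
and α·p_j/p₀ the mean count of replicate *j*. The shared intensity
makes replicate counts positively correlated, as they are in real data.

A 3-state hidden Markov chain (initial distribution ν, transition
matrix Q) moves between low/medium/high states; two states absorb the
piece-wise baseline so the third tracks genuine targets. π and α are
state-independent and are fitted once from the pooled controls by a
zero-inflated negative binomial maximum-likelihood fit (EM with a
damped-Newton inner solver); ν, Q and the per-state probability
vectors are estimated by Baum-Welch; the reported segmentation is the
Viterbi path, with the posterior probability of the called state as a
per-window confidence. The model estimates 3r + 9 parameters.

Quality control extracts five features — Q[high→low], the minimum
high/medium emission-rate ratio across replicates, the target fraction,
the variance explained by the discretization, and the mean replicate
correlation — and feeds them to an RBF-kernel SVM trained on a
simulator-generated corpus under stratified 10-fold cross-validation.
The bundled model (`src/chipseg/data/qc_model.json`) is trained on
synthetic data only.

## Worked example

Simulate a small experiment (1 control, 2 replicates, 1500 windows) and
discretize it:

```sh
$ chipseg simulate --out-dir sim --seed 5 --n-windows 2000 --chroms 1
wrote 1 control and 2 chip BED files to sim
$ chipseg discretize -c sim/control1.bed -i sim/chip1.bed -i sim/chip2.bed \
      --chrom-lengths sim/chrom_lengths.tsv --out-prefix out/run
2000 windows, 140 targets, loglik -7736.29, QC accepted
```

The run called 140 of 2000 windows (7%) as targets and the QC verdict
is *accepted*: the replicates agree and the signal-to-noise of the high
state is clearly above baseline. Outputs:

* `out/run.windows.tsv` — per window: chrom, start, end, state
  (0=low, 1=medium, 2=high) and confidence in [0, 1];
* `out/run.targets.bed` — maximal runs of target windows, BED;
* `out/run.params.tsv` — π, α, ν, Q and emission probabilities;
* `out/run.report.json` — configuration, log-likelihood, QC features
  and the accept/reject verdict. A rejected profile exits with status 3.

The same pipeline is available as a library:

```python
from chipseg import build_count_matrix, discretize, extract_features

counts = build_count_matrix(["input.bed"], ["rep1.bed", "rep2.bed"],
                            chrom_lengths={"chr1": 248_956_422})
profile = discretize(counts)           # DiscretizedProfile
features = extract_features(profile.fit, counts)
```

`chipseg evaluate` compares discretizations: it places a set of calls
on the Pareto plane (number of targets vs reads captured; no
discretization can beat the front formed by sorting windows by read
count) and scores peak calls against a motif-occurrence BED with
precision (peaks containing a motif / peaks), recall (motifs covered /
motifs) and F1.

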