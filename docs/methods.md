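# Methods

## Model

A sample's circadian time t (hours on the 24-h modulus; internally
minutes on a 1440-min modulus, since errors are reported in minutes) is
represented by the unit vector

    s = sin(2πt/24 + π/2),  c = −cos(2πt/24 + π/2),

so midnight is (1, 0) and 06:00 is (0, 1). Each sub-predictor is a
multilayer perceptron — input = z-scored expression of its gene feature
set, three fully connected ReLU hidden layers (default widths 32/16/8),
two linear outputs — trained to point toward the encoded time. The loss
is the mean over the batch of `1 − cosine similarity` between the
encoded truth and the raw two-dimensional output. Because cosine
similarity ignores vector magnitude, the network output needs no
normalisation and decoding is invariant to positive rescaling:
`t = atan2(s, −c)`, shifted and wrapped to [0, 24). The decoder is
defined operationally as the exact inverse of the encoder; the
round-trip identity on all 1440 integer minutes is a tested contract.
The loss is bounded in [0, 2]: 0 for exact directions, 1 for orthogonal
(6 h off), 2 for antipodal (12 h off). A 1e−12 norm floor guards the
division; a numerically zero output vector decodes to a fixed fallback
direction rather than crashing.

Signed circular error is `((pred − true + 720) mod 1440) − 720` with
the antipodal tie broken to +720. Positive = advanced (clock running
early). The circular mean of a set of estimates is the decoded vector
sum of their encodings; it equals the minimiser of the mean squared
*chordal* distance on the circle (the brute-force oracle used in the
tests). When the resultant length divided by n falls below 1e−6 the
direction is meaningless and a `DegenerateCircularMeanWarning` is
raised instead of silently returning.

## Optimisation

Training is Adam (β₁ = 0.9, β₂ = 0.999) with seeded minibatch
shuffling and an L2 penalty on the weights; every random draw
(initialisation, shuffling) is keyed from the hyperparameter seed, so a
seed reproduces weights exactly. The angular objective on very small
training sets (tens of samples) has genuinely bad local minima — a fit
can converge with the predicted direction wound incorrectly around part
of the cycle. `n_restarts` therefore refits from k seeded
initialisations and keeps the lowest final training loss (default 1;
the selection machinery uses 2–3). For the feature-selection inner
loop, full-batch gradients (batch size ≥ n) with a higher learning rate
are markedly more stable than small minibatches and also faster in this
implementation; the tuned per-member batch size applies to final
training.

## Cross-validation

Fivefold CV drives both feature selection and tuning. Folds are built
over *unique time labels*, dealt round-robin around the clock from a
seeded start, so every fold spans the cycle and replicates of a
timepoint never straddle folds (no leakage of a timepoint into its own
training folds). Within one SFS run the fold partition is fixed, making
all candidate costs paired comparisons. The CV cost is the mean
absolute circular error in minutes. Under label permutation this cost
concentrates near 360 min — the analytic mean |error| for uniform
guesses on a 1440-min circle — which is the null every accuracy claim
is measured against.

## Feature selection

One SFS run: (1) bootstrap 50 % of the genes that pass the rhythmicity
prior filter (Q < 0.05); (2) shortlist the top 25 genes per 4-h peak
phase bin by ascending Q (ties broken by gene id; short bins contribute
what they have — six full bins give the canonical 150); (3) seed the
set with one random shortlist gene; (4) repeatedly pick an
under-represented phase bin (minimum current count among bins with
remaining candidates, random among ties; if the minimal bin is
exhausted the next least-represented bin is used), trial-insert every
remaining shortlist gene of that bin, and commit the argmin-cost
insertion (cost ties keep the earlier-evaluated, lexicographically
first gene); (5) from 8 genes onward, after each insertion trial-remove
every gene except the newest addition and greedily commit removals that
strictly lower the cost, re-testing after each commit, never below 3
genes; (6) stop at 40 genes, shortlist exhaustion, or the budget. The
budget is counted in cost evaluations (deterministic and
hardware-independent) rather than wall-clock hours; every evaluation is
logged (action, gene, cost, set size) and the *best state visited* is
returned, so the algorithm is anytime.

The returned-best-state rule means a run's outcome is only as good as
the cost signal. Two design consequences surfaced during development:
(a) with noiseless marker genes, two genes with complementary phases
already saturate the cost, so nothing pushes the optimum past tiny
sets — realistic per-sample noise and per-experiment batch offsets in
the evaluation fixtures are what make larger, phase-balanced sets
genuinely better, mirroring real data; (b) when a bin offers many
uninformative candidates, the winner's curse of picking the argmin of
many noisy evaluations can admit a noise gene, so evaluation stability
(full-batch training, restarts, moderate L2) matters more than raw
network capacity.

## Ensemble

Run i of n uses seed base+i for its bootstrap, shortlist draw, folds
and network. After SFS, each member's learning rate (log-uniform
[1e−4, 1e−2]), batch size ({4, 8, 16, 28}) and L2 factor (log-uniform
[1e−6, 1e−2]) are tuned by random search (default 20 trials at study
scale; fewer in the scaled-down benchmarks) with the same CV cost, then
the member is trained on all training samples. Failed runs are skipped
with a warning rather than retried, preserving the seed bookkeeping.
Test-time estimates are aggregated by circular mean. When truth is
known, per-member signed errors are labelled accurate (|e| ≤ th),
advanced (e > +th) or delayed (e < −th); the default threshold is
60 min with 90 min used for noisier backgrounds. For mutant/wild-type
contrasts, feature-gene groups are formed per label after restricting
to members accurate in the matched wild-type sample; groups may
overlap, and gene lists are exported for external enrichment tooling.

## Scaling policies

All scaling is per gene. RNA-seq test data uses the *training* mean/sd
(sample sd, ddof = 1); features missing from a test set are imputed as
TPM 0 before scaling (absent ⇒ lowly expressed). Microarray and
cross-species data are z-scored independently with their own
statistics — intensity and TPM scales only correspond after per-set
standardisation — and features missing from a probeset require
reducing the ensemble's feature space and retraining
(`retrain_with_features`), one reduced ensemble per platform. Genes
with zero variance scale to 0, not NaN, and are flagged. No log
transform is applied to TPM.

## Rhythmicity prior

The selector consumes an externally computed MetaCycle/meta2d-style
table (gene, Q, phase, period); phases are reduced mod 24 and binned
into six half-open 4-h intervals [4k, 4k+4) — half-open guarantees a
partition, so phase 4.0 is bin 1 and 24.0 is bin 0. Filtering is
strictly Q < 0.05. When only a raw time course exists, a cosinor
fallback fits x(t) = M + a·cos(ωt) + b·sin(ωt) per gene by least
squares, tests the harmonic pair with an F-test, adjusts across genes
by Benjamini–Hochberg, and reports amplitude √(a²+b²) and peak phase
atan2(b, a)/ω. On pure-noise data the fallback flags well under 5 % of
genes; on noiseless sinusoids it recovers phases to solver precision.

## Baselines

*Molecular timetable.* Per gene, a 24-h cosine is fitted to the
within-study z-normalised training course; genes whose cosine fit
reaches Pearson r ≥ 0.89 (the tuned threshold) become time-indicating
genes with a peak phase. A test sample's CT is the 1-min-grid argmin of
the summed squared deviation between the sample's per-gene z-scores and
the unit cosines at each candidate time (unweighted; the original
amplitude weighting is not restated in the sources this follows).
Because the z-normalisation runs across the *test study's* samples, a
single-sample study raises `WithinStudyNormalizationError` — a real
limitation of the method, not of the implementation. With only two
samples the z-scores collapse to ±1/√2, and the grid argmin is unbiased
only when the pair is ~12 h apart and the gene phases are dense; this
is why the method's own usage guidance demands two timepoints about
half a cycle apart.

*PLS ensemble.* `PLSCyclicRegressor` predicts the (s, c) encoding with
scikit-learn's PLSRegression, choosing the latent-factor count on
[1, 10] (capped by features and samples) by the same fivefold CV cost;
`PLSREnsemble` swaps this learner into the identical SFS/ensemble
machinery. No ordering between the neural and PLS ensembles is asserted
on synthetic data — the observed advantage of the nonlinear model on
real data is an observation, not an invariant.

## Cross-species remapping

An ortholog table maps focal-species genes to reference features. Focal
expression is collapsed first (arithmetic mean of TPM over the focal
orthologs of each reference feature — averaged, not summed, so totals
are conserved only under one-to-one maps), then z-scored independently.
Each member's feature set is intersected with the mappable features and
the member retrained on the original training data restricted to the
surviving features; sets shrinking below 3 genes drop their member with
a warning. Remapped sets are always subsets of the originals.

## Synthetic data

The generator emulates what the training corpus looks like: rhythmic
genes follow 24-h cosines with gene-specific phase (round-robin across
the six bins by default, uniform within bin), amplitude (uniform
1–4), and mesor (uniform 3–10); expression noise is Gaussian with sd =
0.3 × amplitude by default; each experiment adds per-gene batch offsets
(sd 0.4–0.6); light–dark experiments optionally damp the waveform by
0.7 during simulated darkness, creating the LL/LD waveform mismatch
seen between free-running and square-wave-entrained courses; background
genes carry mesor, batch and noise only; values are truncated at zero
(TPM is non-negative). The training-like layout is 4 experiments (2 LL
+ 2 LD), 14 timepoints each spaced 24/14 h so all 56 samples are
distinct on the circle and LL/LD counts balance at 28/28. Held-out
sets reuse the gene-truth seed with fresh noise/batch draws and shifted
sampling times. The generator does not model count noise
(negative-binomial reads), splicing, tissue mixtures, or
period ≠ 24 h; passing tests therefore demonstrate the machinery's
correctness and calibration under idealised sinusoidal rhythms, not
performance on real field data.

## Benchmark problem sizes

The reference experiments (`chronogauge.benchmarks`) run at desk scale:
a 10-member ensemble (SFS budget 60 evaluations, 3 tuning trials) on
the 56-sample training-like study, scoring 24 held-out samples against
a 50-permutation null; planted-feature recovery uses 6 sinusoids (one
per bin, noise sd 0.35 × amplitude) among 300 background genes whose
prior Q-values are deliberately drawn significant, a top-5-per-bin
shortlist, full universe (no bootstrap, so the check exercises the
selector rather than the subsample), and a 60-evaluation budget with a
full-batch evaluation network (lr 0.03, L2 1e−3, 600 epochs, best of 3
restarts); the null calibration uses 2000 pure-noise genes. The
100-member, 25-per-bin study scale runs through the same code path.

## Known limitations

- The two-timepoint period readout (`period_from_two_timepoints`) is a
  linear drift model on an idealised 24-h reference — the error
  accumulated over half a cycle is doubled per full cycle:
  period = 24 − (err₁₂ − err₀)/60 × 2. It reproduces near-24-h
  wild-type readings and reads delays as long periods, but it is a
  narrative approximation, not a period estimator.
- Fingerprint labels use strict inequalities; boundary errors count as
  accurate.
- Bonferroni family size in `compare_groups` is an explicit argument,
  never inferred from call counts.
- Correlations between estimated and true times are not computed on the
  wrapped scale anywhere in the package; error summaries are circular
  by construction.
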