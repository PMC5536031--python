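# Methods

## Model and assumptions

The predictor treats per-residue hotspot calling as binary
classification of windowed physicochemical-variance features.

**Feature model.** A residue's sequence profile SPᵢ (20 substitution
frequencies, non-negative, summing to 1) is combined with each
amino-acid property AAPⱼ by the elementwise product MSKᵢⱼ = SPᵢ × AAPⱼ;
the feature is the spread STDᵢⱼ of the 20 products. The modelling
assumption is that the *evolutionary variance of physicochemical
properties* — not the wild-type identity itself — carries the hotspot
signal: a position whose substitution spectrum concentrates property
mass differently from the background is informative regardless of which
letter occupies it. Consistent with this, property lookups go through
the profile only; non-standard residues (X, B, Z, U) need no special
casing beyond sequence-length bookkeeping.

The standard deviation uses the **population form (divisor 20)**: the 20
products are the complete outcome set, not a sample. The sample form
would scale every feature by the constant √(20/19), which is irrelevant
to nearest-neighbour geometry, but the choice is fixed for
reproducibility. Features are deliberately **not standardized** before
projection; k-NN operates on raw STD scales.

**Windows.** A sliding window of odd length `winLen` (default 13)
concatenates the J-vectors of the neighbours; out-of-sequence positions
contribute an all-zero J-block. Zero padding keeps the dimension
constant and marks missing context; mirroring or repeating flanks was
rejected because it invents evolutionary signal that is not there.

**Projection.** X_R = X R with Rᵤᵥ ~ Uniform[0, 1) i.i.d. and columns
scaled to unit Euclidean norm. The uniform, non-negative entries are
taken at face value and are *not* mean-centred; the columns therefore
share a large common direction, and projected squared-distance ratios
are noticeably more dispersed than for Gaussian projections (measured
coefficient of variation ≈ 1.0–1.3 at L1 = 1000, L2 = 50; the
regression test pins a generous bound of 2.0). This dispersion is part
of the design: diversity among projections is what the ensemble
averages over.

**Base learner and rebalancing.** Exact k-NN under Euclidean distance,
k = 1 by default (the simplest instance-based learner; laziness means
fitting is just storage). Because hotspots are <2% of residues, each
learner trains on a balanced undersample: every minority-class instance
is kept and an equal number of majority-class instances is drawn without
replacement. Undersampling avoids the duplicate coordinates that
oversampling would hand a distance-based classifier. Distance ties at
the k-th neighbour expand the vote set to all tied instances, making
predictions independent of storage order; vote ties go to the negative
class — the conservative call at this prevalence. The 1:1 target ratio
holds to ±1 instance by construction.

**Ensemble protocol.** For each of K seeded projections: project; hold
out a stratified ~1/n_folds inner validation split; rebalance the inner
training part; fit; score F1 on the *unbalanced* validation part.
Selection on a rebalanced validation set would inflate every candidate
by the same prevalence factor and blur the ranking, so the unbalanced
split is used. Candidates are ranked by validation F1 (ties broken by
projection seed, ascending) and the top N retained *as fitted* — no
refit on the full training set, so the reported member F1 describes
exactly the model that votes. An undefined validation F1 (no true or
predicted positives) ranks as 0. A residue is positive when at least
⌈N/2⌉ members vote positive: 2-of-3, and 1-of-2 for N = 2, reading
"half the classifiers" inclusively.

**Outer evaluation.** 10-fold cross-validation, stratified by label by
default (at 1.8% prevalence unstratified folds can lack positives
entirely; a positive-free fold is still evaluated, with a warning).
Fold assignment deals shuffled per-class indices round-robin, so fold
sizes differ by ≤1 overall and per-class counts by ≤1 per class.
Transfer mode (train corpus A, test corpus B) bypasses the outer loop.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_length` | 13 | sliding-window length, residues (odd) |
| `n_projections` K | 100 | candidate projections trained |
| `top_n` N | 3 | members retained for voting |
| `target_dim` L2 | 5 | reduced dimension |
| `k` | 1 | neighbours per base learner |
| `n_folds` | 10 | outer CV folds; inner validation share is 1/n_folds |
| `master_seed` | 0 | single integer reproducing the whole experiment |

One master seed drives everything: each consumer (projection *j*, inner
split *j*, resample *j*, fold assignment, synthetic corpus, baseline)
derives its own seed via `SeedSequence([master, role, index])`
(`hotspot_rp.seeds`), so a logged config re-runs bit-identically.

## Metrics

Sen = TP/(TP+FN), Prec = TP/(TP+FP), F1 = 2·Prec·Sen/(Prec+Sen),
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN)). A zero
denominator yields NaN — an explicit "undefined" marker — rather than a
silent 0, except MCC, which is 0 on a zero denominator (the standard
convention: the score of an uninformative predictor). The
random-predictor baseline labels each residue positive with a
configurable rate (0.983 reproduces the reference sensitivity) and
averages the *metrics* over runs, not the counts. For any
truth-independent predictor, expected precision equals prevalence and
expected MCC is 0; the simulation confirms both to within ±0.002 and
±0.01 at 1000 runs on a 54/2895 composition.

ROC-style curves can be built from ensemble vote fractions as scores;
the vote fraction is exposed per residue in the predictions table. This
is a natural extension of the voting rule rather than part of the core
protocol.

## Synthetic data: what it emulates and what it does not

`hotspot_rp.synthetic` generates seeded corpora shaped like a curated
whole-sequence hotspot benchmark: 20 chains of 80–220 residues (~3000
residues), hotspot prevalence 0.018, peaked Dirichlet profiles
(wild-type concentration 10, background 0.5 — PSSM-like rows), and a
64-index property panel of i.i.d. standard-normal values (synthetic
indices are exchangeable, so a 64-index panel is statistically
equivalent to a 544-index one for this generator; the count is
configurable).

The planted signal tilts Dirichlet concentration onto a fixed
hydrophobic subset (I/L/M/F/W) over a **triangularly decaying ±3-residue
patch** centred on each hotspot — full strength at the hotspot, zero
beyond the patch. Real hotspots sit inside binding patches whose
flanking residues share the evolutionary signature; that spatial
correlation is also precisely what a sliding-window encoding exploits
(it is why window 13 can outperform window 1). A point signal confined
to the hotspot residue would leave the other 12 window blocks pure
noise and make the window a handicap by construction. The tilt scales
linearly with `effect_size`: at 0 hotspot and background profiles are
identical in law; at the default 2.0 the full pipeline (K = 20, N = 3,
L2 = 5, winLen = 13) beats the random baseline in 10/10 test seeds
while the null corpus does not.

What the generator does **not** emulate: real amino-acid composition
biases, sequence-identity structure between chains, real AAindex
correlations (real indices are heavily clustered; synthetic ones are
independent), alignment-depth-dependent profile noise, or 3-D spatial
(as opposed to sequence-adjacent) interface patches. Passing tests on
synthetic corpora therefore demonstrate that the pipeline recovers a
profile-borne, window-correlated signal at realistic prevalence — not
that it attains any particular accuracy on real curated datasets.

## Numerical choices and degenerate inputs

- Profiles renormalize to sum 1 (tolerance 1e-9); all-zero PSSM rows
  become the uniform 1/20 background rather than a zero vector (zero
  rows otherwise produce zero-variance artifacts).
- AAindex1 records containing any missing (`NA`) cell are dropped, so J
  is a property of the input file; imputation was rejected as silent
  data invention. The two-row I-block concatenates to the canonical
  ARNDCQEGHILKMFPSTWYV order used everywhere.
- PSSM data rows must carry 40 numeric columns after position and
  wild type; the two trailing per-row statistics columns of real
  PSI-BLAST output are tolerated and ignored.
- Positions are 1-based in every file format and public type, 0-based
  internally.
- MCC is computed with exact integer arithmetic in the numerator and
  under the square root before a single float division.
- Degenerate requests fail loudly: single-class training data,
  even window lengths, k outside [1, n], target dimension above the
  source dimension, empty ensembles.

## Problem sizes used in the shipped checks

The shipped verification runs use desk-scale versions of the study
conditions, chosen as the package's own defaults: synthetic corpora of
~3000 residues with a 64-index panel, K = 20 candidates, and
1000-replicate baseline simulations. All are configurable upward
(K = 100, J = 544, L2 and window sweeps) through the same interfaces.

## Known limitations

- Exact k-NN is O(n·m) per prediction batch; no tree acceleration is
  attempted (the contract is exactness, and corpora at this scale do
  not need it).
- The ensemble stores dense projection matrices in memory; persistence
  is by (l1, l2, seed) descriptor only, and there is no model
  serialization — transfer mode retrains from features.
- Feature dumps are dense TSV, convenient and diffable but large
  (~35 MB for 3000 residues × 832 features).
- The random-projection columns are not mean-centred (faithful to the
  stated Uniform[0, 1) construction); users wanting tighter
  Johnson–Lindenstrauss concentration should centre features upstream.
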