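# Methods

## Model

m6A detection is cast as multiple instance learning: a candidate DRACH site
is a bag of reads, the bag label y_i (modified / unmodified) is observed,
the per-read status y_ij is not. Every read contributes a 15-dimensional
feature vector — z-scored event mean, event spread and dwell at the
centered fivemer and its two neighbours, plus a learned 2-d embedding of
each of the three fivemers. The read encoder F is a feed-forward network
(ReLU hidden layers of width 150 and 32, scalar sigmoid output) giving a
read probability p_ij; the site probability is the noisy-OR
P_i = 1 − ∏_j (1 − p_ij), computed as −expm1(Σ log1p(−p_ij)). Training
minimizes mean binary cross entropy between P_i and y_i; embedding and
encoder are learned jointly. The noisy-OR assumption — a site is modified
iff at least one molecule is — also propagates gradient through every read,
which is what makes the read probabilities meaningful at single-molecule
level despite the absence of read labels.

Assumptions worth stating: reads are conditionally independent given the
site; signal perturbation is local to the DRACH window (the default feature
window is the center ±1 fivemer; the flank width w is configurable, giving
input width 5·(2w+1)); direct-RNA reads are sense-strand by construction,
so no reverse-complement handling exists anywhere.

The activation function and initialisation are not dictated by the
formulation; we use ReLU and He initialisation. The output-layer bias is
initialised to logit(1 − 2^(−1/20)) ≈ −3.34 so that a 20-read bag pools to
P ≈ 0.5 at initialisation; a zero bias would start every site saturated at
P ≈ 1 − 2^(−20) and spend the first epochs escaping the clamp. Dropout and
weight decay default to 0 and are exposed in `TrainingConfig`.

The fivemer vocabulary is the exact enumeration of fivemers that can occur
at offsets −w..w of a DRACH center (66 entries at w = 1: 18 DRACH motifs,
24 upstream, 24 downstream); out-of-vocabulary lookups raise. The pooling
layer is fixed to noisy-OR in this implementation — gradients are derived
by hand, so alternative poolings (attention and gated attention are the
obvious candidates) would need their own backward pass; this is a known
extension point, not a configuration switch.

## Preprocessing

Input is a nanopolish-eventalign-style TSV (one row per segmented event).
Steps and the decisions behind them:

- **Event collapsing.** Multiple events mapping to the same
  (transcript, position, read) are collapsed to one observation; mean and
  spread are averaged with weights proportional to event dwell, and dwell
  is summed. Dwell is proportional to the number of raw current samples in
  the event, so this is the natural "group size" weighting; the choice is
  pinned by a split-invariance property test (subdividing an event changes
  nothing).
- **Mismatch filtering.** An observation is kept iff its basecalled model
  fivemer equals the reference fivemer in every constituent event. The
  comparison is reference vs basecall (not reference vs FASTA), since the
  FASTA is by definition consistent with the reference column.
- **Normalization.** Per-fivemer mean and sample standard deviation
  (ddof = 1, hence the two-observation minimum) of each feature are fitted
  across the dataset being processed; entries with fewer than two
  observations or zero variance are flagged unusable and sites touching
  them are skipped with a warning. A fitted table can be saved and reused
  so that samples compared against one model are scaled identically — the
  stoichiometry workflow below depends on this.
- **Coordinates and alphabet.** Positions are 0-based; eventalign reports a
  fivemer at the position of its first base, and stored site positions are
  re-indexed to the central base (a single +2 constant,
  `eventalign.CENTER_OFFSET`). U is canonicalized to T on input because
  eventalign emits the DNA alphabet. Duplicate observations at a position
  keep the first occurrence.
- **Bags.** A site enters the dataset when its center fivemer matches DRACH
  (optional), every read in the bag covers all 2w+1 window positions, and
  at least `min_reads` (default 20) such reads exist. Reads are ordered by
  read id, features upstream→downstream.

## Training protocol

Defaults follow the published protocol for this model family: 60 epochs of
Adam with the AMSGrad variant at a fixed learning rate of 4e-4, mini-batches
of 512 sites, 20 reads sampled per site per step (without replacement when
the bag has ≥ 20 reads, with replacement otherwise), and per-epoch
oversampling of the minority class with replacement to a 1:1 site-class
ratio (in the intended use the modified class is the minority; the
implementation balances whichever class is smaller). Model selection keeps
the epoch with the best validation criterion (ROC AUC by default; loss and
PR AUC are available), ties resolved toward the earlier epoch. The
validation read sample is drawn once before training so that epochs are
compared on identical inputs.

Randomness is organised as one master seed fanned out via
`numpy.random.SeedSequence.spawn` into independent initialisation,
read-sampling, shuffling and validation streams; identical configuration and
seed reproduce training and prediction bit-exactly (tested). Probabilities
are clamped to [1e-7, 1 − 1e-7] before logs.

At inference each site's probability is the mean of five noisy-OR poolings
of 20 sampled reads (sampling degenerates to the identity when the bag has
exactly 20 reads, and the mean short-circuits so the degenerate case is
bit-exact). Per-read probabilities are computed once, deterministically —
sampling affects only the site-level pooling. The penultimate-layer
activations (width 32) are exportable per read for downstream projection or
visualisation.

## Stoichiometry

A read is called modified when p_ij strictly exceeds a threshold τ chosen
by maximizing Youden's J = TPR − FPR over the observed read scores (ties go
to the smaller threshold; a near-zero best J is logged as uninformative).
τ is calibrated on labelled validation reads at training time and stored in
the checkpoint, so inference needs no labels. The per-site modification
rate is the fraction of called reads; with matched wild-type and
writer-knockout samples the relative methylation rate
(rate − rate_KO)/(rate_WT − rate_KO) maps it onto the 0–1 design scale,
unclipped, with sites of identical WT and KO rates excluded. Candidate
sites for cross-condition analysis default to P > 0.9 in WT and P < 0.2 in
KO; both thresholds are parameters (a relaxed 0.7/0.4 pair is a reasonable
alternative when coverage is low).

## Synthetic data generator

The generator emulates what preprocessing sees, not pore physics. Each
fivemer gets a Gaussian baseline for event mean (level uniform in
80–130 pA, read-to-read noise 2–4 pA) and spread (1–3 pA, noise 0.2–0.5)
and a log-normal dwell (median 5–20 ms) — the ranges segmented direct-RNA
events occupy. A modified read's features at the affected window offsets
(default: the center fivemer only) are shifted by δ in units of the
baseline noise sd; the default δ = (4, 0, 0) shifts only the event mean and
makes reads clearly separable, mirroring strongly perturbed motifs.
Transcripts are built from an A-free filler alphabet with DRACH motifs
planted at known centers, so the candidate-site set equals the truth table
exactly. Per-site stoichiometry is fixed or Beta-distributed; read labels
are independent Bernoulli draws. Observations are split into 1–3 events
sharing the observation's statistics and partitioning its dwell, which
exercises the collapse step; basecall mismatches are injected at a
configurable rate with the corrupted rows recorded.

Random draws are organised into five independent streams (sequences,
baselines, site assignment, read labels, signal noise), so two datasets
with the same seed and layout share sequences, baselines and noise
regardless of stoichiometry settings — that is what makes clean
wild-type/knockout pools for mixing. `mix_reads` blends two pools site by
site at a fixed modified-read fraction without replacement, as in
in-vitro-transcribed control designs.

What the generator does *not* emulate: heavy-tailed or multimodal signal
distributions, position-dependent coverage, truncated reads, alignment
errors beyond the mismatch flag, or perturbation spreading over
neighbouring fivemers (unless `affected_offsets` says so). Passing tests on
this data show the estimator and training machinery recover planted
structure; they do not certify accuracy on real signal, where effect sizes
vary by motif and labels are noisy.

A per-read log likelihood-ratio oracle built from the generator's own
baselines provides the Bayes-optimal read score and anchors the
separability checks (AUC → 0.5 as δ → 0, > 0.99 at δ = 4 sd).

## Problem sizes

The test suite and the acceptance script run entirely on generated data.
The MIL-recovery study uses 300 sites (100 transcripts × 3) at coverage 30,
δ = 4 sd, stoichiometry 0.5, a 75/25 gene-level split and the full
60-epoch protocol; read-level ROC AUC against hidden read labels is ≥ 0.9
there. At this dataset size the 512-site mini-batch cap would make every
epoch a single full-batch step — a different optimization regime from the
protocol's stochastic mini-batching over large data — so the study runs use
32-site mini-batches (about seven steps per epoch); the 512 default is
untouched. Stoichiometry recovery mixes 90-site wild-type/knockout pools
(coverage 50) at 0/25/50/75/100% modified-read fractions, 40 reads per
site, normalized with the training-time table; the median relative
methylation rate across valid sites tracks the design ratio within ±0.1 at
every level. Smaller configurations (around 120–180 sites, 10–40 epochs)
back the unit tests. With one batch per epoch at these sizes, training is
seconds, not minutes.

## Known limitations

- The mismatch filter assumes whole observations are corrupted or clean;
  partially corrupted event groups are dropped wholesale.
- Normalization entries for fivemers absent from the fitted table cause
  observations (and occasionally whole sites) to be skipped rather than
  imputed.
- The noisy-OR pooling is not swappable without writing its gradient.
- Read ids must be unique within a dataset; `mix_reads` prefixes pool
  labels to enforce this across pools.
- The generator's per-site Bernoulli labelling means realized stoichiometry
  fluctuates binomially around the design value at low coverage.
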