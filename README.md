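# nanomil

Detection of m6A RNA modifications from nanopore direct-RNA sequencing
signal, using a multiple-instance-learning (MIL) neural network with
noisy-OR pooling — with read-level modification probabilities and per-site
stoichiometry estimates learned from **site-level labels only**.

## The problem

N6-methyladenosine (m6A) is the most common internal mRNA modification; it
occurs at the central A of DRACH motifs (D = A/G/U, R = A/G, H = A/C/U).
Nanopore direct RNA sequencing reads native molecules, and the modification
perturbs the measured current, so m6A is in principle detectable from
segmented signal features (event mean, spread, dwell time per transcript
position per read). The catch is that experimental labels (e.g. from
antibody-based protocols) exist only per *site*, while any site carries a
mixture of modified and unmodified molecules — a classic multiple instance
learning problem: bags (sites) are labelled, instances (reads) are not.

## The model

Each candidate DRACH site *i* with reads *j = 1..N_i* is a bag. A read is
described by z-scored signal features (mean μ, spread σ, dwell *l*) at the
centered fivemer and its ±1 neighbours, plus a learned 2-dimensional
embedding *f(S)* of each of the three fivemers (vocabulary size 66, the
exact enumeration of fivemers that can appear in a DRACH-centered window):

    x_ij = (μ_{i-1,j}, μ_{i,j}, μ_{i+1,j},
            σ_{i-1,j}, σ_{i,j}, σ_{i+1,j},
            l_{i-1,j}, l_{i,j}, l_{i+1,j},
            f(S_{i-1}), f(S_i), f(S_{i+1}))          ∈ R^15

A feed-forward encoder F (hidden widths 150 and 32, ReLU, sigmoid output)
maps x_ij to a read-level modification probability p_ij = F(x_ij), and the
site probability pools the reads with a noisy-OR:

    P_i = 1 − ∏_j (1 − p_ij)

i.e. a site is modified if at least one of its reads is. Embedding and
encoder are trained end-to-end by minimizing binary cross entropy between
P_i and the site label y_i (Adam with AMSGrad, fixed learning rate 4e-4,
mini-batches of 512 sites, 20 reads sampled per site per step, modified
sites oversampled to class parity, 60 epochs, model selection on validation
ROC AUC). At test time site probabilities average five pooling runs of 20
sampled reads each; read probabilities are deterministic.

Because the noisy-OR gradient spreads credit across all reads of a bag, the
trained encoder yields calibrated *single-molecule* probabilities without
ever seeing a read label. A read threshold τ chosen by maximizing Youden's
J (TPR − FPR) on labelled reads turns these into a per-site modification
rate (fraction of reads with p_ij > τ), and matched wild-type/METTL3-KO
samples normalize it to a relative methylation rate
(rate − rate_KO)/(rate_WT − rate_KO).

The package also ships a synthetic eventalign-style data generator
(fivemer-conditional Gaussian signal baselines, configurable modified-read
shift and per-site stoichiometry, known read-level truth) so the entire
method is testable without any sequencing data.

## Worked example

```python
import nanomil as nm

# synthetic study: 180 DRACH sites, coverage 30, 4-sd signal shift on
# modified reads, 50% stoichiometry at modified sites
cfg = nm.GeneratorConfig(n_transcripts=60, sites_per_transcript=3,
                         coverage=30, delta=(4.0, 0.0, 0.0),
                         stoichiometry=0.5, seed=2)
sim = nm.simulate_dataset(cfg)

# preprocessing: collapse events, z-normalize per fivemer, build site bags
obs = nm.collapse_table(sim.events)
table = nm.fit_normalization(obs)
bags = nm.build_site_bags(nm.normalize_observations(obs, table), sim.sequences)

# gene-level split, then fit
train_sites, _ = nm.gene_level_split(sim.site_truth, (0.75, 0.25), seed=0)
keys = list(map(tuple, bags.index[["transcript_id", "position"]].itertuples(index=False)))
in_train = set(map(tuple, train_sites[["transcript_id", "position"]].itertuples(index=False)))
tr = [i for i, k in enumerate(keys) if k in in_train]
va = [i for i, k in enumerate(keys) if k not in in_train]
model = nm.MILSiteModel(bags.subset(tr), sim.site_truth,
                        bags.subset(va), sim.site_truth,
                        nm.TrainingConfig(epochs=25, seed=3))
results = model.fit()
print(results.summary())
```

```
MIL site classifier (noisy-OR pooling)
==============================================
feature window        : 3 fivemers (flank width 1)
input width           : 15
encoder hidden widths : 150, 32
embedding             : 66 fivemers -> R^2
trainable parameters  : 7397
best epoch            : 25 / 25
validation loss       : 0.4059
validation ROC AUC    : 0.9683
validation PR AUC     : 0.9779
```

The validation ROC AUC says held-out genes' modified sites are ranked above
unmodified ones almost perfectly at this effect size. Site and read
predictions:

```python
preds = results.predict(bags.subset(va), seed=0)
print(preds.site_frame().head(5).to_string(index=False))
```

```
transcript_id  transcript_position  n_reads  probability_modified    kmer
       tx0005                   22       30              0.264520 GAGACTT
       tx0005                   47       30              0.604624 TGGACAC
       tx0005                   72       30              0.385168 GTAACTC
       tx0007                   22       30              0.728354 CAGACCC
       tx0007                   47       30              0.801120 TTGACTC
```

`probability_modified` is the noisy-OR site probability (averaged over five
20-read pooling runs); `preds.read_frame()` holds the per-read
probabilities behind it, and `nm.site_modification_rates(...)` turns them
into stoichiometry estimates.

The same workflow is available from the shell:

```sh
nanomil simulate --out sim --seed 4 --n-transcripts 40
nanomil dataprep --eventalign sim/eventalign.tsv --fasta sim/transcripts.fa --out prep/bags
nanomil train --bags prep/bags --labels sim/site_truth.tsv \
              --read-labels sim/read_truth.tsv --out model/ckpt.npz --epochs 40
nanomil predict --model model/ckpt.npz --bags prep/bags --out preds
nanomil stoichiometry --reads preds/reads.tsv --model model/ckpt.npz --out rates.tsv
nanomil evaluate --sites preds/sites.tsv --labels sim/site_truth.tsv --out metrics.json
```

Every subcommand accepts `--config file.yaml` (flat key-value, same names
as the flags) and writes a `manifest.json` with the effective configuration
and input checksums.

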