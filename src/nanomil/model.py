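"""Model/Results objects for training and running the MIL site classifier.

:class:`MILSiteModel` is constructed from a training bag dataset with site
labels (plus a validation set for model selection); ``fit()`` runs the
training loop -- per-epoch minority oversampling to class parity, 20 reads
sampled per site per step, Adam with the AMSGrad variant -- and returns a
:class:`MILResults` carrying the selected parameters, the per-epoch history
and prediction/diagnostic methods.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network
from .bags import BagDataset
from .evaluate import roc_pr_metrics
from .vocabulary import FivemerVocabulary

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol knobs.

    Defaults follow the published protocol: 60 epochs of Adam(amsgrad) at a
    fixed learning rate of 4e-4, mini-batches of 512 sites with 20 reads
    sampled per site per step, modified (minority) sites oversampled to
    class parity each epoch, and the checkpoint chosen by validation
    ROC AUC.
    """

    epochs: int = 60
    learning_rate: float = 4e-4
    batch_sites: int = 512
    reads_per_site: int = 20
    criterion: str = "roc_auc"  # one of: loss, roc_auc, pr_auc
    hidden: tuple[int, int] = (150, 32)
    embedding_dim: int = 2
    dropout: float = 0.0
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.criterion not in ("loss", "roc_auc", "pr_auc"):
            raise ValueError(f"unknown selection criterion {self.criterion!r}")
        for name in ("epochs", "learning_rate", "batch_sites", "reads_per_site"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ModelParameters:
    """Learned weights plus the metadata needed to apply them safely."""

    weights: dict[str, np.ndarray]
    flank_width: int
    vocabulary: FivemerVocabulary
    hidden: tuple[int, int]
    embedding_dim: int = 2
    read_threshold: float | None = None
    norm_table_ref: str | None = None
    config_hash: str | None = None

    @property
    def input_width(self) -> int:
        k = 2 * self.flank_width + 1
        return 3 * k + self.embedding_dim * k

    def save(self, path) -> None:
        meta = {
            "checkpoint_version": CHECKPOINT_VERSION,
            "flank_width": self.flank_width,
            "vocabulary": list(self.vocabulary.fivemers),
            "hidden": list(self.hidden),
            "embedding_dim": self.embedding_dim,
            "read_threshold": self.read_threshold,
            "norm_table_ref": self.norm_table_ref,
            "config_hash": self.config_hash,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.weights)

    @classmethod
    def load(cls, path) -> "ModelParameters":
        arrs = np.load(path, allow_pickle=False)
        meta = json.loads(bytes(arrs["__meta__"]).decode())
        if meta["checkpoint_version"] != CHECKPOINT_VERSION:
            raise ValueError("unsupported checkpoint version")
        weights = {k: arrs[k] for k in arrs.files if k != "__meta__"}
        return cls(weights, meta["flank_width"],
                   FivemerVocabulary(meta["vocabulary"]),
                   tuple(meta["hidden"]), meta["embedding_dim"],
                   meta["read_threshold"], meta["norm_table_ref"],
                   meta["config_hash"])


@dataclass
class SitePrediction:
    """One site's pooled probability and the per-read probabilities under it."""

    transcript_id: str
    position: int
    kmer: str
    n_reads: int
    probability: float
    read_ids: np.ndarray
    read_probabilities: np.ndarray
    run_probabilities: np.ndarray


class SitePredictions:
    """Prediction set with site- and read-level table views."""

    def __init__(self, predictions: list[SitePrediction], skipped: int = 0):
        self.predictions = predictions
        self.skipped = skipped

    def __len__(self):
        return len(self.predictions)

    def __iter__(self):
        return iter(self.predictions)

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"transcript_id": p.transcript_id,
              "transcript_position": p.position, "n_reads": p.n_reads,
              "probability_modified": p.probability, "kmer": p.kmer}
             for p in self.predictions])

    def read_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.predictions:
            for rid, pr in zip(p.read_ids, p.read_probabilities):
                rows.append({"transcript_id": p.transcript_id,
                             "transcript_position": p.position,
                             "read_id": rid, "probability_modified": pr})
        return pd.DataFrame(rows)


def _check_compatible(params: ModelParameters, data: BagDataset) -> None:
    if data.flank_width != params.flank_width:
        raise ValueError(
            f"model was trained with flank width {params.flank_width} but the "
            f"bag dataset was built with {data.flank_width}")
    if data.vocabulary != params.vocabulary:
        raise ValueError("model and bag dataset use different vocabularies")


def _align_labels(data: BagDataset, labels: pd.DataFrame) -> np.ndarray:
    lab = labels.set_index(["transcript_id", "position"])["label"]
    keys = list(zip(data.index["transcript_id"], data.index["position"]))
    missing = [k for k in keys if k not in lab.index]
    if missing:
        raise ValueError(f"{len(missing)} bags have no site label "
                         f"(first: {missing[0]})")
    return lab.loc[keys].to_numpy(dtype=int)


def _sample_reads(rng: np.random.Generator, n_reads: int, k: int) -> np.ndarray:
    """k read indices: without replacement when the bag is large enough."""
    if n_reads >= k:
        return np.sort(rng.choice(n_reads, size=k, replace=False))
    return np.sort(rng.integers(0, n_reads, size=k))


class MILSiteModel:
    """MIL site classifier bound to training/validation bag datasets.

    Parameters
    ----------
    train_data, val_data : BagDataset
        Site bags from disjoint gene sets.
    train_labels, val_labels : DataFrame
        Site labels with columns transcript_id, position, label (0/1).
    config : TrainingConfig
    """

    def __init__(self, train_data: BagDataset, train_labels: pd.DataFrame,
                 val_data: BagDataset, val_labels: pd.DataFrame,
                 config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        self.train_data = train_data
        self.val_data = val_data
        self.y_train = _align_labels(train_data, train_labels)
        self.y_val = _align_labels(val_data, val_labels)
        if self.y_train.sum() == 0:
            raise ValueError("no modified sites in the training data")
        if val_data.n_sites == 0:
            raise ValueError("validation set is empty")
        if self.config.criterion != "loss" and len(np.unique(self.y_val)) < 2:
            raise ValueError("validation set has a single class; AUC model "
                             "selection is undefined")

    @classmethod
    def from_datasets(cls, data: BagDataset, labels: pd.DataFrame,
                      split: tuple[np.ndarray, np.ndarray],
                      config: TrainingConfig | None = None) -> "MILSiteModel":
        """Build from one dataset plus (train_idx, val_idx) site indices."""
        tr, va = split
        return cls(data.subset(tr), labels, data.subset(va), labels, config)

    # -- training ------------------------------------------------------------

    def _gather(self, data: BagDataset, site_idx: np.ndarray,
                rng: np.random.Generator):
        """Sample reads_per_site reads from each listed site into dense arrays."""
        R = self.config.reads_per_site
        B = len(site_idx)
        sig = np.empty((B, R, data.signals.shape[1]))
        kid = np.empty((B, R, data.kmer_idx.shape[1]), dtype=np.int32)
        for b, i in enumerate(site_idx):
            sl = data.reads_of(int(i))
            pick = _sample_reads(rng, sl.stop - sl.start, R) + sl.start
            sig[b] = data.signals[pick]
            kid[b] = data.kmer_idx[pick]
        return sig, kid

    def fit(self, verbose: bool = False) -> "MILResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        rng_init, rng_sample, rng_shuffle, rng_val = (
            np.random.default_rng(s) for s in ss.spawn(4))
        weights = network.init_weights(rng_init, len(self.train_data.vocabulary),
                                       self.train_data.flank_width, cfg.hidden,
                                       cfg.embedding_dim,
                                       init_bag_size=cfg.reads_per_site)
        opt = network.AdamState(weights, lr=cfg.learning_rate)

        # fixed validation read sample: comparable across epochs
        val_sig, val_kid = self._gather(self.val_data,
                                        np.arange(self.val_data.n_sites),
                                        rng_val)

        pos = np.flatnonzero(self.y_train == 1)
        neg = np.flatnonzero(self.y_train == 0)
        history, best = [], None
        sign = 1.0 if cfg.criterion == "loss" else -1.0  # minimise signed score
        for epoch in range(1, cfg.epochs + 1):
            # oversample the minority class with replacement to 1:1
            if len(pos) < len(neg):
                extra = rng_shuffle.choice(pos, size=len(neg), replace=True)
                epoch_idx = np.concatenate([neg, extra])
            elif len(neg) < len(pos):
                extra = rng_shuffle.choice(neg, size=len(pos), replace=True)
                epoch_idx = np.concatenate([pos, extra])
            else:
                epoch_idx = np.arange(len(self.y_train))
            rng_shuffle.shuffle(epoch_idx)

            losses = []
            for start in range(0, len(epoch_idx), cfg.batch_sites):
                batch = epoch_idx[start:start + cfg.batch_sites]
                sig, kid = self._gather(self.train_data, batch, rng_sample)
                loss, _, grads = network.bag_loss_and_grads(
                    weights, sig, kid, self.y_train[batch],
                    weight_decay=cfg.weight_decay)
                opt.step(weights, grads)
                losses.append(loss)

            p_val = network.read_probability(
                weights, val_sig.reshape(-1, val_sig.shape[2]),
                val_kid.reshape(-1, val_kid.shape[2]))
            P_val = -np.expm1(np.sum(np.log1p(-np.clip(
                p_val.reshape(val_sig.shape[0], -1), network.P_EPS,
                1 - network.P_EPS)), axis=1))
            val_loss = network.batch_objective(P_val, self.y_val)
            if len(np.unique(self.y_val)) == 2:
                roc, pr, _ = roc_pr_metrics(P_val, self.y_val)
            else:
                roc = pr = float("nan")
            row = {"epoch": epoch, "train_loss": float(np.mean(losses)),
                   "val_loss": val_loss, "val_roc_auc": roc, "val_pr_auc": pr}
            history.append(row)
            if verbose:
                logger.info("epoch %d: %s", epoch, row)
            score = sign * row[
                {"loss": "val_loss", "roc_auc": "val_roc_auc",
                 "pr_auc": "val_pr_auc"}[cfg.criterion]]
            if best is None or score < best[0]:
                best = (score, epoch, copy.deepcopy(weights))

        params = ModelParameters(
            weights=best[2], flank_width=self.train_data.flank_width,
            vocabulary=self.train_data.vocabulary, hidden=cfg.hidden,
            embedding_dim=cfg.embedding_dim,
            norm_table_ref=self.train_data.norm_table_ref,
            config_hash=cfg.hash)
        return MILResults(params, pd.DataFrame(history), best[1], self.config)


class MILResults:
    """Fitted MIL model: selected parameters, history, prediction methods."""

    def __init__(self, params: ModelParameters, history: pd.DataFrame,
                 best_epoch: int, config: TrainingConfig | None = None):
        self.params = params
        self.history = history
        self.best_epoch = best_epoch
        self.config = config

    # -- inference -----------------------------------------------------------

    def predict(self, data: BagDataset, n_runs: int = 5,
                reads_per_run: int = 20, seed: int = 0,
                min_reads: int = 20) -> SitePredictions:
        """Site and read probabilities for every bag with >= min_reads reads.

        Every read is scored once, deterministically; only the site-level
        noisy-OR pooling samples ``reads_per_run`` reads per run, and the
        reported site probability is the mean over ``n_runs`` runs.
        """
        _check_compatible(self.params, data)
        rng = np.random.default_rng(seed)
        p_all = network.read_probability(self.params.weights, data.signals,
                                         data.kmer_idx) if len(data.signals) \
            else np.empty(0)
        preds, skipped = [], 0
        for i, rec in enumerate(data.index.itertuples(index=False)):
            sl = data.reads_of(i)
            n = sl.stop - sl.start
            if n < min_reads:
                skipped += 1
                continue
            p_site = p_all[sl]
            runs = np.empty(n_runs)
            for r in range(n_runs):
                pick = _sample_reads(rng, n, reads_per_run)
                runs[r] = network.noisy_or_pool(p_site[pick])
            # degenerate sampling (bag size == reads per run) must be exact
            prob = float(runs[0]) if np.all(runs == runs[0]) \
                else float(runs.mean())
            preds.append(SitePrediction(
                rec.transcript_id, int(rec.position), rec.kmer, n,
                prob, data.read_ids[sl].copy(), p_site.copy(), runs))
        if skipped:
            logger.warning("skipped %d bags below min_reads=%d", skipped,
                           min_reads)
        return SitePredictions(preds, skipped)

    def predict_reads(self, data: BagDataset) -> pd.DataFrame:
        """Deterministic per-read probabilities for every read in the dataset."""
        _check_compatible(self.params, data)
        p = network.read_probability(self.params.weights, data.signals,
                                     data.kmer_idx)
        rows = np.repeat(np.arange(data.n_sites),
                         data.index["n_reads"].to_numpy())
        return pd.DataFrame({
            "transcript_id": data.index["transcript_id"].to_numpy()[rows],
            "transcript_position": data.index["position"].to_numpy()[rows],
            "read_id": data.read_ids,
            "probability_modified": p,
        })

    def read_representation(self, data: BagDataset) -> tuple[pd.DataFrame, np.ndarray]:
        """Penultimate-layer representation of every read.

        Returns (table, matrix): the table has one row per read with its
        probability; the matrix row width equals the last hidden width.
        """
        _check_compatible(self.params, data)
        p, h = network.read_probability(self.params.weights, data.signals,
                                        data.kmer_idx, return_hidden=True)
        table = self.predict_reads(data)
        return table, h

    def calibrate_read_threshold(self, read_probs, read_labels) -> float:
        """Select and store the read-level decision threshold (Youden's J)."""
        from .stoichiometry import select_read_threshold

        tau = select_read_threshold(read_probs, read_labels)
        self.params.read_threshold = tau
        return tau

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        p = self.params
        n_par = sum(v.size for v in p.weights.values())
        k = 2 * p.flank_width + 1
        lines = [
            "MIL site classifier (noisy-OR pooling)",
            "=" * 46,
            f"feature window        : {k} fivemers (flank width {p.flank_width})",
            f"input width           : {p.input_width}",
            f"encoder hidden widths : {p.hidden[0]}, {p.hidden[1]}",
            f"embedding             : {len(p.vocabulary)} fivemers -> "
            f"R^{p.embedding_dim}",
            f"trainable parameters  : {n_par}",
            f"best epoch            : {self.best_epoch} / {len(self.history)}",
        ]
        if not self.history.empty:
            row = self.history.set_index("epoch").loc[self.best_epoch]
            lines += [
                f"validation loss       : {row['val_loss']:.4f}",
                f"validation ROC AUC    : {row['val_roc_auc']:.4f}",
                f"validation PR AUC     : {row['val_pr_auc']:.4f}",
            ]
        if p.read_threshold is not None:
            lines.append(f"read threshold (J)    : {p.read_threshold:.4f}")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------------

    def save(self, path) -> None:
        self.params.save(path)
        hist_path = str(path) + ".history.tsv"
        self.history.assign(best_epoch=self.best_epoch).to_csv(
            hist_path, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "MILResults":
        params = ModelParameters.load(path)
        hist_path = str(path) + ".history.tsv"
        try:
            history = pd.read_csv(hist_path, sep="\t")
            best_epoch = int(history["best_epoch"].iloc[0])
            history = history.drop(columns=["best_epoch"])
        except FileNotFoundError:
            history, best_epoch = pd.DataFrame(), 0
        return cls(params, history, best_epoch)
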