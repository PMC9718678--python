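"""Site-bag container: the MIL dataset of candidate sites and their reads.

A bag is one candidate DRACH site on one transcript together with the
z-scored signal features of every read covering the full feature window.
The container keeps all reads of all bags in two dense arrays (signal values
and fivemer vocabulary indices) plus an index frame with one row per site;
this is the on-disk intermediate between signal preprocessing and the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocabulary import FivemerVocabulary

FORMAT_VERSION = 1

INDEX_COLUMNS = ["transcript_id", "position", "kmer", "n_reads", "offset"]


@dataclass
class BagDataset:
    """Dense store of per-site read feature bags.

    index : one row per site -- transcript_id, position (0-based transcript
        coordinate of the central A), kmer (7-mer sequence context),
        n_reads, offset (row offset of the site's first read in the arrays).
    signals : (total_reads, 3*(2w+1)) float64, ordered (means, sds, dwells),
        each block upstream to downstream.
    kmer_idx : (total_reads, 2w+1) int32 vocabulary indices.
    read_ids : (total_reads,) read identifiers.
    """

    index: pd.DataFrame
    signals: np.ndarray
    kmer_idx: np.ndarray
    read_ids: np.ndarray
    flank_width: int
    vocabulary: FivemerVocabulary
    norm_table_ref: str | None = None
    _offsets: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.index = self.index.reset_index(drop=True)
        self._offsets = self.index["offset"].to_numpy()
        if len(self.index) and np.any(self.kmer_idx >= len(self.vocabulary)):
            raise ValueError("kmer index outside vocabulary")

    @property
    def n_sites(self) -> int:
        return len(self.index)

    @property
    def signal_width(self) -> int:
        return 3 * (2 * self.flank_width + 1)

    def reads_of(self, i: int) -> slice:
        start = int(self._offsets[i])
        return slice(start, start + int(self.index["n_reads"].iloc[i]))

    def site_keys(self) -> pd.DataFrame:
        return self.index[["transcript_id", "position"]].copy()

    def subset(self, site_indices) -> "BagDataset":
        """New dataset holding only the given sites (order preserved)."""
        site_indices = np.asarray(site_indices, dtype=int)
        rows, new_idx, off = [], [], 0
        for i in site_indices:
            sl = self.reads_of(int(i))
            rows.append(sl)
            rec = self.index.iloc[int(i)].copy()
            rec["offset"] = off
            off += int(rec["n_reads"])
            new_idx.append(rec)
        if rows:
            signals = np.concatenate([self.signals[s] for s in rows])
            kmer = np.concatenate([self.kmer_idx[s] for s in rows])
            rids = np.concatenate([self.read_ids[s] for s in rows])
            idx = pd.DataFrame(new_idx)
        else:
            signals = np.empty((0, self.signal_width))
            kmer = np.empty((0, 2 * self.flank_width + 1), dtype=np.int32)
            rids = np.empty((0,), dtype=object)
            idx = pd.DataFrame(columns=INDEX_COLUMNS)
        return BagDataset(idx, signals, kmer, rids, self.flank_width,
                          self.vocabulary, self.norm_table_ref)

    # -- persistence --------------------------------------------------------

    def save(self, prefix) -> None:
        """Write ``<prefix>.index.tsv``, ``<prefix>.features.npz`` and
        ``<prefix>.meta.json``."""
        prefix = str(prefix)
        self.index.to_csv(prefix + ".index.tsv", sep="\t", index=False)
        np.savez(prefix + ".features.npz",
                 signals=self.signals,
                 kmer_idx=self.kmer_idx,
                 read_ids=np.asarray(self.read_ids, dtype=str))
        meta = {
            "format_version": FORMAT_VERSION,
            "flank_width": self.flank_width,
            "vocabulary": list(self.vocabulary.fivemers),
            "norm_table_ref": self.norm_table_ref,
            "n_sites": self.n_sites,
            "n_reads_total": int(self.signals.shape[0]),
        }
        with open(prefix + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "BagDataset":
        prefix = str(prefix)
        with open(prefix + ".meta.json") as fh:
            meta = json.load(fh)
        if meta["format_version"] != FORMAT_VERSION:
            raise ValueError(f"unsupported bag-dataset format version "
                             f"{meta['format_version']}")
        index = pd.read_csv(prefix + ".index.tsv", sep="\t")
        if index.empty:
            index = pd.DataFrame(columns=INDEX_COLUMNS)
        arrs = np.load(prefix + ".features.npz", allow_pickle=False)
        return cls(index, arrs["signals"], arrs["kmer_idx"].astype(np.int32),
                   arrs["read_ids"].astype(object), meta["flank_width"],
                   FivemerVocabulary(meta["vocabulary"]), meta["norm_table_ref"])
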