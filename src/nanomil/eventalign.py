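"""Signal-feature preprocessing: eventalign tables -> normalized site bags.

The raw input is a nanopolish-eventalign style TSV with one row per
segmented signal event (transcript, 0-based position of the fivemer's first
base, reference fivemer, read, event mean / spread / dwell, basecall-model
fivemer).  Preprocessing proceeds in four steps:

1. parse and canonicalize (U -> T; drop rows whose model fivemer is the
   all-N sentinel),
2. collapse multiple events of the same (transcript, position, read) into a
   single observation by dwell-weighted averaging, dropping groups whose
   basecall fivemer mismatches the reference,
3. z-normalize each signal feature against per-fivemer statistics fitted
   across the whole dataset,
4. assemble per-site read bags around DRACH centers.

Positions are re-indexed so that a stored site position refers to the
central A of the DRACH motif: eventalign reports the fivemer's first base,
and the central base sits two bases downstream (offset +2).  Direct-RNA
reads are sense-strand by construction, so no reverse-complement handling
is performed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .bags import BagDataset
from .vocabulary import BASES, FivemerVocabulary, is_drach, window_vocabulary

logger = logging.getLogger(__name__)

#: offset from a fivemer's first base (the eventalign coordinate) to its
#: central base, where the modification sits
CENTER_OFFSET = 2

UNKNOWN_KMER = "NNNNN"

DRACH_RE = re.compile("[AGT][AG]AC[ACT]")

_NUMERIC_COLUMNS = ("position", "event_level_mean", "event_stdv", "event_length")


class EventalignFormatError(ValueError):
    """The input table does not look like eventalign output."""


class DataInconsistencyError(ValueError):
    """Rows that must agree (e.g. the reference fivemer of one event group) do not."""


class NormalizationError(ValueError):
    """A fivemer's normalization entry is missing or unusable."""


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class EventRecord:
    """One segmented signal event mapped to a transcript position for one read."""

    transcript_id: str
    position: int
    reference_fivemer: str
    read_id: str
    event_mean: float
    event_sd: float
    event_dwell: float
    model_fivemer: str

    def __post_init__(self):
        if self.event_dwell <= 0:
            raise ValueError("event dwell must be > 0")
        if self.event_sd < 0:
            raise ValueError("event sd must be >= 0")
        if len(self.reference_fivemer) != 5:
            raise ValueError("reference fivemer must have length 5")


@dataclass(frozen=True)
class ReadObservation:
    """Collapsed per-read, per-position signal triple plus fivemer identity.

    Values are raw picoamperes/seconds before normalization and z-scores
    after.
    """

    transcript_id: str
    position: int
    fivemer: str
    read_id: str
    mean: float
    sd: float
    dwell: float


def _canon(kmer: str) -> str:
    return kmer.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# parsing


REQUIRED_COLUMNS = ["contig", "position", "reference_kmer",
                    "event_level_mean", "event_stdv", "event_length", "model_kmer"]


def load_eventalign(path_or_buffer) -> pd.DataFrame:
    """Read an eventalign TSV into a canonical event frame.

    Returns columns transcript_id, position, reference_kmer, read_id,
    event_level_mean, event_stdv, event_length, model_kmer.  Rows whose
    model fivemer is the all-N sentinel are dropped and U is canonicalized
    to T.  Raises :class:`EventalignFormatError` for missing columns and a
    row-numbered error for unparseable numeric fields.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise EventalignFormatError(f"missing required column {col!r}")
    if "read_name" in df.columns:
        read_col = "read_name"
    elif "read_index" in df.columns:
        read_col = "read_index"
    else:
        raise EventalignFormatError(
            "missing required column 'read_index' (or 'read_name')")
    for col in _NUMERIC_COLUMNS:
        src = df["position"] if col == "position" else df[col]
        converted = pd.to_numeric(src, errors="coerce")
        bad = converted.isna() & src.notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        elif src.isna().any():
            line = int(np.flatnonzero(src.isna().to_numpy())[0]) + 2
        else:
            df[col] = converted
            continue
        raise EventalignFormatError(
            f"unparseable value in column {col!r} at line {line}")
    out = pd.DataFrame({
        "transcript_id": df["contig"].astype(str),
        "position": df["position"].astype(int),
        "reference_kmer": df["reference_kmer"].map(_canon),
        "read_id": df[read_col].astype(str),
        "event_level_mean": df["event_level_mean"].astype(float),
        "event_stdv": df["event_stdv"].astype(float),
        "event_length": df["event_length"].astype(float),
        "model_kmer": df["model_kmer"].map(_canon),
    })
    return out[out["model_kmer"] != UNKNOWN_KMER].reset_index(drop=True)


def parse_eventalign(path_or_buffer) -> Iterator[EventRecord]:
    """Yield :class:`EventRecord` in file order (sentinel rows dropped)."""
    df = load_eventalign(path_or_buffer)
    for row in df.itertuples(index=False):
        yield EventRecord(row.transcript_id, int(row.position),
                          row.reference_kmer, row.read_id,
                          float(row.event_level_mean), float(row.event_stdv),
                          float(row.event_length), row.model_kmer)


# ---------------------------------------------------------------------------
# event collapsing


def collapse_events(records: Iterable[EventRecord]) -> ReadObservation:
    """Collapse all events of one (transcript, position, read) into one
    observation.

    Mean and spread are averaged with weights proportional to each event's
    dwell (a proxy for the number of raw samples in the event); dwell is the
    sum of event dwells.
    """
    records = list(records)
    if not records:
        raise ValueError("collapse_events needs at least one record")
    first = records[0]
    for r in records[1:]:
        if (r.transcript_id, r.position, r.read_id) != (
                first.transcript_id, first.position, first.read_id):
            raise DataInconsistencyError(
                "records span multiple (transcript, position, read) groups")
        if r.reference_fivemer != first.reference_fivemer:
            raise DataInconsistencyError(
                f"conflicting reference fivemers {first.reference_fivemer!r} "
                f"vs {r.reference_fivemer!r} at {first.transcript_id}:"
                f"{first.position}")
    dwell = np.array([r.event_dwell for r in records])
    w = dwell / dwell.sum()
    mean = float(np.dot(w, [r.event_mean for r in records]))
    sd = float(np.dot(w, [r.event_sd for r in records]))
    return ReadObservation(first.transcript_id, first.position,
                           first.reference_fivemer, first.read_id,
                           mean, sd, float(dwell.sum()))


def filter_mismatches(reference_fivemer: str, model_fivemer: str) -> bool:
    """Keep an observation iff the basecalled fivemer matches the reference."""
    return _canon(reference_fivemer) == _canon(model_fivemer)


def collapse_table(events: pd.DataFrame, keep_duplicates: str = "first") -> pd.DataFrame:
    """Vectorised collapse of an event frame into one row per
    (transcript, position, read).

    Groups whose basecalled fivemer mismatches the reference in any event are
    discarded (mismatch filtering); groups with conflicting reference
    fivemers raise :class:`DataInconsistencyError`.
    """
    if events.empty:
        return pd.DataFrame(columns=["transcript_id", "position", "fivemer",
                                     "read_id", "mean", "sd", "dwell"])
    renames = {"contig": "transcript_id", "read_index": "read_id",
               "read_name": "read_id"}
    events = events.rename(columns={k: v for k, v in renames.items()
                                    if k in events.columns and v not in events.columns})
    keys = ["transcript_id", "position", "read_id"]
    nref = events.groupby(keys, sort=False)["reference_kmer"].nunique()
    if (nref > 1).any():
        t, p, r = nref[nref > 1].index[0]
        raise DataInconsistencyError(
            f"conflicting reference fivemers at {t}:{p} read {r}")
    df = events.copy()
    df["match"] = df["reference_kmer"] == df["model_kmer"]
    df["wm"] = df["event_level_mean"] * df["event_length"]
    df["ws"] = df["event_stdv"] * df["event_length"]
    g = df.groupby(keys, sort=True)
    out = g.agg(fivemer=("reference_kmer", "first"),
                wm=("wm", "sum"), ws=("ws", "sum"),
                dwell=("event_length", "sum"),
                all_match=("match", "all")).reset_index()
    n_mismatch = int((~out["all_match"]).sum())
    if n_mismatch:
        logger.warning("dropping %d observations with mismatched fivemers",
                       n_mismatch)
    out = out[out["all_match"]].copy()
    out["mean"] = out["wm"] / out["dwell"]
    out["sd"] = out["ws"] / out["dwell"]
    return out[["transcript_id", "position", "fivemer", "read_id",
                "mean", "sd", "dwell"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-fivemer normalization


FEATURES = ("mean", "sd", "dwell")


class NormalizationTable:
    """Per-fivemer mean/sd of each signal feature, used for z-scoring.

    Entries fitted from fewer than two observations, or with zero variance
    in any feature, are flagged unusable; sites touching them are skipped.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table  # index: fivemer; columns: f_mu, f_sigma, n, usable

    @classmethod
    def fit(cls, observations: pd.DataFrame) -> "NormalizationTable":
        g = observations.groupby("fivemer")
        tab = pd.DataFrame({"n": g.size()})
        for f in FEATURES:
            tab[f"{f}_mu"] = g[f].mean()
            tab[f"{f}_sigma"] = g[f].std(ddof=1)
        sigma_cols = [f"{f}_sigma" for f in FEATURES]
        tab["usable"] = (tab["n"] >= 2) & (tab[sigma_cols] > 0).all(axis=1)
        tab[sigma_cols] = tab[sigma_cols].fillna(0.0)
        n_bad = int((~tab["usable"]).sum())
        if n_bad:
            logger.warning("%d fivemer entries unusable (n < 2 or zero variance)",
                           n_bad)
        return cls(tab)

    def entry(self, fivemer: str) -> pd.Series:
        if fivemer not in self.table.index:
            raise NormalizationError(f"no normalization entry for {fivemer!r}")
        row = self.table.loc[fivemer]
        if not row["usable"]:
            raise NormalizationError(
                f"normalization entry for {fivemer!r} is unusable")
        return row

    @property
    def usable_fivemers(self) -> set[str]:
        return set(self.table.index[self.table["usable"]])

    def save(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="fivemer")

    @classmethod
    def load(cls, path) -> "NormalizationTable":
        tab = pd.read_csv(path, sep="\t", index_col="fivemer")
        tab["usable"] = tab["usable"].astype(bool)
        return cls(tab)


def fit_normalization(observations: pd.DataFrame) -> NormalizationTable:
    """Fit per-fivemer feature statistics on collapsed observations."""
    return NormalizationTable.fit(observations)


def znormalize(obs: ReadObservation, table: NormalizationTable) -> ReadObservation:
    """Z-score one observation against its fivemer's statistics."""
    e = table.entry(obs.fivemer)
    return ReadObservation(
        obs.transcript_id, obs.position, obs.fivemer, obs.read_id,
        (obs.mean - e["mean_mu"]) / e["mean_sigma"],
        (obs.sd - e["sd_mu"]) / e["sd_sigma"],
        (obs.dwell - e["dwell_mu"]) / e["dwell_sigma"],
    )


def normalize_observations(observations: pd.DataFrame,
                           table: NormalizationTable) -> pd.DataFrame:
    """Vectorised z-scoring; observations at unusable fivemers are dropped
    with a warning."""
    usable = observations["fivemer"].isin(table.usable_fivemers)
    if (~usable).any():
        logger.warning("dropping %d observations at fivemers without a usable "
                       "normalization entry", int((~usable).sum()))
    df = observations[usable].copy()
    joined = df.join(table.table, on="fivemer")
    for f in FEATURES:
        df[f] = (df[f] - joined[f"{f}_mu"]) / joined[f"{f}_sigma"]
    return df


# ---------------------------------------------------------------------------
# bag assembly


def build_site_bags(
    observations: pd.DataFrame,
    sequences: Mapping[str, str],
    flank_width: int = 1,
    min_reads: int = 20,
    drach_only: bool = True,
    vocabulary: FivemerVocabulary | None = None,
) -> BagDataset:
    """Assemble per-site read bags from normalized observations.

    A bag is emitted for each (transcript, center) where the center fivemer
    matches DRACH (when ``drach_only``), every read in the bag has
    observations at all ``2w+1`` window positions, and at least ``min_reads``
    such reads exist.  Centers whose window leaves the transcript are
    skipped.  Reads within a bag are ordered by read id; features are
    ordered upstream to downstream.
    """
    w = flank_width
    k = 2 * w + 1
    if vocabulary is None:
        if drach_only:
            vocabulary = window_vocabulary(w)
        else:
            vocabulary = FivemerVocabulary(sorted(observations["fivemer"].unique()))
    rows, sig_parts, kid_parts, rid_parts = [], [], [], []
    offset = 0
    for transcript_id, tdf in observations.groupby("transcript_id", sort=True):
        seq = sequences.get(str(transcript_id))
        if seq is None:
            logger.warning("transcript %s missing from FASTA; skipped",
                           transcript_id)
            continue
        seq = _canon(seq)
        piv = {f: tdf.pivot_table(index="read_id", columns="position",
                                  values=f, aggfunc="first")
               for f in FEATURES}
        have = set(piv["mean"].columns)
        if drach_only:
            centers = [m.start() + CENTER_OFFSET
                       for m in re.finditer("(?=([AGT][AG]AC[ACT]))", seq)]
        else:
            centers = [p + CENTER_OFFSET for p in sorted(have)]
        for c in centers:
            first = c - CENTER_OFFSET  # eventalign coordinate of center fivemer
            window = [first + d for d in range(-w, w + 1)]
            if window[0] < 0 or window[-1] + 5 > len(seq):
                logger.info("site %s:%d too close to transcript end; skipped",
                            transcript_id, c)
                continue
            if not all(p in have for p in window):
                continue
            kmers = [seq[p:p + 5] for p in window]
            try:
                kid = np.array([vocabulary.index(f) for f in kmers],
                               dtype=np.int32)
            except KeyError:
                logger.info("site %s:%d touches an out-of-vocabulary fivemer; "
                            "skipped", transcript_id, c)
                continue
            blocks = [piv[f][window] for f in FEATURES]
            complete = pd.concat(blocks, axis=1).notna().all(axis=1)
            read_ids = complete.index[complete].to_numpy()
            n = len(read_ids)
            if n < min_reads:
                continue
            sig = np.concatenate(
                [b.loc[read_ids].to_numpy(dtype=float) for b in blocks], axis=1)
            rows.append({"transcript_id": str(transcript_id), "position": c,
                         "kmer": seq[c - 3:c + 4], "n_reads": n,
                         "offset": offset})
            offset += n
            sig_parts.append(sig)
            kid_parts.append(np.tile(kid, (n, 1)))
            rid_parts.append(read_ids.astype(object))
    if rows:
        index = pd.DataFrame(rows)
        signals = np.concatenate(sig_parts)
        kmer_idx = np.concatenate(kid_parts)
        read_ids = np.concatenate(rid_parts)
    else:
        index = pd.DataFrame(columns=["transcript_id", "position", "kmer",
                                      "n_reads", "offset"])
        signals = np.empty((0, 3 * k))
        kmer_idx = np.empty((0, k), dtype=np.int32)
        read_ids = np.empty((0,), dtype=object)
    return BagDataset(index, signals, kmer_idx, read_ids, w, vocabulary)


# ---------------------------------------------------------------------------
# one-call pipeline


def prepare_bags(
    eventalign_path,
    sequences: Mapping[str, str],
    flank_width: int = 1,
    min_reads: int = 20,
    drach_only: bool = True,
    norm_table: NormalizationTable | None = None,
) -> tuple[BagDataset, NormalizationTable]:
    """Full preprocessing: parse, collapse, normalize, and bag.

    When ``norm_table`` is None the table is fitted on this dataset
    (per-sample normalization); passing a saved table reuses training-time
    statistics.
    """
    events = load_eventalign(eventalign_path)
    obs = collapse_table(events)
    if norm_table is None:
        norm_table = fit_normalization(obs)
    obs = normalize_observations(obs, norm_table)
    bags = build_site_bags(obs, sequences, flank_width=flank_width,
                           min_reads=min_reads, drach_only=drach_only)
    return bags, norm_table


def read_fasta(path) -> dict[str, str]:
    """Load transcript sequences (T-alphabet, uppercase) keyed by record id."""
    from Bio import SeqIO

    return {rec.id: _canon(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
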