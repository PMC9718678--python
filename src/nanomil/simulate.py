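"""Synthetic eventalign-style data with known per-read modification status.

The generator emulates the signal perturbation that m6A induces in nanopore
direct-RNA data: each fivemer has a Gaussian baseline for the event mean and
spread and a log-normal dwell, and a modified read's features at the site's
affected window positions are shifted by a configurable effect ``delta``
expressed in units of the baseline noise sd.  Per-site stoichiometry (the
fraction of modified molecules) is either fixed or Beta-distributed, and
reads are labelled by independent Bernoulli draws, mirroring the mixture
design of in-vitro-transcribed control experiments where fully modified and
unmodified read pools are blended at known ratios.

Transcripts are built from an A-free filler alphabet with DRACH motifs
planted at known centers, so the set of candidate sites is exactly the set
of planted sites and every bag count is checkable against the truth tables.
Each read/position observation is split into 1-3 events that share the
observation's mean and spread and partition its dwell, exercising the
dwell-weighted event collapsing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bags import BagDataset
from .eventalign import CENTER_OFFSET
from .vocabulary import drach_motifs

FILLER = np.array(list("CGT"))  # no A: cannot create an accidental DRACH center

EVENTALIGN_COLUMNS = ["contig", "position", "reference_kmer", "read_index",
                      "strand", "event_index", "event_level_mean",
                      "event_stdv", "event_length", "model_kmer"]


class PoolExhaustedError(ValueError):
    """A read mixture asked for more reads than a pool holds."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    delta is the additive shift, in units of each feature's baseline noise
    sd, applied to a modified read's (mean, sd, log-dwell) at the affected
    window offsets (eventalign positions ``center_fivemer_start + offset``).
    """

    n_transcripts: int = 10
    sites_per_transcript: int = 3
    gap: int = 20                       # filler bases between planted motifs
    coverage: int = 30
    stoichiometry: float | tuple = 0.5  # float, or ("beta", a, b)
    modified_fraction: float = 0.5      # fraction of planted sites modified
    delta: tuple[float, float, float] = (4.0, 0.0, 0.0)
    affected_offsets: tuple[int, ...] = (0,)
    mismatch_rate: float = 0.0
    events_per_obs: tuple[int, int] = (1, 3)
    seed: int = 0

    @property
    def transcript_length(self) -> int:
        k = self.sites_per_transcript
        return (k + 1) * self.gap + 5 * k


@dataclass
class SimulatedDataset:
    """Eventalign frame + FASTA + truth tables tied together by one config."""

    config: GeneratorConfig
    events: pd.DataFrame
    sequences: dict[str, str]
    site_truth: pd.DataFrame    # transcript_id, position, gene_id, stoichiometry, label
    read_truth: pd.DataFrame    # transcript_id, position, read_id, modified
    mismatch_truth: pd.DataFrame  # transcript_id, position, read_id
    fivemer_params: pd.DataFrame = field(repr=False)  # baseline distributions

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "eventalign": outdir / "eventalign.tsv",
            "fasta": outdir / "transcripts.fa",
            "site_truth": outdir / "site_truth.tsv",
            "read_truth": outdir / "read_truth.tsv",
            "mismatch_truth": outdir / "mismatch_truth.tsv",
        }
        self.events.to_csv(paths["eventalign"], sep="\t", index=False,
                           float_format="%.8g")
        with open(paths["fasta"], "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n{self.sequences[name]}\n")
        self.site_truth.to_csv(paths["site_truth"], sep="\t", index=False,
                               float_format="%.8g")
        self.read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
        self.mismatch_truth.to_csv(paths["mismatch_truth"], sep="\t", index=False)
        return paths


def _draw_fivemer_params(fivemers: Sequence[str], rng: np.random.Generator) -> pd.DataFrame:
    """Baseline feature distributions per fivemer.

    Event means sit in the 80-130 pA band with 2-4 pA read-to-read noise;
    event spreads around 1-3 pA; dwells log-normal around 5-20 ms -- the
    ranges segmented direct-RNA events occupy.
    """
    n = len(fivemers)
    return pd.DataFrame({
        "mean_level": rng.uniform(80.0, 130.0, n),
        "mean_noise": rng.uniform(2.0, 4.0, n),
        "sd_level": rng.uniform(1.0, 3.0, n),
        "sd_noise": rng.uniform(0.2, 0.5, n),
        "log_dwell_mu": rng.uniform(np.log(0.005), np.log(0.02), n),
        "log_dwell_sd": rng.uniform(0.25, 0.45, n),
    }, index=pd.Index(fivemers, name="fivemer"))


def _sample_stoichiometry(cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    s = cfg.stoichiometry
    if isinstance(s, tuple):
        kind, a, b = s
        if kind != "beta":
            raise ValueError(f"unknown stoichiometry sampler {kind!r}")
        return float(rng.beta(a, b))
    s = float(s)
    if not 0.0 <= s <= 1.0:
        raise ValueError("stoichiometry must lie in [0, 1]")
    return s


def simulate_dataset(config: GeneratorConfig) -> SimulatedDataset:
    """Generate an eventalign table, transcript FASTA and truth tables.

    The seed in the config fully determines the output.
    """
    cfg = config
    if cfg.coverage < 1:
        raise ValueError("coverage must be >= 1")
    if cfg.gap < 6:
        raise ValueError("gap must be >= 6 to isolate planted motifs")
    # independent streams: datasets that share seed and layout also share
    # sequences, baselines and signal noise regardless of stoichiometry
    # settings, so pools generated for mixing are drawn from one distribution
    ss = np.random.SeedSequence(cfg.seed)
    rng_seq, rng_params, rng_site, rng_read, rng_signal = (
        np.random.default_rng(s) for s in ss.spawn(5))
    motifs = drach_motifs()

    # --- transcripts with planted DRACH centers
    sequences: dict[str, str] = {}
    site_rows = []
    centers: dict[str, list[int]] = {}
    for t in range(cfg.n_transcripts):
        name = f"tx{t:04d}"
        parts, pos, ctrs = [], 0, []
        for s in range(cfg.sites_per_transcript):
            filler = "".join(rng_seq.choice(FILLER, cfg.gap))
            motif = motifs[rng_seq.integers(len(motifs))]
            parts += [filler, motif]
            pos += cfg.gap
            ctrs.append(pos + CENTER_OFFSET)
            pos += 5
        parts.append("".join(rng_seq.choice(FILLER, cfg.gap)))
        sequences[name] = "".join(parts)
        centers[name] = ctrs

    # --- which sites are modified, and how much
    all_sites = [(t, c) for t in sorted(centers) for c in centers[t]]
    n_mod = int(round(cfg.modified_fraction * len(all_sites)))
    mod_idx = set(rng_site.choice(len(all_sites), size=n_mod, replace=False).tolist())
    stoich_by_site: dict[tuple[str, int], float] = {}
    for i, (t, c) in enumerate(all_sites):
        rho = _sample_stoichiometry(cfg, rng_site) if i in mod_idx else 0.0
        stoich_by_site[(t, c)] = rho
        site_rows.append({"transcript_id": t, "position": c, "gene_id": t,
                          "stoichiometry": rho, "label": int(rho > 0)})
    site_truth = pd.DataFrame(site_rows)

    # --- per-fivemer baselines over every fivemer occurring in the data
    observed = sorted({seq[p:p + 5]
                       for seq in sequences.values()
                       for p in range(len(seq) - 4)})
    params = _draw_fivemer_params(observed, rng_params)
    if (params[["mean_noise", "sd_noise", "log_dwell_sd"]] <= 0).any().any():
        raise ValueError("zero-variance baseline with nonzero coverage")

    d_mean, d_sd, d_dwell = cfg.delta
    ev_lo, ev_hi = cfg.events_per_obs

    event_frames, read_rows, mm_rows = [], [], []
    for t in sorted(sequences):
        seq = sequences[t]
        n_pos = len(seq) - 4
        positions = np.arange(n_pos)
        fiv = [seq[p:p + 5] for p in positions]
        par = params.loc[fiv]
        reads = np.array([f"{t}_r{j:04d}" for j in range(cfg.coverage)],
                         dtype=object)

        # per-read modification status at each site; shift mask per position
        shift = np.zeros((cfg.coverage, n_pos), dtype=bool)
        for c in centers[t]:
            rho = stoich_by_site[(t, c)]
            y = rng_read.random(cfg.coverage) < rho
            for j in np.flatnonzero(y):
                read_rows.append({"transcript_id": t, "position": c,
                                  "read_id": reads[j], "modified": 1})
            for j in np.flatnonzero(~y):
                read_rows.append({"transcript_id": t, "position": c,
                                  "read_id": reads[j], "modified": 0})
            for off in cfg.affected_offsets:
                p = c - CENTER_OFFSET + off
                if 0 <= p < n_pos:
                    shift[y, p] = True

        mean_lv = par["mean_level"].to_numpy()[None, :]
        mean_ns = par["mean_noise"].to_numpy()[None, :]
        sd_lv = par["sd_level"].to_numpy()[None, :]
        sd_ns = par["sd_noise"].to_numpy()[None, :]
        ld_mu = par["log_dwell_mu"].to_numpy()[None, :]
        ld_sd = par["log_dwell_sd"].to_numpy()[None, :]

        obs_mean = rng_signal.normal(mean_lv + shift * d_mean * mean_ns, mean_ns)
        obs_sd = np.abs(rng_signal.normal(sd_lv + shift * d_sd * sd_ns, sd_ns))
        obs_sd = np.maximum(obs_sd, 1e-3)
        obs_dwell = np.exp(rng_signal.normal(ld_mu + shift * d_dwell * ld_sd, ld_sd))

        # basecall mismatches: corrupt the model fivemer of whole observations
        ref_kmer = np.tile(np.array(fiv, dtype=object), (cfg.coverage, 1))
        model_kmer = ref_kmer.copy()
        if cfg.mismatch_rate > 0:
            mm = rng_signal.random((cfg.coverage, n_pos)) < cfg.mismatch_rate
            for j, p in zip(*np.nonzero(mm)):
                kmer = list(ref_kmer[j, p])
                b = int(rng_signal.integers(5))
                alt = [x for x in "ACGT" if x != kmer[b]]
                kmer[b] = alt[int(rng_signal.integers(3))]
                model_kmer[j, p] = "".join(kmer)
                mm_rows.append({"transcript_id": t, "position": int(p),
                                "read_id": reads[j]})

        # split each observation into 1-3 events sharing mean/sd,
        # partitioning the dwell
        n_ev = rng_signal.integers(ev_lo, ev_hi + 1, size=(cfg.coverage, n_pos))
        total = int(n_ev.sum())
        flat_nev = n_ev.ravel()
        obs_of_event = np.repeat(np.arange(flat_nev.size), flat_nev)
        frac = rng_signal.random(total)
        sums = np.add.reduceat(frac, np.concatenate([[0], np.cumsum(flat_nev)[:-1]]))
        frac = frac / np.repeat(sums, flat_nev)

        read_of_obs = np.repeat(np.arange(cfg.coverage), n_pos)
        pos_of_obs = np.tile(positions, cfg.coverage)
        ev_read = read_of_obs[obs_of_event]
        ev_pos = pos_of_obs[obs_of_event]
        event_frames.append(pd.DataFrame({
            "contig": t,
            "position": ev_pos,
            "reference_kmer": ref_kmer[ev_read, ev_pos],
            "read_index": reads[ev_read],
            "strand": "t",
            "event_index": np.arange(total),
            "event_level_mean": obs_mean[ev_read, ev_pos],
            "event_stdv": obs_sd[ev_read, ev_pos],
            "event_length": obs_dwell[ev_read, ev_pos] * frac,
            "model_kmer": model_kmer[ev_read, ev_pos],
        }))

    events = pd.concat(event_frames, ignore_index=True)[EVENTALIGN_COLUMNS]
    read_truth = pd.DataFrame(read_rows, columns=["transcript_id", "position",
                                                  "read_id", "modified"])
    mismatch_truth = pd.DataFrame(mm_rows, columns=["transcript_id", "position",
                                                    "read_id"])
    return SimulatedDataset(cfg, events, sequences, site_truth, read_truth,
                            mismatch_truth, params)


# ---------------------------------------------------------------------------
# read mixtures (IVT-style blending of a modified and an unmodified pool)


def mix_reads(
    modified: BagDataset,
    unmodified: BagDataset,
    ratio: float,
    seed: int,
    reads_per_site: int | None = None,
) -> tuple[BagDataset, pd.DataFrame]:
    """Blend two bag datasets site by site at a fixed modified-read ratio.

    For each (transcript, position) present in both pools, ``round(r * n)``
    reads are drawn without replacement from the modified pool and the rest
    from the unmodified pool (n = ``reads_per_site`` or the smaller pool
    size at that site).  Returns the mixed dataset plus an origin table
    (transcript_id, position, read_id, from_modified); read ids are prefixed
    ``mod:``/``unmod:`` so the two pools cannot collide.  Repeated calls with
    different seeds give independent mixings.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    if modified.flank_width != unmodified.flank_width:
        raise ValueError("pools have different flank widths")
    rng = np.random.default_rng(seed)
    key = ["transcript_id", "position"]
    mod_idx = {tuple(r): i for i, r in
               enumerate(modified.index[key].itertuples(index=False))}
    rows, sig, kid, rid, origin = [], [], [], [], []
    offset = 0
    for i_u, rec in enumerate(unmodified.index.itertuples(index=False)):
        k = (rec.transcript_id, rec.position)
        if k not in mod_idx:
            continue
        i_m = mod_idx[k]
        sl_m, sl_u = modified.reads_of(i_m), unmodified.reads_of(i_u)
        n_m_avail = sl_m.stop - sl_m.start
        n_u_avail = sl_u.stop - sl_u.start
        n = reads_per_site if reads_per_site is not None else min(n_m_avail,
                                                                  n_u_avail)
        take_m = int(round(ratio * n))
        take_u = n - take_m
        if take_m > n_m_avail or take_u > n_u_avail:
            raise PoolExhaustedError(
                f"site {k}: need {take_m} modified / {take_u} unmodified reads "
                f"but pools hold {n_m_avail} / {n_u_avail}")
        pick_m = np.sort(rng.choice(n_m_avail, size=take_m, replace=False))
        pick_u = np.sort(rng.choice(n_u_avail, size=take_u, replace=False))
        sig.append(np.concatenate([modified.signals[sl_m][pick_m],
                                   unmodified.signals[sl_u][pick_u]]))
        kid.append(np.concatenate([modified.kmer_idx[sl_m][pick_m],
                                   unmodified.kmer_idx[sl_u][pick_u]]))
        ids = np.concatenate(
            [np.array(["mod:" + r for r in modified.read_ids[sl_m][pick_m]],
                      dtype=object),
             np.array(["unmod:" + r for r in unmodified.read_ids[sl_u][pick_u]],
                      dtype=object)])
        rid.append(ids)
        for j, r in enumerate(ids):
            origin.append({"transcript_id": k[0], "position": k[1],
                           "read_id": r, "from_modified": int(j < take_m)})
        rows.append({"transcript_id": k[0], "position": k[1],
                     "kmer": rec.kmer, "n_reads": n, "offset": offset})
        offset += n
    if not rows:
        raise ValueError("pools share no sites")
    mixed = BagDataset(pd.DataFrame(rows), np.concatenate(sig),
                       np.concatenate(kid), np.concatenate(rid),
                       modified.flank_width, modified.vocabulary)
    return mixed, pd.DataFrame(origin)


# ---------------------------------------------------------------------------
# likelihood-ratio oracle


def likelihood_ratio_scores(sim: SimulatedDataset,
                            observations: pd.DataFrame) -> pd.DataFrame:
    """Per-read log likelihood ratio (modified vs unmodified) at each site.

    Uses the generator's own baseline distributions -- the Bayes-optimal
    read score on this data, used as an oracle for separability checks.
    ``observations`` is the raw (pre-normalization) collapsed frame.
    Returns transcript_id, position (center coordinate), read_id, score.
    """
    cfg = sim.config
    d_mean, d_sd, d_dwell = cfg.delta
    obs = observations.set_index(["transcript_id", "position", "read_id"])
    rows = []
    for site in sim.site_truth.itertuples(index=False):
        t, c = site.transcript_id, site.position
        seq = sim.sequences[t]
        for off in cfg.affected_offsets:
            p = c - CENTER_OFFSET + off
            if not 0 <= p <= len(seq) - 5:
                continue
            par = sim.fivemer_params.loc[seq[p:p + 5]]
            try:
                sub = obs.loc[(t, p)]
            except KeyError:
                continue
            z_mean = (sub["mean"] - par["mean_level"]) / par["mean_noise"]
            z_sd = (sub["sd"] - par["sd_level"]) / par["sd_noise"]
            z_dwell = (np.log(sub["dwell"]) - par["log_dwell_mu"]) / par["log_dwell_sd"]
            score = (d_mean * z_mean - d_mean ** 2 / 2
                     + d_sd * z_sd - d_sd ** 2 / 2
                     + d_dwell * z_dwell - d_dwell ** 2 / 2)
            for read_id, s in score.items():
                rows.append({"transcript_id": t, "position": c,
                             "read_id": read_id, "score": float(s)})
    out = pd.DataFrame(rows)
    return (out.groupby(["transcript_id", "position", "read_id"], sort=True)
               ["score"].sum().reset_index())
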