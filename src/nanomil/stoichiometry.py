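"""Read-threshold selection and modification-rate (stoichiometry) estimation.

A read is called modified when its read-level probability exceeds a
threshold chosen by maximizing Youden's J (TPR - FPR) on labelled reads;
the per-site modification rate is then the fraction of called reads, and
rates can be normalized against matched wild-type / writer-knockout samples
to a relative methylation rate on the 0-1 design scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def select_read_threshold(read_probs, read_labels) -> float:
    """Threshold maximizing TPR - FPR over the read-level ROC curve.

    Candidate thresholds are the observed score values (calls use strict
    ``>``); ties are broken toward the smaller threshold.  Logs a warning
    when the best J is ~0, i.e. the scores carry no information.
    """
    p = np.asarray(read_probs, dtype=float)
    y = np.asarray(read_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("threshold selection needs both read classes")
    n = len(p)
    n_pos = int(y.sum())
    n_neg = n - n_pos
    order = np.argsort(p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    uniq, first = np.unique(p_sorted, return_index=True)
    # scores strictly above uniq[k] form the suffix starting where the next
    # unique value begins
    suffix_start = np.append(first[1:], n)
    suffix_pos = np.append(np.cumsum(y_sorted[::-1])[::-1], 0)
    tp = suffix_pos[suffix_start]
    fp = (n - suffix_start) - tp
    j = tp / n_pos - fp / n_neg
    k = int(np.argmax(j))  # uniq ascending: argmax takes the smallest tie
    j_best, tau_best = float(j[k]), float(uniq[k])
    if j_best < 0.05:
        logger.warning("best Youden's J is %.3f; read scores are close to "
                       "uninformative", j_best)
    return tau_best


def modification_rate(read_probs, tau: float) -> float:
    """Fraction of a site's reads with probability strictly above tau."""
    p = np.asarray(read_probs, dtype=float)
    return float(np.mean(p > tau))


def site_modification_rates(read_table: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Per-site modification rates from a read-probability table.

    ``read_table`` columns: transcript_id, transcript_position, read_id,
    probability_modified.
    """
    g = read_table.groupby(["transcript_id", "transcript_position"], sort=True)
    out = g["probability_modified"].agg(
        n_reads="size", mod_rate=lambda s: float(np.mean(s > tau)))
    return out.reset_index()


def relative_methylation_rate(rate: float, ko_rate: float,
                              wt_rate: float) -> float:
    """(rate - KO rate) / (WT rate - KO rate); not clipped to [0, 1].

    Raises ZeroDivisionError when the wild-type and knockout rates coincide
    (callers exclude such sites with a log entry).
    """
    denom = wt_rate - ko_rate
    if denom == 0:
        raise ZeroDivisionError("WT and KO methylation rates coincide")
    return (rate - ko_rate) / denom


def relative_rates_table(rates: pd.DataFrame, ko_rates: pd.DataFrame,
                         wt_rates: pd.DataFrame) -> pd.DataFrame:
    """Join per-site rates with matched KO/WT rates and normalize.

    All frames need transcript_id, transcript_position, mod_rate.  Sites
    with identical WT and KO rates are excluded with a log entry.
    """
    key = ["transcript_id", "transcript_position"]
    df = (rates.merge(ko_rates[key + ["mod_rate"]].rename(
              columns={"mod_rate": "ko_rate"}), on=key)
               .merge(wt_rates[key + ["mod_rate"]].rename(
              columns={"mod_rate": "wt_rate"}), on=key))
    degenerate = df["wt_rate"] == df["ko_rate"]
    if degenerate.any():
        logger.info("excluding %d sites with WT rate == KO rate",
                    int(degenerate.sum()))
        df = df[~degenerate].copy()
    df["relative_rate"] = (df["mod_rate"] - df["ko_rate"]) / \
        (df["wt_rate"] - df["ko_rate"])
    return df


def select_candidate_sites(predictions_wt: pd.DataFrame,
                           predictions_ko: pd.DataFrame,
                           tau_hi: float = 0.9,
                           tau_lo: float = 0.2) -> pd.DataFrame:
    """Sites confidently modified in WT (P > tau_hi) and unmodified in KO
    (P < tau_lo).

    Both frames need transcript_id, transcript_position,
    probability_modified; only sites present in both are considered.  The
    relaxed pair (0.7, 0.4) is available through the parameters.
    """
    key = ["transcript_id", "transcript_position"]
    merged = predictions_wt[key + ["probability_modified"]].rename(
        columns={"probability_modified": "p_wt"}).merge(
        predictions_ko[key + ["probability_modified"]].rename(
            columns={"probability_modified": "p_ko"}), on=key)
    return merged[(merged["p_wt"] > tau_hi) &
                  (merged["p_ko"] < tau_lo)].reset_index(drop=True)
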