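"""Gene-aware data splitting and accuracy metrics.

Splits are made at the gene level so no gene's sites straddle the
train/validation/test boundary; for synthetic data the transcript doubles
as the gene.  ROC AUC follows the Mann-Whitney convention (ties counted
half) and PR AUC uses the step-function estimator, which avoids the
optimism of linear interpolation between operating points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes and got one."""


def gene_level_split(sites: pd.DataFrame, fractions=(0.6, 0.2, 0.2),
                     seed: int = 0) -> tuple[pd.DataFrame, ...]:
    """Partition a labeled site table by gene.

    ``sites`` needs transcript_id, position and gene_id columns; fractions
    must sum to 1.  Genes are shuffled deterministically and allotted to the
    splits by cumulative gene count; all sites of one gene land in exactly
    one split.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    if sites.duplicated(["transcript_id", "position"]).any():
        raise ValueError("duplicate (transcript, position) rows")
    genes = np.sort(sites["gene_id"].unique())
    rng = np.random.default_rng(seed)
    rng.shuffle(genes)
    bounds = np.round(np.cumsum(fractions) * len(genes)).astype(int)
    pieces, start = [], 0
    for stop in bounds:
        chosen = set(genes[start:stop])
        if not chosen:
            raise ValueError("a split fraction yields zero genes")
        pieces.append(sites[sites["gene_id"].isin(chosen)].reset_index(drop=True))
        start = stop
    return tuple(pieces)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("metric needs both classes present")


def roc_pr_metrics(scores, labels):
    """(ROC AUC, PR AUC, curves) for binary labels.

    ROC AUC equals the normalized Mann-Whitney U statistic; PR AUC is the
    step-wise estimator (average precision).  Curves come back as a dict of
    DataFrames for optional export.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    roc_auc = float(roc_auc_score(labels, scores))
    pr_auc = float(average_precision_score(labels, scores))
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    curves = {
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        "pr": pd.DataFrame({"recall": rec, "precision": prec}),
    }
    return roc_auc, pr_auc, curves


def precision_at_threshold(scores, labels, tau: float = 0.9) -> float | None:
    """Precision among sites scored at or above tau; None when nothing passes."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    passing = scores >= tau
    if not passing.any():
        return None
    return float(labels[passing].mean())
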