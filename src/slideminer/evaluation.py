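"""Slide-level evaluation: ROC AUC, log loss, bootstrap CIs, subtype tables.

The ROC AUC is computed from the rank (concordance) definition: the
probability that a randomly chosen positive slide outscores a randomly
chosen negative one, ties counting one half.  95% confidence intervals use
the percentile bootstrap over slides (default 1000 iterations).  Threshold
-based confusion breakdowns stratify false positives and true negatives by
benign subtype, the diagnostic view used to understand what a slide-level
classifier confuses with carcinoma.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .inference import SlidePrediction
from .synthetic import SlideRecord
from .training import PROB_CLIP

__all__ = [
    "EvalReport",
    "roc_auc",
    "log_loss",
    "bootstrap_ci",
    "confusion_by_subtype",
    "evaluate",
]

logger = logging.getLogger(__name__)

DEFAULT_BOOTSTRAP_ITERATIONS = 1000


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve via the rank formula.

    Equals (#concordant pairs + 0.5 * #tied pairs) / (#pos * #neg).
    Average ranks make ties contribute exactly one half.  Raises if only
    one class is present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC undefined: both classes must be present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def log_loss(labels, scores) -> float:
    """Mean binary cross entropy, scores clipped to [1e-7, 1 - 1e-7]."""
    y = np.asarray(labels, dtype=float)
    if y.size == 0:
        raise ValueError("log loss undefined on empty input")
    p = np.clip(np.asarray(scores, dtype=float), PROB_CLIP, 1.0 - PROB_CLIP)
    return float(np.mean(-(y * np.log(p) + (1 - y) * np.log1p(-p))))


def bootstrap_ci(
    labels,
    scores,
    metric: str,
    B: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap 95% CI of a slide-level metric.

    Slides are resampled with replacement B times; the interval is the
    (2.5th, 97.5th) percentile of the metric over resamples.  AUC
    resamples that contain a single class are redrawn (counted and
    logged); if more than half of all draws are single-class the data are
    too degenerate and an error is raised.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    fns = {"auc": roc_auc, "logloss": log_loss}
    if metric not in fns:
        raise ValueError(f"metric must be one of {sorted(fns)}, got {metric!r}")
    fn = fns[metric]
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redraws = 0
    attempts = 0
    for b in range(B):
        while True:
            attempts += 1
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if metric == "auc" and (yb.min() == yb.max()):
                redraws += 1
                if attempts >= 20 and redraws / attempts > 0.5:
                    raise ValueError(
                        "bootstrap degenerate: more than half of resamples are single-class"
                    )
                continue
            break
        values[b] = fn(yb, s[idx])
    if redraws:
        logger.info("bootstrap: %d single-class resamples redrawn", redraws)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def confusion_by_subtype(
    predictions: list[SlidePrediction],
    manifest: list[SlideRecord],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """FP and TN counts among negative slides, stratified by benign subtype.

    A slide is called positive iff its probability is >= threshold (ties to
    positive).  Negative slides without a subtype tag are bucketed as
    ``unspecified``.  Percentages are within each block (FP block sums to
    100%, TN block sums to 100%), reported to one decimal.
    """
    by_id = {r.slide_id: r for r in manifest}
    rows = []
    for pred in predictions:
        rec = by_id[pred.slide_id]
        if rec.label != 0:
            continue
        subtype = rec.subtype or "unspecified"
        block = "false_positive" if pred.probability >= threshold else "true_negative"
        rows.append({"block": block, "subtype": subtype})
    if not rows:
        return pd.DataFrame(columns=["block", "subtype", "count", "percent"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["block", "subtype"], sort=True).size().rename("count").reset_index()
    )
    totals = out.groupby("block")["count"].transform("sum")
    out["percent"] = (out["count"] / totals * 100).round(1)
    return out


@dataclass
class EvalReport:
    """Evaluation summary for one test set."""

    auc: float
    auc_ci: tuple[float, float]
    logloss: float
    logloss_ci: tuple[float, float]
    n_slides: int
    threshold: float
    confusion: dict[str, int]
    subtype_breakdown: list[dict] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def evaluate(
    predictions: list[SlidePrediction],
    manifest: list[SlideRecord],
    threshold: float = 0.5,
    B: int = DEFAULT_BOOTSTRAP_ITERATIONS,
    seed: int = 0,
) -> EvalReport:
    """Full slide-level report: AUC and log loss with bootstrap 95% CIs,
    threshold confusion counts, and the benign-subtype breakdown."""
    by_id = {r.slide_id: r for r in manifest}
    labels = np.array([by_id[p.slide_id].label for p in predictions])
    scores = np.array([p.probability for p in predictions])
    calls = scores >= threshold
    confusion = {
        "TP": int(((labels == 1) & calls).sum()),
        "FP": int(((labels == 0) & calls).sum()),
        "TN": int(((labels == 0) & ~calls).sum()),
        "FN": int(((labels == 1) & ~calls).sum()),
    }
    breakdown = confusion_by_subtype(predictions, manifest, threshold)
    return EvalReport(
        auc=roc_auc(labels, scores),
        auc_ci=bootstrap_ci(labels, scores, "auc", B=B, seed=seed),
        logloss=log_loss(labels, scores),
        logloss_ci=bootstrap_ci(labels, scores, "logloss", B=B, seed=seed),
        n_slides=len(predictions),
        threshold=threshold,
        confusion=confusion,
        subtype_breakdown=breakdown.to_dict(orient="records"),
    )
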