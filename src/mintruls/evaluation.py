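"""Cross-validation, metrics, score normalization and target classes.

Two cross-validation schemes mirror how the predictor is meant to be
used.  Leave-one-out CV (LOOCV) masks a single cell of the adjacency
matrix, rebuilds the interaction-profile kernel from the masked matrix,
refits and scores that cell; masking a negative cell is a no-op on the
training matrix, so negative cells are scored by the base fit, which is
bitwise identical to the mask-and-refit result.  Leave-target-sites-out
CV (LmiTOCV) holds out a random fraction of site columns wholesale,
zeroes them in training, fits once and scores every held-out cell;
repeated over seeded iterations.

Raw scores are normalized per miRNA to [0, 1] (unity-based rescaling
across that miRNA's scored sites) and pairs are binned into Weak /
Moderate / Strong target classes by the lower and upper quartiles of the
normalized-score population.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import Config
from .data_model import Dataset, InteractionMatrix
from .features import FoldingProvider
from .pipeline import (
    StaticKernels,
    build_static_kernels,
    mirna_kernel,
    prepare_dataset,
    site_kernel,
)
from .rls import ScoreMatrix

__all__ = [
    "PredictionReport",
    "loocv",
    "lmitocv",
    "roc_auc",
    "confusion_metrics",
    "choose_threshold",
    "normalize_scores",
    "quantile_classify",
    "shuffle_labels",
    "ConfusionMetrics",
]


class ConfusionMetrics(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float


@dataclass
class PredictionReport:
    """Per-pair scores plus summary metrics from one evaluation run."""

    records: pd.DataFrame  # mirna_id, site_id, score, normalized, klass, label, fold
    metrics: dict
    threshold: float
    x_bounds: pd.DataFrame = None  # per-miRNA X_min / X_max
    per_iteration: pd.DataFrame = None

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)

    def metrics_json(self) -> dict:
        out = dict(self.metrics)
        out["threshold"] = self.threshold
        return out


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by the rank (Wilcoxon) statistic.

    Equals P(score_pos > score_neg) + 0.5 P(tie) over positive-negative
    pairs.  Requires both classes.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def confusion_metrics(scores, labels, threshold: float) -> ConfusionMetrics:
    """Accuracy, sensitivity, specificity, MCC at a score threshold.

    A pair is predicted positive when score >= threshold.  MCC is defined
    as 0 when any marginal of the 2x2 table is empty.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("confusion_metrics requires both classes present")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / len(y)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return ConfusionMetrics(acc, sens, spec, mcc)


def choose_threshold(scores, labels) -> float:
    """Youden-optimal threshold (max sensitivity + specificity - 1).

    Candidate thresholds are the observed scores; ties in J are broken
    toward the larger threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("choose_threshold requires both classes present")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    t_vals, inverse = np.unique(s, return_inverse=True)  # ascending
    pos_at = np.bincount(inverse, weights=(y == 1), minlength=t_vals.size)
    neg_at = np.bincount(inverse, weights=(y == 0), minlength=t_vals.size)
    # pred positive at threshold t: s >= t  ->  suffix sums
    sens = np.cumsum(pos_at[::-1])[::-1] / n_pos
    spec = (n_neg - np.cumsum(neg_at[::-1])[::-1]) / n_neg
    j = sens + spec - 1
    best = np.flatnonzero(j == j.max())[-1]  # largest threshold on ties
    return float(t_vals[best])


def normalize_scores(score_matrix) -> np.ndarray | ScoreMatrix:
    """Unity-based per-miRNA rescaling: row min -> 0, row max -> 1.

    X' = (X - X_min) / (X_max - X_min) with the extrema taken per miRNA
    across all its sites.  A constant row carries no ranking information
    and is set to 0.5 with a warning.
    """
    if isinstance(score_matrix, ScoreMatrix):
        return ScoreMatrix(list(score_matrix.mirna_ids), list(score_matrix.site_ids),
                           normalize_scores(score_matrix.scores))
    X = np.asarray(score_matrix, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    flat = (span == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant score row(s) set to 0.5", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        Xn = (X - lo) / span
    Xn[flat.nonzero()[0], :] = 0.5
    return Xn


def quantile_classify(normalized_scores) -> np.ndarray:
    """Weak / Moderate / Strong classes from the score quartiles.

    Quartiles (linear-interpolation estimator) are computed over the
    supplied population; score < Q25 is Weak, score > Q75 is Strong,
    everything between (inclusive) is Moderate.
    """
    s = np.asarray(normalized_scores, dtype=float).ravel()
    if s.size < 4:
        raise ValueError("need at least 4 scores to form quartiles")
    q25, q75 = np.percentile(s, [25, 75])
    out = np.full(s.shape, "Moderate", dtype=object)
    out[s < q25] = "Weak"
    out[s > q75] = "Strong"
    return out


def shuffle_labels(matrix: InteractionMatrix, seed: int) -> InteractionMatrix:
    """Place the same number of positives uniformly at random (null control)."""
    rng = np.random.default_rng(seed)
    n = matrix.A.size
    k = int(matrix.A.sum())
    flat = np.zeros(n, dtype=np.int8)
    flat[rng.choice(n, size=k, replace=False)] = 1
    return InteractionMatrix(list(matrix.mirna_ids), list(matrix.site_ids),
                             flat.reshape(matrix.A.shape))


# ---------------------------------------------------------------------------
# cross-validation drivers


def _predict_full(static: StaticKernels, Y: np.ndarray,
                  config: Config) -> np.ndarray:
    """Full score matrix for one training adjacency.

    Both integrated kernels contain a Gaussian interaction-profile
    component, so both are rebuilt from the supplied (possibly masked)
    training matrix before the eigen-route solve.
    """
    Sm = mirna_kernel(static, Y, config)
    St = site_kernel(static, Y, config)
    lm, Qm = np.linalg.eigh(Sm.M)
    lt, Qt = np.linalg.eigh(St.M)
    prod = np.outer(lm, lt)
    H = prod / (prod + config.lam) if config.lam > 0 else np.ones_like(prod)
    C = H * (Qm.T @ Y @ Qt)
    return Qm @ C @ Qt.T


def _normalize_and_classify(df: pd.DataFrame, config: Config) -> pd.DataFrame:
    """Attach per-miRNA normalized scores and quartile classes to records."""
    df = df.copy()
    df["normalized"] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single-cell rows are expected in CV
        for _, idx in df.groupby("mirna_id").groups.items():
            row = df.loc[idx, "score"].to_numpy()[None, :]
            df.loc[idx, "normalized"] = normalize_scores(row).ravel()
    if config.per_mirna_quartiles:
        df["klass"] = "Moderate"
        for _, idx in df.groupby("mirna_id").groups.items():
            vals = df.loc[idx, "normalized"].to_numpy()
            if vals.size >= 4:
                df.loc[idx, "klass"] = quantile_classify(vals)
    elif len(df) >= 4:
        df["klass"] = quantile_classify(df["normalized"].to_numpy())
    else:  # too few pairs for quartiles: everything is mid-population
        df["klass"] = "Moderate"
    return df


def _summary(df: pd.DataFrame, threshold: float) -> dict:
    s, y = df["score"].to_numpy(), df["label"].to_numpy()
    cm = confusion_metrics(s, y, threshold)
    return {
        "auc": roc_auc(s, y),
        "accuracy": cm.accuracy,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "mcc": cm.mcc,
        "n_pairs": int(len(df)),
        "n_positives": int(y.sum()),
    }


def loocv(dataset: Dataset, config: Config | None = None,
          provider: FoldingProvider | None = None) -> PredictionReport:
    """Leave-one-association-out cross-validation.

    Every evaluated positive cell is zeroed in the training matrix, the
    interaction-profile kernel rebuilt from the masked matrix, the model
    refitted and the cell scored -- so the held-out label never reaches
    its own score.  Negative cells are scored by the base fit (masking a
    zero is a no-op, so this is the identical model).  For tractability
    the evaluated set may be a seeded subsample: ``config.max_positives``
    caps evaluated positives and ``config.neg_per_pos`` negatives are
    drawn per positive (None means all).
    """
    config = config or Config()
    dataset = prepare_dataset(dataset, config)
    Y = dataset.interactions.A.astype(float)
    if Y.sum() < 2:
        raise ValueError("LOOCV requires at least 2 positive associations")
    static = build_static_kernels(dataset, config, provider)
    rng = np.random.default_rng(config.seed)

    pos = np.argwhere(Y == 1)
    neg = np.argwhere(Y == 0)
    if config.max_positives is not None and len(pos) > config.max_positives:
        pos = pos[rng.choice(len(pos), config.max_positives, replace=False)]
    if config.neg_per_pos is not None:
        n_neg = min(len(neg), config.neg_per_pos * len(pos))
        neg = neg[rng.choice(len(neg), n_neg, replace=False)]

    base_F = _predict_full(static, Y, config)
    rows = []
    for i, j in neg:
        rows.append((dataset.mirnas[i].id, dataset.sites[j].id,
                     base_F[i, j], 0, len(rows)))
    for i, j in pos:
        Ym = Y.copy()
        Ym[i, j] = 0.0
        F = _predict_full(static, Ym, config)
        rows.append((dataset.mirnas[i].id, dataset.sites[j].id,
                     F[i, j], 1, len(rows)))
    df = pd.DataFrame(rows, columns=["mirna_id", "site_id", "score", "label", "fold"])

    # threshold from base-model (training) scores, applied to CV scores
    eval_cells = np.concatenate([neg, pos])
    train_scores = base_F[eval_cells[:, 0], eval_cells[:, 1]]
    threshold = choose_threshold(train_scores, df["label"].to_numpy())
    df = _normalize_and_classify(df, config)
    bounds = df.groupby("mirna_id")["score"].agg(X_min="min", X_max="max").reset_index()
    return PredictionReport(df, _summary(df, threshold), threshold, bounds)


def lmitocv(dataset: Dataset, config: Config | None = None,
            provider: FoldingProvider | None = None,
            fraction: float | None = None, seed: int | None = None,
            iterations: int | None = None) -> PredictionReport:
    """Leave-target-sites-out cross-validation.

    Each iteration holds out ceil(fraction * n_t) random site columns,
    zeroes every cell of those columns in the training matrix (adjacency
    and interaction profiles alike), fits once and scores all held-out
    cells against the true labels.  Metrics are reported per iteration
    and pooled over all iterations.
    """
    config = config or Config()
    fraction = config.fraction if fraction is None else fraction
    seed = config.seed if seed is None else seed
    iterations = config.iterations if iterations is None else iterations
    dataset = prepare_dataset(dataset, config)
    Y = dataset.interactions.A.astype(float)
    n_t = Y.shape[1]
    if fraction * n_t < 1:
        raise ValueError(
            f"fraction {fraction} of {n_t} sites leaves no column to hold out"
        )
    n_hold = math.ceil(fraction * n_t)
    static = build_static_kernels(dataset, config, provider)
    rng = np.random.default_rng(seed)

    frames, iter_rows, thresholds = [], [], []
    for it in range(iterations):
        cols = np.sort(rng.choice(n_t, size=n_hold, replace=False))
        Ytrain = Y.copy()
        Ytrain[:, cols] = 0.0
        F = _predict_full(static, Ytrain, config)
        held = pd.DataFrame({
            "mirna_id": np.repeat([r.id for r in dataset.mirnas], n_hold),
            "site_id": np.tile([dataset.sites[j].id for j in cols], Y.shape[0]),
            "score": F[:, cols].ravel(),
            "label": Y[:, cols].ravel().astype(int),
            "fold": it,
        })
        frames.append(held)
        train_cols = np.setdiff1d(np.arange(n_t), cols)
        tr_s = F[:, train_cols].ravel()
        tr_y = Ytrain[:, train_cols].ravel().astype(int)
        if len(np.unique(tr_y)) == 2:
            thresholds.append(choose_threshold(tr_s, tr_y))
        if held["label"].nunique() == 2:
            iter_rows.append({"fold": it,
                              "auc": roc_auc(held["score"], held["label"]),
                              "n_pairs": len(held),
                              "n_positives": int(held["label"].sum())})
    df = pd.concat(frames, ignore_index=True)
    if df["label"].nunique() < 2:
        raise ValueError("held-out cells contain a single class; cannot score")
    threshold = float(np.median(thresholds)) if thresholds else 0.5
    df = _normalize_and_classify(df, config)
    metrics = _summary(df, threshold)
    per_iter = pd.DataFrame(iter_rows)
    if len(per_iter):
        metrics["mean_iteration_auc"] = float(per_iter["auc"].mean())
    bounds = df.groupby("mirna_id")["score"].agg(X_min="min", X_max="max").reset_index()
    return PredictionReport(df, metrics, threshold, bounds, per_iter)
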