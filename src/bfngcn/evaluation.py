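"""Repeated random-split evaluation with the six-metric protocol.

The protocol: randomly hold out 20% of subjects for testing, train on the
remaining 80%, and repeat over many independent splits (100 in the full
study), reporting mean ± std of accuracy, sensitivity, specificity,
precision, F1 and AUC.  Metrics come straight from the confusion counts:

    Acc = (TP+TN)/(TP+FP+TN+FN)      Sen = TP/(TP+FN)
    Spe = TN/(TN+FP)                 Pre = TP/(TP+FP)
    F1  = 2·TP/(2·TP+FP+FN)

AUC is the Mann-Whitney rank statistic on the positive-class scores
(exact and tie-robust, equal to the fraction of correctly ordered
positive/negative pairs with ties counted 1/2).

Splits are not stratified; a split whose training half lacks a class is
resampled with a derived seed (logged).  The reported std is the
population standard deviation over repeats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .gcn import GraphSample, TrainConfig, predict_proba, train

logger = logging.getLogger(__name__)

__all__ = [
    "METRICS",
    "RunResult",
    "ExperimentGrid",
    "split",
    "compute_metrics",
    "run_experiment",
    "build_grid",
]

METRICS = ("acc", "sen", "spe", "pre", "f1", "auc")


@dataclass
class RunResult:
    """Metrics of one train/test repeat, recomputable from the confusion."""

    acc: float
    sen: float
    spe: float
    pre: float
    f1: float
    auc: float
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    split_seed: int = 0
    degenerate: tuple[str, ...] = ()  # metrics reported as 0 for a 0/0

    def as_vector(self) -> np.ndarray:
        return np.array([self.acc, self.sen, self.spe, self.pre, self.f1, self.auc])


def split(
    samples: list[GraphSample], fraction: float = 0.8, seed: int = 0
) -> tuple[list[GraphSample], list[GraphSample]]:
    """Random disjoint/exhaustive train-test split; |test| = round((1-f)·N).

    If the training half ends up single-class the split is redrawn with a
    derived seed (logged); after 100 failed redraws an error is raised.
    """
    n = len(samples)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_test = int(round((1.0 - fraction) * n))
    n_test = min(max(n_test, 1), n - 2)
    for attempt in range(100):
        rng = np.random.default_rng((seed, attempt))
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        train = [samples[i] for i in train_idx]
        if len({s.label for s in train}) == 2:
            if attempt:
                logger.info("split seed %d: resampled %d time(s) to get both "
                            "classes in training", seed, attempt)
            return train, [samples[i] for i in test_idx]
    raise ValueError("could not draw a two-class training split in 100 attempts")


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic AUC; 0.5 when either class is absent or scores tie."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    labels, predictions, scores, *, split_seed: int = 0
) -> RunResult:
    """Six metrics from true labels, hard predictions and positive-class scores.

    A zero-denominator metric (e.g. precision with no positive
    predictions) is reported as 0 and its name recorded in
    ``result.degenerate``.
    """
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(labels) == len(predictions) == len(scores)):
        raise ValueError("labels, predictions and scores must share a length")
    tp = int(((labels == 1) & (predictions == 1)).sum())
    fp = int(((labels == 0) & (predictions == 1)).sum())
    tn = int(((labels == 0) & (predictions == 0)).sum())
    fn = int(((labels == 1) & (predictions == 0)).sum())
    degenerate: list[str] = []

    def ratio(name: str, num: int, den: int) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    res = RunResult(
        acc=ratio("acc", tp + tn, tp + fp + tn + fn),
        sen=ratio("sen", tp, tp + fn),
        spe=ratio("spe", tn, tn + fp),
        pre=ratio("pre", tp, tp + fp),
        f1=ratio("f1", 2 * tp, 2 * tp + fp + fn),
        auc=auc_score(labels, scores),
        confusion=(tp, fp, tn, fn),
        split_seed=split_seed,
    )
    res.degenerate = tuple(degenerate)
    if degenerate:
        logger.warning("zero-denominator metrics reported as 0: %s", degenerate)
    return res


def run_experiment(
    samples: list[GraphSample],
    cfg: TrainConfig,
    *,
    n_repeats: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, float], list[RunResult]]:
    """Repeat split→train→predict→metrics; return mean/std per metric.

    Repeat k uses split seed ``seed + k`` and trains with seed
    ``cfg.seed + k`` so repeats are independent but the whole run is
    reproducible from the master seed.
    """
    results: list[RunResult] = []
    for k in range(n_repeats):
        train_set, test_set = split(samples, train_fraction, seed=seed + k)
        rep_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + k})
        params, _ = train(train_set, rep_cfg)
        probs = predict_proba(test_set, params)
        res = compute_metrics(
            [s.label for s in test_set],
            probs.argmax(axis=1),
            probs[:, 1],
            split_seed=seed + k,
        )
        results.append(res)
    mat = np.stack([r.as_vector() for r in results])
    row: dict[str, float] = {}
    for j, name in enumerate(METRICS):
        row[f"{name}_mean"] = float(mat[:, j].mean())
        row[f"{name}_std"] = float(mat[:, j].std())  # population std
    return row, results


@dataclass
class ExperimentGrid:
    """Feature-set × estimator grid of mean ± std metrics."""

    table: pd.DataFrame
    n_repeats: int
    per_repeat: dict[tuple[str, str], list[RunResult]] = field(default_factory=dict)

    def best_flags(self) -> pd.DataFrame:
        """One True per metric column marking its best row (ties → first)."""
        flags = pd.DataFrame(False, index=self.table.index,
                             columns=[f"{m}_mean" for m in METRICS])
        for m in METRICS:
            col = f"{m}_mean"
            flags.loc[self.table[col].idxmax(), col] = True
        return flags

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    @staticmethod
    def from_csv(path, n_repeats: int = 0) -> "ExperimentGrid":
        return ExperimentGrid(table=pd.read_csv(path), n_repeats=n_repeats)


def build_grid(
    sample_builder,
    estimators: list[str],
    feature_sets: list[list[str]],
    cfg: TrainConfig,
    *,
    n_repeats: int = 100,
    seed: int = 0,
) -> ExperimentGrid:
    """Cross-product grid over estimators and feature sets.

    ``sample_builder(estimator, feature_set)`` must return the list of
    :class:`GraphSample` for that cell (building them once per estimator
    is the caller's concern).
    """
    if not estimators or not feature_sets:
        raise ValueError("estimators and feature_sets must be nonempty")
    rows = []
    per_repeat = {}
    for est in estimators:
        for fset in feature_sets:
            label = "+".join(f.upper() for f in fset)
            samples = sample_builder(est, fset)
            row, results = run_experiment(samples, cfg, n_repeats=n_repeats, seed=seed)
            rows.append({"estimator": est, "features": label, **row})
            per_repeat[(est, label)] = results
    table = pd.DataFrame(rows)
    return ExperimentGrid(table=table, n_repeats=n_repeats, per_repeat=per_repeat)
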