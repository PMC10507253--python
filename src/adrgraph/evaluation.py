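"""Five-fold cross-validation protocol and ranking metrics.

Positive pairs are partitioned into five near-equal subsets; each fold
trains on four subsets plus an equal-size random negative sample and tests
on the held-out positives together with every remaining negative pair
(standard link-prediction evaluation under heavy class imbalance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "Fold",
    "FoldSplit",
    "make_folds",
    "auc_aupr",
    "recall_at_k",
    "per_drug_metrics",
    "evaluate_scores",
    "cross_validate",
    "DEFAULT_KS",
]

DEFAULT_KS = tuple(range(30, 241, 30))


@dataclass
class Fold:
    index: int
    train_pos: np.ndarray   # (n, 2) drug/side-effect index pairs
    train_neg: np.ndarray
    test_pos: np.ndarray
    test_neg: np.ndarray

    @property
    def train_pairs(self) -> np.ndarray:
        return np.concatenate([self.train_pos, self.train_neg])

    @property
    def train_labels(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.train_pos)),
                               np.zeros(len(self.train_neg))])

    @property
    def test_pairs(self) -> np.ndarray:
        return np.concatenate([self.test_pos, self.test_neg])

    @property
    def test_labels(self) -> np.ndarray:
        return np.concatenate([np.ones(len(self.test_pos)),
                               np.zeros(len(self.test_neg))])


@dataclass
class FoldSplit:
    folds: list[Fold]
    seed: int
    n_drugs: int
    n_side_effects: int
    n_positives: int
    n_negative_pool: int = field(default=0)

    @property
    def negative_positive_ratio(self) -> float:
        return self.n_negative_pool / self.n_positives


def mask_test_positives(o, fold: Fold) -> np.ndarray:
    """Copy of O with the fold's held-out positive edges zeroed (training
    hygiene: test associations must not leak into graphs or attributes)."""
    o_train = np.array(o, dtype=float, copy=True)
    o_train[fold.test_pos[:, 0], fold.test_pos[:, 1]] = 0.0
    return o_train


def make_folds(o, seed: int, n_folds: int = 5) -> FoldSplit:
    """Deterministic five-fold split of the association matrix.

    Positives are shuffled and partitioned into ``n_folds`` subsets of
    near-equal size (+-1).  Per fold, a balanced training negative sample
    (same count as the training positives) is drawn; all remaining
    negatives join the held-out positives as the test set.
    """
    o = np.asarray(o)
    pos = np.argwhere(o == 1).astype(np.int32)
    neg = np.argwhere(o == 0).astype(np.int32)
    if len(pos) < n_folds:
        raise ValueError(f"need at least {n_folds} positive pairs, got {len(pos)}")
    ss = np.random.SeedSequence(seed)
    rng_split, *rngs_neg = (np.random.default_rng(c) for c in ss.spawn(1 + n_folds))
    subsets = np.array_split(rng_split.permutation(len(pos)), n_folds)
    folds = []
    for f in range(n_folds):
        test_idx = subsets[f]
        train_idx = np.concatenate([subsets[g] for g in range(n_folds) if g != f])
        n_train_neg = len(train_idx)
        chosen = rngs_neg[f].choice(len(neg), size=n_train_neg, replace=False)
        mask = np.zeros(len(neg), dtype=bool)
        mask[chosen] = True
        folds.append(Fold(index=f,
                          train_pos=pos[train_idx],
                          train_neg=neg[chosen],
                          test_pos=pos[test_idx],
                          test_neg=neg[~mask]))
    return FoldSplit(folds=folds, seed=seed,
                     n_drugs=o.shape[0], n_side_effects=o.shape[1],
                     n_positives=len(pos), n_negative_pool=len(neg))


def auc_aupr(scores, labels) -> tuple[float, float]:
    """Rank-based AUC (ties half-credit) and AUPR (precision-recall step
    integration)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least one positive and one negative label")
    return (float(roc_auc_score(labels, scores)),
            float(average_precision_score(labels, scores)))


def _ranked(group: pd.DataFrame) -> pd.DataFrame:
    # stable sort: descending score, ties broken by side-effect index
    return group.sort_values(["score", "side_effect"],
                             ascending=[False, True], kind="stable")


def recall_at_k(scores_df: pd.DataFrame, ks=DEFAULT_KS,
                mode: str = "per_drug") -> dict[int, float]:
    """Fraction of test positives recovered in the top-k ranked candidates.

    ``per_drug`` ranks each drug's candidate side effects separately and
    averages the per-drug recalls (drugs without test positives are
    skipped); ``pooled`` ranks all test pairs in one list.
    """
    ks = [int(k) for k in ks]
    if any(k <= 0 for k in ks):
        raise ValueError("k values must be positive")
    out = {}
    if mode == "pooled":
        ranked = _ranked(scores_df)
        labels = ranked["label"].to_numpy()
        total = labels.sum()
        for k in ks:
            out[k] = float(labels[:k].sum() / total) if total else float("nan")
        return out
    if mode != "per_drug":
        raise ValueError(f"unknown recall mode {mode!r}")
    per_drug = []
    for _, group in scores_df.groupby("drug", sort=True):
        labels = _ranked(group)["label"].to_numpy()
        total = labels.sum()
        if total == 0:
            continue
        per_drug.append([labels[:k].sum() / total for k in ks])
    arr = np.asarray(per_drug, dtype=float)
    for col, k in enumerate(ks):
        out[k] = float(arr[:, col].mean()) if len(arr) else float("nan")
    return out


def per_drug_metrics(scores_df: pd.DataFrame) -> pd.DataFrame:
    """Per-drug AUC/AUPR table; drugs lacking either class are skipped
    with a logged warning."""
    rows = []
    for drug, group in scores_df.groupby("drug", sort=True):
        labels = group["label"].to_numpy()
        if labels.min() == labels.max():
            logger.warning("drug %s skipped: only one class in test pairs", drug)
            continue
        auc, aupr = auc_aupr(group["score"].to_numpy(), labels)
        rows.append({"drug": drug, "auc": auc, "aupr": aupr,
                     "n_pos": int(labels.sum()), "n_pairs": len(labels)})
    return pd.DataFrame(rows, columns=["drug", "auc", "aupr", "n_pos", "n_pairs"])


def evaluate_scores(scores_df: pd.DataFrame, ks=DEFAULT_KS,
                    recall_mode: str = "per_drug") -> dict:
    """Metric report over a (drug, side_effect, score, label, fold) table."""
    per_fold = {}
    for fold, group in scores_df.groupby("fold", sort=True):
        auc, aupr = auc_aupr(group["score"].to_numpy(), group["label"].to_numpy())
        per_fold[int(fold)] = {"auc": auc, "aupr": aupr}
    return {
        "per_fold": per_fold,
        "average_auc": float(np.mean([m["auc"] for m in per_fold.values()])),
        "average_aupr": float(np.mean([m["aupr"] for m in per_fold.values()])),
        "recall_at_k": {str(k): v for k, v in
                        recall_at_k(scores_df, ks, mode=recall_mode).items()},
    }


def score_fold(matrices, fold: Fold, config) -> pd.DataFrame:
    """Train on one fold and score its test pairs."""
    from .model import train_model

    m_chem, m_dise, s, o = matrices
    o_train = mask_test_positives(o, fold)
    model = train_model(m_chem, m_dise, s, o_train,
                        fold.train_pairs, fold.train_labels, config)
    pairs = fold.test_pairs
    scores = model.score_pairs(pairs)
    return pd.DataFrame({"drug": pairs[:, 0], "side_effect": pairs[:, 1],
                         "score": scores,
                         "label": fold.test_labels.astype(int),
                         "fold": fold.index})


def cross_validate(matrices, config, seed: int, n_folds: int = 5,
                   folds: list[int] | None = None) -> tuple[pd.DataFrame, dict]:
    """Full protocol: split, per-fold training/scoring, metric report.

    ``folds`` restricts computation to a subset of fold indices (useful at
    desk scale); metrics are averaged over the folds actually run.
    """
    from dataclasses import replace

    o = matrices[3]
    split = make_folds(o, seed=seed, n_folds=n_folds)
    frames = []
    for fold in split.folds:
        if folds is not None and fold.index not in folds:
            continue
        fold_cfg = replace(config, seed=config.seed + fold.index)
        frames.append(score_fold(matrices, fold, fold_cfg))
        logger.info("fold %d scored", fold.index)
    scores_df = pd.concat(frames, ignore_index=True)
    return scores_df, evaluate_scores(scores_df)
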