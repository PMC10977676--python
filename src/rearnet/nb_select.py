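"""Naive Bayes SNP pre-selection.

The SNP panel is randomly split into disjoint groups; within each group a
categorical Naive Bayes classifier (Laplace-smoothed, features assumed
conditionally independent given the trait class) is scored per SNP by
repeated stratified k-fold cross-validation, and the top-k SNPs per trait are
pooled (union, single entry per SNP) to form that group's input to the
network-structure stage.

The importance score for a SNP is the held-out single-feature separation:
the area under the ROC curve of the ordering induced by the Naive Bayes
posterior P(class | SNP state).  Fold-level AUCs are averaged over all
folds x repeats first and the mean is then folded into [0.5, 1] as
max(m, 1 - m); for traits with more than two states the score is the
maximum over one-vs-one class pairs.  Under independence the score
concentrates at 0.5, and a perfect single-SNP separator scores 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .discretize import DiscreteDataset
from .errors import ValidationError

logger = logging.getLogger(__name__)


def partition_snps(snp_ids, n_groups: int = 10, seed: int = 0) -> list[list[str]]:
    """Randomly split SNP ids into ``n_groups`` disjoint groups of near-equal
    size (sizes differ by at most one)."""
    snp_ids = list(snp_ids)
    if len(set(snp_ids)) != len(snp_ids):
        raise ValidationError("snp_ids must be unique")
    if n_groups < 1:
        raise ValidationError("n_groups must be >= 1")
    if n_groups > len(snp_ids):
        raise ValidationError(
            f"cannot split {len(snp_ids)} SNPs into {n_groups} groups"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(snp_ids))
    groups: list[list[str]] = [[] for _ in range(n_groups)]
    for i, idx in enumerate(order):
        groups[i % n_groups].append(snp_ids[idx])
    return groups


@dataclass
class NaiveBayesModel:
    """Categorical Naive Bayes with Laplace smoothing alpha."""

    classes: np.ndarray
    class_priors: np.ndarray
    feature_names: list[str]
    conditionals: dict[str, np.ndarray]  # feature -> (n_states, n_classes)
    alpha: float

    def predict_proba(self, data: DiscreteDataset) -> np.ndarray:
        """Posterior over classes per row, Bayes rule with the independence
        factorization, normalized over classes."""
        n = len(data.data)
        log_post = np.tile(np.log(self.class_priors), (n, 1))
        for f in self.feature_names:
            cond = self.conditionals[f]
            log_post += np.log(cond[data.codes(f)])
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


def fit_naive_bayes(
    data: DiscreteDataset,
    class_var: str,
    alpha: float = 1.0,
    feature_vars=None,
) -> NaiveBayesModel:
    """Fit class priors and per-feature conditionals from count tables.

    conditionals = (count + alpha) / (class count + alpha * arity);
    priors are the empirical class frequencies.
    """
    if class_var not in data.columns:
        raise ValidationError(f"class variable {class_var!r} not in dataset")
    y = data.codes(class_var)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError(f"class variable {class_var!r} is constant")
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    features = [
        c for c in (feature_vars if feature_vars is not None else data.columns)
        if c != class_var
    ]
    arity = data.arity
    n_classes = classes.size
    class_counts = np.array([(y == c).sum() for c in classes], dtype=float)
    if alpha == 0:
        for f in features:
            for c in range(n_classes):
                counts = np.bincount(
                    data.codes(f)[y == classes[c]], minlength=arity[f]
                )
                if (counts == 0).any():
                    raise ValidationError(
                        "alpha=0 requires every (feature state, class) cell "
                        f"to be populated; feature {f!r} has an empty cell"
                    )
    conditionals = {}
    for f in features:
        r = arity[f]
        table = np.empty((r, n_classes))
        for ci, c in enumerate(classes):
            counts = np.bincount(data.codes(f)[y == c], minlength=r)
            table[:, ci] = (counts + alpha) / (class_counts[ci] + alpha * r)
        conditionals[f] = table
    return NaiveBayesModel(
        classes=classes,
        class_priors=class_counts / class_counts.sum(),
        feature_names=features,
        conditionals=conditionals,
        alpha=alpha,
    )


@dataclass
class ImportanceRanking:
    """Descending per-SNP importance for one trait within one SNP subset."""

    trait: str
    subset_index: int
    entries: list[tuple[str, float]]

    def top(self, k: int) -> list[str]:
        if not self.entries:
            raise ValidationError("empty importance ranking")
        if k > len(self.entries):
            logger.warning(
                "requested top %d of %d ranked SNPs (trait %s, subset %d); "
                "returning all", k, len(self.entries), self.trait,
                self.subset_index,
            )
        return [snp for snp, _ in self.entries[:k]]


def _stratified_folds(y: np.ndarray, folds: int, rng) -> np.ndarray:
    """Fold label per row; each class spread cyclically across folds."""
    assignment = np.empty(y.size, dtype=np.int64)
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def _grouped_auc(scores: np.ndarray, neg: np.ndarray, pos: np.ndarray):
    """AUC when scores take few values: columns are SNPs, rows are feature
    states; ``neg``/``pos`` hold held-out counts per state.  Midrank tie
    handling (each tied pair counts 1/2)."""
    order = np.argsort(scores, axis=0, kind="stable")
    neg_o = np.take_along_axis(neg, order, axis=0).astype(float)
    pos_o = np.take_along_axis(pos, order, axis=0).astype(float)
    cum_neg_below = np.cumsum(neg_o, axis=0) - neg_o
    wins = (pos_o * (cum_neg_below + 0.5 * neg_o)).sum(axis=0)
    n_neg = neg_o.sum(axis=0)
    n_pos = pos_o.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return wins / (n_neg * n_pos)


def cv_importance(
    data: DiscreteDataset,
    class_var: str,
    snp_vars=None,
    folds: int = 10,
    repeats: int = 3,
    seed: int = 0,
    alpha: float = 1.0,
) -> ImportanceRanking:
    """Repeated stratified k-fold single-SNP importance for one trait.

    For every SNP and fold, a single-feature Naive Bayes is fit on the
    training rows and the held-out rows are ranked by posterior; the AUC of
    that ranking (max over one-vs-one class pairs for multiclass traits) is
    averaged over folds x repeats.
    """
    if class_var not in data.columns:
        raise ValidationError(f"class variable {class_var!r} not in dataset")
    y = data.codes(class_var)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError(f"trait {class_var!r} has arity < 2")
    snps = list(snp_vars) if snp_vars is not None else [
        c for c in data.columns if c != class_var
    ]
    if not snps:
        raise ValidationError("no SNP columns to rank")
    min_class = min(int((y == c).sum()) for c in classes)
    if min_class < folds:
        logger.warning(
            "smallest class of %s has %d rows; reducing folds from %d",
            class_var, min_class, folds,
        )
        folds = max(2, min_class)
    X = np.stack([data.codes(s) for s in snps], axis=1)
    arity = data.arities(snps)
    max_r = int(arity.max())
    rng = np.random.default_rng(seed)
    pairs = [
        (a, b) for i, a in enumerate(classes) for b in classes[i + 1:]
    ]
    pair_sums = np.zeros((len(pairs), len(snps)))
    pair_counts = np.zeros((len(pairs), len(snps)))
    for _ in range(repeats):
        fold_of = _stratified_folds(y, folds, rng)
        for f in range(folds):
            train = fold_of != f
            test = ~train
            y_tr, y_te = y[train], y[test]
            X_tr, X_te = X[train], X[test]
            # train counts per (state, class, snp)
            counts = np.stack(
                [
                    np.stack(
                        [(X_tr[y_tr == c] == s).sum(axis=0)
                         for s in range(max_r)], axis=0
                    )
                    for c in classes
                ],
                axis=1,
            )  # (max_r, n_classes, n_snps)
            n_c = np.array([(y_tr == c).sum() for c in classes], dtype=float)
            cond = (counts + alpha) / (n_c[None, :, None] + alpha * arity[None, None, :])
            # held-out counts per (state, class, snp)
            tcounts = np.stack(
                [
                    np.stack(
                        [(X_te[y_te == c] == s).sum(axis=0)
                         for s in range(max_r)], axis=0
                    )
                    for c in classes
                ],
                axis=1,
            )
            for pi, (a, b) in enumerate(pairs):
                ia = int(np.flatnonzero(classes == a)[0])
                ib = int(np.flatnonzero(classes == b)[0])
                score = cond[:, ib, :] / (cond[:, ia, :] + cond[:, ib, :])
                auc = _grouped_auc(score, tcounts[:, ia, :], tcounts[:, ib, :])
                ok = np.isfinite(auc)
                pair_sums[pi, ok] += auc[ok]
                pair_counts[pi, ok] += 1
    with np.errstate(invalid="ignore"):
        pair_means = pair_sums / pair_counts
    folded = np.maximum(pair_means, 1.0 - pair_means)
    importance = np.nanmax(folded, axis=0)
    entries = sorted(
        zip(snps, importance), key=lambda e: (-e[1], e[0])
    )
    return ImportanceRanking(trait=class_var, subset_index=0, entries=entries)


def select_top_k(
    rankings: dict[tuple[str, int], ImportanceRanking], k: int = 20
) -> dict[int, list[str]]:
    """Pool the per-trait top-k lists within each subset (union, deduplicated,
    order of first appearance by subset ranking)."""
    selected: dict[int, list[str]] = {}
    for (trait, subset), ranking in sorted(rankings.items()):
        bucket = selected.setdefault(subset, [])
        for snp in ranking.top(k):
            if snp not in bucket:
                bucket.append(snp)
    return selected
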