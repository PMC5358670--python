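"""Stratified cross-validation and the four reported metrics.

Per fold: the discretization scheme is fit on the training split only,
the model is trained on the discretized training split, and the held-out
split is encoded through the *training* scheme before prediction — so no
information leaks from test to train.  Metrics per fold are AUC,
accuracy (percent), number of rules and number of distinct variables;
the summary reports the mean and the standard error of the mean
(sample standard deviation / sqrt(k)) across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from brl.data import ContinuousDataset
from brl.discretization import DEFAULT_LAMBDA, apply_scheme, ebd_fit_all
from brl.errors import ValidationError
from brl.rules import DEFAULT_ALPHA, RuleBase, parsimony, predict_dataset, tree_to_rules
from brl.search import DEFAULT_BEAM_WIDTH, DEFAULT_MAX_CONJ, gss_search, lss_search


@dataclass
class FoldResult:
    fold_index: int
    auc: float
    accuracy: float
    n_rules: int
    n_variables: int


@dataclass
class CvSummary:
    """Mean and SEM of each metric across folds."""

    mean_auc: float
    sem_auc: float
    mean_accuracy: float
    sem_accuracy: float
    mean_n_rules: float
    sem_n_rules: float
    mean_n_variables: float
    sem_n_variables: float
    folds: list[FoldResult]

    @staticmethod
    def from_folds(folds: list[FoldResult]) -> "CvSummary":
        def ms(xs):
            xs = np.asarray(xs, dtype=float)
            sem = float(xs.std(ddof=1) / np.sqrt(len(xs))) if len(xs) > 1 else 0.0
            return float(xs.mean()), sem

        ma, sa = ms([f.auc for f in folds])
        mc, sc = ms([f.accuracy for f in folds])
        mr, sr = ms([f.n_rules for f in folds])
        mv, sv = ms([f.n_variables for f in folds])
        return CvSummary(ma, sa, mc, sc, mr, sr, mv, sv, folds)


def stratified_folds(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition indices into k folds preserving class proportions.

    Within each class, indices are shuffled under ``seed`` and dealt
    round-robin to folds, so per-fold class counts differ by at most one
    instance from proportionality.  Deterministic given the seed.
    """
    labels = np.asarray(labels)
    m = len(labels)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > m:
        raise ValidationError(f"cannot make {k} folds from {m} instances")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[(offset + pos) % k].append(int(i))
        offset += len(idx)  # stagger so small classes don't pile on fold 0
    return [np.array(sorted(f), dtype=np.intp) for f in folds]


def auc_score(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute one half.

    ``labels`` are binary (1 = positive); ``scores`` are the predicted
    positive-class probabilities or any monotone score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: one class absent")
    ranks = rankdata(scores)  # average ranks handle ties -> half credit
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _macro_auc(probs: np.ndarray, y: np.ndarray, n_classes: int) -> float:
    """One-vs-rest macro-averaged AUC; reduces to plain AUC for 2 classes."""
    if n_classes == 2:
        return auc_score(probs[:, 1], y == 1)
    aucs = []
    for c in range(n_classes):
        pos = y == c
        if pos.all() or not pos.any():
            continue
        aucs.append(auc_score(probs[:, c], pos))
    if not aucs:
        raise ValidationError("AUC undefined on this fold")
    return float(np.mean(aucs))


def train_model(train: ContinuousDataset, method: str = "lss",
                max_conj: int = DEFAULT_MAX_CONJ, beam_width: int = DEFAULT_BEAM_WIDTH,
                lam: float = DEFAULT_LAMBDA, alpha: float = DEFAULT_ALPHA) -> RuleBase:
    """Discretize, search, and convert to a rule base in one step."""
    scheme = ebd_fit_all(train, lam=lam)
    disc = apply_scheme(scheme, train)
    search = {"gss": gss_search, "lss": lss_search}.get(method)
    if search is None:
        raise ValidationError(f"unknown method {method!r}; expected 'gss' or 'lss'")
    model = search(disc, max_conj=max_conj, beam_width=beam_width)
    return tree_to_rules(
        model.tree, disc, alpha=alpha, scheme=scheme,
        config={"method": method, "max_conj": max_conj, "beam_width": beam_width,
                "lambda": lam, "alpha": alpha},
    )


def run_cv(dataset: ContinuousDataset, method: str = "lss", *,
           max_conj: int = DEFAULT_MAX_CONJ, beam_width: int = DEFAULT_BEAM_WIDTH,
           lam: float = DEFAULT_LAMBDA, alpha: float = DEFAULT_ALPHA,
           k: int = 10, seed: int = 0) -> CvSummary:
    """Stratified k-fold cross-validation of one search method.

    Each fold refits the discretization scheme on its own training split.
    Folds whose training split contains a single class are skipped with a
    warning (recorded by the warnings machinery).
    """
    codes, class_values = dataset.class_codes()
    folds = stratified_folds(codes, k, seed)
    results = []
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(dataset.m, dtype=bool)
        train_mask[test_idx] = False
        train_idx = np.flatnonzero(train_mask)
        if len(np.unique(codes[train_idx])) < 2:
            warnings.warn(f"fold {fi}: single-class training split; skipped")
            continue
        train = ContinuousDataset(
            dataset.values[train_idx], dataset.feature_names,
            [dataset.class_labels[i] for i in train_idx], dataset.class_name)
        test = ContinuousDataset(
            dataset.values[test_idx], dataset.feature_names,
            [dataset.class_labels[i] for i in test_idx], dataset.class_name)
        rulebase = train_model(train, method, max_conj, beam_width, lam, alpha)
        preds, probs = predict_dataset(rulebase, test)
        y = codes[test_idx]
        accuracy = 100.0 * float(np.mean(preds == y))
        try:
            auc = _macro_auc(probs, y, len(class_values))
        except ValidationError:
            warnings.warn(f"fold {fi}: AUC undefined (one class absent in test split)")
            continue
        n_rules, n_vars = parsimony(rulebase)
        results.append(FoldResult(fi, auc, accuracy, n_rules, n_vars))
    if not results:
        raise ValidationError("no fold produced a usable result")
    return CvSummary.from_folds(results)
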