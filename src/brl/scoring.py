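"""K2 Bayesian score over CPT-tree leaves.

The score of a model is the log marginal likelihood of the target under a
Dirichlet(1) parameter prior, factored over the leaves of the CPT decision
tree (each leaf plays the role of one parent configuration):

    score(leaf j) = log [ (r_t - 1)! / (N_j + r_t - 1)!  *  prod_k N_jk! ]

with ``r_t`` the target arity, ``N_jk`` the count of class ``k`` in leaf
``j`` and ``N_j = sum_k N_jk``.  Computed via log-gamma so it never
overflows.  A uniform structure prior is assumed: models are compared by
marginal likelihood alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from brl.errors import InternalError, ValidationError


@dataclass(frozen=True)
class LeafCounts:
    """Class-count vector of one leaf: ``counts[k] = N_jk``."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValidationError("leaf counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts)


def k2_leaf_logscore_from_counts(counts) -> float:
    """Log K2 contribution of one leaf given its raw class-count vector.

    An empty leaf contributes ``log 1 = 0``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.min(initial=0.0) < 0:
        raise ValidationError("leaf counts must be non-negative")
    r_t = counts.shape[-1]
    n = counts.sum(axis=-1)
    return gammaln(r_t) - gammaln(n + r_t) + gammaln(counts + 1.0).sum(axis=-1)


def k2_leaf_logscore(leaf: LeafCounts, target_arity: int) -> float:
    """Log K2 contribution of one leaf."""
    if target_arity < 2:
        raise ValidationError("target arity must be >= 2")
    if len(leaf.counts) != target_arity:
        raise ValidationError("counts length must equal target arity")
    return float(k2_leaf_logscore_from_counts(leaf.counts))


def k2_model_logscore(leaves, target_arity: int, m: int | None = None) -> float:
    """Sum of leaf log scores for a set of leaves partitioning the data.

    Parameters
    ----------
    leaves : iterable of LeafCounts or count vectors
    target_arity : int
    m : int, optional
        Expected total instance count; if given, coverage is checked
        (``sum_j N_j == m``) and a violation raises ``InternalError``.
    """
    total_n = 0
    score = 0.0
    for leaf in leaves:
        counts = leaf.counts if isinstance(leaf, LeafCounts) else tuple(leaf)
        if len(counts) != target_arity:
            raise ValidationError("counts length must equal target arity")
        total_n += sum(counts)
        score += float(k2_leaf_logscore_from_counts(counts))
    if m is not None and total_n != m:
        raise InternalError(f"leaves cover {total_n} instances, expected {m}")
    return score
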