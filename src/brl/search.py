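"""Structure search over target-centric Bayesian networks.

Two regimes share one machinery:

``gss_search`` (global structure)
    best-first beam search over *parent sets* of the target; each model's
    CPT is the fully expanded decision tree over its parents, with one
    leaf per joint parent-value assignment (``prod r_i`` leaves).

``lss_search`` (local structure)
    best-first beam search over *decision-tree CPTs*: starting from
    singleton models (one complete split of a single variable), leaves are
    specialized one at a time by binary or complete splits of a new
    variable, so contexts whose class distributions do not differ are
    simply never split apart — the tree encodes context-specific
    independence and yields fewer rules than the global form.

Both are scored by the K2 marginal likelihood (``brl.scoring``), are fully
deterministic, keep at most ``beam_width`` candidate models, and cap the
number of distinct variables per model at ``max_conj``.

Specialization cost is kept proportional to the data, not to the number of
candidate splits: for each (leaf, variable) pair a single value-by-class
count table is accumulated from the matching instances, and every binary
and complete split is then scored from that table by one matrix product —
instances are only repartitioned for the winning split.
"""

from __future__ import annotations

import bisect
import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from brl.data import DiscreteDataset
from brl.errors import InternalError, ValidationError
from brl.scoring import k2_leaf_logscore_from_counts

DEFAULT_MAX_CONJ = 8
DEFAULT_BEAM_WIDTH = 1000

# A path is the ordered conjunction of (variable, value-code block) pairs
# from the root to a leaf; blocks are sorted tuples of codes.
Path = tuple[tuple[int, tuple[int, ...]], ...]


@dataclass(frozen=True)
class Leaf:
    """One leaf of a CPT tree: its path, class counts and matching instances."""

    path: Path
    counts: tuple[int, ...]
    logscore: float
    indices: np.ndarray | None = None

    @property
    def total(self) -> int:
        return int(sum(self.counts))


@dataclass
class CptTree:
    """Decision tree over parent-variable value partitions; leaves hold class counts.

    ``structure_kind`` is ``"global"`` (fully expanded over the parent
    set) or ``"local"`` (merged, context-specific).  Leaves partition the
    joint value space of the used variables (mutually exclusive and
    exhaustive), which is what makes the derived rule base ME&E.
    """

    leaves: list[Leaf]
    structure_kind: str
    target_arity: int
    _ckey: frozenset | None = field(default=None, repr=False, compare=False)

    @property
    def used_variables(self) -> frozenset[int]:
        return frozenset(v for leaf in self.leaves for v, _ in leaf.path)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def canonical_key(self) -> frozenset:
        """Structure identity: the set of leaf antecedents, order-free."""
        if self._ckey is None:
            self._ckey = frozenset(frozenset(leaf.path) for leaf in self.leaves)
        return self._ckey

    def logscore(self) -> float:
        return float(sum(leaf.logscore for leaf in self.leaves))

    def validate(self, data: DiscreteDataset) -> None:
        """Check the partition invariants against a dataset (test helper).

        Every instance must match exactly one leaf, no variable may repeat
        on a path, and leaf counts must reproduce a full scan.
        """
        hits = np.zeros(data.m, dtype=int)
        for leaf in self.leaves:
            vars_on_path = [v for v, _ in leaf.path]
            if len(vars_on_path) != len(set(vars_on_path)):
                raise InternalError("variable repeats on a root-to-leaf path")
            mask = _match_mask(data, leaf.path)
            hits += mask
            counts = np.bincount(data.target_codes[mask], minlength=data.target_arity)
            if tuple(counts) != tuple(leaf.counts):
                raise InternalError("leaf counts disagree with full scan")
        if not np.all(hits == 1):
            raise InternalError("leaves do not partition the instances")


@dataclass
class CandidateModel:
    """A scored tree plus the per-model set of variables already explored."""

    tree: CptTree
    logscore: float
    explored: frozenset[int] = frozenset()

    @property
    def used_variables(self) -> frozenset[int]:
        return self.tree.used_variables

    @property
    def n_vars(self) -> int:
        return len(self.tree.used_variables)

    @property
    def n_leaves(self) -> int:
        return self.tree.n_leaves

    def structure_key(self):
        return self.tree.canonical_key()


class Beam:
    """Capacity-bounded, score-ordered store of structurally unique models.

    Items expose ``logscore``, ``n_vars``, ``n_leaves`` and
    ``structure_key()`` (``CandidateModel`` does; the global search uses a
    lighter parent-set item).  Ordering: higher score first; ties broken
    toward fewer used variables, then fewer leaves, then earlier
    insertion — a deterministic preference for parsimony.
    """

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValidationError("beam capacity must be >= 1")
        self.capacity = capacity
        self._keys: list[tuple] = []
        self._models: list = []
        self._present: set = set()
        self._counter = itertools.count()

    def _key(self, model) -> tuple:
        return (-model.logscore, model.n_vars, model.n_leaves, next(self._counter))

    def push(self, model) -> bool:
        """Insert unless a structurally identical model is present; evict the
        worst member when over capacity.  Returns True if inserted and kept."""
        ck = model.structure_key()
        if ck in self._present:
            return False
        key = self._key(model)
        pos = bisect.bisect_left(self._keys, key)
        self._keys.insert(pos, key)
        self._models.insert(pos, model)
        self._present.add(ck)
        if len(self._models) > self.capacity:
            worst = self._models.pop()
            self._keys.pop()
            self._present.discard(worst.structure_key())
            return worst is not model
        return True

    def pop_best(self):
        if not self._models:
            raise InternalError("pop from an empty beam")
        self._keys.pop(0)
        model = self._models.pop(0)
        self._present.discard(model.structure_key())
        return model

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self):
        return iter(self._models)


def enumerate_binary_splits(arity: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All partitions of ``{0..arity-1}`` into two non-empty blocks.

    There are ``2^(arity-1) - 1`` of them; the block containing code 0
    comes first.  Arity below 2 admits no split.
    """
    if arity < 2:
        return []
    rest = list(range(1, arity))
    out = []
    # subsets of `rest` joined to code 0; the complement must be non-empty
    for mask in range(2 ** len(rest) - 1):
        block0 = (0, *[rest[i] for i in range(len(rest)) if mask >> i & 1])
        block1 = tuple(v for v in rest if v not in block0)
        out.append((block0, block1))
    return out


def enumerate_complete_split(arity: int) -> tuple[tuple[int, ...], ...]:
    """One singleton block per value code, in code order."""
    if arity < 2:
        raise ValidationError("complete split requires arity >= 2")
    return tuple((v,) for v in range(arity))


def _split_partitions(arity: int) -> list[tuple[tuple[int, ...], ...]]:
    """Candidate partitions tried at a leaf: all binary splits, then the
    complete split (identical to the sole binary split when arity is 2)."""
    parts: list[tuple[tuple[int, ...], ...]] = list(enumerate_binary_splits(arity))
    if arity > 2:
        parts.append(enumerate_complete_split(arity))
    return parts


@lru_cache(maxsize=None)
def _partition_tables(arity: int):
    """Flattened block-membership masks for all candidate partitions.

    Returns (partitions, masks, starts) where ``masks`` is a boolean
    (total blocks, arity) matrix and ``starts`` delimits each partition's
    blocks, so all splits are scored with one matrix product.
    """
    parts = _split_partitions(arity)
    masks = []
    starts = [0]
    for part in parts:
        for block in part:
            row = np.zeros(arity, dtype=float)
            row[list(block)] = 1.0
            masks.append(row)
        starts.append(len(masks))
    return parts, np.array(masks), np.array(starts[:-1], dtype=np.intp)


def count_matches(data: DiscreteDataset, antecedent) -> np.ndarray:
    """Per-class counts of instances satisfying every (variable, value-set) conjunct.

    A vectorized full scan; an empty antecedent yields the class marginals
    and an empty value-set yields the zero vector.
    """
    mask = np.ones(data.m, dtype=bool)
    for var, codes in antecedent:
        if not 0 <= var < data.n:
            raise ValidationError(f"variable index {var} out of range")
        mask &= np.isin(data.codes[:, var], list(codes))
    return np.bincount(data.target_codes[mask], minlength=data.target_arity)


def _match_mask(data: DiscreteDataset, path: Path) -> np.ndarray:
    mask = np.ones(data.m, dtype=bool)
    for var, codes in path:
        mask &= np.isin(data.codes[:, var], list(codes))
    return mask


def _make_leaf(path: Path, indices: np.ndarray, data: DiscreteDataset) -> Leaf:
    counts = np.bincount(data.target_codes[indices], minlength=data.target_arity)
    return Leaf(
        path=path,
        counts=tuple(int(c) for c in counts),
        logscore=float(k2_leaf_logscore_from_counts(counts)),
        indices=indices,
    )


def root_model(data: DiscreteDataset, kind: str = "local") -> CandidateModel:
    """The trivial model: a single leaf holding all instances (no parents)."""
    leaf = _make_leaf((), np.arange(data.m), data)
    tree = CptTree([leaf], kind, data.target_arity)
    return CandidateModel(tree, tree.logscore())


def _singleton_model(data: DiscreteDataset, var: int) -> CandidateModel:
    """Complete split of one variable at the root."""
    leaves = []
    for code in range(data.arities[var]):
        idx = np.flatnonzero(data.codes[:, var] == code)
        leaves.append(_make_leaf(((var, (code,)),), idx, data))
    tree = CptTree(leaves, "local", data.target_arity)
    return CandidateModel(tree, tree.logscore(), explored=frozenset({var}))


def specialize_leaf(model: CandidateModel, leaf_index: int, variable: int,
                    data: DiscreteDataset, stats: dict | None = None) -> CandidateModel:
    """Best model obtained by splitting one leaf on one variable.

    Every binary split plus the complete split of ``variable`` is
    evaluated at the leaf from a single value-by-class count table; the
    highest-scoring resulting model is returned regardless of whether it
    improves on ``model`` (acceptance is the caller's decision).  Ties
    prefer the earliest-enumerated split, i.e. fewer branches.
    """
    leaf = model.tree.leaves[leaf_index]
    if any(v == variable for v, _ in leaf.path):
        raise ValidationError(f"variable {variable} already on the leaf's path")
    if leaf.indices is None:
        raise InternalError("leaf carries no instance indices; cannot specialize")
    arity = data.arities[variable]
    k = data.target_arity
    col = data.codes[leaf.indices, variable]
    table = np.bincount(col * k + data.target_codes[leaf.indices],
                        minlength=arity * k).reshape(arity, k).astype(float)
    parts, masks, starts = _partition_tables(arity)
    if stats is not None:
        stats["specializations"] = stats.get("specializations", 0) + len(parts)
    block_counts = masks @ table  # (total blocks, k)
    block_scores = (gammaln(k) - gammaln(block_counts.sum(axis=1) + k)
                    + gammaln(block_counts + 1.0).sum(axis=1))
    part_scores = np.add.reduceat(block_scores, starts)
    best_p = int(np.argmax(part_scores))
    partition = parts[best_p]
    new_leaves = []
    for block in partition:
        idx = leaf.indices[np.isin(col, block)]
        new_leaves.append(_make_leaf(leaf.path + ((variable, block),), idx, data))
    score = model.logscore - leaf.logscore + float(part_scores[best_p])
    leaves = list(model.tree.leaves)
    leaves[leaf_index:leaf_index + 1] = new_leaves
    tree = CptTree(leaves, model.tree.structure_kind, data.target_arity)
    return CandidateModel(tree, score, explored=model.explored | {variable})


def _eligible_variables(data: DiscreteDataset) -> list[int]:
    # arity-1 variables carry no information and admit no split
    return [i for i in range(data.n) if data.arities[i] >= 2]


def _better(a, b) -> bool:
    return (-a.logscore, a.n_vars, a.n_leaves) < (-b.logscore, b.n_vars, b.n_leaves)


def lss_search(data: DiscreteDataset, max_conj: int = DEFAULT_MAX_CONJ,
               beam_width: int = DEFAULT_BEAM_WIDTH,
               stats: dict | None = None) -> CandidateModel:
    """Bayesian local structure search.

    The working beam is seeded with one singleton model per predictor
    (complete split at the root).  Models are popped best-first; one
    specialization sweep tries every variable at every leaf it is not
    already conditioned on (``specialize_leaf``), registering the best
    model ever seen, and only the single best specialization of the sweep
    re-enters the beam — and only if its score strictly improves on the
    model it came from.  Scores along any queue chain therefore increase
    strictly, each popped model costs one O(n * leaves * m * r) sweep,
    and the search terminates deterministically.
    """
    if max_conj < 1 or beam_width < 1:
        raise ValidationError("max_conj and beam_width must be >= 1")
    variables = _eligible_variables(data)
    if not variables:
        return root_model(data)
    beam = Beam(beam_width)
    best: CandidateModel | None = None
    for var in variables:
        model = _singleton_model(data, var)
        if best is None or _better(model, best):
            best = model
        beam.push(model)
    while len(beam):
        model = beam.pop_best()
        sweep_best: CandidateModel | None = None
        for var in variables:
            on_path = [any(v == var for v, _ in leaf.path)
                       for leaf in model.tree.leaves]
            if (var not in model.used_variables
                    and len(model.used_variables) >= max_conj):
                continue
            for leaf_index in range(model.tree.n_leaves):
                if on_path[leaf_index]:
                    continue
                cand = specialize_leaf(model, leaf_index, var, data, stats=stats)
                if _better(cand, best):
                    best = cand
                if sweep_best is None or _better(cand, sweep_best):
                    sweep_best = cand
        if sweep_best is not None and sweep_best.logscore > model.logscore:
            beam.push(sweep_best)
    return best


def expanded_tree(data: DiscreteDataset, parents) -> CptTree:
    """Fully expanded CPT tree over a parent set: one leaf per joint assignment."""
    parents = sorted(parents)
    if not parents:
        return CptTree([_make_leaf((), np.arange(data.m), data)], "global",
                       data.target_arity)
    arities = [data.arities[v] for v in parents]
    k = data.target_arity
    n_cells = int(np.prod(arities))
    joint = np.zeros(data.m, dtype=np.intp)
    for v, r in zip(parents, arities):
        joint = joint * r + data.codes[:, v]
    counts = np.bincount(joint * k + data.target_codes,
                         minlength=n_cells * k).reshape(n_cells, k)
    scores = k2_leaf_logscore_from_counts(counts.astype(float))
    leaves = []
    for cell, assignment in enumerate(itertools.product(*[range(r) for r in arities])):
        path = tuple((v, (c,)) for v, c in zip(parents, assignment))
        leaves.append(Leaf(path=path, counts=tuple(int(c) for c in counts[cell]),
                           logscore=float(scores[cell])))
    return CptTree(leaves, "global", data.target_arity)


@dataclass
class _ParentSetModel:
    """Lightweight beam item for the global search: a scored parent set.

    The fully expanded tree is only materialized (``expanded_tree``) for
    the model finally returned.
    """

    parents: frozenset[int]
    logscore: float
    n_leaves: int

    @property
    def n_vars(self) -> int:
        return len(self.parents)

    def structure_key(self):
        return self.parents


def _parent_set_score(data: DiscreteDataset, parents) -> tuple[float, int]:
    """K2 score and leaf count of the fully expanded CPT, without building it."""
    parents = sorted(parents)
    if not parents:
        counts = np.bincount(data.target_codes, minlength=data.target_arity)
        return float(k2_leaf_logscore_from_counts(counts.astype(float))), 1
    arities = [data.arities[v] for v in parents]
    k = data.target_arity
    n_cells = int(np.prod(arities))
    joint = np.zeros(data.m, dtype=np.intp)
    for v, r in zip(parents, arities):
        joint = joint * r + data.codes[:, v]
    # empty cells contribute log 1 = 0, so only occupied cells are counted;
    # the dense bincount is used while the cell space is comparable to m
    if n_cells <= 16 * data.m:
        counts = np.bincount(joint * k + data.target_codes,
                             minlength=n_cells * k).reshape(n_cells, k)
        occupied = counts[counts.sum(axis=1) > 0].astype(float)
    else:
        _, inverse = np.unique(joint, return_inverse=True)
        occupied = np.bincount(
            inverse * k + data.target_codes,
            minlength=(int(inverse.max()) + 1) * k).reshape(-1, k).astype(float)
    return float(k2_leaf_logscore_from_counts(occupied).sum()), n_cells


def gss_search(data: DiscreteDataset, max_conj: int = DEFAULT_MAX_CONJ,
               beam_width: int = DEFAULT_BEAM_WIDTH,
               stats: dict | None = None) -> CandidateModel:
    """Global structure search over parent sets with fully expanded CPTs.

    Best-first beam over parent sets, seeded with all single-parent
    models.  Scored parent sets are cached globally (shared across the
    whole beam) so no structure is ever evaluated twice.  Popping a model
    scores every one-parent extension and queues the best of them for
    further growth (parent sets strictly grow, so every chain ends at
    ``max_conj``).  Returns the highest-scoring model ever seen, as a
    fully expanded tree.
    """
    if max_conj < 1 or beam_width < 1:
        raise ValidationError("max_conj and beam_width must be >= 1")
    variables = _eligible_variables(data)
    if not variables:
        return root_model(data, kind="global")

    scored: dict[frozenset, _ParentSetModel] = {}

    def model_for(parent_set: frozenset) -> _ParentSetModel:
        if parent_set not in scored:
            if stats is not None:
                stats["parent_sets"] = stats.get("parent_sets", 0) + 1
            score, n_leaves = _parent_set_score(data, parent_set)
            scored[parent_set] = _ParentSetModel(parent_set, score, n_leaves)
        return scored[parent_set]

    beam = Beam(beam_width)
    best: _ParentSetModel | None = None
    for var in variables:
        model = model_for(frozenset({var}))
        if best is None or _better(model, best):
            best = model
        beam.push(model)
    while len(beam):
        model = beam.pop_best()
        if len(model.parents) >= max_conj:
            continue
        sweep_best: _ParentSetModel | None = None
        for var in variables:
            if var in model.parents:
                continue
            cand = model_for(model.parents | {var})
            if _better(cand, best):
                best = cand
            if sweep_best is None or _better(cand, sweep_best):
                sweep_best = cand
        # the best extension continues the chain even without an immediate
        # score gain: parent sets strictly grow, so chains end at max_conj
        if sweep_best is not None:
            beam.push(sweep_best)
    tree = expanded_tree(data, best.parents)
    return CandidateModel(tree, best.logscore, explored=best.parents)
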