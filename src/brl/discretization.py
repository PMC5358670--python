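"""Supervised Bayesian discretization (EBD).

Each continuous feature is discretized against the class by maximizing a
Bayesian score over cut-point sets:

* a prior over cut-point sets that is geometric in the number of
  cut-points ``c`` — parameterized so that the expected count equals
  ``lambda``: ``p (1 - p)^c`` with ``p = 1 / (1 + lambda)`` — and uniform
  over the ``C(B, c)`` ways of placing ``c`` cuts among the ``B``
  candidate boundaries.  The combinatorial factor is the multiplicity
  correction that keeps the free choice of cut *positions* from acting as
  an unpenalized degree of freedom; without it the maximum over the
  ``2^B`` placements capitalizes on chance and shreds class-independent
  features into many spurious intervals;
* per interval, the multinomial-Dirichlet marginal likelihood of the class
  labels falling in that interval, with a uniform Dirichlet(1) prior —
  exactly the K2 leaf evidence used elsewhere in the package.

Candidate cut-points are midpoints between consecutive *distinct* sorted
values across which the class composition changes; equal values can never
be separated.  The optimum is found by dynamic programming over candidate
boundaries, which is exact for this additive-per-interval score.

Intervals are right-closed: a value ``v`` maps to code ``j`` with
``c_j < v <= c_{j+1}`` (``c_0 = -inf``, ``c_{k+1} = +inf``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from brl.data import ContinuousDataset, DiscreteDataset
from brl.errors import ConfigurationError, ValidationError
from brl.scoring import k2_leaf_logscore_from_counts

DEFAULT_LAMBDA = 0.5
DEFAULT_MAX_INTERVALS = 16


@dataclass
class DiscretizationScheme:
    """Per-variable ordered cut-points mapping continuous values to codes.

    A variable with ``k`` cut-points has arity ``k + 1`` even if some
    interval is empty in a particular dataset, so that a scheme learned on
    a training fold applies unchanged to held-out data.
    """

    cutpoints: dict[str, list[float]]
    lam: float = DEFAULT_LAMBDA
    class_values: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValidationError("lambda must be positive")
        for name, cuts in self.cutpoints.items():
            if any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ValidationError(f"cut-points for {name!r} not strictly increasing")

    def arity(self, feature: str) -> int:
        return len(self.cutpoints[feature]) + 1

    def interval_labels(self, feature: str) -> list[str]:
        cuts = self.cutpoints[feature]
        if not cuts:
            return ["(-inf, inf)"]
        edges = [float("-inf"), *cuts, float("inf")]
        labels = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            left = "(-inf" if lo == float("-inf") else f"({lo:g}"
            right = "inf)" if hi == float("inf") else f"{hi:g}]"
            labels.append(f"{left}, {right}")
        return labels

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "prior": "p(1-p)^c / C(B, c) with p = 1/(1+lambda): geometric over the cut-point count c, uniform over placements among the B candidate boundaries",
            "interval_convention": "right-closed",
            "class_values": list(self.class_values),
            "cutpoints": {k: list(map(float, v)) for k, v in self.cutpoints.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationScheme":
        return cls(
            cutpoints={k: list(v) for k, v in d["cutpoints"].items()},
            lam=d["lambda"],
            class_values=d.get("class_values", []),
        )


def _log_prior_per_cutpoint(lam: float) -> tuple[float, float]:
    """Return (log p, log(1-p)) of the geometric prior with mean ``lam`` cut-points."""
    p = 1.0 / (1.0 + lam)
    return math.log(p), math.log1p(-p)


def ebd_score(cutpoints: list[float], values: np.ndarray, labels: np.ndarray,
              lam: float, n_classes: int | None = None) -> float:
    """Log Bayesian score of an explicit cut-point set on (values, labels).

    Prior term — geometric in the cut-point count, uniform over the
    ``C(B, c)`` placements among the data's candidate boundaries — plus
    the sum of Dirichlet(1)-multinomial log marginal likelihoods of the
    class within each induced interval.  ``ebd_fit`` maximizes this same
    quantity by dynamic programming.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=np.intp)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    log_p, log_q = _log_prior_per_cutpoint(lam)
    n_candidates = len(_candidate_boundaries(values, labels)[0])
    c = len(cutpoints)
    score = log_p + c * log_q - _log_binomial(n_candidates, c)
    codes = np.searchsorted(np.asarray(cutpoints, dtype=float), values, side="left")
    for j in range(len(cutpoints) + 1):
        counts = np.bincount(labels[codes == j], minlength=n_classes)
        score += k2_leaf_logscore_from_counts(counts)
    return score


def _log_binomial(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf  # no way to place k cuts among n candidates
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _candidate_boundaries(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate cut-points and per-run class counts.

    Sorts the pairs, groups equal values into runs, and proposes the
    midpoint between adjacent runs whenever the two runs are not both pure
    in the same single class (a boundary between such runs can never help).

    Returns
    -------
    midpoints : (B,) array of candidate cut-points
    run_counts : (R, K) per-run class count matrix, runs in value order,
        together with ``boundary_after`` indices mapping each candidate to
        the run it follows — flattened here into cumulative counts for the
        DP, so the second element is the (B+1, K) cumulative class-count
        matrix at the candidate boundaries (prefix sums including ends).
    """
    order = np.argsort(values, kind="stable")
    sv, sl = values[order], labels[order]
    n_classes = int(labels.max()) + 1
    # runs of equal values
    run_starts = np.flatnonzero(np.r_[True, sv[1:] != sv[:-1]])
    run_ends = np.r_[run_starts[1:], len(sv)]
    n_runs = len(run_starts)
    run_counts = np.zeros((n_runs, n_classes), dtype=np.int64)
    for r in range(n_runs):
        run_counts[r] = np.bincount(sl[run_starts[r]:run_ends[r]], minlength=n_classes)
    mids, cut_runs = [], []
    for r in range(n_runs - 1):
        a, b = run_counts[r], run_counts[r + 1]
        same_pure = (
            np.count_nonzero(a) == 1
            and np.count_nonzero(b) == 1
            and np.argmax(a) == np.argmax(b)
        )
        if not same_pure:
            mids.append((sv[run_ends[r] - 1] + sv[run_starts[r + 1]]) / 2.0)
            cut_runs.append(r)
    # cumulative class counts at segment edges: segment between consecutive
    # candidates aggregates the runs it spans
    cum = np.zeros((len(mids) + 2, n_classes), dtype=np.int64)
    run_cum = np.vstack([np.zeros(n_classes, dtype=np.int64), np.cumsum(run_counts, axis=0)])
    edges = [0, *[r + 1 for r in cut_runs], n_runs]
    for i, e in enumerate(edges):
        cum[i] = run_cum[e]
    return np.asarray(mids), cum


def ebd_fit(values, labels, lam: float = DEFAULT_LAMBDA,
            max_intervals: int = DEFAULT_MAX_INTERVALS) -> list[float]:
    """Fit EBD cut-points for one feature against the class.

    Dynamic programming over candidate boundaries: ``best[j]`` is the best
    log evidence (likelihood plus per-cut-point prior factors) of a
    segmentation of the first ``j`` segments.  ``max_intervals`` caps the
    number of intervals as a guard; the geometric prior already favors few
    cut-points.

    Returns the ordered cut-point list (possibly empty).  Constant inputs
    yield no candidates and hence ``[]``.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=np.intp).ravel()
    if values.shape != labels.shape:
        raise ValidationError("values and labels must have equal length")
    if len(values) < 2:
        raise ValidationError("need at least 2 instances")
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least 2 classes among labels")
    if max_intervals < 1:
        raise ValidationError("max_intervals must be >= 1")

    mids, cum = _candidate_boundaries(values, labels)
    n_seg = len(mids) + 1  # atomic segments delimited by candidates
    if n_seg == 1:
        return []
    _, log_q = _log_prior_per_cutpoint(lam)

    # seg_ll[i][j]: log marginal likelihood of merged segments i..j-1
    # (interval spanning candidate i-1 .. candidate j-1)
    seg_ll = np.empty((n_seg, n_seg + 1))
    for i in range(n_seg):
        for j in range(i + 1, n_seg + 1):
            seg_ll[i, j] = k2_leaf_logscore_from_counts(cum[j] - cum[i])

    NEG = -np.inf
    # dp[j][t]: best score of segments 0..j-1 using t intervals
    dp = np.full((n_seg + 1, max_intervals + 1), NEG)
    back = np.full((n_seg + 1, max_intervals + 1), -1, dtype=np.intp)
    dp[0, 0] = 0.0
    for j in range(1, n_seg + 1):
        for t in range(1, min(j, max_intervals) + 1):
            cand = dp[:j, t - 1] + seg_ll[:j, j]
            i = int(np.argmax(cand))
            dp[j, t] = cand[i]
            back[j, t] = i
    # total score: dp + prior over (t-1) cut-points placed among the
    # candidates (the constant log p is omitted from the comparison)
    n_candidates = n_seg - 1
    max_t = min(max_intervals, n_candidates + 1)
    ts = np.arange(max_t)
    totals = dp[n_seg, 1:max_t + 1] + ts * log_q - np.array(
        [_log_binomial(n_candidates, int(t)) for t in ts])
    t_best = int(np.argmax(totals)) + 1
    # trace back boundary positions
    cuts, j, t = [], n_seg, t_best
    while t > 0:
        i = int(back[j, t])
        if i > 0:
            cuts.append(mids[i - 1])
        j, t = i, t - 1
    return sorted(float(c) for c in cuts)


def ebd_fit_all(dataset: ContinuousDataset, lam: float = DEFAULT_LAMBDA,
                max_intervals: int = DEFAULT_MAX_INTERVALS) -> DiscretizationScheme:
    """Fit EBD independently per feature of a continuous dataset."""
    class_codes, class_values = dataset.class_codes()
    cutpoints = {}
    for j, name in enumerate(dataset.feature_names):
        cutpoints[name] = ebd_fit(dataset.values[:, j], class_codes, lam, max_intervals)
    return DiscretizationScheme(cutpoints, lam=lam, class_values=class_values)


def apply_scheme(scheme: DiscretizationScheme, dataset: ContinuousDataset) -> DiscreteDataset:
    """Encode a continuous dataset through a discretization scheme.

    Values map to right-closed intervals; out-of-range held-out values fall
    into the open outer intervals, so codes are always valid.
    """
    for name in dataset.feature_names:
        if name not in scheme.cutpoints:
            raise ConfigurationError(f"scheme has no cut-points for feature {name!r}")
    m, n = dataset.values.shape
    codes = np.empty((m, n), dtype=np.intp)
    arities, value_labels = [], []
    for j, name in enumerate(dataset.feature_names):
        cuts = np.asarray(scheme.cutpoints[name], dtype=float)
        codes[:, j] = np.searchsorted(cuts, dataset.values[:, j], side="left")
        arities.append(len(cuts) + 1)
        value_labels.append(scheme.interval_labels(name))
    if scheme.class_values:
        class_values = list(scheme.class_values)
        lut = {lbl: k for k, lbl in enumerate(class_values)}
        try:
            target = np.array([lut[lbl] for lbl in dataset.class_labels], dtype=np.intp)
        except KeyError as e:
            raise ValidationError(f"unknown class label {e.args[0]!r} for this scheme") from e
    else:
        target, class_values = dataset.class_codes()
    return DiscreteDataset(
        codes=codes,
        arities=arities,
        value_labels=value_labels,
        target_codes=target,
        target_arity=max(2, len(class_values)),
        feature_names=list(dataset.feature_names),
        class_values=class_values,
    )
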