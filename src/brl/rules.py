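"""Probabilistic IF-THEN rules derived from a learned CPT tree.

Each leaf of the tree becomes one rule: the antecedent is the conjunction
of (variable, value-set) constraints along the root-to-leaf path, and the
consequent is the predicted class with its smoothed posterior.  With
smoothing factor ``alpha`` (default 1):

    posterior probability = (TP + alpha) / ((TP + alpha) + (FP + alpha))
    posterior odds        = (TP + alpha) / (FP + alpha)

where TP is the count of training instances matching the antecedent with
the predicted class and FP the count matching with any other class.  The
rule base inherits mutual exclusivity and exhaustiveness from the leaf
partition: every instance matches exactly one rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from brl.data import ContinuousDataset, DiscreteDataset
from brl.discretization import DiscretizationScheme, apply_scheme
from brl.errors import ValidationError
from brl.search import CptTree, Leaf

DEFAULT_ALPHA = 1.0


@dataclass
class Rule:
    """One IF-THEN rule with its training evidence and smoothed posterior."""

    antecedent: tuple[tuple[int, tuple[int, ...]], ...]
    predicted_class: int
    tp: int
    fp: int
    alpha: float
    class_distribution: tuple[float, ...]
    raw_counts: tuple[int, ...]

    @property
    def posterior_probability(self) -> float:
        return (self.tp + self.alpha) / ((self.tp + self.alpha) + (self.fp + self.alpha))

    @property
    def posterior_odds(self) -> float:
        return (self.tp + self.alpha) / (self.fp + self.alpha)

    def matches(self, codes: np.ndarray) -> bool:
        """Whether a full discrete instance (1-D code vector) satisfies the antecedent."""
        return all(int(codes[var]) in block for var, block in self.antecedent)


@dataclass
class RuleBase:
    """Ordered, mutually exclusive and exhaustive rule list plus its provenance.

    Carries the discretization scheme so that continuous test instances
    can be encoded exactly as the training fold was, the model log score,
    and enough naming metadata to render human-readable rules.
    """

    rules: list[Rule]
    scheme: DiscretizationScheme | None
    model_logscore: float
    feature_names: list[str]
    value_labels: list[list[str]]
    class_values: list
    majority_class: int
    structure_kind: str = "local"
    alpha: float = DEFAULT_ALPHA
    config: dict = field(default_factory=dict)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def used_variables(self) -> set[int]:
        return {v for rule in self.rules for v, _ in rule.antecedent}


def tree_to_rules(tree: CptTree, data: DiscreteDataset, alpha: float = DEFAULT_ALPHA,
                  scheme: DiscretizationScheme | None = None,
                  config: dict | None = None) -> RuleBase:
    """Convert a CPT tree into a rule base against its training data.

    One rule per leaf, including leaves with no training evidence (their
    smoothed distribution is uniform and their prediction falls back to
    the training majority class).  Rules are ordered by posterior odds
    descending for readability; order has no semantic effect.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be positive")
    majority = data.majority_class()
    rules = []
    for leaf in tree.leaves:
        rules.append(_leaf_to_rule(leaf, alpha, majority, data.target_arity))
    rules.sort(key=lambda r: (-r.posterior_odds, r.antecedent))
    return RuleBase(
        rules=rules,
        scheme=scheme,
        model_logscore=tree.logscore(),
        feature_names=list(data.feature_names),
        value_labels=[list(v) for v in data.value_labels],
        class_values=list(data.class_values) or list(range(data.target_arity)),
        majority_class=majority,
        structure_kind=tree.structure_kind,
        alpha=alpha,
        config=dict(config or {}),
    )


def _leaf_to_rule(leaf: Leaf, alpha: float, majority: int, target_arity: int) -> Rule:
    counts = np.asarray(leaf.counts, dtype=float)
    smoothed = counts + alpha
    dist = smoothed / smoothed.sum()
    winners = np.flatnonzero(counts == counts.max())
    # tie in the class distribution: predict the training majority class
    if len(winners) == 1:
        predicted = int(winners[0])
    elif majority in winners:
        predicted = int(majority)
    else:
        predicted = int(winners[0])
    tp = int(counts[predicted])
    fp = int(counts.sum() - tp)
    return Rule(
        antecedent=tuple(sorted(leaf.path)),
        predicted_class=predicted,
        tp=tp,
        fp=fp,
        alpha=alpha,
        class_distribution=tuple(float(x) for x in dist),
        raw_counts=tuple(int(c) for c in leaf.counts),
    )


def _encode_instance(rulebase: RuleBase, record) -> np.ndarray:
    """Map a record (dict, Series or full code vector) to discrete codes."""
    if isinstance(record, np.ndarray) and record.dtype.kind in "iu":
        return record
    values = dict(record)
    used = {rulebase.feature_names[v] for v in rulebase.used_variables}
    missing = sorted(used - set(values))
    if missing:
        raise ValidationError(f"instance is missing used variables: {missing}")
    if rulebase.scheme is None:
        raise ValidationError("continuous instance given but rule base stores no scheme")
    codes = np.zeros(len(rulebase.feature_names), dtype=np.intp)
    for v in rulebase.used_variables:
        name = rulebase.feature_names[v]
        cuts = np.asarray(rulebase.scheme.cutpoints[name], dtype=float)
        codes[v] = int(np.searchsorted(cuts, float(values[name]), side="left"))
    return codes


def predict(rulebase: RuleBase, instance) -> tuple[int, float, Rule]:
    """Classify one instance; returns (class code, smoothed probability, rule).

    The instance may be a discrete code vector or a mapping of feature
    name to continuous value (encoded through the stored scheme).  Exactly
    one rule fires by the ME&E invariant.
    """
    codes = _encode_instance(rulebase, instance)
    fired = [r for r in rulebase.rules if r.matches(codes)]
    if len(fired) != 1:
        raise ValidationError(
            f"{len(fired)} rules matched; rule base violates mutual exclusivity/exhaustiveness"
        )
    rule = fired[0]
    return rule.predicted_class, rule.posterior_probability, rule


def predict_dataset(rulebase: RuleBase, dataset) -> tuple[np.ndarray, np.ndarray]:
    """Vector of predicted class codes and per-class probability matrix.

    Accepts a ContinuousDataset (encoded through the stored scheme) or a
    DiscreteDataset with compatible coding.
    """
    if isinstance(dataset, ContinuousDataset):
        if rulebase.scheme is None:
            raise ValidationError("rule base stores no discretization scheme")
        missing = [rulebase.feature_names[v] for v in rulebase.used_variables
                   if rulebase.feature_names[v] not in dataset.feature_names]
        if missing:
            raise ValidationError(f"input is missing used variables: {sorted(missing)}")
        sub = ContinuousDataset(
            values=dataset.values,
            feature_names=dataset.feature_names,
            class_labels=dataset.class_labels,
            class_name=dataset.class_name,
        )
        disc = apply_scheme(_scheme_for(rulebase, sub), sub)
        name_to_col = {n: j for j, n in enumerate(disc.feature_names)}
        codes = np.zeros((disc.m, len(rulebase.feature_names)), dtype=np.intp)
        for v in rulebase.used_variables:
            codes[:, v] = disc.codes[:, name_to_col[rulebase.feature_names[v]]]
        m = disc.m
    elif isinstance(dataset, DiscreteDataset):
        codes, m = dataset.codes, dataset.m
    else:
        raise ValidationError("unsupported dataset type for prediction")
    k = len(rulebase.class_values)
    preds = np.empty(m, dtype=np.intp)
    probs = np.empty((m, k), dtype=float)
    for s in range(m):
        fired = [r for r in rulebase.rules if r.matches(codes[s])]
        if len(fired) != 1:
            raise ValidationError("rule base is not mutually exclusive and exhaustive")
        preds[s] = fired[0].predicted_class
        probs[s] = fired[0].class_distribution
    return preds, probs


def _scheme_for(rulebase: RuleBase, dataset: ContinuousDataset) -> DiscretizationScheme:
    # restrict the stored scheme to the features present in the input
    cuts = {}
    for name in dataset.feature_names:
        cuts[name] = list(rulebase.scheme.cutpoints.get(name, []))
    # class_values intentionally dropped: prediction inputs need not carry
    # (or match) the training labels
    return DiscretizationScheme(cuts, lam=rulebase.scheme.lam)


def parsimony(rulebase: RuleBase) -> tuple[int, int]:
    """(number of rules, number of distinct variables used in any antecedent)."""
    return rulebase.n_rules, len(rulebase.used_variables)


# ---------------------------------------------------------------------------
# serialization

def format_rule(rulebase: RuleBase, rule: Rule, index: int) -> str:
    """Human-readable rule block in the style of a published BRL rule set."""
    if rule.antecedent:
        conj = " AND ".join(
            f"({rulebase.feature_names[v]} = "
            f"{' or '.join(rulebase.value_labels[v][c] for c in block)})"
            for v, block in rule.antecedent
        )
    else:
        conj = "(TRUE)"
    cls = rulebase.class_values[rule.predicted_class]
    dist = ", ".join(f"{p:.2f}" for p in rule.class_distribution)
    return (
        f"Rule {index}: IF {conj} THEN class = {cls}  [{dist}]\n"
        f"  TP={rule.tp} FP={rule.fp} "
        f"posterior probability={rule.posterior_probability:.2f} "
        f"posterior odds={rule.posterior_odds:.2f}"
    )


def write_rulebase(rulebase: RuleBase, path, fmt: str = "text") -> None:
    """Write a rule base as readable text or as a loss-less machine bundle.

    The machine format (JSON) stores the rules, the discretization scheme,
    the model score and the run configuration, so prediction on continuous
    test data is self-contained.
    """
    if not rulebase.rules:
        raise ValidationError("refusing to write an empty rule base")
    if fmt == "text":
        blocks = [format_rule(rulebase, r, i + 1) for i, r in enumerate(rulebase.rules)]
        header = (
            f"# BRL rule base ({rulebase.structure_kind} structure), "
            f"{rulebase.n_rules} rules, "
            f"{len(rulebase.used_variables)} variables, "
            f"log score {rulebase.model_logscore:.4f}\n"
        )
        text = header + "\n".join(blocks) + "\n"
        with open(path, "w") as fh:
            fh.write(text)
    elif fmt == "machine":
        payload = {
            "format": "brl-rulebase",
            "version": 1,
            "structure_kind": rulebase.structure_kind,
            "model_logscore": rulebase.model_logscore,
            "alpha": rulebase.alpha,
            "majority_class": rulebase.majority_class,
            "feature_names": rulebase.feature_names,
            "value_labels": rulebase.value_labels,
            "class_values": list(rulebase.class_values),
            "config": rulebase.config,
            "scheme": rulebase.scheme.to_dict() if rulebase.scheme else None,
            "rules": [
                {
                    "antecedent": [[v, list(block)] for v, block in r.antecedent],
                    "predicted_class": r.predicted_class,
                    "tp": r.tp,
                    "fp": r.fp,
                    "alpha": r.alpha,
                    "class_distribution": list(r.class_distribution),
                    "raw_counts": list(r.raw_counts),
                }
                for r in rulebase.rules
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValidationError(f"unknown rule-base format {fmt!r}")


def read_rulebase(path) -> RuleBase:
    """Load a machine-format rule base written by ``write_rulebase``."""
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "brl-rulebase":
        raise ValidationError("not a BRL machine rule-base file")
    rules = [
        Rule(
            antecedent=tuple((int(v), tuple(int(c) for c in block))
                             for v, block in r["antecedent"]),
            predicted_class=int(r["predicted_class"]),
            tp=int(r["tp"]),
            fp=int(r["fp"]),
            alpha=float(r["alpha"]),
            class_distribution=tuple(float(x) for x in r["class_distribution"]),
            raw_counts=tuple(int(c) for c in r["raw_counts"]),
        )
        for r in payload["rules"]
    ]
    scheme = (DiscretizationScheme.from_dict(payload["scheme"])
              if payload.get("scheme") else None)
    return RuleBase(
        rules=rules,
        scheme=scheme,
        model_logscore=float(payload["model_logscore"]),
        feature_names=list(payload["feature_names"]),
        value_labels=[list(v) for v in payload["value_labels"]],
        class_values=list(payload["class_values"]),
        majority_class=int(payload["majority_class"]),
        structure_kind=payload["structure_kind"],
        alpha=float(payload["alpha"]),
        config=dict(payload.get("config", {})),
    )
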