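"""Synthetic gene-expression-like data with planted rule structure.

The generator emulates the shape of high-throughput expression matrices:
many continuous features, of which a small planted subset carries
class-conditional location shifts (depth 1) or a two-feature interaction
in which only the *joint* value determines the class-conditional means
(depth 2, XOR-style); everything else is class-independent Gaussian
noise.  Effects are expressed in units of the noise standard deviation so
specifications are scale-free.  All randomness flows through one seeded
``numpy`` generator, so a spec is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from brl.data import ContinuousDataset, DiscreteDataset
from brl.errors import ValidationError


@dataclass
class PlantedSpec:
    """Ground-truth description of a synthetic dataset.

    ``informative`` lists (feature index, per-class mean shift in sd
    units, noise sd) triples; ``rule_depth`` 1 plants marginal location
    shifts, 2 plants an XOR-style interaction on the first two informative
    features.
    """

    m: int = 100
    n: int = 50
    informative: list[tuple[int, float, float]] = field(default_factory=list)
    rule_depth: int = 1
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValidationError("need m >= 2 instances")
        if self.n < 1:
            raise ValidationError("need n >= 1 features")
        if not 0 < self.class_balance < 1:
            raise ValidationError("class_balance must be in (0, 1)")
        if self.rule_depth not in (1, 2):
            raise ValidationError("rule_depth must be 1 or 2")
        for idx, _shift, sd in self.informative:
            if not 0 <= idx < self.n:
                raise ValidationError(f"informative index {idx} out of range")
            if sd <= 0:
                raise ValidationError("noise sd must be positive")
        if self.rule_depth == 2 and len(self.informative) < 2:
            raise ValidationError("rule_depth 2 needs at least 2 informative features")


def generate(spec: PlantedSpec) -> tuple[ContinuousDataset, dict]:
    """Draw a dataset from a planted spec; returns (dataset, ground truth).

    Classes are labelled ``"case"`` / ``"control"``; cases occur with
    probability ``class_balance``.  Depth-1 informative features have mean
    ``+shift*sd`` in cases and 0 in controls; depth-2 pairs assign the
    shifted mean when the XOR of the two latent feature states matches the
    class, so neither feature is marginally informative.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.m) < spec.class_balance).astype(int)  # 1 = case
    if len(np.unique(y)) < 2:  # force both classes at tiny m
        y[0], y[-1] = 0, 1
    values = rng.normal(0.0, 1.0, size=(spec.m, spec.n))
    truth = {"informative": [], "rule_depth": spec.rule_depth, "seed": spec.seed}
    if spec.rule_depth == 1:
        for idx, shift, sd in spec.informative:
            values[:, idx] = rng.normal(0.0, sd, size=spec.m) + shift * sd * y
            truth["informative"].append({"feature": idx, "shift_sd": shift, "sd": sd})
    else:
        (i1, shift1, sd1), (i2, shift2, sd2) = spec.informative[0], spec.informative[1]
        # latent binary states whose XOR equals the class: marginally flat
        s1 = rng.integers(0, 2, size=spec.m)
        s2 = s1 ^ y
        values[:, i1] = rng.normal(0.0, sd1, size=spec.m) + shift1 * sd1 * s1
        values[:, i2] = rng.normal(0.0, sd2, size=spec.m) + shift2 * sd2 * s2
        truth["informative"] = [
            {"feature": i1, "shift_sd": shift1, "sd": sd1, "interaction": True},
            {"feature": i2, "shift_sd": shift2, "sd": sd2, "interaction": True},
        ]
        for idx, shift, sd in spec.informative[2:]:
            values[:, idx] = rng.normal(0.0, sd, size=spec.m) + shift * sd * y
            truth["informative"].append({"feature": idx, "shift_sd": shift, "sd": sd})
    labels = ["case" if c else "control" for c in y]
    names = [f"gene{j}" for j in range(spec.n)]
    return ContinuousDataset(values, names, labels), truth


def generate_fig3_like(distributions: dict, m: int, seed: int = 0,
                       arities: tuple[int, int] = (2, 2)) -> DiscreteDataset:
    """Sample a discrete two-predictor dataset from explicit cell distributions.

    ``distributions`` maps each joint predictor assignment ``(a, b)`` to
    the class probability vector of the target in that cell; cells are
    visited with equal probability.  Used to exercise leaf merging: give
    two cells the same class distribution and a local structure search
    has nothing to gain by distinguishing them.
    """
    if m < 1:
        raise ValidationError("need m >= 1 instances")
    r_a, r_b = arities
    cells = sorted(distributions)
    if set(cells) != {(a, b) for a in range(r_a) for b in range(r_b)}:
        raise ValidationError("distributions must cover every joint predictor assignment")
    k = len(next(iter(distributions.values())))
    for cell, p in distributions.items():
        p = np.asarray(p, dtype=float)
        if len(p) != k or (p < 0).any() or (p > 1).any() or not np.isclose(p.sum(), 1.0):
            raise ValidationError(f"cell {cell}: invalid probability vector")
    rng = np.random.default_rng(seed)
    ab = rng.integers(0, len(cells), size=m)
    codes = np.array([cells[i] for i in ab], dtype=np.intp)
    target = np.empty(m, dtype=np.intp)
    for i, cell_i in enumerate(ab):
        target[i] = rng.choice(k, p=np.asarray(distributions[cells[cell_i]], dtype=float))
    return DiscreteDataset(
        codes=codes,
        arities=[r_a, r_b],
        value_labels=[[f"v{c}" for c in range(r_a)], [f"v{c}" for c in range(r_b)]],
        target_codes=target,
        target_arity=k,
        feature_names=["GeneA", "GeneB"],
        class_values=[f"class{c}" for c in range(k)],
    )
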