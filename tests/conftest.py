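"""Shared fixtures: tiny datasets built in memory or on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from brl.data import ContinuousDataset, DiscreteDataset


def make_discrete(codes, arities, target, target_arity=2, **kw) -> DiscreteDataset:
    codes = np.asarray(codes)
    return DiscreteDataset(
        codes=codes,
        arities=list(arities),
        value_labels=[[f"v{c}" for c in range(r)] for r in arities],
        target_codes=np.asarray(target),
        target_arity=target_arity,
        **kw,
    )


def random_discrete(rng, m, n, arity=2, target_arity=2) -> DiscreteDataset:
    """Random dataset with both classes guaranteed present."""
    codes = rng.integers(0, arity, size=(m, n))
    y = rng.integers(0, target_arity, size=m)
    y[0], y[-1] = 0, 1
    return make_discrete(codes, [arity] * n, y, target_arity)


@pytest.fixture
def tiny_continuous() -> ContinuousDataset:
    values = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0], [4.0, 40.0]])
    return ContinuousDataset(values, ["gA", "gB"], ["case", "control", "case", "control"])


@pytest.fixture
def fig3_dataset() -> DiscreteDataset:
    """Two binary predictors; both GeneA=1 cells share the class distribution.

    Exact per-cell counts: (A=0,B=0) -> 50/5 (smoothed posterior 51/57, i.e.
    0.89), (A=0,B=1) -> 25/75, (A=1,B=*) -> 34/66 each.
    """
    rows, ys = [], []
    for (a, b), n_true, n_cell in [((0, 0), 50, 55), ((0, 1), 25, 100),
                                   ((1, 0), 34, 100), ((1, 1), 34, 100)]:
        for i in range(n_cell):
            rows.append([a, b])
            ys.append(0 if i < n_true else 1)
    return make_discrete(
        np.array(rows), [2, 2], np.array(ys), 2,
        feature_names=["GeneA", "GeneB"], class_values=["true", "false"],
    )
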