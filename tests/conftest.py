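"""Shared fixtures: small count matrices and a hand-enumerable toy network."""

import numpy as np
import pandas as pd
import pytest

from cernaforge.cerna_network import CeRNAAxis, CeRNANetwork
from cernaforge.coexpression import CoexprPair
from cernaforge.expression_io import CountMatrix
from cernaforge.target_prediction import InteractionSet

SAMPLES = ["c1", "c2", "c3", "t1", "t2", "t3"]
GROUPS = {"c1": "control", "c2": "control", "c3": "control",
          "t1": "treated", "t2": "treated", "t3": "treated"}


def make_matrix(counts: np.ndarray, feature_ids=None) -> CountMatrix:
    counts = np.asarray(counts)
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(counts.shape[0])]
    df = pd.DataFrame(counts, index=feature_ids, columns=SAMPLES[: counts.shape[1]])
    groups = {s: GROUPS[s] for s in df.columns}
    return CountMatrix(df, groups)


@pytest.fixture
def six_sample_matrix() -> CountMatrix:
    rng = np.random.default_rng(0)
    return make_matrix(rng.poisson(50, size=(20, 6)))


@pytest.fixture
def toy_network() -> CeRNANetwork:
    """pairs {(c1,m1),(c1,m2),(c2,m1)}, sponges {(c1,u1),(c1,u2),(c2,u1)},
    targets {(u1,m1),(u2,m2)}, all miRNAs expressed -> axes enumerated by hand:
    (c1,u1,m1), (c1,u2,m2), (c2,u1,m1)."""
    axes = frozenset({
        CeRNAAxis("c1", "u1", "m1"),
        CeRNAAxis("c1", "u2", "m2"),
        CeRNAAxis("c2", "u1", "m1"),
    })
    return CeRNANetwork(axes)


@pytest.fixture
def toy_inputs():
    pairs = [
        CoexprPair("c1", "m1", 0.99, 1e-4, 1e-3, 6),
        CoexprPair("c1", "m2", 0.97, 2e-4, 1e-3, 6),
        CoexprPair("c2", "m1", 0.95, 3e-4, 1e-3, 6),
    ]
    inter = InteractionSet(
        circ_mir=frozenset({("c1", "u1"), ("c1", "u2"), ("c2", "u1")}),
        mir_mrna=frozenset({("u1", "m1"), ("u2", "m2")}),
    )
    expressed = {"u1", "u2"}
    return pairs, inter, expressed
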