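"""Genealogical-nearest-neighbour baseline classifier.

The established approach linearizes the coalescent context of a focal
leaf into population proportions of the reference leaves found under each
of its first ``depth`` ancestral nodes, combined with the average sample
time of those leaves, and feeds the flattened features to a small
multilayer perceptron.  It serves as the paired comparison point for the
graph transformer: both models are always trained and evaluated on the
same (tree, focal) example sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from arglai.arg_io import MarginalTree, Population, SampleMeta, ancestor_chain
from arglai.nn.autograd import Tensor, relu, softmax
from arglai.nn.layers import Linear, Params, init_params
from arglai.subgraph import DEFAULT_CAP

__all__ = ["REF_POP_ORDER", "GNNFeatures", "gnn_features",
           "build_baseline_params", "baseline_logits", "baseline_forward"]

#: Fixed order of reference populations in proportion vectors.
REF_POP_ORDER = (Population.ANA, Population.WHG, Population.EHG,
                 Population.CHG, Population.NEO, Population.YAM)

DEFAULT_DEPTH = 5


@dataclass
class GNNFeatures:
    """Per-level reference-population proportions and mean sample times.

    ``proportions[l]`` sums to 1 where any reference leaf exists under
    ancestor ``l+1`` of the focal; otherwise it is all-zero and
    ``empty[l]`` is set (this covers truncated chains on shallow trees).
    """

    proportions: np.ndarray   # (depth, len(REF_POP_ORDER))
    avg_times: np.ndarray     # (depth,) generations
    empty: np.ndarray         # (depth,) bool

    def flatten(self, time_scale: float = float(DEFAULT_CAP)) -> np.ndarray:
        """Feature vector for the MLP; times are scaled to O(1)."""
        return np.concatenate([
            self.proportions.ravel(),
            self.avg_times / time_scale,
            self.empty.astype(float),
        ])

    @staticmethod
    def dim(depth: int = DEFAULT_DEPTH) -> int:
        return depth * (len(REF_POP_ORDER) + 2)


def gnn_features(tree: MarginalTree, focal: int,
                 metadata: Mapping[int, SampleMeta],
                 depth: int = DEFAULT_DEPTH) -> GNNFeatures:
    """Aggregate reference-leaf composition under the focal's ancestors.

    Level ``l`` looks at the subtree of the focal's ``l``-th ancestor,
    counting reference leaves only (the focal itself and non-reference
    extant haplotypes are excluded, mirroring the reference-panel logic
    of the transformer's subgraph).
    """
    if not tree.is_leaf(focal):
        raise ValueError(f"focal {focal} is not an extant leaf")
    chain = ancestor_chain(tree, focal, depth)
    P = len(REF_POP_ORDER)
    props = np.zeros((depth, P))
    times = np.zeros(depth)
    empty = np.ones(depth, dtype=bool)
    pop_index = {p: i for i, p in enumerate(REF_POP_ORDER)}
    for level, anc in enumerate(chain.nodes):
        refs = [v for v in tree.subtree_leaves(anc)
                if v != focal and metadata[v].is_reference]
        if not refs:
            continue
        counts = np.zeros(P)
        for v in refs:
            counts[pop_index[metadata[v].population]] += 1
        props[level] = counts / counts.sum()
        times[level] = float(np.mean([metadata[v].sample_time for v in refs]))
        empty[level] = False
    return GNNFeatures(proportions=props, avg_times=times, empty=empty)


HIDDEN = 64
N_CLASSES = 4


def build_baseline_params(rng: np.random.Generator,
                          input_dim: int | None = None,
                          dtype=np.float64) -> Params:
    """Two-hidden-layer perceptron (64 units each) over flattened features."""
    d = input_dim if input_dim is not None else GNNFeatures.dim()
    shapes = {}
    shapes.update(Linear.shapes("fc1", d, HIDDEN))
    shapes.update(Linear.shapes("fc2", HIDDEN, HIDDEN))
    shapes.update(Linear.shapes("out", HIDDEN, N_CLASSES))
    return init_params(shapes, rng, dtype=dtype)


def baseline_logits(params: Params, features: np.ndarray) -> Tensor:
    """Class logits for a (B, F) feature matrix."""
    x = Tensor(np.atleast_2d(np.asarray(
        features, dtype=params["fc1.weight"].data.dtype)))
    if not np.isfinite(x.data).all():
        raise ValueError("non-finite feature values")
    h = relu(Linear.apply(params, "fc1", x))
    h = relu(Linear.apply(params, "fc2", h))
    return Linear.apply(params, "out", h)


def baseline_forward(params: Params, features: np.ndarray) -> np.ndarray:
    """Class probabilities (B, 4); rows sum to 1."""
    return softmax(baseline_logits(params, features), axis=-1).data
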