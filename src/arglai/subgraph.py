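"""Fixed-size classification examples around a focal extant haplotype.

A subgraph holds the focal leaf, its ``k`` nearest reference haplotypes by
TMRCA (populations pooled), and its ``m`` immediate ancestral nodes —
29 tokens under the defaults ``k=25, m=3``.  Relative position between
tokens is the clamped, asymmetric relative TMRCA

    psi(i, j) = min(tmrca(i, j) - tau_i, cap),        cap = 1000

rounded half-up to an integer bucket, so an encoding table with
``cap + 1`` rows can be indexed directly.  psi is asymmetric because it is
measured from node i's own sample time tau_i; below the cap it satisfies
``psi(i, j) + tau_i == psi(j, i) + tau_j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from arglai.arg_io import (
    MarginalTree,
    Population,
    SampleMeta,
    ancestor_chain,
    tmrca,
)

__all__ = [
    "DEFAULT_CAP",
    "AncestryLabel",
    "TokenVocabulary",
    "Subgraph",
    "psi",
    "nearest_references",
    "build_subgraph",
]

logger = logging.getLogger(__name__)

#: Default clamp of the relative TMRCA, in generations.
DEFAULT_CAP = 1000

#: Token count under the defaults: focal + 25 references + 3 ancestors.
DEFAULT_TOKENS = 29


class AncestryLabel:
    """The four ancestral classes a segment can be assigned to."""

    CLASSES = (Population.ANA, Population.WHG, Population.EHG, Population.CHG)

    @classmethod
    def index(cls, pop: Population) -> int:
        return cls.CLASSES.index(pop)

    @classmethod
    def from_index(cls, idx: int) -> Population:
        return cls.CLASSES[idx]


# Special tokens: the focal haplotype is deliberately blinded (it never
# carries its own, possibly admixed, population label) and internal nodes
# of the ARG are unlabeled.
FOCAL_UNKNOWN = "FOCAL_UNKNOWN"
ANCESTOR = "ANCESTOR"
PAD = "PAD"


@dataclass(frozen=True)
class TokenVocabulary:
    """Injective mapping from population labels and special tokens to ids."""

    token_to_id: Mapping[str, int]

    @classmethod
    def default(cls) -> "TokenVocabulary":
        names = [p.value for p in Population] + [FOCAL_UNKNOWN, ANCESTOR, PAD]
        return cls(token_to_id={name: i for i, name in enumerate(names)})

    def __getitem__(self, token: str | Population) -> int:
        if isinstance(token, Population):
            token = token.value
        return self.token_to_id[token]

    def __len__(self) -> int:
        return len(self.token_to_id)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]


@dataclass
class Subgraph:
    """One model input: tokens, node times and the psi matrix.

    ``tokens[0]`` is always the focal haplotype (FOCAL_UNKNOWN).  ``mask``
    is True for real tokens, False for padding.  ``short`` flags examples
    drawn from trees too small for the requested (k, m).
    """

    focal: int
    node_ids: np.ndarray        # (S,) tree node ids, -1 for padding
    tokens: np.ndarray          # (S,) int token ids
    node_times: np.ndarray      # (S,) generations
    psi: np.ndarray             # (S, S) int in [0, cap]
    mask: np.ndarray            # (S,) bool
    truth_label: Optional[int] = None   # index into AncestryLabel.CLASSES
    short: bool = False

    def __post_init__(self) -> None:
        S = len(self.tokens)
        assert self.psi.shape == (S, S) and len(self.node_times) == S
        assert np.all(np.diag(self.psi)[self.mask] == 0)


def psi(tree: MarginalTree, i: int, j: int, cap: int = DEFAULT_CAP) -> int:
    """Clamped relative TMRCA bucket of the ordered pair (i, j)."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    if i == j:
        return 0
    raw = tmrca(tree, i, j) - tree.time(i)
    return _bucketize(raw, cap)


def _bucketize(raw: float, cap: int) -> int:
    if raw < 0:
        # only numerical noise can produce this: tmrca >= max(tau_i, tau_j)
        logger.warning("negative relative TMRCA %g clamped to 0", raw)
        return 0
    # round half-up, then clamp
    return int(min(np.floor(raw + 0.5), cap))


@dataclass
class NearestReferences:
    """k reference leaves in increasing psi order, plus a shortfall flag."""

    leaves: list[int]
    psis: list[int]
    short: bool


def nearest_references(
    tree: MarginalTree,
    focal: int,
    metadata: Mapping[int, SampleMeta],
    k: int = 25,
    cap: int = DEFAULT_CAP,
) -> NearestReferences:
    """The k reference leaves nearest to ``focal`` by TMRCA, pooled.

    All reference populations compete together; the focal itself and any
    non-reference extant haplotype are excluded.  Ties on psi break by
    ascending haplotype_id.  Fewer than k references yields all of them
    with ``short=True``.
    """
    if not tree.is_leaf(focal):
        raise ValueError(f"focal {focal} is not an extant leaf")
    refs = [
        h for h, m in metadata.items()
        if m.is_reference and h != focal and tree.is_leaf(h)
    ]
    if not refs:
        raise ValueError("no reference haplotypes in tree")
    scored = sorted((psi(tree, focal, r, cap), r) for r in refs)
    chosen = scored[:k]
    return NearestReferences(
        leaves=[r for _, r in chosen],
        psis=[p for p, _ in chosen],
        short=len(chosen) < k,
    )


def build_subgraph(
    tree: MarginalTree,
    focal: int,
    metadata: Mapping[int, SampleMeta],
    vocab: TokenVocabulary,
    k: int = 25,
    m: int = 3,
    cap: int = DEFAULT_CAP,
    pad: bool = True,
) -> Subgraph:
    """Extract the (1 + k + m)-token example around ``focal``.

    Token order is [focal, k references in psi order, m ancestors in
    increasing time order].  psi is computed between every ordered pair of
    included nodes.  Trees too small for (k, m) yield flagged examples,
    padded to full size by default (pad token, psi = cap, masked out).
    """
    near = nearest_references(tree, focal, metadata, k=k, cap=cap)
    chain = ancestor_chain(tree, focal, m)
    nodes = [int(focal)] + near.leaves + chain.nodes
    short = near.short or chain.truncated

    tokens = [vocab[FOCAL_UNKNOWN]]
    tokens += [vocab[metadata[r].population] for r in near.leaves]
    tokens += [vocab[ANCESTOR]] * len(chain.nodes)

    S_full = 1 + k + m
    n_real = len(nodes)
    times = np.array([tree.time(v) for v in nodes])

    # pairwise psi over included nodes: intersect precomputed root paths
    paths = [tree.root_path(v) for v in nodes]
    psi_mat = np.zeros((n_real, n_real), dtype=np.int64)
    for a in range(n_real):
        set_a = {v: None for v in paths[a]}
        for b in range(n_real):
            if a == b:
                continue
            t_mrca = None
            for v in paths[b]:   # first node of b's root path also above a
                if v in set_a:
                    t_mrca = tree.time(v)
                    break
            if t_mrca is None:
                raise ValueError(
                    f"nodes {nodes[a]}, {nodes[b]} share no ancestor in tree")
            psi_mat[a, b] = _bucketize(t_mrca - times[a], cap)

    if pad and n_real < S_full:
        pad_n = S_full - n_real
        tokens += [vocab.pad_id] * pad_n
        times = np.concatenate([times, np.zeros(pad_n)])
        full = np.full((S_full, S_full), cap, dtype=np.int64)
        full[:n_real, :n_real] = psi_mat
        np.fill_diagonal(full, 0)
        psi_mat = full
        node_ids = np.array(nodes + [-1] * pad_n, dtype=np.int64)
        mask = np.array([True] * n_real + [False] * pad_n)
    else:
        node_ids = np.array(nodes, dtype=np.int64)
        mask = np.ones(n_real, dtype=bool)

    return Subgraph(
        focal=int(focal),
        node_ids=node_ids,
        tokens=np.array(tokens, dtype=np.int64),
        node_times=times,
        psi=psi_mat,
        mask=mask,
        short=short,
    )
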