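"""Dataset assembly, training loops and paired evaluation.

Examples are drawn from marginal trees with a stride (every 10th tree for
training, every 100th for validation by default) to mitigate the local
correlation between adjacent trees.  Each example's truth label is the
true-ancestry segment covering the tree's interval midpoint.  Both the
transformer and the GNN baseline consume the same (tree, focal) example
sets so accuracy comparisons are paired.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from arglai.arg_io import Population, TreeSequenceHandle
from arglai.baseline import (
    GNNFeatures,
    baseline_logits,
    build_baseline_params,
    gnn_features,
)
from arglai.demography import TruthSegment
from arglai.model import ModelConfig, build_params, forward_logits
from arglai.nn.autograd import softmax
from arglai.nn.layers import Adam, CrossEntropy, Params
from arglai.subgraph import AncestryLabel, TokenVocabulary, build_subgraph

__all__ = [
    "DatasetSpec", "SubgraphDataset", "make_dataset",
    "TrainConfig", "TrainResult", "train_transformer", "train_baseline",
    "EvalReport", "evaluate",
]

#: Focal sample classes evaluated by default (the admixed classes).
DEFAULT_TARGET_CLASSES = (Population.NEO, Population.YAM,
                          Population.POSTNEO, Population.PRESENT)


@dataclass
class DatasetSpec:
    """How to turn tree sequences into a classification dataset."""

    stride: int = 10                  # keep every stride-th tree
    target_classes: tuple = DEFAULT_TARGET_CLASSES
    max_examples: int = 100_000
    focal_per_tree: int = 10          # focal draws per retained tree
    k: int = 25                       # nearest references per example
    m: int = 3                        # ancestral nodes per example
    cap: int = 1000
    gnn_depth: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.max_examples <= 0:
            raise ValueError("max_examples must be > 0")


@dataclass
class SubgraphDataset:
    """Columnar example container; one row per (tree, focal) example.

    Carries both the transformer representation (tokens/psi/mask) and the
    baseline's flattened GNN features for the same examples.
    """

    tokens: np.ndarray      # (E, S) int16
    psi: np.ndarray         # (E, S, S) int16
    node_times: np.ndarray  # (E, S) float32
    mask: np.ndarray        # (E, S) bool
    labels: np.ndarray      # (E,) int8, index into AncestryLabel.CLASSES
    focal_class: np.ndarray  # (E,) int8, index into Population order
    gnn: np.ndarray         # (E, F) float32
    focal: np.ndarray       # (E,) int32 haplotype ids

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, idx: np.ndarray) -> "SubgraphDataset":
        return SubgraphDataset(*(getattr(self, f)[idx] for f in (
            "tokens", "psi", "node_times", "mask", "labels",
            "focal_class", "gnn", "focal")))

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, tokens=self.tokens, psi=self.psi,
                            node_times=self.node_times, mask=self.mask,
                            labels=self.labels, focal_class=self.focal_class,
                            gnn=self.gnn, focal=self.focal)

    @classmethod
    def load(cls, path: str | Path) -> "SubgraphDataset":
        with np.load(path) as z:
            return cls(**{k: z[k] for k in z.files})

    def dump_tsv(self, path: str | Path, vocab: TokenVocabulary,
                 max_rows: int = 100) -> None:
        """Human-readable debug dump: tokens and the psi matrix per example."""
        id_to_token = {v: k for k, v in vocab.token_to_id.items()}
        with open(path, "w") as fh:
            for e in range(min(len(self), max_rows)):
                toks = "\t".join(id_to_token[int(t)] for t in self.tokens[e])
                label = AncestryLabel.from_index(int(self.labels[e])).value
                fh.write(f"# example {e} focal={self.focal[e]} "
                         f"label={label}\n{toks}\n")
                for row in self.psi[e]:
                    fh.write("\t".join(str(int(x)) for x in row) + "\n")


POP_ORDER = list(Population)


def _truth_lookup(truth: Sequence[TruthSegment]):
    """haplotype -> (starts, ends, label indices) arrays for interval search."""
    by: dict[int, list[TruthSegment]] = {}
    for s in truth:
        by.setdefault(s.haplotype_id, []).append(s)
    out = {}
    for h, segs in by.items():
        segs.sort(key=lambda s: s.start)
        out[h] = (np.array([s.start for s in segs]),
                  np.array([s.end for s in segs]),
                  np.array([AncestryLabel.index(s.label) for s in segs]))
    return out


def _label_at(lookup, hap: int, pos: float) -> int:
    starts, ends, labels = lookup[hap]
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    if i < 0 or pos >= ends[i]:
        raise ValueError(f"truth gap for haplotype {hap} at position {pos}")
    return int(labels[i])


def make_dataset(handle: TreeSequenceHandle,
                 truth: Sequence[TruthSegment],
                 spec: DatasetSpec,
                 vocab: TokenVocabulary) -> SubgraphDataset:
    """Extract subgraph + GNN examples from every stride-th tree.

    Per retained tree, ``focal_per_tree`` focal haplotypes are drawn
    uniformly by class first (among target classes present), then
    uniformly within the class.  Deterministic under a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    lookup = _truth_lookup(truth)
    class_names = {c.value for c in spec.target_classes}
    eligible: dict[str, list[int]] = {}
    for h, m in handle.metadata.items():
        if m.population.value in class_names:
            eligible.setdefault(m.population.value, []).append(h)
    if not eligible:
        raise ValueError("no haplotypes of the requested target classes")
    for v in eligible.values():
        v.sort()
    classes_present = sorted(eligible)

    rows = {f: [] for f in ("tokens", "psi", "node_times", "mask", "labels",
                            "focal_class", "gnn", "focal")}
    n = 0
    for t_index, tree in enumerate(handle.trees()):
        if t_index % spec.stride != 0:
            continue
        mid = tree.midpoint
        for _ in range(spec.focal_per_tree):
            cls = classes_present[rng.integers(len(classes_present))]
            focal = eligible[cls][rng.integers(len(eligible[cls]))]
            sg = build_subgraph(tree, focal, handle.metadata, vocab,
                                k=spec.k, m=spec.m, cap=spec.cap)
            feats = gnn_features(tree, focal, handle.metadata,
                                 depth=spec.gnn_depth)
            rows["tokens"].append(sg.tokens.astype(np.int16))
            rows["psi"].append(sg.psi.astype(np.int16))
            rows["node_times"].append(sg.node_times.astype(np.float32))
            rows["mask"].append(sg.mask)
            rows["labels"].append(_label_at(lookup, focal, mid))
            rows["focal_class"].append(POP_ORDER.index(Population(cls)))
            rows["gnn"].append(feats.flatten().astype(np.float32))
            rows["focal"].append(focal)
            n += 1
            if n >= spec.max_examples:
                break
        if n >= spec.max_examples:
            break
    return SubgraphDataset(
        tokens=np.stack(rows["tokens"]),
        psi=np.stack(rows["psi"]),
        node_times=np.stack(rows["node_times"]),
        mask=np.stack(rows["mask"]),
        labels=np.array(rows["labels"], dtype=np.int8),
        focal_class=np.array(rows["focal_class"], dtype=np.int8),
        gnn=np.stack(rows["gnn"]),
        focal=np.array(rows["focal"], dtype=np.int32),
    )


@dataclass
class TrainConfig:
    batch_size: int = 256
    lr: float = 1e-3
    epochs: int = 30
    seed: int = 0
    cosine_decay: bool = True
    dtype: str = "float32"    # training precision; float32 is plenty here


@dataclass
class TrainResult:
    params: Params               # checkpoint with minimal validation loss
    best_epoch: int
    log: pd.DataFrame            # per-epoch train/val loss and accuracy


def _run_training(params: Params,
                  loss_fn: Callable[[Params, np.ndarray, np.ndarray, object],
                                    object],
                  predict_fn: Callable[[Params, np.ndarray], np.ndarray],
                  train: SubgraphDataset, val: SubgraphDataset,
                  cfg: TrainConfig) -> TrainResult:
    rng = np.random.default_rng(cfg.seed)
    n = len(train)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    opt = Adam(params, lr=cfg.lr,
               total_steps=steps_per_epoch * cfg.epochs
               if cfg.cosine_decay else None)
    best = (np.inf, -1, None)
    records = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_loss, tot_correct = 0.0, 0
        for s in range(steps_per_epoch):
            idx = order[s * cfg.batch_size:(s + 1) * cfg.batch_size]
            loss = loss_fn(params, idx, train, rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {s}: {loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_loss += float(loss.data) * len(idx)
        train_loss = tot_loss / n
        val_probs = predict_fn(params, np.arange(len(val)))
        val_pred = val_probs.argmax(axis=1)
        val_acc = float((val_pred == val.labels).mean())
        eps = 1e-12
        val_loss = float(-np.log(
            val_probs[np.arange(len(val)), val.labels] + eps).mean())
        records.append(dict(epoch=epoch, train_loss=train_loss,
                            val_loss=val_loss, val_acc=val_acc))
        if val_loss < best[0]:
            best = (val_loss, epoch,
                    {k: copy.deepcopy(v.data) for k, v in params.items()})
    best_loss, best_epoch, best_state = best
    for k, v in params.items():
        v.data = best_state[k]
    return TrainResult(params=params, best_epoch=best_epoch,
                       log=pd.DataFrame.from_records(records))


def train_transformer(model_cfg: ModelConfig, train: SubgraphDataset,
                      val: SubgraphDataset, cfg: TrainConfig) -> TrainResult:
    """Train the graph transformer; returns the best-val-loss checkpoint."""
    rng0 = np.random.default_rng(cfg.seed)
    params = build_params(model_cfg, rng0, dtype=np.dtype(cfg.dtype))

    def loss_fn(p, idx, ds, rng):
        logits = forward_logits(p, model_cfg, ds.tokens[idx], ds.psi[idx],
                                ds.mask[idx],
                                rng=rng if model_cfg.dropout > 0 else None)
        return CrossEntropy.apply(logits, ds.labels[idx])

    def predict_fn(p, idx, batch: int = 512):
        outs = []
        for s in range(0, len(idx), batch):
            sl = idx[s:s + batch]
            logits = forward_logits(p, model_cfg, val.tokens[sl],
                                    val.psi[sl], val.mask[sl], rng=None)
            outs.append(softmax(logits, axis=-1).data)
        return np.concatenate(outs)

    return _run_training(params, loss_fn, predict_fn, train, val, cfg)


def train_baseline(train: SubgraphDataset, val: SubgraphDataset,
                   cfg: TrainConfig) -> TrainResult:
    """Train the GNN-feature MLP baseline on the same example sets."""
    rng0 = np.random.default_rng(cfg.seed)
    params = build_baseline_params(rng0, input_dim=train.gnn.shape[1],
                                   dtype=np.dtype(cfg.dtype))

    def loss_fn(p, idx, ds, rng):
        return CrossEntropy.apply(baseline_logits(p, ds.gnn[idx]),
                                  ds.labels[idx])

    def predict_fn(p, idx):
        return softmax(baseline_logits(p, val.gnn[idx]), axis=-1).data

    return _run_training(params, loss_fn, predict_fn, train, val, cfg)


def predict_dataset(kind: str, params: Params, ds: SubgraphDataset,
                    model_cfg: ModelConfig | None = None,
                    batch: int = 512) -> np.ndarray:
    """Class probabilities for a whole dataset, batched."""
    if kind == "baseline":
        return softmax(baseline_logits(params, ds.gnn), axis=-1).data
    outs = []
    for s in range(0, len(ds), batch):
        logits = forward_logits(params, model_cfg, ds.tokens[s:s + batch],
                                ds.psi[s:s + batch], ds.mask[s:s + batch],
                                rng=None)
        outs.append(softmax(logits, axis=-1).data)
    return np.concatenate(outs)


def save_model(path: str | Path, kind: str, params: Params,
               model_cfg: ModelConfig | None = None,
               vocab: TokenVocabulary | None = None,
               extra: dict | None = None) -> None:
    """One checkpoint format for both model kinds (npz + JSON header)."""
    from dataclasses import asdict

    header = {
        "version": 1,
        "kind": kind,
        "config": asdict(model_cfg) if model_cfg is not None else None,
        "vocab": dict(vocab.token_to_id) if vocab is not None else None,
        "extra": extra or {},
    }
    arrays = {f"param:{k}": v.data for k, v in params.items()}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(),
                                        dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> tuple[str, Params,
                                          ModelConfig | None,
                                          TokenVocabulary | None, dict]:
    from arglai.nn.autograd import Tensor

    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        params = {k[len("param:"):]: Tensor(z[k], requires_grad=True)
                  for k in z.files if k.startswith("param:")}
    cfg = ModelConfig(**header["config"]) if header["config"] else None
    vocab = TokenVocabulary(token_to_id={k: int(v) for k, v in
                                         header["vocab"].items()}) \
        if header["vocab"] else None
    return header["kind"], params, cfg, vocab, header.get("extra", {})


@dataclass
class EvalReport:
    """Per-population accuracy (mean ± sd over replicates), optionally a
    paired delta between two models on identical example sets."""

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False,
                                    float_format=lambda x: f"{x:.2f}")

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def evaluate(predictions: dict[str, list[np.ndarray]],
             test_sets: Sequence[SubgraphDataset]) -> EvalReport:
    """Accuracy per focal-sample population class, over test replicates.

    ``predictions`` maps model name -> one (E, 4) probability array per
    replicate.  With two models, a paired per-replicate delta column is
    added (second minus first).  Accuracies are percentages; classes
    absent from every replicate are omitted from the table.
    """
    names = list(predictions)
    classes = sorted({int(c) for ds in test_sets for c in ds.focal_class})
    rows = []
    for c in classes:
        row: dict = {"population": POP_ORDER[c].value}
        per_model: dict[str, list[float]] = {}
        for name in names:
            accs = []
            for probs, ds in zip(predictions[name], test_sets):
                sel = ds.focal_class == c
                if sel.sum() == 0:
                    continue
                pred = probs[sel].argmax(axis=1)
                accs.append(100.0 * float((pred == ds.labels[sel]).mean()))
            per_model[name] = accs
            row[f"{name}_mean"] = float(np.mean(accs)) if accs else np.nan
            row[f"{name}_sd"] = float(np.std(accs, ddof=1)) \
                if len(accs) > 1 else 0.0
            row[f"{name}_n"] = int(sum(
                int((ds.focal_class == c).sum()) for ds in test_sets))
        if len(names) == 2 and per_model[names[0]] and per_model[names[1]]:
            deltas = [b - a for a, b in zip(per_model[names[0]],
                                           per_model[names[1]])]
            row["delta_mean"] = float(np.mean(deltas))
        rows.append(row)
    return EvalReport(table=pd.DataFrame(rows))
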