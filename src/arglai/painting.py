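"""Genome paintings, ancestry masking of phased VCFs, and
ancestry-conditioned allele frequencies.

A painting tiles each haplotype with predicted-ancestry segments.
Per-tree predictions are merged by pure run-length encoding (no
cross-tree smoothing): consecutive trees with the same argmax class fuse
into one segment whose class probabilities are length-weighted means.

Masking sets every allele whose covering segment is not of the target
ancestry to missing, preserving site order, sample order, phase and
ploidy — the masked VCF feeds ancestry-specific PCA, f-statistics or
selection scans run by external tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from arglai.arg_io import Population, SampleMeta, TreeSequenceHandle
from arglai.model import ModelConfig, forward
from arglai.nn.layers import Params
from arglai.subgraph import AncestryLabel, TokenVocabulary, build_subgraph

__all__ = [
    "PaintedSegment", "predict_path", "write_paintings", "load_paintings",
    "haplotype_columns", "mask_vcf", "ancestry_allele_frequency",
]


@dataclass(frozen=True)
class PaintedSegment:
    """Predicted ancestry of one haplotype over [start, end) bp."""

    haplotype_id: int
    chrom: str
    start: float
    end: float
    label: Population                  # argmax of probs
    probs: tuple[float, float, float, float]   # ANA, WHG, EHG, CHG

    def __post_init__(self) -> None:
        assert abs(sum(self.probs) - 1.0) < 1e-6
        assert AncestryLabel.CLASSES[int(np.argmax(self.probs))] == self.label


def predict_path(params: Params, model_cfg: ModelConfig,
                 handle: TreeSequenceHandle,
                 focal_haplotypes: Sequence[int],
                 vocab: TokenVocabulary,
                 k: int = 25, m: int = 3, cap: int = 1000,
                 chrom: str = "1") -> list[PaintedSegment]:
    """Paint each focal haplotype tree by tree with the transformer.

    One prediction per (tree, focal); adjacent trees with the same argmax
    merge, averaging probabilities weighted by tree span.
    """
    focal_haplotypes = [int(h) for h in focal_haplotypes]
    per_tree: list[tuple[float, float, np.ndarray]] = []
    for tree in handle.trees():
        for h in focal_haplotypes:
            if not tree.is_leaf(h):
                raise ValueError(f"focal {h} absent from tree {tree.interval}")
        batch = [build_subgraph(tree, h, handle.metadata, vocab,
                                k=k, m=m, cap=cap) for h in focal_haplotypes]
        probs = forward(params, model_cfg,
                        np.stack([s.tokens for s in batch]),
                        np.stack([s.psi for s in batch]),
                        np.stack([s.mask for s in batch]))
        per_tree.append((tree.interval[0], tree.interval[1], probs))

    segments: list[PaintedSegment] = []
    for i, h in enumerate(focal_haplotypes):
        run_start = per_tree[0][0]
        run_probs = np.zeros(4)
        run_len = 0.0
        run_class = int(per_tree[0][2][i].argmax())
        for left, right, probs in per_tree:
            cls = int(probs[i].argmax())
            if cls != run_class:
                segments.append(_make_segment(h, chrom, run_start, left,
                                              run_probs / run_len, run_class))
                run_start, run_probs, run_len, run_class = left, np.zeros(4), \
                    0.0, cls
            span = right - left
            run_probs += span * probs[i]
            run_len += span
        segments.append(_make_segment(h, chrom, run_start, per_tree[-1][1],
                                      run_probs / run_len, run_class))
    return segments


def _make_segment(h: int, chrom: str, start: float, end: float,
                  probs: np.ndarray, cls: int) -> PaintedSegment:
    # length-weighted averaging cannot change the argmax within a run
    probs = probs / probs.sum()
    return PaintedSegment(h, chrom, start, end,
                          AncestryLabel.from_index(cls),
                          tuple(float(p) for p in probs))


PAINTING_COLUMNS = ["haplotype_id", "chrom", "start", "end", "ancestry",
                    "p_ANA", "p_WHG", "p_EHG", "p_CHG"]


def write_paintings(segments: Sequence[PaintedSegment],
                    path: str | Path) -> None:
    rows = [(s.haplotype_id, s.chrom, int(s.start), int(s.end),
             s.label.value, *s.probs) for s in segments]
    pd.DataFrame(rows, columns=PAINTING_COLUMNS).to_csv(
        path, sep="\t", index=False)


def load_paintings(path: str | Path) -> list[PaintedSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [PaintedSegment(int(r.haplotype_id), r.chrom, float(r.start),
                           float(r.end), Population(r.ancestry),
                           (r.p_ANA, r.p_WHG, r.p_EHG, r.p_CHG))
            for r in df.itertuples(index=False)]


class _PaintingIndex:
    """Fast covering-segment lookup per haplotype."""

    def __init__(self, segments: Sequence[PaintedSegment]):
        by: dict[int, list[PaintedSegment]] = {}
        for s in segments:
            by.setdefault(s.haplotype_id, []).append(s)
        self.tables = {}
        for h, segs in by.items():
            segs.sort(key=lambda s: s.start)
            self.tables[h] = (np.array([s.start for s in segs]),
                              np.array([s.end for s in segs]),
                              [s.label for s in segs])

    def haplotypes(self) -> set[int]:
        return set(self.tables)

    def label_at(self, hap: int, pos: float) -> Optional[Population]:
        if hap not in self.tables:    # unpainted haplotype: no ancestry call
            return None
        starts, ends, labels = self.tables[hap]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= ends[i]:
            return None
        return labels[i]


def haplotype_columns(metadata: Mapping[int, SampleMeta]
                      ) -> dict[str, tuple[int, ...]]:
    """individual_id -> its haplotype ids in phase order.

    The n-th allele of a sample's phased genotype corresponds to the n-th
    smallest haplotype_id of that individual (the convention declared in
    the metadata TSV).
    """
    by: dict[str, list[int]] = {}
    for h, m in sorted(metadata.items()):
        by.setdefault(m.individual_id, []).append(h)
    return {ind: tuple(haps) for ind, haps in by.items()}


def mask_vcf(vcf_in: str | Path, vcf_out: str | Path,
             paintings: Sequence[PaintedSegment],
             target: Population,
             metadata: Mapping[int, SampleMeta]) -> dict[str, int]:
    """Keep only alleles painted with ``target`` ancestry; others → missing.

    Works on phased VCFs; diploid genotypes may become half-missing but
    phase and ploidy are never altered.  Returns counters (records,
    kept/masked allele calls).
    """
    from cyvcf2 import VCF, Writer

    index = _PaintingIndex(paintings)
    columns = haplotype_columns(metadata)
    vcf = VCF(str(vcf_in))
    for sample in vcf.samples:
        if sample not in columns:
            raise ValueError(f"VCF sample {sample} absent from metadata")
        for hap in columns[sample]:
            if hap not in index.haplotypes():
                raise ValueError(
                    f"haplotype {hap} (sample {sample}) is unpainted")
    writer = Writer(str(vcf_out), vcf)
    n_rec = n_kept = n_masked = 0
    for variant in vcf:
        pos = variant.POS - 1    # 0-based
        genotypes = variant.genotypes
        new = []
        for sample, gt in zip(vcf.samples, genotypes):
            alleles, phased = list(gt[:-1]), gt[-1]
            haps = columns[sample]
            for a in range(len(alleles)):
                label = index.label_at(haps[a], pos)
                if label == target and alleles[a] >= 0:
                    n_kept += 1
                else:
                    alleles[a] = -1
                    n_masked += 1
            new.append(alleles + [phased])
        variant.genotypes = new
        writer.write_record(variant)
        n_rec += 1
    writer.close()
    vcf.close()
    return {"records": n_rec, "kept": n_kept, "masked": n_masked}


def ancestry_allele_frequency(vcf_path: str | Path,
                              paintings: Sequence[PaintedSegment],
                              site: tuple[str, int],
                              ancestry: Population,
                              metadata: Mapping[int, SampleMeta]
                              ) -> tuple[float, int, int]:
    """Derived-allele frequency at ``site`` among calls painted ``ancestry``.

    ``site`` is (chrom, 1-based position).  Returns (frequency, derived
    count, total non-missing calls of that ancestry); frequency is NaN
    when the denominator is zero.
    """
    from cyvcf2 import VCF

    index = _PaintingIndex(paintings)
    columns = haplotype_columns(metadata)
    chrom, pos1 = site
    vcf = VCF(str(vcf_path))
    hit = None
    for variant in vcf:   # linear scan: works on unindexed text VCFs too
        if variant.CHROM == chrom and variant.POS == pos1:
            hit = variant
            break
    if hit is None:
        raise ValueError(f"site {chrom}:{pos1} not present in VCF")
    num = den = 0
    for sample, gt in zip(vcf.samples, hit.genotypes):
        alleles = gt[:-1]
        haps = columns.get(sample)
        if haps is None:
            continue
        for a, allele in enumerate(alleles):
            if allele < 0:
                continue
            if index.label_at(haps[a], hit.POS - 1) == ancestry:
                den += 1
                num += int(allele > 0)
    vcf.close()
    freq = num / den if den else float("nan")
    return freq, num, den
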