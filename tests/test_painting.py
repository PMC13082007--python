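"""Paintings, VCF masking and ancestry-conditioned frequencies."""

import textwrap

import numpy as np
import pytest

from arglai.arg_io import Population, SampleMeta
from arglai.model import ModelConfig, build_params
from arglai.painting import (
    PaintedSegment,
    ancestry_allele_frequency,
    haplotype_columns,
    load_paintings,
    mask_vcf,
    predict_path,
    write_paintings,
)
from arglai.subgraph import AncestryLabel


def constant_class_params(cfg, cls, rng=None):
    """Model weights that predict class ``cls`` everywhere."""
    params = build_params(cfg, rng or np.random.default_rng(0))
    for name, t in params.items():
        t.data[:] = 1.0 if name.endswith(".gain") else 0.0
    params["head.bias"].data[cls] = 10.0
    return params


@pytest.fixture(scope="module")
def painted_toy(toy_world, vocab):
    _, handle, _ = toy_world
    targets = [h for h, m in sorted(handle.metadata.items())
               if not m.is_reference][:4]
    cfg = ModelConfig(vocab_size=len(vocab), d_model=8, n_heads=1,
                      n_layers=1, d_ff=8, dropout=0.0)
    return handle, targets, cfg


class TestPredictPath:
    def test_constant_model_yields_one_segment_per_haplotype(
            self, painted_toy, vocab):
        handle, targets, cfg = painted_toy
        params = constant_class_params(cfg, cls=2)   # EHG
        segments = predict_path(params, cfg, handle, targets, vocab,
                                k=5, m=2)
        assert len(segments) == len(targets)
        for s in segments:
            assert (s.start, s.end) == (0.0, handle.sequence_length)
            assert s.label is Population.EHG
            assert np.argmax(s.probs) == 2

    def test_segments_tile_and_probs_are_simplex(self, painted_toy, vocab):
        handle, targets, cfg = painted_toy
        params = build_params(cfg, np.random.default_rng(3))
        segments = predict_path(params, cfg, handle, targets[:2], vocab,
                                k=5, m=2)
        for h in targets[:2]:
            segs = sorted((s for s in segments if s.haplotype_id == h),
                          key=lambda s: s.start)
            assert segs[0].start == 0.0
            assert segs[-1].end == handle.sequence_length
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start
                assert a.label is not b.label   # merged runs alternate
            for s in segs:
                assert sum(s.probs) == pytest.approx(1.0)

    def test_breakpoints_lie_on_tree_boundaries(self, painted_toy, vocab):
        handle, targets, cfg = painted_toy
        params = build_params(cfg, np.random.default_rng(4))
        boundaries = {t.interval[0] for t in handle.trees()} | \
            {handle.sequence_length}
        segments = predict_path(params, cfg, handle, targets[:2], vocab,
                                k=5, m=2)
        for s in segments:
            assert s.start in boundaries
            assert s.end in boundaries

    def test_matches_run_length_oracle(self, painted_toy, vocab):
        """Per-tree argmax calls, run-length encoded independently."""
        from arglai.model import forward
        from arglai.subgraph import build_subgraph

        handle, targets, cfg = painted_toy
        params = build_params(cfg, np.random.default_rng(5))
        focal = targets[0]
        calls, intervals = [], []
        for tree in handle.trees():
            sg = build_subgraph(tree, focal, handle.metadata, vocab,
                                k=5, m=2)
            probs = forward(params, cfg, sg.tokens[None], sg.psi[None],
                            sg.mask[None])[0]
            calls.append(int(np.argmax(probs)))
            intervals.append(tree.interval)
        # oracle run-length encoding
        expected = []
        start, current = intervals[0][0], calls[0]
        for (left, right), c in zip(intervals, calls):
            if c != current:
                expected.append((start, left, current))
                start, current = left, c
        expected.append((start, intervals[-1][1], current))

        segments = sorted(
            (s for s in predict_path(params, cfg, handle, [focal], vocab,
                                     k=5, m=2)),
            key=lambda s: s.start)
        got = [(s.start, s.end, AncestryLabel.index(s.label))
               for s in segments]
        assert got == expected

    def test_absent_focal_raises(self, painted_toy, vocab):
        handle, targets, cfg = painted_toy
        params = constant_class_params(cfg, cls=0)
        with pytest.raises(ValueError, match="absent"):
            predict_path(params, cfg, handle, [10**7], vocab, k=5, m=2)


def test_paintings_tsv_round_trip(tmp_path):
    segs = [
        PaintedSegment(0, "1", 0.0, 500.0, Population.ANA,
                       (0.7, 0.1, 0.1, 0.1)),
        PaintedSegment(0, "1", 500.0, 1000.0, Population.CHG,
                       (0.1, 0.1, 0.1, 0.7)),
    ]
    path = tmp_path / "paint.tsv"
    write_paintings(segs, path)
    back = load_paintings(path)
    assert [(s.haplotype_id, s.start, s.end, s.label) for s in back] == \
        [(s.haplotype_id, s.start, s.end, s.label) for s in segs]


# ---------------------------------------------------------------------------
# masking and frequencies on a printed toy VCF

TOY_VCF = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=1,length=1000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS0\tS1\tS2\tS3\tS4
    """)


def toy_vcf(tmp_path, genotypes):
    """genotypes: (n_sites, 5) list of 'a|b' strings; positions 100, 200..."""
    lines = [TOY_VCF]
    for s, row in enumerate(genotypes):
        pos = 100 * (s + 1)
        lines.append(f"1\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t" +
                     "\t".join(row) + "\n")
    path = tmp_path / "toy.vcf"
    path.write_text("".join(lines))
    return path


def toy_metadata():
    out = {}
    for ind in range(5):
        for a in range(2):
            h = 2 * ind + a
            out[h] = SampleMeta(h, f"S{ind}", Population.PRESENT, 0.0, False)
    return out


def paint_all(label, n_haps=10, length=1000):
    probs = tuple(0.97 if AncestryLabel.CLASSES[i] is label else 0.01
                  for i in range(4))
    return [PaintedSegment(h, "1", 0.0, length, label, probs)
            for h in range(n_haps)]


class TestMaskVcf:
    def test_all_target_paintings_keep_everything(self, tmp_path):
        gts = [["0|1", "1|1", "0|0", "1|0", "0|1"] for _ in range(10)]
        vcf_in = toy_vcf(tmp_path, gts)
        out = tmp_path / "masked.vcf"
        counts = mask_vcf(vcf_in, out, paint_all(Population.ANA),
                          Population.ANA, toy_metadata())
        assert counts == {"records": 10, "kept": 100, "masked": 0}
        from cyvcf2 import VCF
        for v_in, v_out in zip(VCF(str(vcf_in)), VCF(str(out))):
            assert v_in.genotypes == v_out.genotypes

    def test_all_non_target_masks_everything(self, tmp_path):
        gts = [["0|1", "1|1", "0|0", "1|0", "0|1"] for _ in range(4)]
        vcf_in = toy_vcf(tmp_path, gts)
        out = tmp_path / "masked.vcf"
        counts = mask_vcf(vcf_in, out, paint_all(Population.WHG),
                          Population.ANA, toy_metadata())
        assert counts["masked"] == 40 and counts["kept"] == 0
        from cyvcf2 import VCF
        for v in VCF(str(out)):
            for gt in v.genotypes:
                assert gt[0] == -1 and gt[1] == -1

    def test_mixed_paintings_match_interval_oracle(self, tmp_path):
        """Missing-call count equals an interval-overlap oracle's count."""
        from intervaltree import IntervalTree

        rng = np.random.default_rng(8)
        gts = [["0|1", "1|1", "0|0", "1|0", "0|1"] for _ in range(10)]
        vcf_in = toy_vcf(tmp_path, gts)
        paintings = []
        for h in range(10):
            cut = float(rng.integers(50, 950))
            for (a, b, lab) in [(0.0, cut, Population.ANA),
                                (cut, 1000.0, Population.EHG)]:
                probs = tuple(0.97 if AncestryLabel.CLASSES[i] is lab
                              else 0.01 for i in range(4))
                paintings.append(PaintedSegment(h, "1", a, b, lab, probs))
        out = tmp_path / "masked.vcf"
        counts = mask_vcf(vcf_in, out, paintings, Population.ANA,
                          toy_metadata())
        trees = {}
        for s in paintings:
            trees.setdefault(s.haplotype_id, IntervalTree())[
                s.start:s.end] = s.label
        expected_masked = 0
        for site in range(10):
            pos0 = 100 * (site + 1) - 1
            for h in range(10):
                hit = next(iter(trees[h][pos0])).data
                if hit is not Population.ANA:
                    expected_masked += 1
        assert counts["masked"] == expected_masked
        assert counts["kept"] + counts["masked"] == 100

    def test_unpainted_haplotype_raises(self, tmp_path):
        gts = [["0|1", "1|1", "0|0", "1|0", "0|1"]]
        vcf_in = toy_vcf(tmp_path, gts)
        paintings = paint_all(Population.ANA)[:-1]   # haplotype 9 unpainted
        with pytest.raises(ValueError, match="haplotype 9"):
            mask_vcf(vcf_in, tmp_path / "m.vcf", paintings,
                     Population.ANA, toy_metadata())


class TestAncestryFrequency:
    def test_hand_counted_fraction(self, tmp_path):
        # 8 haplotypes painted ANA (first 4 samples), 3 carry derived
        gts = [["1|0", "1|0", "1|0", "0|0", "1|1"]]
        vcf_in = toy_vcf(tmp_path, gts)
        paintings = paint_all(Population.ANA, n_haps=8)
        paintings += [
            PaintedSegment(8, "1", 0.0, 1000.0, Population.WHG,
                           (0.01, 0.97, 0.01, 0.01)),
            PaintedSegment(9, "1", 0.0, 1000.0, Population.WHG,
                           (0.01, 0.97, 0.01, 0.01)),
        ]
        f, num, den = ancestry_allele_frequency(
            vcf_in, paintings, ("1", 100), Population.ANA, toy_metadata())
        assert (num, den) == (3, 8)
        assert f == pytest.approx(0.375)

    def test_all_and_none_derived(self, tmp_path):
        gts = [["1|1", "1|1", "1|1", "1|1", "1|1"],
               ["0|0", "0|0", "0|0", "0|0", "0|0"]]
        vcf_in = toy_vcf(tmp_path, gts)
        paintings = paint_all(Population.ANA)
        f1, _, _ = ancestry_allele_frequency(
            vcf_in, paintings, ("1", 100), Population.ANA, toy_metadata())
        f0, _, _ = ancestry_allele_frequency(
            vcf_in, paintings, ("1", 200), Population.ANA, toy_metadata())
        assert (f1, f0) == (1.0, 0.0)

    def test_zero_denominator_is_undefined(self, tmp_path):
        gts = [["1|0", "0|0", "0|0", "0|0", "0|0"]]
        vcf_in = toy_vcf(tmp_path, gts)
        paintings = paint_all(Population.ANA)
        f, num, den = ancestry_allele_frequency(
            vcf_in, paintings, ("1", 100), Population.CHG, toy_metadata())
        assert np.isnan(f) and (num, den) == (0, 0)

    def test_numerators_sum_to_unmasked_count(self, tmp_path):
        """Per-ancestry derived counts partition the total derived count."""
        rng = np.random.default_rng(9)
        gts = [["|".join(map(str, rng.integers(0, 2, 2)))
                for _ in range(5)] for _ in range(6)]
        vcf_in = toy_vcf(tmp_path, gts)
        paintings = []
        for h in range(10):
            lab = AncestryLabel.CLASSES[int(rng.integers(0, 4))]
            probs = tuple(0.97 if AncestryLabel.CLASSES[i] is lab else 0.01
                          for i in range(4))
            paintings.append(PaintedSegment(h, "1", 0.0, 1000.0, lab, probs))
        meta = toy_metadata()
        for site in range(6):
            pos = 100 * (site + 1)
            total = sum(int(a) for row in [gts[site]] for gt in row
                        for a in gt.split("|"))
            by_anc = sum(
                ancestry_allele_frequency(vcf_in, paintings, ("1", pos),
                                          anc, meta)[1]
                for anc in AncestryLabel.CLASSES)
            assert by_anc == total

    def test_missing_site_raises(self, tmp_path):
        vcf_in = toy_vcf(tmp_path, [["0|0"] * 5])
        with pytest.raises(ValueError, match="not present"):
            ancestry_allele_frequency(vcf_in, paint_all(Population.ANA),
                                      ("1", 999), Population.ANA,
                                      toy_metadata())


def test_haplotype_columns_phase_order():
    cols = haplotype_columns(toy_metadata())
    assert cols == {f"S{i}": (2 * i, 2 * i + 1) for i in range(5)}
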