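"""Paint haplotypes, mask a phased VCF to one ancestry, and compute an
ancestry-conditioned allele frequency.

Trains a small transformer on a toy two-ancestry world, paints the
admixed haplotypes tree by tree, writes a VCF with everything except
ANA-painted alleles set to missing, and conditions a derived-allele
frequency on local ancestry — the inputs ancestry-specific PCA,
f-statistics and selection scans consume.
"""

import tempfile
from pathlib import Path

import numpy as np

from arglai.demography import simulate, true_local_ancestry, \
    two_population_toy
from arglai.model import ModelConfig
from arglai.painting import (ancestry_allele_frequency, mask_vcf,
                             predict_path, write_paintings)
from arglai.arg_io import Population
from arglai.subgraph import TokenVocabulary
from arglai.training import (DatasetSpec, TrainConfig, make_dataset,
                             train_transformer)

vocab = TokenVocabulary.default()
config = two_population_toy(sequence_length=1e6)
handle, _ = simulate(config, seed=5)

truth = true_local_ancestry(handle, config)
ds = make_dataset(handle, truth,
                  DatasetSpec(stride=1, max_examples=600, focal_per_tree=6,
                              seed=1), vocab)
model_cfg = ModelConfig(vocab_size=len(vocab), d_model=32, n_heads=4,
                        n_layers=2, d_ff=64, dropout=0.0)
result = train_transformer(model_cfg, ds, ds,
                           TrainConfig(batch_size=256, epochs=3, seed=2))
print(f"painter trained to {result.log.val_acc[result.best_epoch]:.1%} "
      "accuracy (in-sample; this example is about the downstream tools)")

targets = [h for h, m in sorted(handle.metadata.items())
           if not m.is_reference][:10]
segments = predict_path(result.params, model_cfg, handle, targets, vocab)
print(f"painted {len(targets)} haplotypes into {len(segments)} segments")

workdir = Path(tempfile.mkdtemp())
vcf_path = workdir / "cohort.vcf"
names = [f"ind{i.id}" for i in handle.ts.individuals()]
with open(vcf_path, "w") as fh:
    handle.ts.write_vcf(fh, individual_names=names)

# restrict the VCF to the painted individuals, then mask to ANA ancestry
import subprocess
painted_inds = sorted({handle.metadata[h].individual_id for h in targets})
sub_vcf = workdir / "painted.vcf"
subprocess.run(["bcftools", "view", "-s", ",".join(painted_inds),
                "-o", str(sub_vcf), str(vcf_path)], check=True)
masked_vcf = workdir / "masked.vcf"
counts = mask_vcf(sub_vcf, masked_vcf, segments, Population.ANA,
                  handle.metadata)
print(f"masked VCF written: kept {counts['kept']} allele calls, "
      f"set {counts['masked']} to missing across {counts['records']} sites")

first_pos = next(int(line.split("\t")[1]) for line in open(sub_vcf)
                 if not line.startswith("#"))
f, num, den = ancestry_allele_frequency(sub_vcf, segments, ("1", first_pos),
                                        Population.ANA, handle.metadata)
print(f"site 1:{first_pos}: derived-allele frequency on ANA-painted "
      f"haplotypes = {f if den else float('nan'):.3f} ({num}/{den} calls)")
print("Only calls whose covering painted segment is ANA enter the "
      "numerator/denominator, so the frequency is specific to that "
      "ancestral background.")
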