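"""Simulate the four-way admixture world and extract exact truth labels.

Builds a scaled-down version of the default demography (Anatolian farmers
and three hunter-gatherer groups merging into Neolithic, Yamnaya and
later European gene pools), simulates a tree sequence with census
recording, and prints the true genome-wide ancestry dosage of the
admixed sample classes.
"""

import collections

import numpy as np

from arglai.demography import (SamplingEvent, default_config, simulate,
                               true_local_ancestry)

config = default_config()
config.sequence_length = 5e5
config.sampling = [
    SamplingEvent("ANA", "ANA", 280.0, 8),
    SamplingEvent("WHG", "WHG", 300.0, 8),
    SamplingEvent("EHG", "EHG", 300.0, 8),
    SamplingEvent("CHG", "CHG", 320.0, 6),
    SamplingEvent("NEO", "NEO", 180.0, 8),
    SamplingEvent("YAM", "YAM", 160.0, 4),
    SamplingEvent("EUR", "POSTNEO", 50.0, 6),
    SamplingEvent("EUR", "PRESENT", 0.0, 6),
]

handle, genotypes = simulate(config, seed=1)
print(f"simulated {handle.num_trees} marginal trees over "
      f"{handle.sequence_length:.0f} bp, {handle.ts.num_samples} haplotypes, "
      f"{genotypes.shape[1]} variant sites")

truth = true_local_ancestry(handle, config)
span = collections.defaultdict(lambda: collections.Counter())
for seg in truth:
    pop = handle.metadata[seg.haplotype_id].population.value
    span[pop][seg.label.value] += seg.end - seg.start

print("\nmean true ancestry dosage by sample class "
      "(fraction of genome per ancestral class):")
for pop in ("NEO", "YAM", "POSTNEO", "PRESENT"):
    total = sum(span[pop].values())
    parts = ", ".join(f"{anc}={span[pop][anc] / total:.2f}"
                      for anc in ("ANA", "WHG", "EHG", "CHG"))
    print(f"  {pop:8s} {parts}")

print("\nNEO haplotypes should carry mostly ANA with some WHG; YAM splits "
      "between CHG and EHG; POSTNEO/PRESENT mix all four.")
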