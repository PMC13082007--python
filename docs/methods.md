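# Methods

## Problem and model

Local ancestry inference assigns each genomic segment of an admixed
haplotype to its source population.  `arglai` treats this as subgraph
classification on the marginal coalescent trees of an ARG: the ancestry
of a segment determines which reference haplotypes its lineage coalesces
with first, so the local tree around the focal haplotype carries the
signal directly, even for admixture old enough that haplotype-frequency
methods lose power.

### Subgraph extraction

For a focal extant haplotype in one marginal tree we keep

* the focal leaf (token `FOCAL_UNKNOWN` — deliberately blinded so the
  label being predicted can never leak through its own token, and so
  admixed target samples cannot shortcut through their cohort label);
* its *k* = 25 nearest reference leaves by TMRCA, all reference
  populations pooled.  References are the four ancestral classes plus the
  admixed-but-informative Neolithic (ANA+WHG) and Yamnaya (CHG+EHG)
  samples; post-Neolithic and present-day haplotypes are never
  references.  Ties in ψ break by ascending haplotype id so extraction is
  deterministic;
* its *m* = 3 immediate ancestral nodes (token `ANCESTOR`; internal ARG
  nodes carry no population label).

Trees too shallow for (*k*, *m*) yield flagged examples padded with a
`PAD` token (ψ = cap against everything, excluded by the attention mask).

### Relative position

ψ(i, j) = min(τ_MRCA(i, j) − τ_i, cap) with cap = 1000 generations,
rounded half-up to an integer, giving L = 1001 table rows.  ψ is
asymmetric because it is measured from each node's own sample time;
below the cap ψ(i,j) + τ_i = ψ(j,i) + τ_j.  ψ is computed uniformly for
every ordered token pair, ancestors included, using each node's own time
as τ.  Negative raw values can arise only from numerical noise and are
clamped to 0 with a warning.  Metadata sample times are authoritative
for leaf times (inferred genealogies may carry perturbed leaf times).

### Transformer

Per layer and head: q/k/v projections of the token embeddings, attention
scores (q_i·k_j + q_i·P_query[ψ_ij] + k_j·P_key[ψ_ij]) / √d_z, row
softmax (max-subtracted; masked positions at −10⁹), and outputs
Σ_j â_ij (v_j + P_value[ψ_ij]).  The ψ tables are shared across heads
within a layer, separate across layers (a config flag shares them
everywhere), and the bias is applied in every layer.  Blocks are
pre-layer-norm residual with a ReLU feed-forward; the classifier reads
the focal token's final representation (a masked-mean readout is
available as a config option).  Defaults: 4 layers, 8 heads,
d_model = 128 (d_z = 16), feed-forward 512, dropout 0.1 — small enough
for desk-scale training on 29-token examples.  Attention is permutation
equivariant, so the classification is invariant to reference token order;
with all ψ tables zero the network reduces exactly to a plain
transformer encoder.  Both properties are asserted in the tests, as is
agreement of the attention block with an element-by-element oracle and
of backpropagated gradients with finite differences.

### Numerical stack

No automatic-differentiation framework ships in the dependency set, so
the package carries a ~300-line reverse-mode tape over numpy
(`arglai.nn.autograd`): broadcasting arithmetic, two-operand einsum with
a GEMM-shaped backward, table gather with bincount scatter-add, and the
usual nonlinearities.  Training defaults to float32 (float64 is the
construction default elsewhere); the optimizer is Adam (lr 10⁻³, cosine
decay, batch 256, ≤30 epochs) and the checkpoint kept is the epoch with
minimal validation loss.  Cross-entropy over the four ancestral classes
is the only loss; admixed sample classes enter training solely through
their segments' true ancestral labels.

### GNN baseline

The comparison method aggregates, for each of the focal's first five
ancestral nodes, the population proportions of reference leaves in that
ancestor's subtree plus their mean sample time (one scalar per level;
a global-mean variant is a config switch), zero-padding shallow chains
with explicit flags.  Proportions count reference leaves only, matching
the transformer's panel logic.  The flattened 40-dimensional vector
feeds a 2×64 ReLU MLP trained with the same optimizer, loss and example
sets as the transformer, so accuracy comparisons are paired by
construction.

## Simulation and ground truth

The default world is a structurally faithful four-way model with round
numbers: ANA/WHG and EHG/CHG diverge at 1,500 generations from western
and eastern ancestors that join at 3,000; pulses form NEO at 250
(0.75 ANA + 0.25 WHG), YAM at 200 (0.5 CHG + 0.5 EHG) and the European
gene pool at 150 (0.5 NEO + 0.5 YAM); sample counts default to the
reference-panel sizes of the real cohort the model family targets
(22 ANA, 48 WHG, 42 EHG, 13 CHG, 159 NEO, 13 YAM, 654 post-Neolithic,
660 present-day diploids), with ancient sample ages between 160 and 320
generations.  Effective sizes default to 5,000 (ancient), 10,000
(admixed) and 20,000 (recent).  Mutation rate 1.25×10⁻⁸ /bp/gen, flat
recombination 10⁻⁸ /bp/gen (a HapMap-format genetic map is pluggable);
genomes are diploid.  The exact parameterization of any published
demography can be supplied as YAML; configs also record the effective
size (30,000) and mutation rate conventionally passed to external
genealogy inference for users who run it on the simulated VCFs.

Ground truth comes from census recording: census events sit one
generation above every admixture pulse, so each lineage of an admixed
sample carries census nodes, and the first one (climbing rootward) whose
population is an ancestral class is the segment's true ancestry.
Samples drawn directly from ancestral-class populations are pure by
construction and labelled without climbing (they may predate every
census).  The labelling agrees exactly with an independent oracle built
on the tree-sequence library's `link_ancestors` in the tests.

Misspecified worlds scale each effective size by a two-sided factor of
1–50%, increase admixture times by 1–25% (never decrease, so the
demography stays consistent with sample ages) and move divergence times
±1–25%; inconsistent draws are resampled with bounded retries.  Genotype
error flips each haplotype call independently with probability 0.001
(applied per haploid call; the alternative per-diploid-genotype reading
is not used).

## Dataset and evaluation conventions

Training keeps every 10th tree and validation every 100th ("skipping"
is read as decimation — keeping 1 tree in 10 — matching its stated
purpose of reducing local correlation; the drop-1-in-10 reading is a
config option).  A tree's example label is the truth segment covering
its interval midpoint.  Focal haplotypes are drawn per retained tree,
uniformly over the eligible target classes (NEO, YAM, POSTNEO, PRESENT
by default) and then uniformly within class; balance across classes is
the default with a config override.  Evaluation reports per-class
accuracy as mean ± sd over test replicates, with a paired delta when two
models are given.  Paintings merge consecutive same-argmax trees by pure
run-length encoding (no smoothing layer) with span-weighted mean
probabilities; breakpoints therefore always lie on tree boundaries.

Masking preserves ploidy and phase: each allele is independently kept or
set to missing according to the painted ancestry of its haplotype at
that site, so diploid genotypes can be half-missing.  How downstream
tools treat half-missing genotypes is left to them.
Ancestry-conditioned allele frequencies count only non-missing calls
whose covering segment has the requested ancestry; a zero denominator is
reported as undefined with counts (0, 0), not as 0%.

## What the synthetic worlds do and do not show

The generator reproduces the genealogical mechanism the classifier
exploits — admixture pulses, drift, recombination, sample ages, census
truth — and the misspecification scheme used for robustness checks.  It
does not emulate genealogy-inference error beyond the flat genotype-flip
rate (no tree-topology error model), phasing or imputation artifacts, or
the exact published demography parameterization, which is deliberately
not bundled.  Passing tests therefore demonstrate correctness of the
machinery and the expected learning behaviour under idealized trees, not
field accuracy on inferred ARGs.

The learning-sanity benchmark in the acceptance tests uses the easy
two-ancestry world (effective size 200 so most coalescence falls below
the ψ cap, divergence at 5,000 generations, 50/50 pulse at 100), with
5,000 training and 1,000 validation examples from independent replicates
and a reduced architecture (2 layers, 4 heads, d_model 64, no dropout),
sized to finish in a few minutes on one CPU.  Under these conditions the
transformer reaches 100% validation accuracy and the GNN baseline ~91%;
the full-scale benchmark deltas reported for this model family require
the published demography, inferred (not true) genealogies and
500,000-example replicates, and are outside this package's test scope.

## Known limitations

* Attention is quadratic in subgraph size; fine at 29 tokens, but whole
  trees are not a supported input.
* ψ discretization is one row per generation; demographies whose
  informative coalescence happens almost entirely above the 1,000
  generation cap leave both ψ and the nearest-reference ranking
  uninformative (the ranking sorts clamped values).
* The CPU-only numpy engine trains desk-scale models; hundreds of
  thousands of examples at the default architecture call for a GPU
  framework implementation of the same equations.
* Polytomies are accepted as-is; no resolution is attempted.
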