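"""Simulation, perturbation, error injection and ground-truth labelling."""

import collections

import msprime
import numpy as np
import pytest

from arglai.arg_io import Population
from arglai.demography import (
    AdmixturePulse,
    DemographyConfig,
    PerturbationConfig,
    PopulationSpec,
    SamplingEvent,
    Split,
    TruthSegment,
    default_config,
    inject_genotype_error,
    load_truth_segments,
    perturb,
    simulate,
    true_local_ancestry,
    two_population_toy,
    write_truth_segments,
)


class TestSimulate:
    def test_schedule_counts_and_times(self):
        config = DemographyConfig(
            populations=[PopulationSpec("WHG", 1000.0)],
            splits=[], pulses=[],
            sampling=[SamplingEvent("WHG", "WHG", 250.0, 10)],
            sequence_length=1e5, ploidy=1)
        handle, _ = simulate(config, seed=1, mutations=False)
        leaves = handle.samples()
        assert len(leaves) == 10
        assert all(handle.metadata[v].sample_time == 250.0 for v in leaves)
        assert all(handle.metadata[v].population is Population.WHG
                   for v in leaves)

    def test_same_seed_reproduces(self):
        config = two_population_toy(sequence_length=2e5)
        h1, g1 = simulate(config, seed=9)
        h2, g2 = simulate(config, seed=9)
        assert h1.ts.tables.edges == h2.ts.tables.edges
        assert (g1 == g2).all()

    def test_neutral_diversity_matches_coalescent_expectation(self):
        # single constant-size population: E[pi] = 4 Ne mu per site
        Ne, mu = 2000.0, 1e-7
        config = DemographyConfig(
            populations=[PopulationSpec("A", Ne)],
            splits=[], pulses=[],
            sampling=[SamplingEvent("A", "WHG", 0.0, 10)],
            sequence_length=2e5, mutation_rate=mu, ploidy=2)
        pis = []
        for rep in range(20):
            handle, _ = simulate(config, seed=1000 + rep)
            pis.append(handle.ts.diversity())
        expected = 4 * Ne * mu
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(np.mean(pis) - expected) < 3 * se

    def test_invalid_config_fails_before_simulation(self):
        config = two_population_toy()
        config.sampling[2] = SamplingEvent("NEO", "NEO", 500.0, 5)  # > pulse
        with pytest.raises(ValueError, match="older than the event"):
            simulate(config, seed=1)


class TestPerturb:
    def test_zero_width_ranges_are_identity(self):
        config = default_config()
        p = PerturbationConfig(ne_lo=0, ne_hi=0, admix_lo=0, admix_hi=0,
                               div_lo=0, div_hi=0)
        out = perturb(config, p, seed=4)
        assert [x.Ne for x in out.populations] == \
            [x.Ne for x in config.populations]
        assert [x.time for x in out.pulses] == [x.time for x in config.pulses]
        assert [x.time for x in out.splits] == [x.time for x in config.splits]

    def test_ne_factors_within_band_and_outside_deadzone(self):
        config = default_config()
        p = PerturbationConfig()
        factors = []
        for rep in range(100):
            out = perturb(config, p, seed=rep)
            factors += [a.Ne / b.Ne for a, b in
                        zip(out.populations, config.populations)]
        factors = np.array(factors)
        assert len(factors) == 1000
        assert ((factors >= 0.5) & (factors <= 1.5)).all()
        assert (np.abs(factors - 1.0) >= 0.01 - 1e-12).all()

    def test_admixture_times_strictly_increase(self):
        config = default_config()
        p = PerturbationConfig()
        for rep in range(100):
            out = perturb(config, p, seed=5000 + rep)
            for new, old in zip(out.pulses, config.pulses):
                assert new.time > old.time
                assert new.time <= old.time * 1.25 + 1e-9

    def test_divergence_times_two_sided(self):
        config = default_config()
        seen_older = seen_younger = False
        for rep in range(50):
            out = perturb(config, PerturbationConfig(), seed=7000 + rep)
            for new, old in zip(out.splits, config.splits):
                ratio = new.time / old.time
                assert 0.75 - 1e-9 <= ratio <= 1.25 + 1e-9
                seen_older |= ratio > 1
                seen_younger |= ratio < 1
        assert seen_older and seen_younger

    def test_perturbed_worlds_always_simulate(self):
        config = default_config()
        config.sequence_length = 1e5
        for ev in config.sampling:
            ev.n_individuals = 2
        for rep in range(5):
            out = perturb(config, PerturbationConfig(), seed=100 + rep)
            handle, _ = simulate(out, seed=1, mutations=False)
            assert handle.num_trees >= 1


class TestGenotypeError:
    def test_rate_zero_is_identity(self):
        g = np.random.default_rng(0).integers(0, 2, (50, 40))
        out, n = inject_genotype_error(g, rate=0.0, seed=1)
        assert (out == g).all() and n == 0

    def test_rate_one_complements(self):
        g = np.random.default_rng(0).integers(0, 2, (50, 40))
        out, n = inject_genotype_error(g, rate=1.0, seed=1)
        assert (out == 1 - g).all() and n == g.size

    def test_realized_rate_within_binomial_error(self):
        g = np.zeros((1000, 1000), dtype=np.int8)
        out, n = inject_genotype_error(g, rate=0.001, seed=3)
        frac = n / g.size
        sd = np.sqrt(0.001 * 0.999 / g.size)
        assert abs(frac - 0.001) < 4 * sd
        assert (out != g).sum() == n

    def test_shape_and_order_preserved(self):
        g = np.random.default_rng(1).integers(0, 2, (10, 20))
        out, _ = inject_genotype_error(g, rate=0.5, seed=2)
        assert out.shape == g.shape

    def test_bad_rate_raises(self):
        with pytest.raises(ValueError, match="outside"):
            inject_genotype_error(np.zeros((2, 2), dtype=int), rate=1.5)


def segments_by_hap(segments):
    by = collections.defaultdict(list)
    for s in segments:
        by[s.haplotype_id].append(s)
    for v in by.values():
        v.sort(key=lambda s: s.start)
    return by


def oracle_truth_link_ancestors(handle, config):
    """Independent oracle: the tree-sequence library's link_ancestors maps
    each sample interval to its census-node ancestor directly."""
    ts = handle.ts
    flags = ts.tables.nodes.flags
    census = np.where((flags & msprime.NODE_IS_CEN_EVENT) != 0)[0]
    pop_names = {p.id: p.metadata["name"] for p in ts.populations()}
    node_pop = ts.tables.nodes.population
    samples = [h for h in handle.samples()
               if handle.metadata[h].population.value
               not in ("ANA", "WHG", "EHG", "CHG")]
    edges = ts.tables.link_ancestors(samples=samples,
                                     ancestors=census.tolist())
    out = collections.defaultdict(list)
    for left, right, parent, child in zip(edges.left, edges.right,
                                          edges.parent, edges.child):
        if child in samples:
            out[int(child)].append(
                (float(left), float(right),
                 Population(pop_names[node_pop[parent]])))
    for v in out.values():
        v.sort()
    return out


class TestTruthLabels:
    def test_reference_haplotypes_are_pure(self, toy_world):
        config, handle, truth = toy_world
        by = segments_by_hap(truth)
        for h, m in handle.metadata.items():
            if m.population is Population.WHG:
                assert len(by[h]) == 1
                seg = by[h][0]
                assert (seg.start, seg.end, seg.label) == \
                    (0.0, handle.sequence_length, Population.WHG)

    def test_degenerate_full_pulse_labels_everything_source(self):
        config = two_population_toy(sequence_length=3e5,
                                    proportions=(1.0, 0.0))
        handle, _ = simulate(config, seed=31, mutations=False)
        truth = true_local_ancestry(handle, config)
        for s in truth:
            if not handle.metadata[s.haplotype_id].is_reference:
                assert s.label is Population.ANA

    def test_segments_tile_every_haplotype(self, toy_world):
        _, handle, truth = toy_world
        by = segments_by_hap(truth)
        for h in handle.samples():
            segs = by[h]
            assert segs[0].start == 0.0
            assert segs[-1].end == handle.sequence_length
            for a, b in zip(segs, segs[1:]):
                assert a.end == b.start

    def test_balanced_pulse_mean_fraction(self):
        """Genome-wide ANA fraction ~ 0.5 under a 50/50 pulse.

        Haplotypes within one replicate share the drift of the admixture
        pulse, so the standard error is taken over independent replicate
        means, not over haplotypes.
        """
        config = two_population_toy(n_target_individuals=50,
                                    sequence_length=2e6, Ne=500.0,
                                    admixture_time=50.0)
        rep_means = []
        for rep in range(10):
            handle, _ = simulate(config, seed=600 + rep, mutations=False)
            truth = true_local_ancestry(handle, config)
            by = segments_by_hap(truth)
            fracs = [
                sum(s.end - s.start for s in by[h]
                    if s.label is Population.ANA) / handle.sequence_length
                for h in handle.samples()
                if not handle.metadata[h].is_reference
            ]
            rep_means.append(np.mean(fracs))
        se = np.std(rep_means, ddof=1) / np.sqrt(len(rep_means))
        assert abs(np.mean(rep_means) - 0.5) < 3 * se

    def test_labels_agree_exactly_with_link_ancestors_oracle(self):
        config = two_population_toy(n_target_individuals=100,
                                    sequence_length=2e6)
        handle, _ = simulate(config, seed=77, mutations=False)
        truth = true_local_ancestry(handle, config)
        targets = [h for h in handle.samples()
                   if not handle.metadata[h].is_reference]
        by = segments_by_hap(truth)
        oracle = oracle_truth_link_ancestors(handle, config)
        for h in targets:
            ours = [(s.start, s.end, s.label) for s in by[h]]
            merged = []
            for left, right, label in oracle[h]:
                if merged and merged[-1][2] is label \
                        and merged[-1][1] == left:
                    merged[-1] = (merged[-1][0], right, label)
                else:
                    merged.append((left, right, label))
            assert ours == merged

    def test_missing_census_raises(self):
        config = two_population_toy(sequence_length=1e5)
        handle, _ = simulate(config, seed=5, mutations=False)
        ts = handle.ts
        tables = ts.dump_tables()
        flags = tables.nodes.flags
        flags[:] = flags & ~np.uint32(msprime.NODE_IS_CEN_EVENT)
        tables.nodes.flags = flags
        from arglai.arg_io import TreeSequenceHandle
        stripped = TreeSequenceHandle(tables.tree_sequence(), handle.metadata)
        with pytest.raises(ValueError, match="census"):
            true_local_ancestry(stripped, config)


def test_truth_segments_tsv_round_trip(tmp_path, toy_world):
    _, _, truth = toy_world
    path = tmp_path / "truth.tsv"
    write_truth_segments(truth, path)
    back = load_truth_segments(path)
    assert [(s.haplotype_id, s.start, s.end, s.label) for s in back] == \
        [(s.haplotype_id, s.start, s.end, s.label) for s in truth]


def test_config_yaml_round_trip(tmp_path):
    config = default_config()
    path = tmp_path / "demo.yaml"
    config.to_yaml(path)
    back = DemographyConfig.from_yaml(path)
    assert back == config
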