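"""The pooled-plaque generator: truth bookkeeping, noise field, determinism."""

import numpy as np
import pytest

from plaquecall.calling import round_half_up
from plaquecall.pileup_counts import EventKey
from plaquecall.spectrum_stats import SUB_CLASSES, classify
from plaquecall.synthetic import (
    ConfigError,
    SimConfig,
    build_noise_field,
    random_gene,
    simulate_calibration_mixture,
    simulate_pools,
    simulate_wildtype_pools,
)


def small_config(gene, **overrides):
    defaults = dict(
        gene=gene,
        n_samples=2,
        n_plaques=40,
        depth=4000,
        seed=5,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_unnormalized_class_probs(self, toy_gene):
        with pytest.raises(ConfigError):
            SimConfig(gene=toy_gene, class_probs={"GC>TA": 0.5})

    def test_unknown_class(self, toy_gene):
        with pytest.raises(ConfigError):
            SimConfig(gene=toy_gene, class_probs={"bogus": 1.0})

    def test_clonal_fraction_domain(self, toy_gene):
        with pytest.raises(ConfigError):
            SimConfig(gene=toy_gene, clonal_fraction=1.0)

    def test_hotspot_weights_shape(self, toy_gene):
        with pytest.raises(ConfigError):
            SimConfig(gene=toy_gene, hotspot_weights=np.ones(10))


class TestTruthTable:
    def test_driving_copies_sum_to_n_plaques(self, toy_gene):
        result = simulate_pools(small_config(toy_gene))
        for animal in result.truth.mutations:
            assert result.truth.driving_copies(animal) == 40

    def test_zero_clonal_fraction_gives_distinct_singletons(self, toy_gene):
        result = simulate_pools(small_config(toy_gene, clonal_fraction=0.0))
        for mutations in result.truth.mutations.values():
            assert all(m.copies == 1 for m in mutations)
            events = [m.event for m in mutations]
            assert len(events) == len(set(events)) == 40

    def test_classes_match_events(self, toy_gene):
        result = simulate_pools(small_config(toy_gene))
        for mutations in result.truth.mutations.values():
            for m in mutations:
                if m.event.kind == "sub":
                    assert classify(toy_gene.base(m.event.position), m.event) == m.mutation_class
                else:
                    assert m.mutation_class in ("ins", "del")

    def test_substitution_positions_respect_class_strand(self, toy_gene):
        result = simulate_pools(small_config(toy_gene, seed=9))
        for mutations in result.truth.mutations.values():
            for m in mutations:
                if m.mutation_class in SUB_CLASSES:
                    pair = m.mutation_class.split(">")[0]
                    assert toy_gene.base(m.event.position) in pair

    def test_hotspot_weights_concentrate_mutations(self, toy_gene):
        weights = np.full(len(toy_gene), 1e-6)
        weights[99:110] = 1.0  # positions 100-110 dominate
        result = simulate_pools(
            small_config(toy_gene, hotspot_weights=weights, clonal_fraction=0.0, seed=3)
        )
        positions = [
            m.event.position
            for mutations in result.truth.mutations.values()
            for m in mutations
        ]
        inside = sum(1 for p in positions if 95 <= p <= 115)
        assert inside / len(positions) > 0.95


class TestNoiseField:
    def test_rates_within_configured_range(self, toy_gene):
        config = small_config(toy_gene)
        rng = np.random.default_rng(0)
        rates = build_noise_field(config, rng)
        lo, hi = config.sub_noise_range
        subs = [r for e, r in rates.items() if e.kind == "sub"]
        assert min(subs) >= lo and max(subs) <= hi
        assert len(subs) == 3 * len(toy_gene)

    def test_homopolymer_indel_elevation(self, toy_gene):
        config = small_config(toy_gene, indel_noise_multiplier_at_homopolymers=1000.0)
        rng = np.random.default_rng(0)
        rates = build_noise_field(config, rng)
        from plaquecall.reference import find_homopolymers

        runs = {r.start: r for r in find_homopolymers(toy_gene, config.homopolymer_min_len)}
        hi = config.sub_noise_range[1]
        elevated = [
            r for e, r in rates.items() if e.kind == "del" and e.position in runs and r > hi
        ]
        assert elevated, "indel noise at long homopolymers should exceed the substitution range"

    def test_shared_across_libraries(self, toy_gene):
        """Per-event proportions vary across libraries like binomial draws
        around one common rate, not like independent rates."""
        config = small_config(toy_gene, depth=20_000, pcr_error_rate=0.0)
        result = simulate_wildtype_pools(config, n_pools=4)
        ratios = []
        for event, rate in result.noise_truth.false_prop.items():
            if event.kind != "sub" or not 1e-3 < rate < 1e-2:
                continue
            props = [
                pair[i].counts.get(event, 0) / config.depth
                for pair in result.matrices.values()
                for i in range(2)
            ]
            binom_var = rate * (1 - rate) / config.depth
            ratios.append(np.var(props, ddof=1) / binom_var)
        assert 0.5 < float(np.mean(ratios)) < 2.0


class TestGeneratedCounts:
    def test_seeded_determinism(self, toy_gene):
        config = small_config(toy_gene)
        first = simulate_pools(config)
        second = simulate_pools(small_config(toy_gene))
        for animal in first.matrices:
            for a, b in zip(first.matrices[animal], second.matrices[animal]):
                assert a == b
        assert first.truth.mutations == second.truth.mutations

    def test_noiseless_single_plaque_limit(self):
        gene = random_gene(120, seed=1)
        config = SimConfig(
            gene=gene,
            n_samples=1,
            n_plaques=1,
            depth=10_000,
            sub_noise_range=(0.0, 0.0),
            pcr_error_rate=0.0,
            groups=("treated",),
            seed=2,
        )
        result = simulate_pools(config)
        (mutation,) = result.truth.mutations["treated1"]
        for matrix in result.matrices["treated1"]:
            assert matrix.counts == {mutation.event: 10_000}
            assert int(matrix.depth[0]) == 10_000

    def test_event_counts_never_exceed_depth(self, toy_gene):
        result = simulate_pools(small_config(toy_gene, n_plaques=5, depth=200))
        for pair in result.matrices.values():
            for matrix in pair:
                per_position = {}
                for event, count in matrix.counts.items():
                    per_position[event.position] = per_position.get(event.position, 0) + count
                for position, total in per_position.items():
                    assert total <= matrix.depth[position - 1]

    def test_proportions_track_truth_within_binomial_error(self, toy_gene):
        config = small_config(toy_gene, depth=30_000, seed=11, groups=("treated",))
        result = simulate_pools(config)
        for animal, mutations in result.truth.mutations.items():
            for matrix in result.matrices[animal]:
                for m in mutations:
                    rate = m.copies / config.n_plaques + result.noise_truth.get(m.event)
                    rate = min(rate, 1.0)
                    sigma = np.sqrt(rate * (1 - rate) / config.depth) or 1 / config.depth
                    observed = matrix.counts.get(m.event, 0) / config.depth
                    assert abs(observed - rate) < 5 * sigma + 2 / config.depth


class TestCalibrationMixture:
    def test_noiseless_proportions_exact(self):
        gene = random_gene(300, seed=4)
        copies = [1, 2, 4, 8, 16]
        depth = 31_000  # multiple of sum(copies): exact expected counts
        points, (rep_a, _), events = simulate_calibration_mixture(
            copies, gene, depth=depth, noise=None, seed=6
        )
        total = sum(copies)
        for event, c in zip(events, copies):
            assert rep_a.counts[event] == round_half_up(depth * c / total)
        assert [p.observed_count for p in points] == copies

    def test_hundred_unique_mutants_all_detected(self):
        gene = random_gene(600, seed=4)
        points, _, events = simulate_calibration_mixture(
            [1] * 100, gene, depth=50_000, noise=None, seed=7
        )
        assert len(set(events)) == 100
        assert all(p.observed_count == 1 for p in points)

    def test_plaque_weights_distort_proportions(self):
        gene = random_gene(300, seed=4)
        _, (rep_a, _), events = simulate_calibration_mixture(
            [1, 1], gene, depth=30_000, noise=None, seed=8, plaque_weights=[3.0, 1.0]
        )
        heavy, light = (rep_a.counts[e] for e in events)
        assert heavy == pytest.approx(3 * light, rel=0.01)

    def test_invalid_copies_rejected(self):
        gene = random_gene(60, seed=4)
        with pytest.raises(ValueError):
            simulate_calibration_mixture([0, 2], gene)
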