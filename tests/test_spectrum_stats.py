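"""Mutation classes, spectra, group statistics, hotspots and power."""

import numpy as np
import pytest
from scipy import stats

from plaquecall.calling import MutationCall, SamplePool
from plaquecall.pileup_counts import EventKey
from plaquecall.reference import COMPLEMENT, HomopolymerRun, ReferenceGene
from plaquecall.spectrum_stats import (
    ALL_CLASSES,
    DELETION,
    INSERTION,
    Spectrum,
    build_spectrum,
    classify,
    compare_classes,
    compare_mutant_frequency,
    compare_spectra,
    find_hotspots,
    homopolymer_association,
    is_transition,
    is_transversion,
    power_simulation,
)
from plaquecall.synthetic import DEFAULT_CLASS_PROBS


def make_call(event, count=1, sample="s1"):
    return MutationCall(
        event=event,
        true_prop_rep1=0.05,
        true_prop_rep2=0.05,
        threshold_used=0.01,
        raw_count=count,
        adjusted_count=count,
        sample=sample,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "ref,alt,expected,transversion",
        [
            ("G", "T", "GC>TA", True),
            ("C", "A", "GC>TA", True),
            ("A", "G", "AT>GC", False),
            ("T", "C", "AT>GC", False),
            ("G", "A", "GC>AT", False),
            ("A", "T", "AT>TA", True),
            ("C", "G", "GC>CG", True),
            ("T", "G", "AT>CG", True),
        ],
    )
    def test_collapsed_classes(self, ref, alt, expected, transversion):
        cls = classify(ref, EventKey(1, "sub", alt))
        assert cls == expected
        assert is_transversion(cls) is transversion
        assert is_transition(cls) is (not transversion)

    def test_indel_classes(self):
        assert classify("A", EventKey(1, "ins", "GT")) == INSERTION
        assert classify("A", EventKey(1, "del", 2)) == DELETION

    def test_complement_involution(self):
        for ref in "ACGT":
            for alt in "ACGT":
                if alt == ref:
                    continue
                direct = classify(ref, EventKey(1, "sub", alt))
                mirrored = classify(COMPLEMENT[ref], EventKey(1, "sub", COMPLEMENT[alt]))
                assert direct == mirrored

    def test_identity_rejected(self):
        with pytest.raises(ValueError):
            classify("G", EventKey(1, "sub", "G"))


class TestBuildSpectrum:
    @pytest.fixture()
    def gene(self):
        return ReferenceGene(name="g", sequence="GGGAAA")

    def test_independent_weighting(self, gene):
        calls = [
            make_call(EventKey(1, "sub", "T"), count=3),  # GC>TA
            make_call(EventKey(4, "sub", "T"), count=1),  # AT>TA
        ]
        props = build_spectrum(calls, gene, independent_only=True).proportions
        assert props["GC>TA"] == pytest.approx(0.5)
        assert props["AT>TA"] == pytest.approx(0.5)

    def test_copy_weighting(self, gene):
        calls = [
            make_call(EventKey(1, "sub", "T"), count=3),
            make_call(EventKey(4, "sub", "T"), count=1),
        ]
        props = build_spectrum(calls, gene, independent_only=False).proportions
        assert props["GC>TA"] == pytest.approx(0.75)
        assert props["AT>TA"] == pytest.approx(0.25)

    def test_same_event_two_samples_counts_twice(self, gene):
        calls = [
            make_call(EventKey(1, "sub", "T"), sample="s1"),
            make_call(EventKey(1, "sub", "T"), sample="s2"),
        ]
        assert build_spectrum(calls, gene).n_mutations == 2

    def test_proportions_sum_to_one(self, gene):
        rng = np.random.default_rng(1)
        calls = []
        for i in range(50):
            pos = int(rng.integers(1, 7))
            ref = gene.base(pos)
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            calls.append(make_call(EventKey(pos, "sub", alt), count=int(rng.integers(1, 5)),
                                   sample=f"s{i}"))
        for flag in (True, False):
            spectrum = build_spectrum(calls, gene, independent_only=flag)
            assert sum(spectrum.proportions.values()) == pytest.approx(1.0, abs=1e-12)


class TestCompareSpectra:
    def test_identical_counts(self):
        a = Spectrum(counts={"GC>TA": 10, "AT>TA": 10})
        result = compare_spectra(a, Spectrum(counts=dict(a.counts)))
        assert result["chi2"] == pytest.approx(0.0)
        assert result["p"] > 0.99

    def test_hand_computed_two_by_two(self):
        result = compare_spectra(
            Spectrum(counts={"GC>TA": 10, "AT>TA": 0}),
            Spectrum(counts={"GC>TA": 0, "AT>TA": 10}),
        )
        assert result["chi2"] == pytest.approx(20.0)
        assert result["df"] == 1

    def test_matches_scipy_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            counts_a = rng.integers(5, 60, size=4)
            counts_b = rng.integers(5, 60, size=4)
            a = Spectrum(counts={c: int(v) for c, v in zip(ALL_CLASSES, counts_a)})
            b = Spectrum(counts={c: int(v) for c, v in zip(ALL_CLASSES, counts_b)})
            result = compare_spectra(a, b)
            table = np.array([counts_a, counts_b])
            expected = stats.chi2_contingency(table, correction=False)
            if not result["monte_carlo"]:
                assert result["chi2"] == pytest.approx(expected.statistic)
                assert result["p"] == pytest.approx(expected.pvalue)
            else:
                assert result["chi2"] == pytest.approx(expected.statistic)
                assert 0.0 <= result["p"] <= 1.0

    def test_sparse_table_takes_monte_carlo_path(self):
        result = compare_spectra(
            Spectrum(counts={"GC>TA": 2, "AT>TA": 30}),
            Spectrum(counts={"GC>TA": 1, "AT>TA": 28}),
            n_mc=5000,
        )
        assert result["monte_carlo"] is True
        assert 0.0 <= result["p"] <= 1.0

    def test_monte_carlo_p_agrees_with_exact_enumeration_on_2x2(self):
        """MC p-value against exact enumeration of the conditional null."""
        a_counts, b_counts = (2, 20), (9, 8)
        a = Spectrum(counts={"GC>TA": a_counts[0], "AT>TA": a_counts[1]})
        b = Spectrum(counts={"GC>TA": b_counts[0], "AT>TA": b_counts[1]})
        result = compare_spectra(a, b, n_mc=100_000)
        assert result["monte_carlo"] is True

        def chi2_of(k):  # table [[k, na-k], [c1-k, nb-c1+k]] with fixed margins
            table = np.array(
                [
                    [k, sum(a_counts) - k],
                    [a_counts[0] + b_counts[0] - k, b_counts[1] - a_counts[0] + k],
                ],
                dtype=float,
            )
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row @ col / table.sum()
            return ((table - expected) ** 2 / expected).sum()

        n_a, n_b = sum(a_counts), sum(b_counts)
        c1 = a_counts[0] + b_counts[0]
        observed = chi2_of(a_counts[0])
        p_exact = sum(
            stats.hypergeom.pmf(k, n_a + n_b, c1, n_a)
            for k in range(max(0, c1 - n_b), min(n_a, c1) + 1)
            if chi2_of(k) >= observed - 1e-9
        )
        assert result["p"] == pytest.approx(p_exact, abs=0.01)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(ValueError):
            compare_spectra(Spectrum(counts={}), Spectrum(counts={"GC>TA": 2}))

    def test_per_class_holm_correction(self):
        a = Spectrum(counts={"GC>TA": 80, "GC>AT": 40, "AT>TA": 30})
        b = Spectrum(counts={"GC>TA": 20, "GC>AT": 60, "AT>TA": 32})
        result = compare_classes(a, b, method="holm")
        assert set(result) == {"GC>TA", "GC>AT", "AT>TA"}
        for entry in result.values():
            assert entry["p_adj"] >= entry["p_raw"]
        assert result["GC>TA"]["significant"]


class TestCompareMutantFrequency:
    def make_pools(self, control_rate, treated_rate, n=3, total_pfu=300_000, seed=0):
        rng = np.random.default_rng(seed)
        pools = []
        for group, rate in (("control", control_rate), ("treated", treated_rate)):
            for i in range(n):
                mutant = int(rng.poisson(rate * total_pfu))
                pools.append(SamplePool(f"{group}{i}", group, 100, mutant, total_pfu))
        return pools

    def test_identical_rates_give_unit_ratio(self):
        result = compare_mutant_frequency(self.make_pools(1e-4, 1e-4, n=6, seed=1))
        assert result["rate_ratio"] == pytest.approx(1.0, rel=0.25)
        assert result["p"] > 0.01

    def test_eighty_fold_induction_recovered(self):
        result = compare_mutant_frequency(self.make_pools(1e-4, 8e-3, seed=2))
        assert result["rate_ratio"] == pytest.approx(80.0, rel=0.2)
        assert result["p"] < 1e-3

    def test_single_animal_per_group_flagged(self):
        result = compare_mutant_frequency(self.make_pools(1e-4, 1e-3, n=1, seed=3))
        assert any("single-animal" in f for f in result["flags"])

    def test_zero_group_falls_back_to_exact_test(self):
        pools = [SamplePool(f"c{i}", "control", 100, 0, 300_000) for i in range(3)]
        pools += [SamplePool(f"t{i}", "treated", 100, 50, 300_000) for i in range(3)]
        result = compare_mutant_frequency(pools)
        assert result["method"] == "exact-cond"
        assert result["p"] < 0.001

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            compare_mutant_frequency([SamplePool("a", "control", 10, 1, 100)])


class TestHotspots:
    def test_one_per_animal_across_five_animals(self):
        calls = [make_call(EventKey(25, "sub", "T"), sample=f"m{i}") for i in range(5)]
        assert find_hotspots(calls, min_independent=4) == [(25, 5, 5)]

    def test_five_copies_in_one_animal_is_not_a_hotspot(self):
        calls = [make_call(EventKey(25, "sub", "T"), count=5, sample="m1")]
        assert find_hotspots(calls, min_independent=4) == []

    def test_empty(self):
        assert find_hotspots([], min_independent=4) == []

    def test_min_zero_returns_every_mutated_position_once(self):
        rng = np.random.default_rng(8)
        calls = [
            make_call(EventKey(int(p), "sub", "T"), sample=f"m{rng.integers(3)}")
            for p in rng.integers(1, 50, size=30)
        ]
        rows = find_hotspots(calls, min_independent=0)
        positions = [r[0] for r in rows]
        assert sorted(positions) == sorted({c.event.position for c in calls})

    def test_two_alt_bases_count_separately(self):
        calls = [
            make_call(EventKey(25, "sub", "T"), sample="m1"),
            make_call(EventKey(25, "sub", "A"), sample="m1"),
        ]
        assert find_hotspots(calls, min_independent=1) == [(25, 2, 2)]


class TestHomopolymerAssociation:
    RUNS = [HomopolymerRun(10, 3, "A"), HomopolymerRun(30, 2, "T")]

    def test_inside_run_counted(self):
        calls = [make_call(EventKey(11, "del", 1))]
        result = homopolymer_association(calls, self.RUNS, min_run_len=3, adjacency_bp=1)
        assert result[DELETION] == {"n_inside_or_adjacent": 1, "n_total": 1}

    def test_adjacent_counted(self):
        calls = [make_call(EventKey(9, "del", 1)), make_call(EventKey(13, "ins", "A"))]
        result = homopolymer_association(calls, self.RUNS, min_run_len=3, adjacency_bp=1)
        assert result[DELETION]["n_inside_or_adjacent"] == 1
        assert result[INSERTION]["n_inside_or_adjacent"] == 1

    def test_short_runs_and_substitutions_excluded(self):
        calls = [make_call(EventKey(30, "del", 1)), make_call(EventKey(11, "sub", "T"))]
        result = homopolymer_association(calls, self.RUNS, min_run_len=3, adjacency_bp=1)
        assert result[DELETION] == {"n_inside_or_adjacent": 0, "n_total": 1}
        assert result[INSERTION]["n_total"] == 0


class TestPowerSimulation:
    def full_list(self, n=350, seed=10):
        rng = np.random.default_rng(seed)
        classes = list(DEFAULT_CLASS_PROBS)
        probs = np.array(list(DEFAULT_CLASS_PROBS.values()))
        return list(rng.choice(classes, size=n, p=probs))

    def test_full_subsample_has_power_one(self):
        mutants = self.full_list(60)
        assert power_simulation(mutants, k=60, n_iter=50, seed=1) == 1.0

    def test_k_larger_than_list_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(self.full_list(20), k=21)

    def test_hundred_mutants_give_high_power(self):
        """~100 subsampled mutants retain the animal's spectrum in most draws."""
        power = power_simulation(self.full_list(350), k=100, n_iter=1000, alpha=0.05, seed=3)
        assert power >= 0.7

    def test_custom_metric_strategy(self):
        always_significant = lambda sub, full, rng: 0.0
        assert power_simulation(self.full_list(50), k=10, n_iter=20, metric=always_significant) == 0.0
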