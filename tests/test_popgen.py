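"""Frequency spectra, F_ST estimators, and permutation significance."""

import itertools

import numpy as np
import pytest

from tagarmt import (
    FrequencySpectrum,
    HVRIHaplotype,
    SampleRecord,
    SeriesTable,
    build_distance_matrix,
    fst_frequencies,
    fst_sequences,
    haplogroup_frequency,
    haplotype_spectrum,
    macro_fractions,
    pairwise_sequence_distance,
    parse_haplotype_string,
    permutation_test,
    slatkin_linearized,
)

H = parse_haplotype_string  # shorthand


def pop(haps, prefix="s", stage="P", name="pop"):
    return SeriesTable(
        [SampleRecord(f"{prefix}{i}", stage, h) for i, h in enumerate(haps)],
        name=name,
    )


# ---------------------------------------------------------------- spectra

class TestSpectrum:
    def test_fixture_diversity(self, series):
        spec = haplotype_spectrum(series)
        assert spec.total == 79
        assert spec.n_distinct == 39
        assert spec.n_singletons == 22

    def test_fixture_modal_haplotype(self, series):
        key, count = haplotype_spectrum(series).modal()
        assert key == "16126C-16163G-16186T-16189C-16294T"
        assert count == 10

    def test_identical_records(self):
        spec = haplotype_spectrum(pop([H("16311C")] * 3))
        assert spec.n_distinct == 1
        assert spec.n_singletons == 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            haplotype_spectrum(SeriesTable([]))

    def test_counts_must_sum(self):
        with pytest.raises(ValueError):
            FrequencySpectrum({"a": 2}, total=5)


class TestFractions:
    def test_overall_macro_split(self, called, motifs):
        west, east = macro_fractions(called, motifs)
        assert round(100 * west, 1) == 64.6
        assert round(100 * east, 1) == 35.4

    def test_stagewise_east(self, called, motifs):
        stages = called.stages()
        assert round(100 * macro_fractions(stages["Early"], motifs)[1], 1) == 34.8
        assert round(100 * macro_fractions(stages["Middle"], motifs)[1], 1) == 45.8

    def test_unassigned_record_named_in_error(self, motifs):
        bad = pop([H("16311C")])
        with pytest.raises(ValueError, match="s0"):
            macro_fractions(bad, motifs)

    def test_joint_cd_frequency(self, called, motifs):
        stages = called.stages()
        assert round(
            100 * haplogroup_frequency(stages["Early"], {"C", "D"}, motifs), 1
        ) == 8.7
        assert round(
            100 * haplogroup_frequency(stages["Middle"], {"C", "D"}, motifs), 1
        ) == 37.5

    def test_all_roots_give_unity(self, called, motifs):
        roots = {motifs.root(r.haplogroup_label) for r in called}
        assert haplogroup_frequency(called, roots, motifs) == 1.0

    def test_nested_labels_counted(self, called, motifs):
        # U4 aggregates its U4a3 sub-clade carriers
        assert round(100 * haplogroup_frequency(called, {"U4"}, motifs), 1) == 10.1
        assert round(100 * haplogroup_frequency(called, {"T1"}, motifs), 1) == 13.9


# ---------------------------------------------------------------- distance

class TestDistance:
    def test_self_distance_zero(self):
        h = H("16223T-16362C")
        assert pairwise_sequence_distance(h, h) == 0

    def test_distance_to_reference(self):
        assert pairwise_sequence_distance(H("rCRS"), H("16223T-16362C")) == 2

    def test_one_extra_substitution(self):
        # neighbouring fixture haplotypes differing by 16320T
        assert pairwise_sequence_distance(
            H("16223T-16362C"), H("16223T-16320T-16362C")
        ) == 1

    def test_same_position_different_state(self):
        # 16129A vs 16129C: the sequences differ at one position
        assert pairwise_sequence_distance(H("16129A"), H("16129C")) == 1

    def test_uncertain_and_indels_excluded_by_default(self):
        a = H("16051G-16129C-16183C-(16193insC)-16362C")
        b = H("16051G-16129C-16183C-16362C")
        assert pairwise_sequence_distance(a, b) == 0
        assert pairwise_sequence_distance(a, b, include_uncertain=True,
                                          include_indels=True) == 1


# ---------------------------------------------------------------- F_ST

def brute_force_fst(haps_a, haps_b):
    """Independent oracle: explicit pair enumeration, no shared code path."""
    def d(x, y):
        sx = {(v.position, v.derived) for v in x.variants
              if v.kind == "substitution" and not v.uncertain}
        sy = {(v.position, v.derived) for v in y.variants
              if v.kind == "substitution" and not v.uncertain}
        px = dict(sx); py = dict(sy)
        return sum(1 for p in set(px) | set(py) if px.get(p) != py.get(p))

    def mean_within(hs):
        pairs = [(i, j) for i in range(len(hs)) for j in range(i + 1, len(hs))]
        return sum(d(hs[i], hs[j]) for i, j in pairs) / len(pairs) if pairs else 0.0

    pi_w = 0.5 * (mean_within(haps_a) + mean_within(haps_b))
    pi_b = sum(d(x, y) for x in haps_a for y in haps_b) / (len(haps_a) * len(haps_b))
    if pi_b == 0:
        return 0.0
    return min(max((pi_b - pi_w) / pi_b, 0.0), 1.0)


class TestFstSequences:
    def test_identical_populations_zero(self):
        a = pop([H("16311C"), H("16223T")], "a")
        b = pop([H("16311C"), H("16223T")], "b")
        assert fst_sequences(a, b).fst == 0.0

    def test_fixed_difference_is_one(self):
        a = pop([H("16311C")] * 3, "a")
        b = pop([H("rCRS")] * 3, "b")
        assert fst_sequences(a, b).fst == 1.0

    def test_frozen_mixed_example(self):
        # popA = {h1,h1,h2}, popB = {h2,h2}, d(h1,h2)=1:
        # pi_W = (2/3 + 0)/2 = 1/3, pi_B = 4/6 = 2/3, F = 1/2
        h1, h2 = H("rCRS"), H("16311C")
        a = pop([h1, h1, h2], "a")
        b = pop([h2, h2], "b")
        assert fst_sequences(a, b).fst == pytest.approx(0.5)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fst_sequences(pop([H("rCRS")]), pop([H("rCRS")] * 2))

    def test_exhaustive_grid_matches_oracle(self):
        # all two-population splits of <= 6 individuals over 3 haplotypes
        haps = [H("rCRS"), H("16311C"), H("16223T-16362C")]
        for na in (2, 3):
            for nb in (2, 3):
                for ca in itertools.combinations_with_replacement(range(3), na):
                    for cb in itertools.combinations_with_replacement(range(3), nb):
                        a = pop([haps[i] for i in ca], "a")
                        b = pop([haps[i] for i in cb], "b")
                        got = fst_sequences(a, b).fst
                        want = brute_force_fst(
                            [haps[i] for i in ca], [haps[i] for i in cb]
                        )
                        assert got == pytest.approx(want, abs=1e-12)


class TestFstFrequencies:
    def test_identical_spectra_zero(self):
        s = FrequencySpectrum({"a": 2, "b": 2})
        assert fst_frequencies(s, s).fst == 0.0

    def test_disjoint_monomorphic_is_one(self):
        # H_S = 0 forces F_ST = 1
        assert fst_frequencies(
            FrequencySpectrum({"a": 4}), FrequencySpectrum({"b": 4})
        ).fst == 1.0

    def test_hand_computed_example(self):
        # {a:3,b:1} vs {a:1,b:3}: H_S = 0.375, H_T = 0.5, F = 0.25
        r = fst_frequencies(
            FrequencySpectrum({"a": 3, "b": 1}), FrequencySpectrum({"a": 1, "b": 3})
        )
        assert r.fst == pytest.approx(0.25)

    def test_shared_monomorphic_warns_zero(self):
        s = FrequencySpectrum({"a": 3})
        with pytest.warns(UserWarning, match="monomorphic"):
            assert fst_frequencies(s, s).fst == 0.0


class TestSlatkin:
    def test_half_maps_to_one(self):
        assert slatkin_linearized(0.5) == pytest.approx(1.0)

    def test_monotone_on_unit_interval(self):
        xs = np.linspace(0, 0.99, 50)
        ys = [slatkin_linearized(x) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))

    def test_zero_fixed_point(self):
        assert slatkin_linearized(0.0) == 0.0


# ------------------------------------------------------------- permutation

class TestPermutation:
    def test_same_seed_same_p(self):
        a = pop([H("rCRS")] * 3 + [H("16311C")], "a")
        b = pop([H("16311C")] * 3, "b")
        p1 = fst_sequences(a, b, n_permutations=100, seed=5).p_value
        p2 = fst_sequences(a, b, n_permutations=100, seed=5).p_value
        assert p1 == p2

    def test_identical_populations_not_significant(self):
        a = pop([H("rCRS"), H("16311C")] * 3, "a")
        b = pop([H("rCRS"), H("16311C")] * 3, "b")
        p = fst_sequences(a, b, n_permutations=100, seed=0).p_value
        assert p > 0.5

    def test_disjoint_monomorphic_attains_floor(self):
        # no permutation of two large fixed groups reaches F_ST = 1
        a = pop([H("rCRS")] * 10, "a")
        b = pop([H("16311C")] * 10, "b")
        r = fst_sequences(a, b, n_permutations=100, seed=1)
        assert r.p_value == pytest.approx(1 / 101)

    def test_p_resolution(self):
        a = pop([H("rCRS")] * 4, "a")
        b = pop([H("16311C")] * 4, "b")
        r = fst_sequences(a, b, n_permutations=19, seed=2)
        assert (r.p_value * 20) == pytest.approx(round(r.p_value * 20))

    def test_invalid_permutation_count(self):
        with pytest.raises(ValueError):
            permutation_test([1], [2], lambda x, y: 0.0, n=0)

    def test_null_p_values_are_valid(self):
        # random splits of one pooled population: P(p <= alpha) <= alpha + MC err;
        # clamping F_ST at 0 makes the test conservative, never anti-conservative
        rng = np.random.default_rng(7)
        haps = [H(s) for s in ["rCRS", "16126C", "16189C-16294T", "16223T",
                               "16223T-16362C", "16311C"]]
        ps = []
        for rep in range(60):
            idx = rng.integers(0, len(haps), size=16)
            records = [SampleRecord(f"r{rep}x{i}", "P", haps[k])
                       for i, k in enumerate(idx)]
            a = SeriesTable(records[:8], name="a")
            b = SeriesTable(records[8:], name="b")
            ps.append(fst_sequences(a, b, n_permutations=49, seed=rep).p_value)
        ps = np.asarray(ps)
        for alpha in (0.05, 0.2, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / len(ps))
            assert np.mean(ps <= alpha) <= alpha + 3 * se
        assert np.mean(ps <= 0.5) > 0.0  # non-degenerate


# ------------------------------------------------------------- matrices

class TestDistanceMatrix:
    def test_three_identical_populations(self):
        p = [H("rCRS"), H("16311C")]
        pops = [pop(p, f"p{i}", name=f"pop{i}") for i in range(3)]
        m = build_distance_matrix(pops)
        assert np.allclose(m.values, 0.0)

    def test_stage_partition_properties(self, called):
        pops = list(called.stages().values())
        m = build_distance_matrix(pops)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0.0)
        assert np.all(np.isfinite(m.values))
        assert m.labels == [p.name for p in pops]

    def test_linearized_entries(self, called):
        pops = list(called.stages().values())
        raw = build_distance_matrix(pops, linearize=False)
        lin = build_distance_matrix(pops, linearize=True)
        assert np.all(lin.values >= raw.values - 1e-15)

    def test_failure_names_the_pair(self):
        good = pop([H("rCRS"), H("16311C")], "g", name="good")
        tiny = pop([H("rCRS")], "t", name="tiny")
        with pytest.raises(ValueError, match="tiny"):
            build_distance_matrix([good, good, tiny])
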