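"""Connectivity measures and group statistics."""

import numpy as np
import pandas as pd
import pytest

from monotrace import (CountMatrix, DistanceSample, build_count_matrix,
                       ci_table, convergence_index, cumulative_fraction,
                       distance_sample, input_fraction, ks_compare, kw_tukey,
                       pearson, proportions_longrange, top_k_coverage)
from conftest import make_cell_table


def small_count_matrix():
    counts = pd.DataFrame(
        {"A1": [60, 40], "AuD": [10, 5], "AuV": [5, 5],
         "MGv": [50, 30], "AC_contra": [30, 15], "MGd": [20, 5]},
        index=pd.Index(["a1", "a2"], name="animal_id"))
    starters = pd.Series([100, 50], index=counts.index)
    groups = pd.Series(["PV", "SST"], index=counts.index)
    return CountMatrix(counts=counts, starters=starters, groups=groups)


class TestConvergenceIndex:
    def test_zero_inputs(self):
        assert convergence_index(0, 10) == 0.0

    def test_direct_ratio(self):
        assert convergence_index(300, 100) == 3.0

    def test_zero_starters_is_an_error(self):
        with pytest.raises(ValueError):
            convergence_index(5, 0)

    def test_ci_table_splits_local_and_longrange(self):
        cm = small_count_matrix()
        ci = ci_table(cm)
        assert ci.loc["a1", "ci_total"] == pytest.approx(1.75)
        assert ci.loc["a1", "ci_local"] == pytest.approx(0.75)
        assert ci.loc["a1", "ci_longrange"] == pytest.approx(1.0)


class TestProportions:
    def test_rows_sum_to_one(self):
        props = proportions_longrange(small_count_matrix())
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)
        assert list(props.columns) == ["MGv", "AC_contra", "MGd"]

    def test_known_values(self):
        props = proportions_longrange(small_count_matrix())
        assert props.loc["a1"].tolist() == pytest.approx([0.5, 0.3, 0.2])

    def test_single_nonzero_region(self):
        cm = small_count_matrix()
        cm.counts.loc["a1", ["AC_contra", "MGd"]] = 0
        props = proportions_longrange(cm)
        assert props.loc["a1", "MGv"] == 1.0

    def test_all_zero_animal_excluded(self):
        cm = small_count_matrix()
        cm.counts.loc["a2", ["MGv", "AC_contra", "MGd"]] = 0
        props = proportions_longrange(cm)
        assert list(props.index) == ["a1"]


class TestInputFractions:
    def test_local_fraction(self):
        frac = input_fraction(small_count_matrix(), "local")
        assert frac["a1"] == pytest.approx(75 / 175)

    def test_all_local_gives_one(self):
        cm = small_count_matrix()
        cm.counts.loc[:, ["MGv", "AC_contra", "MGd"]] = 0
        assert (input_fraction(cm, "local") == 1.0).all()

    def test_contralateral_fraction(self):
        frac = input_fraction(small_count_matrix(), "contralateral")
        assert frac["a1"] == pytest.approx(30 / 175)

    def test_fractions_in_unit_interval(self):
        cm = small_count_matrix()
        for sel in ("local", "contralateral"):
            f = input_fraction(cm, sel)
            assert ((f >= 0) & (f <= 1)).all()

    def test_binomial_split_matches_longrange_fraction(self, small_config):
        """With longrange_fraction = 0.25, mean local fraction across animals
        should sit within 3 SE of 0.75."""
        from monotrace import simulate_experiment

        truth = simulate_experiment(small_config, seed=21)
        cm = build_count_matrix(truth.cells, truth.longrange_counts)
        frac = input_fraction(cm, "local")
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.75) <= 3 * max(se, 1e-6)


class TestTopK:
    def test_k_all_regions_is_one(self):
        props = proportions_longrange(small_count_matrix())
        assert np.allclose(top_k_coverage(props, 3), 1.0)
        assert np.allclose(top_k_coverage(props, 99), 1.0)

    def test_top_two(self):
        props = proportions_longrange(small_count_matrix())
        assert top_k_coverage(props, 2)["a1"] == pytest.approx(0.8)


class TestDistances:
    def test_coincident_input_and_starter(self):
        st = make_cell_table([100.0], channel_class="starter")
        inp = make_cell_table([100.0])
        d = distance_sample(inp, st, axis="dv", mode="pairwise")
        assert d.distances.tolist() == [0.0]

    def test_pairwise_and_centerline_arithmetic(self):
        st = make_cell_table([0.0, 100.0], channel_class="starter")
        inp = make_cell_table([40.0])
        pw = distance_sample(inp, st, axis="dv", mode="pairwise")
        assert sorted(pw.distances) == [40.0, 60.0]
        cl = distance_sample(inp, st, axis="dv", mode="centerline")
        assert cl.distances.tolist() == [10.0]

    def test_pairwise_sample_size(self, rng):
        st = make_cell_table(rng.uniform(0, 100, 7), channel_class="starter")
        inp = make_cell_table(rng.uniform(0, 100, 13))
        d = distance_sample(inp, st, axis="dv", mode="pairwise")
        assert len(d.distances) == 7 * 13

    def test_animals_never_mixed(self):
        st = pd.concat([
            make_cell_table([0.0], animal_id="A", channel_class="starter"),
            make_cell_table([1000.0], animal_id="B", channel_class="starter"),
        ], ignore_index=True)
        inp = pd.concat([
            make_cell_table([10.0], animal_id="A"),
            make_cell_table([990.0], animal_id="B"),
        ], ignore_index=True)
        d = distance_sample(inp, st, axis="dv", mode="pairwise")
        assert sorted(d.distances) == [10.0, 10.0]

    def test_layer_restriction(self):
        st = make_cell_table([0.0], channel_class="starter")
        inp = pd.concat([make_cell_table([50.0], layer="L2/3"),
                         make_cell_table([70.0], layer="L5")],
                        ignore_index=True)
        d = distance_sample(inp, st, axis="dv", mode="pairwise", layer="L5")
        assert d.distances.tolist() == [70.0]

    def test_empty_tables_rejected(self):
        st = make_cell_table([0.0], channel_class="starter")
        with pytest.raises(ValueError):
            distance_sample(st.iloc[:0], st, "dv", "pairwise")


class TestCumulativeFraction:
    def test_single_value_step(self):
        sample = DistanceSample(np.array([5.0]), "dv", "pairwise")
        grid = np.array([0.0, 4.9, 5.0, 10.0])
        np.testing.assert_allclose(cumulative_fraction(sample, grid),
                                   [0.0, 0.0, 1.0, 1.0])

    def test_uniform_sample_within_dkw_band(self, rng):
        d = rng.uniform(0.0, 1000.0, 10_000)
        grid = np.linspace(0.0, 1000.0, 201)
        cdf = cumulative_fraction(DistanceSample(d, "dv", "pairwise"), grid)
        assert np.max(np.abs(cdf - grid / 1000.0)) < 0.02

    def test_monotone_and_reaches_one(self, rng):
        d = rng.exponential(100.0, 500)
        grid = np.linspace(0.0, d.max() + 1.0, 100)
        cdf = cumulative_fraction(DistanceSample(d, "dv", "pairwise"), grid)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == 1.0


def brute_force_ks(a, b):
    """sup over pooled sample points of |F_a - F_b|, by direct counting."""
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        best = max(best, abs(fa - fb))
    return best


class TestKS:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        stat, p = ks_compare(a, a.copy())
        assert stat == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        stat, _ = ks_compare(np.array([1.0, 2.0, 3.0]),
                             np.array([4.0, 5.0, 6.0]))
        assert stat == 1.0

    def test_statistic_matches_brute_force(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(2, 15))
            b = rng.normal(0.5, 1.5, rng.integers(2, 15))
            stat, _ = ks_compare(a, b)
            assert stat == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ks_compare(np.array([1.0]), np.array([1.0, 2.0]))


class TestGroupComparison:
    def test_null_type_one_error_near_alpha(self):
        """Permuted-label null: the omnibus should reject in about 5% of
        replicates at alpha = .05."""
        rng = np.random.default_rng(7)
        n_rep, rejections = 500, 0
        for _ in range(n_rep):
            groups = {g: rng.normal(0, 1, 10) for g in ("PV", "SST", "VIP")}
            if kw_tukey(groups).p_value < 0.05:
                rejections += 1
        assert 0.025 <= rejections / n_rep <= 0.075

    def test_strong_shift_all_pairwise_significant(self):
        rng = np.random.default_rng(11)
        groups = {"PV": rng.normal(0, 1, 10), "SST": rng.normal(3, 1, 10),
                  "VIP": rng.normal(6, 1, 10)}
        comp = kw_tukey(groups)
        assert comp.p_value < 0.05
        assert comp.posthoc == "tukey"
        assert len(comp.pairwise) == 3 and all(c.significant for c in comp.pairwise)

    def test_identical_constant_groups_degenerate(self):
        comp = kw_tukey({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0]})
        assert comp.p_value == 1.0 and comp.degenerate

    def test_no_posthoc_when_omnibus_fails(self):
        rng = np.random.default_rng(3)
        comp = kw_tukey({"a": rng.normal(0, 1, 8), "b": rng.normal(0, 1, 8)},
                        alpha=1e-6)
        assert comp.posthoc is None and comp.pairwise == []

    def test_dunn_alternative_agrees_on_strong_effect(self):
        rng = np.random.default_rng(13)
        groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(4, 1, 12)}
        comp = kw_tukey(groups, posthoc="dunn")
        assert comp.posthoc == "dunn"
        assert comp.pairwise[0].significant


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(1.0, 15.0)
        r, p = pearson(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self):
        x = np.arange(1.0, 10.0)
        r, _ = pearson(x, -x + 5.0)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(0, 1, 14)
        y = rng.normal(0, 1, 14)
        r, _ = pearson(x, y)
        manual = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std(ddof=0) * y.std(ddof=0)))
        assert r == pytest.approx(manual, rel=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEndToEndPatterns:
    def test_sst_curve_rightmost_at_median(self, small_config,
                                           default_geometry):
        """With sigma_SST > sigma_PV = sigma_VIP, the SST pairwise-distance
        distribution should have the largest median in >= 95% of replicates."""
        from monotrace import sample_local_inputs, sample_starters

        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            medians = {}
            for gi, group in enumerate(("PV", "SST", "VIP")):
                st = sample_starters(small_config, group, 100 * rep + gi,
                                     geometry=default_geometry, n=50)
                li = sample_local_inputs(st, small_config, 100 * rep + gi + 50,
                                         geometry=default_geometry, n=200)
                d = distance_sample(li, st, axis="dv", mode="pairwise")
                medians[group] = np.median(d.distances)
            if medians["SST"] == max(medians.values()):
                wins += 1
        assert wins / n_rep >= 0.95

    def test_ci_independent_of_starter_count(self, small_config):
        """With a fixed per-starter input rate, the correlation between
        starter count and CI is centred at zero across replicates."""
        from monotrace import simulate_animal

        rs = []
        for rep in range(30):
            cis, counts = [], []
            for a in range(8):
                cells, lr, tot = simulate_animal(
                    small_config, "PV", f"PV{a}", 1000 * rep + a)
                cis.append((tot["n_local"] + tot["n_longrange"])
                           / tot["n_starters"])
                counts.append(tot["n_starters"])
            r, _ = pearson(counts, cis)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.2
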