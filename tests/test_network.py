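"""Ratio normalization, Spearman statistics, edge filtering, network diffing."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vinemet import network, synth
from vinemet.io import BIOCHEMICAL_CLASSES
from tests.conftest import make_table


def brute_force_spearman(x, y):
    """Independent oracle: Pearson on hand-averaged ranks."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            mean_rank = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = mean_rank
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def brute_force_exact_p(x, y):
    """Enumerate every permutation of y and count |rho| at least as extreme."""
    rho_obs = brute_force_spearman(x, y)
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(brute_force_spearman(x, perm)) >= abs(rho_obs) - 1e-12:
            hits += 1
    return hits / total


class TestRatioToControl:
    def test_division_by_control_mean(self):
        table = make_table(
            {("Cs", "25"): [[2.0], [2.0], [2.0], [2.0]], ("Cs", "35"): [[3.0], [2.0], [1.0]]},
            ["M"],
        )
        ratio = network.ratio_to_control(table, "Cs")
        assert ratio.ratios["M"].tolist() == [1.5, 1.0, 0.5]

    def test_control_subset_size(self):
        table = make_table(
            {("Cs", "25"): [[1.0], [3.0], [100.0]], ("Cs", "35"): [[4.0], [2.0], [2.0]]},
            ["M"],
        )
        ratio = network.ratio_to_control(table, "Cs", n_control=2)
        assert ratio.ratios["M"].iloc[0] == pytest.approx(2.0)

    def test_missing_group_rejected(self, tiny_table):
        with pytest.raises(ValueError, match="no control samples"):
            network.ratio_to_control(tiny_table, "Cs", control_temp="15")

    def test_planted_fold_change_appears_as_mean_ratio(self, fixture_effects):
        config = synth.SimConfig(
            effects=fixture_effects, n_replicates=1000, noise_sd=0.05, seed=23
        )
        table = synth.generate_abundance_table(config)
        ratio = network.ratio_to_control(table, "Sh")
        assert ratio.ratios["Raffinose"].mean() == pytest.approx(3.13, rel=0.05)


class TestSpearmanRho:
    def test_monotone_transform_gives_unity(self):
        x = np.arange(1.0, 9.0)
        assert network.spearman_rho(x, x**2) == pytest.approx(1.0)
        assert network.spearman_rho(x, -x) == pytest.approx(-1.0)

    def test_tied_data_matches_hand_ranked_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        assert network.spearman_rho(x, y) == pytest.approx(
            brute_force_spearman(x, y), abs=1e-12
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            network.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @given(
        st.lists(st.integers(0, 20), min_size=4, max_size=8),
        st.sampled_from([np.exp, np.cbrt, lambda v: 3 * v + 7]),
    )
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_strictly_monotone_maps(self, values, transform):
        x = np.arange(len(values), dtype=float)
        y = np.asarray(values, float)
        if np.ptp(y) == 0:
            return
        before = network.spearman_rho(x, y)
        after = network.spearman_rho(x, transform(y))
        assert before == pytest.approx(after, abs=1e-12)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(size=12), rng.normal(size=12)
            assert network.spearman_rho(x, y) == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12
            )


class TestSpearmanPvalue:
    def test_perfect_monotone_n5_exact_tail(self):
        x = [1, 2, 3, 4, 5]
        rho, p = network.spearman_pvalue(x, [2, 4, 6, 8, 10], method="exact_permutation")
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_zero_correlation_p_is_one(self):
        # x symmetric, y constant ranks pattern with rho exactly 0
        x = [1, 2, 3, 4]
        y = [1, 4, 4, 1]
        rho, p_exact = network.spearman_pvalue(x, y, method="exact_permutation")
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert p_exact == pytest.approx(1.0)
        _, p_t = network.spearman_pvalue(x, y, method="t_approx")
        assert p_t == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_exact_p_equals_brute_force_enumeration(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        y = rng.integers(0, 3, size=n).astype(float)  # ties on purpose
        if np.ptp(y) == 0:
            y[0] += 1.0
        _, p = network.spearman_pvalue(x, y, method="exact_permutation")
        assert p == pytest.approx(brute_force_exact_p(x, y), abs=1e-12)

    def test_t_approx_against_monte_carlo_permutation_at_n12(self):
        """The t approximation tracks the permutation null at n = 12.

        In the far tail (rho ~ 0.7) the t approximation is known to run
        ~20% anticonservative relative to the exact permutation null, so the
        check asserts agreement within 25% and an identical accept/reject
        decision at the pipeline's working alpha of 0.05.
        """
        rng = np.random.default_rng(42)
        x = np.arange(12.0)
        y = x + rng.normal(0, 4.0, size=12)
        rho, p_t = network.spearman_pvalue(x, y, method="t_approx")
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        draws = 100_000
        perm = np.array([rng.permutation(ry) for _ in range(draws)])
        rxc = rx - rx.mean()
        null = (perm - ry.mean()) @ rxc / np.sqrt(
            ((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum()
        )
        p_mc = np.mean(np.abs(null) >= abs(rho) - 1e-12)
        assert p_t == pytest.approx(p_mc, rel=0.25)
        assert (p_t < 0.05) == (p_mc < 0.05)

    def test_perfect_correlation_under_t_approx_falls_back(self):
        x = np.arange(12.0)
        _, p = network.spearman_pvalue(x, 2 * x, method="t_approx")
        assert p == pytest.approx(2 / math.factorial(12))

    def test_auto_switches_at_nine(self):
        x9, y9 = np.arange(9.0), np.arange(9.0) ** 2
        _, p9 = network.spearman_pvalue(x9, y9, method="auto")
        assert p9 == pytest.approx(2 / math.factorial(9))


@pytest.fixture
def abc_ratio():
    """Three profiles engineered so A-B is strong+, A-C strong-, B-C weak."""
    rng = np.random.default_rng(7)
    a = np.linspace(0.5, 2.0, 12) + rng.normal(0, 0.01, 12)
    b = a * rng.normal(1, 0.02, 12)
    c = 2.5 - a + rng.normal(0, 0.01, 12)
    d = np.abs(rng.normal(1, 0.3, 12)) + 0.05
    return network.RatioMatrix(
        variety="Cs", ratios=pd.DataFrame({"A": a, "B": b, "C": c, "D": d})
    )


ANNOT = {n: "glycolysis" for n in "ABCD"}


class TestBuildNetwork:
    def test_default_filter_keeps_significant_positive_only(self, abc_ratio):
        net = network.build_network(abc_ratio, ANNOT)
        assert ("A", "B") in net.edges
        assert all(rho > 0 for rho, _ in net.edges.values())
        assert ("A", "C") not in net.edges  # strong but negative
        assert set(net.nodes) == {m for pair in net.edges for m in pair}

    def test_both_policy_admits_negative_edges(self, abc_ratio):
        net = network.build_network(abc_ratio, ANNOT, sign_policy="both")
        assert ("A", "C") in net.edges
        assert net.edges[("A", "C")][0] < 0

    def test_no_filter_limit_gives_complete_graph(self, abc_ratio):
        net = network.build_network(
            abc_ratio, ANNOT, threshold=0.0, alpha=1.01, sign_policy="both"
        )
        assert net.n_edges == 6

    def test_filter_monotonicity(self, abc_ratio):
        """Raising the threshold or lowering alpha never adds edges."""
        loose = network.build_network(abc_ratio, ANNOT, threshold=0.3, alpha=0.2)
        for threshold, alpha in [(0.5, 0.2), (0.3, 0.05), (0.8, 0.01)]:
            tight = network.build_network(
                abc_ratio, ANNOT, threshold=threshold, alpha=alpha
            )
            assert tight.edge_pairs() <= loose.edge_pairs()

    def test_constant_profile_excluded_with_notice(self, caplog):
        ratios = pd.DataFrame(
            {"A": np.arange(1.0, 13.0), "B": np.ones(12), "C": np.arange(12.0, 0, -1)}
        )
        matrix = network.RatioMatrix(variety="Sh", ratios=ratios)
        with caplog.at_level("WARNING", logger="vinemet.network"):
            net = network.build_network(matrix, ANNOT, sign_policy="both")
        assert "constant ratio profile" in caplog.text
        assert "B" not in net.nodes

    def test_planted_block_edges_recovered_at_n12(self, fixture_effects):
        """rho_block = 0.85 blocks: >=80% sensitivity, <=10% false edges."""
        config = synth.SimConfig(
            effects=fixture_effects,
            n_replicates=12,
            block_correlation={c: 0.85 for c in BIOCHEMICAL_CLASSES},
            seed=29,
        )
        table = synth.generate_abundance_table(config)
        truth = synth.planted_truth(config, threshold=0.5)
        ratio = network.ratio_to_control(table, "Cs")
        net = network.build_network(ratio, config.annotation())
        edges = net.edge_pairs()
        planted = {pair for pair, flag in truth.items() if flag}
        background = {pair for pair, flag in truth.items() if not flag}
        sensitivity = len(edges & planted) / len(planted)
        false_rate = len(edges & background) / len(background)
        assert sensitivity >= 0.80
        assert false_rate <= 0.10


def _net(variety, pairs):
    return network.CorrelationNetwork(
        variety=variety,
        nodes={n: "glycolysis" for pair in pairs for n in pair},
        edges={tuple(sorted(p)): (0.9, 0.01) for p in pairs},
    )


class TestCompareNetworks:
    def test_set_arithmetic(self):
        cmp = network.compare_networks(
            _net("Cs", [("A", "B"), ("B", "C")]), _net("Sh", [("A", "B"), ("C", "D")])
        )
        assert cmp.common == {("A", "B")}
        assert cmp.unique["Cs"] == {("B", "C")}
        assert cmp.unique["Sh"] == {("C", "D")}
        assert cmp.percent_common["Cs"] == pytest.approx(50.0)

    def test_percent_common_from_published_counts(self):
        """112 edges of which 28 shared -> 25%; 137 of 28 -> 20%."""
        assert round(100 * 28 / 112) == 25
        cs_edges = [("A", f"n{i}") for i in range(112)]
        sh_edges = cs_edges[:28] + [("B", f"m{i}") for i in range(109)]
        cmp = network.compare_networks(_net("Cs", cs_edges), _net("Sh", sh_edges))
        assert len(cmp.common) == 28
        assert round(cmp.percent_common["Cs"]) == 25
        assert round(cmp.percent_common["Sh"]) == 20

    def test_identical_networks_fully_common(self):
        net = _net("Cs", [("A", "B"), ("B", "C")])
        cmp = network.compare_networks(net, _net("Sh", [("A", "B"), ("B", "C")]))
        assert cmp.unique["Cs"] == frozenset()
        assert cmp.percent_common["Cs"] == pytest.approx(100.0)

    def test_common_set_symmetric(self, abc_ratio):
        net_a = network.build_network(abc_ratio, ANNOT)
        shifted = network.RatioMatrix(
            variety="Sh", ratios=abc_ratio.ratios.iloc[::-1].reset_index(drop=True)
        )
        net_b = network.build_network(shifted, ANNOT)
        ab = network.compare_networks(net_a, net_b)
        ba = network.compare_networks(net_b, net_a)
        assert ab.common == ba.common

    def test_unique_edge_network_drops_common(self):
        net_a = _net("Cs", [("A", "B"), ("B", "C")])
        net_b = _net("Sh", [("A", "B")])
        cmp = network.compare_networks(net_a, net_b)
        uniq = network.unique_edge_network(net_a, cmp)
        assert set(uniq.edges) == {("B", "C")}
        assert set(uniq.nodes) == {"B", "C"}
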