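import numpy as np
import pytest
from scipy import stats

from infoflow import dev_analysis as da
from infoflow.significance import FunctionalNetwork


def _network(te, p_sig=1e-9):
    """FunctionalNetwork from a dense TE matrix (nonzero => significant)."""
    te = np.asarray(te, dtype=np.float64)
    n = te.shape[0]
    te = te.copy()
    p = np.where(te != 0, p_sig, 0.5)
    np.fill_diagonal(te, np.nan)
    np.fill_diagonal(p, np.nan)
    ids = tuple(f"e{i}" for i in range(n))
    return FunctionalNetwork(node_ids=ids, te=te, p=p, alpha_family=0.01,
                             n_tests=n * (n - 1))


def _rich_network(rng, n=6, frac=0.6):
    te = rng.exponential(1.0, (n, n)) * (rng.random((n, n)) < frac)
    return _network(te)


# -- brute-force oracles -----------------------------------------------------

def brute_spearman(x, y):
    """Average-rank Spearman with t-distribution two-sided p."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        for val in np.unique(v):
            m = v == val
            r[m] = r[m].mean()
        return r
    rx, ry = ranks(np.asarray(x, float)), ranks(np.asarray(y, float))
    rx -= rx.mean(); ry -= ry.mean()
    rho = (rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    n = len(rx)
    t = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, p


def brute_t_test(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((na - 1) * a.var(ddof=1)) + ((nb - 1) * b.var(ddof=1))) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def brute_binom_tail(k, n, alpha):
    from math import comb
    return sum(comb(n, j) * alpha ** j * (1 - alpha) ** (n - j)
               for j in range(k, n + 1))


class TestEdgeLockin:
    def test_identical_networks_correlate_perfectly(self, rng):
        net = _rich_network(rng)
        rho, p, n = da.edge_lockin(net, net)
        assert rho == pytest.approx(1.0)
        assert n == 30

    def test_rank_reversal_gives_minus_one(self, rng):
        te = rng.exponential(1.0, (6, 6)) + 0.1  # all nonzero -> no ties
        early = _network(te)
        late = _network(te.max() + 0.1 - te)
        rho, _, _ = da.edge_lockin(early, late)
        assert rho == pytest.approx(-1.0)

    def test_sparse_network_is_gated_out(self, rng):
        sparse = _network(np.zeros((6, 6)))
        rich = _rich_network(rng)
        with pytest.raises(da.GateError):
            da.edge_lockin(sparse, rich)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            a, b = _rich_network(rng), _rich_network(rng)
            rho, p, _ = da.edge_lockin(a, b)
            rho0, p0 = brute_spearman(a.edge_values(), b.edge_values())
            assert rho == pytest.approx(rho0, abs=1e-12)
            assert p == pytest.approx(p0, abs=1e-12)


class TestNodeFlowLockin:
    def test_single_edge_gives_single_nonzero_out_mean(self):
        te = np.zeros((5, 5))
        te[1, 3] = 2.0
        net = _network(te)
        # gate needs 10 significant values; bypass by calling mean_te directly
        out = net.mean_te("out")
        assert out[1] == pytest.approx(0.5)
        assert (out[[0, 2, 3, 4]] == 0).all()

    def test_symmetric_matrix_balances_in_and_out(self, rng):
        te = rng.exponential(1.0, (6, 6))
        te = te + te.T
        net = _network(te)
        np.testing.assert_allclose(net.mean_te("out"), net.mean_te("in"))

    def test_matches_brute_force_means(self, rng):
        a, b = _rich_network(rng), _rich_network(rng)
        rho, p, n = da.node_flow_lockin(a, b, "out")
        te_a = np.where(np.isnan(a.te), 0, a.te)
        te_b = np.where(np.isnan(b.te), 0, b.te)
        rho0, p0 = brute_spearman(
            te_a.sum(axis=1) / 5, te_b.sum(axis=1) / 5
        )
        assert rho == pytest.approx(rho0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)


class TestRoleRatio:
    @pytest.mark.parametrize(
        "out,inn,expected",
        [(2.0, 0.0, 1.0), (0.0, 3.0, 0.0), (1.5, 1.5, 0.5)],
    )
    def test_transmitter_receiver_mediator(self, out, inn, expected):
        r = da.role_ratio({"n": out}, {"n": inn})
        assert r["n"] == pytest.approx(expected)

    def test_zero_total_is_omitted(self):
        assert da.role_ratio({"n": 0.0}, {"n": 0.0}) == {}


class TestPositionRoleCorrelation:
    def test_monotone_relation_gives_one(self):
        pos = {f"n{i}": float(i + 1) for i in range(10)}
        tot = {f"n{i}": float(2 * i + 3) for i in range(10)}
        rho, p, n = da.position_role_correlation(pos, tot)
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_constant_totals_have_no_defined_direction(self):
        pos = {f"n{i}": float(i) for i in range(8)}
        tot = {f"n{i}": 1.0 for i in range(8)}
        rho, p, n = da.position_role_correlation(pos, tot)
        assert np.isnan(rho)

    def test_position_filter_restricts_nodes(self):
        pos = {f"n{i}": float(i) for i in range(30)}
        tot = {f"n{i}": float(-i if i > 20 else i) for i in range(30)}
        rho_all, _, n_all = da.position_role_correlation(pos, tot)
        rho_late, _, n_late = da.position_role_correlation(
            pos, tot, min_position=20
        )
        assert n_late == 9
        assert rho_late == pytest.approx(-1.0)
        assert rho_all > rho_late

    def test_matches_brute_force_with_ties(self, rng):
        pos = {f"n{i}": float(v) for i, v in
               enumerate(rng.integers(1, 6, 15))}
        tot = {f"n{i}": float(v) for i, v in
               enumerate(rng.integers(0, 4, 15))}
        rho, p, _ = da.position_role_correlation(pos, tot)
        keys = sorted(pos)
        rho0, p0 = brute_spearman([pos[k] for k in keys],
                                  [tot[k] for k in keys])
        assert rho == pytest.approx(rho0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)


class TestMeanTEComparison:
    def test_identical_samples_give_t_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        t, p = da.mean_te_comparison(v, v)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_gaussians_are_detected(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        _, p = da.mean_te_comparison(a, b)
        assert p < 1e-10

    def test_matches_hand_computation(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 9.0]
        t, p = da.mean_te_comparison(a, b)
        t0, p0 = brute_t_test(a, b)
        assert t == pytest.approx(t0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError):
            da.mean_te_comparison([1.0, 1.0], [1.0, 1.0])


class TestSignificanceCountTest:
    def test_all_significant_tail_is_alpha_power_n(self):
        k, n, tail, stars = da.significance_count_test([0.01] * 7, 0.05)
        assert (k, n) == (7, 7)
        assert tail == pytest.approx(0.05 ** 7, rel=1e-9)
        assert stars == "**"

    def test_none_significant_tail_is_one(self):
        k, n, tail, stars = da.significance_count_test([0.9] * 9, 0.05)
        assert (k, tail, stars) == (0, pytest.approx(1.0), "")

    def test_single_hit_closed_form(self):
        p_values = [0.01] + [0.9] * 8
        k, n, tail, _ = da.significance_count_test(p_values, 0.05)
        assert tail == pytest.approx(1 - 0.95 ** 9, rel=1e-12)

    def test_matches_brute_force_binomial(self, rng):
        p_values = rng.random(20)
        k, n, tail, _ = da.significance_count_test(p_values, 0.05)
        assert tail == pytest.approx(brute_binom_tail(k, n, 0.05), rel=1e-9)

    def test_bonferroni_factor_demotes_stars(self):
        p_values = [0.01] * 3 + [0.5] * 4
        *_, stars_raw = da.significance_count_test(p_values, 0.05)
        *_, stars_corr = da.significance_count_test(
            p_values, 0.05, bonferroni_factor=1000
        )
        assert stars_raw != "" and stars_corr == ""

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            da.significance_count_test([])


class TestSummarizeDistributions:
    def test_all_zero_recording(self):
        s = da.summarize_distributions(np.zeros(20))
        assert s.mean_te == 0.0
        assert s.n_significant == 0

    def test_small_constructed_case(self):
        s = da.summarize_distributions(np.array([1.0, 2.0, 3.0, 4.0]))
        assert s.mean_te == pytest.approx(2.5)
        assert s.n_significant == 4

    def test_extreme_outlier_excluded_from_quartiles_not_mean(self, rng):
        base = rng.normal(10, 1, 500)
        outlier = base.mean() + 12 * base.std(ddof=1)
        values = np.r_[base, outlier]
        s = da.summarize_distributions(values)
        assert s.n_outliers_excluded == 1
        assert s.mean_te == pytest.approx(values.mean())
        assert s.quartiles[2] < outlier

    def test_density_bandwidth_is_tenth_of_range(self, rng):
        vals = rng.uniform(0, 10, 200)
        s = da.summarize_distributions(vals)
        assert s.density is not None
        # the kde integrates to ~1 over the padded grid
        area = np.trapezoid(s.density, s.density_grid)
        assert area == pytest.approx(1.0, abs=0.05)


class TestLockinTable:
    def test_all_day_pairs_present_and_gated(self, rng):
        nets = {4: _rich_network(rng), 14: _rich_network(rng),
                20: _network(np.zeros((6, 6)))}
        table = da.lockin_table(nets, "edge")
        assert len(table) == 3
        gated = table[table.day_late == 20]
        assert gated.rho.isna().all()


class TestLongitudinalSet:
    def test_days_must_increase_and_nodes_match(self, rng):
        a, b = _rich_network(rng), _rich_network(rng)
        ls = da.LongitudinalSet("c1", {4: a, 14: b})
        assert ls.days == [4, 14]
        table = ls.edge_lockin_table()
        assert len(table) == 1
        small = FunctionalNetwork(
            node_ids=("x", "y"), te=np.full((2, 2), np.nan),
            p=np.full((2, 2), np.nan), n_tests=2,
        )
        with pytest.raises(ValueError, match="node universe"):
            da.LongitudinalSet("c1", {4: a, 14: small})


class TestLognormalityCheck:
    def test_lognormal_values_look_lognormal(self, rng):
        vals = rng.lognormal(0.0, 1.0, 500)
        stat, p = da.lognormality_check(vals)
        assert p > 0.01

    def test_uniform_values_do_not(self, rng):
        vals = rng.uniform(0.5, 1.0, 500) ** 8
        stat, p = da.lognormality_check(np.r_[vals, np.zeros(50)])
        assert p < 0.01

    def test_needs_enough_positive_values(self):
        with pytest.raises(ValueError):
            da.lognormality_check(np.ones(5))
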