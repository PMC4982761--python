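import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

import readthru as rt


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


def brute_force_ks_d(x, y):
    """Supremum of |ECDF difference| evaluated by explicit loops."""
    pts = sorted(set(list(x) + list(y)))
    best = 0.0
    for t in pts:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def kolmogorov_series_sf(lam, terms=100):
    """Q(lambda) = 2 * sum_{k>=1} (-1)^(k-1) exp(-2 k^2 lambda^2)."""
    if lam <= 0:
        return 1.0
    s = sum((-1) ** (k - 1) * math.exp(-2 * k * k * lam * lam)
            for k in range(1, terms + 1))
    return min(1.0, max(0.0, 2 * s))


def test_ks_identical_and_disjoint():
    res = rt.ks_two_sample([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
    assert res.statistic == 0.0 and res.p_value == 1.0
    res = rt.ks_two_sample([1, 2, 3], [4, 5, 6])
    assert res.statistic == 1.0


def test_ks_matches_brute_force_and_series():
    rng = np.random.default_rng(3)
    for _ in range(25):
        x = rng.normal(size=30)
        y = rng.normal(0.3, 1.2, size=40)
        res = rt.ks_two_sample(x, y)
        assert res.statistic == pytest.approx(brute_force_ks_d(x, y), abs=1e-14)
        ne = 30 * 40 / 70
        assert res.p_value == pytest.approx(
            kolmogorov_series_sf(math.sqrt(ne) * res.statistic), abs=1e-6
        )
        # ties: integer-valued samples
        xi = rng.integers(0, 5, size=20)
        yi = rng.integers(0, 5, size=25)
        res = rt.ks_two_sample(xi, yi)
        assert res.statistic == pytest.approx(brute_force_ks_d(xi, yi), abs=1e-14)


def test_ks_statistic_agrees_with_scipy():
    rng = np.random.default_rng(8)
    for _ in range(10):
        x = rng.exponential(size=35)
        y = rng.exponential(1.5, size=20)
        assert rt.ks_two_sample(x, y).statistic == pytest.approx(
            sps.ks_2samp(x, y).statistic, abs=1e-14
        )


def test_ks_invariant_under_monotone_transform():
    rng = np.random.default_rng(5)
    x = rng.normal(size=30)
    y = rng.normal(1.0, size=30)
    a = rt.ks_two_sample(x, y)
    b = rt.ks_two_sample(np.exp(x), np.exp(y))
    assert a.statistic == pytest.approx(b.statistic, abs=1e-14)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        rt.ks_two_sample([], [1.0])


# ---------------------------------------------------------------------------
# Fisher's exact test


def brute_force_fisher(table):
    """Full enumeration over margin-consistent tables via itertools."""
    t = np.asarray(table, dtype=np.int64)
    rows, cols = t.sum(axis=1), t.sum(axis=0)

    def log_prob(tab):
        from scipy.special import gammaln
        tab = np.asarray(tab)
        return (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                - gammaln(tab.sum() + 1) - gammaln(tab + 1).sum())

    lp_obs = log_prob(t)
    total = 0.0
    r, c = t.shape
    free_cells = [(i, j) for i in range(r - 1) for j in range(c - 1)]
    ranges = [range(int(min(rows[i], cols[j])) + 1) for i, j in free_cells]
    for combo in itertools.product(*ranges):
        tab = np.zeros((r, c), dtype=np.int64)
        for (i, j), v in zip(free_cells, combo):
            tab[i, j] = v
        tab[:-1, -1] = rows[:-1] - tab[:-1, :-1].sum(axis=1)
        tab[-1, :] = cols - tab[:-1, :].sum(axis=0)
        if (tab < 0).any():
            continue
        lp = log_prob(tab)
        if lp <= lp_obs + math.log1p(1e-12):
            total += math.exp(lp)
    return min(1.0, total)


def test_fisher_modal_table_p_is_one():
    assert rt.fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_fisher_extreme_table_closed_form():
    res = rt.fisher_exact([[10, 0], [0, 10]])
    assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)


@pytest.mark.parametrize(
    "table",
    [
        [[3, 7], [6, 2]],
        [[12, 5], [4, 9]],
        [[2, 5, 9], [8, 4, 2]],
        [[1, 0, 6], [5, 7, 2]],
    ],
)
def test_fisher_matches_full_enumeration(table):
    assert rt.fisher_exact(table).p_value == pytest.approx(
        brute_force_fisher(table), abs=1e-12
    )


def test_fisher_agrees_with_scipy_2x2():
    for table in ([[3, 7], [6, 2]], [[12, 5], [4, 9]], [[1, 9], [8, 2]]):
        _, p = sps.fisher_exact(table)
        assert rt.fisher_exact(table).p_value == pytest.approx(p, rel=1e-7)


def test_fisher_invariances_and_limits():
    t = [[2, 5, 9], [8, 4, 2]]
    p = rt.fisher_exact(t).p_value
    assert rt.fisher_exact(np.asarray(t)[:, ::-1]).p_value == pytest.approx(p, abs=1e-12)
    assert rt.fisher_exact(np.asarray(t).T).p_value == pytest.approx(p, abs=1e-12)
    with pytest.raises(ValueError, match="too large"):
        rt.fisher_exact(np.ones((4, 3), dtype=int))
    with pytest.raises(ValueError):
        rt.fisher_exact([[1, -2], [3, 4]])


# ---------------------------------------------------------------------------
# Pearson co-occupancy matrix


def test_pearson_trivial_pairs():
    rng = np.random.default_rng(1)
    base = rng.normal(size=100)
    corr = rt.pearson_matrix({"a": base, "b": base.copy(), "c": -base})
    i, j = corr.labels.index("a"), corr.labels.index("b")
    assert corr.matrix[i, j] == pytest.approx(1.0)
    assert corr.matrix[i, corr.labels.index("c")] == pytest.approx(-1.0)
    assert np.allclose(corr.matrix, corr.matrix.T)
    assert np.allclose(np.diag(corr.matrix), 1.0)


def test_pearson_matches_direct_formula():
    rng = np.random.default_rng(2)
    tracks = {f"t{i}": rng.normal(size=200) for i in range(5)}
    corr = rt.pearson_matrix(tracks)
    labs = corr.labels
    for i in range(5):
        for j in range(5):
            x, y = tracks[labs[i]], tracks[labs[j]]
            direct = (((x - x.mean()) * (y - y.mean())).mean()
                      / (x.std() * y.std()))
            assert corr.matrix[i, j] == pytest.approx(direct, abs=1e-12)


def test_pearson_zero_variance_names_label():
    with pytest.raises(ValueError, match="flatliner"):
        rt.pearson_matrix({"ok": np.r_[1.0, 2, 3], "flatliner": np.r_[2.0, 2, 2]})


def test_pearson_leaf_order_deterministic():
    rng = np.random.default_rng(4)
    tracks = {f"t{i}": rng.normal(size=50) for i in range(4)}
    a = rt.pearson_matrix(tracks)
    b = rt.pearson_matrix(tracks)
    assert a.leaf_order == b.leaf_order
    assert sorted(a.leaf_order) == [0, 1, 2, 3]


# ---------------------------------------------------------------------------
# t-test


def test_t_test_basics():
    x = np.r_[1.0, 2, 3, 4, 5]
    res = rt.t_test_two_tailed(x, x.copy())
    assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    rng = np.random.default_rng(6)
    a = rng.normal(0, 1, size=20)
    b = rng.normal(3, 1, size=20)
    assert rt.t_test_two_tailed(a, b).p_value < 1e-3

    r1 = rt.t_test_two_tailed(a, b)
    r2 = rt.t_test_two_tailed(10 * a, 10 * b)
    assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    with pytest.raises(ValueError):
        rt.t_test_two_tailed([1.0], [1.0, 2.0])
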