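"""Per-site binomial-logistic LRT against independent likelihood oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

import editome as ed
from editome.differential import SiteGroupCounts, dataframe_to_counts


def _counts(ka, na, kb, nb):
    return SiteGroupCounts(
        site=("chr1", 1, "+"), group_a="A", group_b="B",
        k_a=list(ka), n_a=list(na), k_b=list(kb), n_b=list(nb),
    )


def oracle_lrt(ka, na, kb, nb):
    """Brute-force likelihood maximisation: bounded scalar optimisation of the
    binomial log-likelihood per group and pooled (independent of the closed
    form under test)."""

    def nll(ks, ns):
        ks, ns = np.array(ks, float), np.array(ns, float)

        def f(p):
            p = min(max(p, 1e-12), 1 - 1e-12)
            return -float(np.sum(ks * np.log(p) + (ns - ks) * np.log(1 - p)))

        res = minimize_scalar(f, bounds=(1e-9, 1 - 1e-9), method="bounded",
                              options={"xatol": 1e-12})
        return res.fun

    ll1 = -(nll(ka, na) + nll(kb, nb))
    ll0 = -nll(list(ka) + list(kb), list(na) + list(nb))
    d = max(2 * (ll1 - ll0), 0.0)
    return d, chi2.sf(d, 1)


def g_test_2x2(k1, n1, k2, n2):
    """Closed-form likelihood-ratio (G) statistic of the pooled 2x2 table."""
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    tot = obs.sum()
    exp = obs.sum(axis=1, keepdims=True) * obs.sum(axis=0, keepdims=True) / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return 2 * terms.sum()


class TestLRT:
    def test_identical_groups_null(self):
        d, p = ed.lrt_binomial_glm(_counts([10] * 3, [100] * 3, [10] * 3, [100] * 3))
        assert d == 0.0 and p == 1.0

    def test_boundary_all_zero_or_all_edited(self):
        d, p = ed.lrt_binomial_glm(_counts([0, 0], [50, 50], [0], [50]))
        assert d == 0.0 and p == 1.0
        d, p = ed.lrt_binomial_glm(_counts([50], [50], [50, 50], [50, 50]))
        assert d == 0.0 and p == 1.0
        assert np.isfinite(d)

    def test_matches_brute_force_oracle(self):
        d, p = ed.lrt_binomial_glm(_counts([10] * 3, [100] * 3, [30] * 3, [100] * 3))
        d0, p0 = oracle_lrt([10] * 3, [100] * 3, [30] * 3, [100] * 3)
        assert abs(p - p0) <= 1e-4
        assert d == pytest.approx(d0, abs=1e-6)

    def test_fifty_random_tables_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            reps_a = int(rng.integers(1, 4))
            reps_b = int(rng.integers(1, 4))
            na = rng.integers(10, 200, size=reps_a)
            nb = rng.integers(10, 200, size=reps_b)
            ka = rng.binomial(na, rng.uniform(0.05, 0.95))
            kb = rng.binomial(nb, rng.uniform(0.05, 0.95))
            d, p = ed.lrt_binomial_glm(_counts(ka, na, kb, nb))
            d0, p0 = oracle_lrt(ka, na, kb, nb)
            assert abs(p - p0) <= 1e-4

    def test_single_replicate_equals_g_test(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n1, n2 = int(rng.integers(10, 300)), int(rng.integers(10, 300))
            k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            d, _ = ed.lrt_binomial_glm(_counts([k1], [n1], [k2], [n2]))
            assert d == pytest.approx(g_test_2x2(k1, n1, k2, n2), abs=1e-8)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ed.lrt_binomial_glm(_counts([5], [3], [1], [10]))  # k > n
        with pytest.raises(ValueError):
            ed.lrt_binomial_glm(_counts([], [], [1], [10]))


class TestBH:
    def test_hand_step_up(self):
        # step-up on p=(0.01..0.05), m=5: q_i = min over j>=i of p_j*m/j = 0.05
        q = ed.bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_single_and_ties(self):
        assert ed.bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(ed.bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_monotone_in_rank_and_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        q = ed.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q >= p - 1e-15) & (q <= 1.0))

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            ed.bh_fdr([0.5, 1.5])


class TestClassification:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["site", "level_a", "level_b", "delta", "statistic", "p", "q"])

    def test_threshold_pairs(self):
        res = self._results([
            {"site": 1, "level_a": 0.1, "level_b": 0.25, "delta": 0.15, "statistic": 9, "p": 0.001, "q": 0.01},
            {"site": 2, "level_a": 0.1, "level_b": 0.6, "delta": 0.5, "statistic": 1, "p": 0.15, "q": 0.20},
        ])
        summary = ed.classify_sites(res, fdr=0.05)
        assert summary["10p"] == {"up": 1, "down": 0, "ns": 1}
        assert summary["20p"] == {"up": 0, "down": 0, "ns": 2}

    def test_nesting_and_symmetry(self):
        rng = np.random.default_rng(31)
        rows = []
        for i in range(300):
            n = 150
            pa, pb = rng.uniform(0.05, 0.95, size=2)
            ka, kb = rng.binomial(n, pa), rng.binomial(n, pb)
            rows.append({"site": i, "group": "A", "k": int(ka), "n": n})
            rows.append({"site": i, "group": "B", "k": int(kb), "n": n})
        df = pd.DataFrame(rows)
        res = ed.test_differential(df, fdr=0.05)
        called_10 = set(res.loc[res["class_10p"] != "ns", "site"])
        called_20 = set(res.loc[res["class_20p"] != "ns", "site"])
        assert called_20 <= called_10
        # swapping groups flips up/down exactly
        df_sw = df.copy()
        df_sw["group"] = df_sw["group"].map({"A": "B", "B": "A"})
        res_sw = ed.test_differential(df_sw, fdr=0.05).set_index("site")
        res_i = res.set_index("site")
        for s in res_i.index:
            assert res_i.loc[s, "delta"] == pytest.approx(-res_sw.loc[s, "delta"])
            flips = {"up": "down", "down": "up", "ns": "ns"}
            assert res_sw.loc[s, "class_10p"] == flips[res_i.loc[s, "class_10p"]]

    def test_min_coverage_gate(self):
        counts = [
            _counts([5, 5, 5], [9, 50, 50], [5, 5, 5], [50, 50, 50]),  # one rep below 10
            _counts([5, 5, 5], [50, 50, 50], [25, 25, 25], [50, 50, 50]),
        ]
        res = ed.test_differential(counts, min_coverage=10)
        assert len(res) == 1

    def test_type_one_error_calibrated(self):
        # null: both groups share each site's level; depth 50 x 3 reps
        rng = np.random.default_rng(101)
        m = 2000
        levels = rng.uniform(0.1, 0.9, size=m)
        k1 = rng.binomial(150, levels)
        k2 = rng.binomial(150, levels)
        _, p = ed.lrt_binomial_many(k1, np.full(m, 150), k2, np.full(m, 150))
        for alpha in (0.01, 0.05):
            emp = float((p < alpha).mean())
            band = 2 * np.sqrt(alpha * (1 - alpha) / m)
            assert abs(emp - alpha) <= band + 0.005

    def test_delta_mode_mean_vs_pooled(self):
        c = _counts([10, 30], [100, 100], [20, 20], [100, 100])
        pooled = ed.test_differential([c], min_coverage=0)
        mean = ed.test_differential([c], min_coverage=0, delta_mode="mean")
        assert pooled.iloc[0]["delta"] == pytest.approx(0.0)
        assert mean.iloc[0]["delta"] == pytest.approx(0.0)
        c2 = _counts([10, 30], [20, 180], [20, 20], [100, 100])
        pooled2 = ed.test_differential([c2], min_coverage=0)
        mean2 = ed.test_differential([c2], min_coverage=0, delta_mode="mean")
        assert pooled2.iloc[0]["delta"] != pytest.approx(mean2.iloc[0]["delta"])
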