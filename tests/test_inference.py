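"""Permutation ANOVA, BH-FDR, and contrast machinery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from audiophys import (bh_adjust, pairwise_contrasts, permanova_oneway,
                       permanova_twoway, t_vs_baseline)


def _brute_force_exact_p(values, labels):
    """Independent enumeration oracle: F over all index permutations."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.size
    levels = np.unique(labels)
    g = levels.size

    def F(lab):
        gm = values.mean()
        ssb = sum((lab == l).sum() * (values[lab == l].mean() - gm) ** 2
                  for l in levels)
        ssw = sum(((values[lab == l] - values[lab == l].mean()) ** 2).sum()
                  for l in levels)
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ssb / (g - 1)) / (ssw / (n - g))

    f_obs = F(labels)
    seen = set()
    fs = []
    for perm in itertools.permutations(range(n)):
        key = tuple(labels[list(perm)])
        if key in seen:
            continue
        seen.add(key)
        fs.append(F(np.asarray(key)))
    fs = np.asarray(fs)
    with np.errstate(invalid="ignore"):
        return float(np.mean(fs >= f_obs - 1e-12))


class TestOnewayPermanova:
    def test_separated_groups_exact_enumeration(self):
        res = permanova_oneway([0, 0, 0, 1, 1, 1],
                               ["a", "a", "a", "b", "b", "b"],
                               method="exact")
        assert res.p("intensity") == pytest.approx(0.1)

    def test_degenerate_all_equal(self):
        res = permanova_oneway([2.0] * 6, ["a"] * 3 + ["b"] * 3)
        assert res.degenerate
        assert res.p("intensity") == 1.0

    def test_eta2_one_when_within_zero(self):
        res = permanova_oneway([0, 0, 1, 1], ["a", "a", "b", "b"],
                               method="exact")
        assert res.eta2("intensity") == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_exact_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = int(rng.integers(2, min(n // 2, 3) + 1))
        labels = np.array([i % g for i in range(n)])
        rng.shuffle(labels)
        if np.bincount(labels).min() < 2:
            return
        values = rng.normal(size=n).round(3)
        res = permanova_oneway(values, labels, method="exact")
        assert res.p("intensity") == pytest.approx(
            _brute_force_exact_p(values, labels), abs=1e-12)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        lab = np.repeat(["a", "b", "c", "d"], 5)
        p1 = permanova_oneway(v, lab, n_perm=499, seed=1).p("intensity")
        order = rng.permutation(20)
        p2 = permanova_oneway(v[order], lab[order], n_perm=499,
                              seed=1).p("intensity")
        assert p1 == p2

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        lab = np.repeat(["a", "b"], 10)
        assert (permanova_oneway(v, lab, seed=7, n_perm=999).p("intensity")
                == permanova_oneway(v, lab, seed=7, n_perm=999).p("intensity"))

    def test_matches_skbio_pseudo_f(self):
        from skbio.stats.distance import permanova as sk_permanova
        from skbio import DistanceMatrix
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.0, 1, 8)])
        lab = ["a"] * 8 + ["b"] * 8
        dm = DistanceMatrix(np.abs(v[:, None] - v[None, :]),
                            ids=[str(i) for i in range(16)])
        sk = sk_permanova(dm, grouping=lab, permutations=999)
        res = permanova_oneway(v, np.asarray(lab), n_perm=9999, seed=0)
        assert res.factors["F"].iloc[0] == pytest.approx(sk["test statistic"],
                                                         rel=1e-9)
        assert res.p("intensity") == pytest.approx(sk["p-value"], abs=0.03)

    def test_small_level_rejected(self):
        with pytest.raises(ValueError):
            permanova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestTwowayPermanova:
    def _data(self, seed=0, effect_a=0.0, effect_b=0.0, inter=0.0,
              n_sub=10, na=3, nb=2):
        rng = np.random.default_rng(seed)
        rows = []
        for a in range(na):
            for b in range(nb):
                v = rng.normal(effect_a * a + effect_b * b + inter * a * b,
                               1.0, n_sub)
                rows += [(a, b, x) for x in v]
        df = pd.DataFrame(rows, columns=["A", "B", "value"])
        return df

    def test_detects_a_effect(self):
        df = self._data(effect_a=2.0)
        res = permanova_twoway(df["value"], df["A"], df["B"], n_perm=999,
                               names=("A", "B"))
        assert res.p("A") < 0.01
        # the null factor carries far less of the decomposition
        assert res.eta2("B") < 0.1 < res.eta2("A")

    def test_single_level_b_reduces_to_oneway(self):
        df = self._data(effect_a=1.0, nb=1)
        two = permanova_twoway(df["value"], df["A"], df["B"], n_perm=999,
                               seed=3, names=("A", "B"))
        one = permanova_oneway(df["value"], df["A"], n_perm=999, seed=3)
        assert two.factors["F"].iloc[0] == one.factors["F"].iloc[0]
        assert two.p("A") == one.p("intensity")

    def test_empty_cell_named(self):
        df = self._data().query("~(A == 1 and B == 1)")
        with pytest.raises(ValueError, match="empty design cell"):
            permanova_twoway(df["value"], df["A"], df["B"])

    def test_eta2_partition(self):
        df = self._data(effect_a=1.0, effect_b=0.5)
        res = permanova_twoway(df["value"], df["A"], df["B"], n_perm=99,
                               names=("A", "B"))
        assert (res.factors["eta2"] >= 0).all()
        assert res.factors["eta2"].sum() <= 1.0 + 1e-12


def _bh_oracle(p):
    """Step-up oracle: independent of statsmodels."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


class TestBhAdjust:
    def test_hand_example_all_adjust_to_largest(self):
        adj = bh_adjust([0.01, 0.04, 0.03, 0.02])
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    @given(st.integers(0, 10 ** 6))
    def test_matches_step_up_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, int(rng.integers(1, 20)))
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestContrasts:
    def _long(self, shift=0.0, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n):
            base = rng.normal()
            for k, lev in enumerate([70.9, 84.5, 94.5]):
                rows.append((s, lev, base + rng.normal(0, 0.2)
                             + (shift if lev == 94.5 else 0.0)))
        return pd.DataFrame(rows, columns=["subject", "intensity", "value"])

    def test_paired_t_matches_scipy(self):
        from scipy import stats
        df = self._long(shift=1.0)
        tab = pairwise_contrasts(df)
        row = tab[(tab.level_a == 70.9) & (tab.level_b == 94.5)].iloc[0]
        a = df[df.intensity == 70.9].sort_values("subject")["value"].to_numpy()
        b = df[df.intensity == 94.5].sort_values("subject")["value"].to_numpy()
        t, p = stats.ttest_rel(a, b)
        assert row["t"] == pytest.approx(t)
        assert row["p"] == pytest.approx(p)

    def test_shifted_level_detected_after_fdr(self):
        tab = pairwise_contrasts(self._long(shift=2.0))
        hit = tab[(tab.level_a == 70.9) & (tab.level_b == 94.5)]
        assert hit["p_fdr"].iloc[0] < 0.01

    def test_insufficient_pairs_missing(self):
        df = self._long().groupby("intensity").head(2)
        tab = pairwise_contrasts(df)
        assert tab["p"].isna().all()


class TestTvsBaseline:
    def test_constant_offset_detected(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"intensity": np.repeat([70.9, 94.5], 20),
                           "value": np.concatenate([
                               rng.normal(0, 0.01, 20),
                               rng.normal(0.5, 0.01, 20)])})
        tab = t_vs_baseline(df)
        assert tab[tab.intensity == 94.5]["p"].iloc[0] < 1e-3
        assert tab[tab.intensity == 70.9]["p"].iloc[0] > 0.05

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            df = pd.DataFrame({"intensity": [70.9] * 15,
                               "value": rng.normal(0, 1, 15)})
            if t_vs_baseline(df)["p"].iloc[0] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_sim <= 0.09

    def test_too_few_subjects_missing(self):
        df = pd.DataFrame({"intensity": [70.9, 70.9], "value": [0.1, 0.2]})
        assert np.isnan(t_vs_baseline(df)["p"].iloc[0])
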