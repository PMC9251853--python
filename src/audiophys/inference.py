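"""Permutational ANOVA, effect sizes, and FDR-corrected contrasts.

On univariate metrics with a Euclidean distance, PERMANOVA reduces to a
permutation ANOVA: the observed pseudo-F compares between-group to
within-group sums of squares, and its p-value is the add-one-corrected
fraction of label permutations with an F at least as large,
``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)``.  Effect size is
``η² = SS_effect / SS_total``.  The two-way variant decomposes a crossed
(intensity × window or intensity × ROI) design and permutes raw
observations unrestrictedly for every term.  Post hoc contrasts are
paired-by-subject t-tests with Benjamini–Hochberg step-up FDR control.

Observations are canonicalized (sorted) before permuting, so p-values do
not depend on input row order, and a fixed seed reproduces them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "permanova_oneway", "permanova_twoway",
           "pairwise_contrasts", "t_vs_baseline", "bh_adjust"]


@dataclass
class StatResult:
    """Per-factor pseudo-F, permutation p, and η², plus optional post hoc
    contrast table."""

    factors: pd.DataFrame                    # factor, F, p, eta2, df
    posthoc: pd.DataFrame | None = None
    n_perm: int = 0
    degenerate: bool = False
    extra: dict = field(default_factory=dict)

    def p(self, factor: str) -> float:
        return float(self.factors.set_index("factor").loc[factor, "p"])

    def eta2(self, factor: str) -> float:
        return float(self.factors.set_index("factor").loc[factor, "eta2"])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _canonical(values: np.ndarray, labels: np.ndarray, *more):
    order = np.lexsort((values,) + tuple(np.asarray(m) for m in more[::-1])
                       + (labels,))
    return (values[order], labels[order]) + tuple(np.asarray(m)[order] for m in more)


def _oneway_ss(values: np.ndarray, group_idx: list) -> tuple[float, float]:
    gm = values.mean()
    ss_total = float(np.sum((values - gm) ** 2))
    ss_between = float(sum(len(ix) * (values[ix].mean() - gm) ** 2
                           for ix in group_idx))
    return ss_between, ss_total


def permanova_oneway(values, labels, n_perm: int = 9999,
                     seed: int | None = 0, method: str = "permutation"
                     ) -> StatResult:
    """One-way permutation ANOVA (Euclidean PERMANOVA) on a univariate metric.

    ``method="exact"`` enumerates every distinct labeling instead of
    sampling; p is then ``#{F >= F_obs} / #labelings`` with no add-one
    correction.  A dataset with zero total variance is flagged degenerate
    (p = 1, η² = 0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    ok = np.isfinite(values)
    values, labels = values[ok], labels[ok]
    values, labels = _canonical(values, labels)
    levels, inv = np.unique(labels, return_inverse=True)
    if levels.size < 2:
        raise ValueError("need at least 2 factor levels")
    counts = np.bincount(inv)
    if counts.min() < 2:
        raise ValueError("every level needs at least 2 observations")
    n, g = values.size, levels.size
    group_idx = [np.where(inv == k)[0] for k in range(g)]
    ss_b, ss_t = _oneway_ss(values, group_idx)
    if ss_t <= 1e-30:
        fac = pd.DataFrame([("intensity", np.nan, 1.0, 0.0, g - 1)],
                           columns=["factor", "F", "p", "eta2", "df"])
        return StatResult(factors=fac, degenerate=True)
    df_b, df_w = g - 1, n - g

    def _F(ssb: np.ndarray) -> np.ndarray:
        ssw = ss_t - ssb
        with np.errstate(divide="ignore"):
            return (ssb / df_b) / (ssw / df_w)

    F_obs = float(_F(np.array(ss_b)))
    if method == "exact":
        from sympy.utilities.iterables import multiset_permutations
        fs = []
        for perm in multiset_permutations(list(inv)):
            pi = np.asarray(perm)
            ssb = sum(values[pi == k].sum() ** 2 / counts[k] for k in range(g)) \
                - values.sum() ** 2 / n
            fs.append(_F(np.array(ssb)))
        fs = np.asarray(fs, dtype=float)
        with np.errstate(invalid="ignore"):
            p = float(np.mean(fs >= F_obs - 1e-12))
        n_used = fs.size
    else:
        rng = np.random.default_rng(seed)
        # vectorized: permute values over fixed label positions
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        V = values[idx]
        ssb = np.zeros(n_perm)
        for k in range(g):
            ssb += V[:, group_idx[k]].sum(axis=1) ** 2 / counts[k]
        ssb -= values.sum() ** 2 / n
        fs = _F(ssb)
        p = (1.0 + np.sum(fs >= F_obs - 1e-12)) / (1.0 + n_perm)
        n_used = n_perm
    eta2 = ss_b / ss_t
    fac = pd.DataFrame([("intensity", F_obs, p, eta2, df_b)],
                       columns=["factor", "F", "p", "eta2", "df"])
    return StatResult(factors=fac, n_perm=n_used)


def _twoway_ss(values: np.ndarray, ia: np.ndarray, ib: np.ndarray,
               na: int, nb: int) -> tuple[float, float, float, float, float]:
    n = values.size
    gm = values.mean()
    ss_t = float(np.sum((values - gm) ** 2))
    ss_a = sum(np.sum(ia == a) * (values[ia == a].mean() - gm) ** 2
               for a in range(na))
    ss_b = sum(np.sum(ib == b) * (values[ib == b].mean() - gm) ** 2
               for b in range(nb))
    ss_cells = 0.0
    cell = ia * nb + ib
    for c in np.unique(cell):
        sel = cell == c
        ss_cells += sel.sum() * (values[sel].mean() - gm) ** 2
    ss_ab = ss_cells - ss_a - ss_b
    ss_res = ss_t - ss_cells
    return float(ss_a), float(ss_b), float(ss_ab), float(ss_res), ss_t


def permanova_twoway(values, factor_a, factor_b, n_perm: int = 9999,
                     seed: int | None = 0,
                     names: tuple = ("intensity", "tw")) -> StatResult:
    """Two-way crossed permutation ANOVA with unrestricted raw permutation.

    Sums of squares follow the balanced crossed decomposition (A, B, A×B,
    residual); each term's p comes from the same set of raw-data
    permutations.  An empty design cell is an error naming the cell.
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    ok = np.isfinite(values)
    values, fa, fb = values[ok], fa[ok], fb[ok]
    values, fa, fb = _canonical(values, fa, fb)
    la, ia = np.unique(fa, return_inverse=True)
    lb, ib = np.unique(fb, return_inverse=True)
    na, nb = la.size, lb.size
    if nb == 1:
        # degenerate crossing: the design is one-way
        res = permanova_oneway(values, fa, n_perm=n_perm, seed=seed)
        res.factors.loc[0, "factor"] = names[0]
        return res
    for a in range(na):
        for b in range(nb):
            if not np.any((ia == a) & (ib == b)):
                raise ValueError(f"empty design cell ({la[a]}, {lb[b]})")
    n = values.size
    ss_a, ss_b, ss_ab, ss_res, ss_t = _twoway_ss(values, ia, ib, na, nb)
    if ss_t <= 1e-30:
        fac = pd.DataFrame(
            [(names[0], np.nan, 1.0, 0.0, na - 1),
             (names[1], np.nan, 1.0, 0.0, nb - 1),
             ("interaction", np.nan, 1.0, 0.0, (na - 1) * (nb - 1))],
            columns=["factor", "F", "p", "eta2", "df"])
        return StatResult(factors=fac, degenerate=True)
    df = {"a": na - 1, "b": nb - 1, "ab": (na - 1) * (nb - 1)}
    df_res = n - na * nb

    def _fs(sa, sb, sab, sres):
        with np.errstate(divide="ignore", invalid="ignore"):
            return (np.asarray(sa) / df["a"] / (np.asarray(sres) / df_res),
                    np.asarray(sb) / df["b"] / (np.asarray(sres) / df_res),
                    np.asarray(sab) / df["ab"] / (np.asarray(sres) / df_res))

    Fa, Fb, Fab = (float(v) for v in _fs(ss_a, ss_b, ss_ab, ss_res))
    rng = np.random.default_rng(seed)
    # vectorized permutations: level/cell sums via indicator matmuls
    cell = ia * nb + ib
    Ia = np.eye(na)[ia]                     # (n, na)
    Ib = np.eye(nb)[ib]
    lc, ic = np.unique(cell, return_inverse=True)
    Ic = np.eye(lc.size)[ic]
    ca, cb, cc = Ia.sum(0), Ib.sum(0), Ic.sum(0)
    gsq = values.sum() ** 2 / n
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    V = values[idx]
    sa = (V @ Ia) ** 2 / ca
    sb = (V @ Ib) ** 2 / cb
    sc = (V @ Ic) ** 2 / cc
    ssa_p = sa.sum(1) - gsq
    ssb_p = sb.sum(1) - gsq
    ssc_p = sc.sum(1) - gsq
    ssab_p = ssc_p - ssa_p - ssb_p
    ssres_p = ss_t - ssc_p
    fa_p, fb_p, fab_p = _fs(ssa_p, ssb_p, ssab_p, ssres_p)
    counts = np.array([np.sum(fa_p >= Fa - 1e-12),
                       np.sum(fb_p >= Fb - 1e-12),
                       np.sum(fab_p >= Fab - 1e-12)])
    ps = (1.0 + counts) / (1.0 + n_perm)
    fac = pd.DataFrame(
        [(names[0], Fa, ps[0], ss_a / ss_t, df["a"]),
         (names[1], Fb, ps[1], ss_b / ss_t, df["b"]),
         ("interaction", Fab, ps[2], ss_ab / ss_t, df["ab"])],
        columns=["factor", "F", "p", "eta2", "df"])
    return StatResult(factors=fac, n_perm=n_perm)


def pairwise_contrasts(table: pd.DataFrame, factor: str = "intensity",
                       value: str = "value", subject: str = "subject"
                       ) -> pd.DataFrame:
    """All level pairs, paired-by-subject two-sided t-tests, BH-adjusted.

    A contrast with fewer than 3 complete pairs is reported missing rather
    than dropped from the family.
    """
    levels = sorted(table[factor].unique())
    rows = []
    for a, b in combinations(levels, 2):
        wa = table[table[factor] == a].set_index(subject)[value]
        wb = table[table[factor] == b].set_index(subject)[value]
        common = wa.index.intersection(wb.index)
        xa, xb = wa.loc[common], wb.loc[common]
        keep = np.isfinite(xa.to_numpy()) & np.isfinite(xb.to_numpy())
        if keep.sum() < 3:
            rows.append((a, b, np.nan, np.nan, keep.sum()))
            continue
        t, p = stats.ttest_rel(xa.to_numpy()[keep], xb.to_numpy()[keep])
        rows.append((a, b, float(t), float(p), int(keep.sum())))
    out = pd.DataFrame(rows, columns=["level_a", "level_b", "t", "p", "n"])
    finite = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if finite.any():
        adj[finite.to_numpy()] = bh_adjust(out.loc[finite, "p"].to_numpy())
    out["p_fdr"] = adj
    return out


def t_vs_baseline(table: pd.DataFrame, factor: str = "intensity",
                  value: str = "value") -> pd.DataFrame:
    """One-sample t of each level's values against zero (the baseline after
    baseline subtraction), BH-corrected across levels."""
    rows = []
    for lev, grp in table.groupby(factor):
        v = grp[value].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        if v.size < 3:
            rows.append((lev, np.nan, np.nan, v.size))
            continue
        t, p = stats.ttest_1samp(v, 0.0)
        rows.append((lev, float(t), float(p), int(v.size)))
    out = pd.DataFrame(rows, columns=[factor, "t", "p", "n"])
    finite = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if finite.any():
        adj[finite.to_numpy()] = bh_adjust(out.loc[finite, "p"].to_numpy())
    out["p_fdr"] = adj
    return out
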