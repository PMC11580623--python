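"""Association statistics against independent oracles."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import optimize, stats

from sdrscan.association import (AlleleCounts2x2, bh_fdr, fdr_threshold,
                                 fisher_exact_allelic, lrt_allele_freq,
                                 site_counts, site_stats, wc_components,
                                 wc_fst_site, wc_fst_weighted)


def fet_oracle(a, b, c, d):
    """Arbitrary-precision two-sided FET by full hypergeometric enumeration."""
    nf, nm, k = a + b, c + d, a + c
    total = comb(nf + nm, k)
    pmf = {x: Fraction(comb(nf, x) * comb(nm, k - x), total)
           for x in range(max(0, k - nm), min(k, nf) + 1)}
    obs = pmf[a]
    return float(sum(p for p in pmf.values() if p <= obs))


def test_fisher_small_table_enumeration():
    # margins (2,2)/(2,2): pmf {1/6, 4/6, 1/6} -> two-sided 1/3
    assert fisher_exact_allelic(AlleleCounts2x2(2, 0, 0, 2)) == \
        pytest.approx(1 / 3, rel=1e-12)


def test_fisher_no_association_and_monomorphic():
    assert fisher_exact_allelic(AlleleCounts2x2(10, 10, 10, 10)) == \
        pytest.approx(1.0)
    assert fisher_exact_allelic(AlleleCounts2x2(0, 48, 0, 40)) == 1.0


def test_fisher_fully_sexlinked_table_matches_oracle():
    p = fisher_exact_allelic(AlleleCounts2x2(24, 24, 0, 40))
    assert p == pytest.approx(fet_oracle(24, 24, 0, 40), rel=1e-12)


@given(st.integers(0, 200), st.data())
def test_fisher_matches_enumeration_oracle(seed, data):
    rng = np.random.default_rng(seed)
    nf, nm = rng.integers(2, 101, size=2)
    k = int(rng.integers(1, nf + nm))
    a = int(rng.integers(max(0, k - nm), min(k, nf) + 1))
    t = (a, int(nf) - a, k - a, int(nm) - (k - a))
    assert fisher_exact_allelic(AlleleCounts2x2(*t)) == \
        pytest.approx(fet_oracle(*t), rel=1e-12)


def test_lrt_equal_frequencies():
    assert lrt_allele_freq(AlleleCounts2x2(10, 10, 10, 10)) == 1.0


def test_lrt_matches_numeric_likelihood_oracle():
    """G from the closed form equals 2*(unrestricted - pooled) maximised
    numerically over the two binomial likelihoods."""
    a, b, c, d = 24, 24, 0, 40

    def nll_pooled(p):
        return -(stats.binom.logpmf(a, a + b, p)
                 + stats.binom.logpmf(c, c + d, p))

    def nll_free(x):
        return -(stats.binom.logpmf(a, a + b, x[0])
                 + stats.binom.logpmf(c, c + d, x[1]))

    r0 = optimize.minimize_scalar(nll_pooled, bounds=(1e-9, 1 - 1e-9),
                                  method="bounded")
    r1 = optimize.minimize(nll_free, [0.4, 0.1],
                           bounds=[(1e-9, 1 - 1e-9)] * 2)
    g_oracle = 2 * (r0.fun - r1.fun)
    p_oracle = stats.chi2.sf(g_oracle, df=1)
    assert lrt_allele_freq(AlleleCounts2x2(a, b, c, d)) == \
        pytest.approx(p_oracle, rel=1e-6)


def test_lrt_doubling_counts_decreases_p():
    base = AlleleCounts2x2(20, 28, 10, 30)
    doubled = AlleleCounts2x2(40, 56, 20, 60)
    assert lrt_allele_freq(doubled) < lrt_allele_freq(base)


def test_bh_stepup_hand_example():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([1.0]) == pytest.approx([1.0])
    assert bh_fdr([]).size == 0


def bh_oracle(p):
    """Step-up definition: q_i = min_{j: p_(j) >= p_(i)} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@given(st.integers(0, 100))
def test_bh_matches_stepup_definition_and_permutation(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(size=rng.integers(1, 60))
    q = bh_fdr(p)
    assert q == pytest.approx(bh_oracle(p))
    assert q.max() <= 1.0
    perm = rng.permutation(len(p))
    assert bh_fdr(p[perm]) == pytest.approx(q[perm])


def test_fdr_threshold():
    assert fdr_threshold([1e-8, 0.5, 0.9], 0.05) == 1e-8
    assert fdr_threshold([0.9, 0.9, 0.9], 0.05) is None
    rng = np.random.default_rng(1)
    p = np.concatenate([rng.random(50) * 1e-6, rng.random(50)])
    thr = fdr_threshold(p, 0.05)
    assert thr in set(p)  # always an element of the input


def wc_oracle(ns, ps, hs):
    """Textbook 1984 components evaluated over explicit population loops."""
    ns, ps, hs = map(np.asarray, (ns, ps, hs))
    r = len(ns)
    nbar = ns.mean()
    nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (ns * ps).sum() / (r * nbar)
    s2 = (ns * (ps - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (ns * hs).sum() / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c, a / (a + b + c)


def test_wc_fst_canonical_sexlinked_site():
    """24 females p=0.5 h=1 vs 20 males p=0 h=0 gives F_ST ~ 0.478."""
    a, b, c, fst = wc_fst_site(24, 0.5, 1.0, 20, 0.0, 0.0)
    oa, ob, oc, ofst = wc_oracle([24, 20], [0.5, 0.0], [1.0, 0.0])
    assert (a, b, c, fst) == pytest.approx((oa, ob, oc, ofst), rel=1e-12)
    assert fst == pytest.approx(0.478, abs=5e-4)
    assert 0.392 <= fst <= 0.576


def test_wc_identical_populations_nonpositive():
    a, b, c, fst = wc_fst_site(22, 0.3, 0.42, 22, 0.3, 0.42)
    assert a <= 0 and fst <= 0


def test_wc_monomorphic_excluded():
    a, b, c, fst = wc_fst_site(24, 0.0, 0.0, 20, 0.0, 0.0)
    assert np.isnan(fst)
    assert np.isnan(wc_fst_weighted(np.array([[np.nan, np.nan, np.nan]])))


def test_wc_weighted_single_site_equals_site_value():
    a, b, c, fst = wc_fst_site(24, 0.5, 1.0, 20, 0.0, 0.0)
    assert wc_fst_weighted(np.array([[a, b, c]])) == pytest.approx(fst)


def test_weighted_fst_near_zero_on_panmictic_panel(noisy_cohort):
    """Genome-wide weighted F_ST over >= 10,000 autosomal sites is ~0."""
    c = noisy_cohort
    auto = (c.table.sites["chrom"] != c.config.sdr_chrom).to_numpy()
    sub = c.table.subset_sites(auto)
    assert sub.n_sites >= 10_000
    cts = site_counts(sub, c.sexframe)
    comps = np.column_stack(wc_components(
        cts["n_f"], cts["p_f"], cts["h_f"],
        cts["n_m"], cts["p_m"], cts["h_m"]))
    assert abs(wc_fst_weighted(comps)) < 0.005


def test_site_stats_flags_planted_sites(noiseless_cohort):
    c = noiseless_cohort
    df, summary = site_stats(c.table, c.sexframe)
    planted = {p for _, p in c.truth.planted_sexlinked}
    hit = df[df["pos"].isin(planted) & (df["chrom"] == "chr2")]
    assert (hit["q_fet"] <= 0.05).all() and (hit["q_lrt"] <= 0.05).all()
    assert summary["fet_fdr_threshold"] is not None
    # every fully sex-linked site sits in the published per-site range
    assert hit["fst"].between(0.392, 0.576).all()
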