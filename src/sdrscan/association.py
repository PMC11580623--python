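"""Per-site sex-association statistics.

Sexes are treated as two populations. Each biallelic site gets

* an allelic Fisher's exact test on the 2x2 minor/major x F/M allele-count
  table (two-sided by the minimum-likelihood rule),
* a binomial likelihood-ratio test of shared allele frequency (G statistic,
  chi-square with 1 df) — a count-based stand-in for genotype-likelihood
  differentiation tests,
* Benjamini–Hochberg q-values, and
* the Weir & Cockerham (1984) two-population F_ST variance components,
  with a genome-wide weighted estimate as ratio of summed components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .qc import MISSING, GenotypeTable, SexFrame


@dataclass(frozen=True)
class AlleleCounts2x2:
    """Allele counts: a/b minor/major in females, c/d minor/major in males."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")


def fisher_exact_allelic(counts: AlleleCounts2x2) -> float:
    """Two-sided Fisher's exact p for a 2x2 allele-count table.

    Sums hypergeometric point probabilities of all tables with the same
    margins whose probability is <= the observed one (within 1e-12
    relative tolerance, to keep exact ties together). Monomorphic tables
    (a zero allele margin) return p = 1 by convention.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    n_f, n_m = a + b, c + d
    k_minor = a + c
    n = n_f + n_m
    if n_f == 0 or n_m == 0 or k_minor == 0 or (b + d) == 0:
        return 1.0
    lo = max(0, k_minor - n_m)
    hi = min(k_minor, n_f)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, k_minor, n_f)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def _binom_ll(k: float, n: float) -> float:
    """Binomial log-likelihood at the MLE p = k/n (0 ln 0 := 0)."""
    if n == 0:
        return 0.0
    out = 0.0
    if 0 < k:
        out += k * np.log(k / n)
    if k < n:
        out += (n - k) * np.log((n - k) / n)
    return out


def lrt_allele_freq(counts: AlleleCounts2x2) -> float:
    """Likelihood-ratio test of equal allele frequency between sexes.

    G = 2[ll(p_F) + ll(p_M) - ll(p_pooled)] on allele counts, referred to
    chi-square with 1 df; G is clipped at 0. Monomorphic sites give p = 1.
    """
    a, b, c, d = counts.a, counts.b, counts.c, counts.d
    n_f, n_m = a + b, c + d
    if n_f == 0 or n_m == 0 or (a + c) == 0 or (b + d) == 0:
        return 1.0
    g = 2.0 * (_binom_ll(a, n_f) + _binom_ll(c, n_m)
               - _binom_ll(a + c, n_f + n_m))
    g = max(g, 0.0)
    return float(stats.chi2.sf(g, df=1))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def fdr_threshold(pvals, alpha: float = 0.05):
    """Largest raw p whose BH q-value is <= alpha; None if no site passes."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return None
    q = bh_fdr(p)
    sig = p[q <= alpha]
    return float(sig.max()) if sig.size else None


def wc_fst_site(n_f, p_f, h_f, n_m, p_m, h_m):
    """Weir & Cockerham (1984) variance components for two populations.

    n = called diploid sample size, p = allele frequency, h = observed
    heterozygote proportion per population. Returns (a, b, c, fst); all
    NaN when the site is monomorphic across both sexes. fst = a/(a+b+c)
    and may be negative.
    """
    a_wc, b_wc, c_wc = wc_components(
        np.atleast_1d(float(n_f)), np.atleast_1d(float(p_f)),
        np.atleast_1d(float(h_f)), np.atleast_1d(float(n_m)),
        np.atleast_1d(float(p_m)), np.atleast_1d(float(h_m)))
    a_wc, b_wc, c_wc = float(a_wc[0]), float(b_wc[0]), float(c_wc[0])
    if np.isnan(a_wc):
        return (np.nan,) * 4
    denom = a_wc + b_wc + c_wc
    fst = a_wc / denom if denom != 0 else np.nan
    return a_wc, b_wc, c_wc, fst


def wc_components(n1, p1, h1, n2, p2, h2):
    """Vectorised W&C 1984 components (r = 2 populations).

    Monomorphic sites (pooled frequency 0 or 1 with no heterozygotes)
    yield NaN components.
    """
    n1, p1, h1 = map(np.asarray, (n1, p1, h1))
    n2, p2, h2 = map(np.asarray, (n2, p2, h2))
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    mono = ((pbar <= 0) | (pbar >= 1)) & (hbar <= 0)
    a = np.where(mono, np.nan, a)
    b = np.where(mono, np.nan, b)
    c = np.where(mono, np.nan, c)
    return a, b, c


def wc_fst_weighted(components) -> float:
    """Genome-wide weighted F_ST: sum(a) / sum(a+b+c) over defined sites."""
    arr = np.asarray(components, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 3:
        raise ValueError("components must be an (n, 3) array of (a, b, c)")
    ok = ~np.isnan(arr).any(axis=1)
    arr = arr[ok]
    if arr.shape[0] == 0:
        return np.nan
    denom = arr.sum()
    if denom <= 0:
        import warnings

        warnings.warn("non-positive total variance; weighted F_ST undefined")
        return np.nan
    return float(arr[:, 0].sum() / denom)


def site_counts(table: GenotypeTable, sexframe: SexFrame):
    """Per-site called n, alt frequency and het proportion by sex."""
    fmask = sexframe.mask(table.samples, "F")
    mmask = sexframe.mask(table.samples, "M")
    out = {}
    for tag, mask in (("f", fmask), ("m", mmask)):
        c = table.codes[:, mask]
        called = (c != MISSING).sum(axis=1)
        alt = np.where(c == MISSING, 0, c).sum(axis=1)
        het = (c == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"n_{tag}"] = called
            out[f"p_{tag}"] = np.where(called > 0, alt / (2.0 * called), np.nan)
            out[f"h_{tag}"] = np.where(called > 0, het / called, np.nan)
            out[f"alt_{tag}"] = alt
    return out


def site_stats(table: GenotypeTable, sexframe: SexFrame,
               alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Run FET, LRT, BH-FDR and W&C F_ST over every site.

    Returns the per-site table and a genome summary (weighted F_ST and the
    raw-p FDR thresholds at ``alpha`` for both tests).
    """
    cts = site_counts(table, sexframe)
    n_f2, n_m2 = 2 * cts["n_f"], 2 * cts["n_m"]
    alt_total = cts["alt_f"] + cts["alt_m"]
    total = n_f2 + n_m2
    # orient to the global minor allele
    minor_is_alt = alt_total * 2 <= total
    a = np.where(minor_is_alt, cts["alt_f"], n_f2 - cts["alt_f"]).astype(int)
    b = (n_f2 - a).astype(int)
    c = np.where(minor_is_alt, cts["alt_m"], n_m2 - cts["alt_m"]).astype(int)
    d = (n_m2 - c).astype(int)

    p_fet = np.array([
        fisher_exact_allelic(AlleleCounts2x2(*t)) for t in zip(a, b, c, d)
    ])
    p_lrt = np.array([
        lrt_allele_freq(AlleleCounts2x2(*t)) for t in zip(a, b, c, d)
    ])
    a_wc, b_wc, c_wc = wc_components(cts["n_f"], cts["p_f"], cts["h_f"],
                                     cts["n_m"], cts["p_m"], cts["h_m"])
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a_wc + b_wc + c_wc
        fst = np.where(denom != 0, a_wc / denom, np.nan)

    df = table.sites[["chrom", "pos"]].copy()
    for k, v in (("minor_f", a), ("major_f", b), ("minor_m", c),
                 ("major_m", d), ("p_fet", p_fet), ("p_lrt", p_lrt)):
        df[k] = v
    df["q_fet"] = bh_fdr(p_fet) if len(df) else []
    df["q_lrt"] = bh_fdr(p_lrt) if len(df) else []
    df["fst"] = fst
    df["a_wc"], df["b_wc"], df["c_wc"] = a_wc, b_wc, c_wc

    summary = {
        "weighted_fst": wc_fst_weighted(np.column_stack([a_wc, b_wc, c_wc]))
        if len(df) else np.nan,
        "fet_fdr_threshold": fdr_threshold(p_fet, alpha) if len(df) else None,
        "lrt_fdr_threshold": fdr_threshold(p_lrt, alpha) if len(df) else None,
        "alpha": alpha,
    }
    return df, summary
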