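"""Sex-specific SNP detection and heterogamety classification.

A fully sex-linked SNP in the heterogametic sex is heterozygous in every
individual of that sex and fixed homozygous in the other. With miscalls
and missing data the rule is relaxed to: at least ``min_het_count``
heterozygotes in the focal sex (observed heterozygosity >= ``min_ho``)
and *zero* heterozygotes in the other sex, all of whose called genotypes
must be the same homozygote. Depth at hit sites and a co-locating
sex-limited coverage region separate a true ZW/XY signal from a deletion
artefact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicRegion
from .qc import HET, HOM_ALT, HOM_REF, MISSING, GenotypeTable, SexFrame


@dataclass
class SexSpecificRule:
    min_het_count: int | None = 18
    min_ho: float = 0.75
    max_other_het: int = 0

    def __post_init__(self):
        if self.min_het_count is not None and self.min_het_count < 1:
            raise ValueError("min_het_count must be >= 1")
        if not (0 < self.min_ho <= 1):
            raise ValueError("min_ho must be in (0, 1]")
        if self.max_other_het != 0:
            raise ValueError("the detector requires zero other-sex heterozygotes")

    def het_count_for(self, n_focal: int) -> int:
        """Minimum heterozygote count; ceil(min_ho * n_focal) when unset.

        With 24 focal-sex samples and an Ho floor of 0.75 this derives 18.
        """
        if self.min_het_count is not None:
            return self.min_het_count
        return math.ceil(self.min_ho * n_focal)


def derive_min_het_count(min_ho: float, n_focal: int) -> int:
    return math.ceil(min_ho * n_focal)


def observed_heterozygosity(codes_row: np.ndarray, subset: np.ndarray) -> float:
    """Het proportion among called genotypes of a sample subset.

    Returns NaN when no genotype in the subset is called.
    """
    c = codes_row[subset]
    called = int((c != MISSING).sum())
    if called == 0:
        return float("nan")
    return float((c == HET).sum() / called)


def detect_sex_specific(table: GenotypeTable, sexframe: SexFrame,
                        rule: SexSpecificRule | None = None) -> pd.DataFrame:
    """Report sites satisfying the heterozygosity-contrast rule.

    Output columns: chrom, pos, focal_sex, het_count_focal, called_focal,
    ho_focal, other_sex_allele ('ref'/'alt'), site index. Both-sex hits are
    impossible because each focal call requires zero heterozygotes in the
    other sex.
    """
    rule = rule or SexSpecificRule()
    fmask = sexframe.mask(table.samples, "F")
    mmask = sexframe.mask(table.samples, "M")
    rows = []
    for focal_sex, focal, other in (("F", fmask, mmask), ("M", mmask, fmask)):
        cf = table.codes[:, focal]
        co = table.codes[:, other]
        het_f = (cf == HET).sum(axis=1)
        called_f = (cf != MISSING).sum(axis=1)
        het_o = (co == HET).sum(axis=1)
        n_hr = (co == HOM_REF).sum(axis=1)
        n_ha = (co == HOM_ALT).sum(axis=1)
        called_o = n_hr + n_ha + het_o
        min_het = rule.het_count_for(int(focal.sum()))
        with np.errstate(invalid="ignore", divide="ignore"):
            ho = np.where(called_f > 0, het_f / called_f, np.nan)
        one_allele = (called_o > 0) & ((n_hr == called_o) | (n_ha == called_o))
        hit = (
            (het_f >= min_het)
            & (ho >= rule.min_ho)
            & (het_o == 0)
            & one_allele
        )
        for i in np.flatnonzero(hit):
            rows.append({
                "chrom": table.sites.at[i, "chrom"],
                "pos": int(table.sites.at[i, "pos"]),
                "focal_sex": focal_sex,
                "het_count_focal": int(het_f[i]),
                "called_focal": int(called_f[i]),
                "ho_focal": float(ho[i]),
                "other_sex_allele": "ref" if n_hr[i] == called_o[i] else "alt",
                "site_index": int(i),
            })
    cols = ["chrom", "pos", "focal_sex", "het_count_focal", "called_focal",
            "ho_focal", "other_sex_allele", "site_index"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def hit_depth_summary(table: GenotypeTable, hits: pd.DataFrame,
                      sexframe: SexFrame) -> tuple[pd.DataFrame, dict]:
    """Per-hit and pooled depth (mean/sd) by sex with Welch p per hit.

    Uses the per-call DP of each SNP in each individual. The pooled record
    carries a ``no_depth_difference`` flag, true when Welch p >= 0.05 at
    every hit — the signature of a segregating (non-hemizygous) site.
    """
    fmask = sexframe.mask(table.samples, "F")
    mmask = sexframe.mask(table.samples, "M")
    recs = []
    for _, h in hits.iterrows():
        i = int(h["site_index"])
        df_, dm_ = table.dp[i, fmask].astype(float), table.dp[i, mmask].astype(float)
        rec = {
            "chrom": h["chrom"], "pos": h["pos"],
            "mean_depth_f": float(df_.mean()), "sd_depth_f": float(df_.std(ddof=1)),
            "mean_depth_m": float(dm_.mean()), "sd_depth_m": float(dm_.std(ddof=1)),
        }
        from .coverage import welch_t

        _, _, p = welch_t(df_, dm_)
        rec["welch_p"] = p
        recs.append(rec)
    per_hit = pd.DataFrame(recs)
    pooled = {}
    if len(per_hit):
        all_f = table.dp[hits["site_index"].to_numpy()][:, fmask].astype(float)
        all_m = table.dp[hits["site_index"].to_numpy()][:, mmask].astype(float)
        pooled = {
            "mean_depth_f": float(all_f.mean()),
            "sd_depth_f": float(all_f.mean(axis=1).std(ddof=1)),
            "mean_depth_m": float(all_m.mean()),
            "sd_depth_m": float(all_m.mean(axis=1).std(ddof=1)),
            "no_depth_difference": bool((per_hit["welch_p"] >= 0.05).all()),
        }
    return per_hit, pooled


def ld_r2(table: GenotypeTable, site_indices) -> tuple[np.ndarray, float]:
    """Pairwise genotype-dosage r^2 among hit sites.

    r^2 is the squared Pearson correlation of alt dosage (0/1/2) over
    samples called at both sites; pairs sharing < 4 called samples, or
    with zero dosage variance, are NaN. Returns the symmetric matrix and
    the mean of defined off-diagonal entries.
    """
    idx = np.asarray(site_indices, dtype=int)
    if idx.size < 2:
        raise ValueError("ld_r2 needs at least two sites")
    dos = table.dosage()[idx]
    k = idx.size
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            both = ~np.isnan(dos[i]) & ~np.isnan(dos[j])
            if both.sum() < 4:
                continue
            x, y = dos[i, both], dos[j, both]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            mat[i, j] = mat[j, i] = r * r
    off = mat[np.triu_indices(k, 1)]
    mean = float(np.nanmean(off)) if np.isfinite(off).any() else float("nan")
    if not np.isfinite(off).any():
        import warnings

        warnings.warn("all pairwise r^2 undefined")
    return mat, mean


@dataclass
class SystemCall:
    system: str  # ZW | XY | ambiguous
    provisional: bool
    rationale: str


def classify_system(hits: pd.DataFrame,
                    depth_uniform_at_hits: bool | None = None,
                    coverage_regions: list[GenomicRegion] | None = None,
                    minority_tol: float = 0.10) -> SystemCall:
    """Call ZW vs XY from detector hits plus coverage corroboration.

    Heterozygote excess in females suggests ZW, in males XY — but alone it
    cannot exclude a deleted region on the other sex chromosome, so a
    definitive call additionally requires either uniform depth between
    sexes at the hit sites or a co-locating sex-limited coverage region of
    the matching sex. Conflicting focal sexes (> ``minority_tol`` minority)
    or contradictory coverage give 'ambiguous'.
    """
    if hits is None or len(hits) == 0:
        return SystemCall("ambiguous", True, "no sex-specific SNPs")
    n_f = int((hits["focal_sex"] == "F").sum())
    n_m = len(hits) - n_f
    minority = min(n_f, n_m) / len(hits)
    if minority > minority_tol:
        return SystemCall(
            "ambiguous", False,
            f"conflicting focal sexes (F={n_f}, M={n_m})")
    focal = "F" if n_f >= n_m else "M"
    system = "ZW" if focal == "F" else "XY"
    hit_chroms = set(hits["chrom"])
    coloc = None
    contradiction = False
    for reg in coverage_regions or []:
        if reg.chrom in hit_chroms and reg.sex is not None:
            if reg.sex == focal:
                coloc = reg
            else:
                contradiction = True
    if contradiction and coloc is None:
        return SystemCall(
            "ambiguous", False,
            f"coverage shows a {('male' if focal == 'F' else 'female')}-limited "
            "region on the hit chromosome, contradicting the genotype signal")
    if depth_uniform_at_hits or coloc is not None:
        why = []
        if depth_uniform_at_hits:
            why.append("uniform depth between sexes at hit sites")
        if coloc is not None:
            why.append(f"co-locating {focal}-limited region "
                       f"{coloc.chrom}:{coloc.start}-{coloc.end}")
        return SystemCall(system, False,
                          f"heterozygote excess in {focal}; " + "; ".join(why))
    return SystemCall(system, True,
                      f"heterozygote excess in {focal} without coverage "
                      "corroboration (provisional)")
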