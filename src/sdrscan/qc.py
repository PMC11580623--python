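"""Genotype ingestion and the six-criterion SNP filter cascade.

A multi-sample VCF plus a sample-sex sheet become a :class:`GenotypeTable`
(biallelic SNPs only) and a :class:`SexFrame`. Quality control mirrors the
standard resequencing recipe: per-call GQ/DP masking, then site-level
filtering on quality, call rate per cohort and per sex, and minor allele
frequency with a per-sex rescue rule.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


class SampleMismatchError(ValueError):
    pass


class SexFrame:
    """Sample sheet: sample_id, sex in {F, M}, optional genome mean depth."""

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        required = {"sample_id", "sex"}
        if not required.issubset(df.columns):
            raise ValueError(f"sex table needs columns {sorted(required)}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad = set(df["sex"]) - {"F", "M"}
        if bad:
            raise ValueError(f"sex must be F or M, got {sorted(bad)}")
        if set(df["sex"]) != {"F", "M"}:
            raise ValueError("both sexes must be represented")
        if "genome_mean_depth" not in df.columns:
            df["genome_mean_depth"] = np.nan
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "SexFrame":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def sex_of(self, sample: str) -> str:
        return self.df.set_index("sample_id").loc[sample, "sex"]

    def mask(self, samples, sex: str) -> np.ndarray:
        """Boolean mask over ``samples`` selecting the given sex."""
        lut = dict(zip(self.df["sample_id"], self.df["sex"]))
        missing = [s for s in samples if s not in lut]
        if missing:
            raise SampleMismatchError(
                f"samples absent from sex table: {missing}"
            )
        return np.array([lut[s] == sex for s in samples], dtype=bool)

    def depth_of(self, samples) -> np.ndarray:
        lut = dict(zip(self.df["sample_id"], self.df["genome_mean_depth"]))
        return np.array([lut[s] for s in samples], dtype=float)


@dataclass
class GenotypeTable:
    """Biallelic-SNP genotype matrix with per-call DP/GQ.

    ``sites`` has columns chrom, pos, ref, alt, qual (pos 1-based, strictly
    increasing within chrom); ``codes`` is (n_sites, n_samples) int8 using
    HOM_REF/HET/HOM_ALT/MISSING; ``dp`` and ``gq`` are parallel int arrays.
    """

    samples: list[str]
    sites: pd.DataFrame
    codes: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    n_skipped_non_biallelic: int = 0

    def __post_init__(self):
        n_sites, n_samples = self.codes.shape
        assert len(self.sites) == n_sites and len(self.samples) == n_samples
        assert self.dp.shape == self.codes.shape == self.gq.shape

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def called(self) -> np.ndarray:
        return self.codes != MISSING

    def subset_sites(self, mask_or_index) -> "GenotypeTable":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            sites=self.sites.iloc[idx].reset_index(drop=True),
            codes=self.codes[idx],
            dp=self.dp[idx],
            gq=self.gq[idx],
        )

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (0/1/2) with NaN for missing calls."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        return d


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade; defaults follow the standard
    resequencing criteria (Q >= 30, GQ >= 20, DP >= 7, 90% call rate,
    12 called per sex, global MAF >= 0.05 with per-sex 0.20 rescue)."""

    min_site_q: float = 30.0
    min_gq: int = 20
    min_dp: int = 7
    min_callrate: float = 0.90
    min_called_per_sex: int = 12
    global_maf: float = 0.05
    rescue_local_maf: float = 0.20

    def __post_init__(self):
        if not (0 < self.min_callrate <= 1):
            raise ValueError("min_callrate must be in (0, 1]")
        for name in ("min_site_q", "min_gq", "min_dp", "global_maf",
                     "rescue_local_maf", "min_called_per_sex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def load_genotypes(vcf_path, sex_table_path) -> tuple[GenotypeTable, SexFrame]:
    """Read a VCF and sex sheet into a GenotypeTable + SexFrame.

    Only biallelic SNP records are representable; others are skipped and
    counted. Phasing is ignored; half-missing genotypes are missing. Every
    VCF sample must appear in the sex table.
    """
    from cyvcf2 import VCF

    sexframe = SexFrame.from_tsv(sex_table_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    known = set(sexframe.samples)
    offenders = [s for s in samples if s not in known]
    if offenders:
        raise SampleMismatchError(
            f"VCF samples absent from sex table: {offenders}"
        )

    rows, codes, dps, gqs = [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0=hom_ref, 1=het, 2=hom_alt, 3=unknown
        g = var.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        # half-missing genotypes (./x) are missing, not partial calls
        half = np.fromiter(
            ((gt[0] < 0 or gt[1] < 0) for gt in var.genotypes),
            dtype=bool, count=len(samples))
        g[half] = MISSING
        dp = var.format("DP")
        gq = var.format("GQ")
        dp = (np.zeros(len(samples), int) if dp is None
              else np.nan_to_num(dp.astype(float)).astype(int).ravel())
        gq = (np.zeros(len(samples), int) if gq is None
              else np.nan_to_num(gq.astype(float)).astype(int).ravel())
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0],
                     float(var.QUAL) if var.QUAL is not None else 0.0))
        codes.append(g)
        dps.append(dp)
        gqs.append(gq)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    n = len(sites)
    table = GenotypeTable(
        samples=samples,
        sites=sites,
        codes=(np.vstack(codes) if n else np.empty((0, len(samples)), np.int8)),
        dp=(np.vstack(dps) if n else np.empty((0, len(samples)), int)),
        gq=(np.vstack(gqs) if n else np.empty((0, len(samples)), int)),
        n_skipped_non_biallelic=n_skipped,
    )
    return table, sexframe


def mask_low_quality_calls(table: GenotypeTable, cfg: FilterConfig = None
                           ) -> tuple[GenotypeTable, dict]:
    """Set calls with GQ < min_gq or DP < min_dp to missing."""
    cfg = cfg or FilterConfig()
    called = table.called()
    bad = called & ((table.gq < cfg.min_gq) | (table.dp < cfg.min_dp))
    codes = table.codes.copy()
    codes[bad] = MISSING
    report = {
        "masked_low_gq": int((called & (table.gq < cfg.min_gq)).sum()),
        "masked_low_dp": int((called & (table.dp < cfg.min_dp)).sum()),
        "masked_total": int(bad.sum()),
    }
    return replace(table, codes=codes), report


def _allele_freq(codes: np.ndarray, sample_mask=None):
    """Alt allele frequency from called genotypes; NaN if none called."""
    c = codes if sample_mask is None else codes[:, sample_mask]
    called = (c != MISSING).sum(axis=1)
    alt = np.where(c == MISSING, 0, c).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, alt / (2.0 * called), np.nan), called


def filter_sites(table: GenotypeTable, sexframe: SexFrame,
                 cfg: FilterConfig = None) -> tuple[GenotypeTable, dict]:
    """Apply the site-level cascade; returns retained table + drop counts.

    Cascade order for reporting: (a) biallelic (applied at load), (b) site
    quality, (c) — per-call DP, applied by mask_low_quality_calls — then
    (d) call-rate overall and per sex, (e)/(f) MAF with rescue. The
    retained set itself is order-independent.
    """
    cfg = cfg or FilterConfig()
    n_samples = len(table.samples)
    fmask = sexframe.mask(table.samples, "F")
    mmask = sexframe.mask(table.samples, "M")

    qual_ok = table.sites["qual"].to_numpy() >= cfg.min_site_q
    called = table.called()
    callrate_ok = called.sum(axis=1) / n_samples >= cfg.min_callrate
    persex_ok = (
        (called[:, fmask].sum(axis=1) >= cfg.min_called_per_sex)
        & (called[:, mmask].sum(axis=1) >= cfg.min_called_per_sex)
    )
    p_all, _ = _allele_freq(table.codes)
    p_f, _ = _allele_freq(table.codes, fmask)
    p_m, _ = _allele_freq(table.codes, mmask)
    maf = np.minimum(p_all, 1 - p_all)
    with np.errstate(invalid="ignore"):
        maf_f = np.minimum(p_f, 1 - p_f)
        maf_m = np.minimum(p_m, 1 - p_m)
        rescue = (maf_f >= cfg.rescue_local_maf) | (maf_m >= cfg.rescue_local_maf)
    maf_ok = (maf >= cfg.global_maf) | rescue

    keep = qual_ok & callrate_ok & persex_ok & maf_ok
    # cascade-ordered drop attribution: each site counted at its first failure
    surviving = np.ones(table.n_sites, bool)
    report = {"non_biallelic": table.n_skipped_non_biallelic}
    for name, ok in [("site_quality", qual_ok),
                     ("callrate_overall", callrate_ok),
                     ("callrate_per_sex", persex_ok),
                     ("maf", maf_ok)]:
        report[f"dropped_{name}"] = int((surviving & ~ok).sum())
        surviving &= ok
    report["retained"] = int(keep.sum())
    return table.subset_sites(keep), report


def write_vcf(table: GenotypeTable, path, chrom_lengths: dict | None = None
              ) -> None:
    """Write the table as a minimal VCF v4.2 with GT:DP:GQ."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=sdrscan\n")
    if chrom_lengths:
        for c, ln in chrom_lengths.items():
            buf.write(f"##contig=<ID={c},length={ln}>\n")
    else:
        for c in dict.fromkeys(table.sites["chrom"]):
            buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    buf.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(table.samples) + "\n")
    sites = table.sites
    for i in range(table.n_sites):
        row = sites.iloc[i]
        calls = "\t".join(
            f"{_GT_STR[int(c)]}:{int(d)}:{int(g)}"
            for c, d, g in zip(table.codes[i], table.dp[i], table.gq[i])
        )
        buf.write(f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t"
                  f"{row.qual:.6g}\t.\t.\tGT:DP:GQ\t{calls}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
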