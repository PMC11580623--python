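"""Depth-of-coverage comparison between sexes and hemizygous-region calling.

A region present on the W only shows up as ~half the individual's
genome-wide depth in ZW females and near-zero depth in ZZ males. Each
position (or window) is screened with Welch's t-test; significant
positions must also pass the half-depth band in the present sex and the
<= 2X ceiling in the absent sex — the ceiling is what separates true
hemizygosity from a copy-number difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicRegion
from .qc import SexFrame


@dataclass
class CoverageCallConfig:
    welch_p_max: float = 1e-4
    half_depth_band: tuple = (0.35, 0.65)
    absent_depth_max: float = 2.0
    merge_gap: int = 200
    min_region_len: int = 1000
    window: int = 1

    def __post_init__(self):
        lo, hi = self.half_depth_band
        if not (0 < lo < hi < 1):
            raise ValueError("half_depth_band must be within (0, 1)")
        if not (0 < self.welch_p_max < 1):
            raise ValueError("welch_p_max must be in (0, 1)")


@dataclass
class DepthMatrix:
    """Per-position X-coverage for one chromosome (positions 1-based)."""

    chrom: str
    positions: np.ndarray
    depth: np.ndarray  # (n_positions, n_samples)
    samples: list[str]

    def __post_init__(self):
        assert self.depth.shape == (len(self.positions), len(self.samples))
        if (np.diff(self.positions) <= 0).any():
            raise ValueError("positions must be strictly increasing")

    @classmethod
    def from_tsv(cls, path) -> "DepthMatrix":
        df = pd.read_csv(path, sep="\t")
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("one DepthMatrix per chromosome")
        samples = [c for c in df.columns if c not in ("chrom", "pos")]
        return cls(chrom=str(chroms[0]),
                   positions=df["pos"].to_numpy(int),
                   depth=df[samples].to_numpy(float),
                   samples=samples)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.depth, columns=self.samples)
        df.insert(0, "pos", self.positions)
        df.insert(0, "chrom", self.chrom)
        df.to_csv(path, sep="\t", index=False)

    def row_means(self) -> np.ndarray:
        """Mean depth per sample over all covered positions."""
        return self.depth.mean(axis=0)


def welch_t(group_a, group_b):
    """Welch's unequal-variance t-test: (t, df, two-sided p).

    Degenerate inputs: both groups constant and equal -> (0, nan, 1);
    both constant but unequal -> (inf, nan, 0), flagged by p == 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.var(ddof=0) == 0 and b.var(ddof=0) == 0:
        if a.mean() == b.mean():
            return 0.0, float("nan"), 1.0
        return float("inf"), float("nan"), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def scan_depth(matrix: DepthMatrix, sexframe: SexFrame,
               cfg: CoverageCallConfig | None = None,
               genome_means: np.ndarray | None = None) -> pd.DataFrame:
    """Per-position sex comparison with hemizygosity candidate flags.

    ``genome_means`` are per-sample genome-wide mean depths (defaults to
    the sex table's ``genome_mean_depth`` column, falling back to matrix
    row means). The half-depth criterion is the per-individual depth
    ratio to its own genome mean, averaged within the present sex.

    Returns a frame with mean_f/mean_m, ratio_f/ratio_m, p and the
    ``candidate_f`` / ``candidate_m`` flags.
    """
    cfg = cfg or CoverageCallConfig()
    fmask = sexframe.mask(matrix.samples, "F")
    mmask = sexframe.mask(matrix.samples, "M")
    if genome_means is None:
        genome_means = sexframe.depth_of(matrix.samples)
        if np.isnan(genome_means).any():
            genome_means = matrix.row_means()

    positions = matrix.positions
    depth = matrix.depth
    if cfg.window > 1:
        n = (len(positions) // cfg.window) * cfg.window
        depth = depth[:n].reshape(-1, cfg.window, depth.shape[1]).mean(axis=1)
        starts = positions[:n:cfg.window]
        ends = positions[cfg.window - 1: n: cfg.window]
    else:
        starts = ends = positions

    dfm = depth[:, fmask]
    dmm = depth[:, mmask]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(dfm, dmm, axis=1, equal_var=False)
    # degenerate rows: identical constants -> p 1; distinct constants -> p 0
    const = (dfm.var(axis=1) == 0) & (dmm.var(axis=1) == 0)
    p = np.where(const & (dfm.mean(axis=1) == dmm.mean(axis=1)), 1.0, p)
    p = np.where(const & (dfm.mean(axis=1) != dmm.mean(axis=1)), 0.0, p)

    ratio_f = (dfm / genome_means[fmask]).mean(axis=1)
    ratio_m = (dmm / genome_means[mmask]).mean(axis=1)
    mean_f, mean_m = dfm.mean(axis=1), dmm.mean(axis=1)
    lo, hi = cfg.half_depth_band
    sig = p < cfg.welch_p_max
    cand_f = sig & (ratio_f >= lo) & (ratio_f <= hi) & (mean_m <= cfg.absent_depth_max)
    cand_m = sig & (ratio_m >= lo) & (ratio_m <= hi) & (mean_f <= cfg.absent_depth_max)
    return pd.DataFrame({
        "chrom": matrix.chrom, "start": starts, "end": ends,
        "mean_f": mean_f, "mean_m": mean_m,
        "ratio_f": ratio_f, "ratio_m": ratio_m, "p": p,
        "candidate_f": cand_f, "candidate_m": cand_m,
    })


def call_regions(scan: pd.DataFrame, cfg: CoverageCallConfig | None = None,
                 sex: str = "F") -> list[GenomicRegion]:
    """Merge candidate positions into sex-limited hemizygous regions.

    Runs of candidates separated by <= merge_gap uncovered bases are
    joined; regions shorter than min_region_len are dropped. Coordinates
    are 1-based inclusive.
    """
    cfg = cfg or CoverageCallConfig()
    col = f"candidate_{sex.lower()}"
    cand = scan[scan[col]]
    if len(cand) == 0:
        return []
    from .intervals import merge_intervals

    merged = merge_intervals(
        list(zip(cand["start"], cand["end"])), gap=cfg.merge_gap)
    chrom = scan["chrom"].iloc[0]
    return [
        GenomicRegion(chrom, s, e, kind="sex_specific_haploid", sex=sex.upper())
        for s, e in merged
        if e - s + 1 >= cfg.min_region_len
    ]
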