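"""Assembling the sex determining region from its evidence layers.

Sex-specific SNPs cluster into sex-linked segments, which are extended by
a fixed flank (5 kb by default); the SDR is the span over those segments
plus any sex-limited hemizygous region lying between (or overlapping)
them. Region summaries include repeat content as the fraction of the
region covered by the union of repeat intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .intervals import GenomicRegion, interval_length, merge_intervals


@dataclass
class AssemblyConfig:
    flank_bp: int = 5000
    snp_cluster_gap: int = 10000
    clip_to_chrom: bool = True

    def __post_init__(self):
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")


def kb(value_bp: int, decimals: int = 1) -> float:
    """bp -> Kb with round-half-away-from-zero (1 Kb = 1000 bp)."""
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(int(value_bp)) / Decimal(1000)).quantize(q, ROUND_HALF_UP))


def cluster_snps(hits: pd.DataFrame, cfg: AssemblyConfig | None = None,
                 chrom_lengths: dict | None = None) -> list[GenomicRegion]:
    """Group sex-specific SNPs into flanked sex-linked regions.

    Consecutive hits on a chromosome separated by <= snp_cluster_gap share
    a cluster; each cluster span is extended by flank_bp on both sides and
    clipped to [1, chrom_length]. Flanked clusters that overlap are merged
    into one region (flanks are annotation, not evidence).
    """
    cfg = cfg or AssemblyConfig()
    if hits is None or len(hits) == 0:
        return []
    out = []
    for chrom, grp in hits.groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy(int))
        clusters = [[pos[0], pos[0], [int(pos[0])]]]
        for p in pos[1:]:
            if p - clusters[-1][1] <= cfg.snp_cluster_gap:
                clusters[-1][1] = int(p)
                clusters[-1][2].append(int(p))
            else:
                clusters.append([int(p), int(p), [int(p)]])
        flanked = []
        for s, e, members in clusters:
            fs, fe = int(s - cfg.flank_bp), int(e + cfg.flank_bp)
            if cfg.clip_to_chrom:
                fs = max(1, fs)
                if chrom_lengths and chrom in chrom_lengths:
                    fe = min(chrom_lengths[chrom], fe)
            flanked.append((fs, fe, tuple(members)))
        # merge overlapping flanked clusters
        merged = []
        for fs, fe, members in sorted(flanked):
            if merged and fs <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], fe),
                              merged[-1][2] + members)
            else:
                merged.append((fs, fe, members))
        for fs, fe, members in merged:
            out.append(GenomicRegion(chrom, fs, fe, kind="sex_linked",
                                     provenance=tuple(members)))
    return out


def assemble_sdr(sex_linked: list[GenomicRegion],
                 haploid: list[GenomicRegion] | None = None
                 ) -> tuple[GenomicRegion | None, pd.DataFrame]:
    """Combine sex-linked and hemizygous regions into the SDR.

    The SDR spans [min start, max end] over the sex-linked regions plus
    any haploid region lying between them or overlapping them; haploid
    regions outside that span are excluded from the SDR but still listed
    in the component table (included=False). Multi-chromosome input keeps
    only the chromosome with most sex-linked evidence, with a warning.
    """
    haploid = haploid or []
    if not sex_linked and not haploid:
        return None, pd.DataFrame(
            columns=["chrom", "start", "end", "kind", "length_bp",
                     "length_kb", "included"])
    pool = sex_linked if sex_linked else haploid
    chroms = {r.chrom for r in pool}
    if len(chroms) > 1:
        import warnings

        counts = {c: sum(r.chrom == c for r in pool) for c in chroms}
        keep = max(counts, key=counts.get)
        warnings.warn(f"regions on multiple chromosomes; keeping {keep}")
        sex_linked = [r for r in sex_linked if r.chrom == keep]
        haploid = [r for r in haploid if r.chrom == keep]
        pool = sex_linked if sex_linked else haploid
    chrom = pool[0].chrom

    anchors = sex_linked if sex_linked else haploid
    span_s = min(r.start for r in anchors)
    span_e = max(r.end for r in anchors)
    rows = []
    included_regions = list(anchors)
    for r in haploid if sex_linked else []:
        inside = r.start >= span_s and r.end <= span_e
        overlapping = r.start <= span_e and r.end >= span_s
        if inside or overlapping:
            included_regions.append(r)
    for r in sorted(set(included_regions) | set(haploid),
                    key=lambda r: (r.start, r.end)):
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end, "kind": r.kind,
            "length_bp": r.length, "length_kb": kb(r.length),
            "included": r in included_regions,
        })
    sdr_s = min(r.start for r in included_regions)
    sdr_e = max(r.end for r in included_regions)
    prov = tuple((r.kind, r.start, r.end) for r in included_regions)
    sdr = GenomicRegion(chrom, sdr_s, sdr_e, kind="sdr", provenance=prov)
    table = pd.DataFrame(rows)
    return sdr, table


def sdr_report(sdr: GenomicRegion, components: pd.DataFrame) -> dict:
    """Headline numbers: total bp, Kb to one decimal and to integer."""
    total = sdr.length
    return {
        "chrom": sdr.chrom, "start": sdr.start, "end": sdr.end,
        "length_bp": total, "length_kb": kb(total),
        "length_kb_headline": int(kb(total, 0)),
        "n_components": int(components["included"].sum()),
    }


def repeat_fraction(region: GenomicRegion, repeats) -> float:
    """Fraction of the region covered by the union of repeat intervals.

    ``repeats`` is an iterable of (start, end) 1-based inclusive pairs or
    GenomicRegions on the same chromosome; mutual overlaps are unioned
    before intersecting with the region.
    """
    ivs = []
    for r in repeats:
        if isinstance(r, GenomicRegion):
            if r.chrom != region.chrom:
                continue
            s, e = r.start, r.end
        else:
            s, e = int(r[0]), int(r[1])
        s, e = max(s, region.start), min(e, region.end)
        if s <= e:
            ivs.append((s, e))
    covered = sum(interval_length(s, e) for s, e in merge_intervals(ivs))
    return covered / region.length
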