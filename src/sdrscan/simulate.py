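"""Seeded synthetic ZW/XY cohort generator.

Emulates a population-resequencing sex study end to end: a reference
genome assembled from the heterogametic individual (so it carries the
sex-limited insertion), autosomal SNPs drawn from Hardy–Weinberg
proportions, fully sex-linked SNPs heterozygous in the heterogametic sex,
a hemizygous insertion at half depth in that sex and near-zero depth in
the other, a diploid paralog of part of the insertion differing by
internal gaps, gene models, repeats and a shared primer pair. Identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import DepthMatrix
from .intervals import GenomicRegion, interval_length
from .markers import PrimerPair, revcomp
from .qc import HET, HOM_REF, MISSING, GenotypeTable, SexFrame, write_vcf

_PRIMER_LEN = 20
_FWD_OFFSET = 10  # forward primer 5' offset inside the haploid segment
_REV_MARGIN = 36  # reverse primer 5' sits this far from the segment's 3' end


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ParalogSpec:
    """Haploid source inside the hemizygous insertion, its diploid
    destination locus, and the gap lengths inserted into the diploid copy."""

    source: tuple = (25_000, 25_589)
    dest_start: int = 70_000
    gaps: tuple = (40, 30, 27)
    dest_chrom: str | None = None  # defaults to the SDR chromosome


@dataclass
class CohortConfig:
    n_females: int = 24
    n_males: int = 20
    system: str = "ZW"
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 500_000, "chr2": 80_000})
    n_autosomal_snps: int = 10_000
    sdr_chrom: str = "chr2"
    sexlinked_intervals: tuple = ((10_001, 19_301), (46_500, 48_000))
    n_sexlinked_snps: int = 20
    hemizygous_interval: tuple = (24_500, 45_825)
    mean_depth_range: tuple = (20.0, 41.0)
    depth_dispersion: float = 20.0
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.02
    # ("beta", a, b[, lo, hi]): beta-distributed alt frequency rescaled
    # into [lo, hi] (default [0.05, 0.95])
    maf_dist: tuple = ("beta", 0.8, 0.8)
    paralog: ParalogSpec = field(default_factory=ParalogSpec)
    flank_bp: int = 5000
    seed: int = 0

    def validate(self) -> None:
        if self.n_females < 2 or self.n_males < 2:
            raise ConfigurationError("need at least 2 individuals per sex")
        if self.system not in ("ZW", "XY"):
            raise ConfigurationError("system must be ZW or XY")
        if self.sdr_chrom not in self.chrom_lengths:
            raise ConfigurationError(f"{self.sdr_chrom} not in chrom_lengths")
        L = self.chrom_lengths[self.sdr_chrom]
        hs, he = self.hemizygous_interval
        for s, e in (*self.sexlinked_intervals, self.hemizygous_interval):
            if not (1 <= s <= e <= L):
                raise ConfigurationError(
                    f"interval ({s}, {e}) outside {self.sdr_chrom} [1, {L}]")
        for s, e in self.sexlinked_intervals:
            if s <= he and e >= hs:
                raise ConfigurationError(
                    "hemizygous interval overlaps a sex-linked interval")
        ss, se = self.paralog.source
        if not (hs <= ss <= se <= he):
            raise ConfigurationError(
                "paralog source must lie inside the hemizygous interval")
        if any(g <= 0 for g in self.paralog.gaps):
            raise ConfigurationError("paralog gap lengths must be positive")
        dchrom = self.paralog.dest_chrom or self.sdr_chrom
        dlen = interval_length(ss, se) + sum(self.paralog.gaps)
        ds, de = self.paralog.dest_start, self.paralog.dest_start + dlen - 1
        if de > self.chrom_lengths[dchrom]:
            raise ConfigurationError("paralog destination outside chromosome")
        if dchrom == self.sdr_chrom and ds <= he and de >= hs:
            raise ConfigurationError(
                "paralog destination overlaps the hemizygous interval")

    @property
    def heterogametic_sex(self) -> str:
        return "F" if self.system == "ZW" else "M"


@dataclass
class TruthSet:
    planted_sexlinked: list  # [(chrom, pos), ...]
    hemizygous_region: GenomicRegion
    expected_sdr: GenomicRegion
    paralog_haploid: GenomicRegion
    paralog_diploid: GenomicRegion
    total_gap_bp: int
    primers: PrimerPair
    expected_bands: dict  # sex -> {length: copies}
    sdr_gene_ids: list


@dataclass
class Cohort:
    config: CohortConfig
    reference: dict
    table: GenotypeTable
    depth: DepthMatrix
    sexframe: SexFrame
    gff_text: str
    repeats: list  # [(chrom, start, end), ...] 1-based inclusive
    primers: PrimerPair
    truth: TruthSet

    def write(self, outdir) -> dict:
        """Write all study files; returns the path map."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {k: out / v for k, v in {
            "fasta": "reference.fa", "vcf": "cohort.vcf",
            "depth": "depth.tsv", "sex": "sex.tsv", "gff": "genes.gff3",
            "repeats": "repeats.bed", "primers": "primers.tsv",
            "truth": "truth.json"}.items()}
        write_fasta(self.reference, paths["fasta"])
        write_vcf(self.table, paths["vcf"], self.config.chrom_lengths)
        self.depth.to_tsv(paths["depth"])
        self.sexframe.to_tsv(paths["sex"])
        paths["gff"].write_text(self.gff_text)
        with open(paths["repeats"], "w") as fh:  # BED: 0-based half-open
            for chrom, s, e in self.repeats:
                fh.write(f"{chrom}\t{s - 1}\t{e}\trepeat\n")
        with open(paths["primers"], "w") as fh:
            fh.write("name\tforward\treverse\n")
            fh.write(f"{self.primers.name}\t{self.primers.forward}\t"
                     f"{self.primers.reverse}\n")
        t = self.truth
        paths["truth"].write_text(json.dumps({
            "planted_sexlinked": t.planted_sexlinked,
            "hemizygous_region": [t.hemizygous_region.chrom,
                                  t.hemizygous_region.start,
                                  t.hemizygous_region.end],
            "expected_sdr": [t.expected_sdr.chrom, t.expected_sdr.start,
                             t.expected_sdr.end],
            "paralog_haploid": [t.paralog_haploid.chrom,
                                t.paralog_haploid.start, t.paralog_haploid.end],
            "paralog_diploid": [t.paralog_diploid.chrom,
                                t.paralog_diploid.start, t.paralog_diploid.end],
            "total_gap_bp": t.total_gap_bp,
            "primers": [t.primers.name, t.primers.forward, t.primers.reverse],
            "expected_bands": t.expected_bands,
            "sdr_gene_ids": t.sdr_gene_ids,
        }, indent=1))
        return paths


_BASE_LUT = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return (rng.integers(0, 4, size=length, dtype=np.uint8)
            .tobytes().translate(_BASE_LUT).decode())


def write_fasta(reference: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def plant_paralog(reference: dict, spec: ParalogSpec, sdr_chrom: str,
                  hemizygous_interval: tuple, rng: np.random.Generator
                  ) -> tuple[dict, GenomicRegion, GenomicRegion]:
    """Copy the haploid source segment to the destination locus with the
    configured gap sequences inserted internally.

    The diploid copy equals the haploid copy plus the gaps; both copies
    keep identical flanks of at least primer length because insertions are
    placed away from the segment ends. Returns the modified reference and
    the two interval records.
    """
    hs, he = hemizygous_interval
    ss, se = spec.source
    if not (hs <= ss <= se <= he):
        raise ConfigurationError("paralog source outside hemizygous interval")
    dchrom = spec.dest_chrom or sdr_chrom
    h_seq = reference[sdr_chrom][ss - 1:se]
    margin = _REV_MARGIN + _PRIMER_LEN  # keep primer sites gap-free
    lo, hi = _FWD_OFFSET + _PRIMER_LEN + 5, len(h_seq) - margin - 5
    if spec.gaps and hi <= lo + len(spec.gaps):
        raise ConfigurationError("source segment too short for gap placement")
    offsets = sorted(rng.choice(np.arange(lo, hi), size=len(spec.gaps),
                                replace=False).tolist()) if spec.gaps else []
    d_parts, prev = [], 0
    for off, gap in zip(offsets, spec.gaps):
        d_parts.append(h_seq[prev:off])
        d_parts.append(_random_seq(rng, gap))
        prev = off
    d_parts.append(h_seq[prev:])
    d_seq = "".join(d_parts)
    ds = spec.dest_start
    de = ds + len(d_seq) - 1
    if dchrom == sdr_chrom and ds <= he and de >= hs:
        raise ConfigurationError("destination overlaps hemizygous interval")
    if de > len(reference[dchrom]):
        raise ConfigurationError("destination outside chromosome")
    seq = reference[dchrom]
    reference = dict(reference)
    reference[dchrom] = seq[:ds - 1] + d_seq + seq[ds - 1 + len(d_seq):]
    hap = GenomicRegion(sdr_chrom, ss, se, kind="paralog_haploid")
    dip = GenomicRegion(dchrom, ds, de, kind="paralog_diploid")
    return reference, hap, dip


def _simulate_genotypes(cfg: CohortConfig, rng, reference, samples, het_mask):
    """Site frame + genotype codes before error/missingness."""
    autosomes = [c for c in cfg.chrom_lengths if c != cfg.sdr_chrom]
    rows, codes = [], []
    per = {c: cfg.n_autosomal_snps // len(autosomes) for c in autosomes}
    per[autosomes[-1]] += cfg.n_autosomal_snps - sum(per.values())
    n_samples = len(samples)
    _, a, b, *bounds = cfg.maf_dist
    lo_f, hi_f = bounds if bounds else (0.05, 0.95)
    for chrom in cfg.chrom_lengths:
        if chrom == cfg.sdr_chrom:
            ivs = cfg.sexlinked_intervals
            lens = np.array([interval_length(s, e) for s, e in ivs])
            counts = np.maximum(1, np.round(
                cfg.n_sexlinked_snps * lens / lens.sum())).astype(int)
            counts[-1] += cfg.n_sexlinked_snps - counts.sum()
            pos = np.sort(np.concatenate([
                rng.choice(np.arange(s, e + 1), size=c, replace=False)
                for (s, e), c in zip(ivs, counts)]))
            for p in pos:
                g = np.where(het_mask, HET, HOM_REF).astype(np.int8)
                rows.append((chrom, int(p), True))
                codes.append(g)
        else:
            pos = np.sort(rng.choice(
                np.arange(1, cfg.chrom_lengths[chrom] + 1),
                size=per[chrom], replace=False))
            p_alt = lo_f + (hi_f - lo_f) * rng.beta(a, b, size=len(pos))
            dosage = rng.binomial(2, p_alt[:, None],
                                  size=(len(pos), n_samples))
            for i, p in enumerate(pos):
                rows.append((chrom, int(p), False))
                codes.append(dosage[i].astype(np.int8))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "sex_linked"])
    return sites, np.vstack(codes)


def _alleles_for(sites, reference, rng):
    refs, alts = [], []
    others = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        base = reference[chrom][pos - 1]
        refs.append(base)
        alts.append(others[base][rng.integers(3)])
    return refs, alts


def _gene_gff(gene_id, chrom, start, strand):
    """One gene: UTR-exon-intron-exon-UTR, CDS lengths divisible by 3."""
    e1s, e1e = start, start + 249
    e2s, e2e = start + 650, start + 1049
    utr_l = (e1s, e1s + 99)
    cds1 = (e1s + 100, e1e)          # 150 bp
    cds2 = (e2s, e2s + 251)          # 252 bp
    utr_r = (e2s + 252, e2e)
    utr5, utr3 = (utr_l, utr_r) if strand == "+" else (utr_r, utr_l)
    mrna = f"{gene_id}.t1"
    lines = [
        f"{chrom}\tsim\tgene\t{e1s}\t{e2e}\t.\t{strand}\t.\tID={gene_id}",
        f"{chrom}\tsim\tmRNA\t{e1s}\t{e2e}\t.\t{strand}\t.\t"
        f"ID={mrna};Parent={gene_id}",
    ]
    for s, e in ((e1s, e1e), (e2s, e2e)):
        lines.append(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                     f"Parent={mrna}")
    for s, e in (cds1, cds2):
        lines.append(f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
                     f"Parent={mrna}")
    lines.append(f"{chrom}\tsim\tfive_prime_UTR\t{utr5[0]}\t{utr5[1]}\t.\t"
                 f"{strand}\t.\tParent={mrna}")
    lines.append(f"{chrom}\tsim\tthree_prime_UTR\t{utr3[0]}\t{utr3[1]}\t.\t"
                 f"{strand}\t.\tParent={mrna}")
    return lines, (e1s, e2e)


def _build_genes(cfg: CohortConfig, sdr_span: tuple):
    """Seven genes inside the SDR span, plus decoys outside it."""
    lines = ["##gff-version 3"]
    sdr_ids = []
    s, e = sdr_span
    slots = np.linspace(s + 200, e - 1400, 7).astype(int)
    for i, gs in enumerate(slots, 1):
        gid = f"sdr_gene{i}"
        gl, _ = _gene_gff(gid, cfg.sdr_chrom, int(gs),
                          "+" if i % 2 else "-")
        lines += gl
        sdr_ids.append(gid)
    decoys = []
    L = cfg.chrom_lengths[cfg.sdr_chrom]
    cand = e + 6000
    if cand + 1100 < min(cfg.paralog.dest_start, L):
        decoys.append((f"flank_gene1", cfg.sdr_chrom, cand, "+"))
    for j, chrom in enumerate(c for c in cfg.chrom_lengths
                              if c != cfg.sdr_chrom):
        decoys.append((f"auto_gene{j + 1}", chrom, 10_000, "-"))
    for gid, chrom, gs, strand in decoys:
        gl, _ = _gene_gff(gid, chrom, gs, strand)
        lines += gl
    return "\n".join(lines) + "\n", sdr_ids


def _build_repeats(cfg: CohortConfig, rng) -> list:
    """Tile ~56% of the hemizygous insertion, plus scattered decoys."""
    hs, he = cfg.hemizygous_interval
    out = []
    pos = hs
    while pos <= he:
        out.append((cfg.sdr_chrom, pos, min(pos + 279, he)))
        pos += 500
    for chrom in cfg.chrom_lengths:
        if chrom == cfg.sdr_chrom:
            continue
        for _ in range(3):
            s = int(rng.integers(1, cfg.chrom_lengths[chrom] - 2000))
            out.append((chrom, s, s + int(rng.integers(200, 1500))))
    return out


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic study from a seeded configuration."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    reference = {
        chrom: _random_seq(rng, length)
        for chrom, length in cfg.chrom_lengths.items()
    }
    reference, hap_region, dip_region = plant_paralog(
        reference, cfg.paralog, cfg.sdr_chrom, cfg.hemizygous_interval, rng)

    # samples and per-individual genome-wide mean depth
    samples = ([f"F{i + 1:02d}" for i in range(cfg.n_females)]
               + [f"M{i + 1:02d}" for i in range(cfg.n_males)])
    sexes = ["F"] * cfg.n_females + ["M"] * cfg.n_males
    lo, hi = cfg.mean_depth_range
    m = rng.uniform(lo, hi, size=len(samples))
    het_mask = np.array([sx == cfg.heterogametic_sex for sx in sexes])

    sites, codes = _simulate_genotypes(cfg, rng, reference, samples, het_mask)
    n_sites, n_samples = codes.shape

    # genotype errors, then missingness
    err = rng.random(codes.shape) < cfg.genotype_error_rate
    if err.any():
        shift = rng.integers(1, 3, size=int(err.sum()))
        codes[err] = ((codes[err] + shift) % 3).astype(np.int8)
    miss = rng.random(codes.shape) < cfg.missing_rate
    codes[miss] = MISSING

    # per-call depth and genotype quality
    k = cfg.depth_dispersion
    mu = np.broadcast_to(m, (n_sites, n_samples))
    dp = rng.negative_binomial(k, k / (k + mu)).astype(int)
    gq = np.clip(np.round(rng.normal(65, 18, size=codes.shape)), 3, 99)
    gq_err = np.clip(np.round(rng.normal(12, 6, size=codes.shape)), 3, 99)
    gq = np.where(err, gq_err, gq).astype(int)
    qual = np.clip(0.7 * dp.sum(axis=1), 30, None)

    ref_a, alt_a = _alleles_for(sites, reference, rng)
    site_df = pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"],
        "ref": ref_a, "alt": alt_a, "qual": qual.astype(float)})
    table = GenotypeTable(samples=samples, sites=site_df, codes=codes,
                          dp=dp, gq=gq)

    # per-position depth matrix on the SDR chromosome
    L = cfg.chrom_lengths[cfg.sdr_chrom]
    hs, he = cfg.hemizygous_interval
    mu_pos = np.tile(m, (L, 1))
    inside = slice(hs - 1, he)
    mu_pos[inside, het_mask] *= 0.5
    mu_pos[inside, ~het_mask] = 0.25
    depth_vals = rng.negative_binomial(k, k / (k + mu_pos)).astype(float)
    depth = DepthMatrix(chrom=cfg.sdr_chrom,
                        positions=np.arange(1, L + 1),
                        depth=depth_vals, samples=samples)

    sexframe = SexFrame(pd.DataFrame({
        "sample_id": samples, "sex": sexes,
        "genome_mean_depth": np.round(m, 3)}))

    # primers in the conserved flanks of the haploid segment
    h_seq = reference[cfg.sdr_chrom][hap_region.start - 1:hap_region.end]
    fwd = h_seq[_FWD_OFFSET:_FWD_OFFSET + _PRIMER_LEN]
    rev_rc_start = len(h_seq) - _REV_MARGIN - _PRIMER_LEN
    rev = revcomp(h_seq[rev_rc_start:rev_rc_start + _PRIMER_LEN])
    primers = PrimerPair(name="sexmark1", forward=fwd, reverse=rev)
    hap_amplicon = len(h_seq) - _REV_MARGIN - _FWD_OFFSET
    dip_amplicon = hap_amplicon + sum(cfg.paralog.gaps)
    het = cfg.heterogametic_sex
    hom = "M" if het == "F" else "F"
    expected_bands = {het: {dip_amplicon: 2, hap_amplicon: 1},
                      hom: {dip_amplicon: 2}}

    planted = [(c, int(p)) for c, p, sl in
               zip(sites["chrom"], sites["pos"], sites["sex_linked"]) if sl]
    pmin = min(p for _, p in planted)
    pmax = max(p for _, p in planted)
    sdr_span = (max(1, pmin - cfg.flank_bp), min(L, pmax + cfg.flank_bp))
    gff_text, sdr_gene_ids = _build_genes(cfg, sdr_span)
    repeats = _build_repeats(cfg, rng)

    truth = TruthSet(
        planted_sexlinked=planted,
        hemizygous_region=GenomicRegion(cfg.sdr_chrom, hs, he,
                                        kind="sex_specific_haploid", sex=het),
        expected_sdr=GenomicRegion(cfg.sdr_chrom, *sdr_span, kind="sdr"),
        paralog_haploid=hap_region,
        paralog_diploid=dip_region,
        total_gap_bp=sum(cfg.paralog.gaps),
        primers=primers,
        expected_bands=expected_bands,
        sdr_gene_ids=sdr_gene_ids,
    )
    return Cohort(config=cfg, reference=reference, table=table, depth=depth,
                  sexframe=sexframe, gff_text=gff_text, repeats=repeats,
                  primers=primers, truth=truth)
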