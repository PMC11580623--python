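"""Variant classification against gene models and region gene census.

Each SNP gets exactly one category: a coding-effect call inside CDS
(synonymous / missense / nonsense via translation on the coding strand),
UTR, intron, upstream/downstream within a fixed flank of a gene span
(5 kb by default), or intergenic. Precedence within a transcript is
CDS > UTR > intron; across overlapping genes the highest-precedence
category wins, ties broken by smallest gene id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .intervals import GenomicRegion

CATEGORIES = ("exon_synonymous", "exon_missense", "exon_nonsense",
              "five_utr", "three_utr", "intron", "upstream", "downstream",
              "intergenic")
# smaller = higher precedence for within-gene categories
_PRECEDENCE = {"exon_nonsense": 0, "exon_missense": 0, "exon_synonymous": 0,
               "five_utr": 1, "three_utr": 1, "intron": 2}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    phase: int = 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class Transcript:
    id: str
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s.start for s in self.exons) if self.exons else 0

    @property
    def end(self) -> int:
        return max(s.end for s in self.exons) if self.exons else 0


@dataclass
class GeneModel:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list = field(default_factory=list)


def load_gene_models(gff, from_string: bool = False) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS/UTR features into GeneModel objects."""
    import gffutils

    db = gffutils.create_db(
        str(gff) if not from_string else gff,
        dbfn=":memory:", from_string=from_string, force=True,
        keep_order=True, merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene", order_by="start"):
        gene = GeneModel(id=g.id, chrom=g.seqid, strand=g.strand,
                         start=g.start, end=g.end)
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            tr = Transcript(id=t.id)
            for feat, attr in (("exon", "exons"), ("CDS", "cds"),
                               ("five_prime_UTR", "utr5"),
                               ("three_prime_UTR", "utr3")):
                for f in db.children(t, featuretype=feat, order_by="start"):
                    phase = int(f.frame) if f.frame not in (None, ".") else 0
                    getattr(tr, attr).append(Segment(f.start, f.end, phase))
            gene.transcripts.append(tr)
        genes.append(gene)
    return genes


@dataclass
class VariantAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    category: str
    distance: int | None = None  # for upstream/downstream
    aa_change: str | None = None  # for coding effects


def _seq_get(reference, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice from a dict-of-strings or pyfaidx Fasta."""
    seq = reference[chrom]
    return str(seq[start - 1:end]).upper()


def _coding_effect(tr: Transcript, strand: str, reference, chrom: str,
                   pos: int, ref: str, alt: str):
    """Translate the codon containing ``pos`` with ref vs alt base."""
    segs = sorted(tr.cds, key=lambda s: s.start)
    order = segs if strand == "+" else segs[::-1]
    coding = []
    var_off = None
    cum = 0
    for s in order:
        piece = _seq_get(reference, chrom, s.start, s.end)
        if strand == "-":
            piece = str(Seq(piece).reverse_complement())
        if s.contains(pos):
            var_off = cum + (pos - s.start if strand == "+" else s.end - pos)
        coding.append(piece)
        cum += s.end - s.start + 1
    cds_seq = "".join(coding)
    phase = order[0].phase
    cds_seq = cds_seq[phase:]
    var_off -= phase
    if var_off < 0:
        warnings.warn(f"{chrom}:{pos} falls in the out-of-frame phase "
                      "overhang; no effect call")
        return "exon_missense", None
    codon_i = var_off // 3
    cstart = codon_i * 3
    codon = cds_seq[cstart:cstart + 3]
    if len(codon) < 3:
        warnings.warn(f"incomplete terminal codon at {chrom}:{pos}")
        return "exon_missense", None
    base = ref if strand == "+" else str(Seq(ref).reverse_complement())
    alt_b = alt if strand == "+" else str(Seq(alt).reverse_complement())
    k = var_off - cstart
    if codon[k] != base:
        raise AnnotationError(
            f"CDS base at {chrom}:{pos} is {codon[k]}, VCF ref is {ref}")
    alt_codon = codon[:k] + alt_b + codon[k + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    change = f"{aa_ref}{codon_i + 1}{aa_alt}"
    if aa_ref == aa_alt:
        return "exon_synonymous", change
    if aa_alt == "*":
        return "exon_nonsense", change
    return "exon_missense", change


def _classify_in_transcript(tr: Transcript, strand: str, reference,
                            chrom: str, pos: int, ref: str, alt: str):
    in_cds = any(s.contains(pos) for s in tr.cds)
    if in_cds:
        return _coding_effect(tr, strand, reference, chrom, pos, ref, alt)
    if any(s.contains(pos) for s in tr.utr5):
        return "five_utr", None
    if any(s.contains(pos) for s in tr.utr3):
        return "three_utr", None
    if any(s.contains(pos) for s in tr.exons):
        # exonic but outside CDS and annotated UTRs: lean on the nearest
        # UTR side of the coding span
        cds_s = min((s.start for s in tr.cds), default=None)
        cds_e = max((s.end for s in tr.cds), default=None)
        warnings.warn(f"{chrom}:{pos} exonic but outside CDS/UTR annotation")
        if cds_s is None:
            return "five_utr", None
        if pos < cds_s:
            return ("five_utr" if strand == "+" else "three_utr"), None
        if pos > cds_e:
            return ("three_utr" if strand == "+" else "five_utr"), None
        return "intron", None
    return "intron", None


def classify_variant(models: list[GeneModel], chrom: str, pos: int,
                     ref: str, alt: str, reference,
                     flank_bp: int = 5000) -> VariantAnnotation:
    """Assign the single category of a SNP relative to gene models.

    ``reference`` maps chrom -> sequence (dict of strings or pyfaidx
    Fasta); the base at ``pos`` must equal ``ref``.
    """
    obs = _seq_get(reference, chrom, pos, pos)
    if obs != ref.upper():
        raise AnnotationError(
            f"reference base at {chrom}:{pos} is {obs}, VCF ref is {ref}")

    best = None  # (precedence, gene_id, category, aa_change)
    for gene in models:
        if gene.chrom != chrom or not (gene.start <= pos <= gene.end):
            continue
        for tr in gene.transcripts:
            if not (tr.start <= pos <= tr.end):
                continue
            cat, aa = _classify_in_transcript(
                tr, gene.strand, reference, chrom, pos, ref, alt)
            key = (_PRECEDENCE[cat], gene.id)
            if best is None or key < best[0]:
                best = (key, gene.id, cat, aa)
        if not gene.transcripts:
            key = (_PRECEDENCE["intron"], gene.id)
            if best is None or key < best[0]:
                best = (key, gene.id, "intron", None)
    if best is not None:
        _, gid, cat, aa = best
        return VariantAnnotation(chrom, pos, ref, alt, gid, cat, None, aa)

    # outside every gene span: nearest gene within the flank
    nearest = None  # (distance, gene_id, category)
    for gene in models:
        if gene.chrom != chrom:
            continue
        if pos < gene.start:
            dist = gene.start - pos
            cat = "upstream" if gene.strand == "+" else "downstream"
        elif pos > gene.end:
            dist = pos - gene.end
            cat = "downstream" if gene.strand == "+" else "upstream"
        else:  # pragma: no cover - handled above
            continue
        if dist <= flank_bp:
            key = (dist, gene.id)
            if nearest is None or key < (nearest[0], nearest[1]):
                nearest = (dist, gene.id, cat)
    if nearest is not None:
        dist, gid, cat = nearest
        return VariantAnnotation(chrom, pos, ref, alt, gid, cat, dist, None)
    return VariantAnnotation(chrom, pos, ref, alt, None, "intergenic")


def annotate_table(models, sites: pd.DataFrame, reference,
                   flank_bp: int = 5000) -> pd.DataFrame:
    """Classify every row of a sites frame (chrom, pos, ref, alt)."""
    rows = []
    for _, s in sites.iterrows():
        ann = classify_variant(models, s["chrom"], int(s["pos"]),
                               s["ref"], s["alt"], reference, flank_bp)
        rows.append(vars(ann))
    return pd.DataFrame(rows)


def genes_in_region(models: list[GeneModel],
                    region: GenomicRegion) -> pd.DataFrame:
    """Genes whose span intersects the region (closed intervals)."""
    rows = []
    for g in models:
        gr = GenomicRegion(g.chrom, g.start, g.end, kind="gene")
        if gr.overlaps(region):
            rows.append({"gene_id": g.id, "chrom": g.chrom,
                         "start": g.start, "end": g.end,
                         "strand": g.strand,
                         "overlap_bp": gr.overlap_bp(region)})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                       "strand", "overlap_bp"])


def exon_identity_table(query_exons: list[str], subject_exons: list[str],
                        pairing: list[tuple[int, int]] | None = None
                        ) -> tuple[pd.DataFrame, float]:
    """Percent nucleotide identity per exon pair under global alignment.

    Pairs are supplied explicitly or formed by order from the 3' end
    (last query exon with last subject exon, and so on). Identity is
    matches / alignment columns, gap columns counting as mismatch; the
    reported average is the unweighted mean over pairs. Zero-length exons
    skip their pair.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    if pairing is None:
        k = min(len(query_exons), len(subject_exons))
        pairing = [(len(query_exons) - k + i, len(subject_exons) - k + i)
                   for i in range(k)]
    rows = []
    for qi, si in pairing:
        q, s = query_exons[qi], subject_exons[si]
        if len(q) == 0 or len(s) == 0:
            continue
        aln = aligner.align(q, s)[0]
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        pct = 100.0 * counts.identities / columns
        rows.append({"query_exon": qi, "subject_exon": si,
                     "identity_pct": pct, "columns": columns})
    df = pd.DataFrame(rows)
    mean = float(df["identity_pct"].mean()) if len(df) else float("nan")
    return df, mean
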