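"""Variant effect classification and gene census."""

import numpy as np
import pytest

from sdrscan.annotate import (AnnotationError, GeneModel, Segment, Transcript,
                              classify_variant, exon_identity_table,
                              genes_in_region, load_gene_models)
from sdrscan.intervals import GenomicRegion
from sdrscan.markers import revcomp

# independent standard-code oracle (hand-entered, DNA codons)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _reference(length=20_000, seed=0):
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    return seq


def _plus_gene(seq):
    """Gene on +: UTR5 [1001,1050], CDS [1051,1100]+[1201,1252],
    UTR3 [1253,1350]; the first two codons are GAT TAT."""
    for i, b in zip(range(1050, 1056), "GATTAT"):
        seq[i] = b
    tr = Transcript(id="t1",
                    exons=[Segment(1001, 1100), Segment(1201, 1350)],
                    cds=[Segment(1051, 1100), Segment(1201, 1252)],
                    utr5=[Segment(1001, 1050)], utr3=[Segment(1253, 1350)])
    return GeneModel(id="g1", chrom="t", strand="+", start=1001, end=1350,
                     transcripts=[tr])


def test_synonymous_missense_nonsense_calls():
    seq = _reference()
    gene = _plus_gene(seq)
    ref = {"t": "".join(seq)}
    # GAT -> GAC, third position: both Asp -> synonymous
    ann = classify_variant([gene], "t", 1053, "T", "C", ref)
    assert ann.category == "exon_synonymous" and ann.gene_id == "g1"
    # GAT -> AAT: Asp -> Asn missense
    assert classify_variant([gene], "t", 1051, "G", "A", ref).category == \
        "exon_missense"
    # TAT -> TAA: stop gained
    assert classify_variant([gene], "t", 1056, "T", "A", ref).category == \
        "exon_nonsense"


def test_positional_categories():
    seq = _reference()
    gene = _plus_gene(seq)
    ref = {"t": "".join(seq)}

    def cat(pos):
        return classify_variant([gene], "t", pos, "".join(seq)[pos - 1],
                                "A" if seq[pos - 1] != "A" else "G",
                                ref).category

    assert cat(1010) == "five_utr"
    assert cat(1300) == "three_utr"
    assert cat(1150) == "intron"
    ann = classify_variant([gene], "t", 978, seq[977],
                           "A" if seq[977] != "A" else "G", ref)
    assert ann.category == "upstream" and ann.distance == 23
    assert cat(1360) == "downstream"
    assert cat(7351) == "intergenic"  # 6001 bp away, beyond the 5 kb flank


def test_reference_mismatch_raises():
    seq = _reference()
    gene = _plus_gene(seq)
    ref = {"t": "".join(seq)}
    wrong = "A" if seq[1052] != "A" else "C"
    with pytest.raises(AnnotationError):
        classify_variant([gene], "t", 1053, wrong, "G", ref)


def _mirror(seq, gene, pos, ref_b, alt_b):
    """Reverse-complement the chromosome and mirror gene/variant."""
    L = len(seq)
    rc = revcomp("".join(seq))

    def m(x):
        return L - x + 1

    def mseg(s):
        return Segment(m(s.end), m(s.start), s.phase)

    tr = gene.transcripts[0]
    mtr = Transcript(id="t1m",
                     exons=[mseg(s) for s in reversed(tr.exons)],
                     cds=[mseg(s) for s in reversed(tr.cds)],
                     utr5=[mseg(s) for s in reversed(tr.utr5)],
                     utr3=[mseg(s) for s in reversed(tr.utr3)])
    mg = GeneModel(id="g1m", chrom="t", strand="-", start=m(gene.end),
                   end=m(gene.start), transcripts=[mtr])
    return {"t": rc}, mg, m(pos), revcomp(ref_b), revcomp(alt_b)


def test_strand_consistency():
    """Mirroring the gene to the minus strand preserves every call."""
    seq = _reference()
    gene = _plus_gene(seq)
    ref = {"t": "".join(seq)}
    for pos, alt in [(1053, "C"), (1051, "A"), (1056, "A"), (1010, "C"),
                     (1150, "C"), (978, "C")]:
        base = seq[pos - 1]
        if base == alt:
            continue
        fwd = classify_variant([gene], "t", pos, base, alt, ref)
        mref, mg, mpos, mb, malt = _mirror(seq, gene, pos, base, alt)
        rev = classify_variant([mg], "t", mpos, mb, malt, mref)
        assert rev.category == fwd.category


def test_effect_calls_match_bruteforce_oracle():
    """All 9 substitutions of 30 random codons agree with the hand-entered
    codon table."""
    rng = np.random.default_rng(42)
    n_codons = 30
    cds_len = 3 * n_codons
    seq = _reference(5_000, seed=1)
    tr = Transcript(id="t1", exons=[Segment(101, 100 + cds_len)],
                    cds=[Segment(101, 100 + cds_len)])
    gene = GeneModel(id="g", chrom="t", strand="+", start=101,
                     end=100 + cds_len, transcripts=[tr])
    ref = {"t": "".join(seq)}
    for ci in range(n_codons):
        codon = "".join(seq[100 + 3 * ci:103 + 3 * ci])
        for k in range(3):
            for alt in "ACGT":
                if alt == codon[k]:
                    continue
                mutant = codon[:k] + alt + codon[k + 1:]
                aa0, aa1 = CODON_TABLE[codon], CODON_TABLE[mutant]
                want = ("exon_synonymous" if aa0 == aa1
                        else "exon_nonsense" if aa1 == "*"
                        else "exon_missense")
                pos = 101 + 3 * ci + k
                got = classify_variant([gene], "t", pos, codon[k], alt, ref)
                assert got.category == want, (codon, k, alt)


def test_genes_in_region_boundaries():
    tr = Transcript(id="t", exons=[Segment(100, 200)], cds=[Segment(100, 199)])
    g = GeneModel(id="g", chrom="c", strand="+", start=100, end=200,
                  transcripts=[tr])
    inside = genes_in_region([g], GenomicRegion("c", 50, 300))
    assert list(inside["gene_id"]) == ["g"]
    assert inside["overlap_bp"].item() == 101
    # region abutting gene end + 1: closed intervals do not touch
    assert len(genes_in_region([g], GenomicRegion("c", 201, 300))) == 0


def test_gff_roundtrip_and_census(noiseless_cohort):
    c = noiseless_cohort
    models = load_gene_models(c.gff_text, from_string=True)
    census = genes_in_region(models, c.truth.expected_sdr)
    assert sorted(census["gene_id"]) == sorted(c.truth.sdr_gene_ids)
    assert len(census) == 7


def test_exon_identity():
    df, mean = exon_identity_table(["ACGT"], ["ACGT"])
    assert df["identity_pct"].item() == 100.0
    df2, _ = exon_identity_table(["ACGT"], ["ACGA"])
    assert df2["identity_pct"].item() == pytest.approx(75.0)
    _, mean3 = exon_identity_table(["AAAAAA"], ["CCCCCC"])
    assert mean3 <= 5.0
    # pairing by order from the 3' end
    df4, mean4 = exon_identity_table(["GGGG", "ACGT"], ["ACGT"])
    assert df4["query_exon"].item() == 1 and mean4 == 100.0
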