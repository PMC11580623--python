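"""Paralog scanning, in-silico PCR and band prediction."""

import numpy as np
import pytest

from sdrscan._align import affine_fit_align, affine_local_align
from sdrscan.intervals import GenomicRegion
from sdrscan.markers import (AmpliconPrediction, NonSpecificPrimersError,
                             PrimerPair, band_pattern, in_silico_pcr,
                             paralog_scan, revcomp, select_marker_locus)
from sdrscan.simulate import _random_seq


def _rng(seed=0):
    return np.random.default_rng(seed)


def test_alignment_score_matches_dp_oracle():
    """Scores agree with Biopython's full dynamic-programming aligner on
    sequences <= 1 kb (same affine scoring)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    # Biopython charges open on the first gap base; ours charges open+extend
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    rng = _rng(1)
    for trial in range(6):
        a = _random_seq(rng, int(rng.integers(80, 400)))
        core = _random_seq(rng, 200)
        # subject: mutated copy of a chunk of `a` embedded in noise
        chunk = list(a[20:220] if len(a) >= 220 else a)
        for _ in range(8):
            chunk[int(rng.integers(len(chunk)))] = "ACGT"[rng.integers(4)]
        b = core[:50] + "".join(chunk) + core[50:100]
        got = affine_local_align(a, b)
        want = aligner.score(a, b)
        assert got.score == pytest.approx(want)


def test_fit_alignment_score_matches_dp_oracle():
    """Fit-alignment scores (query end-to-end, subject ends free) agree
    with Biopython's dynamic programming under the same affine costs."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    aligner.end_deletion_score = 0  # free end gaps on the subject side
    rng = _rng(4)
    for _ in range(5):
        q = _random_seq(rng, int(rng.integers(60, 250)))
        mut = list(q)
        for _ in range(6):
            mut[int(rng.integers(len(mut)))] = "ACGT"[rng.integers(4)]
        s = _random_seq(rng, 80) + "".join(mut) + _random_seq(rng, 80)
        got = affine_fit_align(q, s)
        want = aligner.score(s, q)
        assert got.score == pytest.approx(want)


def test_alignment_gap_accounting():
    q = _random_seq(_rng(11), 60)  # non-repetitive so the gap is forced
    s = q[:30] + "T" * 5 + q[30:]
    for fn in (affine_local_align, affine_fit_align):
        aln = fn(q, s)
        assert aln.n_gaps == 1
        assert aln.gap_bp_query == 5 and aln.gap_bp_subject == 0
        assert aln.matches == len(q)


def _genome_with_duplicate(seed=2, gaps=(), mutations=0):
    rng = _rng(seed)
    chrom = _random_seq(rng, 30_000)
    src = chrom[5_000:5_590]  # 590 bp query at 1-based [5001, 5590]
    copy = list(src)
    for _ in range(mutations):
        copy[int(rng.integers(60, len(copy) - 60))] = "ACGT"[rng.integers(4)]
    copy = "".join(copy)
    if gaps:
        offs = sorted(rng.choice(np.arange(60, len(copy) - 60), len(gaps),
                                 replace=False))
        parts, prev = [], 0
        for off, g in zip(offs, gaps):
            parts += [copy[prev:off], _random_seq(rng, g)]
            prev = off
        parts.append(copy[prev:])
        copy = "".join(parts)
    genome = {"chr2": chrom[:20_000] + copy + chrom[20_000 + len(copy):]}
    dest = (20_001, 20_000 + len(copy))
    return genome, src, (5_001, 5_590), dest


def test_paralog_scan_exact_duplicate():
    genome, src, qloc, dest = _genome_with_duplicate()
    hits = paralog_scan(src, genome, query_locus=("chr2", *qloc))
    assert len(hits) == 1
    h = hits[0]
    assert (h.subject_start, h.subject_end) == dest
    assert h.identity_pct == 100.0 and h.total_gap_bp == 0


def test_paralog_scan_three_gaps_sum_97():
    genome, src, qloc, dest = _genome_with_duplicate(gaps=(40, 30, 27),
                                                     mutations=5)
    hits = paralog_scan(src, genome, query_locus=("chr2", *qloc))
    assert len(hits) == 1
    h = hits[0]
    assert h.n_gaps == 3 and h.total_gap_bp == 97
    assert (h.subject_end - h.subject_start + 1) == 687


def test_paralog_scan_symmetric():
    genome, src, qloc, dest = _genome_with_duplicate(gaps=(40, 30, 27),
                                                     mutations=5)
    fwd = paralog_scan(src, genome, query_locus=("chr2", *qloc))[0]
    subject_seq = genome["chr2"][dest[0] - 1:dest[1]]
    back = paralog_scan(subject_seq, genome, query_locus=("chr2", *dest))
    assert len(back) == 1
    b = back[0]
    assert (b.subject_start, b.subject_end) == qloc
    assert abs(b.identity_pct - fwd.identity_pct) <= 0.5


def test_paralog_scan_no_hit_on_unrelated_sequence():
    genome, *_ = _genome_with_duplicate()
    other = _random_seq(_rng(99), 400)
    assert paralog_scan(other, genome) == []


def test_paralog_scan_rejects_bad_query():
    genome, *_ = _genome_with_duplicate()
    with pytest.raises(ValueError):
        paralog_scan("ACGTN" * 50, genome)
    with pytest.raises(ValueError):
        paralog_scan("ACGT", genome, min_len=200)


def test_select_marker_locus_rules():
    genome, src, qloc, dest = _genome_with_duplicate(gaps=(40, 30, 27))
    hits = paralog_scan(src, genome, query_locus=("chr2", *qloc))
    hap = [GenomicRegion("chr2", 4_500, 6_000,
                         kind="sex_specific_haploid", sex="F")]
    cands, _ = select_marker_locus(hits, hap, query_chrom="chr2")
    assert len(cands) == 1
    assert cands[0].haploid_copy == "query"
    assert cands[0].total_gap_bp == 97
    assert all(run[2] >= 20 for run in cands[0].conserved_flanks)
    # identical copies: zero length difference -> rejected
    genome0, src0, qloc0, _ = _genome_with_duplicate()
    hits0 = paralog_scan(src0, genome0, query_locus=("chr2", *qloc0))
    cands0, why = select_marker_locus(hits0, hap, query_chrom="chr2")
    assert cands0 == [] and "length difference" in why
    # both copies outside any haploid region -> rejected
    cands1, why1 = select_marker_locus(
        hits, [GenomicRegion("chr1", 1, 10, sex="F")], query_chrom="chr2")
    assert cands1 == [] and "neither" in why1


def _pcr_template():
    rng = _rng(7)
    fwd = "TGCTCTTGCCAAAACACTGC"
    rev = "GGGATTTGGTGTCTGGCAGA"
    middle = _random_seq(rng, 641 - 40)
    seq = _random_seq(rng, 100) + fwd + middle + revcomp(rev) + \
        _random_seq(rng, 100)
    return {"tpl": seq}, PrimerPair("p", fwd, rev)


def test_in_silico_pcr_product_length():
    genome, primers = _pcr_template()
    amps = in_silico_pcr(genome, primers)
    assert len(amps) == 1
    a = amps[0]
    assert (a.start, a.end, a.length) == (101, 741, 641)


def test_in_silico_pcr_shortened_template_gives_544():
    genome, primers = _pcr_template()
    seq = genome["tpl"]
    genome2 = {"tpl": seq[:300] + seq[397:]}  # remove 97 bp inside
    amps = in_silico_pcr(genome2, primers)
    assert [a.length for a in amps] == [544]


def test_in_silico_pcr_requires_opposing_orientation():
    rng = _rng(9)
    fwd = "TGCTCTTGCCAAAACACTGC"
    rev = "GGGATTTGGTGTCTGGCAGA"
    # both primers in the same orientation: no product
    seq = _random_seq(rng, 100) + fwd + _random_seq(rng, 300) + rev + \
        _random_seq(rng, 100)
    assert in_silico_pcr({"t": seq}, PrimerPair("p", fwd, rev)) == []


def test_in_silico_pcr_nonspecific_aborts():
    fwd = "TGCTCTTGCCAAAACACTGC"
    rev = "GGGATTTGGTGTCTGGCAGA"
    unit = fwd + "AC" * 30 + revcomp(rev) + "GT" * 10
    with pytest.raises(NonSpecificPrimersError):
        in_silico_pcr({"t": unit * 150}, PrimerPair("p", fwd, rev),
                      max_product=3000)


def test_band_pattern_female_two_bands_male_one():
    hap = GenomicRegion("chr2", 24_500, 45_825,
                        kind="sex_specific_haploid", sex="F")
    preds = [
        AmpliconPrediction("chr2", 70_000, 70_640, 641, "forward"),
        AmpliconPrediction("chr2", 25_000, 25_543, 544, "forward"),
    ]
    pat = band_pattern(preds, [hap])
    assert [(b["length"], b["copies"]) for b in pat["bands"]["F"]] == \
        [(641, 2), (544, 1)]
    assert [(b["length"], b["copies"]) for b in pat["bands"]["M"]] == \
        [(641, 2)]
    assert pat["informative"]
    assert any("reduced dosage" in n for n in pat["dosage_notes"])


def test_band_pattern_uninformative_and_xy_mirror():
    preds = [AmpliconPrediction("chr1", 100, 740, 641, "forward")]
    pat = band_pattern(preds, [])
    assert not pat["informative"]
    hap_m = GenomicRegion("chr1", 50, 900,
                          kind="sex_specific_haploid", sex="M")
    pat2 = band_pattern(preds, [hap_m])
    assert pat2["bands"]["M"] and not pat2["bands"]["F"]


def test_truthset_primers_reproduce_expected_bands(noiseless_cohort):
    """PCR on the synthetic reference with the truth primers reproduces
    the planted band lengths, and the band difference equals the paralog
    gap total."""
    c = noiseless_cohort
    amps = in_silico_pcr(c.reference, c.primers)
    pat = band_pattern(amps, [c.truth.hemizygous_region])
    got = {s: {b["length"]: b["copies"] for b in pat["bands"][s]}
           for s in "FM"}
    want = {s: {int(k): v for k, v in d.items()}
            for s, d in c.truth.expected_bands.items()}
    assert got == want
    lengths = sorted(got["F"])
    assert lengths[1] - lengths[0] == c.truth.total_gap_bp
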