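"""Paralog-length-polymorphism sex markers and in-silico PCR.

A sequence present single-copy in the heterogametic sex only (inside a
hemizygous region) and paralogous to a diploid locus elsewhere, with an
internal length difference, yields a one-tube diagnostic: shared primers
in the conserved flanks amplify one band in the homogametic sex and two
bands — the extra one at half dosage — in the heterogametic sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import LocalAlignment, affine_fit_align
from .intervals import GenomicRegion

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class NonSpecificPrimersError(RuntimeError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, each written 5'->3' on its own strand."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self):
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if set(seq.upper()) - set("ACGT"):
                raise ValueError(f"{label} primer has non-ACGT symbols")
            if len(seq) < 15:
                raise ValueError(f"{label} primer shorter than 15 nt")


@dataclass
class ParalogHit:
    chrom: str
    strand: str
    query_start: int  # 1-based inclusive, genome coords when query_locus given
    query_end: int
    subject_start: int  # 1-based inclusive genome coords
    subject_end: int
    identity_pct: float
    n_gaps: int
    total_gap_bp: int
    score: float
    alignment: LocalAlignment = field(repr=False, default=None)


def _seed_clusters(query: str, subject: str, k: int, band: int):
    """Diagonal-banded clusters of exact k-mer seed matches."""
    qk: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qk.setdefault(query[i:i + k], []).append(i)
    diags = []
    for j in range(len(subject) - k + 1):
        hit = qk.get(subject[j:j + k])
        if hit:
            for qi in hit:
                diags.append(j - qi)
    if not diags:
        return []
    diags.sort()
    clusters = [[diags[0], diags[0]]]
    for d in diags[1:]:
        if d - clusters[-1][1] <= band:
            clusters[-1][1] = d
        else:
            clusters.append([d, d])
    return clusters


def paralog_scan(query: str, genome: dict, query_locus=None,
                 min_identity: float = 80.0, min_len: int = 200,
                 k: int = 15, band: int = 150, pad: int = 100,
                 match: float = 1, mismatch: float = -2,
                 gap_open: float = -5, gap_extend: float = -2
                 ) -> list[ParalogHit]:
    """Find paralogous copies of ``query`` across the genome.

    Exact k-mer seeds are chained per diagonal band, then each band is
    refined by an affine-gap fit alignment of the full query against the
    banded subject window (end-to-end in the query, so paralog copies are
    compared across their internal indels; the window's flanks are free). ``query_locus`` = (chrom, start, end) 1-based marks
    the query's own location, whose hit is excluded. Hits with identity
    below ``min_identity`` or aligned span below ``min_len`` are dropped.
    """
    query = query.upper()
    if set(query) - set("ACGT"):
        raise ValueError("query has non-ACGT symbols")
    if len(query) < min_len:
        raise ValueError(f"query shorter than min_len={min_len}")
    hits: dict[tuple, ParalogHit] = {}
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        for strand, q in (("+", query), ("-", revcomp(query))):
            for d_lo, d_hi in _seed_clusters(q, seq, k, band):
                w_lo = max(0, d_lo - pad)
                w_hi = min(len(seq), d_hi + len(q) + pad)
                aln = affine_fit_align(q, seq[w_lo:w_hi], match, mismatch,
                                       gap_open, gap_extend)
                q_span = aln.q_end - aln.q_start
                s_span = aln.s_end - aln.s_start
                if max(q_span, s_span) < min_len:
                    continue
                if aln.identity_pct < min_identity:
                    continue
                # re-express subject coordinates genome-wide (0-based in the
                # alignment record, 1-based in the hit)
                aln.s_start += w_lo
                aln.s_end += w_lo
                s_start = aln.s_start + 1
                s_end = aln.s_end
                if query_locus is not None and strand == "+":
                    qc, qs, qe = query_locus
                    if chrom == qc and s_start <= qe and s_end >= qs:
                        continue  # self-hit
                if query_locus is not None:
                    qc, qs, _ = query_locus
                    q_start = qs + aln.q_start
                    q_end = qs + aln.q_end - 1
                    q_chrom = qc
                else:
                    q_start, q_end = aln.q_start + 1, aln.q_end
                    q_chrom = "query"
                hit = ParalogHit(
                    chrom=chrom, strand=strand,
                    query_start=q_start, query_end=q_end,
                    subject_start=s_start, subject_end=s_end,
                    identity_pct=aln.identity_pct,
                    n_gaps=aln.n_gaps,
                    total_gap_bp=abs(aln.gap_bp_query - aln.gap_bp_subject),
                    score=aln.score, alignment=aln)
                key = (chrom, strand, s_start, s_end)
                if key not in hits or hit.score > hits[key].score:
                    hits[key] = hit
    return sorted(hits.values(), key=lambda h: -h.score)


@dataclass
class MarkerCandidate:
    hit: ParalogHit
    haploid_copy: str  # "query" or "subject"
    total_gap_bp: int
    conserved_flanks: list  # (q_start_1based, s_start_1based, length)


def select_marker_locus(hits: list[ParalogHit],
                        haploid_regions: list[GenomicRegion],
                        min_diff_bp: int = 20,
                        min_flank: int = 20,
                        query_chrom: str | None = None
                        ) -> tuple[list[MarkerCandidate], str]:
    """Keep hits whose copies straddle a sex-limited haploid region.

    A qualifying hit has exactly one copy inside a haploid region and a
    length difference >= ``min_diff_bp`` (gel-resolvable). Candidates are
    ranked by length difference then identity; each reports conserved
    windows (exact-match runs >= ``min_flank`` bp) usable for shared
    primers. Returns (candidates, explanation) — explanation is non-empty
    when nothing qualifies.
    """
    def inside(chrom, s, e):
        return any(r.chrom == chrom and r.start <= s and e <= r.end
                   for r in haploid_regions)

    out = []
    reasons = []
    for h in hits:
        qc = query_chrom or h.chrom
        q_in = inside(qc, h.query_start, h.query_end)
        s_in = inside(h.chrom, h.subject_start, h.subject_end)
        if q_in == s_in:
            reasons.append(
                f"{h.chrom}:{h.subject_start}-{h.subject_end}: "
                + ("both" if q_in else "neither")
                + " copy in a haploid region")
            continue
        if h.total_gap_bp < min_diff_bp:
            reasons.append(
                f"{h.chrom}:{h.subject_start}-{h.subject_end}: length "
                f"difference {h.total_gap_bp} bp < {min_diff_bp} bp")
            continue
        flanks = [run for run in h.alignment.match_runs()
                  if run[2] >= min_flank]
        out.append(MarkerCandidate(
            hit=h, haploid_copy="query" if q_in else "subject",
            total_gap_bp=h.total_gap_bp, conserved_flanks=flanks))
    out.sort(key=lambda c: (-c.total_gap_bp, -c.hit.identity_pct))
    explanation = "" if out else ("no qualifying paralog pair: "
                                  + "; ".join(reasons) if reasons
                                  else "no hits supplied")
    return out, explanation


@dataclass
class AmpliconPrediction:
    chrom: str
    start: int  # 1-based inclusive outer 5' end of the upstream primer
    end: int  # outer 5' end of the downstream primer
    length: int
    upstream_primer: str  # which primer sits upstream on the plus strand


def _find_sites(seq: str, primer: str, max_mismatch: int,
                protect: str) -> list[int]:
    """0-based start positions where ``primer`` matches the plus strand.

    ``protect`` in {'start','end'} marks which end of the match window
    corresponds to the primer's 3' terminus and must match exactly when
    mismatches are tolerated.
    """
    primer = primer.upper()
    if max_mismatch == 0:
        out, at = [], seq.find(primer)
        while at != -1:
            out.append(at)
            at = seq.find(primer, at + 1)
        return out
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    L = len(primer)
    if len(arr) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(arr, L)
    mism = (windows != p).sum(axis=1)
    ok = mism <= max_mismatch
    tri = 0 if protect == "start" else L - 1
    ok &= windows[:, tri] == p[tri]
    return np.flatnonzero(ok).tolist()


def in_silico_pcr(genome: dict, primers: PrimerPair,
                  max_mismatch: int = 0, max_product: int = 3000,
                  max_products: int = 100) -> list[AmpliconPrediction]:
    """Predict PCR products of a primer pair against the genome.

    A product forms when one primer matches the plus strand and the
    reverse-complement of the other matches downstream (both primer
    assignments are tried). Product length is the inclusive span between
    the two primers' outer 5' ends. Products longer than ``max_product``
    are dropped; more than ``max_products`` products raises
    :class:`NonSpecificPrimersError`.
    """
    fwd, rev = primers.forward.upper(), primers.reverse.upper()
    found: dict[tuple, AmpliconPrediction] = {}
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        for up, down, label in ((fwd, rev, "forward"), (rev, fwd, "reverse")):
            up_sites = _find_sites(seq, up, max_mismatch, protect="end")
            down_sites = _find_sites(seq, revcomp(down), max_mismatch,
                                     protect="start")
            for i in up_sites:
                for j in down_sites:
                    end = j + len(down)  # 1-based outer 5' of downstream
                    length = end - i
                    if j < i or length < max(len(up), len(down)):
                        continue
                    if length > max_product:
                        continue
                    key = (chrom, i + 1, end)
                    found.setdefault(key, AmpliconPrediction(
                        chrom=chrom, start=i + 1, end=end,
                        length=length, upstream_primer=label))
    if len(found) > max_products:
        raise NonSpecificPrimersError(
            f"non-specific primers: {len(found)} products")
    return sorted(found.values(), key=lambda a: (a.chrom, a.start))


def band_pattern(predictions: list[AmpliconPrediction],
                 haploid_regions: list[GenomicRegion]) -> dict:
    """Expected gel bands per genetic sex.

    An amplicon fully inside a sex-limited haploid region has copy number
    1 in that region's sex and 0 in the other; all other template loci
    are diploid in both sexes. Returns per-sex band lists (length, copies),
    an ``informative`` flag (band patterns differ between sexes) and a
    dosage note for bands expected at half yield.
    """
    bands = {"F": [], "M": []}
    for amp in predictions:
        region = next(
            (r for r in haploid_regions
             if r.chrom == amp.chrom and r.start <= amp.start
             and amp.end <= r.end and r.sex is not None),
            None)
        if region is None:
            copies = {"F": 2, "M": 2}
        else:
            copies = {"F": 0, "M": 0}
            copies[region.sex] = 1
        for sex in "FM":
            if copies[sex] > 0:
                bands[sex].append({"length": amp.length,
                                   "copies": copies[sex],
                                   "chrom": amp.chrom,
                                   "start": amp.start, "end": amp.end})
    for sex in "FM":
        bands[sex].sort(key=lambda b: -b["length"])
    sig = {s: sorted((b["length"], b["copies"]) for b in bands[s])
           for s in "FM"}
    informative = sig["F"] != sig["M"]
    notes = []
    for sex in "FM":
        lengths = {b["length"]: b["copies"] for b in bands[sex]}
        if len(set(lengths.values())) > 1:
            low = [ln for ln, c in lengths.items() if c == min(lengths.values())]
            notes.append(f"{sex}: band(s) {low} expected at reduced dosage")
    return {"bands": bands, "informative": informative,
            "dosage_notes": notes}
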