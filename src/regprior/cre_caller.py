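"""Cis-regulatory element calling around a target TSS.

Candidate CREs are formed by unioning peak calls per histone mark /
accessibility assay across cell types, restricting to a window around the
TSS (default +/- 20 kb), merging nearby peaks, classifying each merged
element from the marks that support it, and numbering elements 5'->3'
along the gene strand so the promoter-proximal cluster receives the
lowest numbers.

Classification precedence: an element overlapping any H3K4me3 peak is a
promoter; otherwise H3K4me1 evidence makes it an enhancer; otherwise it is
accessible_only.  H3K27ac (active-element mark) contributes to element
boundaries but not to the promoter/enhancer distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .formats_io import GenomicInterval, LookupMissError, SignalTrack

DEFAULT_WINDOW_BP = 20_000
DEFAULT_MERGE_GAP_BP = 200
DEFAULT_MIN_CELLTYPES = 1

MARK_H3K4ME1 = "H3K4me1"
MARK_H3K4ME3 = "H3K4me3"
MARK_H3K27AC = "H3K27ac"
MARK_DNASE = "DNase"

CLASS_PROMOTER = "promoter"
CLASS_ENHANCER = "enhancer"
CLASS_ACCESSIBLE = "accessible_only"


@dataclass
class CRE:
    """A numbered, classified cis-regulatory element."""

    interval: GenomicInterval
    number: int
    cre_class: str
    signal_summary: dict[str, float] = field(default_factory=dict)
    n_celltypes_supporting: int = 1

    @property
    def label(self) -> str:
        return f"CRE{self.number}"

    def as_bed_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.interval.chrom, self.interval.start, self.interval.end,
            self.interval.strand, name=f"CRE{self.number}:{self.cre_class}",
        )


class NoPromoterError(ValueError):
    """No promoter-class CRE was available for core-promoter selection."""


# ---------------------------------------------------------------------------
# Signal aggregation
# ---------------------------------------------------------------------------

def aggregate_signal(track: SignalTrack, interval: GenomicInterval) -> float:
    """Length-weighted mean of track values over the interval.

    Positions without track coverage contribute 0, so the divisor is the
    full interval length.  Raises LookupMissError for an unknown chromosome.
    """
    if interval.chrom not in track.chroms:
        raise LookupMissError(
            f"chromosome {interval.chrom!r} absent from track {track.mark!r}"
        )
    total = track.weighted_sum(interval.chrom, interval.start, interval.end)
    return total / len(interval)


# ---------------------------------------------------------------------------
# Interval machinery
# ---------------------------------------------------------------------------

def _support_union(
    peaks_by_celltype: Mapping[str, Sequence[GenomicInterval]],
    chrom: str,
    min_celltypes: int,
) -> list[tuple[int, int]]:
    """Regions of ``chrom`` covered by peaks in >= min_celltypes cell types."""
    events: list[tuple[int, int]] = []
    for ct_peaks in peaks_by_celltype.values():
        merged = _merge_plain(
            [(p.start, p.end) for p in ct_peaks if p.chrom == chrom], gap=0
        )
        for s, e in merged:
            events.append((s, +1))
            events.append((e, -1))
    if not events:
        return []
    events.sort()
    out: list[tuple[int, int]] = []
    depth = 0
    open_start: int | None = None
    for pos, delta in events:
        prev = depth
        depth += delta
        if prev < min_celltypes <= depth:
            open_start = pos
        elif prev >= min_celltypes > depth and open_start is not None:
            if pos > open_start:
                out.append((open_start, pos))
            open_start = None
    return _merge_plain(out, gap=0)


def _merge_plain(
    intervals: Sequence[tuple[int, int]], gap: int
) -> list[tuple[int, int]]:
    """Merge sorted-or-not (start, end) pairs whose separation is < gap."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for s, e in ordered[1:]:
        if s - merged[-1][1] < gap or s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _clip(
    intervals: Sequence[tuple[int, int]], lo: int, hi: int
) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def _any_overlap(iv: tuple[int, int], others: Sequence[tuple[int, int]]) -> bool:
    s, e = iv
    return any(s < oe and os_ < e for os_, oe in others)


# ---------------------------------------------------------------------------
# CRE calling
# ---------------------------------------------------------------------------

def call_cres(
    peaks: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
    tss: GenomicInterval,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_celltypes: int = DEFAULT_MIN_CELLTYPES,
    merge_gap_bp: int = DEFAULT_MERGE_GAP_BP,
    tracks: Mapping[str, SignalTrack] | None = None,
) -> list[CRE]:
    """Call, classify, and number CREs within ``window_bp`` of the TSS.

    Parameters
    ----------
    peaks
        mark -> cell type -> peak intervals (e.g. from BED files).
    tss
        1-bp interval at the TSS; its strand is the gene strand and drives
        the numbering direction.
    min_celltypes
        A base contributes only where >= this many cell types have a peak
        for the mark (default 1 = plain union).
    tracks
        Optional mark -> SignalTrack; if given, each CRE's signal_summary
        holds the length-weighted mean per mark.

    Returns elements numbered consecutively from 1 in 5'->3' order along
    the gene strand (descending genomic coordinate for a minus-strand
    gene), so the promoter-proximal cluster is lowest-numbered.
    """
    if not peaks:
        raise ValueError("at least one mark must be supplied")
    chrom = tss.chrom
    tss_point = tss.start
    lo = max(0, tss_point - window_bp)
    hi = tss_point + window_bp

    mark_support: dict[str, list[tuple[int, int]]] = {}
    mark_ncelltypes: dict[str, Mapping[str, Sequence[GenomicInterval]]] = {}
    for mark, by_ct in peaks.items():
        support = _support_union(by_ct, chrom, min_celltypes)
        mark_support[mark] = _clip(support, lo, hi)
        mark_ncelltypes[mark] = by_ct

    all_support = [iv for ivs in mark_support.values() for iv in ivs]
    elements = _merge_plain(all_support, gap=merge_gap_bp)
    if not elements:
        return []

    descending = tss.strand == "-"
    ordered = sorted(elements, reverse=descending)

    cres: list[CRE] = []
    for number, (start, end) in enumerate(ordered, start=1):
        iv = (start, end)
        if _any_overlap(iv, mark_support.get(MARK_H3K4ME3, [])):
            cls = CLASS_PROMOTER
        elif _any_overlap(iv, mark_support.get(MARK_H3K4ME1, [])):
            cls = CLASS_ENHANCER
        else:
            cls = CLASS_ACCESSIBLE
        n_ct = 0
        for by_ct in mark_ncelltypes.values():
            n = sum(
                1
                for ct_peaks in by_ct.values()
                if any(
                    p.chrom == chrom and p.start < end and start < p.end
                    for p in ct_peaks
                )
            )
            n_ct = max(n_ct, n)
        summary: dict[str, float] = {}
        region = GenomicInterval(chrom, start, end, tss.strand)
        if tracks:
            for mark, track in tracks.items():
                try:
                    summary[mark] = aggregate_signal(track, region)
                except LookupMissError:
                    summary[mark] = 0.0
        cres.append(
            CRE(interval=region, number=number, cre_class=cls,
                signal_summary=summary, n_celltypes_supporting=max(n_ct, 1))
        )
    return cres


def select_core_promoter(
    cres: Sequence[CRE],
    dnase_track: SignalTrack,
    tss: GenomicInterval,
) -> CRE:
    """Pick the core-promoter CRE: promoter-class, at/upstream of the TSS,
    with maximal DNase aggregate signal (tie -> smallest genomic start).

    Raises NoPromoterError if no promoter-class CRE exists.
    """
    promoters = [c for c in cres if c.cre_class == CLASS_PROMOTER]
    if not promoters:
        raise NoPromoterError(
            "no promoter-class CRE among candidates; cannot select core promoter"
        )
    tss_point = tss.start

    def _upstream_or_overlapping(c: CRE) -> bool:
        iv = c.interval
        if iv.start <= tss_point < iv.end:
            return True
        if tss.strand == "-":
            return iv.start > tss_point
        return iv.end <= tss_point

    eligible = [c for c in promoters if _upstream_or_overlapping(c)] or promoters
    scored = []
    for c in eligible:
        try:
            sig = aggregate_signal(dnase_track, c.interval)
        except LookupMissError:
            sig = 0.0
        scored.append((-sig, c.interval.start, c))
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2]


def renumber(cres: Sequence[CRE], gene_strand: str = "+") -> list[CRE]:
    """Re-assign consecutive numbers from 1 after any filtering."""
    descending = gene_strand == "-"
    ordered = sorted(cres, key=lambda c: c.interval.start, reverse=descending)
    return [
        CRE(c.interval, i, c.cre_class, dict(c.signal_summary),
            c.n_celltypes_supporting)
        for i, c in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# TSS metaprofiles
# ---------------------------------------------------------------------------

def tss_profile_matrix(
    coverage: SignalTrack,
    tss_list: Sequence[GenomicInterval],
    flank_bp: int = 2_000,
    n_bins: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Binned mean coverage around each TSS, plus the column-mean profile.

    Each row covers [TSS - flank, TSS + flank) in ``n_bins`` equal bins
    (deterministic truncation if the span does not divide evenly).  Rows
    for minus-strand TSSs are flipped so bin 0 is always 5' of the gene.
    """
    if not tss_list:
        raise ValueError("empty TSS list")
    bin_width = (2 * flank_bp) // n_bins
    if bin_width < 1:
        raise ValueError("flank too small for the requested number of bins")
    matrix = np.zeros((len(tss_list), n_bins))
    for r, tss in enumerate(tss_list):
        left = tss.start - flank_bp
        for b in range(n_bins):
            s, e = left + b * bin_width, left + (b + 1) * bin_width
            if e <= 0 or tss.chrom not in coverage.chroms:
                val = 0.0
            else:
                s = max(s, 0)
                val = coverage.weighted_sum(tss.chrom, s, e) / bin_width
            matrix[r, b] = val
        if tss.strand == "-":
            matrix[r] = matrix[r, ::-1]
    return matrix, matrix.mean(axis=0)
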