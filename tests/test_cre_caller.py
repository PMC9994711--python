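"""CRE calling, classification, numbering, core-promoter pick, metaprofiles."""

import numpy as np
import pytest

from regprior import cre_caller as cc
from regprior.formats_io import GenomicInterval, LookupMissError, SignalTrack


def make_track(pairs, chrom="chrT", mark="DNase"):
    ivs = [GenomicInterval(chrom, s, e) for s, e, _ in pairs]
    return SignalTrack(ivs, [v for _, _, v in pairs], mark=mark)


# ---------------------------------------------------------------------------
# aggregate_signal
# ---------------------------------------------------------------------------

def test_aggregate_constant_track():
    track = make_track([(0, 100, 2.0)])
    assert cc.aggregate_signal(track, GenomicInterval("chrT", 10, 50)) == 2.0


def test_aggregate_half_covered_weighted_mean():
    # half at 4.0, half uncovered -> (50*4 + 50*0)/100 = 2.0
    track = make_track([(0, 50, 4.0)])
    assert cc.aggregate_signal(track, GenomicInterval("chrT", 0, 100)) == 2.0


def test_aggregate_no_overlap_is_zero():
    track = make_track([(0, 50, 4.0)])
    assert cc.aggregate_signal(track, GenomicInterval("chrT", 60, 80)) == 0.0


def test_aggregate_unknown_chrom_raises():
    track = make_track([(0, 50, 4.0)])
    with pytest.raises(LookupMissError):
        cc.aggregate_signal(track, GenomicInterval("chrX", 0, 10))


# ---------------------------------------------------------------------------
# call_cres
# ---------------------------------------------------------------------------

TSS = GenomicInterval("chrT", 50_000, 50_001, "+", name="TARGET")


def peaks_of(mark_intervals):
    return {
        mark: {"ct1": [GenomicInterval("chrT", s, e) for s, e in ivs]}
        for mark, ivs in mark_intervals.items()
    }


def test_no_peaks_gives_empty_list():
    assert cc.call_cres({cc.MARK_H3K4ME1: {"ct1": []}}, TSS) == []


def test_merge_two_close_enhancer_peaks():
    peaks = peaks_of({cc.MARK_H3K4ME1: [(51_000, 51_200), (51_300, 51_500)]})
    cres = cc.call_cres(peaks, TSS, merge_gap_bp=200)
    assert len(cres) == 1
    assert cres[0].cre_class == cc.CLASS_ENHANCER
    assert (cres[0].interval.start, cres[0].interval.end) == (51_000, 51_500)


def test_distant_peaks_stay_separate():
    peaks = peaks_of({cc.MARK_H3K4ME1: [(51_000, 51_200), (51_500, 51_700)]})
    assert len(cc.call_cres(peaks, TSS, merge_gap_bp=200)) == 2


def test_promoter_class_precedence_over_enhancer():
    peaks = peaks_of({
        cc.MARK_H3K4ME3: [(49_500, 49_900)],
        cc.MARK_H3K4ME1: [(49_600, 49_950)],
    })
    cres = cc.call_cres(peaks, TSS)
    assert len(cres) == 1 and cres[0].cre_class == cc.CLASS_PROMOTER


def test_dnase_only_element_is_accessible_only():
    peaks = peaks_of({cc.MARK_DNASE: [(52_000, 52_300)],
                      cc.MARK_H3K4ME1: {}.get("x", [])})
    cres = cc.call_cres(peaks, TSS)
    assert cres[0].cre_class == cc.CLASS_ACCESSIBLE


def test_window_excludes_far_peaks():
    peaks = peaks_of({cc.MARK_H3K4ME1: [(80_000, 80_500)]})
    assert cc.call_cres(peaks, TSS, window_bp=20_000) == []


def test_numbering_follows_gene_strand():
    ivs = [(49_000, 49_400), (55_000, 55_400), (60_000, 60_400)]
    plus = cc.call_cres(peaks_of({cc.MARK_H3K4ME1: ivs}), TSS)
    minus_tss = GenomicInterval("chrT", 50_000, 50_001, "-", name="TARGET")
    minus = cc.call_cres(peaks_of({cc.MARK_H3K4ME1: ivs}), minus_tss)
    assert [c.interval.start for c in plus] == [49_000, 55_000, 60_000]
    assert [c.interval.start for c in minus] == [60_000, 55_000, 49_000]
    assert [c.number for c in plus] == [1, 2, 3]
    assert [c.number for c in minus] == [1, 2, 3]


def test_min_celltypes_requires_support():
    peaks = {
        cc.MARK_H3K4ME1: {
            "ct1": [GenomicInterval("chrT", 51_000, 51_400)],
            "ct2": [GenomicInterval("chrT", 51_200, 51_600)],
            "ct3": [],
        }
    }
    union = cc.call_cres(peaks, TSS, min_celltypes=1)
    strict = cc.call_cres(peaks, TSS, min_celltypes=2)
    assert (union[0].interval.start, union[0].interval.end) == (51_000, 51_600)
    assert (strict[0].interval.start, strict[0].interval.end) == (51_200, 51_400)
    assert cc.call_cres(peaks, TSS, min_celltypes=3) == []


def test_window_monotonicity():
    """Enlarging the window never removes a called CRE."""
    ivs = [(45_000, 45_300), (55_000, 55_300), (65_000, 65_300)]
    small = cc.call_cres(peaks_of({cc.MARK_H3K4ME1: ivs}), TSS, window_bp=10_000)
    large = cc.call_cres(peaks_of({cc.MARK_H3K4ME1: ivs}), TSS, window_bp=20_000)
    small_spans = {(c.interval.start, c.interval.end) for c in small}
    large_spans = {(c.interval.start, c.interval.end) for c in large}
    assert small_spans <= large_spans


def test_called_cres_sorted_nonoverlapping_inside_window():
    ivs = [(49_000, 49_400), (51_000, 51_300), (55_000, 55_200)]
    cres = cc.call_cres(peaks_of({cc.MARK_H3K4ME1: ivs}), TSS, window_bp=20_000)
    spans = sorted((c.interval.start, c.interval.end) for c in cres)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 <= s2
    for s, e in spans:
        assert s >= 30_000 and e <= 70_000
    assert sorted(c.number for c in cres) == list(range(1, len(cres) + 1))


def test_renumber_consecutive_after_filter():
    ivs = [(49_000, 49_400), (51_000, 51_300), (55_000, 55_200)]
    cres = cc.call_cres(peaks_of({cc.MARK_H3K4ME1: ivs}), TSS)
    filtered = [c for c in cres if c.number != 2]
    renumbered = cc.renumber(filtered, "+")
    assert [c.number for c in renumbered] == [1, 2]


# ---------------------------------------------------------------------------
# select_core_promoter
# ---------------------------------------------------------------------------

def _prom(start, end, number=1):
    return cc.CRE(GenomicInterval("chrT", start, end, "+"), number,
                  cc.CLASS_PROMOTER)


def test_single_promoter_returned_regardless_of_signal():
    track = make_track([(0, 100_000, 0.0)])
    cre = _prom(49_000, 49_500)
    assert cc.select_core_promoter([cre], track, TSS) is cre


def test_max_dnase_promoter_wins():
    track = make_track([(48_000, 48_500, 1.0), (49_000, 49_500, 5.0)])
    low, high = _prom(48_000, 48_500, 1), _prom(49_000, 49_500, 2)
    assert cc.select_core_promoter([low, high], track, TSS) is high


def test_tie_break_smaller_start():
    track = make_track([(48_000, 48_500, 2.0), (49_000, 49_500, 2.0)])
    a, b = _prom(48_000, 48_500, 1), _prom(49_000, 49_500, 2)
    assert cc.select_core_promoter([a, b], track, TSS) is a


def test_no_promoter_raises_diagnostic():
    enh = cc.CRE(GenomicInterval("chrT", 51_000, 51_400), 1, cc.CLASS_ENHANCER)
    with pytest.raises(cc.NoPromoterError):
        cc.select_core_promoter([enh], make_track([(0, 100, 1.0)]), TSS)


# ---------------------------------------------------------------------------
# tss_profile_matrix
# ---------------------------------------------------------------------------

def test_profile_constant_coverage():
    track = make_track([(0, 100_000, 3.0)])
    matrix, mean = cc.tss_profile_matrix(track, [TSS], flank_bp=2_000, n_bins=100)
    assert np.allclose(matrix, 3.0) and np.allclose(mean, 3.0)


def test_profile_delta_peak_central():
    track = make_track([(49_990, 50_010, 10.0)])
    _, mean = cc.tss_profile_matrix(track, [TSS], flank_bp=2_000, n_bins=100)
    assert mean.argmax() in (49, 50)
    assert mean[0] == 0.0 and mean[-1] == 0.0


def test_profile_minus_strand_mirrored():
    track = make_track([(50_500, 50_700, 8.0)])  # downstream of + TSS
    plus, _ = cc.tss_profile_matrix(track, [TSS], 2_000, 100)
    minus_tss = GenomicInterval("chrT", 50_000, 50_001, "-")
    minus, _ = cc.tss_profile_matrix(track, [minus_tss], 2_000, 100)
    assert np.allclose(minus[0], plus[0][::-1])


def test_profile_empty_tss_list_raises():
    with pytest.raises(ValueError):
        cc.tss_profile_matrix(make_track([(0, 10, 1.0)]), [])
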