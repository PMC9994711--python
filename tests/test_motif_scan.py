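"""PWM construction, exact thresholding, strand-aware scanning, Bumscore."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from regprior.formats_io import PFM, GenomicInterval
from regprior.motif_scan import (
    ConfigurationError,
    build_pwm,
    collapse_overlapping,
    compute_bumscore,
    locus_background,
    reverse_complement,
    scan,
    score_threshold,
)


def one_hot_pfm(consensus, count=10.0, off=0.0):
    L = len(consensus)
    counts = [[off] * L for _ in range(4)]
    for j, b in enumerate(consensus):
        counts["ACGT".index(b)][j] = count
    return PFM("M1", "TFX", tuple(tuple(r) for r in counts))


def random_pfm(rng, L):
    counts = rng.dirichlet(np.ones(4), size=L).T * 20 + 0.1
    return PFM("MR", "TFR", tuple(tuple(r) for r in counts))


def enumeration_tail(pwm, lattice_score):
    """Independent oracle: background-weighted fraction of all 4^L k-mers
    whose lattice score reaches ``lattice_score``."""
    L = pwm.length
    total = 0.0
    for kmer in itertools.product(range(4), repeat=L):
        s = sum(int(pwm.lattice[b, j]) for j, b in enumerate(kmer))
        if s >= lattice_score:
            total += float(np.prod([pwm.background[b] for b in kmer]))
    return total


# ---------------------------------------------------------------------------
# build_pwm
# ---------------------------------------------------------------------------

def test_uniform_counts_uniform_background_gives_zero():
    pfm = PFM("M", "T", tuple(tuple([2.5] * 4) for _ in range(4)))
    pwm = build_pwm(pfm)
    assert np.allclose(pwm.logodds, 0.0)


def test_one_hot_entry_matches_arithmetic():
    # count 10 for A, pseudocount 0.5, uniform background:
    # entry(A) = log2((10 + 0.5*0.25) / (10 + 0.5) / 0.25)
    pfm = one_hot_pfm("AAAA", count=10.0)
    pwm = build_pwm(pfm, pseudocount=0.5)
    expected = math.log2((10 + 0.125) / 10.5 / 0.25)
    assert pwm.logodds[0, 0] == pytest.approx(expected)


def test_background_shift_closed_form():
    pfm = one_hot_pfm("ACGT", count=10.0, off=1.0)
    uni = build_pwm(pfm, background=(0.25,) * 4)
    skew = build_pwm(pfm, background=(0.3, 0.2, 0.2, 0.3))
    # with the background-weighted pseudocount, probabilities also shift,
    # so verify entries directly from the closed form
    counts = pfm.matrix
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    expected = np.log2(
        (counts + 0.5 * bg[:, None]) / (counts.sum(0) + 0.5) / bg[:, None]
    )
    assert np.allclose(skew.logodds, expected)
    assert not np.allclose(skew.logodds, uni.logodds)


def test_nonpositive_pseudocount_rejected():
    with pytest.raises(ConfigurationError):
        build_pwm(one_hot_pfm("ACGT"), pseudocount=0.0)


def test_locus_background_sums_to_one():
    bg = locus_background("ACGTACGTGGGG")
    assert bg.sum() == pytest.approx(1.0)
    assert bg[2] > bg[1]  # G-rich


# ---------------------------------------------------------------------------
# score_threshold
# ---------------------------------------------------------------------------

def test_threshold_p1_is_minimum_score():
    pwm = build_pwm(one_hot_pfm("ACGTA"))
    assert score_threshold(pwm, 1.0) == pytest.approx(pwm.min_score())


def test_threshold_monotone_in_p():
    pwm = build_pwm(one_hot_pfm("ACGTA"))
    ps = [1.0, 0.5, 0.1, 1e-2, 1e-3, 1e-4]
    ts = [score_threshold(pwm, p) for p in ps]
    assert all(a <= b for a, b in zip(ts, ts[1:]))


def test_dp_tail_equals_enumeration_length5(rng):
    pwm = build_pwm(random_pfm(rng, 5))
    support, tail = pwm._null()
    # spot-check the DP tail against brute force over all 1,024 k-mers
    for k in np.linspace(support[0], support[-1], 7).astype(int):
        assert pwm.pvalue(int(k)) == pytest.approx(
            enumeration_tail(pwm, int(k)), abs=1e-12
        )


# ---------------------------------------------------------------------------
# scan
# ---------------------------------------------------------------------------

def planted_sequence(consensus, position, length, rng, revcomp=False):
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))
    insert = reverse_complement(consensus) if revcomp else consensus
    seq[position : position + len(insert)] = insert
    return "".join(seq)


def test_scan_finds_planted_consensus(rng):
    consensus = "ACGTACGTAC"
    pwm = build_pwm(one_hot_pfm(consensus, count=50.0))
    seq = planted_sequence(consensus, 10, 60, rng)
    hits = scan(seq, pwm, p=1e-4)
    plus = [h for h in hits if h.strand == "+"]
    assert any(h.interval.start == 10 and h.interval.end == 20 for h in plus)


def test_scan_reverse_complement_hit(rng):
    consensus = "ACGTACGTAC"
    pwm = build_pwm(one_hot_pfm(consensus, count=50.0))
    seq = planted_sequence(consensus, 10, 60, rng, revcomp=True)
    hits = [h for h in scan(seq, pwm, p=1e-4) if h.strand == "-"]
    assert any(h.interval.start == 10 and h.interval.end == 20 for h in hits)


def test_all_n_sequence_has_no_hits():
    pwm = build_pwm(one_hot_pfm("ACGTAC", count=50.0))
    assert scan("N" * 50, pwm, p=1e-3) == []


def test_hit_pvalues_at_or_below_requested(rng):
    pwm = build_pwm(random_pfm(rng, 6))
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))
    for h in scan(seq, pwm, p=1e-2):
        assert h.pvalue <= 1e-2


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_scan_strand_symmetry(seed):
    """Scanning the reverse-complemented sequence mirrors the hit set."""
    rng = np.random.default_rng(seed)
    pwm = build_pwm(random_pfm(rng, int(rng.integers(5, 9))))
    n = 300
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
    fwd = scan(seq, pwm, p=1e-2)
    rev = scan(reverse_complement(seq), pwm, p=1e-2)
    flip = {"+": "-", "-": "+"}
    mirrored = {
        (n - h.interval.end, n - h.interval.start, flip[h.strand],
         round(h.score, 9))
        for h in fwd
    }
    observed = {
        (h.interval.start, h.interval.end, h.strand, round(h.score, 9))
        for h in rev
    }
    assert mirrored == observed


# ---------------------------------------------------------------------------
# collapse / bumscore
# ---------------------------------------------------------------------------

def test_collapse_keeps_best_scoring(rng):
    pwm = build_pwm(one_hot_pfm("ACACACAC", count=50.0))
    # palindrome-ish repeats produce overlapping hits; collapse must keep
    # non-overlapping ones only
    seq = "ACACACACACACACAC"
    hits = scan(seq, pwm, p=1e-3)
    kept = collapse_overlapping(hits)
    for a, b in itertools.combinations(kept, 2):
        assert not a.interval.overlaps(b.interval)
    assert kept and max(h.score for h in hits) == max(h.score for h in kept)


def test_bumscore_zero_cres():
    pwm = build_pwm(one_hot_pfm("ACGTAC"))
    assert compute_bumscore([pwm], [], {"c": "ACGT" * 100})[0].bumscore == 0


def test_bumscore_counts_planted_sites(rng):
    consensus = "ACGTACGTTG"
    pwm = build_pwm(one_hot_pfm(consensus, count=50.0))
    background = "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))
    seq = list(background)
    # 2 sites in CRE A (0-300), 2 in CRE B (500-800)
    for pos in (10, 100, 520, 700):
        seq[pos : pos + 10] = consensus
    genome = {"chrT": "".join(seq)}
    cres = [GenomicInterval("chrT", 0, 300, name="CREA"),
            GenomicInterval("chrT", 500, 800, name="CREB")]
    (rec,) = compute_bumscore([pwm], cres, genome, p=1e-5)
    assert rec.per_cre == {"CREA": 2, "CREB": 2}
    assert rec.bumscore == 4


def test_bumscore_monotone_in_p(rng):
    pwm = build_pwm(random_pfm(rng, 7))
    genome = {"chrT": "".join("ACGT"[i] for i in rng.integers(0, 4, size=3000))}
    cres = [GenomicInterval("chrT", 0, 1500, name="CRE1"),
            GenomicInterval("chrT", 1500, 3000, name="CRE2")]
    scores = [
        compute_bumscore([pwm], cres, genome, p=p)[0].bumscore
        for p in (1e-4, 1e-3, 1e-2)
    ]
    assert scores == sorted(scores)


def test_bumscore_out_of_bounds_cre():
    pwm = build_pwm(one_hot_pfm("ACGTAC"))
    with pytest.raises(IndexError):
        compute_bumscore([pwm], [GenomicInterval("chrT", 0, 500)],
                         {"chrT": "ACGT" * 10})
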