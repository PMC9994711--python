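"""PWM scanning with exact score-distribution thresholding and Bumscore.

A position frequency matrix (PFM) is turned into a log2-odds position
weight matrix (PWM) against a 0-order background.  Hit calling uses an
exact p-value: the null score distribution of a random background k-mer is
computed by dynamic programming over a discretized score lattice, and a hit
is any window (either strand) whose score reaches the smallest score whose
background tail probability is <= p.

The "Bumscore" of a transcription factor is the total number of predicted
binding sites across the identified cis-regulatory elements (CREs):
non-overlapping significant PWM hits, counted per CRE and summed.

Scanning is done on the integer score lattice itself, so the p-value
attached to each hit is *exactly* the DP tail probability of its score;
discretization error relative to continuous scores is bounded by
``L * lattice_step / 2`` bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .formats_io import PFM, GenomicInterval

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_PVALUE = 1e-4
LATTICE_STEP = 1e-3  # bits; DP discretization of the log-odds scores
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class ConfigurationError(ValueError):
    """Invalid analysis parameter."""


# ---------------------------------------------------------------------------
# PWM construction
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Log2-odds position weight matrix with its exact null distribution.

    ``logodds`` is 4 x L in bits.  ``lattice`` is the same matrix rounded to
    integer multiples of ``step``; all hit decisions are made on the
    lattice so DP p-values are exact for reported scores.
    """

    motif_id: str
    tf_name: str
    logodds: np.ndarray
    background: np.ndarray
    pseudocount: float
    step: float = LATTICE_STEP

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isfinite(self.logodds).all():
            raise ValueError("log-odds entries must be finite")
        self.lattice = np.rint(self.logodds / self.step).astype(np.int64)
        # row 4 = worst case per column, used to score N bases
        self._ext = np.vstack([self.lattice, self.lattice.min(axis=0)])
        self._null_support: np.ndarray | None = None
        self._null_tail: np.ndarray | None = None

    @property
    def length(self) -> int:
        return self.logodds.shape[1]

    # -- exact null distribution over the lattice ---------------------------

    def _null(self) -> tuple[np.ndarray, np.ndarray]:
        """(integer support offset, tail probability array) of the null score.

        ``tail[k]`` = P_background(lattice score >= min_score + k).
        """
        if self._null_tail is None:
            q = self.lattice
            mins = q.min(axis=0)
            dist = np.array([1.0])
            for j in range(q.shape[1]):
                col = q[:, j] - mins[j]
                new = np.zeros(len(dist) + int(col.max()))
                for b in range(4):
                    new[col[b] : col[b] + len(dist)] += self.background[b] * dist
                dist = new
            tail = np.cumsum(dist[::-1])[::-1]
            self._null_support = np.arange(len(dist)) + mins.sum()
            self._null_tail = tail
        return self._null_support, self._null_tail

    def pvalue(self, lattice_score: int) -> float:
        """Exact background tail probability P(score >= lattice_score)."""
        support, tail = self._null()
        if lattice_score <= support[0]:
            return 1.0
        if lattice_score > support[-1]:
            return 0.0
        return float(tail[lattice_score - support[0]])

    def min_score(self) -> float:
        support, _ = self._null()
        return support[0] * self.step

    def max_score(self) -> float:
        support, _ = self._null()
        return support[-1] * self.step


def build_pwm(
    pfm: PFM,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] = UNIFORM_BG,
) -> PWM:
    """Log2-odds PWM from counts with background-weighted pseudocount.

    entry(b, j) = log2( (count(b,j) + pseudocount * bg(b))
                        / (colsum(j) + pseudocount) / bg(b) )
    """
    if pseudocount <= 0:
        raise ConfigurationError(f"pseudocount must be > 0, got {pseudocount}")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ConfigurationError(
            "background must be 4 positive probabilities summing to 1"
        )
    counts = pfm.matrix
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    logodds = np.log2(probs / bg[:, None])
    return PWM(pfm.motif_id, pfm.tf_name, logodds, bg, pseudocount)


def locus_background(sequence: str) -> np.ndarray:
    """0-order background estimated from a sequence (N bases ignored)."""
    counts = np.array([sequence.count(b) for b in "ACGT"], dtype=float)
    if counts.sum() == 0:
        raise ConfigurationError("sequence has no A/C/G/T content")
    counts += 1.0  # avoid zero-probability bases
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# Thresholding and scanning
# ---------------------------------------------------------------------------

def score_threshold(pwm: PWM, p: float) -> float:
    """Smallest score s (bits) with P_background(score >= s) <= p.

    Computed exactly on the discretized lattice.  ``p = 1`` returns the
    minimum achievable score.
    """
    if not (0 < p <= 1):
        raise ConfigurationError(f"p must be in (0, 1], got {p}")
    return _lattice_threshold(pwm, p) * pwm.step


def _lattice_threshold(pwm: PWM, p: float) -> int:
    support, tail = pwm._null()
    idx = np.searchsorted(-tail, -p, side="left")  # first tail[idx] <= p
    if idx >= len(tail):
        return int(support[-1]) + 1  # no score attains the tail bound
    return int(support[idx])


@dataclass(frozen=True)
class MotifHit:
    """A significant PWM match on either strand, in forward coordinates."""

    tf: str
    interval: GenomicInterval
    strand: str
    score: float  # bits, on the lattice
    pvalue: float


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an A/C/G/T/N string to integer codes 0..4."""
    try:
        return np.array([_BASE_INDEX[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from exc


def _window_scores(codes: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Integer lattice score of every length-L window of ``codes``."""
    L = ext.shape[1]
    n = len(codes) - L + 1
    scores = np.zeros(n, dtype=np.int64)
    for j in range(L):
        scores += ext[codes[j : j + n], j]
    return scores


def _revcomp_ext(pwm: PWM) -> np.ndarray:
    """Lattice matrix scoring the reverse-complement strand at forward windows."""
    rc = pwm.lattice[::-1, ::-1]  # complement rows, reverse columns
    return np.vstack([rc, rc.min(axis=0)])


def scan(
    sequence: str,
    pwm: PWM,
    p: float = DEFAULT_PVALUE,
    chrom: str = "seq",
    offset: int = 0,
) -> list[MotifHit]:
    """Score every window of ``sequence`` on both strands; return hits.

    Hits are windows whose exact background p-value is <= ``p``.
    Reverse-strand hits are reported in forward coordinates.  Windows
    containing N are scored with the per-position worst case, so they never
    reach a stringent threshold.
    """
    L = pwm.length
    if len(sequence) < L:
        return []
    k_thresh = _lattice_threshold(pwm, p)
    codes = encode_sequence(sequence.upper())
    hits: list[MotifHit] = []
    for strand, ext in (("+", pwm._ext), ("-", _revcomp_ext(pwm))):
        scores = _window_scores(codes, ext)
        for i in np.nonzero(scores >= k_thresh)[0]:
            k = int(scores[i])
            hits.append(
                MotifHit(
                    tf=pwm.tf_name,
                    interval=GenomicInterval(chrom, offset + int(i), offset + int(i) + L),
                    strand=strand,
                    score=k * pwm.step,
                    pvalue=pwm.pvalue(k),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def collapse_overlapping(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Greedy non-overlapping resolution of same-TF hits.

    Keeps the best-scoring hit among mutually overlapping ones; ties broken
    by leftmost start, then + strand.  Prevents palindromic double-counting.
    """
    ordered = sorted(
        hits, key=lambda h: (-h.score, h.interval.start, h.strand != "+")
    )
    kept: list[MotifHit] = []
    for hit in ordered:
        if all(not hit.interval.overlaps(k.interval) for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: (h.interval.start, h.strand))
    return kept


# ---------------------------------------------------------------------------
# Bumscore
# ---------------------------------------------------------------------------

@dataclass
class BumscoreRecord:
    """Per-TF binding-site counts: one count per CRE plus their total."""

    tf: str
    per_cre: dict[str, int]
    bumscore: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.per_cre.values()):
            raise ValueError("negative per-CRE count")
        if self.bumscore != sum(self.per_cre.values()):
            raise ValueError("bumscore must equal the sum of per-CRE counts")


def compute_bumscore(
    pwms: Sequence[PWM],
    cres: Sequence,  # CRE objects or GenomicIntervals
    genome: Mapping[str, str],
    p: float = DEFAULT_PVALUE,
) -> list[BumscoreRecord]:
    """Count non-overlapping significant hits per TF per CRE.

    ``cres`` may be cre_caller.CRE objects or bare GenomicIntervals.  The
    Bumscore of a TF is the sum of its per-CRE counts.
    """
    intervals: list[tuple[str, GenomicInterval]] = []
    for i, cre in enumerate(cres, start=1):
        iv = getattr(cre, "interval", cre)
        label = getattr(cre, "label", None) or (iv.name or f"CRE{i}")
        if iv.chrom not in genome:
            raise KeyError(f"CRE chromosome {iv.chrom!r} absent from genome")
        if iv.end > len(genome[iv.chrom]):
            raise IndexError(
                f"CRE {label} ({iv.chrom}:{iv.start}-{iv.end}) outside sequence"
            )
        intervals.append((label, iv))

    records: list[BumscoreRecord] = []
    for pwm in pwms:
        per_cre: dict[str, int] = {}
        for label, iv in intervals:
            seq = genome[iv.chrom][iv.start : iv.end]
            hits = collapse_overlapping(
                scan(seq, pwm, p=p, chrom=iv.chrom, offset=iv.start)
            )
            per_cre[label] = len(hits)
        records.append(
            BumscoreRecord(tf=pwm.tf_name, per_cre=per_cre,
                           bumscore=sum(per_cre.values()))
        )
    return records


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]
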