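"""Synthetic study generator with planted ground truth.

Emulates, at a single locus, the statistical structure the regulator-
prioritization pipeline assumes: a multi-kb locus with a handful of
cis-regulatory elements (one promoter immediately upstream of the TSS,
enhancers in the gene body within 20 kb), binding sites of one true
regulator TF planted inside every CRE among a library of decoy motifs,
Gaussian-bump chromatin tracks with clipped Gaussian noise, an expression
matrix in which the true TF correlates with the target gene at a
configured Pearson r on the log scale, DE tables with exact UP/DOWN
fractions, and ChIP peaks placed within (or beyond) the target-assignment
window of simulated gene TSSs.

All randomness derives from one master seed through independent
per-generator streams, so e.g. changing ``n_samples`` never perturbs the
locus sequence.  Identical config => byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .formats_io import PFM, DERecord, ExpressionMatrix, GenomicInterval, SignalTrack
from . import cre_caller

CHROM = "chrSim"
CHIP_CHROM = "chrChip"
TARGET_GENE = "TARGET"

# stream indices of the per-generator RNGs spawned from the master seed
_STREAMS = ("motifs", "locus", "tracks", "expression", "de", "chip")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 0
    locus_length: int = 50_000
    n_cres: int = 7
    cre_width: int = 600
    n_tf_decoys: int = 50
    true_tf_sites_per_cre: int = 2
    motif_length: int = 8
    n_samples: int = 40
    target_tf_correlation: float = 0.7
    track_noise_sd: float = 0.2
    peak_height: float = 5.0
    de_up_fraction: float = 0.1
    de_down_fraction: float = 0.1
    gene_strand: str = "+"
    n_celltypes: int = 1
    true_tf_is_de: bool = True
    n_chip_genes: int = 500
    chip_bound_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_cres * self.cre_width >= self.locus_length:
            raise ConfigurationError("CREs do not fit in the locus")
        if not (-1.0 < self.target_tf_correlation < 1.0):
            raise ConfigurationError(
                f"|target_tf_correlation| must be < 1, got {self.target_tf_correlation}"
            )
        if self.track_noise_sd < 0:
            raise ConfigurationError("track_noise_sd must be >= 0")
        if not (0 <= self.de_up_fraction <= 1 and 0 <= self.de_down_fraction <= 1
                and self.de_up_fraction + self.de_down_fraction <= 1):
            raise ConfigurationError("DE fractions must be in [0,1] and sum <= 1")
        if self.gene_strand not in ("+", "-"):
            raise ConfigurationError("gene_strand must be '+' or '-'")
        if self.n_cres < 2:
            raise ConfigurationError("need >= 2 CREs (one promoter + enhancers)")
        if self.motif_length < 4:
            raise ConfigurationError("motif_length must be >= 4")

    def rng(self, stream: str) -> np.random.Generator:
        seq = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS.index(stream),))
        return np.random.default_rng(seq)


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    true_tf: str
    consensus: str
    planted_sites: list[GenomicInterval]
    cre_intervals: list[tuple[GenomicInterval, str]]  # (interval, intended class)
    tss: GenomicInterval
    de_status: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site in self.planted_sites:
            n_hosts = sum(
                1 for iv, _ in self.cre_intervals
                if iv.start <= site.start and site.end <= iv.end
            )
            if n_hosts != 1:
                raise ValueError(
                    f"planted site {site.start}-{site.end} lies inside "
                    f"{n_hosts} CREs (must be exactly 1)"
                )


# ---------------------------------------------------------------------------
# Motif library
# ---------------------------------------------------------------------------

def simulate_motifs(config: SimulationConfig) -> tuple[list[PFM], str, str]:
    """Motif library: one sharp true-regulator PFM among Dirichlet decoys.

    Returns (pfms, true_tf_id, true_tf_consensus).  The true PFM puts 91
    of 100 counts on the consensus base per column; decoy columns are
    drawn from a flat Dirichlet and never planted in the locus.
    """
    rng = config.rng("motifs")
    L = config.motif_length
    n_tfs = config.n_tf_decoys + 1
    names = [f"TF{i + 1:03d}" for i in range(n_tfs)]
    true_idx = int(rng.integers(n_tfs))
    consensus = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))

    pfms: list[PFM] = []
    for i, name in enumerate(names):
        if i == true_idx:
            counts = np.full((4, L), 3.0)
            for j, base in enumerate(consensus):
                counts["ACGT".index(base), j] = 91.0
        else:
            counts = (rng.dirichlet(np.ones(4), size=L).T * 100.0).round(2)
            counts = np.maximum(counts, 0.01)
        pfms.append(PFM(f"M{i + 1:03d}", name, tuple(map(tuple, counts))))
    return pfms, names[true_idx], consensus


# ---------------------------------------------------------------------------
# Locus
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# geometry of the planted locus (bp)
_PROMOTER_TSS_GAP = 100       # promoter CRE ends this far upstream of the TSS
_ENHANCER_MIN_OFFSET = 1_000  # enhancers start at least this far downstream
_ENHANCER_MIN_SEPARATION = 600  # > default merge gap, keeps CREs distinct
_PLACEMENT_RETRIES = 1_000


def simulate_locus(
    config: SimulationConfig,
) -> tuple[dict[str, str], GenomicInterval, GroundTruth]:
    """Uniform-background locus with planted CREs and true-TF sites.

    The TSS sits mid-locus; one promoter-class CRE is placed immediately
    upstream of it (gene-strand sense) and the remaining CREs are
    enhancers placed non-overlapping on the gene-body side, all within
    20 kb of the TSS, so that 5'->3' numbering gives the promoter the
    lowest number.  ``config.true_tf_sites_per_cre`` consensus instances
    of the true TF (random strand) are written into every CRE; decoy
    motifs are never planted.
    """
    rng = config.rng("locus")
    pfms, true_tf, consensus = simulate_motifs(config)
    L = len(consensus)
    length = config.locus_length
    tss_point = length // 2
    sign = 1 if config.gene_strand == "+" else -1
    tss = GenomicInterval(CHROM, tss_point, tss_point + 1, config.gene_strand,
                          name=TARGET_GENE)

    seq = rng.integers(0, 4, size=length)

    w = config.cre_width
    if sign > 0:
        prom = (tss_point - _PROMOTER_TSS_GAP - w, tss_point - _PROMOTER_TSS_GAP)
    else:
        prom = (tss_point + _PROMOTER_TSS_GAP, tss_point + _PROMOTER_TSS_GAP + w)
    if prom[0] < 0 or prom[1] > length:
        raise ConfigurationError("locus too short for promoter placement")

    max_offset = min(cre_caller.DEFAULT_WINDOW_BP,
                     tss_point if sign < 0 else length - tss_point) - w
    n_enh = config.n_cres - 1
    placements: list[tuple[int, int]] | None = None
    for _ in range(_PLACEMENT_RETRIES):
        offsets = np.sort(
            rng.integers(_ENHANCER_MIN_OFFSET, max_offset, size=n_enh)
        )
        if n_enh > 1 and np.diff(offsets).min() < w + _ENHANCER_MIN_SEPARATION:
            continue
        placements = [
            (tss_point + off, tss_point + off + w)
            if sign > 0
            else (tss_point - off - w, tss_point - off)
            for off in offsets
        ]
        break
    if placements is None:
        raise ConfigurationError(
            "could not place non-overlapping enhancer CREs; "
            "reduce n_cres or cre_width, or enlarge the locus"
        )

    cre_intervals: list[tuple[GenomicInterval, str]] = [
        (GenomicInterval(CHROM, *prom, config.gene_strand), cre_caller.CLASS_PROMOTER)
    ] + [
        (GenomicInterval(CHROM, s, e, config.gene_strand), cre_caller.CLASS_ENHANCER)
        for s, e in placements
    ]
    # 5'->3' along the gene strand: the promoter comes first by construction
    cre_intervals.sort(key=lambda t: t[0].start, reverse=(sign < 0))

    consensus_codes = np.array(["ACGT".index(b) for b in consensus])
    rc = consensus.translate(_COMPLEMENT)[::-1]
    rc_codes = np.array(["ACGT".index(b) for b in rc])

    planted: list[GenomicInterval] = []
    for iv, _cls in cre_intervals:
        usable = len(iv) - L
        for _ in range(_PLACEMENT_RETRIES):
            offs = np.sort(rng.integers(0, usable, size=config.true_tf_sites_per_cre))
            if len(offs) > 1 and np.diff(offs).min() < L:
                continue
            break
        else:
            raise ConfigurationError("could not place non-overlapping motif sites")
        for off in offs:
            strand = "+" if rng.random() < 0.5 else "-"
            start = iv.start + int(off)
            seq[start : start + L] = consensus_codes if strand == "+" else rc_codes
            planted.append(GenomicInterval(CHROM, start, start + L, strand))

    fasta = {CHROM: "".join("ACGT"[b] for b in seq)}
    truth = GroundTruth(
        true_tf=true_tf, consensus=consensus, planted_sites=planted,
        cre_intervals=cre_intervals, tss=tss,
    )
    return fasta, tss, truth


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

_TRACK_BIN_BP = 10

# which CRE classes each assay marks, and the bump height multiplier there
_MARK_DESIGN: dict[str, dict[str, float]] = {
    cre_caller.MARK_H3K4ME3: {cre_caller.CLASS_PROMOTER: 1.0},
    cre_caller.MARK_H3K4ME1: {cre_caller.CLASS_ENHANCER: 1.0},
    cre_caller.MARK_H3K27AC: {cre_caller.CLASS_PROMOTER: 1.0,
                              cre_caller.CLASS_ENHANCER: 1.0},
    cre_caller.MARK_DNASE: {cre_caller.CLASS_PROMOTER: 1.0,
                            cre_caller.CLASS_ENHANCER: 0.5},
}


@dataclass
class SimulatedTracks:
    """Per-mark signal tracks and peak calls (optionally per cell type)."""

    tracks: dict[str, dict[str, SignalTrack]]  # mark -> cell type -> track
    peaks: dict[str, dict[str, list[GenomicInterval]]]

    def track(self, mark: str, celltype: str = "ct01") -> SignalTrack:
        return self.tracks[mark][celltype]


def simulate_tracks(truth: GroundTruth, config: SimulationConfig) -> SimulatedTracks:
    """Gaussian-bump tracks over the CREs plus their peak supports.

    H3K4me3 and the strongest DNase bump sit at the promoter-class CRE,
    H3K4me1 at enhancer-class CREs, H3K27ac at all; bump sd is a quarter
    of the CRE width.  Non-negative clipped Gaussian noise with
    sd = ``track_noise_sd`` is added per cell type.  Peak intervals are
    the bump supports, i.e. the CRE intervals the mark covers.
    """
    rng = config.rng("tracks")
    length = config.locus_length
    centers = np.arange(_TRACK_BIN_BP // 2, length, _TRACK_BIN_BP, dtype=float)
    n_bins = len(centers)
    starts = np.arange(0, n_bins) * _TRACK_BIN_BP
    ends = np.minimum(starts + _TRACK_BIN_BP, length)
    celltypes = [f"ct{i + 1:02d}" for i in range(config.n_celltypes)]

    tracks: dict[str, dict[str, SignalTrack]] = {}
    peaks: dict[str, dict[str, list[GenomicInterval]]] = {}
    for mark, design in _MARK_DESIGN.items():
        signal = np.zeros(n_bins)
        support: list[GenomicInterval] = []
        for iv, cls in truth.cre_intervals:
            mult = design.get(cls)
            if mult is None:
                continue
            mu = (iv.start + iv.end) / 2.0
            sd = len(iv) / 4.0
            signal += config.peak_height * mult * np.exp(
                -0.5 * ((centers - mu) / sd) ** 2
            )
            support.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        support.sort(key=lambda p: p.start)
        tracks[mark] = {}
        peaks[mark] = {ct: list(support) for ct in celltypes}
        for ct in celltypes:
            noisy = signal
            if config.track_noise_sd > 0:
                noisy = signal + rng.normal(0.0, config.track_noise_sd, size=n_bins)
            noisy = np.clip(noisy, 0.0, None)
            intervals = [
                GenomicInterval(CHROM, int(s), int(e))
                for s, e in zip(starts, ends)
            ]
            tracks[mark][ct] = SignalTrack(
                intervals, [float(v) for v in noisy], mark=mark, sample=ct
            )
    return SimulatedTracks(tracks=tracks, peaks=peaks)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

_LOG_MEAN = 7.0  # log2-CPM location of simulated genes (~128 CPM)
_LOG_SD = 1.0


def simulate_expression(
    truth: GroundTruth, config: SimulationConfig
) -> ExpressionMatrix:
    """CPM-scale matrix: target + all TFs across ``n_samples`` samples.

    The target and the true TF share a bivariate normal structure on the
    log2 scale with population Pearson r = ``target_tf_correlation``;
    decoy TFs are independent of the target.  Values are exponentiated to
    a CPM-like scale, so the planted correlation is (up to the +1 in the
    pipeline's log2(CPM+1)) recovered on the analysis scale.
    """
    import pandas as pd

    rng = config.rng("expression")
    n = config.n_samples
    r = config.target_tf_correlation
    n_tfs = config.n_tf_decoys + 1
    tf_names = [f"TF{i + 1:03d}" for i in range(n_tfs)]

    z_target = rng.normal(size=n)
    z_all = rng.normal(size=(n_tfs, n))
    true_row = tf_names.index(truth.true_tf)
    z_all[true_row] = r * z_target + math.sqrt(1.0 - r * r) * z_all[true_row]

    rows = np.vstack([z_target[None, :], z_all])
    cpm = np.exp2(_LOG_MEAN + _LOG_SD * rows)
    genes = [TARGET_GENE] + tf_names
    samples = [f"S{i + 1:03d}" for i in range(n)]
    return ExpressionMatrix(pd.DataFrame(cpm, index=genes, columns=samples))


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

_UP_LFC_RANGE = (math.log2(1.5) + 0.05, 3.0)
_NDE_LFC_RANGE = (-0.3, 0.3)


def simulate_de_table(
    genes: Sequence[str],
    config: SimulationConfig,
    force_up: Sequence[str] = (),
) -> tuple[list[DERecord], dict[str, str]]:
    """DE table with exact UP/DOWN fractions at the strict thresholds.

    round(de_up_fraction * n) genes get log2fc > log2(1.5) with FDR <
    0.05, the symmetric count get the negative rule, the rest are null
    (FDR >= 0.05).  ``force_up`` genes (e.g. the true TF when it is DE
    upon stimulus) are placed in the UP set, displacing random picks.
    Returns (records, {gene: UP/DOWN/NDE}).
    """
    rng = config.rng("de")
    genes = list(genes)
    n = len(genes)
    n_up = int(round(config.de_up_fraction * n))
    n_down = int(round(config.de_down_fraction * n))
    if n_up + n_down > n:
        raise ConfigurationError("DE fractions select more genes than exist")

    order = list(rng.permutation(n))
    forced = [genes.index(g) for g in force_up if g in genes]
    if len(forced) > n_up:
        raise ConfigurationError("more forced-UP genes than UP slots")
    order = forced + [i for i in order if i not in set(forced)]
    up_idx = set(order[:n_up])
    down_idx = set(order[n_up : n_up + n_down])

    records: list[DERecord] = []
    status: dict[str, str] = {}
    for i, gene in enumerate(genes):
        if i in up_idx:
            lfc = rng.uniform(*_UP_LFC_RANGE)
            fdr = rng.uniform(1e-6, 0.049)
            status[gene] = "UP"
        elif i in down_idx:
            lfc = -rng.uniform(*_UP_LFC_RANGE)
            fdr = rng.uniform(1e-6, 0.049)
            status[gene] = "DOWN"
        else:
            lfc = rng.uniform(*_NDE_LFC_RANGE)
            fdr = rng.uniform(0.05, 1.0)
            status[gene] = "NDE"
        records.append(DERecord(gene, float(lfc), float(fdr)))
    return records, status


# ---------------------------------------------------------------------------
# ChIP peaks
# ---------------------------------------------------------------------------

_CHIP_GENE_SPACING = 10_000
_CHIP_PEAK_HALF_WIDTH = 200


def simulate_chip_peaks(
    config: SimulationConfig,
) -> tuple[list[GenomicInterval], list[GenomicInterval], set[str]]:
    """TSS annotation + ChIP peaks with a known bound gene set.

    round(chip_bound_fraction * n) genes get a peak whose nearest edge is
    within 2 kb of their TSS; a third of the remaining genes get a decoy
    peak well outside the window.  Returns (tss_list, peaks, bound_genes).
    """
    rng = config.rng("chip")
    n = config.n_chip_genes
    tss_list = [
        GenomicInterval(CHIP_CHROM, _CHIP_GENE_SPACING * (i + 1),
                        _CHIP_GENE_SPACING * (i + 1) + 1,
                        "+" if i % 2 == 0 else "-", name=f"G{i + 1:04d}")
        for i in range(n)
    ]
    n_bound = int(round(config.chip_bound_fraction * n))
    bound_idx = set(rng.choice(n, size=n_bound, replace=False).tolist())
    peaks: list[GenomicInterval] = []
    bound_genes: set[str] = set()
    for i, tss in enumerate(tss_list):
        if i in bound_idx:
            off = int(rng.integers(-1500, 1501))
            s = tss.start + off - _CHIP_PEAK_HALF_WIDTH
            peaks.append(GenomicInterval(CHIP_CHROM, s, s + 2 * _CHIP_PEAK_HALF_WIDTH))
            bound_genes.add(tss.name)
        elif i % 3 == 0:
            s = tss.start + 6_000
            peaks.append(GenomicInterval(CHIP_CHROM, s, s + 2 * _CHIP_PEAK_HALF_WIDTH))
    return tss_list, peaks, bound_genes


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Every input the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    fasta: dict[str, str]
    tss: GenomicInterval
    truth: GroundTruth
    pfms: list[PFM]
    tracks: SimulatedTracks
    expression: ExpressionMatrix
    de_records: list[DERecord]
    chip_tss: list[GenomicInterval]
    chip_peaks: list[GenomicInterval]
    chip_bound: set[str]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the complete synthetic study from one master seed."""
    fasta, tss, truth = simulate_locus(config)
    pfms, _, _ = simulate_motifs(config)
    tracks = simulate_tracks(truth, config)
    expression = simulate_expression(truth, config)
    tf_names = [p.tf_name for p in pfms]
    force_up = [truth.true_tf] if config.true_tf_is_de else []
    de_records, de_status = simulate_de_table(tf_names, config, force_up=force_up)
    truth.de_status = de_status
    chip_tss, chip_peaks, chip_bound = simulate_chip_peaks(config)
    return SimulatedStudy(
        config=config, fasta=fasta, tss=tss, truth=truth, pfms=pfms,
        tracks=tracks, expression=expression, de_records=de_records,
        chip_tss=chip_tss, chip_peaks=chip_peaks, chip_bound=chip_bound,
    )
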