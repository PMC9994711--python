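"""ChIP-peak target assignment, DE classification, crosstab, CPM filtering
and Fisher-exact geneset enrichment.

A gene is a ChIP target when any peak's nearest edge lies within a window
(default 2 kb, inclusive) of its TSS point.  Targets are crossed with a
differential-expression classification (UP / DOWN / NDE from FDR and
linear fold-change cutoffs) to quantify how much of the bound gene set
responds transcriptionally.  Enrichment of a gene list in user-supplied
genesets uses the one-sided Fisher exact test (hypergeometric tail) with
Benjamini-Hochberg adjustment across genesets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .formats_io import DERecord, ExpressionMatrix, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_TARGET_WINDOW_BP = 2_000
DEFAULT_FDR_MAX = 0.05
DEFAULT_FC_MIN = 1.5

UP, DOWN, NDE = "UP", "DOWN", "NDE"


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Peak -> gene assignment
# ---------------------------------------------------------------------------

@dataclass
class TargetAssignment:
    gene: str
    tss: GenomicInterval
    supporting_peaks: list[GenomicInterval] = field(default_factory=list)
    min_distance_bp: int = 0


def _tss_peak_distance(tss_point: int, peak: GenomicInterval) -> int:
    """Distance from the TSS point to the peak's nearest covered base."""
    if peak.start <= tss_point < peak.end:
        return 0
    if tss_point < peak.start:
        return peak.start - tss_point
    return tss_point - (peak.end - 1)


def assign_targets(
    peaks: Sequence[GenomicInterval],
    tss_annotation: Sequence[GenomicInterval],
    window_bp: int = DEFAULT_TARGET_WINDOW_BP,
) -> list[TargetAssignment]:
    """Genes whose TSS lies within ``window_bp`` (inclusive) of any peak.

    A peak may support multiple genes.  The TSS annotation must use unique
    gene ids (interval ``name``); the TSS point is the interval start.
    """
    genes = [t.name for t in tss_annotation]
    if len(set(genes)) != len(genes):
        raise ValueError("TSS annotation has duplicate gene ids")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: list[TargetAssignment] = []
    for tss in tss_annotation:
        support = []
        best = None
        for p in by_chrom.get(tss.chrom, ()):
            d = _tss_peak_distance(tss.start, p)
            if d <= window_bp:
                support.append(p)
                best = d if best is None else min(best, d)
        if support:
            out.append(
                TargetAssignment(gene=tss.name, tss=tss,
                                 supporting_peaks=support,
                                 min_distance_bp=best)
            )
    return out


# ---------------------------------------------------------------------------
# DE classification and crosstab
# ---------------------------------------------------------------------------

def classify_de(
    de: Sequence[DERecord],
    fdr_max: float = DEFAULT_FDR_MAX,
    fc_min: float = DEFAULT_FC_MIN,
) -> dict[str, str]:
    """UP / DOWN / NDE per gene from FDR and linear fold-change cutoffs.

    UP: fdr < fdr_max and linear fold change > fc_min (log2fc > log2(fc_min));
    DOWN: fdr < fdr_max and fold change < 1/fc_min; otherwise NDE.
    """
    if fc_min <= 1:
        raise ConfigurationError(f"fc_min must be > 1, got {fc_min}")
    log_cut = math.log2(fc_min)
    classes: dict[str, str] = {}
    for rec in de:
        if rec.fdr < fdr_max and rec.log2fc > log_cut:
            classes[rec.gene] = UP
        elif rec.fdr < fdr_max and rec.log2fc < -log_cut:
            classes[rec.gene] = DOWN
        else:
            classes[rec.gene] = NDE
    return classes


@dataclass
class CrosstabResult:
    n_targets: int
    counts: dict[str, int]
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_targets:
            raise ValueError("crosstab counts must sum to n_targets")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("crosstab fractions must sum to 1")


def crosstab_targets(
    targets: Sequence[TargetAssignment] | Sequence[str],
    de_classes: Mapping[str, str],
) -> CrosstabResult:
    """UP/DOWN/NDE counts and fractions over the target gene set.

    Target genes missing from the DE classification default to NDE (with a
    warning); DE genes that are not targets are ignored.
    """
    genes = [t.gene if isinstance(t, TargetAssignment) else t for t in targets]
    if not genes:
        raise ValueError("crosstab requires at least one target gene")
    counts = {UP: 0, DOWN: 0, NDE: 0}
    n_missing = 0
    for g in genes:
        cls = de_classes.get(g)
        if cls is None:
            cls = NDE
            n_missing += 1
        counts[cls] += 1
    if n_missing:
        logger.warning(
            "%d target gene(s) absent from the DE table; classified NDE",
            n_missing,
        )
    n = len(genes)
    return CrosstabResult(
        n_targets=n,
        counts=counts,
        fractions={k: v / n for k, v in counts.items()},
    )


# ---------------------------------------------------------------------------
# CPM normalization and expression filtering
# ---------------------------------------------------------------------------

def cpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million: count / library size * 1e6, per sample column."""
    libsize = counts.data.sum(axis=0)
    zero = libsize[libsize <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return ExpressionMatrix(counts.data / libsize * 1e6, is_counts=False)


def expression_filter(
    counts: ExpressionMatrix,
    group_sizes: Sequence[int],
    multimap_fraction: Mapping[str, float] | None = None,
    cpm_min: float = 1.0,
    multimap_max: float = 0.20,
) -> set[str]:
    """Expressed-gene filter applied before differential testing.

    Keep a gene iff the number of samples with CPM > ``cpm_min`` exceeds
    (min group size - 1), and — when a per-gene multimapping fraction is
    provided — that fraction is below ``multimap_max``.
    """
    if sum(group_sizes) != counts.data.shape[1]:
        raise ValueError("group sizes do not sum to the number of samples")
    cpm = counts if not counts.is_counts else cpm_normalize(counts)
    needed = min(group_sizes) - 1
    n_pass = (cpm.data > cpm_min).sum(axis=1)
    kept = set(cpm.data.index[n_pass > needed])
    if multimap_fraction is not None:
        kept = {
            g for g in kept if multimap_fraction.get(g, 0.0) < multimap_max
        }
    return kept


# ---------------------------------------------------------------------------
# Fisher-exact geneset enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    geneset: str
    overlap: int
    set_only: int
    list_only: int
    neither: int
    odds_ratio: float
    p: float
    adjusted_p: float = float("nan")
    continuity_corrected: bool = False

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.overlap, self.set_only, self.list_only, self.neither)


def fisher_pvalue(overlap: int, set_only: int, list_only: int, neither: int) -> float:
    """One-sided (over-representation) Fisher exact p.

    Hypergeometric upper tail: probability of drawing >= ``overlap`` set
    members when sampling ``overlap + list_only`` genes from a universe
    with ``overlap + set_only`` set members.
    """
    universe = overlap + set_only + list_only + neither
    n_set = overlap + set_only
    n_list = overlap + list_only
    return float(scipy.stats.hypergeom.sf(overlap - 1, universe, n_set, n_list))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, >= raw, <= 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        return p
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def fisher_enrichment(
    gene_list: Iterable[str],
    genesets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    two_sided: bool = False,
) -> list[EnrichmentResult]:
    """Fisher exact enrichment of ``gene_list`` in each geneset.

    Genesets are intersected with the universe; the gene list must be a
    subset of the universe.  BH adjustment is applied across genesets.
    The odds ratio uses a 0.5 continuity correction only when a table
    margin is zero (flagged on the result).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    glist = set(gene_list)
    stray = glist - universe_set
    if stray:
        raise ValueError(
            f"gene list contains {len(stray)} gene(s) outside the universe, "
            f"e.g. {sorted(stray)[:3]}"
        )
    results: list[EnrichmentResult] = []
    for name, members in genesets.items():
        gset = set(members) & universe_set
        overlap = len(gset & glist)
        set_only = len(gset - glist)
        list_only = len(glist - gset)
        neither = len(universe_set) - overlap - set_only - list_only
        if two_sided:
            p = float(
                scipy.stats.fisher_exact(
                    [[overlap, set_only], [list_only, neither]],
                    alternative="two-sided",
                )[1]
            )
        else:
            p = fisher_pvalue(overlap, set_only, list_only, neither)
        corrected = False
        a, b, c, d = overlap, set_only, list_only, neither
        if min(a + b, c + d, a + c, b + d) == 0 or b * c == 0:
            if b * c == 0 or a * d == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                corrected = True
        odds = (a * d) / (b * c) if b * c else float("inf")
        results.append(
            EnrichmentResult(
                geneset=name, overlap=overlap, set_only=set_only,
                list_only=list_only, neither=neither,
                odds_ratio=float(odds), p=min(p, 1.0),
                continuity_corrected=corrected,
            )
        )
    adjusted = benjamini_hochberg([r.p for r in results])
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "geneset": [r.geneset for r in results],
            "overlap": [r.overlap for r in results],
            "set_only": [r.set_only for r in results],
            "list_only": [r.list_only for r in results],
            "neither": [r.neither for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "p": [r.p for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
        }
    )
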