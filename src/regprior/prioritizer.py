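"""Composite ranking and candidate selection of putative regulators.

Each TF carries three prioritization inputs: its Bumscore (predicted
binding sites across the CREs), its Pearson coexpression with the target,
and the chromatin accessibility (DNase aggregate) of the core promoter
where it has at least one predicted site.  The composite score is a rank
product — the geometric mean of the three descending ranks (average ranks
on ties) — so lower is better and a TF best on all three scores exactly 1.

Selection follows the published filter logic:
  rule A (corr_and_sites): bumscore > 3 and r > 0.3 (strict inequalities);
  rule B (de_and_sites):   differentially expressed upon stimulus and
                           bumscore > 2;
the union is capped (default 96 TFs) by ascending composite score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_BUMSCORE_STRICT = 3
DEFAULT_R_MIN = 0.3
DEFAULT_BUMSCORE_RELAXED = 2
DEFAULT_CAP = 96

RULE_CORR = "corr_and_sites"
RULE_DE = "de_and_sites"
RULE_NONE = "none"


class ConfigurationError(ValueError):
    pass


@dataclass
class CandidateRecord:
    """Everything the selection logic knows about one TF."""

    tf: str
    bumscore: int
    r_target: float
    accessibility: float = 0.0
    de_flag: bool = False
    composite_rank_score: float = float("nan")
    selected: bool = False
    selection_rule: str = RULE_NONE


def composite_score(records: Sequence[CandidateRecord]) -> list[CandidateRecord]:
    """Attach the rank-product composite score (lower = better)."""
    if not records:
        return []
    df = pd.DataFrame(
        {
            "bumscore": [r.bumscore for r in records],
            "r_target": [r.r_target for r in records],
            "accessibility": [r.accessibility for r in records],
        }
    )
    ranks = df.rank(ascending=False, method="average")
    composite = np.power(ranks.prod(axis=1), 1.0 / 3.0)
    return [
        replace(rec, composite_rank_score=float(composite[i]))
        for i, rec in enumerate(records)
    ]


def select_candidates(
    records: Sequence[CandidateRecord],
    bumscore_strict: int = DEFAULT_BUMSCORE_STRICT,
    r_min: float = DEFAULT_R_MIN,
    bumscore_relaxed: int = DEFAULT_BUMSCORE_RELAXED,
    cap: int | None = DEFAULT_CAP,
) -> list[CandidateRecord]:
    """Apply the two selection rules and the candidate cap.

    Rule A: bumscore > bumscore_strict AND r_target > r_min.
    Rule B: de_flag AND bumscore > bumscore_relaxed.
    Rule A takes precedence for labeling.  The union is capped at ``cap``
    TFs by ascending composite score, ties broken by TF id; ``cap=None``
    disables the cap.  Inequalities are strict throughout.
    """
    if bumscore_strict <= 0 or bumscore_relaxed <= 0:
        raise ConfigurationError("bumscore thresholds must be positive")
    if bumscore_strict <= bumscore_relaxed:
        raise ConfigurationError("strict threshold must exceed relaxed threshold")
    if cap is not None and cap < 1:
        raise ConfigurationError(f"cap must be >= 1, got {cap}")

    records = composite_score(records)
    labeled: list[CandidateRecord] = []
    for rec in records:
        rule_a = rec.bumscore > bumscore_strict and rec.r_target > r_min
        rule_b = rec.de_flag and rec.bumscore > bumscore_relaxed
        if rule_a:
            rule = RULE_CORR
        elif rule_b:
            rule = RULE_DE
        else:
            rule = RULE_NONE
        labeled.append(replace(rec, selected=rule != RULE_NONE, selection_rule=rule))

    if cap is not None:
        chosen = sorted(
            (r for r in labeled if r.selected),
            key=lambda r: (r.composite_rank_score, r.tf),
        )
        keep = {r.tf for r in chosen[:cap]}
        labeled = [
            rec if rec.tf in keep
            else replace(rec, selected=False, selection_rule=RULE_NONE)
            for rec in labeled
        ]
    return labeled


def ranked_table(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Candidate table sorted by composite score (then TF id)."""
    df = pd.DataFrame(
        {
            "tf": [r.tf for r in records],
            "bumscore": [r.bumscore for r in records],
            "r_target": [r.r_target for r in records],
            "accessibility": [r.accessibility for r in records],
            "de_flag": [r.de_flag for r in records],
            "composite_rank_score": [r.composite_rank_score for r in records],
            "selected": [r.selected for r in records],
            "selection_rule": [r.selection_rule for r in records],
        }
    )
    return df.sort_values(
        ["composite_rank_score", "tf"], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class RecoveryReport:
    true_tf_rank: int
    selected: bool
    n_selected: int


def recover_planted(true_tf: str, records: Sequence[CandidateRecord]) -> RecoveryReport:
    """Rank and selection status of a known planted regulator."""
    table = ranked_table(records)
    if true_tf not in set(table["tf"]):
        raise KeyError(f"true TF {true_tf!r} absent from candidate records")
    rank = int(table.index[table["tf"] == true_tf][0]) + 1
    row = table.loc[table["tf"] == true_tf].iloc[0]
    return RecoveryReport(
        true_tf_rank=rank,
        selected=bool(row["selected"]),
        n_selected=int(table["selected"].sum()),
    )
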