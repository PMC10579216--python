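"""Rank-sum method scoring and the end-to-end evaluation report.

Each extraction method (or treatment arm) is scored on three criteria:

* repeatability — % of detected compounds with CV below threshold (higher
  is better);
* metabolome coverage — % of the compound universe undetected (lower is
  better);
* metabolite recovery — average % recovery of the spike compounds (higher
  is better).

Within each criterion methods are ranked (rank 1 = best, competition rank on
ties) and the cumulative score is the rank sum; the method with the lowest
cumulative score is the preferred one.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .coverage import build_detection_matrix, percent_undetected, unique_compounds
from .normalization import normalize_pipeline
from .peaktable_io import (
    NormalizationState,
    PeakTable,
    SampleMeta,
    SpikeGroup,
    SpikeMixture,
    StudyConfig,
    UrimexError,
    samples_for,
)
from .recovery import RecoveryResult, assess_recovery
from .repeatability import RepeatabilityResult, assess_repeatability

__all__ = [
    "Direction",
    "CRITERION_DIRECTIONS",
    "CriterionScore",
    "MethodRanking",
    "rank_criterion",
    "cumulative_score",
    "build_ranking",
    "EvaluationReport",
    "evaluate_design",
    "GroupMeanRatio",
    "group_mean_ratio",
]


class Direction(str, enum.Enum):
    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


#: Fixed orientation of the three validation criteria.
CRITERION_DIRECTIONS: Mapping[str, Direction] = {
    "repeatability": Direction.HIGHER_BETTER,
    "coverage": Direction.LOWER_BETTER,
    "recovery": Direction.HIGHER_BETTER,
}


@dataclass(frozen=True)
class CriterionScore:
    method_label: str
    criterion: str
    value: float
    direction: Direction

    def __post_init__(self) -> None:
        expected = CRITERION_DIRECTIONS.get(self.criterion)
        if expected is not None and expected is not Direction(self.direction):
            raise UrimexError(
                f"criterion {self.criterion!r} is fixed as {expected.value}"
            )


def rank_criterion(scores: Sequence[CriterionScore]) -> dict[str, int]:
    """Competition (min) ranks for one criterion; rank 1 is best."""
    if len(scores) < 2:
        raise UrimexError("ranking needs at least 2 methods")
    labels = [s.method_label for s in scores]
    if len(set(labels)) != len(labels):
        raise UrimexError("duplicate method labels in criterion scores")
    criteria = {s.criterion for s in scores}
    if len(criteria) != 1:
        raise UrimexError(f"scores mix criteria: {sorted(criteria)}")
    directions = {s.direction for s in scores}
    if len(directions) != 1:
        raise UrimexError("scores mix directions")
    values = np.array([s.value for s in scores], dtype=float)
    if next(iter(directions)) is Direction.HIGHER_BETTER:
        values = -values
    ranks = rankdata(values, method="min").astype(int)
    return dict(zip(labels, ranks))


@dataclass(frozen=True)
class MethodRanking:
    """Method x criterion rank matrix with the cumulative (rank-sum) score."""

    ranks: pd.DataFrame  # index = methods, columns = criteria, int
    cumulative: Mapping[str, int]
    ordering: tuple[str, ...]  # ascending cumulative score
    ties_present: bool


def cumulative_score(ranks: pd.DataFrame) -> dict[str, int]:
    """Integer rank sum per method; every cell must be present."""
    if ranks.isna().any().any():
        missing = [
            (m, c)
            for m in ranks.index
            for c in ranks.columns
            if pd.isna(ranks.loc[m, c])
        ]
        raise UrimexError(f"missing rank cells: {missing[:5]}")
    sums = ranks.sum(axis=1)
    return {m: int(v) for m, v in sums.items()}


def build_ranking(
    scores_by_criterion: Mapping[str, Sequence[CriterionScore]],
) -> MethodRanking:
    """Rank every criterion, sum into the cumulative score, sort ascending."""
    rank_maps = {c: rank_criterion(s) for c, s in scores_by_criterion.items()}
    criteria = list(scores_by_criterion)
    methods = list(rank_maps[criteria[0]])
    for c in criteria[1:]:
        if set(rank_maps[c]) != set(methods):
            raise UrimexError("criteria cover different method sets")
    ranks = pd.DataFrame(
        {c: [rank_maps[c][m] for m in methods] for c in criteria}, index=methods
    )
    ties = any(
        len(set(rank_maps[c].values())) != len(methods) for c in criteria
    )
    cum = cumulative_score(ranks)
    ordering = tuple(sorted(methods, key=lambda m: (cum[m], m)))
    if ties:
        warnings.warn("tied criterion scores: competition ranks used", stacklevel=2)
    return MethodRanking(ranks, cum, ordering, ties)


# ---------------------------------------------------------------------------
# end-to-end evaluation

@dataclass(frozen=True)
class EvaluationReport:
    """Full per-arm evaluation: criterion values, ranks, cumulative scores."""

    arms: tuple[str, ...]
    criteria_used: tuple[str, ...]
    scores: pd.DataFrame  # arms x criteria raw values
    ranking: MethodRanking
    repeatability: Mapping[str, RepeatabilityResult]
    recovery: Mapping[str, RecoveryResult]
    n_universe: int
    unique_counts: Mapping[str, int]  # secondary coverage column
    warnings_: tuple[str, ...] = ()

    @property
    def best(self) -> str:
        return self.ranking.ordering[0]

    def to_dict(self) -> dict:
        return {
            "arms": list(self.arms),
            "criteria": list(self.criteria_used),
            "tie_rule": "competition (min) rank",
            "criterion_directions": {
                c: CRITERION_DIRECTIONS[c].value for c in self.criteria_used
            },
            "scores": {
                a: {c: float(self.scores.loc[a, c]) for c in self.criteria_used}
                for a in self.arms
            },
            "ranks": {
                a: {
                    c: int(self.ranking.ranks.loc[a, c])
                    for c in self.criteria_used
                }
                for a in self.arms
            },
            "cumulative": {a: int(self.ranking.cumulative[a]) for a in self.arms},
            "ordering": list(self.ranking.ordering),
            "ties_present": self.ranking.ties_present,
            "n_universe": self.n_universe,
            "unique_compound_counts": {
                a: int(self.unique_counts[a]) for a in self.arms
            },
            "warnings": list(self.warnings_),
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path

    def write_csv(self, path: str | Path) -> Path:
        """Rank-matrix CSV with the cumulative column, lowest score first."""
        path = Path(path)
        out = self.ranking.ranks.copy()
        out["cumulative_score"] = [self.ranking.cumulative[a] for a in out.index]
        out = out.loc[list(self.ranking.ordering)]
        out.rename_axis(index="Method").to_csv(path)
        return path


def evaluate_design(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    spike: SpikeMixture,
    cfg: StudyConfig | None = None,
    arms: Sequence[str] | None = None,
) -> EvaluationReport:
    """Run all three criteria per arm and assemble the rank-sum report.

    A raw table is normalized first (IS then creatinine, as configured).
    Arms lacking pre/post spike groups have recovery marked "not assessed";
    the criterion is then dropped from the rank matrix for all arms (ranks
    must cover every arm) and the reduced criterion set is recorded.
    """
    cfg = cfg or StudyConfig()
    if arms is None:
        arms = list(dict.fromkeys(m.method_label for m in meta))
    arms = list(arms)
    if len(arms) < 2:
        raise UrimexError("evaluation needs at least 2 arms")
    if table.normalization_state is NormalizationState.RAW:
        table = normalize_pipeline(table, meta, cfg)
    notes: list[str] = []

    rep: dict[str, RepeatabilityResult] = {}
    for arm in arms:
        group = SpikeGroup.PRE if samples_for(meta, arm, SpikeGroup.PRE) else None
        if group is None:
            notes.append(f"{arm}: no pre-spike samples, repeatability/coverage use all samples")
        rep[arm] = assess_repeatability(table, meta, arm, cfg, spike_group=group)

    dm = build_detection_matrix(table, meta, cfg, methods=arms)
    cov = {arm: percent_undetected(dm, arm) for arm in arms}
    uniq = {arm: len(unique_compounds(dm, arm)) for arm in arms}

    rec: dict[str, RecoveryResult] = {}
    assessable = True
    for arm in arms:
        has_pre = bool(samples_for(meta, arm, SpikeGroup.PRE))
        has_post = bool(samples_for(meta, arm, SpikeGroup.POST))
        if has_pre and has_post:
            rec[arm] = assess_recovery(table, meta, spike, arm)
        else:
            assessable = False
            notes.append(f"{arm}: recovery not assessed (missing pre/post spike groups)")
    if not assessable:
        rec = {}

    scores_by_criterion: dict[str, list[CriterionScore]] = {
        "repeatability": [
            CriterionScore(a, "repeatability", rep[a].percent_below_threshold,
                           Direction.HIGHER_BETTER)
            for a in arms
        ],
        "coverage": [
            CriterionScore(a, "coverage", cov[a], Direction.LOWER_BETTER)
            for a in arms
        ],
    }
    if rec:
        scores_by_criterion["recovery"] = [
            CriterionScore(a, "recovery", rec[a].average_recovery_percent,
                           Direction.HIGHER_BETTER)
            for a in arms
        ]
    ranking = build_ranking(scores_by_criterion)
    criteria = tuple(scores_by_criterion)
    scores = pd.DataFrame(
        {
            c: [s.value for s in scores_by_criterion[c]]
            for c in criteria
        },
        index=arms,
    )
    return EvaluationReport(
        arms=tuple(arms),
        criteria_used=criteria,
        scores=scores,
        ranking=ranking,
        repeatability=rep,
        recovery=rec,
        n_universe=dm.n_total,
        unique_counts=uniq,
        warnings_=tuple(notes),
    )


# ---------------------------------------------------------------------------
# between-group signal ratios (urea reduction)

@dataclass(frozen=True)
class GroupMeanRatio:
    """Mean signal of a compound in group A divided by the mean in group B."""

    compound: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    value: float
    infinite: bool = False  # positive numerator over zero denominator
    undefined: bool = False  # both means zero


def group_mean_ratio(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    compound: str,
    group_a: str,
    group_b: str,
) -> GroupMeanRatio:
    """Between-group mean-signal ratio for one compound (e.g. urea).

    Used to quantify signal suppression: a urease-treated versus non-treated
    ratio of 0.1 for urea means a tenfold urea reduction.
    """
    col = table.resolve_compound(compound)
    a = samples_for(meta, group_a)
    b = samples_for(meta, group_b)
    if not a or not b:
        raise UrimexError(
            f"both groups must be non-empty (got {len(a)} in {group_a!r}, "
            f"{len(b)} in {group_b!r})"
        )
    mean_a = float(table.data.loc[[m.sample_id for m in a], col].mean())
    mean_b = float(table.data.loc[[m.sample_id for m in b], col].mean())
    if mean_b > 0:
        return GroupMeanRatio(compound, group_a, group_b, mean_a, mean_b,
                              mean_a / mean_b)
    if mean_a > 0:
        return GroupMeanRatio(compound, group_a, group_b, mean_a, mean_b,
                              math.inf, infinite=True)
    return GroupMeanRatio(compound, group_a, group_b, mean_a, mean_b,
                          math.nan, undefined=True)
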