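"""Spike-compound recovery: the pre/post ratio and per-method averages.

The spiking mixture is added to half of a method's samples before extraction
("pre-spike": the spike experiences the same losses as endogenous analytes)
and to the other half after extraction ("post-spike": the spike bypasses the
losses).  For each spike compound

    % recovery = pre-spike average / post-spike average x 100

so a perfectly recovered compound scores 100.  Values above 100 are legal and
preserved — they typically mean the compound is also endogenously present in
the urine matrix; such rows are flagged rather than corrected, because the
score is defined as the raw ratio.  A zero post-spike average yields a
recovery of 0 (the compound was never seen), with a diagnostic flag
distinguishing 0/0 from x/0.

The method-level score is the arithmetic mean of the per-compound recoveries
over ALL spike compounds, zeros included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .peaktable_io import (
    PeakTable,
    SampleMeta,
    SpikeGroup,
    SpikeMixture,
    UrimexError,
    samples_for,
)

__all__ = [
    "round_half_up",
    "compound_recovery",
    "RecoveryRow",
    "RecoveryResult",
    "assess_recovery",
    "recovery_result_from_rows",
    "write_recovery_result",
]


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, the convention printed tables use.

    Plain ``round`` is banker's rounding on binary floats, so e.g. a mean of
    22.215 would print 22.21; reference tables print 22.22.  The value is
    first quantized a few digits below ``ndigits`` so that binary-float noise
    around a decimal half-case (22.214999...96 for 222.15/10) does not flip
    the direction.
    """
    import decimal

    d = decimal.Decimal(repr(value)).quantize(
        decimal.Decimal(10) ** -(ndigits + 4), rounding=decimal.ROUND_HALF_UP
    )
    return float(
        d.quantize(decimal.Decimal(10) ** -ndigits, rounding=decimal.ROUND_HALF_UP)
    )


def compound_recovery(pre_average: float, post_average: float) -> float:
    """100 x pre/post, defined as 0 when the post-spike average is 0."""
    if not (math.isfinite(pre_average) and math.isfinite(post_average)):
        raise UrimexError("recovery inputs must be finite")
    if pre_average < 0 or post_average < 0:
        raise UrimexError("recovery inputs must be >= 0")
    if post_average == 0:
        return 0.0
    return 100.0 * pre_average / post_average


@dataclass(frozen=True)
class RecoveryRow:
    compound: str
    compound_class: str
    pre_average: float
    post_average: float
    recovery_percent: float
    zero_post: bool = False  # post-spike average was 0 (recovery forced to 0)
    zero_over_zero: bool = False  # both averages 0: compound never seen at all
    endogenous_suspect: bool = False  # both averages well above the spike level


@dataclass(frozen=True)
class RecoveryResult:
    method_label: str
    rows: tuple[RecoveryRow, ...]
    average_recovery_percent: float

    def __post_init__(self) -> None:
        if any(r.recovery_percent < 0 for r in self.rows):
            raise UrimexError("recovery_percent must be >= 0")
        mean = float(np.mean([r.recovery_percent for r in self.rows]))
        if not math.isclose(mean, self.average_recovery_percent, abs_tol=1e-9):
            raise UrimexError(
                "average_recovery_percent must equal the mean of the rows"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "Compound": [r.compound for r in self.rows],
                "Class": [r.compound_class for r in self.rows],
                "PreAverage": [r.pre_average for r in self.rows],
                "PostAverage": [r.post_average for r in self.rows],
                "RecoveryPercent": [r.recovery_percent for r in self.rows],
            }
        )
        return df


def recovery_result_from_rows(
    method_label: str, rows: Sequence[RecoveryRow]
) -> RecoveryResult:
    """Aggregate per-compound rows into a method result (mean over all rows)."""
    if not rows:
        raise UrimexError("recovery needs at least one spike compound")
    average = float(np.mean([r.recovery_percent for r in rows]))
    return RecoveryResult(method_label, tuple(rows), average)


def assess_recovery(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    spike: SpikeMixture,
    method_label: str,
) -> RecoveryResult:
    """Compute per-compound and average recovery for one method arm.

    Pre- and post-spike averages are arithmetic means of the (normalized)
    values over the respective replicate groups.  Spike compounds absent from
    the table become rows with both averages 0.
    """
    pre = samples_for(meta, method_label, SpikeGroup.PRE)
    post = samples_for(meta, method_label, SpikeGroup.POST)
    if not pre or not post:
        raise UrimexError(
            f"method {method_label!r} needs >= 1 pre-spike and >= 1 "
            f"post-spike sample (got {len(pre)} pre, {len(post)} post)"
        )
    pre_tab = table.subset_samples([m.sample_id for m in pre])
    post_tab = table.subset_samples([m.sample_id for m in post])
    rows = []
    for entry in spike:
        if table.has_compound(entry.compound):
            col = table.resolve_compound(entry.compound)
            pre_avg = float(pre_tab.data[col].mean())
            post_avg = float(post_tab.data[col].mean())
        else:
            pre_avg = post_avg = 0.0
        rec = compound_recovery(pre_avg, post_avg)
        rows.append(
            RecoveryRow(
                compound=entry.compound,
                compound_class=entry.compound_class.value,
                pre_average=pre_avg,
                post_average=post_avg,
                recovery_percent=rec,
                zero_post=post_avg == 0,
                zero_over_zero=pre_avg == 0 and post_avg == 0,
                endogenous_suspect=rec > 100.0,
            )
        )
    return recovery_result_from_rows(method_label, rows)


def write_recovery_result(
    results: Sequence[RecoveryResult], path: str | Path
) -> Path:
    """Export recovery results as CSV: per-compound rows plus an average row."""
    path = Path(path)
    frames = []
    for res in results:
        df = res.to_frame()
        df.insert(0, "Method", res.method_label)
        avg = pd.DataFrame(
            [
                {
                    "Method": res.method_label,
                    "Compound": "Average recovery",
                    "Class": "",
                    "PreAverage": np.nan,
                    "PostAverage": np.nan,
                    "RecoveryPercent": res.average_recovery_percent,
                }
            ]
        )
        frames.append(pd.concat([df, avg], ignore_index=True))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path
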