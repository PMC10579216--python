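"""Two-step normalization: internal standard first, then creatinine.

Every sample receives the internal standard (3-phenylbutyric acid, 50 ppm), so
dividing a sample's areas by its IS area removes injection-to-injection
instrument drift.  Dividing by creatinine afterwards corrects for urine
dilution, the standard practice in urinary metabolomics.  The order is fixed
and enforced through the table's normalization-state flag; composing the two
steps equals a single division by IS x creatinine, and applying a step twice
is an error, never a silent double division.

The IS feature is removed from the returned table: its ratio is identically 1
and it is an instrument control, not an analyte.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .peaktable_io import (
    NormalizationState,
    PeakTable,
    SampleMeta,
    StudyConfig,
    UrimexError,
    DEFAULT_INTERNAL_STANDARD,
)

__all__ = [
    "normalize_by_internal_standard",
    "normalize_by_creatinine",
    "normalize_pipeline",
]


def normalize_by_internal_standard(
    table: PeakTable, is_name: str = DEFAULT_INTERNAL_STANDARD
) -> PeakTable:
    """Divide each sample's intensities by that sample's IS area.

    The IS column is dropped from the result.  A zero IS area means a failed
    injection, not a zero ratio, so it is rejected naming the sample.
    """
    if table.normalization_state is not NormalizationState.RAW:
        raise UrimexError(
            "table is already normalized "
            f"({table.normalization_state.value}); IS normalization applies "
            "to raw tables only"
        )
    is_col = table.resolve_compound(is_name)
    is_values = table.data[is_col]
    bad = is_values[~(is_values > 0)]
    if len(bad):
        raise UrimexError(
            f"internal standard {is_name!r} has non-positive area in "
            f"sample(s) {list(bad.index)}; cannot normalize"
        )
    normalized = table.data.drop(columns=[is_col]).div(is_values, axis=0)
    return PeakTable(normalized, NormalizationState.IS_NORMALIZED)


def normalize_by_creatinine(
    table: PeakTable,
    meta: Sequence[SampleMeta] | None = None,
    source: str = "sample_sheet",
    creatinine_compound: str = "Creatinine",
) -> PeakTable:
    """Divide each sample's (IS-normalized) values by its creatinine value.

    ``source`` selects where creatinine comes from: ``"sample_sheet"`` uses
    the externally measured per-sample value from the metadata, while
    ``"peak_table"`` consumes the table's own creatinine feature (removing it
    from the result).  A missing or non-positive creatinine value is rejected
    naming the sample.
    """
    if table.normalization_state is not NormalizationState.IS_NORMALIZED:
        raise UrimexError(
            "creatinine normalization requires an IS-normalized table, got "
            f"state {table.normalization_state.value!r}"
        )
    data = table.data
    if source == "sample_sheet":
        if meta is None:
            raise UrimexError("sample metadata required for sample_sheet source")
        by_id = {m.sample_id: m for m in meta}
        values = []
        for sid in table.sample_ids:
            m = by_id.get(sid)
            if m is None or m.creatinine_value is None:
                raise UrimexError(
                    f"sample {sid!r}: no creatinine value in the sample sheet"
                )
            values.append(m.creatinine_value)
        creatinine = np.asarray(values, dtype=float)
    elif source == "peak_table":
        col = table.resolve_compound(creatinine_compound)
        creatinine = data[col].to_numpy(dtype=float)
        bad = [
            sid for sid, v in zip(table.sample_ids, creatinine) if not v > 0
        ]
        if bad:
            raise UrimexError(
                f"creatinine feature is zero in sample(s) {bad}; cannot normalize"
            )
        data = data.drop(columns=[col])
    else:
        raise UrimexError(
            f"unknown creatinine source {source!r} "
            "(expected 'sample_sheet' or 'peak_table')"
        )
    normalized = data.div(creatinine, axis=0)
    return PeakTable(normalized, NormalizationState.IS_AND_CREATININE_NORMALIZED)


def normalize_pipeline(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    cfg: StudyConfig | None = None,
) -> PeakTable:
    """Apply the full two-step normalization as configured."""
    cfg = cfg or StudyConfig()
    out = normalize_by_internal_standard(table, cfg.internal_standard_name)
    return normalize_by_creatinine(
        out, meta, source=cfg.creatinine_source,
        creatinine_compound=cfg.creatinine_compound,
    )
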