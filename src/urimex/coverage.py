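"""Metabolome coverage: detection calls, % undetected, unique-compound sets.

A compound counts as detected for a method when it is nonzero in at least a
configurable fraction of that method's pre-spike replicates (default 0.5,
i.e. at least half).  The compound universe is data-defined: the union of all
methods' detections, reported alongside every percentage rather than assumed
to be a fixed size.  Coverage statistics:

``percent_undetected``
    100 x (universe size - detected) / universe size, per method (lower is
    better coverage).
``unique_compounds``
    compounds only one method detects.
``unique_to_group``
    compounds some method of a group detects but no method outside it does
    (e.g. the organic-acid methods versus direct analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .peaktable_io import (
    PeakTable,
    SampleMeta,
    SpikeGroup,
    StudyConfig,
    UniqueCompoundLists,
    UrimexError,
    samples_for,
)

__all__ = [
    "DetectionMatrix",
    "CoverageResult",
    "build_detection_matrix",
    "percent_undetected",
    "unique_compounds",
    "unique_to_group",
    "coverage_result",
    "detection_matrix_from_unique_lists",
    "write_detection_matrix",
]


@dataclass(frozen=True)
class DetectionMatrix:
    """Method x compound boolean detection calls over a compound universe."""

    detected: pd.DataFrame  # bool, index = methods, columns = universe
    detection_fraction: float | str

    def __post_init__(self) -> None:
        df = self.detected.astype(bool)
        # universe is the union of detections: every compound seen somewhere
        orphan = df.columns[~df.any(axis=0)]
        if len(orphan):
            raise UrimexError(
                f"universe contains compounds detected by no method: "
                f"{list(orphan[:5])}"
            )
        object.__setattr__(self, "detected", df)

    @property
    def methods(self) -> list[str]:
        return list(self.detected.index)

    @property
    def universe(self) -> list[str]:
        return list(self.detected.columns)

    @property
    def n_total(self) -> int:
        return self.detected.shape[1]

    def detected_set(self, method: str) -> set[str]:
        self._check(method)
        row = self.detected.loc[method]
        return set(row.index[row])

    def _check(self, method: str) -> None:
        if method not in self.detected.index:
            raise UrimexError(f"unknown method {method!r}")


@dataclass(frozen=True)
class CoverageResult:
    n_total: int
    percent_undetected: Mapping[str, float]
    unique_by_method: Mapping[str, frozenset[str]]
    group_unique: Mapping[str, frozenset[str]]


def build_detection_matrix(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    cfg: StudyConfig | None = None,
    methods: Sequence[str] | None = None,
) -> DetectionMatrix:
    """Call detections per method from its pre-spike replicates.

    A compound is detected when its nonzero fraction across the method's
    pre-spike samples reaches ``cfg.detection_fraction``; with the ``"any"``
    rule a single nonzero replicate suffices (the literal zero-average
    criterion).  Methods without pre-spike samples fall back to all of their
    samples (spike-less treatment designs).  Compounds no method detects are
    dropped, so the universe is exactly the union of detections.
    """
    cfg = cfg or StudyConfig()
    if table.n_samples == 0 or table.n_compounds == 0:
        raise UrimexError("empty peak table")
    if methods is None:
        methods = list(dict.fromkeys(m.method_label for m in meta))
    if not methods:
        raise UrimexError("no methods in the sample metadata")
    rows = {}
    for label in methods:
        selected = samples_for(meta, label, SpikeGroup.PRE)
        if not selected:
            selected = samples_for(meta, label, None)
        if not selected:
            raise UrimexError(f"method {label!r} has no samples")
        sub = table.subset_samples([m.sample_id for m in selected])
        nonzero_fraction = (sub.intensities > 0).mean(axis=0)
        if cfg.detection_fraction == "any":
            called = nonzero_fraction > 0
        else:
            called = nonzero_fraction >= cfg.detection_fraction
        rows[label] = called
    detected = pd.DataFrame.from_dict(
        rows, orient="index", columns=table.compound_ids
    )
    detected = detected.loc[:, detected.any(axis=0)]
    return DetectionMatrix(detected, cfg.detection_fraction)


def percent_undetected(dm: DetectionMatrix, method: str) -> float:
    """100 x (compounds in the universe the method misses) / universe size."""
    dm._check(method)
    n_detected = int(dm.detected.loc[method].sum())
    return 100.0 * (dm.n_total - n_detected) / dm.n_total


def unique_compounds(dm: DetectionMatrix, method: str) -> set[str]:
    """Compounds detected by this method and by no other."""
    dm._check(method)
    counts = dm.detected.sum(axis=0)
    mine = dm.detected.loc[method]
    only_mine = mine & (counts == 1)
    return set(only_mine.index[only_mine])


def unique_to_group(
    dm: DetectionMatrix, group: Sequence[str], others: Sequence[str]
) -> set[str]:
    """Compounds detected by >= 1 group method and by no method in ``others``."""
    group, others = list(group), list(others)
    if not group or not others:
        raise UrimexError("group and others must both be non-empty")
    if set(group) & set(others):
        raise UrimexError("group and others must be disjoint")
    for label in (*group, *others):
        dm._check(label)
    in_group = dm.detected.loc[group].any(axis=0)
    in_others = dm.detected.loc[others].any(axis=0)
    hit = in_group & ~in_others
    return set(hit.index[hit])


def coverage_result(
    dm: DetectionMatrix,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> CoverageResult:
    """Assemble the full coverage summary, optionally with group-unique sets.

    ``groups`` maps a label to the member methods; the complement within the
    matrix serves as the out-group.
    """
    pu = {m: percent_undetected(dm, m) for m in dm.methods}
    uniq = {m: frozenset(unique_compounds(dm, m)) for m in dm.methods}
    group_unique = {}
    for label, members in (groups or {}).items():
        others = [m for m in dm.methods if m not in members]
        group_unique[label] = frozenset(unique_to_group(dm, members, others))
    return CoverageResult(dm.n_total, pu, uniq, group_unique)


def detection_matrix_from_unique_lists(
    lists: UniqueCompoundLists,
    n_shared_core: int = 71,
    target_universe: int | None = 220,
) -> DetectionMatrix:
    """Reconstruct a detection matrix consistent with published unique lists.

    Each per-method unique compound is detected only by its method.  The
    remaining group-list compounds (detected by some organic-acid method but
    never by direct analysis) are detected by every group method.  A shared
    core of ``n_shared_core`` synthetic compounds detected by all methods
    pads the universe to ``target_universe`` when that is consistent.

    Two reconciliations of the published lists are applied: ``lists.aliases``
    maps naming variants in the group list to the per-method spelling of the
    same feature, and a name appearing in both the group list and an
    out-group method's unique list is treated as two distinct chromatographic
    features (the group-side copy gets a disambiguating suffix).
    """
    methods = list(lists.methods)
    group_methods = list(lists.group_methods)
    out_methods = [m for m in methods if m not in group_methods]
    unique_owner: dict[str, str] = {}
    for m, compounds in lists.methods.items():
        for c in compounds:
            unique_owner[c] = m
    columns: dict[str, set[str]] = {}  # compound -> detecting methods
    for c, m in unique_owner.items():
        columns[c] = {m}
    for raw_name in lists.group:
        name = lists.aliases.get(raw_name, raw_name)
        owner = unique_owner.get(name)
        if owner is not None and owner in group_methods:
            continue  # already placed as that method's unique compound
        if owner is not None:  # collides with an out-group unique compound
            name = f"{raw_name} ({lists.group_label})"
        columns[name] = set(group_methods)
    n_core = n_shared_core
    if target_universe is not None:
        n_core = target_universe - len(columns)
        if n_core < 0:
            raise UrimexError(
                f"target universe {target_universe} smaller than the "
                f"{len(columns)} listed compounds"
            )
    for i in range(n_core):
        columns[f"Shared {i + 1:03d}"] = set(methods)
    detected = pd.DataFrame(
        {c: [m in owners for m in methods] for c, owners in columns.items()},
        index=methods,
    )
    return DetectionMatrix(detected, 0.5)


def write_detection_matrix(dm: DetectionMatrix, path: str | Path) -> Path:
    """Export the detection calls as long CSV (one row per method x compound)."""
    path = Path(path)
    long = (
        dm.detected.rename_axis(index="Method", columns="Compound")
        .stack()
        .rename("Detected")
        .reset_index()
    )
    long["Detected"] = long["Detected"].astype(int)
    long.to_csv(path, index=False)
    return path
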