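"""Peak tables, sample sheets and spike mixtures: domain types, CSV I/O, fixtures.

The central exchange object is :class:`PeakTable`, a sample x compound matrix of
non-negative peak areas.  Absence of a compound in a sample is encoded as
exactly 0 — deconvolution software exports either an empty cell or a zero, and
every downstream statistic (detection calls, CV, recovery averages) treats the
two identically.

Two CSV dialects are supported.  Long form is canonical::

    Sample,Compound,Area
    M1_pre_1,Citric acid,0.57

Wide form has one column per compound with the sample id first.  Sample and
compound order is first-appearance order and survives a write/read round trip
bit-exactly.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationState",
    "SpikeGroup",
    "CompoundClass",
    "PeakTable",
    "SampleMeta",
    "SpikeEntry",
    "SpikeMixture",
    "StudyConfig",
    "UrimexError",
    "DEFAULT_INTERNAL_STANDARD",
    "read_peak_table",
    "write_peak_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_spike_mixture",
    "write_spike_mixture",
    "default_spike_mixture",
    "load_fixture",
    "UniqueCompoundLists",
    "RankFixture",
    "samples_for",
]

#: Internal-standard compound added to every sample at 50 ppm.
DEFAULT_INTERNAL_STANDARD = "3-phenylbutyric acid"


class UrimexError(ValueError):
    """Base error for invalid inputs or contract violations."""


class NormalizationState(str, enum.Enum):
    RAW = "raw"
    IS_NORMALIZED = "is_normalized"
    IS_AND_CREATININE_NORMALIZED = "is_and_creatinine_normalized"


class SpikeGroup(str, enum.Enum):
    PRE = "pre"
    POST = "post"
    NONE = "none"


class CompoundClass(str, enum.Enum):
    AMINO_ACID = "amino_acid"
    ORGANIC_ACID = "organic_acid"
    FATTY_ACID = "fatty_acid"


def _canon(name: str) -> str:
    return name.strip().casefold()


@dataclass(frozen=True)
class PeakTable:
    """Sample x compound matrix of peak areas with a normalization state flag.

    ``data`` is a pandas DataFrame indexed by sample id with one column per
    compound.  All values are finite and >= 0; after normalization they are
    dimensionless ratios.
    """

    data: pd.DataFrame
    normalization_state: NormalizationState = NormalizationState.RAW

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise UrimexError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise UrimexError(f"duplicate compound ids: {dupes}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise UrimexError("peak table contains non-finite intensities")
        if values.size and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise UrimexError(
                f"negative intensity at sample {df.index[i]!r}, "
                f"compound {df.columns[j]!r}: {values[i, j]}"
            )
        object.__setattr__(self, "data", df.astype(float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def intensities(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.data.shape[1]

    def resolve_compound(self, name: str) -> str:
        """Return the stored compound id matching ``name``.

        Matching is case-insensitive after whitespace trimming; no fuzzy
        matching — an ambiguous or missing name raises.
        """
        wanted = _canon(name)
        hits = [c for c in self.data.columns if _canon(c) == wanted]
        if not hits:
            raise UrimexError(f"compound {name!r} not present in the peak table")
        if len(hits) > 1:
            raise UrimexError(f"compound name {name!r} is ambiguous: {hits}")
        return hits[0]

    def has_compound(self, name: str) -> bool:
        wanted = _canon(name)
        return any(_canon(c) == wanted for c in self.data.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise UrimexError(f"unknown sample ids: {missing}")
        return replace(self, data=self.data.loc[list(sample_ids)])


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: method arm, spike group, replicate, tags, creatinine."""

    sample_id: str
    method_label: str
    spike_group: SpikeGroup = SpikeGroup.NONE
    replicate: int = 1
    treatment_tags: frozenset[str] = frozenset()
    creatinine_value: float | None = None

    def __post_init__(self) -> None:
        if self.replicate <= 0:
            raise UrimexError(
                f"sample {self.sample_id!r}: replicate must be positive, "
                f"got {self.replicate}"
            )
        if self.creatinine_value is not None:
            if not math.isfinite(self.creatinine_value) or self.creatinine_value <= 0:
                raise UrimexError(
                    f"sample {self.sample_id!r}: creatinine value must be positive, "
                    f"got {self.creatinine_value}"
                )
        object.__setattr__(self, "treatment_tags", frozenset(self.treatment_tags))


@dataclass(frozen=True)
class SpikeEntry:
    compound: str
    compound_class: CompoundClass
    concentration_ppm: float

    def __post_init__(self) -> None:
        if not self.concentration_ppm > 0:
            raise UrimexError(
                f"spike compound {self.compound!r}: concentration must be > 0"
            )


@dataclass(frozen=True)
class SpikeMixture:
    """Known-compound spiking solution used for recovery scoring."""

    entries: tuple[SpikeEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        names = [_canon(e.compound) for e in entries]
        if len(set(names)) != len(names):
            raise UrimexError("spike mixture contains duplicate compound names")
        object.__setattr__(self, "entries", entries)

    @property
    def compounds(self) -> list[str]:
        return [e.compound for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class StudyConfig:
    """Tunable study-level parameters with the evaluation's defaults.

    cv_threshold
        Repeatability cut-off in percent; a method is scored by the share of
        detected compounds with CV strictly below it.
    detection_fraction
        Fraction of a method's replicates in which a compound must be nonzero
        to count as detected (0.5 = at least half).  The string ``"any"``
        selects the literal zero-average rule: one nonzero replicate suffices.
    creatinine_source
        Where per-sample creatinine comes from: the sample sheet (an external
        measurement) or the peak table's own creatinine feature.
    """

    internal_standard_name: str = DEFAULT_INTERNAL_STANDARD
    cv_threshold: float = 50.0
    detection_fraction: float | str = 0.5
    creatinine_source: str = "sample_sheet"  # or "peak_table"
    creatinine_compound: str = "Creatinine"

    def __post_init__(self) -> None:
        if not self.cv_threshold > 0:
            raise UrimexError("cv_threshold must be > 0")
        if isinstance(self.detection_fraction, str):
            if self.detection_fraction != "any":
                raise UrimexError(
                    "detection_fraction must be a fraction in (0, 1] or 'any'"
                )
        elif not (0 < self.detection_fraction <= 1):
            raise UrimexError("detection_fraction must lie in (0, 1]")
        if self.creatinine_source not in ("sample_sheet", "peak_table"):
            raise UrimexError(
                "creatinine_source must be 'sample_sheet' or 'peak_table'"
            )


# ---------------------------------------------------------------------------
# peak table I/O

def _finalize_matrix(df: pd.DataFrame) -> pd.DataFrame:
    df = df.apply(pd.to_numeric)
    return df.fillna(0.0)


def read_peak_table(path: str | Path, dialect: str = "long") -> PeakTable:
    """Read a peak-table CSV in ``long`` or ``wide`` dialect.

    Missing or empty cells become 0 (not detected).  Negative areas and
    duplicate records are rejected.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(
            path, dtype={"Sample": str, "Compound": str},
            float_precision="round_trip",
        )
        expected = ["Sample", "Compound", "Area"]
        if list(df.columns[:3]) != expected:
            raise UrimexError(
                f"long peak table must start with columns {expected}, "
                f"got {list(df.columns)}"
            )
        dup = df.duplicated(subset=["Sample", "Compound"])
        if dup.any():
            row = df[dup].iloc[0]
            raise UrimexError(
                f"duplicate record for sample {row['Sample']!r}, "
                f"compound {row['Compound']!r}"
            )
        neg = pd.to_numeric(df["Area"]).fillna(0.0) < 0
        if neg.any():
            row = df[neg].iloc[0]
            raise UrimexError(
                f"negative area at sample {row['Sample']!r}, "
                f"compound {row['Compound']!r}: {row['Area']}"
            )
        samples = list(dict.fromkeys(df["Sample"]))
        compounds = list(dict.fromkeys(df["Compound"]))
        wide = df.pivot(index="Sample", columns="Compound", values="Area")
        wide = wide.reindex(index=samples, columns=compounds)
        matrix = _finalize_matrix(wide)
        matrix.index.name = None
        matrix.columns.name = None
    elif dialect == "wide":
        df = pd.read_csv(path, float_precision="round_trip")
        first = df.columns[0]
        if first != "Sample":
            raise UrimexError(
                f"wide peak table must have first column 'Sample', got {first!r}"
            )
        samples = df[first].astype(str)
        if samples.duplicated().any():
            dupes = samples[samples.duplicated()].unique().tolist()
            raise UrimexError(f"duplicate sample id in wide table: {dupes}")
        matrix = df.set_index(first).pipe(_finalize_matrix)
        matrix.index = matrix.index.astype(str)
        matrix.index.name = None
    else:
        raise UrimexError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")
    state = _read_sidecar_state(path)
    return PeakTable(matrix, state)


def write_peak_table(
    table: PeakTable, path: str | Path, dialect: str = "long"
) -> Path:
    """Write a peak table CSV plus a small JSON sidecar with the state flag."""
    path = Path(path)
    if dialect == "long":
        long = (
            table.data.rename_axis(index="Sample", columns="Compound")
            .stack()
            .rename("Area")
            .reset_index()
        )
        # keep first-appearance order of samples then compounds
        long["Sample"] = pd.Categorical(
            long["Sample"], categories=table.sample_ids, ordered=True
        )
        long["Compound"] = pd.Categorical(
            long["Compound"], categories=table.compound_ids, ordered=True
        )
        long = long.sort_values(["Sample", "Compound"], kind="stable")
        long.to_csv(path, index=False)
    elif dialect == "wide":
        table.data.rename_axis(index="Sample").to_csv(path)
    else:
        raise UrimexError(f"unknown dialect {dialect!r}")
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"normalization_state": table.normalization_state.value}) + "\n"
    )
    return path


def _read_sidecar_state(path: Path) -> NormalizationState:
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return NormalizationState(meta["normalization_state"])
    return NormalizationState.RAW


# ---------------------------------------------------------------------------
# sample sheet I/O

_SHEET_COLUMNS = ["Sample", "Method", "SpikeGroup", "Replicate", "Tags", "Creatinine"]


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read a sample sheet CSV (one :class:`SampleMeta` per row).

    ``Tags`` is split on ``;``; a blank ``Creatinine`` cell means absent; the
    spike-group token is parsed case-insensitively.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != _SHEET_COLUMNS:
        raise UrimexError(
            f"sample sheet must have columns {_SHEET_COLUMNS}, got {list(df.columns)}"
        )
    metas = []
    for _, row in df.iterrows():
        token = row["SpikeGroup"].strip().lower()
        if token == "":
            token = "none"
        try:
            group = SpikeGroup(token)
        except ValueError:
            raise UrimexError(
                f"sample {row['Sample']!r}: unknown spike group "
                f"{row['SpikeGroup']!r}"
            ) from None
        tags = frozenset(t.strip() for t in row["Tags"].split(";") if t.strip())
        creat = row["Creatinine"].strip()
        metas.append(
            SampleMeta(
                sample_id=row["Sample"],
                method_label=row["Method"],
                spike_group=group,
                replicate=int(row["Replicate"]),
                treatment_tags=tags,
                creatinine_value=float(creat) if creat else None,
            )
        )
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise UrimexError("sample sheet contains duplicate sample ids")
    return metas


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for m in metas:
        rows.append(
            {
                "Sample": m.sample_id,
                "Method": m.method_label,
                "SpikeGroup": m.spike_group.value,
                "Replicate": m.replicate,
                "Tags": ";".join(sorted(m.treatment_tags)),
                "Creatinine": "" if m.creatinine_value is None else m.creatinine_value,
            }
        )
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, index=False)
    return path


def samples_for(
    metas: Iterable[SampleMeta],
    method_label: str,
    spike_group: SpikeGroup | str | None = None,
) -> list[SampleMeta]:
    """Select the metadata rows of one method arm, optionally one spike group."""
    if spike_group is not None:
        spike_group = SpikeGroup(spike_group)
    return [
        m
        for m in metas
        if m.method_label == method_label
        and (spike_group is None or m.spike_group == spike_group)
    ]


# ---------------------------------------------------------------------------
# spike mixture I/O

def read_spike_mixture(path: str | Path) -> SpikeMixture:
    df = pd.read_csv(path, dtype={"Compound": str, "Class": str})
    expected = ["Compound", "Class", "Concentration_ppm"]
    if list(df.columns) != expected:
        raise UrimexError(
            f"spike mixture must have columns {expected}, got {list(df.columns)}"
        )
    entries = tuple(
        SpikeEntry(
            compound=row["Compound"],
            compound_class=CompoundClass(row["Class"].strip().lower()),
            concentration_ppm=float(row["Concentration_ppm"]),
        )
        for _, row in df.iterrows()
    )
    return SpikeMixture(entries)


def write_spike_mixture(spike: SpikeMixture, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "Compound": [e.compound for e in spike],
            "Class": [e.compound_class.value for e in spike],
            "Concentration_ppm": [e.concentration_ppm for e in spike],
        }
    ).to_csv(path, index=False)
    return path


def default_spike_mixture() -> SpikeMixture:
    """The study's 10-compound spiking solution, everything at 50 ppm.

    Six amino acids, three organic acids and one fatty acid — three compound
    classes so that class-specific extraction bias shows up in recovery.
    """
    aa, oa, fa = (
        CompoundClass.AMINO_ACID,
        CompoundClass.ORGANIC_ACID,
        CompoundClass.FATTY_ACID,
    )
    names = [
        ("4-Aminobutyric acid (GABA)", aa),
        ("L-Alanine", aa),
        ("L-Leucine", aa),
        ("L-Phenylalanine", aa),
        ("L-Tryptophan", aa),
        ("L-Tyrosine", aa),
        ("Ascorbic acid", oa),
        ("Citric acid", oa),
        ("Succinic acid", oa),
        ("Palmitic acid", fa),
    ]
    return SpikeMixture(
        tuple(SpikeEntry(n, c, 50.0) for n, c in names)
    )


# ---------------------------------------------------------------------------
# in-package reference fixtures

@dataclass(frozen=True)
class UniqueCompoundLists:
    """Published unique-compound lists: per-method sets plus the OA-group set.

    ``aliases`` maps naming variants in the group list onto the per-method
    spelling of the same feature (the group list reports malonic acid under
    its diethyl-ester derivative name).
    """

    methods: Mapping[str, tuple[str, ...]]
    group: tuple[str, ...]
    group_label: str
    group_methods: tuple[str, ...]
    aliases: Mapping[str, str]


@dataclass(frozen=True)
class RankFixture:
    """A published rank matrix: methods x criteria, with the printed rank sums."""

    criteria: tuple[str, ...]
    ranks: pd.DataFrame  # index = method labels, columns = criteria
    printed_cumulative: Mapping[str, int]


_FIXTURE_NAMES = (
    "table1_unique_lists",
    "table2_recovery",
    "table3_ranks",
    "table4_ranks",
    "table5_ranks",
)


def _data_path(name: str):
    return resources.files("urimex.data").joinpath(name)


def load_fixture(name: str):
    """Load one of the bundled reference fixtures.

    ``table1_unique_lists``
        :class:`UniqueCompoundLists` of per-method unique compounds.
    ``table2_recovery``
        DataFrame with columns Compound, Class, Method, PreAverage,
        PostAverage, RecoveryPercent (10 spike compounds x 5 methods).
    ``table3_ranks`` / ``table4_ranks`` / ``table5_ranks``
        :class:`RankFixture` rank matrices of the Part-A and Part-B designs.
    """
    if name == "table1_unique_lists":
        raw = json.loads(_data_path("table1_unique_compounds.json").read_text())
        return UniqueCompoundLists(
            methods={k: tuple(v) for k, v in raw["methods"].items()},
            group=tuple(raw["group"]),
            group_label=raw["group_label"],
            group_methods=tuple(raw["group_methods"]),
            aliases=dict(raw["aliases"]),
        )
    if name == "table2_recovery":
        with resources.as_file(_data_path("table2_recovery.csv")) as p:
            return pd.read_csv(p)
    if name in ("table3_ranks", "table4_ranks", "table5_ranks"):
        raw = json.loads(_data_path(f"{name}.json").read_text())
        ranks = pd.DataFrame.from_dict(
            raw["ranks"], orient="index", columns=raw["criteria"]
        )
        return RankFixture(
            criteria=tuple(raw["criteria"]),
            ranks=ranks,
            printed_cumulative=dict(raw["printed_cumulative"]),
        )
    raise UrimexError(f"unknown fixture {name!r} (expected one of {_FIXTURE_NAMES})")
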