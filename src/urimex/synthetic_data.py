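"""Synthetic GC-MS peak-table generator emulating the extraction-method study.

The generator draws a panel of endogenous urinary compounds once per study
(lognormal abundances, class-labelled), then produces per-sample peak areas

    observed = (endogenous x class recovery x censoring + spike) x noise

where the multiplicative noise is mean-one lognormal with a configurable
replicate CV, and censoring sets a compound to a hard zero with probability
1 - detection probability (class-resolved), mirroring the missing-as-zero
convention of the I/O layer.

The pre/post spike design is encoded directly: pre-spike samples receive the
spiking mixture *before* extraction, so the spike signal is multiplied by the
method's class recovery; post-spike samples receive it afterwards at full
strength.  This makes the true recovery identifiable as the pre/post ratio.
Spike compounds have no endogenous background by default, so the noise-free
estimate equals the configured recovery exactly.

Special channels: an internal-standard feature at a fixed level, a creatinine
feature (with between-sample spread, also written to the sample sheet as the
external measurement) and a high-abundance urea feature that urease or
drying arms attenuate (optionally with a collateral attenuation of all
endogenous signals, emulating the global signal loss urease causes).

Everything is driven by one ``numpy.random.default_rng(seed)``; an identical
seed gives a bit-identical study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .peaktable_io import (
    DEFAULT_INTERNAL_STANDARD,
    NormalizationState,
    PeakTable,
    SampleMeta,
    SpikeGroup,
    SpikeMixture,
    UrimexError,
    default_spike_mixture,
)

__all__ = [
    "MethodProfile",
    "SimulationConfig",
    "SimulationResult",
    "GroundTruth",
    "simulate_study",
    "ground_truth",
    "part_a_profiles",
    "part_a_config",
    "urease_profiles",
    "urease_config",
    "UREA", "CREATININE",
]

UREA = "Urea"
CREATININE = "Creatinine"

#: Endogenous panel: compound count per class (default desk-scale study).
DEFAULT_CLASS_COUNTS: Mapping[str, int] = {
    "amino_acid": 30,
    "organic_acid": 60,
    "fatty_acid": 20,
    "sugar": 50,
    "other": 40,
}


@dataclass(frozen=True)
class MethodProfile:
    """Generative description of one extraction method / treatment arm.

    recovery_fraction_by_class
        Fraction of an analyte's amount surviving extraction, per compound
        class (1.0 = lossless).  Classes absent from the map fall back to
        ``default_recovery``.
    detection_probability
        Probability that a nonzero extracted signal is actually called by
        deconvolution, scalar or per class — low values emulate censoring
        near the detection limit.
    replicate_cv
        Multiplicative lognormal noise level between replicate injections
        (0.1 = 10% CV).
    artifact_rate
        Expected number of spurious method-specific compounds (Poisson),
        e.g. reagent artifacts only this method produces.
    urea_attenuation
        Multiplier on the urea channel (urease or extra-drying arms < 1).
    collateral_attenuation
        Multiplier applied to ALL endogenous signals (urease reduces overall
        metabolic signal, not just urea).
    """

    label: str
    recovery_fraction_by_class: Mapping[str, float] = field(default_factory=dict)
    default_recovery: float = 0.5
    detection_probability: float | Mapping[str, float] = 0.9
    replicate_cv: float = 0.2
    artifact_rate: float = 0.0
    urea_attenuation: float = 1.0
    collateral_attenuation: float = 1.0
    treatment_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for cls, frac in {**self.recovery_fraction_by_class,
                          "<default>": self.default_recovery}.items():
            if not (0.0 <= frac <= 1.0):
                raise UrimexError(
                    f"profile {self.label!r}: recovery fraction for {cls} "
                    f"must lie in [0, 1], got {frac}"
                )
        probs = (
            self.detection_probability.values()
            if isinstance(self.detection_probability, Mapping)
            else [self.detection_probability]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise UrimexError(
                f"profile {self.label!r}: detection probabilities must lie in [0, 1]"
            )
        if not self.replicate_cv >= 0:
            raise UrimexError(f"profile {self.label!r}: replicate_cv must be >= 0")
        if self.artifact_rate < 0:
            raise UrimexError(f"profile {self.label!r}: artifact_rate must be >= 0")
        for name, v in (("urea_attenuation", self.urea_attenuation),
                        ("collateral_attenuation", self.collateral_attenuation)):
            if not (0.0 <= v <= 1.0):
                raise UrimexError(
                    f"profile {self.label!r}: {name} must lie in [0, 1], got {v}"
                )

    def recovery(self, compound_class: str) -> float:
        return self.recovery_fraction_by_class.get(
            compound_class, self.default_recovery
        )

    def detection_prob(self, compound_class: str) -> float:
        if isinstance(self.detection_probability, Mapping):
            return self.detection_probability.get(compound_class, 1.0)
        return self.detection_probability


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator settings (design sizes, abundances, channels)."""

    profiles: tuple[MethodProfile, ...]
    seed: int
    n_compounds_per_class: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    base_abundance_median: float = 1.0
    base_abundance_sigma: float = 1.0  # lognormal dispersion, ln units
    spike: SpikeMixture = field(default_factory=default_spike_mixture)
    spike_signal_per_50ppm: float = 1.0  # area units a 50 ppm spike adds
    internal_standard_level: float = 1.0
    internal_standard_name: str = DEFAULT_INTERNAL_STANDARD
    creatinine_level: float = 1.0
    creatinine_sigma: float = 0.2  # between-sample spread, ln units
    urea_level: float = 50.0  # urea dominates untreated urine profiles
    replicates_per_group: int = 3
    spike_groups: bool = True  # pre/post design; False = plain replicate arms

    def __post_init__(self) -> None:
        if not self.profiles:
            raise UrimexError("at least one method profile is required")
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise UrimexError("duplicate profile labels")
        if any(n < 1 for n in self.n_compounds_per_class.values()):
            raise UrimexError("compound counts per class must be >= 1")
        if self.replicates_per_group < 1:
            raise UrimexError("replicates_per_group must be >= 1")
        if self.seed is None:
            raise UrimexError("a seed is mandatory for any stochastic run")
        object.__setattr__(self, "profiles", tuple(self.profiles))


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed for parameter-recovery assertions."""

    compound_classes: Mapping[str, str]
    true_levels: Mapping[str, float]  # endogenous level per compound
    true_recovery: Mapping[str, Mapping[str, float]]  # method -> compound -> frac
    expected_pre_signal: pd.DataFrame  # method x compound, noise/censoring-free
    true_detection_sets: Mapping[str, frozenset[str]]
    urea_attenuation: Mapping[str, float]


@dataclass(frozen=True)
class SimulationResult:
    table: PeakTable
    meta: tuple[SampleMeta, ...]
    truth: GroundTruth


def ground_truth(result: SimulationResult) -> GroundTruth:
    """Expose the generator's ground-truth record for a simulated study."""
    return result.truth


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with E[noise] = 1 and CV exactly ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(size) - 0.5 * sigma * sigma)


def simulate_study(cfg: SimulationConfig) -> SimulationResult:
    """Generate a raw peak table, sample sheet and ground-truth record."""
    rng = np.random.default_rng(cfg.seed)

    # --- compound panel (drawn once per study) -----------------------------
    classes: dict[str, str] = {}
    levels: dict[str, float] = {}
    idx = 1
    for cls, count in cfg.n_compounds_per_class.items():
        for _ in range(count):
            name = f"Analyte {idx:03d}"
            classes[name] = cls
            levels[name] = cfg.base_abundance_median * float(
                np.exp(cfg.base_abundance_sigma * rng.standard_normal())
            )
            idx += 1
    classes[UREA] = "urea"
    levels[UREA] = cfg.urea_level
    spike_names = []
    for entry in cfg.spike:
        classes[entry.compound] = entry.compound_class.value
        levels.setdefault(entry.compound, 0.0)  # exogenous by default
        spike_names.append(entry.compound)
    spike_signal = {
        e.compound: cfg.spike_signal_per_50ppm * e.concentration_ppm / 50.0
        for e in cfg.spike
    }
    artifacts: dict[str, list[str]] = {}
    for profile in cfg.profiles:
        k = int(rng.poisson(profile.artifact_rate))
        names = [f"{profile.label} artifact {j + 1:02d}" for j in range(k)]
        artifacts[profile.label] = names
        for name in names:
            classes[name] = "artifact"
            levels[name] = cfg.base_abundance_median * float(
                np.exp(cfg.base_abundance_sigma * rng.standard_normal())
            )
    classes[CREATININE] = "creatinine"
    compounds = (
        [c for c in levels if classes[c] not in ("artifact",)]
        + [a for p in cfg.profiles for a in artifacts[p.label]]
        + [CREATININE, cfg.internal_standard_name]
    )

    groups = (
        [SpikeGroup.PRE, SpikeGroup.POST] if cfg.spike_groups else [SpikeGroup.NONE]
    )

    # --- per-sample generation --------------------------------------------
    rows: list[np.ndarray] = []
    metas: list[SampleMeta] = []
    n_analytes = len(compounds) - 2  # everything but creatinine + IS
    analyte_names = compounds[:n_analytes]
    base_level = np.array([levels[c] for c in analyte_names])
    analyte_class = [classes[c] for c in analyte_names]
    for profile in cfg.profiles:
        rec = np.array([profile.recovery(cls) for cls in analyte_class])
        det = np.array([profile.detection_prob(cls) for cls in analyte_class])
        atten = np.full(n_analytes, profile.collateral_attenuation)
        atten[analyte_names.index(UREA)] *= profile.urea_attenuation
        own = set(artifacts[profile.label])
        artifact_mask = np.array(
            [1.0 if (classes[c] != "artifact" or c in own) else 0.0
             for c in analyte_names]
        )
        spike_pre = np.array(
            [spike_signal.get(c, 0.0) * profile.recovery(classes[c])
             * profile.collateral_attenuation
             for c in analyte_names]
        )
        spike_post = np.array(
            [spike_signal.get(c, 0.0) for c in analyte_names]
        )
        for group in groups:
            for rep in range(1, cfg.replicates_per_group + 1):
                sid = f"{profile.label}_{group.value}_{rep}"
                endo = base_level * rec * atten * artifact_mask
                censor = rng.random(n_analytes) < det
                signal = endo * censor
                if group is SpikeGroup.PRE:
                    signal = signal + spike_pre
                elif group is SpikeGroup.POST:
                    signal = signal + spike_post
                noise = _mean_one_lognormal(rng, profile.replicate_cv, n_analytes)
                observed = signal * noise
                creat_true = cfg.creatinine_level * float(
                    np.exp(cfg.creatinine_sigma * rng.standard_normal())
                )
                creat_area = (
                    creat_true
                    * profile.recovery("creatinine")
                    * profile.collateral_attenuation
                    * float(_mean_one_lognormal(rng, profile.replicate_cv, 1)[0])
                )
                if rng.random() >= profile.detection_prob("creatinine"):
                    creat_area = 0.0
                is_area = cfg.internal_standard_level * float(
                    _mean_one_lognormal(rng, profile.replicate_cv, 1)[0]
                )
                rows.append(np.concatenate([observed, [creat_area, is_area]]))
                metas.append(
                    SampleMeta(
                        sample_id=sid,
                        method_label=profile.label,
                        spike_group=group,
                        replicate=rep,
                        treatment_tags=frozenset(profile.treatment_tags),
                        creatinine_value=creat_true,
                    )
                )
    table = PeakTable(
        pd.DataFrame(
            np.vstack(rows), index=[m.sample_id for m in metas], columns=compounds
        ),
        NormalizationState.RAW,
    )

    # --- ground truth -------------------------------------------------------
    expected = {}
    for profile in cfg.profiles:
        own = set(artifacts[profile.label])
        sig = {}
        for c in analyte_names:
            cls = classes[c]
            if cls == "artifact" and c not in own:
                sig[c] = 0.0
                continue
            atten = profile.collateral_attenuation
            if c == UREA:
                atten *= profile.urea_attenuation
            value = levels[c] * profile.recovery(cls) * atten
            if cfg.spike_groups:
                value += spike_signal.get(c, 0.0) * profile.recovery(cls) * \
                    profile.collateral_attenuation
            sig[c] = value
        # creatinine channel at its median level (sample-sheet normalization
        # leaves it in the table, so detection calls see it)
        sig[CREATININE] = (
            cfg.creatinine_level
            * profile.recovery("creatinine")
            * profile.collateral_attenuation
        )
        expected[profile.label] = sig
    expected_df = pd.DataFrame.from_dict(expected, orient="index")
    truth = GroundTruth(
        compound_classes=dict(classes),
        true_levels=dict(levels),
        true_recovery={
            p.label: {c: p.recovery(classes[c]) for c in spike_names}
            for p in cfg.profiles
        },
        expected_pre_signal=expected_df,
        true_detection_sets={
            p.label: frozenset(
                c for c, v in expected[p.label].items() if v > 0
            )
            for p in cfg.profiles
        },
        urea_attenuation={p.label: p.urea_attenuation for p in cfg.profiles},
    )
    return SimulationResult(table, tuple(metas), truth)


# ---------------------------------------------------------------------------
# study-shaped default designs

def part_a_profiles() -> tuple[MethodProfile, ...]:
    """Five-arm design: four organic-acid extraction variants + direct analysis.

    The organic-acid (OA) arms are biased toward organic and fatty acids with
    poor amino-acid/sugar recovery and detection; the direct-analysis arm is
    broad, with the lowest replicate noise.  The acetonitrile arm trades the
    best OA extraction efficiency for the largest replicate noise.
    """
    oa_recovery = {"amino_acid": 0.02, "organic_acid": 0.70, "fatty_acid": 0.65,
                   "sugar": 0.02, "other": 0.30, "urea": 0.6, "creatinine": 0.02}
    oa_detection = {"amino_acid": 0.10, "organic_acid": 0.80, "fatty_acid": 0.70,
                    "sugar": 0.05, "other": 0.45, "urea": 1.0, "creatinine": 0.1,
                    "artifact": 0.95}
    def oa(label, *, recovery_boost=0.0, cv, artifact_rate, detection_shift=0.0):
        rec = {k: min(1.0, v + (recovery_boost if k in ("organic_acid", "fatty_acid") else 0.0))
               for k, v in oa_recovery.items()}
        det = {k: float(np.clip(v + detection_shift, 0.0, 1.0))
               for k, v in oa_detection.items()}
        return MethodProfile(
            label=label, recovery_fraction_by_class=rec, default_recovery=0.3,
            detection_probability=det, replicate_cv=cv,
            artifact_rate=artifact_rate,
        )
    direct = MethodProfile(
        label="Method 5",
        recovery_fraction_by_class={
            "amino_acid": 0.50, "organic_acid": 0.90, "fatty_acid": 0.70,
            "sugar": 0.85, "other": 0.70, "urea": 1.0, "creatinine": 0.9,
            "artifact": 1.0,
        },
        default_recovery=0.7,
        detection_probability={
            "amino_acid": 0.90, "organic_acid": 0.90, "fatty_acid": 0.90,
            "sugar": 0.90, "other": 0.90, "urea": 1.0, "creatinine": 0.95,
            "artifact": 0.95,
        },
        replicate_cv=0.25,
        artifact_rate=5.0,
    )
    return (
        oa("Method 1", cv=0.45, artifact_rate=0.0, detection_shift=-0.10),
        oa("Method 2", recovery_boost=0.15, cv=0.70, artifact_rate=13.0,
           detection_shift=0.10),
        oa("Method 3", cv=0.40, artifact_rate=1.0, detection_shift=-0.05),
        oa("Method 4", recovery_boost=0.08, cv=0.40, artifact_rate=7.0,
           detection_shift=0.02),
        direct,
    )


def part_a_config(seed: int, **overrides) -> SimulationConfig:
    """Default Part-A study: 5 arms x (3 pre-spike + 3 post-spike) samples."""
    return SimulationConfig(profiles=part_a_profiles(), seed=seed, **overrides)


def urease_profiles() -> tuple[MethodProfile, ...]:
    """Urease pre-treatment design: UT/NT/WT x heating, UT/NT x sonication.

    All arms are direct-analysis-like; urease-treated (UT) arms attenuate
    urea tenfold but lose overall signal and repeatability, water-treated
    (WT) gains slightly from dilution.
    """
    base_rec = {"amino_acid": 0.50, "organic_acid": 0.90, "fatty_acid": 0.70,
                "sugar": 0.85, "other": 0.70, "urea": 1.0, "creatinine": 0.9}

    def arm(label, tags, *, urea, collateral, cv, det):
        return MethodProfile(
            label=label, recovery_fraction_by_class=base_rec,
            default_recovery=0.7, detection_probability=det, replicate_cv=cv,
            urea_attenuation=urea, collateral_attenuation=collateral,
            treatment_tags=tags,
        )

    return (
        arm("UT-H", ("urease", "heating"), urea=0.10, collateral=0.70,
            cv=0.40, det=0.70),
        arm("NT-H", ("heating",), urea=1.00, collateral=1.00, cv=0.30, det=0.85),
        arm("WT-H", ("water", "heating"), urea=0.95, collateral=1.00,
            cv=0.25, det=0.90),
        arm("UT-S", ("urease", "sonication"), urea=0.12, collateral=0.80,
            cv=0.33, det=0.78),
        arm("NT-S", ("sonication",), urea=1.00, collateral=1.00,
            cv=0.28, det=0.87),
    )


def urease_config(seed: int, **overrides) -> SimulationConfig:
    """Default Part-B urease study: 5 treatment arms with pre/post spikes."""
    return SimulationConfig(profiles=urease_profiles(), seed=seed, **overrides)
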