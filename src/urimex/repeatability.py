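"""Analytical repeatability: per-compound CV and a PCA scores view.

A method's repeatability is scored on its pre-spike replicates.  For each
compound the coefficient of variation (CV, sample standard deviation over the
mean, in percent) is computed across replicates; the method's score is the
percentage of detected compounds with CV strictly below the threshold
(default 50%) — the more, the better.

The PCA scores plot is the complementary multivariate view: tight per-method
clustering (a small 95% confidence ellipse) indicates a repeatable method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .peaktable_io import (
    PeakTable,
    SampleMeta,
    SpikeGroup,
    StudyConfig,
    UrimexError,
    samples_for,
)

__all__ = [
    "cv_percent",
    "RepeatabilityResult",
    "assess_repeatability",
    "GroupEllipse",
    "PCAResult",
    "pca_scores",
    "NoDetectedCompoundsError",
]


class NoDetectedCompoundsError(UrimexError):
    """All compounds are absent in every replicate of the arm."""


def cv_percent(values: Sequence[float]) -> float | None:
    """Coefficient of variation in percent, or None when the mean is zero.

    Uses the sample (n-1) standard deviation.  Requires at least two
    replicate measurements, all >= 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise UrimexError("CV requires at least 2 replicate values")
    if (arr < 0).any():
        raise UrimexError("CV is defined on non-negative peak areas")
    mean = arr.mean()
    if mean == 0:
        return None
    return 100.0 * arr.std(ddof=1) / mean


@dataclass(frozen=True)
class RepeatabilityResult:
    method_label: str
    cv_by_compound: Mapping[str, float]  # only compounds with defined CV
    n_detected: int
    percent_below_threshold: float
    threshold: float

    def __post_init__(self) -> None:
        if not (0 <= self.percent_below_threshold <= 100):
            raise UrimexError("percent_below_threshold must lie in [0, 100]")


def assess_repeatability(
    table: PeakTable,
    meta: Sequence[SampleMeta],
    method_label: str,
    cfg: StudyConfig | None = None,
    spike_group: SpikeGroup | str | None = SpikeGroup.PRE,
) -> RepeatabilityResult:
    """Score one method arm's repeatability on its replicate samples.

    By default the pre-spike replicates are used (the spiked compounds would
    otherwise contaminate the CV of endogenous features); pass
    ``spike_group=None`` for designs without spike groups to use all of the
    arm's samples.  Compounds with zero mean across the replicates have no
    defined CV and are excluded from the detected count.
    """
    cfg = cfg or StudyConfig()
    selected = samples_for(meta, method_label, spike_group)
    if len(selected) < 2:
        raise UrimexError(
            f"method {method_label!r} has {len(selected)} "
            f"{'' if spike_group is None else SpikeGroup(spike_group).value + '-spike '}"
            f"sample(s); repeatability needs at least 2 replicates"
        )
    sub = table.subset_samples([m.sample_id for m in selected])
    values = sub.intensities
    means = values.mean(axis=0)
    detected = means > 0
    if not detected.any():
        raise NoDetectedCompoundsError(
            f"method {method_label!r}: no detected compounds in its replicates"
        )
    sds = values.std(axis=0, ddof=1)
    cvs = {
        compound: 100.0 * sd / mean
        for compound, sd, mean, keep in zip(
            sub.compound_ids, sds, means, detected
        )
        if keep
    }
    n_detected = len(cvs)
    below = sum(1 for v in cvs.values() if v < cfg.cv_threshold)
    return RepeatabilityResult(
        method_label=method_label,
        cv_by_compound=cvs,
        n_detected=n_detected,
        percent_below_threshold=100.0 * below / n_detected,
        threshold=cfg.cv_threshold,
    )


# ---------------------------------------------------------------------------
# PCA scores view

@dataclass(frozen=True)
class GroupEllipse:
    """95% confidence region of a group's scores in the PC1-PC2 plane.

    The boundary is {x : (x - center)' cov^{-1} (x - center) = scale} with a
    Hotelling T-squared scale 2(n-1)/(n-2) * F_{0.95}(2, n-2).
    """

    center: np.ndarray  # shape (2,)
    covariance: np.ndarray  # shape (2, 2)
    scale: float
    n_samples: int

    @property
    def area(self) -> float:
        det = float(np.linalg.det(self.covariance))
        return float(np.pi * self.scale * np.sqrt(max(det, 0.0)))


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x components, columns PC1, PC2, ...
    explained_variance_fraction: np.ndarray
    loadings: pd.DataFrame  # compounds x components
    group_ellipses: Mapping[str, GroupEllipse]
    dropped_compounds: tuple[str, ...]


def pca_scores(
    table: PeakTable,
    meta: Sequence[SampleMeta] | None = None,
    scaling: str = "autoscale",
    n_components: int = 2,
) -> PCAResult:
    """Deterministic PCA of the (scaled) peak table with per-group ellipses.

    ``scaling="autoscale"`` mean-centres and divides each compound by its
    standard deviation (unit variance); ``"center_only"`` just centres.
    Zero-variance compounds are dropped with a warning before scaling.  The
    sign convention is fixed — the largest-magnitude loading of each
    component is made positive — so repeated runs are bit-identical.
    """
    if scaling not in ("autoscale", "center_only"):
        raise UrimexError(f"unknown scaling {scaling!r}")
    if table.n_samples < 2:
        raise UrimexError("PCA requires at least 2 samples")
    max_comp = min(table.n_samples - 1, table.n_compounds)
    if not (1 <= n_components <= max_comp):
        raise UrimexError(
            f"n_components must lie in [1, {max_comp}] for this table, "
            f"got {n_components}"
        )
    data = table.data
    sds = data.std(axis=0, ddof=1)
    dropped = tuple(sds.index[sds == 0])
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} zero-variance compound(s) before PCA",
            stacklevel=2,
        )
        data = data.drop(columns=list(dropped))
        if data.shape[1] == 0:
            raise UrimexError("all compounds have zero variance; PCA undefined")
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scaling == "autoscale":
        x = x / x.std(axis=0, ddof=1)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    components = pca.components_
    # fixed sign convention: largest-magnitude loading per component positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
    names = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=table.sample_ids, columns=names)
    loadings_df = pd.DataFrame(components.T, index=list(data.columns), columns=names)
    ellipses: dict[str, GroupEllipse] = {}
    if meta is not None and n_components >= 2:
        by_method: dict[str, list[str]] = {}
        for m in meta:
            by_method.setdefault(m.method_label, []).append(m.sample_id)
        for label, sids in by_method.items():
            pts = scores_df.loc[[s for s in sids if s in scores_df.index], :"PC2"]
            n = len(pts)
            if n < 3:
                warnings.warn(
                    f"group {label!r}: fewer than 3 samples, no 95% ellipse",
                    stacklevel=2,
                )
                continue
            xy = pts.to_numpy()
            center = xy.mean(axis=0)
            cov = np.cov(xy, rowvar=False)
            scale = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(0.95, 2, n - 2)
            ellipses[label] = GroupEllipse(center, cov, float(scale), n)
    return PCAResult(
        scores=scores_df,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        loadings=loadings_df,
        group_ellipses=ellipses,
        dropped_compounds=dropped,
    )
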