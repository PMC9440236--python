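"""Metabolic-regulome (scMEP) preprocessing, benchmarking and pathway scores.

Mass-cytometry intensities are arcsinh-transformed (cofactor 5) and, where
cell size changes across states, normalised by relative cell volume
(radius cubed). Individual metabolic markers are benchmarked against
protein-synthesis-adjusted SCENITH parameters by ordinary least squares of
per-timepoint arcsinh medians on log-transformed adjusted parameters;
markers with a significant positive slope are retained. A pathway score is
the mean of its member markers' arcsinh medians (population level) or the
mean of per-marker min–max-scaled arcsinh values (single-cell level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ConfigurationError, DegenerateFitError,
                     InsufficientDataError, ValidationError)

DEFAULT_COFACTOR = 5.0

#: Canonical pathway-score definitions (metabolic regulome panel).
PATHWAYS: dict[str, tuple[str, ...]] = {
    "TCA/ETC": ("CS", "ATP5A", "IDH2"),
    "FAO": ("HADHA",),
    "AA": ("ASCT2", "CD98", "GLS"),
    "GLYC-PRED": ("MCT1", "PFKFB4"),
    "GLYC-UP": ("GLUT1", "MCT1", "PFKFB4"),
    "GLYC-CON": ("ENO1", "LDHA", "GAPDH"),
    "GSH": ("GSS",),
    "MITO": ("TOMM20", "PGC1a"),
    "PPP": ("G6PD",),
}


@dataclass(frozen=True)
class PathwayDefinition:
    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ConfigurationError(f"pathway {self.name!r} has no markers")


def builtin_pathways() -> list[PathwayDefinition]:
    return [PathwayDefinition(n, m) for n, m in PATHWAYS.items()]


def arcsinh_transform(x, cofactor: float = DEFAULT_COFACTOR):
    """Inverse-hyperbolic-sine transform, asinh(x / cofactor).

    The standard variance-stabilising transform for mass cytometry;
    monotone and odd.
    """
    if cofactor <= 0:
        raise ValidationError("cofactor must be positive")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def volume_normalize(intensity, radius, reference_radius: float):
    """Divide intensity by relative cell volume (radius / reference)^3.

    Removes the apparent per-cell abundance rise that comes purely from
    cells growing larger during differentiation.
    """
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0) or reference_radius <= 0:
        raise ValidationError("radii must be positive")
    return np.asarray(intensity, dtype=float) / (radius / reference_radius) ** 3


def subsample(table: pd.DataFrame, n_per_group: int = 20000,
              by=("condition", "stage"), seed: int = 0) -> pd.DataFrame:
    """Uniform without-replacement subsample per group.

    Groups smaller than ``n_per_group`` are kept whole with a warning.
    Deterministic under a fixed seed; original row order is preserved
    within the output.
    """
    rng = np.random.default_rng(seed)
    keep = []
    for key, group in table.groupby(list(by), sort=True, observed=True):
        if len(group) <= n_per_group:
            if len(group) < n_per_group:
                warnings.warn(
                    f"group {key}: only {len(group)} cells "
                    f"(< {n_per_group}), kept whole", stacklevel=2)
            keep.append(group.index.to_numpy())
        else:
            keep.append(rng.choice(group.index.to_numpy(), size=n_per_group,
                                   replace=False))
    idx = np.sort(np.concatenate(keep))
    return table.loc[idx]


@dataclass(frozen=True)
class RegressionResult:
    """OLS benchmark of one marker against an adjusted SCENITH parameter."""

    marker: str
    pathway: str
    slope: float
    intercept: float
    rvalue: float
    pvalue: float
    selected: bool


def benchmark_marker(marker_medians, adjusted_param, alpha: float = 0.05,
                     marker: str = "", pathway: str = "") -> RegressionResult:
    """Regress per-timepoint arcsinh marker medians on log adjusted values.

    The predictor is ``log1p(max(adjusted, 0))`` — adjusted parameters can
    legitimately be zero. A marker is selected when its slope is positive
    and the two-sided p-value of the slope t-statistic is below ``alpha``.
    """
    y = np.asarray(marker_medians, dtype=float)
    a = np.asarray(adjusted_param, dtype=float)
    if y.shape != a.shape:
        raise ValidationError("paired series must have equal length")
    if y.size < 3:
        raise InsufficientDataError(
            f"need >= 3 paired timepoints, got {y.size}")
    x = np.log1p(np.maximum(a, 0.0))
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in the predictor")
    if np.ptp(y) == 0:
        return RegressionResult(marker, pathway, 0.0, float(y[0]), 0.0, 1.0,
                                False)
    fit = stats.linregress(x, y)
    selected = bool(fit.slope > 0 and fit.pvalue < alpha)
    return RegressionResult(marker, pathway, float(fit.slope),
                            float(fit.intercept), float(fit.rvalue),
                            float(fit.pvalue), selected)


def benchmark_markers(median_table: pd.DataFrame, adjusted_param,
                      marker_pathways: dict[str, str] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Benchmark every column of a timepoint x marker median table."""
    rows = []
    for marker in median_table.columns:
        res = benchmark_marker(
            median_table[marker].to_numpy(), adjusted_param, alpha=alpha,
            marker=marker,
            pathway=(marker_pathways or {}).get(marker, ""))
        rows.append(res.__dict__)
    return pd.DataFrame(rows)


def population_pathway_score(medians, definition: PathwayDefinition) -> float:
    """Mean of member markers' arcsinh medians for one population.

    Summing member medians and dividing by the member count keeps scores
    comparable between pathways of different sizes; the score always lies
    within [min, max] of the member medians.
    """
    missing = [m for m in definition.markers if m not in medians]
    if missing:
        raise ConfigurationError(
            f"pathway {definition.name!r}: missing marker(s) {missing}")
    return float(np.mean([medians[m] for m in definition.markers]))


def single_cell_pathway_score(events: pd.DataFrame,
                              definition: PathwayDefinition,
                              window: tuple[float, float] = (1.0, 99.0),
                              cofactor: float = DEFAULT_COFACTOR
                              ) -> pd.Series:
    """Per-cell pathway score in [0, 1].

    Each member marker's arcsinh values are min–max scaled over the given
    percentile window (values outside clipped); the score is the mean of
    the scaled member values. A marker with a degenerate window contributes
    a constant 0.5 with a warning.
    """
    lo_p, hi_p = window
    if not 0 <= lo_p < hi_p <= 100:
        raise ConfigurationError(f"invalid scaling window {window}")
    scaled = []
    for marker in definition.markers:
        if marker not in events.columns:
            raise ConfigurationError(
                f"pathway {definition.name!r}: missing marker {marker!r}")
        t = arcsinh_transform(events[marker].to_numpy(), cofactor)
        lo, hi = np.percentile(t, [lo_p, hi_p])
        if hi == lo:
            warnings.warn(f"marker {marker!r}: degenerate scaling window; "
                          f"contributes 0.5", stacklevel=2)
            scaled.append(np.full(len(events), 0.5))
        else:
            scaled.append(np.clip((t - lo) / (hi - lo), 0.0, 1.0))
    return pd.Series(np.mean(scaled, axis=0), index=events.index,
                     name=definition.name)


def correlate_scores(scores, scenith_values) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties) between paired series."""
    s = np.asarray(scores, dtype=float)
    v = np.asarray(scenith_values, dtype=float)
    if s.shape != v.shape:
        raise ValidationError("paired series must have equal length")
    if s.size < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    rho, p = stats.spearmanr(s, v)
    return float(rho), float(p)


def population_medians(events: pd.DataFrame, markers,
                       by=("condition", "stage"),
                       cofactor: float = DEFAULT_COFACTOR,
                       volume_reference: float | None = None
                       ) -> pd.DataFrame:
    """Per-group arcsinh medians, optionally volume-normalised first.

    When ``volume_reference`` is given, each group's intensities are
    divided by (group mean radius / reference)^3 before the transform.
    """
    rows = []
    for key, group in events.groupby(list(by), sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(by, key))
        for marker in markers:
            vals = group[marker].to_numpy(dtype=float)
            if volume_reference is not None:
                vals = volume_normalize(
                    vals, float(group["cell_radius"].mean()),
                    volume_reference)
            row[marker] = float(np.median(arcsinh_transform(vals, cofactor)))
        rows.append(row)
    return pd.DataFrame(rows)
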