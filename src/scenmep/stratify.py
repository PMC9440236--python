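"""Quantile stratification and maturation-class assignment.

Single-cell populations are split along one marker's expression either into
equal-frequency quantile bins (default; ties broken by stable cell order)
or into equal-width bins over the observed arcsinh expression range. Bin 1
holds the lowest-expressing cells and bin k the highest. Maturation classes
are the k=3 special case on HLA-DR, labelled low / mid / high.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, InsufficientDataError,
                     ScenmepError)
from .scmep import DEFAULT_COFACTOR, arcsinh_transform

MODES = ("equal_frequency", "equal_range")


class DegenerateStratificationError(ScenmepError):
    """All cells share one expression value; equal-range bins undefined."""


def quantile_stratify(events: pd.DataFrame, marker: str, k: int = 4,
                      mode: str = "equal_frequency",
                      cofactor: float = DEFAULT_COFACTOR) -> pd.Series:
    """Assign each event a bin index 1..k along *marker* expression.

    equal_frequency: empirical k-quantile bins of near-equal size (sizes
    differ by at most one; ties broken by stable input order).
    equal_range: k equal-width bins over [min, max] of the arcsinh-
    transformed expression; raises when the range is degenerate.

    The partition is exhaustive and disjoint; bin k contains the
    highest-expressing cells.
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; one of {MODES}")
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if marker not in events.columns:
        raise ConfigurationError(f"marker {marker!r} not in table")
    n = len(events)
    if n < k:
        raise InsufficientDataError(f"{n} cells < k={k}")
    values = events[marker].to_numpy(dtype=float)

    if mode == "equal_frequency":
        order = np.argsort(values, kind="stable")
        bins = np.empty(n, dtype=int)
        # sizes n//k or n//k + 1, larger bins first
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        start = 0
        for b, size in enumerate(sizes, start=1):
            bins[order[start:start + size]] = b
            start += size
    else:
        t = arcsinh_transform(values, cofactor)
        lo, hi = float(np.min(t)), float(np.max(t))
        if hi == lo:
            raise DegenerateStratificationError(
                f"marker {marker!r}: all cells share one expression value")
        edges = np.linspace(lo, hi, k + 1)
        bins = np.digitize(t, edges[1:-1], right=False) + 1

    return pd.Series(bins, index=events.index, name=f"{marker}_bin")


_CLASS_LABELS = {1: "low", 2: "mid", 3: "high"}


def maturation_classes(events: pd.DataFrame, marker: str = "HLA-DR",
                       mode: str = "equal_frequency",
                       cofactor: float = DEFAULT_COFACTOR) -> pd.Series:
    """Split a gated HLA-DR+CD86+ population into low / mid / high classes.

    Three-way stratification on *marker* (HLA-DR by default); returns a
    string series aligned with the input.
    """
    if len(events) == 0:
        raise InsufficientDataError("empty population")
    bins = quantile_stratify(events, marker, k=3, mode=mode,
                             cofactor=cofactor)
    return bins.map(_CLASS_LABELS).rename(f"{marker}_class")


def class_frequencies(classes: pd.Series, sample_keys: pd.DataFrame | None
                      = None) -> pd.DataFrame:
    """Class frequency table, optionally per sample."""
    if sample_keys is None:
        counts = classes.value_counts()
        return pd.DataFrame({"class": counts.index,
                             "n": counts.to_numpy(),
                             "fraction": (counts / counts.sum()).to_numpy()})
    frame = sample_keys.copy()
    frame["_class"] = classes.to_numpy()
    out = (frame.groupby(list(sample_keys.columns) + ["_class"],
                         observed=True)
           .size().rename("n").reset_index()
           .rename(columns={"_class": "class"}))
    totals = out.groupby(list(sample_keys.columns))["n"].transform("sum")
    out["fraction"] = out["n"] / totals
    return out
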