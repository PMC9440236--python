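"""SCENITH metabolic-dependence parameters from inhibitor-well readouts.

SCENITH infers single-cell energetic metabolism from protein synthesis
(puromycin incorporation) measured after short treatments with metabolic
inhibitors. With per-well geometric mean fluorescence intensities (gMFI)
of the puromycin stain —

    C    control (DMSO)
    DG   2-deoxyglucose (glycolysis block)
    O    oligomycin (ATP-synthase block)
    DGO  2-DG + oligomycin (full metabolic block; background window)
    Eto  etomoxir (long-chain fatty-acid oxidation block)
    Tele telaglenastat / CB-839 (glutaminase block)

— the dependence/capacity parameters are

    glucose dependence        = 100 (C − DG)  / (C − DGO)
    mitochondrial dependence  = 100 (C − O)   / (C − DGO)
    FAO dependence            = 100 (C − Eto) / (C − DGO)
    glutaminolysis dependence = 100 (C − Tele)/ (C − DGO)
    glycolytic capacity       = 100 − mitochondrial dependence
    FAAO capacity             = 100 − glucose dependence

All parameters are invariant to a common rescaling of the gMFIs; the
complement identities hold exactly on the raw values. Noise can push raw
values slightly outside [0, 100], so clamped copies are stored alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .errors import (DegenerateWellError, InsufficientDataError,
                     ValidationError)
from .io import DEFAULT_MIN_CELLS

#: Parameters computable from the four core wells.
CORE_PARAMS = ("glucose_dependence", "mitochondrial_dependence",
               "glycolytic_capacity", "faao_capacity")
#: Parameters requiring the optional etomoxir / telaglenastat wells.
EXTENDED_PARAMS = ("fao_dependence", "glutaminolysis_dependence")

DEFAULT_GMFI_FLOOR = 1.0  # a.u.; unmixed intensities can be <= 0


def geometric_mfi(values, floor: float = DEFAULT_GMFI_FLOOR) -> float:
    """Geometric mean fluorescence intensity.

    Values at or below ``floor`` are floored before the log; the fraction
    floored is reported via a warning when above 1%. Scale-equivariant:
    ``geometric_mfi(k * v) == k * geometric_mfi(v)`` for k > 0 (when no
    value hits the floor).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric_mfi of empty input")
    if floor <= 0:
        raise ValidationError("floor must be positive")
    n_floored = int(np.sum(arr < floor))
    if n_floored > 0.01 * arr.size:
        warnings.warn(f"geometric_mfi floored {n_floored}/{arr.size} values "
                      f"at {floor}", stacklevel=2)
    return float(np.exp(np.mean(np.log(np.maximum(arr, floor)))))


@dataclass(frozen=True)
class GmfiRecord:
    """Per-well gMFI summary for one analysis group."""

    group: dict
    gmfi: dict[str, float]  # inhibitor -> gMFI, must include C, DG, O, DGO
    n_cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.gmfi.values()):
            raise ValidationError(f"nonpositive gMFI in group {self.group}")

    @property
    def pathological(self) -> bool:
        """True when control translation does not exceed O or DGO wells."""
        c = self.gmfi.get("C", np.inf)
        return c < self.gmfi.get("DGO", -np.inf) or \
            c < self.gmfi.get("O", -np.inf)


@dataclass(frozen=True)
class ScenithProfile:
    """Derived SCENITH parameters for one group.

    ``raw`` holds unclamped percentages (complement identities exact);
    ``clamped`` the [0, 100]-bounded reporting copies. ``protein_synthesis``
    is the control-well gMFI and ``background_window`` is C − DGO.
    """

    group: dict
    raw: dict[str, float]
    protein_synthesis: float
    background_window: float
    n_cells: dict[str, int] = field(default_factory=dict)

    @property
    def clamped(self) -> dict[str, float]:
        return {k: float(np.clip(v, 0.0, 100.0)) for k, v in self.raw.items()}

    @property
    def out_of_range(self) -> list[str]:
        return [k for k, v in self.raw.items() if not 0.0 <= v <= 100.0]


def compute_scenith(record: GmfiRecord) -> ScenithProfile:
    """Evaluate the SCENITH formulas for one gMFI record.

    Requires C > DGO (a positive background window). FAO/glutaminolysis
    dependence are included only when the Eto/Tele wells are present.
    """
    g = record.gmfi
    for well in ("C", "DG", "O", "DGO"):
        if well not in g:
            raise DegenerateWellError(
                f"group {record.group}: missing well {well!r}")
    window = g["C"] - g["DGO"]
    if window <= 0:
        raise DegenerateWellError(
            f"group {record.group}: degenerate background window "
            f"(C={g['C']:.4g} <= DGO={g['DGO']:.4g})")
    raw = {
        "glucose_dependence": 100.0 * (g["C"] - g["DG"]) / window,
        "mitochondrial_dependence": 100.0 * (g["C"] - g["O"]) / window,
    }
    raw["glycolytic_capacity"] = 100.0 - raw["mitochondrial_dependence"]
    raw["faao_capacity"] = 100.0 - raw["glucose_dependence"]
    if "Eto" in g:
        raw["fao_dependence"] = 100.0 * (g["C"] - g["Eto"]) / window
    if "Tele" in g:
        raw["glutaminolysis_dependence"] = \
            100.0 * (g["C"] - g["Tele"]) / window
    return ScenithProfile(group=dict(record.group), raw=raw,
                          protein_synthesis=g["C"],
                          background_window=window,
                          n_cells=dict(record.n_cells))


def adjust_profile(profile: ScenithProfile) -> dict[str, float]:
    """Protein-synthesis-adjusted parameters: raw parameter x (C − DGO).

    Weighting by the background window distinguishes states with the same
    percentual dependence but different absolute translation. Linear in the
    window; units %·a.u.
    """
    return {k: v * profile.background_window for k, v in profile.raw.items()}


def phospho_ratio(numerator_gmfi: float, denominator_gmfi: float) -> float:
    """Signaling-balance index, e.g. p-mTOR : p-AMPK gMFI ratio."""
    if denominator_gmfi <= 0:
        raise ValidationError("denominator gMFI must be positive")
    return float(numerator_gmfi) / float(denominator_gmfi)


def gmfi_records(events: pd.DataFrame,
                 by=("donor_id", "condition", "stage"),
                 floor: float = DEFAULT_GMFI_FLOOR,
                 min_cells: int = DEFAULT_MIN_CELLS,
                 required=("C", "DG", "O", "DGO")) -> list[GmfiRecord]:
    """Summarise a SCENITH event table into per-group gMFI records.

    Groups missing a required well raise a degenerate-well error naming the
    group; wells below ``min_cells`` events raise an insufficient-data
    error.
    """
    by = list(by)
    records = []
    for key, group in events.groupby(by, sort=True, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        gdict = dict(zip(by, key))
        gmfi: dict[str, float] = {}
        n_cells: dict[str, int] = {}
        for inhibitor, well in group.groupby("inhibitor", observed=True):
            if len(well) < min_cells:
                raise InsufficientDataError(
                    f"group {gdict}, well {inhibitor}: {len(well)} cells "
                    f"< min_cells={min_cells}")
            gmfi[str(inhibitor)] = geometric_mfi(
                well["puromycin"].to_numpy(), floor=floor)
            n_cells[str(inhibitor)] = len(well)
        missing = [w for w in required if w not in gmfi]
        if missing:
            raise DegenerateWellError(
                f"group {gdict}: missing inhibitor well(s) {missing}")
        records.append(GmfiRecord(group=gdict, gmfi=gmfi, n_cells=n_cells))
    return records


def profiles_from_events(events: pd.DataFrame,
                         by=("donor_id", "condition", "stage"),
                         floor: float = DEFAULT_GMFI_FLOOR,
                         min_cells: int = DEFAULT_MIN_CELLS,
                         required=("C", "DG", "O", "DGO")
                         ) -> list[ScenithProfile]:
    """Full gMFI → formula pipeline per group."""
    return [compute_scenith(r) for r in
            gmfi_records(events, by=by, floor=floor, min_cells=min_cells,
                         required=required)]


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Tabulate profiles: group keys + raw/clamped parameters + windows."""
    rows = []
    for p in profiles:
        row = dict(p.group)
        for k, v in p.raw.items():
            row[k] = v
            row[f"{k}_clamped"] = p.clamped[k]
        row["protein_synthesis"] = p.protein_synthesis
        row["background_window"] = p.background_window
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Oligomycin-well single-cell classification
# ---------------------------------------------------------------------------

def _arcsinh(x, cofactor: float = 5.0):
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def classify_oligomycin_cells(o_events: pd.DataFrame,
                              c_puromycin=None,
                              dgo_puromycin=None,
                              method: str = "threshold",
                              cofactor: float = 5.0,
                              min_cells: int = DEFAULT_MIN_CELLS,
                              cut: float | None = None) -> pd.DataFrame:
    """Classify oligomycin-well cells as glycolytic vs mitochondrial.

    Cells sustaining translation despite ATP-synthase blockade are running
    on glycolysis; cells whose translation collapses toward the full-block
    (DGO) level are mitochondrially dependent. Classification happens in
    arcsinh-transformed puromycin space:

    - ``threshold`` (default): cells above the cut are glycolytic. The cut
      is the midpoint between the DGO-well median and the C-well median of
      the same group (or an explicit ``cut``, in arcsinh units).
    - ``two-component``: a two-component Gaussian mixture is fit and the
      higher-mean component is labelled glycolytic.

    Every classified cell also receives an equal-frequency puromycin
    tertile (low / mid / high); the partition is exhaustive and disjoint.
    """
    if len(o_events) < min_cells:
        raise InsufficientDataError(
            f"oligomycin well has {len(o_events)} cells < {min_cells}")
    t = _arcsinh(o_events["puromycin"].to_numpy(), cofactor)
    if method == "threshold":
        if cut is None:
            if c_puromycin is None or dgo_puromycin is None:
                raise ValidationError(
                    "threshold method needs C and DGO well puromycin (or an "
                    "explicit cut)")
            lo = float(np.median(_arcsinh(dgo_puromycin, cofactor)))
            hi = float(np.median(_arcsinh(c_puromycin, cofactor)))
            cut = 0.5 * (lo + hi)
        labels = np.where(t > cut, "glycolytic", "mitochondrial")
    elif method == "two-component":
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        comp = gm.fit_predict(t.reshape(-1, 1))
        hi_comp = int(np.argmax(gm.means_.ravel()))
        labels = np.where(comp == hi_comp, "glycolytic", "mitochondrial")
    else:
        raise ValidationError(f"unknown classification method {method!r}")

    tertile = pd.qcut(pd.Series(t).rank(method="first"), 3,
                      labels=["low", "mid", "high"])
    return pd.DataFrame({
        "cell_id": o_events["cell_id"].to_numpy(),
        "metabolic_class": labels,
        "puromycin_tertile": tertile.astype(str).to_numpy(),
    })
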