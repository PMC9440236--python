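"""Synthetic cytometry data with known metabolic ground truth.

The generator emulates a SCENITH experiment: for every combination of
differentiation stage, culture condition, donor and inhibitor well it emits
single-cell puromycin and immune-marker intensities with multiplicative
log-normal noise around per-well geometric means. Because the noise is
multiplicative and the well means are geometric means, the geometric-MFI
estimator is unbiased for the archetype mean and the full analysis pipeline
recovers each archetype's ground-truth metabolic parameters exactly in the
noiseless limit.

Archetypes encode the biology: per-inhibitor geometric-mean translation
levels (control DMSO, 2-deoxyglucose, oligomycin, the 2DG+oligomycin
combination, etomoxir, telaglenastat, harringtonine), immune-marker
geometric means, mean cell radius, and optional CD86-high / CD1c-high
subpopulations whose oligomycin-well translation differs from the bulk.
The built-in archetype set spans the monocyte → immature DC → activated DC
→ mature DC timeline under control and tolerogenic (vitamin D3 ± dexa)
conditions plus ex-vivo blood populations, with ground-truth parameters
matching the reference metabolic-dependence percentages for each state.

A companion generator emits mass-cytometry style metabolic-regulome
("scMEP") event tables whose marker levels are coupled to pathway-activity
multipliers per stage/condition, with cell radius drawn so mean cell volume
rises 4-fold from monocyte to mature DC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (SCENITH_MARKERS, SCMEP_IMMUNE_MARKERS, SCMEP_MARKERS,
                 validate_event_table)

SCENITH_WELLS = ("C", "DG", "O", "DGO", "Eto", "Tele")

#: Relative translation level in the harringtonine (total-blockade) well.
_H_FRACTION_OF_C = 0.02

#: Log-scale SD of per-cell radius noise in the scMEP generator.
_RADIUS_SIGMA = 0.05


@dataclass(frozen=True)
class Subpopulation:
    """A metabolic subpopulation within one archetype.

    ``puromycin_overrides`` replaces the archetype's per-inhibitor geometric
    mean for member cells (typically the oligomycin well); ``marker_scale``
    multiplies archetype marker means (e.g. CD86 x4 for CD86-high cells).
    """

    label: str
    fraction: float
    puromycin_overrides: dict[str, float] = field(default_factory=dict)
    marker_scale: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class Archetype:
    """Ground truth for one (stage, condition) cell state."""

    stage: str
    condition: str
    puromycin_means: dict[str, float]  # per-inhibitor geometric means, a.u.
    marker_means: dict[str, float]
    mean_radius: float = 10.0
    cell_sigma: float = 0.2  # log-scale SD of per-cell noise
    subpopulations: tuple[Subpopulation, ...] = ()

    def __post_init__(self) -> None:
        pm = self.puromycin_means
        missing = [w for w in SCENITH_WELLS if w not in pm]
        if missing:
            raise ConfigurationError(
                f"{self.condition}/{self.stage}: missing well mean(s) "
                f"{missing}")
        if any(v <= 0 for v in pm.values()):
            raise ConfigurationError(
                f"{self.condition}/{self.stage}: nonpositive well mean")
        c, dgo = pm["C"], pm["DGO"]
        for w in ("O", "DG", "Eto", "Tele"):
            if not (dgo <= pm[w] <= c):
                raise ConfigurationError(
                    f"{self.condition}/{self.stage}: {w} mean {pm[w]} "
                    f"outside [DGO={dgo}, C={c}]")
        if any(v <= 0 for v in self.marker_means.values()):
            raise ConfigurationError("marker means must be positive")
        if self.mean_radius <= 0:
            raise ConfigurationError("mean_radius must be positive")
        if self.subpopulations:
            total = sum(s.fraction for s in self.subpopulations)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"subpopulation fractions sum to {total}, expected 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.condition, self.stage)

    def well_means(self, inhibitor: str) -> dict[str, float]:
        """Per-subpopulation geometric means for one inhibitor well.

        Subpopulations with an explicit override use it; the remaining
        ("bulk") components are back-solved so the fraction-weighted
        geometric mean over all subpopulations equals the archetype's
        stated overall well mean. Without subpopulations the overall mean
        is returned for a single implicit bulk component.
        """
        overall = (self.puromycin_means["C"] * _H_FRACTION_OF_C
                   if inhibitor == "H"
                   else self.puromycin_means[inhibitor])
        if not self.subpopulations:
            return {"bulk": overall}
        log_overall = math.log(overall)
        fixed_mass = 0.0
        free_frac = 0.0
        means: dict[str, float] = {}
        for sub in self.subpopulations:
            if inhibitor in sub.puromycin_overrides:
                means[sub.label] = sub.puromycin_overrides[inhibitor]
                fixed_mass += sub.fraction * math.log(means[sub.label])
            else:
                free_frac += sub.fraction
        if free_frac == 0.0:
            return means
        solved = math.exp((log_overall - fixed_mass) / free_frac)
        if solved <= 0 or not math.isfinite(solved):
            raise ConfigurationError(
                f"{self.condition}/{self.stage}: cannot reconcile "
                f"subpopulation overrides with overall {inhibitor} mean")
        for sub in self.subpopulations:
            means.setdefault(sub.label, solved)
        return means

    def ground_truth(self) -> dict[str, float]:
        """Noiseless SCENITH parameters implied by the well means (raw %)."""
        pm = self.puromycin_means
        window = pm["C"] - pm["DGO"]
        return {
            "glucose_dependence": 100.0 * (pm["C"] - pm["DG"]) / window,
            "mitochondrial_dependence": 100.0 * (pm["C"] - pm["O"]) / window,
            "glycolytic_capacity": 100.0 - 100.0 * (pm["C"] - pm["O"]) / window,
            "faao_capacity": 100.0 - 100.0 * (pm["C"] - pm["DG"]) / window,
            "fao_dependence": 100.0 * (pm["C"] - pm["Eto"]) / window,
            "glutaminolysis_dependence":
                100.0 * (pm["C"] - pm["Tele"]) / window,
        }

    def subpopulation_truth(self, label: str) -> dict[str, float]:
        """Ground truth for one subpopulation (overrides where given)."""
        subs = {s.label: s for s in self.subpopulations}
        if label not in subs:
            raise ConfigurationError(f"no subpopulation {label!r}")
        pm = dict(self.puromycin_means)
        pm.update(subs[label].puromycin_overrides)
        return replace(self, subpopulations=(),
                       puromycin_means=pm).ground_truth()


@dataclass(frozen=True)
class DonorModel:
    """Per-donor multiplicative scaling shared by every well and marker."""

    n_donors: int = 3
    donor_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ConfigurationError("need at least one donor")
        if self.donor_sigma < 0:
            raise ConfigurationError("donor_sigma must be >= 0")

    def factors(self, rng: np.random.Generator) -> np.ndarray:
        return np.exp(self.donor_sigma * rng.standard_normal(self.n_donors))


# ---------------------------------------------------------------------------
# Built-in archetypes
# ---------------------------------------------------------------------------

# Immune-marker geometric means per stage under control culture. Values are
# plausible spectral-cytometry magnitudes shaped by the known phenotype
# trajectory (CD14 loss, HLA-DR/CD86/CD1c/PD-L1 gain with maturation,
# transient p-mTOR/pS6K/PPARg rise at activation); no recovered metabolic
# parameter depends on them.
_CTRL_MARKERS = {
    #            mono_0h mono_24h  iDC  actDC   mDC
    "CD14":      (800,   400,      60,   50,    40),
    "HLA-DR":    (100,   150,     400,  700,   900),
    "CD86":      (50,     80,     200,  500,   800),
    "CD1c":      (20,     60,     300,  350,   300),
    "CD206":     (30,    100,     400,  400,   350),
    "CD11c":     (300,   400,     600,  600,   600),
    "CD11b":     (400,   380,     320,  300,   300),
    "CD80":      (20,     30,      60,  300,   400),
    "CD141":     (20,     20,      25,   30,    30),
    "CD276":     (30,     40,      80,  150,   200),
    "CCR7":      (10,     10,      20,  150,   500),
    "PD-L1":     (20,     40,      80,  400,   600),
    "ILT3":      (50,     60,      80,   80,    90),
    "CD36":      (200,   160,     120,  100,    80),
    "CD98":      (100,   150,     220,  300,   280),
    "p-mTOR":    (100,   140,     160,  300,   150),
    "p-AMPK":    (100,   100,     110,   90,   200),
    "mTOR-total": (200,  200,     210,  220,   210),
    "AMPK-total": (200,  200,     200,  200,   210),
    "pS6K":      (100,   130,     150,  250,   120),
    "iNOS":      (20,     25,      30,   80,    50),
    "PPARg":     (30,     35,      45,   90,    40),
}

_CTRL_STAGE_ORDER = ("mono_0h", "mono_24h", "iDC", "actDC", "mDC")

# Tolerogenic conditions: maturation-resistant phenotype — CD14 retained,
# ILT3/PD-L1/CD141/CD36 up, costimulation and CD1c down, p-mTOR dominance.
_VITD3_SCALE = {
    "CD14": 5.0, "HLA-DR": 0.6, "CD86": 0.5, "CD1c": 0.4, "CD141": 5.0,
    "PD-L1": 1.5, "ILT3": 3.0, "CD36": 2.0, "CCR7": 0.4, "CD80": 0.5,
    "p-mTOR": 1.6, "p-AMPK": 0.7, "pS6K": 1.4, "PPARg": 2.0,
}
_VITD3_DEXA_SCALE = dict(_VITD3_SCALE, **{"ILT3": 4.0, "CD141": 6.0,
                                          "CD86": 0.4})

# Cell radii chosen so volume (~ radius^3) rises 4-fold across the control
# timeline from monocyte to mature DC, in equal geometric steps.
_STAGE_RADII = {
    "mono_0h": 10.0,
    "mono_24h": 10.0 * 4 ** (1 / 12),
    "iDC": 10.0 * 4 ** (2 / 12),
    "actDC": 10.0 * 4 ** (3 / 12),
    "mDC": 10.0 * 4 ** (1 / 3),
    "pDC": 9.0,
    "cDC1": 10.5,
}

# Per-inhibitor puromycin geometric means (C, DG, O, DGO, Eto, Tele), a.u.
# Back-solved from the SCENITH formulas so each archetype's ground truth
# equals the reference percentage for that state; entries not pinned by a
# reference value are plausible fillers.
_PUROMYCIN_TABLE = {
    ("ctrl", "mono_0h"):    (1000, 280, 838, 100, 964, 964),
    ("ctrl", "mono_24h"):   (1000, 430, 352, 100, 900, 900),
    ("ctrl", "iDC"):        (1000, 505, 289, 100, 829, 829),
    ("ctrl", "actDC"):      (1300, 580, 400, 100, 1144, 1144),
    ("ctrl", "mDC"):        (1000, 316, 226, 100, 937, 631),
    ("vitd3", "mono_24h"):  (1000, 430, 577, 100, 900, 900),
    ("vitd3", "iDC"):       (1300, 700, 390, 100, 1050, 1050),
    ("vitd3_dexa", "iDC"):  (1000, 640, 325, 100, 850, 850),
    ("exvivo", "mono_0h"):  (1000, 352, 739, 100, 964, 964),
    ("exvivo", "cDC1"):     (1000, 685, 289, 100, 829, 829),
    ("exvivo", "pDC"):      (1000, 685, 460, 100, 850, 850),
}

_SUBPOPULATIONS = {
    ("ctrl", "iDC"): (
        Subpopulation("CD86hi", 0.25, {"O": 271.0}, {"CD86": 4.0}),
        Subpopulation("CD1chi", 0.25, {"O": 415.0}, {"CD1c": 4.0}),
        Subpopulation("bulk", 0.50),
    ),
    ("ctrl", "actDC"): (
        Subpopulation("CD1chi", 0.25, {"O": 700.0}, {"CD1c": 4.0}),
        Subpopulation("bulk", 0.75),
    ),
    ("ctrl", "mDC"): (
        Subpopulation("CD86hi", 0.25, {"O": 190.0}, {"CD86": 4.0}),
        Subpopulation("bulk", 0.75),
    ),
}


def _marker_means(condition: str, stage: str) -> dict[str, float]:
    base_stage = stage if stage in _CTRL_STAGE_ORDER else "mono_0h"
    idx = _CTRL_STAGE_ORDER.index(base_stage)
    means = {m: float(v[idx]) for m, v in _CTRL_MARKERS.items()}
    if condition == "vitd3":
        scale = _VITD3_SCALE
    elif condition == "vitd3_dexa":
        scale = _VITD3_DEXA_SCALE
    else:
        scale = {}
    for marker, s in scale.items():
        means[marker] *= s
    if stage == "pDC":  # plasmacytoid: CD14- CD11c-low CD1c-low
        means.update({"CD14": 20.0, "CD11c": 60.0, "CD1c": 15.0,
                      "HLA-DR": 500.0})
    if stage == "cDC1":  # conventional DC1: CD141-high CD1c-low
        means.update({"CD14": 20.0, "CD141": 400.0, "CD1c": 30.0,
                      "HLA-DR": 600.0, "CD11c": 500.0})
    return means


def builtin_archetypes(cell_sigma: float = 0.2) -> list[Archetype]:
    """The default archetype set covering the DC differentiation study.

    Ground-truth metabolic parameters of each archetype equal the reference
    percentages for that state (e.g. control monocytes 18% mitochondrial
    dependence rising to 72% at 24 h, 79% at iDC and 86% at mDC).
    """
    out = []
    for (condition, stage), row in _PUROMYCIN_TABLE.items():
        pm = dict(zip(SCENITH_WELLS, (float(v) for v in row)))
        out.append(Archetype(
            stage=stage,
            condition=condition,
            puromycin_means=pm,
            marker_means=_marker_means(condition, stage),
            mean_radius=_STAGE_RADII[stage],
            cell_sigma=cell_sigma,
            subpopulations=_SUBPOPULATIONS.get((condition, stage), ()),
        ))
    return out


def _subpopulation_counts(archetype: Archetype, n: int) -> dict[str, int]:
    """Deterministic largest-remainder allocation of n cells to subpops."""
    if not archetype.subpopulations:
        return {"bulk": n}
    fracs = [(s.label, s.fraction) for s in archetype.subpopulations]
    raw = [(label, f * n) for label, f in fracs]
    counts = {label: int(math.floor(x)) for label, x in raw}
    short = n - sum(counts.values())
    by_remainder = sorted(raw, key=lambda t: t[1] - math.floor(t[1]),
                          reverse=True)
    for label, _ in by_remainder[:short]:
        counts[label] += 1
    return counts


def generate_scenith_dataset(
    archetypes,
    n_cells_per_well: int = 5000,
    donor_model: DonorModel = DonorModel(),
    seed: int = 0,
    include_h_well: bool = True,
) -> pd.DataFrame:
    """Simulate a full SCENITH event table.

    One well of ``n_cells_per_well`` events is emitted per
    (archetype, donor, inhibitor). Per-cell puromycin is the well's
    geometric mean x the donor factor x exp(cell_sigma * z); markers are
    drawn analogously. Subpopulation membership uses exact deterministic
    counts so the noiseless limit reproduces each archetype's ground truth
    exactly. Identical seeds give bitwise-identical tables. The emitted
    ``subpopulation`` column is generator ground truth.
    """
    archetypes = list(archetypes)
    if not archetypes:
        raise ConfigurationError("empty archetype list")
    if n_cells_per_well < 1:
        raise ConfigurationError("n_cells_per_well must be >= 1")
    rng = np.random.default_rng(seed)
    donor_factors = donor_model.factors(rng)
    wells = SCENITH_WELLS + (("H",) if include_h_well else ())

    records = []
    for arch in archetypes:
        counts = _subpopulation_counts(arch, n_cells_per_well)
        marker_names = sorted(arch.marker_means)
        sub_scale = {s.label: s.marker_scale for s in arch.subpopulations}
        for d in range(donor_model.n_donors):
            donor = f"D{d + 1}"
            factor = donor_factors[d]
            for inhibitor in wells:
                means = arch.well_means(inhibitor)
                labels = np.concatenate([
                    np.repeat(label, counts.get(label, 0))
                    for label in means]) if arch.subpopulations else \
                    np.repeat("bulk", n_cells_per_well)
                rng.shuffle(labels)
                n = len(labels)
                puro_mean = np.array([means[l] for l in labels])
                z = rng.standard_normal(n)
                puro = puro_mean * factor * np.exp(arch.cell_sigma * z)
                cols = {
                    "cell_id": [f"{arch.condition}.{arch.stage}.{donor}."
                                f"{inhibitor}.{i}" for i in range(n)],
                    "donor_id": donor,
                    "condition": arch.condition,
                    "stage": arch.stage,
                    "inhibitor": inhibitor,
                    "puromycin": puro,
                    "viable": True,
                    "subpopulation": labels,
                }
                for marker in marker_names:
                    base = arch.marker_means[marker]
                    mean = np.array([
                        base * sub_scale.get(l, {}).get(marker, 1.0)
                        for l in labels])
                    zm = rng.standard_normal(n)
                    cols[marker] = mean * factor * np.exp(
                        arch.cell_sigma * zm)
                records.append(pd.DataFrame(cols))
    table = pd.concat(records, ignore_index=True)
    return validate_event_table(table, "scenith")


# ---------------------------------------------------------------------------
# scMEP generator
# ---------------------------------------------------------------------------

#: Generating pathway assignment: each metabolic marker belongs to exactly
#: one group whose activity multiplier scales its geometric mean. Score
#: definitions (which may reuse markers across scores) live in
#: :mod:`scenmep.scmep`.
DEFAULT_COUPLING_MARKERS: dict[str, tuple[str, ...]] = {
    "TCA/ETC": ("CS", "ATP5A", "IDH2"),
    "MITO": ("TOMM20", "PGC1a", "SDHA", "CytC"),
    "FAO": ("HADHA", "CPT1A", "CD36"),
    "AA": ("ASCT2", "CD98", "GLS"),
    "GLYC": ("GLUT1", "MCT1", "PFKFB4", "ENO1", "LDHA", "GAPDH", "PDK1"),
    "GSH": ("GSS",),
    "PPP": ("G6PD",),
}

_DEFAULT_BASELINES = {m: 50.0 for m in SCMEP_MARKERS}


@dataclass(frozen=True)
class CouplingConfig:
    """Marker–metabolism coupling for the scMEP generator.

    ``multipliers[(stage, condition)][pathway]`` scales the baseline
    geometric mean of every marker generated under that pathway.
    """

    pathway_markers: dict[str, tuple[str, ...]]
    baseline_means: dict[str, float]
    multipliers: dict[tuple[str, str], dict[str, float]]

    def __post_init__(self) -> None:
        for pathway, markers in self.pathway_markers.items():
            for m in markers:
                if m not in self.baseline_means:
                    raise ConfigurationError(
                        f"marker {m!r} of pathway {pathway!r} has no "
                        f"baseline mean")
        for key, mults in self.multipliers.items():
            for pathway, v in mults.items():
                if v <= 0:
                    raise ConfigurationError(
                        f"nonpositive multiplier for {pathway!r} at {key}")

    def marker_pathway(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for pathway, markers in self.pathway_markers.items():
            for m in markers:
                out[m] = pathway
        return out

    def marker_mean(self, marker: str, key: tuple[str, str]) -> float:
        pathway = self.marker_pathway().get(marker)
        mult = self.multipliers.get(key, {}).get(pathway, 1.0) \
            if pathway else 1.0
        return self.baseline_means[marker] * mult


def coupling_from_archetypes(archetypes,
                             reference: tuple[str, str] = ("ctrl", "mono_0h"),
                             floor: float = 0.05) -> CouplingConfig:
    """Couple pathway activity to each archetype's adjusted SCENITH truth.

    Multipliers are the archetype's protein-synthesis-adjusted parameter
    (raw parameter x background window C−DGO) normalised to the reference
    state: mitochondrial dependence drives TCA/ETC and mitochondrial-
    dynamics markers, glycolytic capacity the glycolysis group,
    glutaminolysis dependence the amino-acid group, fatty-acid-oxidation
    dependence the FAO group, glucose dependence the GSH/PPP groups. This
    is the structure the benchmarking step assumes: markers of an active
    pathway rise with the matching metabolic dependence.
    """
    archetypes = list(archetypes)
    by_key = {a.key: a for a in archetypes}
    if reference not in by_key:
        reference = archetypes[0].key  # fall back to the first state

    def adjusted(arch: Archetype) -> dict[str, float]:
        truth = arch.ground_truth()
        window = arch.puromycin_means["C"] - arch.puromycin_means["DGO"]
        return {k: max(v, 0.0) * window for k, v in truth.items()}

    ref = adjusted(by_key[reference])
    pathway_param = {
        "TCA/ETC": "mitochondrial_dependence",
        "MITO": "mitochondrial_dependence",
        "FAO": "fao_dependence",
        "AA": "glutaminolysis_dependence",
        "GLYC": "glycolytic_capacity",
        "GSH": "glucose_dependence",
        "PPP": "glucose_dependence",
    }
    multipliers = {}
    for arch in archetypes:
        adj = adjusted(arch)
        multipliers[arch.key] = {
            pw: max(adj[param], floor) / max(ref[param], floor)
            for pw, param in pathway_param.items()}
    return CouplingConfig(
        pathway_markers=dict(DEFAULT_COUPLING_MARKERS),
        baseline_means=dict(_DEFAULT_BASELINES),
        multipliers=multipliers,
    )


def generate_scmep_dataset(
    archetypes,
    coupling: CouplingConfig | None = None,
    donor_model: DonorModel = DonorModel(),
    n_cells: int = 5000,
    seed: int = 0,
    volume_scaling: bool = False,
    volume_reference_radius: float = 10.0,
) -> pd.DataFrame:
    """Simulate a mass-cytometry metabolic-regulome event table.

    Per (archetype, donor), ``n_cells`` events carry the 23 metabolic
    markers (geometric mean = baseline x pathway multiplier), the shared
    immune markers, and a log-normal cell radius around the archetype's
    mean radius. Deterministic under a fixed seed.

    With ``volume_scaling`` the metabolic marker means are additionally
    multiplied by relative cell volume, (mean_radius / reference)^3 —
    larger cells carry proportionally more total protein — which is the
    effect the volume-normalisation step of the analysis removes.
    """
    archetypes = list(archetypes)
    if not archetypes:
        raise ConfigurationError("empty archetype list")
    if coupling is None:
        coupling = coupling_from_archetypes(archetypes)
    for marker in SCMEP_MARKERS:
        if marker not in coupling.baseline_means:
            raise ConfigurationError(f"marker {marker!r} has no baseline")
    rng = np.random.default_rng(seed)
    donor_factors = donor_model.factors(rng)

    records = []
    for arch in archetypes:
        for d in range(donor_model.n_donors):
            donor = f"D{d + 1}"
            factor = donor_factors[d]
            cols = {
                "cell_id": [f"{arch.condition}.{arch.stage}.{donor}.{i}"
                            for i in range(n_cells)],
                "donor_id": donor,
                "condition": arch.condition,
                "stage": arch.stage,
            }
            volume_factor = ((arch.mean_radius / volume_reference_radius)
                             ** 3 if volume_scaling else 1.0)
            for marker in SCMEP_MARKERS:
                mean = coupling.marker_mean(marker, arch.key) * volume_factor
                z = rng.standard_normal(n_cells)
                cols[marker] = mean * factor * np.exp(arch.cell_sigma * z)
            for marker in SCMEP_IMMUNE_MARKERS:
                mean = arch.marker_means.get(marker, 50.0)
                z = rng.standard_normal(n_cells)
                cols[marker] = mean * factor * np.exp(arch.cell_sigma * z)
            zr = rng.standard_normal(n_cells)
            cols["cell_radius"] = arch.mean_radius * np.exp(
                _RADIUS_SIGMA * zr)
            records.append(pd.DataFrame(cols))
    table = pd.concat(records, ignore_index=True)
    return validate_event_table(table, "scmep")
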