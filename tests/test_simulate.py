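"""Synthetic-data generator: ground truth, determinism, recovery."""

import dataclasses

import numpy as np
import pytest

import scenmep as sm
from scenmep.simulate import SCENITH_WELLS


class TestArchetypes:
    def test_builtin_truths_match_reference_percentages(self,
                                                        archetypes_by_key):
        """Ground truths equal the study's printed metabolic parameters."""
        expected = {
            ("ctrl", "mono_0h"): {"mitochondrial_dependence": 18,
                                  "glycolytic_capacity": 82},
            ("ctrl", "mono_24h"): {"mitochondrial_dependence": 72,
                                   "glycolytic_capacity": 28},
            ("ctrl", "iDC"): {"mitochondrial_dependence": 79,
                              "fao_dependence": 19,
                              "glutaminolysis_dependence": 19,
                              "faao_capacity": 45},
            ("ctrl", "mDC"): {"mitochondrial_dependence": 86,
                              "faao_capacity": 24,
                              "glycolytic_capacity": 14,
                              "fao_dependence": 7,
                              "glutaminolysis_dependence": 41},
            ("vitd3", "mono_24h"): {"glycolytic_capacity": 53},
            ("vitd3_dexa", "iDC"): {"faao_capacity": 60},
            ("exvivo", "mono_0h"): {"glucose_dependence": 72,
                                    "glycolytic_capacity": 71},
            ("exvivo", "cDC1"): {"mitochondrial_dependence": 79,
                                 "faao_capacity": 65},
            ("exvivo", "pDC"): {"faao_capacity": 65},
        }
        for key, params in expected.items():
            truth = archetypes_by_key[key].ground_truth()
            for name, value in params.items():
                assert truth[name] == pytest.approx(value), (key, name)

    def test_subpopulation_truths(self, archetypes_by_key):
        idc = archetypes_by_key[("ctrl", "iDC")]
        assert idc.subpopulation_truth("CD86hi")[
            "mitochondrial_dependence"] == pytest.approx(81)
        assert idc.subpopulation_truth("CD1chi")[
            "mitochondrial_dependence"] == pytest.approx(65)
        assert idc.subpopulation_truth("CD1chi")[
            "glycolytic_capacity"] == pytest.approx(35)
        mdc = archetypes_by_key[("ctrl", "mDC")]
        assert mdc.subpopulation_truth("CD86hi")[
            "mitochondrial_dependence"] == pytest.approx(90)
        act = archetypes_by_key[("ctrl", "actDC")]
        assert act.subpopulation_truth("CD1chi")[
            "glycolytic_capacity"] == pytest.approx(50)

    def test_archetype_invariants_hold_for_all_builtins(self, archetypes):
        for a in archetypes:
            pm = a.puromycin_means
            for w in ("O", "DG", "Eto", "Tele"):
                assert pm["DGO"] <= pm[w] <= pm["C"]
            assert all(v > 0 for v in pm.values())
            if a.subpopulations:
                assert sum(s.fraction for s in a.subpopulations) == \
                    pytest.approx(1.0)

    def test_bulk_backsolve_reconciles_overall_mean(self, archetypes_by_key):
        """Fraction-weighted geometric mean of subpop means equals the
        archetype's stated overall well mean."""
        idc = archetypes_by_key[("ctrl", "iDC")]
        means = idc.well_means("O")
        log_mix = sum(s.fraction * np.log(means[s.label])
                      for s in idc.subpopulations)
        assert np.exp(log_mix) == pytest.approx(
            idc.puromycin_means["O"], rel=1e-12)

    def test_inverted_well_means_rejected(self):
        with pytest.raises(sm.ConfigurationError, match="outside"):
            sm.Archetype("iDC", "ctrl",
                         {"C": 100.0, "DG": 50.0, "O": 150.0, "DGO": 10.0,
                          "Eto": 90.0, "Tele": 90.0},
                         {"CD86": 10.0})

    def test_bad_subpopulation_fractions_rejected(self):
        with pytest.raises(sm.ConfigurationError, match="fraction"):
            sm.Archetype("iDC", "ctrl",
                         {"C": 100.0, "DG": 50.0, "O": 60.0, "DGO": 10.0,
                          "Eto": 90.0, "Tele": 90.0},
                         {"CD86": 10.0},
                         subpopulations=(
                             sm.Subpopulation("CD86hi", 0.25),
                             sm.Subpopulation("bulk", 0.5)))


class TestScenithGenerator:
    def test_noiseless_events_equal_well_means(self, archetypes_by_key):
        arch = dataclasses.replace(archetypes_by_key[("ctrl", "mono_0h")],
                                   cell_sigma=0.0)
        table = sm.generate_scenith_dataset(
            [arch], n_cells_per_well=20,
            donor_model=sm.DonorModel(1, 0.0), seed=3)
        for well in SCENITH_WELLS:
            vals = table.loc[table["inhibitor"] == well, "puromycin"]
            assert np.allclose(vals, arch.puromycin_means[well])

    def test_same_seed_gives_identical_tables(self, archetypes_by_key):
        arch = archetypes_by_key[("ctrl", "iDC")]
        kw = dict(n_cells_per_well=50, donor_model=sm.DonorModel(2, 0.1))
        a = sm.generate_scenith_dataset([arch], seed=5, **kw)
        b = sm.generate_scenith_dataset([arch], seed=5, **kw)
        assert a.equals(b)
        c = sm.generate_scenith_dataset([arch], seed=6, **kw)
        assert not a["puromycin"].equals(c["puromycin"])

    def test_well_gmfi_within_one_percent_at_n5000(self, archetypes_by_key):
        arch = archetypes_by_key[("ctrl", "mDC")]
        table = sm.generate_scenith_dataset(
            [arch], n_cells_per_well=5000,
            donor_model=sm.DonorModel(1, 0.0), seed=7)
        for well in ("C", "DG", "DGO"):  # wells without subpop overrides
            vals = table.loc[table["inhibitor"] == well, "puromycin"]
            gmfi = np.exp(np.mean(np.log(vals)))
            assert gmfi == pytest.approx(arch.puromycin_means[well],
                                         rel=0.01)

    def test_subpopulation_counts_are_exact(self, archetypes_by_key):
        arch = archetypes_by_key[("ctrl", "iDC")]
        table = sm.generate_scenith_dataset(
            [arch], n_cells_per_well=400,
            donor_model=sm.DonorModel(1, 0.0), seed=1)
        counts = table[table["inhibitor"] == "O"][
            "subpopulation"].value_counts()
        assert counts["CD86hi"] == 100
        assert counts["CD1chi"] == 100
        assert counts["bulk"] == 200

    def test_subpopulation_marker_shift(self, archetypes_by_key):
        arch = dataclasses.replace(archetypes_by_key[("ctrl", "iDC")],
                                   cell_sigma=0.0)
        table = sm.generate_scenith_dataset(
            [arch], n_cells_per_well=200,
            donor_model=sm.DonorModel(1, 0.0), seed=1)
        cd86hi = table[table["subpopulation"] == "CD86hi"]
        bulk = table[table["subpopulation"] == "bulk"]
        assert cd86hi["CD86"].iloc[0] == pytest.approx(
            4.0 * bulk["CD86"].iloc[0])

    def test_harringtonine_well_near_zero_translation(self,
                                                      archetypes_by_key):
        arch = dataclasses.replace(archetypes_by_key[("ctrl", "mono_0h")],
                                   cell_sigma=0.0, subpopulations=())
        table = sm.generate_scenith_dataset(
            [arch], n_cells_per_well=10,
            donor_model=sm.DonorModel(1, 0.0), seed=1)
        h = table.loc[table["inhibitor"] == "H", "puromycin"]
        assert np.allclose(h, 0.02 * arch.puromycin_means["C"])

    def test_empty_archetype_list_rejected(self):
        with pytest.raises(sm.ConfigurationError, match="empty"):
            sm.generate_scenith_dataset([], n_cells_per_well=10)

    def test_generated_tables_pass_validation(self, small_scenith_table):
        sm.validate_event_table(small_scenith_table, "scenith")


class TestNoiselessRecovery:
    def test_full_pipeline_recovers_every_archetype_exactly(
            self, noiseless_archetypes):
        """Noiseless simulate → gMFI → formulas reproduces all truths."""
        table = sm.generate_scenith_dataset(
            noiseless_archetypes, n_cells_per_well=200,
            donor_model=sm.DonorModel(2, 0.0), seed=1)
        profiles = sm.profiles_from_events(
            table, by=("condition", "stage"), min_cells=100,
            required=("C", "DG", "O", "DGO", "Eto", "Tele"))
        by_key = {a.key: a for a in noiseless_archetypes}
        assert len(profiles) == len(by_key)
        for p in profiles:
            truth = by_key[(p.group["condition"],
                            p.group["stage"])].ground_truth()
            for name, value in truth.items():
                assert p.raw[name] == pytest.approx(value, abs=1e-9), \
                    (p.group, name)

    def test_noisy_recovery_within_two_points_across_seeds(
            self, archetypes_by_key):
        """sigma=0.2, n=5000/well: recovered parameters stay within +/-2
        percentage points of truth over many seeds."""
        arch = archetypes_by_key[("ctrl", "mono_24h")]
        truth = arch.ground_truth()
        for seed in range(20):
            table = sm.generate_scenith_dataset(
                [arch], n_cells_per_well=5000,
                donor_model=sm.DonorModel(1, 0.0), seed=seed,
                include_h_well=False)
            (profile,) = sm.profiles_from_events(
                table, by=("condition", "stage"))
            for name in ("mitochondrial_dependence", "glucose_dependence"):
                assert abs(profile.raw[name] - truth[name]) < 2.0, seed


class TestScmepGenerator:
    def test_unit_multipliers_share_marker_means(self, archetypes_by_key):
        archs = [dataclasses.replace(archetypes_by_key[k], cell_sigma=0.0)
                 for k in (("ctrl", "mono_0h"), ("ctrl", "mDC"))]
        coupling = sm.coupling_from_archetypes(archs)
        flat = sm.CouplingConfig(
            coupling.pathway_markers, coupling.baseline_means,
            {k: {p: 1.0 for p in coupling.pathway_markers}
             for k in coupling.multipliers})
        table = sm.generate_scmep_dataset(
            archs, coupling=flat, donor_model=sm.DonorModel(1, 0.0),
            n_cells=10, seed=1)
        for marker in ("CS", "GLUT1", "HADHA"):
            assert table.groupby("stage", observed=True)[marker] \
                .first().nunique() == 1

    def test_doubling_tca_multiplier_scales_members_only(
            self, archetypes_by_key):
        arch = dataclasses.replace(archetypes_by_key[("ctrl", "mono_0h")],
                                   cell_sigma=0.0)
        coupling = sm.coupling_from_archetypes([arch])
        doubled = sm.CouplingConfig(
            coupling.pathway_markers, coupling.baseline_means,
            {arch.key: dict(coupling.multipliers[arch.key],
                            **{"TCA/ETC":
                               2 * coupling.multipliers[arch.key]["TCA/ETC"]
                               })})
        kw = dict(donor_model=sm.DonorModel(1, 0.0), n_cells=5, seed=2)
        base = sm.generate_scmep_dataset([arch], coupling=coupling, **kw)
        double = sm.generate_scmep_dataset([arch], coupling=doubled, **kw)
        for marker in ("CS", "ATP5A", "IDH2"):
            np.testing.assert_allclose(double[marker], 2 * base[marker])
        for marker in ("SDHA", "CytC", "GLUT1", "HADHA", "GSS"):
            np.testing.assert_allclose(double[marker], base[marker])

    def test_radius_encodes_fourfold_volume_increase(self, archetypes):
        archs = [a for a in archetypes
                 if a.key in (("ctrl", "mono_0h"), ("ctrl", "mDC"))]
        table = sm.generate_scmep_dataset(
            archs, donor_model=sm.DonorModel(2, 0.1), n_cells=4000, seed=7)
        mean_r = table.groupby("stage", observed=True)["cell_radius"].mean()
        ratio = mean_r["mDC"] / mean_r["mono_0h"]
        assert ratio == pytest.approx(4 ** (1 / 3), rel=0.01)

    def test_marker_without_baseline_rejected(self, archetypes_by_key):
        arch = archetypes_by_key[("ctrl", "mono_0h")]
        with pytest.raises(sm.ConfigurationError, match="baseline"):
            sm.CouplingConfig({"TCA/ETC": ("CS", "NOPE")}, {"CS": 50.0}, {})

    def test_deterministic_under_seed(self, archetypes_by_key):
        arch = archetypes_by_key[("ctrl", "iDC")]
        kw = dict(donor_model=sm.DonorModel(2, 0.1), n_cells=30)
        a = sm.generate_scmep_dataset([arch], seed=9, **kw)
        b = sm.generate_scmep_dataset([arch], seed=9, **kw)
        assert a.equals(b)
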