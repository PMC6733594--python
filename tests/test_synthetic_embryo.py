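"""Ground-truth model: geometry, activity fields, marker trajectories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phresh.errors import InvalidParameterError
from phresh.synthetic_embryo import (ActivityField, Cell, PerturbationSpec,
                                     PhaseSchedule, SpinalCordGeometry,
                                     build_embryo, hh_activity,
                                     marker_domain_truth, notch_activity,
                                     notch_activity_vec, hh_activity_vec,
                                     CONTROL_FRACTIONS, MARKERS)


def cord_cell(dv, ml=0.5, cid=0):
    return Cell(cid, "spinal_cord", dv, ml, 100.0)


class TestGeometryAndTypes:
    def test_geometry_invariants_enforced(self):
        with pytest.raises(InvalidParameterError):
            SpinalCordGeometry(dv_height=-1)
        with pytest.raises(InvalidParameterError):
            SpinalCordGeometry(canal_dv_frac=1.5)
        with pytest.raises(InvalidParameterError):
            SpinalCordGeometry(ap_length=50.0, somite_length=25.0)
        with pytest.raises(InvalidParameterError):
            SpinalCordGeometry(cell_diameter=30.0)

    def test_schedule_must_be_contiguous_and_ordered(self):
        with pytest.raises(InvalidParameterError):
            PhaseSchedule(activation=(24, 42), consolidation=(43, 66))
        with pytest.raises(InvalidParameterError):
            PhaseSchedule(activation=(42, 24))

    def test_perturbation_heatshock_contract(self):
        with pytest.raises(InvalidParameterError):
            PerturbationSpec(transgene="NICD")  # no heat-shock time
        with pytest.raises(InvalidParameterError):
            PerturbationSpec(heatshock_time=11.0)  # no transgene
        with pytest.raises(InvalidParameterError):
            PerturbationSpec(drug="nocodazole")


class TestBuildEmbryo:
    def test_seeded_determinism(self, geometry):
        a = build_embryo(geometry, cell_spacing=4.0, seed=42)
        b = build_embryo(geometry, cell_spacing=4.0, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_cells_span_five_somites(self):
        g = SpinalCordGeometry(ap_length=125.0, somite_length=25.0)
        pop = build_embryo(g, cell_spacing=5.0, seed=0)
        somite_idx = np.floor(pop["ap_um"].to_numpy()
                              / g.somite_length).astype(int)
        inside = somite_idx[(pop["ap_um"] >= 0)
                            & (pop["ap_um"] < g.ap_length)]
        assert set(inside) == {0, 1, 2, 3, 4}

    def test_fractions_contained(self, small_population):
        cord = small_population[small_population.tissue == "spinal_cord"]
        assert cord["dv_frac"].between(0, 1).all()
        assert cord["ml_frac"].between(0, 1).all()

    def test_all_tissues_present_and_ids_unique(self, small_population):
        assert set(small_population.tissue) == {"spinal_cord", "somite",
                                                "vasculature"}
        assert small_population["id"].is_unique

    def test_invalid_spacing_rejected(self, geometry):
        with pytest.raises(InvalidParameterError):
            build_embryo(geometry, cell_spacing=0.0)
        with pytest.raises(InvalidParameterError):
            build_embryo(geometry, cell_spacing=100.0)


class TestNotchActivity:
    def test_dv_uniform_during_activation(self):
        assert notch_activity(cord_cell(0.2), 30.0) == \
            notch_activity(cord_cell(0.8), 30.0)

    def test_ly_abolishes_response_after_four_hours(self, ly_treatment):
        assert notch_activity(cord_cell(0.4), 24.0, ly_treatment) == 0.0
        assert notch_activity(cord_cell(0.4), 30.0, ly_treatment) == 0.0

    def test_basal_after_termination(self):
        assert notch_activity(cord_cell(0.4), 80.0) == pytest.approx(0.02)

    def test_nicd_maximal_cordwide_after_heatshock(self):
        nicd = PerturbationSpec(transgene="NICD", heatshock_time=11.0)
        assert notch_activity(cord_cell(0.95), 24.0, nicd) == 1.0

    def test_mindbomb_never_responds(self):
        mib = PerturbationSpec(genotype="mindbomb")
        for t in (24.0, 30.0, 48.0):
            assert notch_activity(cord_cell(0.5), t, mib) == 0.0


class TestHhActivity:
    def test_ventral_graded_response(self):
        lo = hh_activity(cord_cell(0.1), 30.0)
        mid = hh_activity(cord_cell(0.5), 30.0)
        hi = hh_activity(cord_cell(0.9), 30.0)
        assert lo > mid > 0.02
        assert hi == pytest.approx(0.02)

    def test_somite_response_notch_independent(self, ly_treatment):
        cell = Cell(0, "somite", 0.5, 0.5, 100.0)
        assert hh_activity(cell, 30.0, ly_treatment) == \
            hh_activity(cell, 30.0)

    def test_smoM2_blocked_in_notch_off_cord(self):
        smo = PerturbationSpec(transgene="rSmoM2", heatshock_time=20.0)
        cell = cord_cell(0.5)
        assert hh_activity(cell, 30.0, smo, notch_level=0.0) == 0.0
        boosted = hh_activity(cell, 30.0, smo, notch_level=1.0)
        assert boosted > hh_activity(cell, 30.0)

    def test_smoM2_expands_somite_response_despite_ly(self):
        smo_ly = PerturbationSpec(transgene="rSmoM2", heatshock_time=20.0,
                                  drug="LY411575", drug_start=20.0)
        cell = Cell(0, "somite", 0.5, 0.5, 100.0)
        assert hh_activity(cell, 30.0, smo_ly) > hh_activity(cell, 30.0)

    def test_gli1_drive_survives_notch_inhibition_below_max(self):
        gli = PerturbationSpec(transgene="EGFP_Gli1", heatshock_time=20.0,
                               drug="LY411575", drug_start=20.0)
        lvl = hh_activity(cord_cell(0.3), 30.0, gli, notch_level=0.0)
        assert 0.0 < lvl < 1.0

    def test_iguana_low_uniform_response_blocked_by_notch_loss(self):
        igu = PerturbationSpec(genotype="iguana")
        a = hh_activity(cord_cell(0.2), 30.0, igu)
        b = hh_activity(cord_cell(0.7), 30.0, igu)
        assert a == b == pytest.approx(0.3)
        # cyclopamine-insensitive (Smo-independent)
        igu_cyc = PerturbationSpec(genotype="iguana", drug="cyclopamine",
                                   drug_start=20.0)
        assert hh_activity(cord_cell(0.2), 30.0, igu_cyc) == a
        assert hh_activity(cord_cell(0.2), 30.0, igu, notch_level=0.0) == 0.0

    def test_cyclopamine_leaves_residual_cord_floor(self):
        cyc = PerturbationSpec(drug="cyclopamine", drug_start=20.0)
        lvl = hh_activity(cord_cell(0.1), 30.0, cyc)
        assert lvl == pytest.approx(0.1, abs=1e-9)
        somite = Cell(0, "somite", 0.5, 0.5, 100.0)
        assert hh_activity(somite, 30.0, cyc) == 0.0

    def test_invalid_notch_level_rejected(self):
        with pytest.raises(InvalidParameterError):
            hh_activity(cord_cell(0.5), 30.0, notch_level=1.5)


class TestFieldProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dv=st.floats(0, 1), ml=st.floats(0, 1),
           t=st.floats(24, 78), notch=st.floats(0, 1),
           tissue=st.sampled_from(["spinal_cord", "somite", "vasculature"]))
    def test_levels_bounded(self, dv, ml, t, notch, tissue):
        cell = Cell(0, tissue, dv, ml, 100.0)
        for pert in (PerturbationSpec(),
                     PerturbationSpec(drug="LY411575", drug_start=20.0),
                     PerturbationSpec(transgene="rSmoM2",
                                      heatshock_time=20.0)):
            assert 0.0 <= notch_activity(cell, t, pert) <= 1.0
            assert 0.0 <= hh_activity(cell, t, pert, notch) <= 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(dv=st.floats(0, 1), t=st.floats(24, 78), notch=st.floats(0, 1))
    def test_notch_gating_monotone(self, dv, t, notch):
        cell = cord_cell(dv)
        off = hh_activity(cell, t, notch_level=0.0)
        part = hh_activity(cell, t, notch_level=notch)
        on = hh_activity(cell, t, notch_level=1.0)
        assert off <= part <= on
        assert off == 0.0

    def test_dv_monotone_during_activation(self):
        dv = np.linspace(0, 1, 201)
        for t in (24.0, 30.0, 36.0, 41.9):
            lvl = hh_activity_vec(dv, np.full_like(dv, 0.5),
                                  np.full(dv.shape, "spinal_cord"), t,
                                  PerturbationSpec(), np.ones_like(dv),
                                  PhaseSchedule(), SpinalCordGeometry())
            assert np.all(np.diff(lvl) <= 1e-12)

    def test_consolidation_width_non_increasing(self):
        dv = np.linspace(0, 1, 1001)
        widths = []
        for t in np.linspace(42.0, 66.0, 9):
            lvl = hh_activity_vec(dv, np.full_like(dv, 0.5),
                                  np.full(dv.shape, "spinal_cord"), t,
                                  PerturbationSpec(), np.ones_like(dv),
                                  PhaseSchedule(), SpinalCordGeometry())
            widths.append(np.mean(lvl > lvl.max() / 2))
        assert np.all(np.diff(widths) <= 1e-12)

    def test_somite_ly_equality_exact_over_time(self, ly_treatment):
        cell = Cell(0, "somite", 0.3, 0.5, 100.0)
        for t in np.linspace(24, 78, 12):
            assert hh_activity(cell, t, ly_treatment) == \
                hh_activity(cell, t)


class TestActivityField:
    def test_heterogeneity_deterministic_and_bounded(self, small_population):
        f1 = ActivityField(heterogeneity_sigma=0.1, seed=5)
        f2 = ActivityField(heterogeneity_sigma=0.1, seed=5)
        a1 = f1.evaluate(small_population, 30.0, "hh")
        a2 = f2.evaluate(small_population, 30.0, "hh")
        np.testing.assert_array_equal(a1, a2)
        assert (a1 >= 0).all() and (a1 <= 1).all()

    def test_unknown_pathway_rejected(self, small_population):
        with pytest.raises(InvalidParameterError):
            ActivityField().evaluate(small_population, 30.0, "wnt")

    def test_callable_matches_vector_path(self):
        field = ActivityField()
        cell = cord_cell(0.25, cid=3)
        assert field(cell, 30.0, "hh") == pytest.approx(
            hh_activity(cell, 30.0, notch_level=notch_activity(cell, 30.0)))


class TestMarkerDomainTruth:
    def test_ly_timecourse_knots(self, ly_treatment):
        assert marker_domain_truth("ptc2", ly_treatment, 1.0) == \
            pytest.approx(CONTROL_FRACTIONS["ptc2"] * (1 - 0.44))
        assert marker_domain_truth("sox2", ly_treatment, 1.0) == \
            pytest.approx(CONTROL_FRACTIONS["sox2"] * (1 - 0.10))
        assert marker_domain_truth("ptc2", ly_treatment, 2.0) == \
            pytest.approx(CONTROL_FRACTIONS["ptc2"] * 0.50)
        assert marker_domain_truth("sox2", ly_treatment, 3.0) == \
            pytest.approx(CONTROL_FRACTIONS["sox2"] * 0.35)

    def test_gli1_rescue_and_enlargement(self):
        gli_ly = PerturbationSpec(transgene="EGFP_Gli1", heatshock_time=20.0,
                                  drug="LY411575", drug_start=20.0)
        assert marker_domain_truth("olig2", gli_ly, 10.0) == \
            pytest.approx(0.63 * CONTROL_FRACTIONS["olig2"])
        gli = PerturbationSpec(transgene="EGFP_Gli1", heatshock_time=20.0)
        assert marker_domain_truth("olig2", gli, 10.0) == \
            pytest.approx(1.25 * CONTROL_FRACTIONS["olig2"])

    def test_control_trajectory_constant(self):
        for h in (0.0, 1.0, 5.0, 10.0):
            assert marker_domain_truth("ptc2", PerturbationSpec(), h) == \
                CONTROL_FRACTIONS["ptc2"]

    def test_unknown_marker_rejected(self):
        with pytest.raises(InvalidParameterError):
            marker_domain_truth("shha", PerturbationSpec(), 1.0)
        with pytest.raises(InvalidParameterError):
            marker_domain_truth("ptc2", PerturbationSpec(), -1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(marker=st.sampled_from(MARKERS), hours=st.floats(0, 12),
           drug=st.sampled_from(["none", "cyclopamine", "LY411575"]),
           transgene=st.sampled_from(["none", "NICD", "rSmoM2",
                                      "EGFP_Gli1"]),
           genotype=st.sampled_from(["wildtype", "iguana", "mindbomb"]))
    def test_fractions_bounded(self, marker, hours, drug, transgene,
                               genotype):
        pert = PerturbationSpec(
            drug=drug, transgene=transgene, genotype=genotype,
            heatshock_time=20.0 if transgene != "none" else None)
        assert 0.0 <= marker_domain_truth(marker, pert, hours) <= 1.0
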