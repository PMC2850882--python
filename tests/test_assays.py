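import numpy as np
import pandas as pd
import pytest

import p38compete as pc


class TestRunAssay:
    def test_zero_dose_normalises_to_one(self, params, classical):
        drs = pc.run_assay(pc.AssayProtocol(), params, "base", classical,
                           doses=[0.0, 1.0, 10.0, 100.0, 1e3, 1e4])
        for dr in drs.values():
            assert dr.normalized[0] == 1.0

    def test_classical_saturating_dose_abolishes_signal(self, params, classical):
        drs = pc.run_assay(pc.AssayProtocol(), params, "base", classical,
                           doses=[0.0, 1e6 * classical.ki])
        for dr in drs.values():
            assert dr.normalized[-1] < 0.01

    def test_huge_ki_reproduces_uninhibited_trajectory(self, params):
        weak = pc.InhibitorSpec(ki=1e9, inhibitor_class="classical")
        with_i = pc.simulate_protocol(pc.AssayProtocol(), params, "base",
                                      weak, 100.0)
        without = pc.simulate_protocol(pc.AssayProtocol(), params)
        assert with_i.value("pATF2", 7200.0) == pytest.approx(
            without.value("pATF2", 7200.0), rel=1e-3)
        assert with_i.value("pMK2", 1800.0) == pytest.approx(
            without.value("pMK2", 1800.0), rel=1e-3)

    def test_dual_and_single_atf2_virtually_indistinguishable_base(self, params):
        dual = pc.simulate_protocol(pc.AssayProtocol(), params)
        single = pc.simulate_protocol(pc.AssayProtocol.single_atf2(), params)
        rel = abs(dual.value("pATF2", 7200.0) / single.value("pATF2", 7200.0) - 1)
        assert rel < 0.05

    def test_dose_grid_contract(self):
        g = pc.default_dose_grid(1.0)
        assert g[0] == 0.0 and len(g) == 13
        assert g[1] == pytest.approx(0.01) and g[-1] == pytest.approx(1e4)
        assert np.all(np.diff(g) > 0)


class TestMK2Titration:
    def test_zero_mk2_equals_single_substrate_assay_exactly(self, params):
        df = pc.mk2_titration(pc.AssayProtocol(), params, "base",
                              mk2_levels=[0.0, 10.0])
        single = pc.simulate_protocol(pc.AssayProtocol.single_atf2(), params)
        assert df.pATF2_nM.iloc[0] == single.value("pATF2", 7200.0)

    @pytest.mark.parametrize("mech", ["altered_atf2_affinity", "altered_kcat"])
    def test_altered_mechanisms_strictly_decreasing(self, params, mech):
        df = pc.mk2_titration(pc.AssayProtocol(), params, mech,
                              mk2_levels=[0, 5, 10, 20, 50, 100])
        assert np.all(np.diff(df.pATF2_nM.to_numpy()) < 0)

    def test_negative_levels_rejected(self, params):
        with pytest.raises(ValueError):
            pc.mk2_titration(pc.AssayProtocol(), params, "base",
                             mk2_levels=[-1.0, 0.0])


class TestVirtualCompound:
    def test_isotherm_values(self):
        assert pc.virtual_compound_p38(1.0, 1.0, 0.5) == pytest.approx(0.25)
        assert pc.virtual_compound_p38(0.0, 1.0, 0.5) == 0.5
        assert pc.virtual_compound_p38(1e12, 1.0, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pc.virtual_compound_p38(1.0, 0.0, 0.5)
        with pytest.raises(ValueError):
            pc.virtual_compound_p38(-1.0, 1.0, 0.5)

    def test_left_shift_of_patf2_under_altered_mechanism(self, params_lit, ic50_of):
        """In the dual assay with an MK2-altered enzyme the virtual compound
        hits phospho-ATF2 at lower doses than phospho-MK2."""
        drs = pc.virtual_compound_assay(pc.AssayProtocol(), params_lit,
                                        "altered_atf2_affinity", ki=1.0)
        assert ic50_of(drs["pATF2"]) < ic50_of(drs["pMK2"])


class TestIPTwoStage:
    def test_base_mechanism_is_mk2_independent(self, params_lit):
        df = pc.ip_two_stage(params_lit, "base", mk2_levels=(0.0, 10.0, 50.0))
        vals = df.pATF2_nM.to_numpy()
        assert np.allclose(vals, vals[0], rtol=1e-6)
        assert np.allclose(df.p38_carried_nM.to_numpy(), 5.0, rtol=1e-6)

    def test_zero_mk2_matches_single_substrate_assay_at_5nM(self, params_lit):
        df = pc.ip_two_stage(params_lit, "altered_kcat", mk2_levels=(0.0,))
        direct = pc.simulate_protocol(
            pc.AssayProtocol.single_atf2(p38_nM=5.0), params_lit,
            "altered_kcat")
        assert df.pATF2_nM.iloc[0] == pytest.approx(
            direct.value("pATF2", 7200.0), rel=1e-6)

    def test_mk2_preincubation_inhibits_under_altered_mechanism(self, params_lit):
        df = pc.ip_two_stage(params_lit, "altered_kcat",
                             mk2_levels=(0.0, 5.0, 25.0, 100.0))
        vals = df.pATF2_nM.to_numpy()
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.25 * vals[0]  # dramatic inhibition


class TestExport:
    def test_dose_response_frame_schema_and_order(self, params, classical):
        drs = pc.run_assay(pc.AssayProtocol(), params, "base", classical,
                           doses=[0.0, 1.0, 10.0, 100.0, 1e3, 1e4])
        df = pc.dose_responses_to_frame(drs, "demo")
        assert list(df.columns) == [
            "assay_id", "mechanism", "inhibitor_class", "species",
            "dose_nM", "replicate", "raw_nM", "normalized",
        ]
        assert list(df.species.unique()) == sorted(drs)
        assert (df.assay_id == "demo").all()

    def test_csv_round_trip_lossless(self, tmp_path, params, classical):
        drs = pc.run_assay(pc.AssayProtocol(), params, "base", classical,
                           doses=[0.0, 1.0, 10.0, 100.0, 1e3, 1e4])
        df = pc.dose_responses_to_frame(drs, "demo")
        path = tmp_path / "dr.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        back = pd.read_csv(path)
        for col in ("dose_nM", "raw_nM", "normalized"):
            assert np.allclose(back[col], df[col], rtol=1e-12, atol=0)
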