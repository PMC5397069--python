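import numpy as np
import pytest

from betaox import (
    GeneratorConfig,
    build_mfao_topology,
    find_flux_peak,
    find_steady_state,
    generate_ladder,
    integrate,
    scan,
)
from betaox.core import ModelState
from betaox.mfao import substrate_parameter


class TestIntegrate:
    def test_fixed_point_stays_constant(self, mfao_model):
        model = mfao_model.copy()
        model.set_parameter("conc_C16AcylCoACYT", 0.0)
        model.set_parameter("conc_AcetylCoAMAT", 0.0)
        conc = {n: 0.0 for n in model.variable_names}
        for m in model.moieties:
            conc[m.pivot] = m.total
        traj = integrate(model, ModelState(0.0, conc), 100.0)
        end = traj.endpoint()
        for name, value in conc.items():
            assert end.concentrations[name] == pytest.approx(value, abs=1e-8)

    def test_moiety_drift_under_1e6_relative(self, mfao_model):
        model = mfao_model.copy()
        model.set_parameter(substrate_parameter(model), 30.0)
        traj = integrate(model, model.default_state(), 400.0)
        drift = traj.moiety_drift()
        assert max(drift.values()) < 1e-6

    def test_endpoint_matches_steady_state(self, mfao_model):
        # two independent routes to the same fixed point
        model = mfao_model.copy()
        model.set_parameter(substrate_parameter(model), 10.0)
        ss = find_steady_state(model)
        assert ss.converged
        traj = integrate(model, model.default_state(), 3000.0)
        end = traj.endpoint()
        for name, target in ss.state.concentrations.items():
            got = end.concentrations[name]
            assert got == pytest.approx(target, rel=1e-6, abs=1e-9)

    def test_t_end_must_be_positive(self, mfao_model):
        with pytest.raises(ValueError):
            integrate(mfao_model, None, 0.0)


class TestFindSteadyState:
    def test_zero_substrate_gives_zero_flux_and_full_pool(self, mfao_model):
        model = mfao_model.copy()
        model.set_parameter("conc_C16AcylCoACYT", 0.0)
        model.set_parameter("conc_AcetylCoAMAT", 0.0)
        res = find_steady_state(model)
        assert res.converged
        assert res.J_uptake == pytest.approx(0.0, abs=1e-9)
        total = next(m.total for m in model.moieties if m.name == "CoA")
        assert res.state.concentrations["CoAMAT"] == pytest.approx(total, rel=1e-9)

    def test_residual_below_tolerance(self, mfao_ss_low):
        _, res = mfao_ss_low
        assert res.converged
        assert res.residual_norm < 1e-9

    def test_c16_flux_ratio_is_seven(self, mfao_ss_low):
        _, res = mfao_ss_low
        assert res.J_uptake > 0
        assert res.flux_ratio() == pytest.approx(7.0, rel=1e-9)

    def test_c8_ladder_flux_ratio_is_three(self):
        model = generate_ladder(GeneratorConfig(start_chain=8, seed=7))
        model.set_parameter("conc_C8AcylCoACYT", 1.0)
        res = find_steady_state(model)
        assert res.converged and res.J_uptake > 0
        assert res.flux_ratio() == pytest.approx(3.0, rel=1e-9)

    def test_reaction_by_reaction_node_balance(self, mfao_ss_high):
        model, res = mfao_ss_high
        n_var = model.stoichiometry_matrix()
        v = np.array([res.fluxes[rid] for rid in model.reaction_ids])
        assert np.max(np.abs(n_var @ v)) < 1e-9


class TestScan:
    def test_single_point_scan_matches_direct_solve(self, mfao_model):
        model = mfao_model.copy()
        table = scan(model, substrate_parameter(model), [5.0], descending_check=False)
        model.set_parameter(substrate_parameter(model), 5.0)
        direct = find_steady_state(model)
        assert table["J_uptake"].iloc[0] == pytest.approx(direct.J_uptake, rel=1e-9)

    def test_flux_rises_then_declines(self, mfao_model):
        grid = [0.1, 1, 5, 10, 20, 30, 40, 50, 60, 80, 100]
        table = scan(mfao_model.copy(), substrate_parameter(mfao_model), grid,
                     descending_check=False)
        assert table["converged"].all()
        j = table["J_uptake"].to_numpy()
        k = int(np.argmax(j))
        assert 0 < k < len(j) - 1  # interior maximum
        assert j[-1] < j[k]

    def test_short_chain_esters_dominate_accumulation(self, mfao_model):
        grid = [0.1, 60.0]
        table = scan(mfao_model.copy(), substrate_parameter(mfao_model), grid,
                     descending_check=False)
        row = table.iloc[-1]
        assert row["sum_C4C6_esters"] > 0.5 * row["sum_esters"]

    def test_enoyl_flux_routes_through_mtp(self, mfao_model):
        grid = [1.0, 10.0, 40.0]
        table = scan(mfao_model.copy(), substrate_parameter(mfao_model), grid,
                     descending_check=False)
        for _, row in table.iterrows():
            for n in (8, 10, 12, 14, 16):
                assert row[f"flux_vmtpC{n}"] > row[f"flux_vmckatC{n}"]

    def test_descending_rescan_reports_hysteresis_column(self, mfao_model):
        grid = [0.1, 1.0, 5.0]
        table = scan(mfao_model.copy(), substrate_parameter(mfao_model), grid)
        assert "J_uptake_descending" in table
        assert not table["hysteresis"].any()


class TestFindFluxPeak:
    def test_monotone_curve_has_no_interior_peak(self):
        import pandas as pd

        table = pd.DataFrame(
            {"param_value": [1, 2, 3, 4], "J_uptake": [1, 2, 2.5, 2.8],
             "converged": True}
        )
        peak = find_flux_peak(table)
        assert not peak.interior
        assert "no interior peak" in peak.message

    def test_quadratic_vertex_recovered(self):
        import pandas as pd

        x = np.linspace(0, 10, 21)
        y = -((x - 6.3) ** 2) + 40.0
        table = pd.DataFrame({"param_value": x, "J_uptake": y, "converged": True})
        peak = find_flux_peak(table)
        assert peak.interior
        assert peak.location == pytest.approx(6.3, abs=1e-9)
        assert peak.value == pytest.approx(40.0, abs=1e-9)

    def test_mfao_peak_near_50(self, mfao_model):
        grid = np.geomspace(0.5, 100, 16)
        table = scan(mfao_model.copy(), substrate_parameter(mfao_model), grid,
                     descending_check=False)
        peak = find_flux_peak(table, mfao_model.copy(), substrate_parameter(mfao_model))
        assert peak.interior
        assert 35.0 < peak.location < 65.0

    def test_too_few_rows(self):
        import pandas as pd

        table = pd.DataFrame({"param_value": [1.0], "J_uptake": [1.0],
                              "converged": True})
        assert not find_flux_peak(table).interior
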