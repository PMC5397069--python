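import numpy as np
import pytest

from betaox import find_steady_state, generate_linear_chain
from betaox.core import RateLaw
from betaox.mca import (
    NAD_RATIO_PARAMETER,
    chain_specific_fcc,
    control_table,
    dissect_response,
    elasticity,
    flux_control_coefficient,
    get_ratio_parameter,
    response_coefficient,
    set_ratio_parameter,
    summation_check,
    top_responses,
)

from oracles import control_coefficients_linear_chain, symbolic_elasticity


class TestLinearChainOracle:
    @pytest.mark.parametrize("n,seed", [(2, None), (2, 5), (3, None), (3, 11)])
    def test_finite_perturbation_matches_control_matrix(self, n, seed):
        model = generate_linear_chain(n, seed=seed)
        ref = find_steady_state(model)
        assert ref.converged and ref.J_uptake > 0
        oracle = control_coefficients_linear_chain(model, ref.state.concentrations)
        for enzyme, expected in oracle.items():
            est = flux_control_coefficient(model, ref, enzyme)
            assert est.accepted
            assert est.value == pytest.approx(expected, abs=1e-4)

    def test_summation_theorem_on_chains(self, chain2, chain3):
        for model in (chain2, chain3):
            ref = find_steady_state(model)
            total, _ = summation_check(model, ref)
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_near_irreversible_unsaturated_first_step_controls(self):
        model = generate_linear_chain(
            2,
            params={
                "vmax": [20.0, 500.0],
                "km": [200.0, 50.0, 5.0, 100.0],
                "keq": [1e6, 1e6],
            },
        )
        ref = find_steady_state(model)
        est = flux_control_coefficient(model, ref, "E1")
        assert est.value == pytest.approx(1.0, abs=0.05)


class TestMfaoControl:
    def test_cpt1_dominates_at_low_substrate(self, mfao_ss_low):
        model, ref = mfao_ss_low
        cpt1 = flux_control_coefficient(model, ref, "CPT1")
        assert cpt1.accepted
        assert cpt1.value == pytest.approx(1.0, abs=0.05)
        for enzyme in ("CACT", "MSCHAD", "MTP"):
            other = flux_control_coefficient(model, ref, enzyme)
            assert abs(other.value) < 0.05

    def test_summation_theorem_full_model(self, mfao_ss_high):
        model, ref = mfao_ss_high
        total, coeffs = summation_check(model, ref)
        assert total == pytest.approx(1.0, abs=1e-3)
        assert all(c.accepted for c in coeffs.values())

    def test_mckat_takes_over_past_the_peak(self, mfao_ss_high):
        model, ref = mfao_ss_high
        cpt1 = flux_control_coefficient(model, ref, "CPT1")
        mckat = flux_control_coefficient(model, ref, "MCKAT")
        assert cpt1.value < 0
        assert mckat.value > 0.3

    def test_chain_decomposition_closure(self, mfao_ss_high):
        model, ref = mfao_ss_high
        overall = flux_control_coefficient(model, ref, "MCKAT")
        parts = [
            chain_specific_fcc(model, ref, "MCKAT", n).value
            for n in (4, 6, 8, 10, 12, 14, 16)
        ]
        assert sum(parts) == pytest.approx(overall.value, abs=1e-3)

    def test_c4_c6_dominate_mckat_decomposition(self, mfao_ss_high):
        model, ref = mfao_ss_high
        parts = {
            n: chain_specific_fcc(model, ref, "MCKAT", n).value
            for n in (4, 6, 8, 12, 16)
        }
        assert parts[4] + parts[6] > 0.9 * sum(parts.values())

    def test_single_chain_enzyme_equals_overall(self, mfao_ss_low):
        model, ref = mfao_ss_low
        overall = flux_control_coefficient(model, ref, "CPT1")
        per_chain = chain_specific_fcc(model, ref, "CPT1", 16)
        assert per_chain.value == pytest.approx(overall.value, rel=1e-4)

    def test_vmax_response_equals_fcc(self, mfao_ss_low):
        model, ref = mfao_ss_low
        fcc = flux_control_coefficient(model, ref, "MTP")
        rc = response_coefficient(model, ref, "Vmax_MTP")
        assert rc.value == pytest.approx(fcc.value, rel=1e-6, abs=1e-9)

    def test_unused_parameter_has_zero_response(self, chain2):
        from betaox.core import Species

        model = chain2.copy()
        model.species["UNUSED"] = Species("UNUSED", "other", "cytosol",
                                         fixed=True, value=3.0)
        model.invalidate()
        ref = find_steady_state(model)
        rc = response_coefficient(model, ref, "conc_UNUSED")
        assert rc.value == pytest.approx(0.0, abs=1e-9)

    def test_top_responses_at_low_substrate_are_cpt1_related(self, mfao_ss_low):
        model, ref = mfao_ss_low
        params = [
            "Vmax_CPT1", "sf_CPT1_C16", "Km_CPT1_CarCYT", "conc_C16AcylCoACYT",
            "Vmax_MCKAT", "Vmax_MTP", "Keq_MSCHAD", NAD_RATIO_PARAMETER,
            "Vmax_MSCHAD", "Km_MCKAT_C4KetoacylCoAMAT",
        ]
        table = top_responses(model, ref, parameters=params, n_top=4)
        top4 = set(table["entity"])
        assert top4 <= {"Vmax_CPT1", "sf_CPT1_C16", "Km_CPT1_CarCYT",
                        "conc_C16AcylCoACYT"}


class TestElasticity:
    def test_mass_action_limit(self, chain2):
        # [S] << Km: reversible MM behaves mass-action, elasticity -> 1
        model = chain2.copy()
        model.set_parameter("conc_S0", 1e-4)
        model.set_parameter("conc_P", 0.0)
        state = model.default_state()
        state.concentrations["X1"] = 1e-9
        eps = elasticity(model, state, "v1", "S0")
        assert eps == pytest.approx(1.0, abs=1e-4)

    def test_saturated_limit(self, chain2):
        model = chain2.copy()
        model.set_parameter("conc_S0", 1e6)
        model.set_parameter("conc_P", 0.0)
        state = model.default_state()
        state.concentrations["X1"] = 1e-9
        eps = elasticity(model, state, "v1", "S0")
        assert eps == pytest.approx(0.0, abs=1e-4)

    def test_matches_symbolic_derivative(self, rng):
        law = RateLaw(
            sf=0.7,
            vmax=120.0,
            keq=4.2,
            km={"S": 9.0, "P": 17.0, "FAD": 33.0, "FADH2": 8.0, "I1": 21.0,
                "I2": 55.0},
            substrates={"S": 1, "FAD": 1},
            products={"P": 1, "FADH2": 1},
            site_groups={"acyl": ("S", "P", "I1", "I2"),
                         "cofactor": ("FAD", "FADH2")},
        )
        for _ in range(5):
            conc = {k: float(v) for k, v in
                    zip(law.km, rng.uniform(0.5, 80.0, len(law.km)))}
            for ligand in law.km:
                assert law.elasticity(conc, ligand) == pytest.approx(
                    symbolic_elasticity(law, conc, ligand), rel=1e-6, abs=1e-9
                )

    def test_zero_rate_is_flagged(self, chain2):
        model = chain2.copy()
        state = model.default_state()
        # equilibrium state: X1 such that v1 == 0
        s0 = model.species["S0"].value
        keq = model.reaction("v1").law.keq
        state.concentrations["X1"] = s0 * keq
        with pytest.raises(ZeroDivisionError):
            elasticity(model, state, "v1", "S0")


class TestNadRatio:
    def test_joint_adjustment_preserves_pool(self, mfao_model):
        model = mfao_model.copy()
        pool = (model.get_parameter("conc_NADMAT")
                + model.get_parameter("conc_NADHMAT"))
        set_ratio_parameter(model, 3.0)
        assert get_ratio_parameter(model) == pytest.approx(3.0)
        assert (model.get_parameter("conc_NADMAT")
                + model.get_parameter("conc_NADHMAT")) == pytest.approx(pool)

    def test_response_dissection_closes(self, mfao_ss_high):
        model, ref = mfao_ss_high
        table = dissect_response(model, ref, NAD_RATIO_PARAMETER)
        direct = table.attrs["direct_response"]
        assert table.attrs["term_sum"] == pytest.approx(direct, rel=0.01)

    def test_mschad_short_chain_terms_dominate(self, mfao_ss_high):
        model, ref = mfao_ss_high
        table = dissect_response(model, ref, NAD_RATIO_PARAMETER)
        short = table[
            (table["enzyme"] == "MSCHAD") & (table["chain_length"].isin([4, 6]))
        ]["term"].sum()
        assert short > 0
        assert short > 0.8 * table.attrs["term_sum"]

    def test_single_reaction_parameter_has_single_term(self, mfao_ss_low):
        model, ref = mfao_ss_low
        table = dissect_response(model, ref, "Km_CPT1_CarCYT")
        assert set(table["reaction"]) == {"vcpt1"}


def test_control_table_layout(mfao_ss_low):
    model, ref = mfao_ss_low
    table = control_table(model, ref, enzymes=["CPT1", "MCKAT"],
                          chain_enzymes=["SCAD"], parameters=["Keq_CROT"])
    assert list(table.columns) == ["entity", "type", "value", "plus_est",
                                   "minus_est", "discrepancy", "accepted"]
    assert set(table["type"]) == {"FCC", "FCC-chain", "RC"}
    assert len(table[table["type"] == "FCC-chain"]) == 2  # SCAD C4, C6
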