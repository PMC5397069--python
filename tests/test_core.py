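import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betaox import (
    KineticModel,
    ModelConfigurationError,
    ModelState,
    RateLaw,
    integrate,
    promiscuous_rate,
)


def simple_law(**overrides) -> RateLaw:
    """S + FAD <-> P + FADH2 with one cross-chain competitor I."""
    kwargs = dict(
        sf=0.8,
        vmax=100.0,
        keq=5.0,
        km={"S": 10.0, "P": 20.0, "FAD": 40.0, "FADH2": 15.0, "I": 30.0},
        substrates={"S": 1, "FAD": 1},
        products={"P": 1, "FADH2": 1},
        site_groups={"acyl": ("S", "P", "I"), "cofactor": ("FAD", "FADH2")},
    )
    kwargs.update(overrides)
    return RateLaw(**kwargs)


class TestPromiscuousRate:
    def test_substrate_and_cofactor_at_km(self):
        law = simple_law()
        conc = {"S": 10.0, "FAD": 40.0, "P": 0.0, "FADH2": 0.0, "I": 0.0}
        assert promiscuous_rate(law, conc) == pytest.approx(0.8 * 100.0 / 4.0)

    def test_competitor_at_km_adds_denominator_unit(self):
        law = simple_law()
        conc = {"S": 10.0, "FAD": 40.0, "P": 0.0, "FADH2": 0.0, "I": 30.0}
        assert promiscuous_rate(law, conc) == pytest.approx(0.8 * 100.0 / 6.0)

    def test_zero_at_thermodynamic_equilibrium(self):
        law = simple_law()
        # pick concentrations with mass-action ratio == Keq
        conc = {"S": 7.0, "FAD": 11.0, "P": 35.0, "FADH2": 11.0, "I": 13.0}
        assert (conc["P"] * conc["FADH2"]) / (conc["S"] * conc["FAD"]) == law.keq
        assert promiscuous_rate(law, conc) == pytest.approx(0.0, abs=1e-12)

    def test_unknown_ligand_is_configuration_error(self):
        law = simple_law()
        with pytest.raises(ModelConfigurationError):
            law.rate({"S": 1.0})

    def test_nonpositive_km_is_validation_error(self):
        law = simple_law(km={"S": 0.0, "P": 20.0, "FAD": 40.0, "FADH2": 15.0, "I": 30.0})
        with pytest.raises(ModelConfigurationError, match="Km"):
            promiscuous_rate(law, {"S": 1, "P": 0, "FAD": 1, "FADH2": 0, "I": 0})

    @given(
        s=st.floats(0.01, 1e3),
        p=st.floats(0.0, 1e3),
        i=st.floats(0.0, 1e3),
        fad=st.floats(0.01, 1e3),
        fadh2=st.floats(0.0, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_rate_bounded_by_numerator(self, s, p, i, fad, fadh2):
        # denominator >= 1, hence |v| <= sf*Vmax*(forward + reverse)
        law = simple_law()
        conc = {"S": s, "P": p, "I": i, "FAD": fad, "FADH2": fadh2}
        fwd = (s / 10.0) * (fad / 40.0)
        rev = p * fadh2 / (10.0 * 40.0 * 5.0)
        assert abs(law.rate(conc)) <= 0.8 * 100.0 * (fwd + rev) + 1e-9

    @given(
        i=st.floats(0.1, 1e3),
        extra=st.floats(0.1, 1e3),
        s=st.floats(0.1, 500.0),
        p=st.floats(0.0, 500.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_competitor_monotonically_inhibits(self, i, extra, s, p):
        law = simple_law()
        conc = {"S": s, "P": p, "I": i, "FAD": 40.0, "FADH2": 5.0}
        more = dict(conc, I=i + extra)
        v0, v1 = law.rate(conc), law.rate(more)
        if v0 != 0.0:
            assert abs(v1) < abs(v0)

    def test_elasticity_matches_finite_difference(self):
        law = simple_law()
        conc = {"S": 22.0, "P": 4.0, "I": 17.0, "FAD": 55.0, "FADH2": 3.0}
        for ligand in conc:
            h = 1e-6 * conc[ligand]
            up = dict(conc, **{ligand: conc[ligand] + h})
            dn = dict(conc, **{ligand: conc[ligand] - h})
            fd = (law.rate(up) - law.rate(dn)) / (2 * h) * conc[ligand] / law.rate(conc)
            assert law.elasticity(conc, ligand) == pytest.approx(fd, rel=1e-6)


class TestRhs:
    def test_coa_moiety_direction_is_annihilated(self, mfao_model, rng):
        model = mfao_model
        n_var = len(model.variable_names)
        x = rng.uniform(0.1, 50.0, n_var)
        dxdt = model.rhs(x)
        vidx = {n: i for i, n in enumerate(model.variable_names)}
        for m in model.moieties:
            vec = np.zeros(n_var)
            for name in m.members:
                vec[vidx[name]] = 1.0
            assert abs(vec @ dxdt) < 1e-9 * np.max(np.abs(dxdt))

    def test_empty_pathway_is_fixed_point(self, mfao_model):
        model = mfao_model.copy()
        model.set_parameter("conc_C16AcylCoACYT", 0.0)
        # the clamped acetyl-CoA sink must be empty too, else reverse
        # thiolysis repopulates the ester pools
        model.set_parameter("conc_AcetylCoAMAT", 0.0)
        x = np.zeros(len(model.variable_names))
        vidx = {n: i for i, n in enumerate(model.variable_names)}
        for m in model.moieties:
            x[vidx[m.pivot]] = m.total
        assert np.max(np.abs(model.rhs(x))) == pytest.approx(0.0, abs=1e-12)

    def test_rhs_matches_trajectory_derivative(self, mfao_model, rng):
        # derived check: short high-accuracy integration step, central FD
        model = mfao_model.copy()
        state = model.default_state()
        traj = integrate(model, state, 2.0, rtol=1e-11, atol=1e-13)
        t0, dt = 1.0, 1e-4
        fd = (traj.values(t0 + dt) - traj.values(t0 - dt)) / (2 * dt)
        rhs = model.rhs(traj.values(t0))
        scale = np.max(np.abs(rhs))
        assert np.max(np.abs(fd - rhs)) < 1e-5 * scale

    def test_dimension_mismatch_raises(self, mfao_model):
        with pytest.raises(ModelConfigurationError, match="dimension"):
            mfao_model.rhs(np.ones(3))


class TestValidate:
    def test_instance_is_clean(self, mfao_model):
        assert mfao_model.validate() == []

    def test_zero_km_names_reaction(self, mfao_model):
        model = mfao_model.copy()
        model.reaction("vmckatC4").law.km["CoAMAT"] = 0.0
        violations = model.validate()
        assert any("vmckatC4" in v and "Km" in v for v in violations)

    def test_broken_moiety_is_detected(self, mfao_model):
        # derived: moiety vector times stoichiometry has a nonzero entry
        model = mfao_model.copy()
        model.moieties[0].members = tuple(
            m for m in model.moieties[0].members if m != "C4KetoacylCoAMAT"
        )
        model.invalidate()
        violations = model.validate()
        assert any("not conserved" in v for v in violations)


class TestSerialization:
    def test_yaml_round_trip_is_lossless(self, mfao_model, tmp_path):
        path = tmp_path / "model.yaml"
        mfao_model.to_yaml(path)
        back = KineticModel.from_yaml(path)
        assert back.to_dict() == mfao_model.to_dict()

    def test_round_tripped_model_computes_identically(self, mfao_model, rng):
        back = KineticModel.from_yaml(mfao_model.to_yaml())
        x = rng.uniform(0.1, 10.0, len(mfao_model.variable_names))
        np.testing.assert_allclose(back.rhs(x), mfao_model.rhs(x), rtol=0, atol=0)


class TestParameters:
    def test_get_set_round_trip(self, mfao_model):
        model = mfao_model.copy()
        for name in ("Vmax_MCKAT", "sf_MCKAT_C4", "Km_MCKAT_CoAMAT",
                     "Keq_MSCHAD", "conc_NADMAT", "total_CoA"):
            value = model.get_parameter(name)
            model.set_parameter(name, value * 1.5)
            assert model.get_parameter(name) == pytest.approx(value * 1.5)

    def test_printed_constants_are_wired(self, mfao_model):
        assert mfao_model.get_parameter("Keq_MSCHAD") == pytest.approx(2.17e-4)
        assert mfao_model.get_parameter("Keq_CROT") == pytest.approx(3.13)
        assert mfao_model.get_parameter("sf_MCKAT_C4") == pytest.approx(0.49)
        assert mfao_model.get_parameter("sf_MCKAT_C6") == pytest.approx(1.0)
        assert mfao_model.get_parameter(
            "Km_MCKAT_C4KetoacylCoAMAT"
        ) == pytest.approx(12.4)
        assert mfao_model.get_parameter(
            "Km_MCKAT_C6KetoacylCoAMAT"
        ) == pytest.approx(6.7)

    def test_unknown_parameter_raises(self, mfao_model):
        with pytest.raises(ModelConfigurationError):
            mfao_model.get_parameter("Vmax_NOSUCH")

    def test_clipping_negative_state(self, mfao_model):
        x = np.full(len(mfao_model.variable_names), 1.0)
        x[0] = -1e-9
        v = mfao_model.rates(x)
        assert np.all(np.isfinite(v))
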