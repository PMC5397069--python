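"""Finite-perturbation Metabolic Control Analysis.

Control and response coefficients are estimated from paired +/- relative
parameter perturbations (default 1e-6, i.e. 0.0001%), each requiring a
steady-state re-solve seeded from the reference state.  An estimate is
accepted only when the two one-sided values agree within 1% -- the same
acceptance rule the analysis protocol prescribes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import KineticModel, ModelConfigurationError, ModelState
from .simulate import SteadyStateResult, find_steady_state

logger = logging.getLogger(__name__)

#: default relative perturbation (0.0001%)
PERTURBATION = 1e-6
#: plus/minus relative discrepancy above which an estimate is rejected
ACCEPT_DISCREPANCY = 0.01
#: special parameter name: joint NAD+/NADH adjustment at fixed total pool
NAD_RATIO_PARAMETER = "ratio_NAD_NADH"


@dataclass
class CoefficientEstimate:
    """A central coefficient estimate with its one-sided pair."""

    entity: str
    kind: str  # "FCC" | "FCC-chain" | "RC" | "elasticity"
    value: float
    plus_est: float
    minus_est: float
    discrepancy: float
    accepted: bool

    def row(self) -> dict:
        return {
            "entity": self.entity,
            "type": self.kind,
            "value": self.value,
            "plus_est": self.plus_est,
            "minus_est": self.minus_est,
            "discrepancy": self.discrepancy,
            "accepted": self.accepted,
        }


def get_ratio_parameter(model: KineticModel) -> float:
    nad = model.get_parameter("conc_NADMAT")
    nadh = model.get_parameter("conc_NADHMAT")
    return nad / nadh


def set_ratio_parameter(model: KineticModel, ratio: float) -> None:
    """Set [NAD+]/[NADH] holding the summed pool constant."""
    nad = model.get_parameter("conc_NADMAT")
    nadh = model.get_parameter("conc_NADHMAT")
    total = nad + nadh
    model.set_parameter("conc_NADMAT", total * ratio / (1.0 + ratio))
    model.set_parameter("conc_NADHMAT", total / (1.0 + ratio))


def _get_param(model: KineticModel, name: str) -> float:
    if name == NAD_RATIO_PARAMETER:
        return get_ratio_parameter(model)
    return model.get_parameter(name)


def _set_param(model: KineticModel, name: str, value: float) -> None:
    if name == NAD_RATIO_PARAMETER:
        set_ratio_parameter(model, value)
    else:
        model.set_parameter(name, value)


def _one_sided(
    model: KineticModel,
    reference: SteadyStateResult,
    parameter: str,
    rel_step: float,
) -> tuple[float, bool]:
    """Scaled sensitivity (dJ/dp)*(p/J) from one finite perturbation."""
    work = model.copy()
    p0 = _get_param(work, parameter)
    if p0 == 0.0:
        raise ModelConfigurationError(f"cannot perturb zero-valued parameter {parameter!r}")
    _set_param(work, parameter, p0 * (1.0 + rel_step))
    res = find_steady_state(work, reference.state)
    coeff = ((res.J_uptake - reference.J_uptake) / (p0 * rel_step)) * (
        p0 / reference.J_uptake
    )
    return coeff, res.converged


def _paired(
    model: KineticModel,
    reference: SteadyStateResult,
    parameter: str,
    entity: str,
    kind: str,
    rel_step: float,
) -> CoefficientEstimate:
    if not reference.converged:
        raise ModelConfigurationError("reference steady state is not converged")
    if abs(reference.J_uptake) < 1e-12:
        return CoefficientEstimate(entity, kind, float("nan"), float("nan"),
                                   float("nan"), float("inf"), False)
    plus, ok_p = _one_sided(model, reference, parameter, +rel_step)
    minus, ok_m = _one_sided(model, reference, parameter, -rel_step)
    value = 0.5 * (plus + minus)
    scale = max(abs(value), 1e-12)
    disc = abs(plus - minus) / scale
    accepted = ok_p and ok_m and disc <= ACCEPT_DISCREPANCY
    if not (ok_p and ok_m):
        logger.warning("perturbed steady state for %s did not converge", parameter)
    return CoefficientEstimate(entity, kind, value, plus, minus, disc, accepted)


def flux_control_coefficient(
    model: KineticModel,
    reference: SteadyStateResult,
    enzyme: str,
    rel_step: float = PERTURBATION,
) -> CoefficientEstimate:
    """Flux control coefficient of one enzyme via Vmax perturbation."""
    return _paired(model, reference, f"Vmax_{enzyme}", enzyme, "FCC", rel_step)


def chain_specific_fcc(
    model: KineticModel,
    reference: SteadyStateResult,
    enzyme: str,
    chain: int,
    rel_step: float = PERTURBATION,
) -> CoefficientEstimate:
    """Chain-length-specific flux control coefficient via sf perturbation."""
    return _paired(
        model, reference, f"sf_{enzyme}_C{chain}", f"{enzyme}_C{chain}",
        "FCC-chain", rel_step,
    )


def response_coefficient(
    model: KineticModel,
    reference: SteadyStateResult,
    parameter: str,
    rel_step: float = PERTURBATION,
) -> CoefficientEstimate:
    """Flux response coefficient of an arbitrary model parameter."""
    return _paired(model, reference, parameter, parameter, "RC", rel_step)


def summation_check(
    model: KineticModel,
    reference: SteadyStateResult,
    rel_step: float = PERTURBATION,
) -> tuple[float, dict[str, CoefficientEstimate]]:
    """All enzyme FCCs and their sum (summation theorem: sum == 1)."""
    coeffs = {
        enz: flux_control_coefficient(model, reference, enz, rel_step)
        for enz in model.enzymes
    }
    total = float(sum(c.value for c in coeffs.values()))
    return total, coeffs


def elasticity(
    model: KineticModel,
    state: ModelState,
    reaction: str,
    target: str,
    rel_step: float = 1e-6,
    analytic: bool = True,
) -> float:
    """Scaled elasticity of one isolated reaction rate.

    ``target`` is a species name (variable or clamped, perturbed at
    clamped concentrations), a canonical parameter name, or the joint
    NAD ratio parameter.  Species elasticities use the closed-form
    derivative of the rate law by default; parameters and the ratio use
    central log-log finite differences with relative step ``rel_step``.
    """
    rxn = model.reaction(reaction)
    full = model.full_concentrations(state.vector(model.variable_names))
    conc = dict(zip(model.species_order, full))
    v0 = rxn.law.rate(conc)
    if v0 == 0.0:
        raise ZeroDivisionError(f"elasticity undefined: rate of {reaction} is zero")

    if target in model.species:
        if analytic:
            return rxn.law.elasticity(conc, target)
        x0 = conc[target]
        up = dict(conc, **{target: x0 * (1 + rel_step)})
        dn = dict(conc, **{target: x0 * (1 - rel_step)})
        return (rxn.law.rate(up) - rxn.law.rate(dn)) / (2 * rel_step * v0)

    if target == NAD_RATIO_PARAMETER:
        nad, nadh = conc["NADMAT"], conc["NADHMAT"]
        total, ratio = nad + nadh, nad / nadh

        def at(r):
            c = dict(conc)
            c["NADMAT"] = total * r / (1 + r)
            c["NADHMAT"] = total / (1 + r)
            return rxn.law.rate(c)

        return (at(ratio * (1 + rel_step)) - at(ratio * (1 - rel_step))) / (
            2 * rel_step * v0
        )

    # model parameter: isolate the reaction's law, perturb, re-evaluate
    def rate_with(param_value: float) -> float:
        work = model.copy()
        _set_param(work, target, param_value)
        wrxn = work.reaction(reaction)
        wfull = work.full_concentrations(state.vector(work.variable_names))
        return wrxn.law.rate(dict(zip(work.species_order, wfull)))

    p0 = _get_param(model, target)
    return (rate_with(p0 * (1 + rel_step)) - rate_with(p0 * (1 - rel_step))) / (
        2 * rel_step * v0
    )


def dissect_response(
    model: KineticModel,
    reference: SteadyStateResult,
    parameter: str,
    rel_step: float = PERTURBATION,
) -> pd.DataFrame:
    """Partition a response coefficient into per-reaction C_i * eps_i terms.

    The sum over terms reproduces the directly computed response
    coefficient (combined-response / connectivity check, enforced by the
    test suite at 1%).
    """
    direct = response_coefficient(model, reference, parameter, rel_step)
    rows = []
    for rxn in model.reactions:
        try:
            eps = elasticity(model, reference.state, rxn.rid, parameter)
        except ZeroDivisionError:
            eps = float("nan")
        if eps == 0.0 or not np.isfinite(eps):
            continue
        if rxn.chain_length is not None:
            cest = chain_specific_fcc(model, reference, rxn.enzyme, rxn.chain_length,
                                      rel_step)
        else:
            cest = flux_control_coefficient(model, reference, rxn.enzyme, rel_step)
        rows.append(
            {
                "reaction": rxn.rid,
                "enzyme": rxn.enzyme,
                "chain_length": rxn.chain_length,
                "C": cest.value,
                "elasticity": eps,
                "term": cest.value * eps,
                "accepted": cest.accepted,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["direct_response"] = direct.value
    df.attrs["term_sum"] = float(df["term"].sum()) if len(df) else 0.0
    df.attrs["parameter"] = parameter
    return df


def control_table(
    model: KineticModel,
    reference: SteadyStateResult,
    enzymes: list[str] | None = None,
    chain_enzymes: list[str] | None = None,
    parameters: list[str] | None = None,
    rel_step: float = PERTURBATION,
) -> pd.DataFrame:
    """Assemble FCCs, chain-specific FCCs and response coefficients."""
    rows: list[dict] = []
    for enz in enzymes if enzymes is not None else model.enzymes:
        rows.append(flux_control_coefficient(model, reference, enz, rel_step).row())
    for enz in chain_enzymes or []:
        for rxn in model.reactions_of(enz):
            if rxn.chain_length is None:
                continue
            rows.append(
                chain_specific_fcc(model, reference, enz, rxn.chain_length, rel_step).row()
            )
    for par in parameters or []:
        rows.append(response_coefficient(model, reference, par, rel_step).row())
    return pd.DataFrame(rows)


def top_responses(
    model: KineticModel,
    reference: SteadyStateResult,
    parameters: list[str] | None = None,
    n_top: int = 15,
    rel_step: float = PERTURBATION,
) -> pd.DataFrame:
    """Ranked response coefficients (|R| descending, name as tie-break)."""
    if parameters is None:
        parameters = model.parameter_names() + [NAD_RATIO_PARAMETER]
    rows = [
        response_coefficient(model, reference, p, rel_step).row() for p in parameters
    ]
    df = pd.DataFrame(rows)
    df["absval"] = df["value"].abs()
    df = df.sort_values(["absval", "entity"], ascending=[False, True], kind="stable")
    return df.drop(columns="absval").head(n_top).reset_index(drop=True)


def reference_steady_state(model: KineticModel, substrate: float | None = None,
                           substrate_parameter: str | None = None) -> SteadyStateResult:
    """Convenience: steady state at a given substrate concentration."""
    work = model.copy()
    if substrate is not None:
        from .mfao import substrate_parameter as _sp

        work.set_parameter(substrate_parameter or _sp(work), substrate)
    res = find_steady_state(work)
    return res
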