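"""Independent oracles for the test suite.

Everything here is derived from first principles with sympy or plain
linear algebra, deliberately avoiding the package's own rate/derivative
code paths, so that implementation and oracle can disagree.
"""

from __future__ import annotations

import numpy as np
import sympy as sp


def symbolic_rate(law, conc_symbols):
    """Rebuild a rate law symbolically from its declared structure."""
    fwd = sp.Integer(1)
    km_scale = sp.Integer(1)
    for lig, n in law.substrates.items():
        fwd *= (conc_symbols[lig] / law.km[lig]) ** n
        km_scale *= sp.Float(law.km[lig]) ** n
    rev = sp.Integer(1)
    for lig, n in law.products.items():
        rev *= conc_symbols[lig] ** n
    rev = rev / (km_scale * law.keq)
    denom = sp.Integer(1)
    for members in law.site_groups.values():
        denom *= 1 + sum(conc_symbols[m] / law.km[m] for m in members)
    return law.alpha * law.sf * law.vmax * (fwd - rev) / denom


def symbolic_elasticity(law, conc: dict, ligand: str) -> float:
    """Scaled elasticity d ln v / d ln x via sympy differentiation."""
    syms = {name: sp.Symbol(name, positive=True) for name in conc}
    v = symbolic_rate(law, syms)
    x = syms[ligand]
    eps = sp.diff(v, x) * x / v
    return float(eps.subs({syms[k]: conc[k] for k in conc}))


def control_coefficients_linear_chain(model, steady_state: dict) -> dict:
    """Flux control coefficients of an unbranched chain, closed form.

    Uses the implicit-function theorem on the steady-state condition:
    with reduced stoichiometry N, rate Jacobians E_x = dv/dx and
    dv/dVmax_i evaluated symbolically at the steady state,

        dx/dVmax_i = -(N E_x)^{-1} N (dv/dVmax_i)
        dJ/dVmax_i = E_x[last] dx/dVmax_i + d v_last/dVmax_i,

    scaled to C_i = (dJ/dVmax_i) Vmax_i / J.  Independent of the
    package's finite-perturbation re-solve route.
    """
    var_names = model.variable_names
    all_names = model.species_order
    syms = {name: sp.Symbol(name, positive=True) for name in all_names}
    vmax_syms = {r.rid: sp.Symbol(f"Vmax_{r.rid}", positive=True) for r in model.reactions}

    exprs = []
    for rxn in model.reactions:
        law = rxn.law
        # make Vmax symbolic: the numeric law is proportional to it
        exprs.append(symbolic_rate(law, syms) / law.vmax * vmax_syms[rxn.rid])

    subs = {syms[name]: model.species[name].value for name in all_names if
            model.species[name].fixed}
    subs.update({syms[name]: steady_state[name] for name in var_names})
    subs.update({vmax_syms[r.rid]: r.law.vmax for r in model.reactions})

    n_rxn = len(model.reactions)
    n_var = len(var_names)
    N = np.array(model.stoichiometry_matrix(), dtype=float)
    E_x = np.zeros((n_rxn, n_var))
    dv_dV = np.zeros((n_rxn, n_rxn))
    for i, expr in enumerate(exprs):
        for j, name in enumerate(var_names):
            E_x[i, j] = float(sp.diff(expr, syms[name]).subs(subs))
        for k, rxn in enumerate(model.reactions):
            dv_dV[i, k] = float(sp.diff(expr, vmax_syms[rxn.rid]).subs(subs))

    J_row = n_rxn - 1  # chain flux readout: last reaction
    v_at = np.array([float(expr.subs(subs)) for expr in exprs])
    J = v_at[J_row]
    A = N @ E_x  # (n_var x n_var)
    out = {}
    for k, rxn in enumerate(model.reactions):
        dxdV = np.linalg.solve(A, -(N @ dv_dV[:, k]))
        dJdV = E_x[J_row] @ dxdV + dv_dV[J_row, k]
        out[rxn.enzyme] = float(dJdV * rxn.law.vmax / J)
    return out
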