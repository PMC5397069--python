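"""Time integration, steady-state solving and parameter scans."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .core import KineticModel, ModelState

logger = logging.getLogger(__name__)

#: absolute tolerance on ||rhs||_inf at an accepted steady state (uM/min)
STEADY_STATE_TOL = 1e-9
#: longest integration horizon used as root-finding fallback (min)
FALLBACK_HORIZON = 1e4


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last good state."""

    def __init__(self, message: str, last_state: ModelState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass
class Trajectory:
    """Dense solution of one integration."""

    model: KineticModel
    t_end: float
    _sol: object
    names: list[str]

    @property
    def t(self) -> np.ndarray:
        return self._sol.ts if hasattr(self._sol, "ts") else None

    def state(self, t: float) -> ModelState:
        x = np.maximum(self._sol.sol(t), 0.0)
        return ModelState(float(t), dict(zip(self.names, x)))

    def values(self, t) -> np.ndarray:
        """Concentration array (n_species x len(t)), clipped at 0."""
        return np.maximum(self._sol.sol(np.asarray(t, dtype=float)), 0.0)

    def endpoint(self) -> ModelState:
        return self.state(self.t_end)

    def moiety_drift(self) -> dict[str, float]:
        """Max relative drift of each conserved total along the trajectory."""
        ts = np.linspace(0.0, self.t_end, 201)
        xs = self.values(ts)
        idx = {n: i for i, n in enumerate(self.names)}
        out = {}
        for m in self.model.moieties:
            tot = xs[[idx[n] for n in m.members], :].sum(axis=0)
            out[m.name] = float(np.max(np.abs(tot - m.total)) / m.total)
        return out


def integrate(
    model: KineticModel,
    init: ModelState | None = None,
    t_end: float = 400.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model ODEs with dense output on [0, t_end]."""
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    init = init or model.default_state()
    names = model.variable_names
    x0 = init.vector(names)
    sol = solve_ivp(
        lambda t, x: model.rhs(x),
        (0.0, float(t_end)),
        x0,
        method=method,
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = ModelState(float(sol.t[-1]), dict(zip(names, sol.y[:, -1])))
        raise IntegrationError(
            f"integration failed at t={sol.t[-1]:.4g} min: {sol.message}", last
        )
    return Trajectory(model, float(t_end), sol, names)


@dataclass
class SteadyStateResult:
    """A (possibly flagged) steady state with its flux readouts."""

    state: ModelState
    fluxes: dict[str, float]
    J_uptake: float
    J_NADH: float
    converged: bool
    residual_norm: float

    def flux_ratio(self) -> float:
        return self.J_NADH / self.J_uptake


class _Reduction:
    """Algebraic elimination of one species per conserved moiety."""

    def __init__(self, model: KineticModel):
        self.model = model
        self.names = model.variable_names
        self.idx = {n: i for i, n in enumerate(self.names)}
        self.pivots = [m.pivot for m in model.moieties]
        self.free = [n for n in self.names if n not in self.pivots]
        self.free_idx = np.array([self.idx[n] for n in self.free], dtype=np.intp)
        self.pivot_rules = []
        for m in model.moieties:
            others = np.array(
                [self.idx[n] for n in m.members if n != m.pivot], dtype=np.intp
            )
            self.pivot_rules.append((self.idx[m.pivot], m.total, others))

    def to_full(self, x_red: np.ndarray) -> np.ndarray:
        full = np.zeros(len(self.names))
        full[self.free_idx] = x_red
        for piv, total, others in self.pivot_rules:
            full[piv] = total - full[others].sum()
        return full

    def to_reduced(self, x_full: np.ndarray) -> np.ndarray:
        return x_full[self.free_idx]

    def residual(self, x_red: np.ndarray) -> np.ndarray:
        full = self.to_full(x_red)
        # infeasible pivot (moiety overdrawn) -> steer solver back
        penalty = 0.0
        for piv, total, _ in self.pivot_rules:
            if full[piv] < 0:
                penalty += -full[piv]
        rhs = self.model.rhs(np.maximum(full, 0.0))
        res = rhs[self.free_idx]
        if penalty > 0.0:
            res = res + penalty
        return res


def _result_from_state(
    model: KineticModel, x: np.ndarray, tol: float
) -> SteadyStateResult:
    x = np.maximum(x, 0.0)
    names = model.variable_names
    resid = float(np.max(np.abs(model.rhs(x))))
    v = model.rates(x)
    fluxes = dict(zip(model.reaction_ids, v))
    j_uptake = fluxes.get(model.flux_readout, float("nan"))
    n_full = model.stoichiometry_matrix(variable_only=False)
    order = model.species_order
    j_nadh = 0.0
    if model.nadh_species in order:
        row = n_full[order.index(model.nadh_species)]
        j_nadh = float(row @ v)
    return SteadyStateResult(
        state=ModelState(0.0, dict(zip(names, x))),
        fluxes=fluxes,
        J_uptake=float(j_uptake),
        J_NADH=j_nadh,
        converged=resid < tol,
        residual_norm=resid,
    )


def find_steady_state(
    model: KineticModel,
    init: ModelState | None = None,
    tol: float = STEADY_STATE_TOL,
    max_horizon: float = FALLBACK_HORIZON,
) -> SteadyStateResult:
    """Locate a steady state on the moiety-reduced system.

    Newton (hybrid Powell) root finding seeded from ``init``; if the root
    finder stalls, the model is integrated in stages and the root search
    re-seeded from the trajectory endpoint.  Non-convergence is returned
    flagged, never silently.
    """
    init = init or model.default_state()
    red = _Reduction(model)
    x_full = init.vector(model.variable_names)

    def accept(cand: np.ndarray):
        if np.any(cand < -1e-9 * max(1.0, float(np.max(np.abs(cand))))):
            return None
        cand = np.maximum(cand, 0.0)
        if float(np.max(np.abs(model.rhs(cand)))) < tol:
            return cand
        return None

    def polish_linear(x0_full: np.ndarray):
        sol = root(
            red.residual,
            red.to_reduced(x0_full),
            method="hybr",
            options={"xtol": 1e-13, "maxfev": 4000},
        )
        return accept(red.to_full(sol.x))

    def polish_log(x0_full: np.ndarray):
        # positivity-safe polish; handles concentrations spanning many decades
        u0 = np.log(np.maximum(red.to_reduced(x0_full), 1e-20))
        sol = root(
            lambda u: red.residual(np.exp(np.minimum(u, 30.0))),
            u0,
            method="hybr",
            options={"xtol": 1e-13, "maxfev": 4000},
        )
        return accept(red.to_full(np.exp(np.minimum(sol.x, 30.0))))

    def advance(x0_full: np.ndarray, horizon: float) -> np.ndarray:
        st = ModelState(0.0, dict(zip(model.variable_names, x0_full)))
        try:
            return integrate(model, st, horizon, rtol=1e-9, atol=1e-11).endpoint().vector(
                model.variable_names
            )
        except IntegrationError:
            pass
        # stiff near-depletion regime: integrate the moiety-reduced system
        # in log space with BDF (positivity-preserving)
        u0 = np.log(np.maximum(red.to_reduced(x0_full), 1e-15))

        def dudt(_t, u):
            x = np.exp(np.minimum(u, 30.0))
            full = np.maximum(red.to_full(x), 0.0)
            rhs = model.rhs(full)
            return rhs[red.free_idx] / x

        sol = solve_ivp(dudt, (0.0, horizon), u0, method="BDF", rtol=1e-8, atol=1e-8)
        if not sol.success:
            logger.warning("log-space fallback integration failed: %s", sol.message)
        return np.maximum(red.to_full(np.exp(sol.y[:, -1])), 0.0)

    best = x_full
    ok = polish_linear(x_full)
    if ok is None:
        ok = polish_log(x_full)
    horizon, elapsed = 50.0, 0.0
    while ok is None and elapsed < max_horizon:
        best = advance(best, horizon)
        elapsed += horizon
        horizon = min(horizon * 4.0, max_horizon)
        ok = polish_linear(best)
        if ok is None:
            ok = polish_log(best)
    if ok is None:
        logger.warning(
            "steady state not converged for model %s (residual %.3e)",
            model.name,
            float(np.max(np.abs(model.rhs(best)))),
        )
        return _result_from_state(model, best, tol)
    return _result_from_state(model, ok, tol)


def _ester_sums(model: KineticModel, state: ModelState) -> tuple[float, float, float]:
    classes = {"acyl-CoA", "enoyl-CoA", "hydroxyacyl-CoA", "ketoacyl-CoA"}
    total = short = 0.0
    for name, conc in state.concentrations.items():
        sp = model.species[name]
        if sp.species_class in classes and sp.compartment == "mitochondrion":
            total += conc
            if sp.chain_length in (4, 6):
                short += conc
    free_coa = state.concentrations.get("CoAMAT", float("nan"))
    return free_coa, total, short


def scan(
    model: KineticModel,
    parameter: str,
    grid,
    init: ModelState | None = None,
    descending_check: bool = True,
    tol: float = STEADY_STATE_TOL,
) -> pd.DataFrame:
    """Steady-state scan over a parameter grid with continuation.

    Rows carry the headline fluxes, free CoA and ester pool sums, and the
    full per-reaction flux vector.  Ascending continuation is the primary
    sweep; a descending re-scan flags possible multistability in
    ``hysteresis`` (disagreement is reported, not averaged).
    """
    grid = np.asarray(list(grid), dtype=float)
    work = model.copy()
    results: list[SteadyStateResult] = []
    state = init or work.default_state()
    for value in grid:
        work.set_parameter(parameter, value)
        res = find_steady_state(work, state, tol=tol)
        results.append(res)
        if res.converged:
            state = res.state
    rows = []
    for value, res in zip(grid, results):
        free_coa, esters, short = _ester_sums(work, res.state)
        row = {
            "param_value": value,
            "J_uptake": res.J_uptake,
            "J_NADH": res.J_NADH,
            "freeCoA": free_coa,
            "sum_esters": esters,
            "sum_C4C6_esters": short,
            "converged": res.converged,
            "residual": res.residual_norm,
        }
        for rid, flux in res.fluxes.items():
            row[f"flux_{rid}"] = flux
        rows.append(row)
    df = pd.DataFrame(rows)

    if descending_check and len(grid) > 2:
        state = results[-1].state
        j_desc = np.full(len(grid), np.nan)
        for i in range(len(grid) - 1, -1, -1):
            work.set_parameter(parameter, grid[i])
            res = find_steady_state(work, state, tol=tol)
            j_desc[i] = res.J_uptake
            if res.converged:
                state = res.state
        df["J_uptake_descending"] = j_desc
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(j_desc - df["J_uptake"]) / np.maximum(
                np.abs(df["J_uptake"]), 1e-12
            )
        df["hysteresis"] = rel > 1e-4
        if df["hysteresis"].any():
            logger.warning(
                "ascending/descending scans disagree at %d grid points "
                "(possible multistability)",
                int(df["hysteresis"].sum()),
            )
    return df


@dataclass
class FluxPeak:
    """Location/value of an interior flux maximum, if one exists."""

    location: float | None
    value: float | None
    interior: bool
    message: str = ""


def find_flux_peak(
    table: pd.DataFrame,
    model: KineticModel | None = None,
    parameter: str | None = None,
    column: str = "J_uptake",
    refine_tol: float = 1e-3,
) -> FluxPeak:
    """Locate the interior maximum of a scanned flux curve.

    With ``model`` and ``parameter`` given, the grid argmax is refined by
    golden-section search with continuation-seeded steady-state re-solves
    between its neighbouring grid points; otherwise a parabolic fit
    through the bracketing triple is used.
    """
    ok = table[table["converged"]] if "converged" in table else table
    if len(ok) < 3:
        return FluxPeak(None, None, False, "fewer than 3 converged scan points")
    x = ok["param_value"].to_numpy(dtype=float)
    y = ok[column].to_numpy(dtype=float)
    k = int(np.argmax(y))
    if k == 0 or k == len(y) - 1:
        return FluxPeak(None, None, False, "no interior peak in range")
    lo, hi = x[k - 1], x[k + 1]
    if model is not None and parameter is not None:
        work = model.copy()
        state = None

        def j_at(p: float) -> float:
            nonlocal state
            work.set_parameter(parameter, p)
            res = find_steady_state(work, state)
            if res.converged:
                state = res.state
            return res.J_uptake

        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c, d = b - invphi * (b - a), a + invphi * (b - a)
        fc, fd = j_at(c), j_at(d)
        while (b - a) > refine_tol * max(1.0, abs(b)):
            if fc > fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = j_at(c)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = j_at(d)
        loc = 0.5 * (a + b)
        return FluxPeak(float(loc), float(j_at(loc)), True)
    # parabolic vertex through the bracketing triple
    x0, x1, x2 = x[k - 1 : k + 2]
    y0, y1, y2 = y[k - 1 : k + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a_ = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b_ = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a_ >= 0:
        return FluxPeak(float(x1), float(y1), True, "flat bracketing triple")
    loc = -b_ / (2 * a_)
    val = a_ * loc**2 + b_ * loc + (y0 - a_ * x0**2 - b_ * x0)
    return FluxPeak(float(loc), float(val), True)
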