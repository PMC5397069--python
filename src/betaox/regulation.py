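"""Time-dependent regulation analysis of a reaction during a substrate
upshift.

For one reaction and one boundary-substrate transition, each metabolite's
instantaneous contribution to the change of the (log) reaction rate is

    Theta_j(t) = eps_j(t) * d ln X_j / dt,

where ``eps_j`` is the reaction's scaled elasticity towards metabolite j
at the trajectory state and the log time-derivative comes from the exact
ODE right-hand side (not from numerical differentiation of the
trajectory).  The contributions close exactly:  sum_j Theta_j(t) equals
d ln v / dt.  Averaged absolute contributions |Theta-bar|_j are obtained
by adaptive quadrature of |Theta_j| over the transition horizon, and
relative shares are normalized so each reaction's shares sum to one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .core import KineticModel
from .mfao import substrate_parameter
from .simulate import Trajectory, find_steady_state, integrate

logger = logging.getLogger(__name__)

DEFAULT_HORIZON = 400.0


@dataclass
class RegulationTrace:
    """Per-metabolite regulation of one reaction over one transition."""

    reaction: str
    from_conc: float
    to_conc: float
    t_end: float
    t: np.ndarray
    theta: pd.DataFrame  # columns = metabolites, index aligned with t
    abs_avg: dict[str, float]  # |Theta-bar|_j (1/min)
    warnings: list[str] = field(default_factory=list)

    @property
    def metabolites(self) -> list[str]:
        return list(self.theta.columns)

    def relative_shares(self) -> dict[str, float]:
        total = sum(self.abs_avg.values())
        if total == 0.0:
            return {k: 0.0 for k in self.abs_avg}
        return {k: v / total for k, v in self.abs_avg.items()}

    def closure_residual(self, model: KineticModel, n_probe: int = 40) -> float:
        """max_t |sum_j Theta_j - d ln v/dt| / max_t |d ln v/dt|.

        The log rate derivative is estimated independently by central
        finite differences of the dense trajectory rate with a tight,
        time-proportional stencil.
        """
        ev = self._evaluator
        probes = np.geomspace(1e-3 * self.t_end, 0.9 * self.t_end, n_probe)
        totals = np.empty(n_probe)
        dlnv = np.empty(n_probe)
        for k, tp in enumerate(probes):
            totals[k] = sum(ev.theta_at(tp, lig) for lig in self.metabolites)
            dt = 1e-4 * tp
            v_m, v_p = ev.rate_at(tp - dt), ev.rate_at(tp + dt)
            dlnv[k] = (np.log(abs(v_p)) - np.log(abs(v_m))) / (2 * dt)
        scale = float(np.max(np.abs(dlnv)))
        if scale == 0.0:
            return float(np.max(np.abs(totals)))
        return float(np.max(np.abs(totals - dlnv)) / scale)

    def summary(self) -> pd.DataFrame:
        shares = self.relative_shares()
        return pd.DataFrame(
            {
                "metabolite": list(self.abs_avg),
                "abs_avg_theta": list(self.abs_avg.values()),
                "relative_share": [shares[k] for k in self.abs_avg],
            }
        )

    def long_frame(self) -> pd.DataFrame:
        df = self.theta.copy()
        df.insert(0, "t", self.t)
        return df.melt(id_vars="t", var_name="metabolite", value_name="theta")


class _ThetaEvaluator:
    """Theta_j(t) machinery bound to one model, reaction and trajectory."""

    def __init__(self, model: KineticModel, reaction: str, traj: Trajectory):
        self.model = model
        self.rxn = model.reaction(reaction)
        self.traj = traj
        self.var_names = model.variable_names
        self.vidx = {n: i for i, n in enumerate(self.var_names)}
        # all rate-law ligands; clamped pools contribute identically zero
        self.ligands = [lig for lig in self.rxn.law.ligands()]

    def rate_at(self, t: float) -> float:
        x = np.asarray(self.traj.values(t), dtype=float).reshape(len(self.var_names))
        full = self.model.full_concentrations(x)
        return self.rxn.law.rate(dict(zip(self.model.species_order, full)))

    def theta_at(self, t: float, ligand: str) -> float:
        if ligand not in self.vidx:
            return 0.0
        x = self.traj.values(t)
        x = np.asarray(x, dtype=float).reshape(len(self.var_names))
        conc_j = x[self.vidx[ligand]]
        if conc_j <= 0.0:
            return 0.0
        full = self.model.full_concentrations(x)
        conc = dict(zip(self.model.species_order, full))
        eps = self.rxn.law.elasticity(conc, ligand)
        dxdt = self.model.rhs(x)[self.vidx[ligand]]
        return eps * dxdt / conc_j

    def theta_grid(self, ts: np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
        xs = self.traj.values(ts)
        rates = np.empty(len(ts))
        cols = {lig: np.zeros(len(ts)) for lig in self.ligands}
        for k, t in enumerate(ts):
            x = xs[:, k]
            full = self.model.full_concentrations(x)
            conc = dict(zip(self.model.species_order, full))
            rates[k] = self.rxn.law.rate(conc)
            dxdt = self.model.rhs(x)
            for lig in self.ligands:
                i = self.vidx.get(lig)
                if i is None or x[i] <= 0.0:
                    continue
                cols[lig][k] = self.rxn.law.elasticity(conc, lig) * dxdt[i] / x[i]
        return pd.DataFrame(cols), rates


def _abs_quadrature(f, t_end: float, coarse_t: np.ndarray, coarse_y: np.ndarray,
                    rel_tol: float = 1e-6) -> float:
    """integral of |f| over [0, t_end], subdividing at sign changes."""
    points = [0.0]
    sign = np.sign(coarse_y)
    for k in range(len(coarse_t) - 1):
        if sign[k] * sign[k + 1] < 0:
            lo, hi = coarse_t[k], coarse_t[k + 1]
            ylo = coarse_y[k]
            for _ in range(40):  # bisect the crossing
                mid = 0.5 * (lo + hi)
                ymid = f(mid)
                if ylo * ymid <= 0:
                    hi = mid
                else:
                    lo, ylo = mid, ymid
                if hi - lo < 1e-9 * t_end:
                    break
            points.append(0.5 * (lo + hi))
    points.append(t_end)
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        if b <= a:
            continue
        val, _ = quad(lambda t: abs(f(t)), a, b, epsabs=1e-13, epsrel=rel_tol,
                      limit=200)
        total += val
    return total


def regulation_trace(
    model: KineticModel,
    from_conc: float,
    to_conc: float,
    reaction: str,
    t_end: float = DEFAULT_HORIZON,
    parameter: str | None = None,
    n_grid: int = 801,
    quad_rel_tol: float = 1e-6,
) -> RegulationTrace:
    """Quantify per-metabolite regulation of ``reaction`` over an upshift.

    The system is equilibrated at ``from_conc``, the boundary substrate is
    stepped to ``to_conc`` at t = 0, and the relaxation is followed over
    ``t_end`` minutes (extended automatically, with a warning, if the
    endpoint has not reached the post-shift steady state to 1e-6
    relative).
    """
    parameter = parameter or substrate_parameter(model)
    warnings_: list[str] = []

    pre = model.copy()
    pre.set_parameter(parameter, from_conc)
    ss_pre = find_steady_state(pre)
    if not ss_pre.converged:
        raise RuntimeError(f"no converged steady state at {parameter}={from_conc}")

    post = model.copy()
    post.set_parameter(parameter, to_conc)
    ss_post = find_steady_state(post, ss_pre.state)
    if not ss_post.converged:
        warnings_.append(f"post-shift steady state at {to_conc} not converged")

    horizon = t_end
    for _ in range(4):
        traj = integrate(post, ss_pre.state, horizon)
        end = traj.endpoint().vector(post.variable_names)
        target = ss_post.state.vector(post.variable_names)
        rel = np.max(np.abs(end - target) / np.maximum(np.abs(target), 1e-9))
        if rel < 1e-6 or not ss_post.converged:
            break
        horizon *= 2.0
        warnings_.append(
            f"endpoint {rel:.2e} relative from post-shift steady state; "
            f"horizon extended to {horizon:g} min"
        )
        logger.warning(warnings_[-1])

    ev = _ThetaEvaluator(post, reaction, traj)
    # denser early sampling: relaxation dynamics are front-loaded
    ts = np.unique(
        np.concatenate(
            [
                np.geomspace(1e-4, horizon, n_grid // 2),
                np.linspace(0.0, horizon, n_grid - n_grid // 2),
            ]
        )
    )
    theta, rates = ev.theta_grid(ts)
    if np.any(rates == 0.0) or np.any(np.sign(rates) != np.sign(rates[-1])):
        k = int(np.argmax(np.sign(rates) != np.sign(rates[-1])))
        warnings_.append(
            f"rate of {reaction} crosses zero near t={ts[k]:.3g} min; "
            "log-derivative undefined there"
        )
        logger.warning(warnings_[-1])

    abs_avg = {}
    for lig in theta.columns:
        col = theta[lig].to_numpy()
        if not np.any(col):
            abs_avg[lig] = 0.0
            continue
        abs_avg[lig] = (
            _abs_quadrature(lambda t, lig=lig: ev.theta_at(t, lig), horizon, ts, col,
                            rel_tol=quad_rel_tol)
            / horizon
        )

    trace = RegulationTrace(
        reaction=reaction,
        from_conc=from_conc,
        to_conc=to_conc,
        t_end=horizon,
        t=ts,
        theta=theta,
        abs_avg=abs_avg,
        warnings=warnings_,
    )
    trace._rates = rates
    trace._evaluator = ev
    return trace


def regulation_profile(
    model: KineticModel,
    to_concs,
    reaction: str,
    from_conc: float = 0.1,
    t_end: float = DEFAULT_HORIZON,
    parameter: str | None = None,
) -> pd.DataFrame:
    """Relative average absolute contributions per transition (columns).

    Each column sums to 1; metabolites absent from the rate law (or
    clamped) contribute exact zeros.  Failed transitions are flagged and
    their column omitted.
    """
    columns: dict[float, dict[str, float]] = {}
    metabolites: list[str] = []
    for to_conc in to_concs:
        try:
            trace = regulation_trace(
                model, from_conc, to_conc, reaction, t_end, parameter
            )
        except Exception as exc:  # noqa: BLE001 - per-transition isolation
            logger.warning("transition to %g failed: %s", to_conc, exc)
            continue
        shares = trace.relative_shares()
        columns[to_conc] = shares
        for met in shares:
            if met not in metabolites:
                metabolites.append(met)
    df = pd.DataFrame(
        {to_conc: [shares.get(met, 0.0) for met in metabolites]
         for to_conc, shares in columns.items()},
        index=pd.Index(metabolites, name="metabolite"),
    )
    return df
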