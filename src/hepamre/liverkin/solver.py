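"""Steady-state solution of the lumped hepatocyte network.

The model is a boundary-flux problem: plasma metabolites are clamped
(glucose on a 3-12 mM grid, free fatty acids and the phosphorylation state
gamma tied to glucose through transfer functions, the remaining nutrients at
fixed diurnal means) and the internal metabolite pools must balance,
S_int . v(c) = 0.  The solver works in log-concentration space, which keeps
pools strictly positive, using a damped (backtracking) Newton iteration with
a finite-difference Jacobian and an ODE-relaxation fallback for hard starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import fa_of_glucose, gamma_of_glucose, ghk_flux, phospho_activity
from .model import ModelInstance, Reaction, ReferenceModelSpec

__all__ = [
    "PlasmaState",
    "SteadyState",
    "LoadCharacteristic",
    "SolverError",
    "plasma_state_at",
    "steady_state",
    "load_characteristic",
    "DEFAULT_GLUCOSE_GRID",
]

DEFAULT_GLUCOSE_GRID = tuple(np.arange(3.0, 12.0 + 1e-9, 0.5))

RESIDUAL_RTOL = 1e-9  # accepted |S.v|_inf relative to the largest flux


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlasmaState:
    """Clamped plasma boundary conditions plus the derived hormone state."""

    glucose: float  # mM
    fatty_acids: float  # mM
    gamma: float  # phosphorylation state in [0, 1]
    others: Mapping[str, float] = field(default_factory=dict)  # metabolite id -> mM

    def __post_init__(self):
        if self.glucose < 0 or self.fatty_acids < 0:
            raise ValueError("plasma concentrations must be non-negative")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")

    def concentrations(self) -> dict[str, float]:
        out = {"glc_e": self.glucose, "ffa_e": self.fatty_acids}
        out.update(self.others)
        return out


@dataclass(frozen=True)
class SteadyState:
    fluxes: Mapping[str, float]  # reaction id -> µmol/g/h
    concentrations: Mapping[str, float]  # internal metabolite -> mM
    residual: float
    plasma: PlasmaState


@dataclass(frozen=True)
class LoadCharacteristic:
    """Steady-state fluxes and pools along an ascending plasma-glucose grid."""

    glucose_grid: tuple[float, ...]
    states: tuple[SteadyState, ...]

    def flux_series(self, reaction_id: str) -> np.ndarray:
        return np.array([s.fluxes[reaction_id] for s in self.states])

    def pool_series(self, metabolite_id: str) -> np.ndarray:
        return np.array([s.concentrations[metabolite_id] for s in self.states])


def plasma_state_at(spec: ReferenceModelSpec, glucose: float) -> PlasmaState:
    """Boundary conditions at one plasma-glucose level.

    gamma and FFA follow the model's transfer functions; every other plasma
    nutrient is held at its configured diurnal mean.
    """
    gamma = gamma_of_glucose(glucose, **spec.gamma_params)
    ffa = fa_of_glucose(glucose, **spec.ffa_params)
    others = dict(spec.plasma_defaults)
    others.pop("glc_e", None)
    others.pop("ffa_e", None)
    return PlasmaState(glucose=glucose, fatty_acids=ffa, gamma=gamma, others=others)


def _reaction_flux(r: Reaction, vmax: float, c: Mapping[str, float], gamma: float) -> float:
    act = 1.0
    if r.phospho is not None:
        act = phospho_activity(gamma, *r.phospho)
    for met, ki in r.inhibitors.items():
        act *= ki / (ki + c[met])
    if r.kind == "mm_irr":
        sat = 1.0
        for met, km in r.km.items():
            sat *= c[met] / (km + c[met])
        return vmax * act * sat
    if r.kind == "mm_rev":
        s_red = 1.0
        p_red = 1.0
        for met in r.substrates:
            if met in r.km:
                s_red *= c[met] / r.km[met]
        for met in r.products:
            if met in r.km:
                p_red *= c[met] / r.km[met]
        return vmax * act * (s_red - p_red / r.keq) / (1.0 + s_red + p_red)
    if r.kind == "mass_action":
        fwd = 1.0
        for met in r.substrates:
            fwd *= c[met]
        rev = 1.0
        for met in r.products:
            rev *= c[met]
        keq = r.keq if r.keq is not None else np.inf
        return vmax * act * (fwd - rev / keq)
    if r.kind == "ghk":
        (c_in_met,) = r.substrates
        p = r.ghk_params
        return ghk_flux(
            vmax * act,
            z=p.get("z", 1.0),
            V=p["v_membrane"],
            c_in=c[c_in_met],
            c_out=p["c_out"],
            T=p.get("temperature", 310.0),
        )
    raise ValueError(f"unknown rate law kind {r.kind!r}")


class _Network:
    """Flattened view of an instance for fast residual evaluation."""

    def __init__(self, instance: ModelInstance, plasma: PlasmaState):
        spec = instance.spec
        self.spec = spec
        self.reactions = spec.reactions
        self.vmax = np.array([instance.vmax[r.id] for r in self.reactions])
        self.internal = spec.internal_metabolites
        self.idx = {m: i for i, m in enumerate(self.internal)}
        self.gamma = plasma.gamma
        self.boundary = plasma.concentrations()
        # stoichiometric matrix restricted to internal metabolites
        self.S = np.zeros((len(self.internal), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, s in r.stoichiometry.items():
                if met in self.idx:
                    self.S[self.idx[met], j] = s

    def conc_map(self, x: np.ndarray) -> dict[str, float]:
        c = dict(self.boundary)
        c.update({m: np.exp(x[i]) for m, i in self.idx.items()})
        return c

    def fluxes(self, x: np.ndarray) -> np.ndarray:
        c = self.conc_map(x)
        return np.array(
            [
                _reaction_flux(r, v, c, self.gamma)
                for r, v in zip(self.reactions, self.vmax)
            ]
        )

    def residual(self, x: np.ndarray) -> np.ndarray:
        return self.S @ self.fluxes(x)


def _newton(net: _Network, x0: np.ndarray, tol: float, max_iter: int = 80):
    x = x0.copy()
    f = net.residual(x)
    for _ in range(max_iter):
        if np.max(np.abs(f)) < tol:
            return x, f, True
        # finite-difference Jacobian in log space
        n = x.size
        J = np.empty((n, n))
        h = 1e-7
        for k in range(n):
            xp = x.copy()
            xp[k] += h
            J[:, k] = (net.residual(xp) - f) / h
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(J, -f, rcond=None)[0]
        # trust-region style cap on the log-space step
        smax = np.max(np.abs(step))
        if smax > 2.0:
            step *= 2.0 / smax
        norm0 = np.linalg.norm(f)
        lam = 1.0
        for _ in range(25):
            x_new = x + lam * step
            f_new = net.residual(x_new)
            if np.linalg.norm(f_new) < (1.0 - 1e-4 * lam) * norm0 or np.max(
                np.abs(f_new)
            ) < tol:
                break
            lam *= 0.5
        else:
            return x, f, False
        x, f = x_new, f_new
    return x, f, np.max(np.abs(f)) < tol


def steady_state(
    instance: ModelInstance,
    plasma: PlasmaState,
    initial_log_conc: np.ndarray | None = None,
) -> SteadyState:
    """Solve S_int . v = 0 for the internal pools under clamped plasma.

    Deterministic: damped Newton from the model's documented initial
    concentrations (or a caller-supplied warm start), with an ODE-relaxation
    stage (log-space, LSODA) as fallback before a final Newton polish.
    """
    net = _Network(instance, plasma)
    if initial_log_conc is None:
        x0 = np.log(
            [instance.spec.metabolite(m).initial_mm for m in net.internal]
        )
    else:
        x0 = np.asarray(initial_log_conc, dtype=float)

    def tol_for(x):
        vmax_flux = np.max(np.abs(net.fluxes(x)))
        return RESIDUAL_RTOL * max(vmax_flux, 1e-6) * 0.1

    x, f, ok = _newton(net, x0, tol_for(x0))
    if not ok:
        # relax along the (log-space) kinetics, then polish
        def rhs(_, xv):
            c = np.exp(xv)
            return net.residual(xv) / c

        sol = solve_ivp(
            rhs, (0.0, 1e4), x0, method="LSODA", rtol=1e-10, atol=1e-12
        )
        if not sol.success:
            raise SolverError(
                f"ODE relaxation failed: {sol.message}; "
                f"last Newton residual {np.max(np.abs(f)):.3e}"
            )
        x, f, ok = _newton(net, sol.y[:, -1], tol_for(sol.y[:, -1]))
        if not ok:
            raise SolverError(
                f"no steady state found (residual {np.max(np.abs(f)):.3e})"
            )

    def accept_tol(v):
        # scale: largest flux, floored by the largest Vmax so that systems
        # whose fluxes are all (near) zero face a finite absolute bar
        return RESIDUAL_RTOL * max(np.max(np.abs(v)), 1e-3 * np.max(net.vmax), 1e-12)

    # the acceptance scale shrinks with the fluxes at the solution; re-polish
    # until the self-consistent tolerance is met (degenerate near-zero-flux
    # systems need a couple of rounds)
    for _ in range(3):
        v = net.fluxes(x)
        resid = float(np.max(np.abs(net.S @ v)))
        if resid < accept_tol(v):
            break
        x, f, ok = _newton(net, x, 0.5 * accept_tol(v))
        if not ok:
            break
    v = net.fluxes(x)
    resid = float(np.max(np.abs(net.S @ v)))
    if resid >= accept_tol(v):
        raise SolverError(f"steady-state residual {resid:.3e} above tolerance")
    conc = {m: float(np.exp(x[i])) for m, i in net.idx.items()}
    fluxes = {r.id: float(fv) for r, fv in zip(net.reactions, v)}
    return SteadyState(fluxes=fluxes, concentrations=conc, residual=resid, plasma=plasma)


def load_characteristic(
    instance: ModelInstance,
    grid: Sequence[float] = DEFAULT_GLUCOSE_GRID,
) -> LoadCharacteristic:
    """Steady states over an ascending plasma-glucose grid in [3, 12] mM.

    Each grid point is warm-started from the previous solution
    (continuation); the transfer functions supply gamma and FFA per point.
    """
    grid = tuple(float(g) for g in grid)
    if len(grid) < 1:
        raise ValueError("glucose grid must be non-empty")
    if any(g2 < g1 for g1, g2 in zip(grid, grid[1:])):
        raise ValueError("glucose grid must be ascending")
    if grid[0] < 3.0 - 1e-9 or grid[-1] > 12.0 + 1e-9:
        raise ValueError("glucose grid must lie within [3, 12] mM")
    states = []
    warm: np.ndarray | None = None
    for g in grid:
        plasma = plasma_state_at(instance.spec, g)
        try:
            st = steady_state(instance, plasma, initial_log_conc=warm)
        except SolverError as exc:
            raise SolverError(f"at glucose {g} mM: {exc}") from exc
        states.append(st)
        warm = np.log([st.concentrations[m] for m in instance.spec.internal_metabolites])
    return LoadCharacteristic(glucose_grid=grid, states=tuple(states))
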