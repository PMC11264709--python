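"""Steady state of the kinetic ODE system and the per-reaction fluxes there.

The metabolite balance is dC/dt = N v(C, theta), with N the stoichiometric
matrix and v the vector of kinetic rate laws; boundary species are clamped
(their derivative is identically zero).  A steady state is a concentration
vector where every non-boundary derivative vanishes to within an absolute
tolerance.

The solver is deterministic: stiff forward integration (LSODA) over
escalating time chunks pushes the state toward the attractor, and a damped
Newton iteration with a finite-difference Jacobian polishes the root.  A
Newton polish is also attempted between chunks, which makes the warm-started
re-solves after a mutation nearly free.  Failure to converge (oscillation,
divergence, unbounded accumulation) is an in-band result, never an
exception.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import sympy
from scipy.integrate import solve_ivp

from .model import KineticModel, RateEvaluationError

DEFAULT_STEADY_TOL = 1e-9
DEFAULT_TIME_CAP = 1e6


@dataclass
class SteadyStateResult:
    """Converged concentrations and fluxes (or a diagnosed failure)."""

    concentrations: np.ndarray      # over all species, boundary held fixed
    fluxes: np.ndarray              # signed, one per reaction
    residual_norm: float            # max |dC/dt| over non-boundary species
    converged: bool

    def concentration_map(self, model: KineticModel) -> dict[str, float]:
        return {s.id: float(c)
                for s, c in zip(model.species, self.concentrations)}

    def flux_map(self, model: KineticModel) -> dict[str, float]:
        return {r.id: float(f) for r, f in zip(model.reactions, self.fluxes)}


class CompiledModel:
    """Vectorized evaluator for a model's rates and ODE right-hand side."""

    def __init__(self, model: KineticModel):
        self.model = model
        self.species_ids = [s.id for s in model.species]
        self.param_ids = [p.id for p in model.all_parameters()]
        self._param_index = {p: i for i, p in enumerate(self.param_ids)}
        sp_index = {s: i for i, s in enumerate(self.species_ids)}
        n_s, n_r = len(model.species), len(model.reactions)
        self.stoich = np.zeros((n_s, n_r))
        for j, r in enumerate(model.reactions):
            for sid, coeff in r.substrates:
                self.stoich[sp_index[sid], j] -= coeff
            for sid, coeff in r.products:
                self.stoich[sp_index[sid], j] += coeff
        self.boundary = np.array([s.is_boundary for s in model.species])
        self.free = ~self.boundary
        conc_syms = [sympy.Symbol(s) for s in self.species_ids]
        par_syms = [sympy.Symbol(p) for p in self.param_ids]
        exprs = [r.rate.expr for r in model.reactions]
        self._rates = sympy.lambdify([conc_syms, par_syms], exprs,
                                     modules="numpy")

    @classmethod
    def of(cls, model: KineticModel) -> "CompiledModel":
        cached = getattr(model, "_compiled", None)
        if cached is None or cached.model is not model:
            cached = cls(model)
            model._compiled = cached
        return cached

    def param_vector(self, values) -> np.ndarray:
        vec = np.empty(len(self.param_ids))
        for pid, i in self._param_index.items():
            vec[i] = values[pid]
        return vec

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.model.species])

    def rates(self, conc: np.ndarray, params: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            return np.asarray(self._rates(conc, params), dtype=float)

    def rhs(self, conc: np.ndarray, params: np.ndarray) -> np.ndarray:
        out = self.stoich @ self.rates(conc, params)
        out[self.boundary] = 0.0
        return out


def ode_rhs(model: KineticModel, concentrations, parameter_values) -> np.ndarray:
    """dC/dt at the given state; boundary entries are exactly zero.

    Raises :class:`RateEvaluationError` naming the reaction if any rate is
    non-finite.
    """
    cm = CompiledModel.of(model)
    conc = np.asarray(concentrations, dtype=float)
    params = cm.param_vector(parameter_values)
    rates = cm.rates(conc, params)
    bad = ~np.isfinite(rates)
    if bad.any():
        rid = model.reactions[int(np.flatnonzero(bad)[0])].id
        raise RateEvaluationError(f"reaction {rid!r}: non-finite rate")
    out = cm.stoich @ rates
    out[cm.boundary] = 0.0
    return out


def _newton(cm: CompiledModel, conc: np.ndarray, params: np.ndarray,
            tol: float, max_iter: int = 40) -> tuple[np.ndarray, float]:
    """Damped Newton on the free (non-boundary) coordinates.

    Returns the best iterate and its residual norm; never raises.
    """
    free = np.flatnonzero(cm.free)
    c = conc.copy()

    def resid(x):
        f = cm.rhs(x, params)[free]
        return f, float(np.max(np.abs(f))) if f.size else 0.0

    f, norm = resid(c)
    if not np.isfinite(norm):
        return c, np.inf
    for _ in range(max_iter):
        if norm <= tol:
            return c, norm
        n = free.size
        jac = np.empty((n, n))
        for k, j in enumerate(free):
            h = 1e-7 * max(abs(c[j]), 1.0)
            cp = c.copy()
            cp[j] += h
            fp = cm.rhs(cp, params)[free]
            jac[:, k] = (fp - f) / h
        if not np.all(np.isfinite(jac)):
            return c, norm
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            return c, norm
        lam = 1.0
        improved = False
        while lam > 1e-8:
            cn = c.copy()
            cn[free] = c[free] + lam * step
            np.clip(cn, 0.0, None, out=cn)
            fn, nn = resid(cn)
            if np.isfinite(nn) and nn < norm:
                c, f, norm = cn, fn, nn
                improved = True
                break
            lam *= 0.5
        if not improved:
            return c, norm
    return c, norm


def solve_steady_state(model: KineticModel, parameter_values,
                       initial_concentrations=None,
                       steady_tolerance: float = DEFAULT_STEADY_TOL,
                       time_cap: float = DEFAULT_TIME_CAP) -> SteadyStateResult:
    """Find the steady state reached from *initial_concentrations*.

    Non-convergence (no finite root, oscillation, divergence) is reported
    in-band via ``converged=False``.
    """
    if steady_tolerance <= 0:
        raise ValueError("steady_tolerance must be > 0")
    cm = CompiledModel.of(model)
    params = cm.param_vector(parameter_values)
    c = (cm.initial_concentrations() if initial_concentrations is None
         else np.array(initial_concentrations, dtype=float))
    np.clip(c, 0.0, None, out=c)

    def norm_of(x) -> float:
        f = cm.rhs(x, params)[cm.free]
        return float(np.max(np.abs(f))) if f.size else 0.0

    best_c, best_norm = c.copy(), norm_of(c)
    # Newton straight away: after a small parameter perturbation the previous
    # steady state is an excellent starting guess.
    cand, n = _newton(cm, best_c, params, steady_tolerance)
    if n < best_norm:
        best_c, best_norm = cand, n

    elapsed, chunk = 0.0, 1.0
    while best_norm > steady_tolerance and elapsed < time_cap:
        span = min(chunk, time_cap - elapsed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sol = solve_ivp(lambda _t, y: cm.rhs(y, params),
                                (0.0, span), best_c, method="LSODA",
                                rtol=1e-8, atol=1e-12)
            except (RateEvaluationError, ValueError, FloatingPointError):
                break
        if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
            break
        c = np.clip(sol.y[:, -1], 0.0, None)
        elapsed += span
        chunk *= 10.0
        n = norm_of(c)
        if np.isfinite(n) and n < best_norm:
            best_c, best_norm = c, n
        cand, n = _newton(cm, c, params, steady_tolerance)
        if np.isfinite(n) and n < best_norm:
            best_c, best_norm = cand, n

    converged = bool(best_norm <= steady_tolerance)
    fluxes = cm.rates(best_c, params)
    return SteadyStateResult(best_c, fluxes, best_norm, converged)


def reaction_fluxes(model: KineticModel, result: SteadyStateResult,
                    parameter_values) -> np.ndarray:
    """Signed per-reaction rates at the converged steady state."""
    if not result.converged:
        raise ValueError("reaction_fluxes requires a converged steady state")
    cm = CompiledModel.of(model)
    return cm.rates(result.concentrations, cm.param_vector(parameter_values))
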