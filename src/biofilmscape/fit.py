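"""Least-squares estimation of flow/transport/metabolism parameters.

Matches modelled O2 concentration fields to measured (or forward-
generated) microsensor transects.  The objective is the sum of squared
differences between model and data, with the model field interpolated
at the sensor coordinates.  Optimization uses the Nelder-Mead simplex
over smoothly bound-transformed parameters: log scale for permeability
and eddy viscosity, logit for porosity and the effective-diffusivity
ratio, linear-in-bounds for the rate and the turbulent Prandtl number.
Random restarts mitigate trapping in local optima; the best vertex
wins and all restart objectives are reported.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr

from .hydro import FlowConvergenceError, solve_flow, solve_transport
from .hydro.domain import ModelDomain
from .types import FitResult, FitSpec, MicroprofileTransect, ModelParams

logger = logging.getLogger(__name__)

_LOG_PARAMS = {"permeability_m2", "eddy_visc_m2s"}
_LOGIT_PARAMS = {"porosity", "c_eff_diff"}
_FLOW_PARAMS = ("porosity", "permeability_m2", "eddy_visc_m2s")


def init_turbulence(water_depth_m: float, u_star_ms: float) -> tuple[float, float]:
    """Initial eddy viscosity and turbulent Prandtl number.

    nu_t ~ integral length scale (7% of the water depth) times the
    turbulent velocity fluctuation (taken equal to the friction
    velocity); Pr_t starts at 1.
    """
    return 0.07 * water_depth_m * u_star_ms, 1.0


def _to_unit(name: str, x: float, lo: float, hi: float) -> float:
    if name in _LOG_PARAMS:
        return (np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return (x - lo) / (hi - lo)


def _from_unit(name: str, t: float, lo: float, hi: float) -> float:
    t = float(np.clip(t, 0.0, 1.0))
    if name in _LOG_PARAMS:
        return float(np.exp(np.log(lo) + t * (np.log(hi) - np.log(lo))))
    return float(lo + t * (hi - lo))


def _sigmoid(y: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-y))


def _logit(t: float) -> float:
    t = min(max(t, 1e-9), 1 - 1e-9)
    return float(np.log(t / (1 - t)))


class TransectFitter:
    """Objective evaluation with flow-solution caching.

    The flow field only depends on (porosity, permeability, eddy
    viscosity) and the inlet profile; transport re-solves are cheap, so
    flow solutions are memoized across objective evaluations.
    """

    def __init__(
        self,
        domain: ModelDomain,
        transect: MicroprofileTransect,
        base_params: ModelParams,
        inlet_profile=None,
        inlet_conc: float = 0.3,
        advection: bool = False,
        n_correct: int = 1,
    ):
        if not transect.profiles:
            raise ValueError("transect must contain at least one profile")
        self.domain = domain
        self.transect = transect
        self.base = base_params
        self.inlet_profile = inlet_profile
        self.inlet_conc = inlet_conc
        self.advection = advection
        self.n_correct = n_correct
        self._flow_cache: dict[tuple, object] = {}
        self.n_eval = 0
        x, z, c = transect.points()
        self._x_m = x * 1e-3
        self._z_m = z * 1e-3
        self._c_obs = c

    def _flow(self, params: ModelParams):
        key = tuple(round(float(getattr(params, n)), 18) for n in _FLOW_PARAMS)
        if key not in self._flow_cache:
            self._flow_cache[key] = solve_flow(
                self.domain, params, self.inlet_profile, advection=self.advection
            )
        return self._flow_cache[key]

    def predict(self, params: ModelParams) -> np.ndarray:
        """Model concentrations at the sensor coordinates."""
        flow = self._flow(params)
        conc = solve_transport(
            self.domain,
            flow,
            params,
            inlet_conc=self.inlet_conc,
            light=self.transect.light,
            n_correct=self.n_correct,
        )
        return np.asarray(conc.interp(self._x_m, self._z_m))

    def objective(self, params: ModelParams) -> float:
        """Sum of squared model-data residuals ((mol m^-3)^2); +inf on
        solver failure so the simplex retreats."""
        self.n_eval += 1
        try:
            pred = self.predict(params)
        except (FlowConvergenceError, RuntimeError) as exc:
            logger.warning("solver failure during fit: %s", exc)
            return float("inf")
        return float(np.sum((pred - self._c_obs) ** 2))

    def correlations(self, params: ModelParams) -> list[float]:
        """Per-profile Pearson correlation between model and data."""
        pred = self.predict(params)
        out = []
        pos = 0
        for p in self.transect.profiles:
            n = p.z_mm.size
            obs = p.conc
            mod = pred[pos : pos + n]
            pos += n
            if np.std(obs) == 0 or np.std(mod) == 0:
                out.append(float("nan"))
            else:
                out.append(float(pearsonr(obs, mod)[0]))
        return out


def fit_parameters(
    domain: ModelDomain,
    transect: MicroprofileTransect,
    spec: FitSpec,
    base_params: ModelParams | None = None,
    inlet_profile=None,
    inlet_conc: float = 0.3,
    seed: int = 0,
    advection: bool = False,
) -> FitResult:
    """Nelder-Mead estimation of the free parameters of a transect.

    The search runs in a transformed space (sigmoid onto the bounds,
    with log scaling for permeability and eddy viscosity) and stops when
    the simplex spread falls below spec.xtol per variable.  spec.restarts
    runs start from the given initial values and from seeded random
    perturbations; the best objective wins.
    """
    base = base_params or ModelParams()
    fitter = TransectFitter(
        domain,
        transect,
        base,
        inlet_profile=inlet_profile,
        inlet_conc=inlet_conc,
        advection=advection,
    )
    names = list(spec.free)
    history: list[float] = []

    def make_params(y: np.ndarray) -> ModelParams:
        t = _sigmoid(np.asarray(y, dtype=float))
        updates = {
            n: _from_unit(n, t[j], *spec.bounds[n]) for j, n in enumerate(names)
        }
        return base.replace(**updates)

    def fun(y: np.ndarray) -> float:
        val = fitter.objective(make_params(y))
        best = min(history[-1], val) if history else val
        history.append(best)
        return val

    y0 = np.array(
        [_logit(_to_unit(n, spec.init[n], *spec.bounds[n])) for n in names]
    )
    rng = np.random.default_rng(seed)
    starts = [y0] + [
        y0 + rng.normal(0.0, 1.0, size=y0.size) for _ in range(max(0, spec.restarts - 1))
    ]

    best_res = None
    restart_objectives = []
    for y_start in starts:
        res = minimize(
            fun,
            y_start,
            method="Nelder-Mead",
            options={
                "xatol": spec.xtol,
                "fatol": 1e-12,
                "maxiter": spec.max_iter,
                "maxfev": spec.max_iter * 2,
            },
        )
        restart_objectives.append(float(res.fun))
        if best_res is None or res.fun < best_res.fun:
            best_res = res
    if best_res is None or not np.isfinite(best_res.fun):
        raise RuntimeError("all simplex vertices infeasible")

    params_hat = make_params(best_res.x)
    return FitResult(
        params=params_hat,
        objective=float(best_res.fun),
        correlations=fitter.correlations(params_hat),
        n_eval=fitter.n_eval,
        converged=bool(best_res.success),
        history=history,
        restart_objectives=restart_objectives,
    )
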