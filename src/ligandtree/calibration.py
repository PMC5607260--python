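"""Maximum-likelihood calibration of the signaling model.

All kinetic rates are shared across cell lines; the only per-line free
parameters allowed by the fitting scheme are the receptor expression levels.
Measurements y_i at times t_i are linked to the model through an observation
function g (scale, offset, optional log transform) with Gaussian noise of
known standard deviation sigma_i, so that

    chi2(theta) = sum_i ((y_i - g(x(t_i, theta))) / sigma_i)^2

is -2 log L up to a constant.  Optimization is trust-region least squares on
log10-transformed parameters with multi-start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .model import CompiledModel
from .network import CellLineContext, ModelSpec, StimulusCondition
from .params import ConfigurationError, KineticParameterSet

_LOG_FLOOR = 1e-12


class SchemaError(ValueError):
    """A measurement record does not map onto the model."""


class LeakageError(ValueError):
    """A holdout cell line was part of the training data."""


class ValidityError(ValueError):
    """A likelihood-ratio comparison is not valid (non-nested or failed fit)."""


class OptimizationError(RuntimeError):
    """All optimization starts failed."""


@dataclass
class Observable:
    """Observation map entry: y = scale * x + offset (+ noise), optionally
    compared on the log10 scale (sigma then in log10 units)."""

    scale: float = 1.0
    offset: float = 0.0
    sigma: float = 0.1
    log: bool = True

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("observable scale must be > 0")
        if self.sigma <= 0:
            raise ValueError("observable sigma must be > 0")


class ObservationMap(dict):
    """Mapping observable name -> :class:`Observable`."""

    @classmethod
    def uniform(cls, names, scale=1.0, offset=0.0, sigma=0.1, log=True) -> "ObservationMap":
        return cls({n: Observable(scale, offset, sigma, log) for n in names})


@dataclass
class MeasurementSet:
    """Tidy measurement records.

    Columns: cell_line, observable, condition (ligand label, e.g.
    ``"EGF:10"``), time_min, replicate, value, sigma.
    """

    frame: pd.DataFrame

    REQUIRED = ("cell_line", "observable", "condition", "time_min", "replicate", "value", "sigma")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"measurement table misses columns {missing}")
        if (self.frame["sigma"] <= 0).any():
            raise SchemaError("all measurement sigmas must be > 0")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cell_lines(self) -> tuple[str, ...]:
        return tuple(self.frame["cell_line"].unique())

    def subset_lines(self, lines) -> "MeasurementSet":
        return MeasurementSet(self.frame[self.frame["cell_line"].isin(lines)].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "MeasurementSet":
        return cls(pd.read_csv(path, comment="#"))


# ---------------------------------------------------------------------------
# free-parameter bookkeeping

@dataclass(frozen=True)
class FreeParameters:
    """Which parameters the optimizer may move.

    ``global_paths`` are shared kinetic parameter paths (e.g.
    ``"dimer/EGFR-HER2/ka"``); ``per_line_receptors`` frees the receptor
    expression of every training line for the named receptors (the
    calibration scheme of the shared-kinetics model); ``obs_scales`` frees
    the scale of named observables.
    """

    global_paths: tuple[str, ...] = ()
    per_line_receptors: tuple[str, ...] = ()
    obs_scales: tuple[str, ...] = ()

    def names(self, contexts) -> tuple[str, ...]:
        names = list(self.global_paths)
        for ctx in contexts:
            for r in self.per_line_receptors:
                names.append(f"expr:{ctx.name}:{r}")
        for o in self.obs_scales:
            names.append(f"obs:{o}:scale")
        return tuple(names)

    def nominal(self, params: KineticParameterSet, contexts, obs_map: ObservationMap) -> np.ndarray:
        vals = [params.get_path(p) for p in self.global_paths]
        for ctx in contexts:
            for r in self.per_line_receptors:
                vals.append(ctx.receptor_expression[r])
        for o in self.obs_scales:
            vals.append(obs_map[o].scale)
        return np.asarray(vals, dtype=float)

    def apply(self, theta: np.ndarray, params: KineticParameterSet, contexts,
              obs_map: ObservationMap):
        params = params.copy()
        obs_map = ObservationMap({k: replace(v) for k, v in obs_map.items()})
        i = 0
        for p in self.global_paths:
            params.set_path(p, theta[i])
            i += 1
        new_contexts = []
        for ctx in contexts:
            expr = dict(ctx.receptor_expression)
            for r in self.per_line_receptors:
                expr[r] = theta[i]
                i += 1
            new_contexts.append(replace(ctx, receptor_expression=expr))
        for o in self.obs_scales:
            obs_map[o].scale = theta[i]
            i += 1
        return params, new_contexts, obs_map


@dataclass
class FitResult:
    """Outcome of a multi-start maximum-likelihood fit."""

    theta: dict[str, float]
    chi2: float
    n_points: int
    n_free: int
    n_starts: int
    seed: int
    per_start_chi2: list[float]
    training_lines: tuple[str, ...]
    free: FreeParameters
    params: KineticParameterSet
    contexts: list[CellLineContext]
    obs_map: ObservationMap
    message: str = ""

    def fitted_expression(self) -> dict[str, dict[str, float]]:
        return {c.name: dict(c.receptor_expression) for c in self.contexts}

    def to_text(self, path) -> None:
        import yaml

        payload = {
            "chi2": float(self.chi2),
            "n_points": self.n_points,
            "n_free": self.n_free,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "theta": {k: float(v) for k, v in self.theta.items()},
            "per_start_chi2": [float(v) for v in self.per_start_chi2],
            "training_lines": list(self.training_lines),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# chi-square machinery

def _predict_records(model: CompiledModel, contexts, obs_map: ObservationMap,
                     frame: pd.DataFrame, rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Model prediction g(x(t_i)) for every record, in measurement space."""
    ctx_by_name = {c.name: c for c in contexts}
    pred = np.empty(len(frame))
    for (line, condition), grp in frame.groupby(["cell_line", "condition"], sort=False):
        if line not in ctx_by_name:
            raise SchemaError(f"no context supplied for cell line {line!r}")
        times = np.unique(np.concatenate([[0.0], grp["time_min"].to_numpy(float)]))
        stim = StimulusCondition.from_label(condition, horizon=float(times[-1]) if times[-1] > 0 else 240.0,
                                            time_grid=tuple(times))
        traj = model.simulate(ctx_by_name[line], stim, rtol=rtol, atol=atol)
        tindex = {t: i for i, t in enumerate(times)}
        for obs_name, og in grp.groupby("observable", sort=False):
            if obs_name not in obs_map:
                raise SchemaError(f"observable {obs_name!r} missing from observation map")
            om = obs_map[obs_name]
            x = traj.observable(obs_name)
            g = om.scale * x + om.offset
            rows = og.index.to_numpy()
            idx = [tindex[t] for t in og["time_min"].to_numpy(float)]
            pred[rows] = g[idx]
    return pred


def residuals(model: CompiledModel, contexts, obs_map: ObservationMap,
              data: MeasurementSet, rtol=1e-8, atol=1e-10) -> np.ndarray:
    """Weighted residuals (y_i - g_i)/sigma_i, on the log10 scale where the
    observable's log flag is set."""
    frame = data.frame.reset_index(drop=True)
    pred = _predict_records(model, contexts, obs_map, frame, rtol=rtol, atol=atol)
    y = frame["value"].to_numpy(float)
    sig = frame["sigma"].to_numpy(float)
    res = np.empty_like(y)
    for obs_name, grp in frame.groupby("observable", sort=False):
        om = obs_map[obs_name]
        ii = grp.index.to_numpy()
        if om.log:
            res[ii] = (np.log10(np.maximum(y[ii], _LOG_FLOOR))
                       - np.log10(np.maximum(pred[ii], _LOG_FLOOR))) / sig[ii]
        else:
            res[ii] = (y[ii] - pred[ii]) / sig[ii]
    return res


def chi_square(model: CompiledModel, contexts, obs_map: ObservationMap,
               data: MeasurementSet, theta: np.ndarray | None = None,
               free: FreeParameters | None = None, rtol=1e-8, atol=1e-10) -> float:
    """chi2 = sum of squared weighted residuals (>= 0)."""
    if theta is not None:
        if free is None:
            raise ValueError("theta requires a FreeParameters declaration")
        params, contexts, obs_map = free.apply(np.asarray(theta, float), model.params,
                                               contexts, obs_map)
        model = CompiledModel(model.spec, params, validate=False)
    r = residuals(model, contexts, obs_map, data, rtol=rtol, atol=atol)
    return float(np.dot(r, r))


# ---------------------------------------------------------------------------
# fitting

def fit(model: CompiledModel, contexts, data: MeasurementSet,
        free: FreeParameters, starts: int = 50, seed: int = 0,
        obs_map: ObservationMap | None = None,
        start_spread_decades: float = 2.0, bound_decades: float = 6.0,
        extra_starts: list[np.ndarray] | None = None,
        rtol: float = 1e-8, atol: float = 1e-10,
        max_nfev: int | None = None) -> FitResult:
    """Multi-start trust-region least squares in log10 parameter space.

    The first start is the nominal parameter vector; the remaining starts
    are drawn log-uniform within ``start_spread_decades`` of it (seeded, so
    repeated calls are bit-identical).  An empty ``free`` set returns the
    chi-square at the supplied parameters without optimization.
    """
    if obs_map is None:
        raise ValueError("an ObservationMap is required")
    names = free.names(contexts)
    n_free = len(names)
    training_lines = tuple(c.name for c in contexts)

    if n_free == 0:
        c2 = chi_square(model, contexts, obs_map, data, rtol=rtol, atol=atol)
        return FitResult(theta={}, chi2=c2, n_points=len(data), n_free=0,
                         n_starts=0, seed=seed, per_start_chi2=[c2],
                         training_lines=training_lines, free=free,
                         params=model.params.copy(), contexts=list(contexts),
                         obs_map=obs_map, message="no free parameters")
    if starts < 1:
        raise ValueError("starts must be >= 1")

    nominal = free.nominal(model.params, contexts, obs_map)
    if np.any(nominal <= 0):
        raise ConfigurationError("free parameters must be positive for log-space fitting")
    log_nom = np.log10(nominal)
    lo, hi = log_nom - bound_decades, log_nom + bound_decades

    compiled_cache: dict = {}

    def unpack(log_theta):
        theta = 10.0 ** np.asarray(log_theta, float)
        params, ctxs, omap = free.apply(theta, model.params, contexts, obs_map)
        if free.global_paths:
            key = tuple(np.round(np.asarray(log_theta)[: len(free.global_paths)], 12))
            mdl = compiled_cache.get(key)
            if mdl is None:
                mdl = CompiledModel(model.spec, params, validate=False)
                if len(compiled_cache) > 64:
                    compiled_cache.clear()
                compiled_cache[key] = mdl
        else:
            mdl = model
        return mdl, ctxs, omap

    def resfun(log_theta):
        mdl, ctxs, omap = unpack(log_theta)
        try:
            return residuals(mdl, ctxs, omap, data, rtol=rtol, atol=atol)
        except Exception:
            return np.full(len(data), 1e6)

    rng = np.random.default_rng(seed)
    start_points = [log_nom]
    for _ in range(starts - 1):
        start_points.append(log_nom + rng.uniform(-start_spread_decades,
                                                  start_spread_decades, n_free))
    for extra in extra_starts or []:
        start_points.append(np.clip(np.log10(np.maximum(extra, _LOG_FLOOR)), lo, hi))

    best = None
    per_start = []
    diagnostics = []
    for x0 in start_points:
        try:
            sol = least_squares(resfun, np.clip(x0, lo, hi), bounds=(lo, hi),
                                method="trf", x_scale=1.0, diff_step=1e-3,
                                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                max_nfev=max_nfev)
            c2 = float(2 * sol.cost)
            per_start.append(c2)
            diagnostics.append(sol.message)
            if best is None or c2 < best[0]:
                best = (c2, sol.x)
        except Exception as exc:  # keep going; report per-start failure
            per_start.append(float("inf"))
            diagnostics.append(str(exc))
    if best is None or not np.isfinite(best[0]):
        raise OptimizationError(f"all {len(start_points)} starts failed: {diagnostics}")

    theta_hat = 10.0 ** best[1]
    params_hat, ctx_hat, omap_hat = free.apply(theta_hat, model.params, contexts, obs_map)
    return FitResult(
        theta=dict(zip(names, theta_hat)), chi2=best[0], n_points=len(data),
        n_free=n_free, n_starts=len(start_points), seed=seed,
        per_start_chi2=per_start, training_lines=training_lines, free=free,
        params=params_hat, contexts=ctx_hat, obs_map=omap_hat,
        message="; ".join(sorted(set(diagnostics))),
    )


def predict_holdout(fit_result: FitResult, spec: ModelSpec,
                    new_context: CellLineContext, data: MeasurementSet,
                    rtol: float = 1e-8, atol: float = 1e-10) -> dict:
    """Goodness of prediction on a cell line never seen in training, using
    the fitted shared kinetics and only the new line's receptor expression."""
    if new_context.name in fit_result.training_lines:
        raise LeakageError(f"holdout line {new_context.name!r} was in the training set")
    if len(data) == 0:
        return {"cell_line": new_context.name, "n_points": 0, "chi2": 0.0,
                "chi2_per_point": float("nan")}
    extra = set(data.cell_lines) - {new_context.name}
    if extra:
        raise SchemaError(f"holdout data contains other cell lines: {sorted(extra)}")
    model = CompiledModel(spec, fit_result.params, validate=False)
    c2 = chi_square(model, [new_context], fit_result.obs_map, data, rtol=rtol, atol=atol)
    return {"cell_line": new_context.name, "n_points": len(data), "chi2": c2,
            "chi2_per_point": c2 / len(data)}


# ---------------------------------------------------------------------------
# likelihood-ratio test and coverage

def lrt_reduced(full_fit: FitResult, reduced_fit: FitResult,
                boundary: bool = False) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in the full model.

    Returns ``(statistic, df, p)`` with statistic = chi2_reduced - chi2_full
    and df the free-parameter difference.  With ``boundary=True`` the removed
    parameters are rates constrained to be non-negative, so the null
    distribution is the Chernoff mixture sum_j C(df,j) 2^-df chi2_j instead
    of chi2_df.
    """
    if full_fit.n_free <= reduced_fit.n_free:
        raise ValidityError("reduced model must have fewer free parameters")
    df = full_fit.n_free - reduced_fit.n_free
    stat = reduced_fit.chi2 - full_fit.chi2
    # optimizer jitter can leave the nested fit a hair below the full fit
    tol = max(1e-3, 1e-6 * reduced_fit.chi2)
    if stat < -tol:
        raise ValidityError(
            f"chi2_reduced ({reduced_fit.chi2:.6g}) < chi2_full ({full_fit.chi2:.6g}): "
            "models are not nested or a fit failed"
        )
    stat = max(stat, 0.0)
    if stat == 0.0:
        return 0.0, df, 1.0
    if boundary:
        from math import comb

        p = sum(comb(df, j) * 0.5 ** df * (stats.chi2.sf(stat, j) if j > 0 else 0.0)
                for j in range(df + 1))
    else:
        p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), float(p)


def coverage_fraction(model: CompiledModel, contexts, obs_map: ObservationMap,
                      data: MeasurementSet, k: float = 2.0,
                      rtol: float = 1e-8, atol: float = 1e-10) -> float:
    """Fraction of data points within k standard deviations of the model
    prediction (the measurement band interpretation of model uncertainty)."""
    if k <= 0:
        raise ValueError("k must be > 0")
    r = residuals(model, contexts, obs_map, data, rtol=rtol, atol=atol)
    return float(np.mean(np.abs(r) <= k))
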