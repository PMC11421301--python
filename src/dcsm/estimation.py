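"""FIML estimation, standard errors, and nested model comparison.

Covariance matrices are parameterized through lower-triangular square
roots so every optimizer iterate is positive semi-definite; residual
variances are optimized on the log scale.  Standard errors come from the
numerically differentiated observed information at the optimum, mapped
to the natural scale (covariance entries rather than square-root
factors) by the delta method.

Model comparison follows the classical likelihood-ratio ladder: a
constrained model is rejected when twice the log-likelihood difference
exceeds the chi-square critical value at the difference in free
parameters.  For variance components on the boundary this naive
reference is conservative; mixture references are deliberately not
implemented.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data_model import PairDataset
from .dcsm_core import (
    BoundData,
    DCSMParams,
    DCSMSpec,
    ParamGrads,
    bind_data,
    loglik_and_grad,
    loglik_bound,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "LRTResult",
    "ParamTransform",
    "fit_dcsm",
    "likelihood_ratio_test",
    "univariate_selection",
    "bivariate_selection",
    "restrict_params",
    "UnivariateSelection",
    "BivariateSelection",
]

_BIG = 1e12  # objective value returned when a trial point is numerically invalid


def _tril_indices(p: int) -> tuple[np.ndarray, np.ndarray]:
    return np.tril_indices(p)


def _safe_cholesky(S: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating PSD (singular) input via jitter."""
    S = 0.5 * (S + S.T)
    p = S.shape[0]
    if p == 0:
        return np.zeros((0, 0))
    jitter = 0.0
    base = max(np.trace(S) / p, 1e-12)
    for _ in range(8):
        try:
            return np.linalg.cholesky(S + jitter * np.eye(p))
        except np.linalg.LinAlgError:
            jitter = base * 1e-10 if jitter == 0.0 else jitter * 100.0
    raise np.linalg.LinAlgError("covariance block could not be factorized")


class ParamTransform:
    """Bijection between a DCSMSpec's free parameters and an unconstrained
    working vector used by the optimizer.

    Working layout: means, proportional betas, couplings, sex effects,
    lower-triangular square roots of the individual- and pair-level
    factor covariances, log residual variances, residual cross-trait
    covariance.  ``natural_vector`` exposes the same free parameters on
    their natural scale (variances/covariances instead of factors) for
    reporting and delta-method standard errors.
    """

    def __init__(self, spec: DCSMSpec):
        self.spec = spec
        k = spec.n_traits
        self.k = k
        self.nf = spec.n_factors
        self.pair_idx = np.asarray(spec.pair_factor_indices(), dtype=np.intp)
        self.p_pair = len(self.pair_idx)
        self.beta_idx = [i for i, on in enumerate(spec.proportional) if on]
        self.edges = list(spec.coupling)  # (src, dst) -> gamma[dst, src]

        blocks: list[tuple[str, int]] = [("mu_intercept", k), ("mu_slope", k)]
        blocks.append(("beta", len(self.beta_idx)))
        blocks.append(("gamma", len(self.edges)))
        if spec.sex_effects:
            blocks += [("sex_intercept", k), ("sex_slope", k)]
        if spec.ind_level == "full":
            blocks.append(("L_ind", self.nf * (self.nf + 1) // 2))
        blocks.append(("L_pair", self.p_pair * (self.p_pair + 1) // 2))
        blocks.append(("log_resid_var", k))
        if spec.residual_cross_trait:
            blocks.append(("resid_cov", 1))
        self.blocks = [(name, size) for name, size in blocks if size > 0]
        self.slices: dict[str, slice] = {}
        pos = 0
        for name, size in self.blocks:
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.n_working = pos

    @property
    def n_free(self) -> int:
        """Free parameters of the model = length of the working vector."""
        return self.n_working

    # -- working <-> params -------------------------------------------------

    def pack(self, params: DCSMParams) -> np.ndarray:
        x = np.zeros(self.n_working)
        s = self.slices
        x[s["mu_intercept"]] = params.mu_intercept
        x[s["mu_slope"]] = params.mu_slope
        if "beta" in s:
            x[s["beta"]] = params.beta[self.beta_idx]
        if "gamma" in s:
            x[s["gamma"]] = [params.gamma[dst, src] for src, dst in self.edges]
        if "sex_intercept" in s:
            x[s["sex_intercept"]] = params.sex_intercept
            x[s["sex_slope"]] = params.sex_slope
        if "L_ind" in s:
            L = _safe_cholesky(params.sigma_ind)
            x[s["L_ind"]] = L[_tril_indices(self.nf)]
        if "L_pair" in s:
            sub = params.sigma_pair[np.ix_(self.pair_idx, self.pair_idx)]
            L = _safe_cholesky(sub)
            x[s["L_pair"]] = L[_tril_indices(self.p_pair)]
        x[s["log_resid_var"]] = np.log(params.resid_var)
        if "resid_cov" in s:
            x[s["resid_cov"]] = params.resid_cov
        return x

    def unpack(self, x: np.ndarray) -> DCSMParams:
        s = self.slices
        k, nf = self.k, self.nf
        params = DCSMParams.zeros(self.spec)
        params.mu_intercept = np.array(x[s["mu_intercept"]])
        params.mu_slope = np.array(x[s["mu_slope"]])
        if "beta" in s:
            for i, v in zip(self.beta_idx, x[s["beta"]]):
                params.beta[i] = v
        if "gamma" in s:
            for (src, dst), v in zip(self.edges, x[s["gamma"]]):
                params.gamma[dst, src] = v
        if "sex_intercept" in s:
            params.sex_intercept = np.array(x[s["sex_intercept"]])
            params.sex_slope = np.array(x[s["sex_slope"]])
        if "L_ind" in s:
            L = np.zeros((nf, nf))
            L[_tril_indices(nf)] = x[s["L_ind"]]
            params.sigma_ind = L @ L.T
        if "L_pair" in s:
            p = self.p_pair
            L = np.zeros((p, p))
            L[_tril_indices(p)] = x[s["L_pair"]]
            sub = L @ L.T
            params.sigma_pair = np.zeros((nf, nf))
            params.sigma_pair[np.ix_(self.pair_idx, self.pair_idx)] = sub
        params.resid_var = np.exp(np.clip(x[s["log_resid_var"]], -40.0, 40.0))
        if "resid_cov" in s:
            params.resid_cov = float(x[s["resid_cov"]][0])
        return params

    def grad_to_working(self, x: np.ndarray, grads: ParamGrads) -> np.ndarray:
        """Chain a DCSMParams-space gradient to the working vector at x."""
        s = self.slices
        nf = self.nf
        g = np.zeros(self.n_working)
        g[s["mu_intercept"]] = grads.mu_intercept
        g[s["mu_slope"]] = grads.mu_slope
        if "beta" in s:
            g[s["beta"]] = grads.beta[self.beta_idx]
        if "gamma" in s:
            g[s["gamma"]] = [grads.gamma[dst, src] for src, dst in self.edges]
        if "sex_intercept" in s:
            g[s["sex_intercept"]] = grads.sex_intercept
            g[s["sex_slope"]] = grads.sex_slope
        if "L_ind" in s:
            L = np.zeros((nf, nf))
            L[_tril_indices(nf)] = x[s["L_ind"]]
            g[s["L_ind"]] = (2.0 * grads.sigma_ind @ L)[_tril_indices(nf)]
        if "L_pair" in s:
            p = self.p_pair
            L = np.zeros((p, p))
            L[_tril_indices(p)] = x[s["L_pair"]]
            G_sub = grads.sigma_pair[np.ix_(self.pair_idx, self.pair_idx)]
            g[s["L_pair"]] = (2.0 * G_sub @ L)[_tril_indices(p)]
        rv = np.exp(np.clip(x[s["log_resid_var"]], -40.0, 40.0))
        g[s["log_resid_var"]] = grads.resid_var * rv
        if "resid_cov" in s:
            g[s["resid_cov"]] = grads.resid_cov
        return g

    # -- natural-scale reporting --------------------------------------------

    def natural_names(self) -> list[str]:
        spec = self.spec
        tr = spec.traits
        fn = spec.factor_names()
        names = [f"{t}.mean_intercept" for t in tr] + [f"{t}.mean_slope" for t in tr]
        names += [f"{tr[i]}.beta" for i in self.beta_idx]
        names += [f"gamma.{tr[src]}_to_{tr[dst]}" for src, dst in self.edges]
        if spec.sex_effects:
            names += [f"{t}.sex_on_intercept" for t in tr]
            names += [f"{t}.sex_on_slope" for t in tr]
        if spec.ind_level == "full":
            r, c = _tril_indices(self.nf)
            names += [f"sigma_ind[{fn[i]},{fn[j]}]" for i, j in zip(r, c)]
        r, c = _tril_indices(self.p_pair)
        names += [
            f"sigma_pair[{fn[self.pair_idx[i]]},{fn[self.pair_idx[j]]}]" for i, j in zip(r, c)
        ]
        names += [f"{t}.resid_var" for t in tr]
        if spec.residual_cross_trait:
            names += ["resid_cov"]
        return names

    def natural_vector(self, params: DCSMParams) -> np.ndarray:
        out = [params.mu_intercept, params.mu_slope,
               params.beta[self.beta_idx],
               np.asarray([params.gamma[dst, src] for src, dst in self.edges])]
        if self.spec.sex_effects:
            out += [params.sex_intercept, params.sex_slope]
        if self.spec.ind_level == "full":
            out.append(params.sigma_ind[_tril_indices(self.nf)])
        sub = params.sigma_pair[np.ix_(self.pair_idx, self.pair_idx)]
        out.append(sub[_tril_indices(self.p_pair)])
        out.append(params.resid_var)
        if self.spec.residual_cross_trait:
            out.append(np.asarray([params.resid_cov]))
        return np.concatenate([np.atleast_1d(np.asarray(v, dtype=float)) for v in out])


def default_start(spec: DCSMSpec, data: PairDataset) -> DCSMParams:
    """Data-driven starting values.

    Mean intercepts from the first-bin trait means (pooled OLS intercept
    on the bin index as fallback when the first bin is empty); mean
    slopes from the average per-person least-squares slope; beta, gamma
    and sex effects start at 0; diagonal covariance starts scaled to the
    observed trait variance.
    """
    params = DCSMParams.zeros(spec)
    n_bins = spec.grid.n_bins
    for i, trait in enumerate(spec.traits):
        ts, vals, pids = [], [], []
        for a_b in data.pairs:
            for person in a_b:
                for t, obs in person.observations.items():
                    if trait in obs.values:
                        ts.append(t)
                        vals.append(obs.values[trait])
                        pids.append(person.person_id)
        ts = np.asarray(ts, dtype=float)
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            raise ValueError(f"trait {trait!r} has no observations")
        pooled_slope, pooled_icpt = 0.0, float(vals.mean())
        if vals.size >= 2 and np.ptp(ts) > 0:
            pooled_slope, pooled_icpt = np.polyfit(ts, vals, 1)
        slopes = []
        frame = pd.DataFrame({"pid": pids, "t": ts, "v": vals})
        for _, g in frame.groupby("pid"):
            if len(g) >= 2 and g["t"].nunique() >= 2:
                slopes.append(np.polyfit(g["t"], g["v"], 1)[0])
        slope = float(np.mean(slopes)) if slopes else float(pooled_slope)
        at0 = vals[ts == 0]
        icpt = float(at0.mean()) if at0.size else float(pooled_icpt)
        params.mu_intercept[i] = icpt
        params.mu_slope[i] = slope
        V = max(float(np.var(vals)), 1e-6)
        ii, ss = 2 * i, 2 * i + 1
        if spec.ind_level == "full":
            params.sigma_ind[ii, ii] = 0.4 * V
            params.sigma_ind[ss, ss] = 0.01 * V
        pf = spec.pair_factor_indices()
        if ii in pf:
            params.sigma_pair[ii, ii] = 0.1 * V
        if ss in pf:
            params.sigma_pair[ss, ss] = 0.0025 * V
        params.resid_var[i] = 0.3 * V
    return params


@dataclass
class FitResult:
    spec: DCSMSpec
    estimates: DCSMParams
    loglik: float
    n_free: int
    converged: bool
    n_evaluations: int
    names: list[str]
    natural_estimates: np.ndarray
    standard_errors: np.ndarray | None = None  # None when information not invertible
    metadata: dict = field(default_factory=dict)

    def estimate(self, name: str) -> float:
        return float(self.natural_estimates[self.names.index(name)])

    def se(self, name: str) -> float | None:
        if self.standard_errors is None:
            return None
        return float(self.standard_errors[self.names.index(name)])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names,
            "estimate": self.natural_estimates,
            "se": self.standard_errors if self.standard_errors is not None
                  else [np.nan] * len(self.names),
        })

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "loglik": self.loglik,
            "n_free": self.n_free,
            "converged": self.converged,
            "n_evaluations": self.n_evaluations,
            "estimates": {n: float(v) for n, v in zip(self.names, self.natural_estimates)},
            "standard_errors": (
                None if self.standard_errors is None
                else {n: float(v) for n, v in zip(self.names, self.standard_errors)}
            ),
            "params": self.estimates.to_dict(),
            "metadata": self.metadata,
        }


def _grad_hessian(grad, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian by central differences of an analytic gradient."""
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        H[i] = (grad(x + ei) - grad(x - ei)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def _numeric_jacobian(g, x: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    h = rel_step * (1.0 + np.abs(x))
    cols = []
    for i in range(len(x)):
        ei = np.zeros(len(x)); ei[i] = h[i]
        cols.append((g(x + ei) - g(x - ei)) / (2.0 * h[i]))
    return np.stack(cols, axis=1)


def fit_dcsm(
    spec: DCSMSpec,
    data: PairDataset | BoundData,
    start: DCSMParams | None = None,
    extra_starts: Sequence[DCSMParams] = (),
    n_random_starts: int = 0,
    seed: int | None = None,
    maxiter: int = 6000,
    maxfun: int = 200_000,
    ftol: float = 1e-10,
    gtol: float = 1e-5,
    compute_se: bool = True,
) -> FitResult:
    """Maximize the FIML objective for ``spec`` on ``data``.

    Quasi-Newton (L-BFGS-B) maximization on the unconstrained working
    scale, optionally from several starting points (the best final value
    wins).  Non-convergence is reported in ``converged`` and the
    diagnostics, never raised.  When the observed information matrix is
    not positive definite, ``standard_errors`` is None.
    """
    bound = data if isinstance(data, BoundData) else bind_data(spec, data)
    transform = ParamTransform(spec)

    starts = [transform.pack(start if start is not None else default_start(spec, _require_dataset(data, spec)))]
    starts += [transform.pack(p) for p in extra_starts]
    if n_random_starts:
        rng = np.random.default_rng(seed)
        base = starts[0]
        for _ in range(n_random_starts):
            starts.append(base + rng.normal(scale=0.1 * (1.0 + np.abs(base))))

    def negll_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        try:
            value, grads = loglik_and_grad(transform.unpack(x), bound)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            return _BIG, np.zeros_like(x)
        if not np.isfinite(value):
            return _BIG, np.zeros_like(x)
        g = transform.grad_to_working(x, grads)
        if not np.all(np.isfinite(g)):
            return _BIG, np.zeros_like(x)
        return -value, -g

    def negll(x: np.ndarray) -> float:
        return negll_grad(x)[0]

    t0 = time.perf_counter()
    best = None
    n_eval = 0
    for x0 in starts:
        res = optimize.minimize(
            negll_grad, x0, method="L-BFGS-B", jac=True,
            options={"maxiter": maxiter, "maxfun": maxfun, "ftol": ftol, "gtol": gtol},
        )
        n_eval += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None

    xhat = best.x
    loglik = -float(best.fun)
    converged = bool(best.success) and loglik > -_BIG / 2
    if not converged:
        logger.warning("fit did not converge: %s", best.message)

    params_hat = transform.unpack(xhat)
    names = transform.natural_names()
    nat = transform.natural_vector(params_hat)

    ses = None
    se_message = "not requested"
    if compute_se and converged:
        try:
            H = _grad_hessian(lambda z: negll_grad(z)[1], xhat)
            w = np.linalg.eigvalsh(0.5 * (H + H.T))
            if w.min() <= 0:
                cov_x = np.linalg.pinv(0.5 * (H + H.T))
                se_message = "observed information not positive definite; pseudo-inverse used"
                logger.warning(se_message)
            else:
                cov_x = np.linalg.inv(0.5 * (H + H.T))
                se_message = "observed information"
            J = _numeric_jacobian(lambda z: transform.natural_vector(transform.unpack(z)), xhat)
            cov_nat = J @ cov_x @ J.T
            diag = np.diag(cov_nat)
            if np.any(diag < -1e-8 * (1 + np.abs(diag).max())):
                ses = None
                se_message = "delta-method covariance indefinite; SEs unavailable"
                logger.warning(se_message)
            else:
                ses = np.sqrt(np.clip(diag, 0.0, None))
        except np.linalg.LinAlgError as exc:
            ses = None
            se_message = f"information matrix not invertible ({exc})"
            logger.warning(se_message)
    elif compute_se:
        se_message = "skipped: fit not converged"

    return FitResult(
        spec=spec,
        estimates=params_hat,
        loglik=loglik,
        n_free=transform.n_free,
        converged=converged,
        n_evaluations=n_eval,
        names=names,
        natural_estimates=nat,
        standard_errors=ses,
        metadata={
            "optimizer": "L-BFGS-B",
            "message": str(best.message),
            "grad_inf_norm": float(np.max(np.abs(best.jac))) if best.jac is not None else None,
            "n_starts": len(starts),
            "seed": seed,
            "se_method": se_message,
            "elapsed_s": time.perf_counter() - t0,
            "n_units": bound.n_units,
            "n_obs_values": bound.n_obs_values,
        },
    )


def _require_dataset(data, spec) -> PairDataset:
    if isinstance(data, PairDataset):
        return data
    raise ValueError(
        "default starting values need the PairDataset; pass `start=` when fitting bound data"
    )


def restrict_params(params: DCSMParams, nested: DCSMSpec) -> DCSMParams:
    """Project parameters onto a nested spec by zeroing the removed terms
    (a warm start for the constrained fit)."""
    out = params.copy()
    for i, on in enumerate(nested.proportional):
        if not on:
            out.beta[i] = 0.0
    edges = set(nested.coupling)
    k = nested.n_traits
    for i in range(k):
        for j in range(k):
            if i != j and (j, i) not in edges:
                out.gamma[i, j] = 0.0
    if not nested.sex_effects:
        out.sex_intercept[:] = 0.0
        out.sex_slope[:] = 0.0
    pf = set(nested.pair_factor_indices())
    for a in range(2 * k):
        for b in range(2 * k):
            if a not in pf or b not in pf:
                out.sigma_pair[a, b] = 0.0
    if nested.ind_level == "none":
        out.sigma_ind[:] = 0.0
    if not nested.residual_cross_trait:
        out.resid_cov = 0.0
    return out


def _is_nested(full: DCSMSpec, nested: DCSMSpec) -> bool:
    if full.traits != nested.traits or full.grid != nested.grid:
        return False
    if any(n and not f for f, n in zip(full.proportional, nested.proportional)):
        return False
    if not set(nested.coupling) <= set(full.coupling):
        return False
    if not set(nested.pair_factor_indices()) <= set(full.pair_factor_indices()):
        return False
    if nested.ind_level == "full" and full.ind_level == "none":
        return False
    if nested.residual_cross_trait and not full.residual_cross_trait:
        return False
    if nested.sex_effects and not full.sex_effects:
        return False
    return True


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float
    full: FitResult
    nested: FitResult

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "loglik_full": self.full.loglik,
            "loglik_nested": self.nested.loglik,
            "n_free_full": self.full.n_free,
            "n_free_nested": self.nested.n_free,
        }


def likelihood_ratio_test(full: FitResult, nested: FitResult) -> LRTResult:
    """Chi-square likelihood ratio test of a constrained against a full model."""
    if not _is_nested(full.spec, nested.spec):
        raise ValueError("the second model is not nested in the first")
    df = full.n_free - nested.n_free
    if df <= 0:
        raise ValueError(f"no constrained parameters (df = {df})")
    stat = 2.0 * (full.loglik - nested.loglik)
    if stat < 0:
        logger.warning(
            "negative LRT statistic %.3g (nested fit beat the full fit; "
            "floored at 0 — consider warm starts)", stat,
        )
        stat = 0.0
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LRTResult(statistic=float(stat), df=df, p_value=p, full=full, nested=nested)


@dataclass
class UnivariateSelection:
    trait: str
    full: FitResult
    linear: FitResult
    lrt: LRTResult
    proportional_retained: bool
    retained_spec: DCSMSpec

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "proportional_retained": self.proportional_retained,
            "lrt": self.lrt.to_dict(),
            "full": self.full.to_dict(),
            "linear": self.linear.to_dict(),
        }


def univariate_selection(
    data: PairDataset,
    trait: str,
    pair_level: str | tuple = "full",
    alpha_level: float = 0.05,
    **fit_kw,
) -> UnivariateSelection:
    """Test for nonlinear change: full (slope + proportional) vs linear-only.

    The proportional coefficient is retained when dropping it
    significantly worsens fit (LRT p < ``alpha_level``).
    """
    grid = data.grid
    user_start = fit_kw.pop("start", None)
    full_spec = DCSMSpec(traits=(trait,), proportional=(True,), coupling=(),
                         pair_level=pair_level, residual_cross_trait=False, grid=grid)
    lin_spec = DCSMSpec(traits=(trait,), proportional=(False,), coupling=(),
                        pair_level=pair_level, residual_cross_trait=False, grid=grid)
    full = fit_dcsm(full_spec, data, start=user_start, **fit_kw)
    nested = fit_dcsm(lin_spec, data,
                      start=None if user_start is None else restrict_params(user_start, lin_spec),
                      extra_starts=[restrict_params(full.estimates, lin_spec)], **fit_kw)
    if full.loglik < nested.loglik:  # warm-restart the full fit from the nested optimum
        refit = fit_dcsm(full_spec, data, start=nested.estimates, **fit_kw)
        if refit.loglik > full.loglik:
            full = refit
    lrt = likelihood_ratio_test(full, nested)
    keep = lrt.p_value < alpha_level
    return UnivariateSelection(
        trait=trait, full=full, linear=nested, lrt=lrt,
        proportional_retained=keep, retained_spec=full_spec if keep else lin_spec,
    )


@dataclass
class BivariateSelection:
    fits: dict[str, FitResult]
    lrts: dict[str, LRTResult]
    selected: str
    tie: bool
    proportional: tuple[bool, bool]
    univariate: dict[str, UnivariateSelection] | None = None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "tie": self.tie,
            "proportional": list(self.proportional),
            "lrts": {k: v.to_dict() for k, v in self.lrts.items()},
            "loglik": {k: v.loglik for k, v in self.fits.items()},
            "fits": {k: v.to_dict() for k, v in self.fits.items()},
        }


def bivariate_selection(
    data: PairDataset,
    traits: tuple[str, str] = ("fi", "clock"),
    proportional: tuple[bool, bool] | None = None,
    pair_level: str | tuple = "full",
    alpha_level: float = 0.05,
    univariate_pair_level: str | tuple = "full",
    **fit_kw,
) -> BivariateSelection:
    """Coupling-structure selection for a bivariate model.

    Fits four models on top of the retained univariate structure —
    bidirectional coupling, no coupling, and each unidirectional
    coupling — then follows the test ladder: the no-coupling model is
    accepted if it does not fit significantly worse than the
    bidirectional one; otherwise each unidirectional model is accepted
    if it is not significantly worse than bidirectional.  If both
    unidirectional models survive, the tie is reported (the higher
    log-likelihood is listed as selected).

    ``proportional`` fixes which traits keep the proportional term; when
    None it is decided by ``univariate_selection`` per trait.
    """
    user_start = fit_kw.pop("start", None)  # bivariate params; not valid for univariate fits
    uni_reports = None
    if proportional is None:
        uni_reports = {
            t: univariate_selection(data, t, pair_level=univariate_pair_level,
                                    alpha_level=alpha_level, **fit_kw)
            for t in traits
        }
        proportional = tuple(uni_reports[t].proportional_retained for t in traits)

    grid = data.grid
    c_1to0 = f"{traits[1]}_to_{traits[0]}"
    c_0to1 = f"{traits[0]}_to_{traits[1]}"

    def make_spec(coupling):
        return DCSMSpec(traits=traits, proportional=proportional, coupling=coupling,
                        pair_level=pair_level, residual_cross_trait=True, grid=grid)

    specs = {
        "bidirectional": make_spec(((1, 0), (0, 1))),
        c_1to0: make_spec(((1, 0),)),
        c_0to1: make_spec(((0, 1),)),
        "none": make_spec(()),
    }
    fits: dict[str, FitResult] = {}
    fits["bidirectional"] = fit_dcsm(specs["bidirectional"], data, start=user_start, **fit_kw)
    for name in (c_1to0, c_0to1, "none"):
        fits[name] = fit_dcsm(
            specs[name], data,
            start=None if user_start is None else restrict_params(user_start, specs[name]),
            extra_starts=[restrict_params(fits["bidirectional"].estimates, specs[name])],
            **fit_kw,
        )
    best_nested = max((fits[n] for n in (c_1to0, c_0to1, "none")), key=lambda f: f.loglik)
    if fits["bidirectional"].loglik < best_nested.loglik:
        refit = fit_dcsm(specs["bidirectional"], data, start=best_nested.estimates, **fit_kw)
        if refit.loglik > fits["bidirectional"].loglik:
            fits["bidirectional"] = refit

    lrts = {name: likelihood_ratio_test(fits["bidirectional"], fits[name])
            for name in ("none", c_1to0, c_0to1)}

    tie = False
    if lrts["none"].p_value >= alpha_level:
        selected = "none"
    else:
        ok = [n for n in (c_1to0, c_0to1) if lrts[n].p_value >= alpha_level]
        if not ok:
            selected = "bidirectional"
        elif len(ok) == 1:
            selected = ok[0]
        else:
            tie = True
            selected = max(ok, key=lambda n: fits[n].loglik)
            logger.warning(
                "both unidirectional couplings are acceptable (p = %.3f, %.3f); "
                "reporting %s (higher log-likelihood) with tie flag",
                lrts[ok[0]].p_value, lrts[ok[1]].p_value, selected,
            )
    return BivariateSelection(fits=fits, lrts=lrts, selected=selected, tie=tie,
                              proportional=tuple(proportional), univariate=uni_reports)
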