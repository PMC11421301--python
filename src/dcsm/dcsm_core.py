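"""Dual change score models (DCSM) as structured multivariate normals.

A DCSM is a latent growth model in which the change of each trait's
latent true score between adjacent age bins is

    delta y[t] = alpha * S + beta * y[t-1] + sum_j gamma[j] * x_j[t-1]

with alpha fixed to 1, a per-trait proportional (self-feedback)
coefficient beta, and cross-trait coupling coefficients gamma.  Because
the recursion is linear in the growth factors (one intercept and one
slope per trait), the latent trajectory is ``L @ factors`` for a loading
matrix L obtained by forward recursion, and the observed data are
multivariate normal.  Random growth factors live at two levels:
individual and twin pair (the pair-level factors are shared by co-twins,
inducing cross-twin covariance without an explicit genetic model).
Occasion-level residuals are independent across bins and across twins,
with an optional within-person, within-bin cross-trait covariance.

The full-information maximum likelihood (FIML) objective sums, over twin
pairs, the normal log-density of each pair's *observed* sub-vector under
the corresponding sub-moments, which handles arbitrary missingness
(including singleton "pairs" whose co-twin is entirely missing).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data_model import AgeGrid, PairDataset

logger = logging.getLogger(__name__)

__all__ = [
    "DCSMSpec",
    "DCSMParams",
    "ImpliedMoments",
    "PairLayout",
    "build_latent_loadings",
    "implied_moments",
    "bind_data",
    "fiml_loglik",
]

ALPHA = 1.0  # the static-change loading on the slope factor, fixed by convention
PSD_TOL = 1e-10  # eigenvalues above -PSD_TOL are clipped; below raises

_PAIR_LEVEL_CHOICES = ("full", "intercepts_only", "none")




@dataclass(frozen=True)
class DCSMSpec:
    """Structural switches: which parameters exist in the model.

    ``traits`` names the modeled traits (must match dataset labels; order
    fixes the factor layout).  ``proportional`` toggles beta per trait.
    ``coupling`` lists directed edges as (source trait index, target
    trait index); each adds one gamma.  ``pair_level`` selects the
    pair-level random-effect structure: "full", "intercepts_only",
    "none", or an explicit tuple of (trait index, "intercept"|"slope")
    entries for reduced structures (e.g. dropping only one trait's
    pair-level slope when the full structure will not converge).
    """

    traits: tuple[str, ...] = ("fi", "clock")
    proportional: tuple[bool, ...] = (True, True)
    coupling: tuple[tuple[int, int], ...] = ()
    pair_level: str | tuple = "full"
    ind_level: str = "full"  # "full" | "none" (no individual-level factors)
    residual_cross_trait: bool = True
    sex_effects: bool = True
    grid: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "proportional", tuple(bool(b) for b in self.proportional))
        object.__setattr__(self, "coupling", tuple((int(a), int(b)) for a, b in self.coupling))
        if isinstance(self.pair_level, str):
            if self.pair_level not in _PAIR_LEVEL_CHOICES:
                raise ValueError(f"pair_level must be one of {_PAIR_LEVEL_CHOICES} or a tuple")
        else:
            object.__setattr__(self, "pair_level", tuple((int(i), str(w)) for i, w in self.pair_level))
        k = self.n_traits
        if k not in (1, 2):
            raise ValueError("only univariate and bivariate models are supported")
        if len(self.proportional) != k:
            raise ValueError("proportional flags must match the number of traits")
        for src, dst in self.coupling:
            if k != 2:
                raise ValueError("coupling requires a bivariate model")
            if src == dst or not (0 <= src < k and 0 <= dst < k):
                raise ValueError(f"invalid coupling edge ({src}, {dst})")
        if self.residual_cross_trait and k != 2:
            object.__setattr__(self, "residual_cross_trait", False)
        if self.ind_level not in ("full", "none"):
            raise ValueError("ind_level must be 'full' or 'none'")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_factors(self) -> int:
        return 2 * self.n_traits  # intercept and slope per trait

    def factor_names(self) -> list[str]:
        out = []
        for t in self.traits:
            out += [f"{t}_intercept", f"{t}_slope"]
        return out

    def pair_factor_indices(self) -> tuple[int, ...]:
        """Indices (into the factor vector) carrying pair-level variance."""
        if self.pair_level == "none":
            return ()
        if self.pair_level == "full":
            return tuple(range(self.n_factors))
        if self.pair_level == "intercepts_only":
            return tuple(2 * i for i in range(self.n_traits))
        idx = []
        for i, which in self.pair_level:
            if not 0 <= i < self.n_traits:
                raise ValueError(f"pair_level trait index {i} out of range")
            idx.append(2 * i + (0 if which == "intercept" else 1))
        return tuple(sorted(set(idx)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = self.grid.to_dict()
        d["pair_level"] = (
            self.pair_level if isinstance(self.pair_level, str) else [list(x) for x in self.pair_level]
        )
        d["coupling"] = [list(x) for x in self.coupling]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "DCSMSpec":
        d = dict(d)
        d["grid"] = AgeGrid.from_dict(d.get("grid", {}))
        if not isinstance(d.get("pair_level", "full"), str):
            d["pair_level"] = tuple((int(i), str(w)) for i, w in d["pair_level"])
        d["coupling"] = tuple(tuple(x) for x in d.get("coupling", ()))
        return cls(**d)


@dataclass
class DCSMParams:
    """All model parameters; entries switched off by the spec must be 0.

    Factor order is (trait0 intercept, trait0 slope, trait1 intercept,
    trait1 slope).  ``sigma_ind`` / ``sigma_pair`` are covariance
    matrices over that factor vector at the individual and twin-pair
    level; ``gamma[i, j]`` is the effect of trait j's previous latent
    level on trait i's change.  Sex effects shift the factor *means* for
    women (coded 1) and propagate through the dynamics.
    """

    mu_intercept: np.ndarray
    mu_slope: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sex_intercept: np.ndarray
    sex_slope: np.ndarray
    sigma_ind: np.ndarray
    sigma_pair: np.ndarray
    resid_var: np.ndarray
    resid_cov: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_intercept", "mu_slope", "beta", "sex_intercept", "sex_slope", "resid_var"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma_ind = np.asarray(self.sigma_ind, dtype=float)
        self.sigma_pair = np.asarray(self.sigma_pair, dtype=float)
        self.resid_cov = float(self.resid_cov)

    @property
    def n_traits(self) -> int:
        return len(self.mu_intercept)

    @property
    def alpha(self) -> float:
        return ALPHA

    def factor_mean(self, sex: int) -> np.ndarray:
        """Mean growth-factor vector for a person of the given sex."""
        k = self.n_traits
        m = np.empty(2 * k)
        m[0::2] = self.mu_intercept + sex * self.sex_intercept
        m[1::2] = self.mu_slope + sex * self.sex_slope
        return m

    def residual_block(self) -> np.ndarray:
        """Within-person within-bin residual covariance across traits (k x k)."""
        k = self.n_traits
        R = np.diag(self.resid_var)
        if k == 2:
            R[0, 1] = R[1, 0] = self.resid_cov
        return R

    @classmethod
    def zeros(cls, spec: DCSMSpec) -> "DCSMParams":
        k = spec.n_traits
        return cls(
            mu_intercept=np.zeros(k), mu_slope=np.zeros(k), beta=np.zeros(k),
            gamma=np.zeros((k, k)), sex_intercept=np.zeros(k), sex_slope=np.zeros(k),
            sigma_ind=np.zeros((2 * k, 2 * k)), sigma_pair=np.zeros((2 * k, 2 * k)),
            resid_var=np.ones(k), resid_cov=0.0,
        )

    def copy(self) -> "DCSMParams":
        return DCSMParams(
            mu_intercept=self.mu_intercept.copy(), mu_slope=self.mu_slope.copy(),
            beta=self.beta.copy(), gamma=self.gamma.copy(),
            sex_intercept=self.sex_intercept.copy(), sex_slope=self.sex_slope.copy(),
            sigma_ind=self.sigma_ind.copy(), sigma_pair=self.sigma_pair.copy(),
            resid_var=self.resid_var.copy(), resid_cov=self.resid_cov,
        )

    def to_dict(self) -> dict:
        return {
            "mu_intercept": self.mu_intercept.tolist(),
            "mu_slope": self.mu_slope.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "sex_intercept": self.sex_intercept.tolist(),
            "sex_slope": self.sex_slope.tolist(),
            "sigma_ind": self.sigma_ind.tolist(),
            "sigma_pair": self.sigma_pair.tolist(),
            "resid_var": self.resid_var.tolist(),
            "resid_cov": self.resid_cov,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DCSMParams":
        return cls(**{k: np.asarray(v) if isinstance(v, list) else v for k, v in dict(d).items()})


def validate_params(spec: DCSMSpec, params: DCSMParams) -> None:
    """Check shape/PSD invariants and that switched-off parameters are 0."""
    k = spec.n_traits
    if params.n_traits != k:
        raise ValueError(f"params have {params.n_traits} traits, spec has {k}")
    for i, on in enumerate(spec.proportional):
        if not on and params.beta[i] != 0.0:
            raise ValueError(f"beta[{i}] must be 0: proportional change is off for {spec.traits[i]}")
    edges = set(spec.coupling)
    for i in range(k):
        for j in range(k):
            if i != j and (j, i) not in edges and params.gamma[i, j] != 0.0:
                raise ValueError(f"gamma[{i},{j}] must be 0: coupling {j}->{i} is off")
    if not spec.sex_effects and (np.any(params.sex_intercept) or np.any(params.sex_slope)):
        raise ValueError("sex effects are off in the spec but nonzero in params")
    if np.any(params.resid_var <= 0):
        raise ValueError("residual variances must be positive")
    if not spec.residual_cross_trait and params.resid_cov != 0.0:
        raise ValueError("residual cross-trait covariance is off in the spec")
    pf = set(spec.pair_factor_indices())
    scale = max(1.0, float(np.max(np.abs(params.sigma_pair))))
    for a in range(2 * k):
        for b in range(2 * k):
            if (a not in pf or b not in pf) and abs(params.sigma_pair[a, b]) > 1e-10 * scale:
                raise ValueError("sigma_pair has mass outside the spec's pair-level factors")
    if spec.ind_level == "none" and np.any(params.sigma_ind):
        raise ValueError("sigma_ind must be 0 when ind_level='none'")
    _psd_guard(params.sigma_ind, "sigma_ind")
    _psd_guard(params.sigma_pair, "sigma_pair")


def _psd_guard(S: np.ndarray, name: str) -> np.ndarray:
    """Symmetrize and clip eigenvalues in [-PSD_TOL, 0); harder violations raise."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    scale = max(1.0, float(np.max(np.abs(w))) if w.size else 1.0)
    if w.min(initial=0.0) < -PSD_TOL * scale:
        raise ValueError(f"{name} is not positive semi-definite (min eigenvalue {w.min():.3e})")
    if w.min(initial=0.0) < 0:
        w = np.clip(w, 0.0, None)
        S = (V * w) @ V.T
    return S


@dataclass(frozen=True)
class PairLayout:
    """Index map for the stacked pair observation vector.

    Position = twin * (n_traits * n_bins) + trait * n_bins + bin, for
    twin in {0, 1} (A, B).
    """

    n_traits: int
    n_bins: int

    @property
    def per_twin(self) -> int:
        return self.n_traits * self.n_bins

    @property
    def size(self) -> int:
        return 2 * self.per_twin

    def index(self, twin: int, trait: int, t: int) -> int:
        if not (0 <= twin < 2 and 0 <= trait < self.n_traits and 0 <= t < self.n_bins):
            raise IndexError((twin, trait, t))
        return twin * self.per_twin + trait * self.n_bins + t


@dataclass
class ImpliedMoments:
    mean: np.ndarray
    covariance: np.ndarray
    layout: PairLayout


def build_latent_loadings(spec: DCSMSpec, params: DCSMParams) -> np.ndarray:
    """Loadings of each trait's latent score on the growth factors.

    Returns ``L`` with shape (n_traits, n_bins, n_factors) such that the
    latent score of trait i at bin t for a person with factor vector f is
    ``L[i, t] @ f``.  Built by the forward recursion

        y_i[0] = I_i
        y_i[t] = y_i[t-1] + alpha*S_i + beta_i*y_i[t-1] + sum_j gamma[i,j]*y_j[t-1]

    Bin 0 loads only on the intercepts; with beta = gamma = 0 the loading
    of bin t on the slope is exactly t (a linear growth curve).  Because
    sex shifts the factor means, deterministic sex/mean terms propagate
    through this same matrix.
    """
    k = spec.n_traits
    n = spec.grid.n_bins
    L = np.zeros((k, n, 2 * k))
    for i in range(k):
        L[i, 0, 2 * i] = 1.0
    for t in range(1, n):
        prev = L[:, t - 1, :]
        for i in range(k):
            row = prev[i] + params.beta[i] * prev[i]
            row = row.copy()
            row[2 * i + 1] += ALPHA
            for j in range(k):
                if j != i and params.gamma[i, j] != 0.0:
                    row = row + params.gamma[i, j] * prev[j]
            L[i, t] = row
    return L


def stacked_loadings(spec: DCSMSpec, params: DCSMParams) -> np.ndarray:
    """Per-twin loading matrix, shape (n_traits * n_bins, n_factors)."""
    L = build_latent_loadings(spec, params)
    k, n, nf = L.shape
    return L.reshape(k * n, nf)


def implied_moments(
    spec: DCSMSpec,
    params: DCSMParams,
    sexes: tuple[int, int] = (0, 0),
    validate: bool = True,
) -> ImpliedMoments:
    """Model-implied mean and covariance of the stacked pair vector.

    Within-twin covariance is ``L (sigma_ind + sigma_pair) L' + R``;
    cross-twin covariance is ``L sigma_pair L'`` (the pair-level factors
    are shared).  Residuals R are diagonal per trait with the optional
    within-person within-bin cross-trait covariance; residuals never
    correlate across twins or across bins.
    """
    if validate:
        validate_params(spec, params)
    k, n = spec.n_traits, spec.grid.n_bins
    layout = PairLayout(k, n)
    Lf = stacked_loadings(spec, params)  # (m, 2k)
    m = layout.per_twin

    S_ind = _psd_guard(params.sigma_ind, "sigma_ind") if validate else params.sigma_ind
    S_pair = _psd_guard(params.sigma_pair, "sigma_pair") if validate else params.sigma_pair
    shared = Lf @ S_pair @ Lf.T
    within = Lf @ S_ind @ Lf.T + shared

    R = np.zeros((m, m))
    for i in range(k):
        sl = slice(i * n, (i + 1) * n)
        R[sl, sl] += np.eye(n) * params.resid_var[i]
    if k == 2 and params.resid_cov != 0.0:
        cross = np.eye(n) * params.resid_cov
        R[0:n, n:2 * n] += cross
        R[n:2 * n, 0:n] += cross

    cov = np.empty((2 * m, 2 * m))
    cov[:m, :m] = within + R
    cov[m:, m:] = within + R
    cov[:m, m:] = shared
    cov[m:, :m] = shared.T

    mean = np.empty(2 * m)
    for twin, sex in enumerate(sexes):
        mean[twin * m:(twin + 1) * m] = Lf @ params.factor_mean(int(sex))
    return ImpliedMoments(mean=mean, covariance=cov, layout=layout)


# ---------------------------------------------------------------------------
# FIML evaluation


@dataclass
class BoundData:
    """A PairDataset pre-indexed against a spec's pair layout.

    Pairs are grouped by the *size* of their observed sub-vector so the
    per-pattern sub-moments can be gathered and factorized in batches;
    the moments themselves depend on the parameter vector and are
    recomputed per evaluation (sex enters the mean only, so one
    covariance serves every pair).
    """

    spec: DCSMSpec
    layout: PairLayout
    groups: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # (idx (K,d), y (K,d), sexcombo (K,))
    pair_ids: list[list[str]]  # per group, for error messages
    n_obs_values: int
    n_units: int  # pairs with >= 1 observed value


def bind_data(spec: DCSMSpec, data: PairDataset) -> BoundData:
    for trait in spec.traits:
        if trait not in data.trait_labels:
            raise ValueError(f"trait {trait!r} not present in dataset {data.trait_labels}")
    if data.grid != spec.grid:
        raise ValueError("dataset grid does not match spec grid")
    k, n = spec.n_traits, spec.grid.n_bins
    layout = PairLayout(k, n)

    by_dim: dict[int, list[tuple[np.ndarray, np.ndarray, int, str]]] = {}
    n_vals = 0
    n_units = 0
    for a, b in data.pairs:
        idx, vals = [], []
        for twin, person in enumerate((a, b)):
            for t, obs in person.observations.items():
                for trait_pos, trait in enumerate(spec.traits):
                    if trait in obs.values:
                        idx.append(layout.index(twin, trait_pos, t))
                        vals.append(obs.values[trait])
        if not idx:
            continue  # no observed values: contributes 0 to the log-likelihood
        order = np.argsort(idx)
        idx_arr = np.asarray(idx, dtype=np.intp)[order]
        val_arr = np.asarray(vals, dtype=float)[order]
        sexcombo = 2 * int(a.sex) + int(b.sex)
        by_dim.setdefault(len(idx_arr), []).append((idx_arr, val_arr, sexcombo, a.pair_id))
        n_vals += len(idx_arr)
        n_units += 1

    groups, pair_ids = [], []
    for d in sorted(by_dim):
        entries = by_dim[d]
        I = np.stack([e[0] for e in entries])
        Y = np.stack([e[1] for e in entries])
        S = np.asarray([e[2] for e in entries], dtype=np.intp)
        groups.append((I, Y, S))
        pair_ids.append([e[3] for e in entries])
    return BoundData(spec=spec, layout=layout, groups=groups, pair_ids=pair_ids,
                     n_obs_values=n_vals, n_units=n_units)


_LOG_2PI = float(np.log(2.0 * np.pi))


def loglik_bound(params: DCSMParams, bound: BoundData, validate: bool = False) -> float:
    """FIML log-likelihood for pre-bound data.

    The hot path of estimation: validation is off by default because the
    optimizer's square-root parameterization guarantees PSD inputs.
    """
    spec = bound.spec
    mom = implied_moments(spec, params, sexes=(0, 0), validate=validate)
    cov = mom.covariance
    m = bound.layout.per_twin
    Lf = stacked_loadings(spec, params)
    mean_by_sex = np.stack([Lf @ params.factor_mean(s) for s in (0, 1)])  # (2, m)
    # full pair mean for each of the 4 (sexA, sexB) combinations
    M = np.empty((4, 2 * m))
    for c in range(4):
        M[c, :m] = mean_by_sex[c >> 1]
        M[c, m:] = mean_by_sex[c & 1]

    total = 0.0
    for gi, (I, Y, S) in enumerate(bound.groups):
        K, d = I.shape
        sub = cov[I[:, :, None], I[:, None, :]]  # (K, d, d)
        try:
            C = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            for j in range(K):
                try:
                    np.linalg.cholesky(sub[j])
                except np.linalg.LinAlgError:
                    raise np.linalg.LinAlgError(
                        f"singular implied covariance for pair {bound.pair_ids[gi][j]!r} "
                        f"(observed pattern of size {d})"
                    ) from None
            raise
        resid = Y - M[S[:, None], I]  # (K, d)
        z = np.linalg.solve(C, resid[:, :, None])[:, :, 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(C, axis1=1, axis2=2)), axis=1)
        total += float(np.sum(-0.5 * (d * _LOG_2PI + logdet + np.sum(z * z, axis=1))))
    return total


def fiml_loglik(spec: DCSMSpec, params: DCSMParams, data: PairDataset) -> float:
    """FIML log-likelihood of a pair dataset under the model (validated)."""
    validate_params(spec, params)
    return loglik_bound(params, bind_data(spec, data), validate=True)


# ---------------------------------------------------------------------------
# analytic gradient


@dataclass
class ParamGrads:
    """Gradient of the log-likelihood with respect to DCSMParams entries.

    Covariance gradients treat every matrix entry as independent (the
    accumulated matrices are symmetric); downstream square-root chain
    rules rely on that convention.
    """

    mu_intercept: np.ndarray
    mu_slope: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    sex_intercept: np.ndarray
    sex_slope: np.ndarray
    sigma_ind: np.ndarray
    sigma_pair: np.ndarray
    resid_var: np.ndarray
    resid_cov: float


def _loading_derivative(L3: np.ndarray, params: DCSMParams,
                        inject_trait: int, inject_from: int) -> np.ndarray:
    """d(loadings)/d(theta) for a dynamic coefficient by forward recursion.

    ``theta`` multiplies the previous latent level of trait
    ``inject_from`` in the change equation of trait ``inject_trait``
    (theta = beta when the two coincide, gamma otherwise).
    """
    k, n, nf = L3.shape
    D = np.zeros_like(L3)
    for t in range(1, n):
        prev = D[:, t - 1, :]
        for l in range(k):
            row = (1.0 + params.beta[l]) * prev[l]
            for j in range(k):
                if j != l and params.gamma[l, j] != 0.0:
                    row = row + params.gamma[l, j] * prev[j]
            if l == inject_trait:
                row = row + L3[inject_from, t - 1]
            D[l, t] = row
    return D


def loglik_and_grad(params: DCSMParams, bound: BoundData) -> tuple[float, ParamGrads]:
    """FIML log-likelihood and its exact gradient for pre-bound data.

    Standard multivariate-normal calculus: per observed pattern with
    residual r and sub-covariance S, the contributions are S^{-1} r to
    the mean gradient and (S^{-1} r r' S^{-1} - S^{-1})/2 to the
    covariance gradient, scattered back into the full pair layout and
    chained through the loading recursion to the structural parameters.
    """
    spec = bound.spec
    k, n = spec.n_traits, spec.grid.n_bins
    nf = spec.n_factors
    m = k * n
    M2 = 2 * m

    L3 = build_latent_loadings(spec, params)
    Lf = L3.reshape(m, nf)
    Si, Sp = params.sigma_ind, params.sigma_pair
    Wi = Lf @ Si @ Lf.T
    Wp = Lf @ Sp @ Lf.T

    R = np.zeros((m, m))
    for i in range(k):
        sl = slice(i * n, (i + 1) * n)
        R[sl, sl] += np.eye(n) * params.resid_var[i]
    if k == 2 and params.resid_cov != 0.0:
        cross = np.eye(n) * params.resid_cov
        R[0:n, n:2 * n] += cross
        R[n:2 * n, 0:n] += cross

    V = Wi + Wp + R
    cov = np.empty((M2, M2))
    cov[:m, :m] = V
    cov[m:, m:] = V
    cov[:m, m:] = Wp
    cov[m:, :m] = Wp

    f_sex = [params.factor_mean(0), params.factor_mean(1)]
    mu_sex = [Lf @ f for f in f_sex]
    M = np.empty((4, M2))
    for c in range(4):
        M[c, :m] = mu_sex[c >> 1]
        M[c, m:] = mu_sex[c & 1]

    ll = 0.0
    G_flat = np.zeros(M2 * M2)
    gm_flat = np.zeros(4 * M2)
    for gi, (I, Y, S) in enumerate(bound.groups):
        K, d = I.shape
        sub = cov[I[:, :, None], I[:, None, :]]
        try:
            C = np.linalg.cholesky(sub)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular implied covariance in a pattern group of size {d} "
                f"(pairs {bound.pair_ids[gi][:3]}...)"
            ) from None
        Ainv = np.linalg.inv(sub)
        r = Y - M[S[:, None], I]
        u = (Ainv @ r[:, :, None])[:, :, 0]
        logdet = 2.0 * np.sum(np.log(np.diagonal(C, axis1=1, axis2=2)), axis=1)
        ll += float(np.sum(-0.5 * (d * _LOG_2PI + logdet + np.sum(r * u, axis=1))))
        dS = 0.5 * (u[:, :, None] * u[:, None, :] - Ainv)
        rows = (I[:, :, None] * M2 + I[:, None, :]).ravel()
        G_flat += np.bincount(rows, weights=dS.ravel(), minlength=M2 * M2)
        gm_flat += np.bincount((S[:, None] * M2 + I).ravel(), weights=u.ravel(),
                               minlength=4 * M2)
    G = G_flat.reshape(M2, M2)
    gm = gm_flat.reshape(4, 2, m)

    GV = G[:m, :m] + G[m:, m:]
    GP = GV + G[:m, m:] + G[m:, :m]

    g_sigma_ind = Lf.T @ GV @ Lf
    g_sigma_pair = Lf.T @ GP @ Lf
    g_resid_var = np.array([
        np.trace(GV[i * n:(i + 1) * n, i * n:(i + 1) * n]) for i in range(k)
    ])
    g_resid_cov = 2.0 * float(np.trace(GV[0:n, n:2 * n])) if k == 2 else 0.0

    # mean path: h[sex] = d ll / d (per-twin mean of a person of that sex)
    h = np.zeros((2, m))
    for c in range(4):
        h[c >> 1] += gm[c, 0]
        h[c & 1] += gm[c, 1]
    g_f = [Lf.T @ h[0], Lf.T @ h[1]]
    g_m0 = g_f[0] + g_f[1]
    g_ms = g_f[1]

    # loading path (covariance + mean contributions), then dynamic coefficients
    gLf = 2.0 * (GV @ Lf @ Si) + 2.0 * (GP @ Lf @ Sp)
    gLf += np.outer(h[0], f_sex[0]) + np.outer(h[1], f_sex[1])
    gL3 = gLf.reshape(k, n, nf)

    g_beta = np.zeros(k)
    g_gamma = np.zeros((k, k))
    for i in range(k):
        D = _loading_derivative(L3, params, i, i)
        g_beta[i] = float(np.sum(gL3 * D))
        for j in range(k):
            if j != i:
                D = _loading_derivative(L3, params, i, j)
                g_gamma[i, j] = float(np.sum(gL3 * D))

    grads = ParamGrads(
        mu_intercept=g_m0[0::2], mu_slope=g_m0[1::2],
        beta=g_beta, gamma=g_gamma,
        sex_intercept=g_ms[0::2], sex_slope=g_ms[1::2],
        sigma_ind=g_sigma_ind, sigma_pair=g_sigma_pair,
        resid_var=g_resid_var, resid_cov=g_resid_cov,
    )
    return ll, grads
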