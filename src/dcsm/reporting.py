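"""Descriptive and graphical outputs: trajectories, vector fields,
baseline correlations.

Figures are backed by tidy data frames (curve points, arrow lattices)
so results can be tested and regenerated without image comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import PairDataset
from .dcsm_core import stacked_loadings
from .estimation import FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "trajectory_curve",
    "VectorField",
    "vector_field",
    "baseline_correlations",
    "plot_trajectory",
    "plot_vector_field",
]


def trajectory_curve(fit: FitResult, sex_mix: float = 0.0) -> pd.DataFrame:
    """Population-average model-implied latent mean per age bin.

    ``sex_mix`` is the proportion of women; the sex-specific mean curves
    (the mean component of the implied moments) are averaged with
    weights (1 - p, p).  Ages are the bin lower edges, so the first
    value is the mean intercept at the grid's start age.
    """
    if not fit.converged:
        raise ValueError("trajectory_curve requires a converged fit")
    if not 0.0 <= sex_mix <= 1.0:
        raise ValueError("sex_mix must be a proportion in [0, 1]")
    spec, params = fit.spec, fit.estimates
    Lf = stacked_loadings(spec, params)
    mean = (1.0 - sex_mix) * (Lf @ params.factor_mean(0)) + sex_mix * (Lf @ params.factor_mean(1))
    k, n = spec.n_traits, spec.grid.n_bins
    curves = mean.reshape(k, n)
    ages = spec.grid.ages()
    rows = []
    for i, trait in enumerate(spec.traits):
        for t in range(n):
            rows.append({"trait": trait, "bin": t, "age": ages[t], "value": curves[i, t]})
    return pd.DataFrame(rows)


@dataclass
class Ellipse:
    center: np.ndarray  # (clock, fi)
    semi_axes: np.ndarray  # lengths of the 95% ellipse semi-axes
    angle_deg: float  # orientation of the major axis
    covariance: np.ndarray

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points (n, 2) inside the ellipse (Mahalanobis test)."""
        d = points - self.center
        inv = np.linalg.inv(self.covariance)
        r2 = stats.chi2.ppf(0.95, df=2)
        return np.einsum("ni,ij,nj->n", d, inv, d) <= r2


@dataclass
class VectorField:
    """Expected one-age-step changes of the coupled system on a lattice.

    ``points`` columns: clock, fi (lattice coordinates on the display
    scale), d_clock, d_fi (expected changes per age step, display
    scale).  Arrows are exact evaluations of the fitted change
    equations, not numerical differences of trajectories.
    """

    points: pd.DataFrame
    ellipse: Ellipse | None
    clock_scale: float  # display-to-model multiplier applied internally


def vector_field(
    fit: FitResult,
    clock_grid: np.ndarray | None = None,
    fi_grid: np.ndarray | None = None,
    data: PairDataset | None = None,
    clock_scale: float | None = None,
) -> VectorField:
    """Arrow lattice of the fitted bivariate change equations.

    At display coordinates (c, f) the expected changes are

        d_fi    = mu_fi_slope    + beta_fi * f + gamma_clock_to_fi * (s * c)
        d_clock = (mu_clock_slope + beta_clock * (s * c) + gamma_fi_to_clock * f) / s

    where s is ``clock_scale`` (10 when the pace trait was modeled on
    the x10 scale but displayed in original units; inferred from
    ``data.pace_rescaled`` when not given).  Mean slopes are taken at
    the men reference level.  The 95% ellipse summarizes observed
    baseline (clock, fi) points when ``data`` is supplied.
    """
    if fit.spec.n_traits != 2:
        raise ValueError("vector_field requires a bivariate fit")
    if not fit.converged:
        raise ValueError("vector_field requires a converged fit")
    if clock_scale is None:
        clock_scale = 10.0 if (data is not None and data.pace_rescaled) else 1.0
    if clock_grid is None:
        clock_grid = np.arange(0.7, 1.4001, 0.05)
    if fi_grid is None:
        fi_grid = np.arange(0.0, 45.001, 2.5)

    p = fit.estimates
    C, F = np.meshgrid(np.asarray(clock_grid, float), np.asarray(fi_grid, float))
    c_model = clock_scale * C
    d_fi = p.mu_slope[0] + p.beta[0] * F + p.gamma[0, 1] * c_model
    d_clock_model = p.mu_slope[1] + p.beta[1] * c_model + p.gamma[1, 0] * F
    d_clock = d_clock_model / clock_scale
    points = pd.DataFrame({
        "clock": C.ravel(), "fi": F.ravel(),
        "d_clock": d_clock.ravel(), "d_fi": d_fi.ravel(),
    })

    ellipse = None
    if data is not None:
        base = _baseline_table(data, fit.spec.traits)
        xy = base[["clock_display", "fi"]].dropna().to_numpy()
        if len(xy) >= 3:
            center = xy.mean(axis=0)
            cov = np.cov(xy, rowvar=False)
            w, V = np.linalg.eigh(cov)
            r2 = stats.chi2.ppf(0.95, df=2)
            order = np.argsort(w)[::-1]
            w, V = w[order], V[:, order]
            angle = float(np.degrees(np.arctan2(V[1, 0], V[0, 0])))
            ellipse = Ellipse(center=center, semi_axes=np.sqrt(np.clip(w, 0, None) * r2),
                              angle_deg=angle, covariance=cov)
        else:
            logger.warning("not enough baseline points for the 95%% ellipse")
    return VectorField(points=points, ellipse=ellipse, clock_scale=float(clock_scale))


def _baseline_table(data: PairDataset, traits: tuple[str, ...]) -> pd.DataFrame:
    """Each person's first observed wave: age and trait values.

    The clock is also given on the display (original) scale, undoing the
    x10 pace rescaling when the dataset carries it.
    """
    scale = 10.0 if data.pace_rescaled else 1.0
    rows = []
    for person in data.persons():
        first = person.first_observation()
        if first is None:
            continue
        t, obs = first
        row = {"person_id": person.person_id, "age": obs.age}
        for trait in traits:
            row[trait] = obs.values.get(trait, np.nan)
        if len(traits) == 2:
            row["clock_display"] = row[traits[1]] / scale
        rows.append(row)
    return pd.DataFrame(rows)


def baseline_correlations(data: PairDataset,
                          traits: tuple[str, str] | None = None) -> dict:
    """Pearson correlation between the two traits at each person's first
    observed wave, raw and adjusted for exact chronological age.

    The age adjustment residualizes both traits on a linear age term and
    correlates the residuals (a partial correlation).  Cases missing
    either trait at baseline are dropped (pairwise-complete).
    """
    if traits is None:
        if len(data.trait_labels) != 2:
            raise ValueError("specify the two traits to correlate")
        traits = tuple(data.trait_labels)  # type: ignore[assignment]
    base = _baseline_table(data, traits)
    cols = [traits[0], traits[1], "age"]
    if base.empty:
        raise ValueError("no baseline observations")
    complete = base.dropna(subset=cols)
    n = len(complete)
    if n < 3:
        raise ValueError(f"only {n} complete baseline case(s); correlation undefined")
    x = complete[traits[0]].to_numpy()
    y = complete[traits[1]].to_numpy()
    age = complete["age"].to_numpy()
    r = float(stats.pearsonr(x, y).statistic)
    A = np.column_stack([np.ones(n), age])
    rx = x - A @ np.linalg.lstsq(A, x, rcond=None)[0]
    ry = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
    r_partial = float(stats.pearsonr(rx, ry).statistic)
    return {"r": r, "r_age_adjusted": r_partial, "n": n}


# --------------------------------------------------------------------------
# matplotlib wrappers (thin; the dataframes above are the tested surface)


def plot_trajectory(curve: pd.DataFrame, ax=None):
    """Line plot of a trajectory_curve frame (one line per trait)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for trait, g in curve.groupby("trait"):
        ax.plot(g["age"], g["value"], label=trait, lw=2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("model-implied mean")
    ax.legend()
    return ax


def plot_vector_field(vf: VectorField, ax=None, scale: float | None = None):
    """Quiver plot of a VectorField, with the 95% ellipse if available."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse as MplEllipse

    if ax is None:
        _, ax = plt.subplots()
    pts = vf.points
    ax.quiver(pts["clock"], pts["fi"], pts["d_clock"], pts["d_fi"],
              angles="xy", scale=scale)
    if vf.ellipse is not None:
        e = vf.ellipse
        ax.add_patch(MplEllipse(xy=e.center, width=2 * e.semi_axes[0],
                                height=2 * e.semi_axes[1], angle=e.angle_deg,
                                fill=False, ls="--"))
    ax.set_xlabel("clock")
    ax.set_ylabel("frailty index (%)")
    return ax
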