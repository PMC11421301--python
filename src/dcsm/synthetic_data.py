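"""Synthetic twin-cohort generator matching the model's assumptions.

The generator has two halves.  ``sample_design`` emulates the
observation process of a longitudinal twin study of aging (the SATSA
design): same-sex twin pairs and singletons, about 59% women, one to six
visits per person at roughly 3-6 year spacing, entry between ages 50 and
84, visits from age 90 on dropped at binning.  ``simulate_dataset`` then
runs the dual change score model generatively: pair-level growth factors
shared by co-twins, individual-level factors, latent trajectories by the
forward recursion, and occasion residuals, keeping only the scheduled
visits.

The default design constants are study-level facts of the emulated
cohort (sample size 524, visit-count distribution, share of women);
quantities the cohort description does not pin down (entry-age law,
singleton share) are simple choices documented in the methods note.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import AgeGrid, BinObservation, PairDataset, PersonTrajectory
from .dcsm_core import (
    DCSMParams,
    DCSMSpec,
    implied_moments,
    stacked_loadings,
    validate_params,
)
from .estimation import FitResult, ParamTransform, bivariate_selection, fit_dcsm

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "PersonSchedule",
    "sample_design",
    "simulate_dataset",
    "simulate_complete_pairs",
    "recovery_experiment",
    "RecoveryReport",
]

# visit-count distribution of the emulated cohort: 157/123/113/89/41/1 of 524
_WAVE_COUNTS = (157, 123, 113, 89, 41, 1)


@dataclass(frozen=True)
class StudyDesign:
    """Observation-process parameters for the simulated cohort."""

    n_individuals: int = 524
    pair_fraction: float = 0.6  # share of individuals whose co-twin participates
    sex_ratio: float = 0.586  # probability a pair/singleton is female
    wave_count_distribution: tuple[float, ...] = tuple(c / sum(_WAVE_COUNTS) for c in _WAVE_COUNTS)
    wave_spacing: tuple[float, float] = (3.0, 6.0)  # uniform gap between visits, years
    entry_age_range: tuple[float, float] = (50.0, 84.0)  # uniform age at first visit
    zygosity_probs: tuple[float, float, float] = (0.345, 0.653, 0.002)  # MZ, DZ, unknown
    seed: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wave_count_distribution, dtype=float)
        if w.min() < 0 or not np.isclose(w.sum(), 1.0):
            raise ValueError("wave_count_distribution must be a probability vector")
        if not 0.0 <= self.pair_fraction <= 1.0:
            raise ValueError("pair_fraction must be in [0, 1]")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        if self.wave_spacing[0] > self.wave_spacing[1] or self.wave_spacing[0] <= 0:
            raise ValueError("wave_spacing must be an increasing positive range")
        if self.entry_age_range[0] > self.entry_age_range[1]:
            raise ValueError("entry_age_range must be increasing")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d) -> "StudyDesign":
        d = dict(d)
        for key in ("wave_count_distribution", "wave_spacing", "entry_age_range", "zygosity_probs"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PersonSchedule:
    person_id: str
    pair_id: str
    sex: int
    zygosity: str
    ages: tuple[float, ...]  # raw visit ages; binning later drops out-of-grid visits


def sample_design(design: StudyDesign, seed: int | None = None) -> list[PersonSchedule]:
    """Draw a deterministic (given seed) observation schedule.

    Returns one entry per person with visit ages, sex, and pair
    membership.  Twins are same-sex; zygosity is metadata only.
    Scheduled ages may run past the grid's upper edge — such visits are
    dropped when the data are binned, mirroring a real pipeline that
    excludes sparse very-old ages.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.n_individuals
    n_paired = int(round(n * design.pair_fraction))
    n_paired -= n_paired % 2

    schedules: list[PersonSchedule] = []
    zyg_labels = ("MZ", "DZ", "unknown")

    def draw_ages() -> tuple[float, ...]:
        n_waves = 1 + rng.choice(len(design.wave_count_distribution),
                                 p=design.wave_count_distribution)
        entry = rng.uniform(*design.entry_age_range)
        gaps = rng.uniform(design.wave_spacing[0], design.wave_spacing[1], size=n_waves - 1)
        return tuple(entry + np.concatenate([[0.0], np.cumsum(gaps)]))

    pid = 0
    for pair_no in range(n_paired // 2):
        sex = int(rng.random() < design.sex_ratio)
        zyg = zyg_labels[rng.choice(3, p=design.zygosity_probs)]
        for _ in range(2):
            schedules.append(PersonSchedule(
                person_id=f"P{pid:04d}", pair_id=f"T{pair_no:04d}",
                sex=sex, zygosity=zyg, ages=draw_ages(),
            ))
            pid += 1
    for single_no in range(n - n_paired):
        sex = int(rng.random() < design.sex_ratio)
        zyg = zyg_labels[rng.choice(3, p=design.zygosity_probs)]
        schedules.append(PersonSchedule(
            person_id=f"P{pid:04d}", pair_id=f"S{single_no:04d}",
            sex=sex, zygosity=zyg, ages=draw_ages(),
        ))
        pid += 1
    return schedules


def _psd_factor(S: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix (eigen-based; tolerates singularity)."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_dataset(
    spec: DCSMSpec,
    params: DCSMParams,
    design: StudyDesign,
    seed: int | None = None,
    clip_fi: bool = False,
    pace_rescaled: bool = False,
) -> PairDataset:
    """Simulate a pair dataset from the generative model.

    Pair factors ~ N(0, sigma_pair) shared by co-twins, individual
    factors ~ N(0, sigma_ind), sex effects added to the factor means,
    latent trajectories from the forward recursion, occasion residuals
    with the within-bin cross-trait covariance, observed only at the
    scheduled visits (first visit wins when two fall in one bin).

    Trait values are continuous and unbounded, as the Gaussian model
    assumes; ``clip_fi`` clips the first trait to [0, 100] as a
    stress-test of that assumption (off by default).
    """
    validate_params(spec, params)
    rng = np.random.default_rng(design.seed if seed is None else seed)
    schedules = sample_design(design, seed=rng.integers(2**31))

    Lf = stacked_loadings(spec, params)  # (k*n_bins, nf)
    k, n_bins = spec.n_traits, spec.grid.n_bins
    F_pair = _psd_factor(params.sigma_pair)
    F_ind = _psd_factor(params.sigma_ind)
    F_res = _psd_factor(params.residual_block())

    by_pair: dict[str, list[PersonSchedule]] = {}
    for s in schedules:
        by_pair.setdefault(s.pair_id, []).append(s)

    pairs: list[tuple[PersonTrajectory, PersonTrajectory]] = []
    for pair_id in sorted(by_pair):
        members = by_pair[pair_id]
        g = F_pair @ rng.standard_normal(spec.n_factors)
        twins: list[PersonTrajectory] = []
        for sched in members:
            f = F_ind @ rng.standard_normal(spec.n_factors)
            factors = params.factor_mean(sched.sex) + g + f
            latent = (Lf @ factors).reshape(k, n_bins)
            traj = PersonTrajectory(person_id=sched.person_id, pair_id=sched.pair_id,
                                    sex=sched.sex, zygosity=sched.zygosity)
            for age in sched.ages:
                t = spec.grid.assign(age)
                if t is None or t in traj.observations:
                    continue
                obs = latent[:, t] + F_res @ rng.standard_normal(k)
                if clip_fi:
                    obs[0] = np.clip(obs[0], 0.0, 100.0)
                traj.observations[t] = BinObservation(
                    age=age, values={trait: float(obs[i]) for i, trait in enumerate(spec.traits)},
                )
            twins.append(traj)
        if len(twins) == 1:  # singleton: placeholder co-twin, no observations
            ghost = PersonTrajectory(person_id=f"{twins[0].person_id}::cotwin_missing",
                                     pair_id=pair_id, sex=twins[0].sex,
                                     zygosity=twins[0].zygosity)
            twins.append(ghost)
        pairs.append((twins[0], twins[1]))

    return PairDataset(grid=spec.grid, pairs=pairs, trait_labels=spec.traits,
                       pace_rescaled=pace_rescaled)


def simulate_complete_pairs(
    spec: DCSMSpec,
    params: DCSMParams,
    n_pairs: int,
    sexes: tuple[int, int] = (0, 0),
    seed: int | None = None,
) -> np.ndarray:
    """Simulate fully observed pair vectors (n_pairs, 2 * traits * bins).

    Bypasses the visit schedule; used for Monte-Carlo checks of the
    model-implied moments and for toy complete-data likelihood tests.
    """
    validate_params(spec, params)
    rng = np.random.default_rng(seed)
    mom = implied_moments(spec, params, sexes=sexes)
    F = _psd_factor(mom.covariance)
    Z = rng.standard_normal((n_pairs, F.shape[1]))
    return mom.mean + Z @ F.T


@dataclass
class RecoveryReport:
    """Simulate-and-refit summary over replicates."""

    truth: DCSMParams
    spec: DCSMSpec
    table: pd.DataFrame  # per-parameter: truth, mean_est, bias, sd, mc_se, mean_se, coverage
    n_reps: int
    n_converged: int
    fits: list[FitResult]
    selection_counts: dict[str, int] | None = None

    def summary_row(self, name: str) -> pd.Series:
        return self.table.set_index("parameter").loc[name]


def recovery_experiment(
    spec: DCSMSpec,
    params: DCSMParams,
    design: StudyDesign,
    n_reps: int = 10,
    seed: int | None = None,
    start_at_truth: bool = True,
    standard_errors: bool = True,
    selection: bool = False,
    **fit_kw,
) -> RecoveryReport:
    """Repeatedly simulate from (spec, params, design) and refit.

    Reports, per free parameter: mean estimate, bias, empirical SD
    across replicates, Monte-Carlo SE of the mean, mean reported SE, and
    coverage of nominal 95% Wald intervals.  Replicates that fail to
    converge are counted and excluded from the summaries.  As is usual
    in simulation studies the optimizer starts at the generating values
    (``start_at_truth``); set it False to exercise the data-driven
    starts.  With ``selection`` a coupling-structure selection is run
    per replicate and the selected structures tallied.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    transform = ParamTransform(spec)
    truth_vec = transform.natural_vector(params)
    names = transform.natural_names()

    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(2**31, size=2 * n_reps)

    fits: list[FitResult] = []
    estimates, ses = [], []
    sel_counts: dict[str, int] = {}
    n_conv = 0
    for r in range(n_reps):
        data = simulate_dataset(spec, params, design, seed=int(rep_seeds[2 * r]))
        fit = fit_dcsm(spec, data,
                       start=params if start_at_truth else None,
                       compute_se=standard_errors, **fit_kw)
        fits.append(fit)
        if fit.converged:
            n_conv += 1
            estimates.append(fit.natural_estimates)
            ses.append(fit.standard_errors if fit.standard_errors is not None
                       else np.full(len(names), np.nan))
        else:
            logger.warning("replicate %d did not converge; excluded from summaries", r)
        if selection and spec.n_traits == 2:
            rep = bivariate_selection(data, traits=spec.traits,
                                      proportional=spec.proportional,
                                      pair_level=spec.pair_level,
                                      compute_se=False, **fit_kw)
            sel_counts[rep.selected] = sel_counts.get(rep.selected, 0) + 1

    if n_conv == 0:
        raise RuntimeError("no replicate converged; recovery summary unavailable")
    E = np.stack(estimates)
    S = np.stack(ses)
    mean_est = E.mean(axis=0)
    sd = E.std(axis=0, ddof=1) if n_conv > 1 else np.zeros(len(names))
    mc_se = sd / np.sqrt(n_conv)
    with np.errstate(invalid="ignore"):
        lo = E - 1.959963984540054 * S
        hi = E + 1.959963984540054 * S
        covered = (lo <= truth_vec) & (truth_vec <= hi)
        coverage = np.where(np.all(np.isnan(S), axis=0), np.nan,
                            np.nanmean(covered, axis=0))
    table = pd.DataFrame({
        "parameter": names,
        "truth": truth_vec,
        "mean_estimate": mean_est,
        "bias": mean_est - truth_vec,
        "empirical_sd": sd,
        "mc_se": mc_se,
        "mean_se": (np.nanmean(S, axis=0) if not np.all(np.isnan(S))
                    else np.full(len(names), np.nan)),
        "coverage95": coverage,
    })
    return RecoveryReport(truth=params, spec=spec, table=table, n_reps=n_reps,
                          n_converged=n_conv, fits=fits,
                          selection_counts=sel_counts if selection else None)
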