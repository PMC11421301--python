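"""Reference parameter sets and study design for FI-clock dynamics.

These are the package's bundled generating values for simulation and
recovery experiments: best-fitting bivariate dual change score estimates
for the 42-item frailty index (percent scale) paired with each of five
DNA-methylation clocks, from a Swedish twin cohort of 524 adults
followed between ages 50 and 90.  The pace-of-aging clock
(``dunedin_pace``) is on a x10 scale (raw pace ~1.0 becomes ~10), which
keeps its variance components on a magnitude comparable to the other
parameters.

Factor order everywhere: (fi intercept, fi slope, clock intercept,
clock slope).  Published estimates are rounded to two decimals; at that
precision a few covariance blocks are slightly indefinite (e.g. a slope
variance printed as 0.00 next to nonzero covariances), so each block is
projected to the nearest positive semi-definite matrix by clipping
negative eigenvalues at zero before use.
"""

from __future__ import annotations

import numpy as np

from .data_model import AgeGrid
from .dcsm_core import DCSMParams, DCSMSpec
from .synthetic_data import StudyDesign

__all__ = ["CLOCKS", "reference_model", "satsa_like_design", "nearest_psd"]

CLOCKS = ("pc_horvath", "pc_hannum", "pc_pheno", "pc_grim", "dunedin_pace")


def nearest_psd(S: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the PSD cone (eigenvalue clipping)."""
    S = 0.5 * (S + np.asarray(S).T)
    w, V = np.linalg.eigh(S)
    if w.min(initial=0.0) >= 0:
        return S
    return (V * np.clip(w, 0.0, None)) @ V.T


def _sym(i_var, s_var, is_cov, ci_var=None, cs_var=None, c_is_cov=None,
         fi_i_c_i=None, fi_s_c_i=None, fi_i_c_s=None, fi_s_c_s=None) -> np.ndarray:
    """Assemble the 2x2 or 4x4 factor covariance from its unique entries
    (None entries are structurally absent, i.e. zero)."""
    z = lambda v: 0.0 if v is None else float(v)
    if ci_var is None and cs_var is None and fi_i_c_i is None:
        return np.array([[z(i_var), z(is_cov)], [z(is_cov), z(s_var)]])
    return np.array([
        [z(i_var), z(is_cov), z(fi_i_c_i), z(fi_i_c_s)],
        [z(is_cov), z(s_var), z(fi_s_c_i), z(fi_s_c_s)],
        [z(fi_i_c_i), z(fi_s_c_i), z(ci_var), z(c_is_cov)],
        [z(fi_i_c_s), z(fi_s_c_s), z(c_is_cov), z(cs_var)],
    ])


# Each entry: the free parameters of the best-fitting bivariate model for
# (frailty index, clock).  `coupling` uses trait indices (fi=0, clock=1);
# `pair_factors` lists the factors carrying pair-level variance.
_REFERENCE = {
    "pc_horvath": dict(
        mu=(6.03, -0.73, 50.49, 1.12),
        beta=(0.15, None),
        gamma_clock_to_fi=None, gamma_fi_to_clock=None,
        sex=(2.39, -0.36, -2.43, 0.05),
        sigma_ind=_sym(19.95, 0.52, -3.15, 5.89, 0.06, -0.26,
                       6.27, -1.06, -0.47, 0.08),
        sigma_pair=_sym(6.71, 0.12, -0.91, 54.16, 0.00, -0.61,
                        -2.41, 0.65, 0.12, -0.03),
        pair_factors="full",
        resid=(15.52, 9.85, -0.05),
    ),
    "pc_hannum": dict(
        mu=(6.08, -0.77, 52.77, 1.25),
        beta=(0.16, None),
        gamma_clock_to_fi=None, gamma_fi_to_clock=None,
        sex=(2.40, -0.37, -2.07, 0.00),
        sigma_ind=_sym(20.40, 0.56, -3.31, 4.53, 0.02, 0.07,
                       6.89, -1.24, -0.47, 0.09),
        sigma_pair=_sym(6.63, 0.12, -0.92, 43.53, 0.03, -0.70,
                        -4.37, 1.04, 0.26, -0.06),
        pair_factors="full",
        resid=(15.48, 12.24, -0.01),
    ),
    "pc_pheno": dict(
        mu=(6.04, -0.73, 49.79, 0.37),
        beta=(0.15, 0.02),
        gamma_clock_to_fi=None, gamma_fi_to_clock=None,
        sex=(2.46, -0.37, -1.03, -0.04),
        sigma_ind=_sym(20.58, 0.54, -3.26, 9.67, 0.06, -0.35,
                       8.00, -1.32, -0.55, 0.10),
        sigma_pair=_sym(6.04, 0.10, -0.79, 18.13, 0.02, -0.58,
                        -0.50, 0.26, 0.03, -0.02),
        pair_factors="full",
        resid=(15.48, 6.21, 0.30),
    ),
    "pc_grim": dict(
        mu=(6.07, -0.77, 65.00, 0.58),
        beta=(0.16, 0.01),
        gamma_clock_to_fi=None, gamma_fi_to_clock=None,
        sex=(2.50, -0.39, -2.90, 0.03),
        sigma_ind=_sym(19.82, 0.54, -3.22, 4.45, 0.01, -0.20,
                       3.46, -0.60, -0.22, 0.04),
        sigma_pair=_sym(6.54, 0.12, -0.90, 5.29, 0.01, -0.15,
                        -0.61, 0.22, 0.02, -0.01),
        pair_factors="full",
        resid=(15.65, 1.60, 0.20),
    ),
    # pace-of-aging clock on the x10 scale; its pair-level slope factor is
    # dropped (reduced structure used when the full one will not converge)
    "dunedin_pace": dict(
        mu=(6.55, -12.31, 10.04, 0.06),
        beta=(0.06, None),
        gamma_clock_to_fi=1.19, gamma_fi_to_clock=None,
        sex=(0.60, 0.29, 0.01, -0.03),
        sigma_ind=_sym(9.94, 1.10, -2.24, 1.01, 0.004, -0.05,
                       1.94, -0.96, -0.13, 0.04),
        sigma_pair=_sym(2.66, 0.71, 0.29, 0.56, None, None,
                        -0.17, -0.64, None, None),
        pair_factors=((0, "intercept"), (0, "slope"), (1, "intercept")),
        resid=(14.52, 0.99, 0.03),
    ),
}
# note: the dunedin_pace individual-level clock slope variance is printed as
# 0.00 (significant, i.e. small but nonzero); 0.004 is used so the factor
# covariance admits the printed correlations after PSD projection.


def reference_model(clock: str = "dunedin_pace",
                    grid_kwargs: dict | None = None) -> tuple[DCSMSpec, DCSMParams]:
    """Spec and generating parameters for the FI paired with one clock.

    ``clock`` is one of ``CLOCKS``.  Trait labels are ``("fi", "clock")``
    with trait 0 the frailty index in percent.
    """
    if clock not in _REFERENCE:
        raise KeyError(f"unknown clock {clock!r}; choose from {CLOCKS}")
    ref = _REFERENCE[clock]
    grid = AgeGrid(**(grid_kwargs or {}))
    coupling = []
    if ref["gamma_clock_to_fi"] is not None:
        coupling.append((1, 0))
    if ref["gamma_fi_to_clock"] is not None:
        coupling.append((0, 1))
    spec = DCSMSpec(
        traits=("fi", "clock"),
        proportional=(ref["beta"][0] is not None, ref["beta"][1] is not None),
        coupling=tuple(coupling),
        pair_level=ref["pair_factors"],
        residual_cross_trait=True,
        grid=grid,
    )
    mu = ref["mu"]
    sex = ref["sex"]
    gamma = np.zeros((2, 2))
    if ref["gamma_clock_to_fi"] is not None:
        gamma[0, 1] = ref["gamma_clock_to_fi"]
    if ref["gamma_fi_to_clock"] is not None:
        gamma[1, 0] = ref["gamma_fi_to_clock"]
    sigma_pair = nearest_psd(ref["sigma_pair"])
    mask = np.zeros(4, dtype=bool)
    mask[list(spec.pair_factor_indices())] = True
    sigma_pair[~mask, :] = 0.0  # projection round-off outside the pair factors
    sigma_pair[:, ~mask] = 0.0
    params = DCSMParams(
        mu_intercept=np.array([mu[0], mu[2]]),
        mu_slope=np.array([mu[1], mu[3]]),
        beta=np.array([ref["beta"][0] or 0.0, ref["beta"][1] or 0.0]),
        gamma=gamma,
        sex_intercept=np.array([sex[0], sex[2]]),
        sex_slope=np.array([sex[1], sex[3]]),
        sigma_ind=nearest_psd(ref["sigma_ind"]),
        sigma_pair=sigma_pair,
        resid_var=np.array([ref["resid"][0], ref["resid"][1]]),
        resid_cov=ref["resid"][2],
    )
    return spec, params


def satsa_like_design(**overrides) -> StudyDesign:
    """The default simulated cohort: 524 individuals in same-sex twin
    pairs and singletons with the emulated visit process."""
    return StudyDesign(**overrides)
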