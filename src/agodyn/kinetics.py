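"""Equilibrium and kinetic models of AGO2-guide target engagement.

Three measurement designs are covered:

* **Equilibrium titration.**  Fraction of target bound F versus total
  enzyme concentration [E_T] at fixed total target [S_T], fit with the
  ligand-depletion (quadratic) isotherm

      F = B_max * ((E_T + S_T + K_D) - sqrt((E_T + S_T + K_D)^2
                                            - 4 E_T S_T)) / (2 S_T)

  which reduces to the hyperbola B_max*E_T/(E_T + K_D) as S_T -> 0.

* **Dissociation (chase).**  Fraction bound normalized to time zero versus
  time after adding excess unlabeled competitor, fit with a two-phase decay
  F(t) = A_f exp(-k_fast t) + (1 - A_f - plateau) exp(-k_slow t) + plateau.
  When the two rates are not separable (k_fast/k_slow below a threshold)
  the fit falls back to a single exponential and flags it.

* **Association.**  Fraction bound versus time after adding enzyme, fit per
  concentration with F(t) = F_max (1 - exp(-k_obs t)); the line
  k_obs = k_on [E] + intercept across concentrations gives the second-order
  k_on (the theoretical intercept is k_off).

Concentrations are in nM throughout; rates carry the time unit of the input.
K_D = k_off / k_on converts explicitly (nM^-1 -> M^-1 is a factor 1e9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "EquilibriumFit",
    "DecayFit",
    "AssociationFit",
    "LineFit",
    "equilibrium_model",
    "fit_equilibrium",
    "biexp_decay_model",
    "fit_dissociation",
    "association_model",
    "fit_association_single",
    "kon_from_kobs",
    "kd_from_rates",
]

#: Minimum k_fast/k_slow ratio at which two decay phases are reported.
PHASE_SEPARATION_THRESHOLD = 3.0


@dataclass
class EquilibriumFit:
    kd_nM: float
    bmax: float
    kd_se: float
    bmax_se: float
    rss: float
    converged: bool


@dataclass
class DecayFit:
    a_fast: float
    k_fast: float
    k_slow: float
    plateau: float
    rss: float
    converged: bool
    single_phase: bool = False
    #: set when the biphasic fit collapsed below the separation threshold
    fallback: bool = False


@dataclass
class AssociationFit:
    k_obs: float
    f_max: float
    rss: float
    converged: bool
    flat: bool = False


@dataclass
class LineFit:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    flat: bool = False


def equilibrium_model(e_total, s_total: float, kd: float, bmax: float):
    """Ligand-depletion binding isotherm (quadratic solution).

    ``e_total`` may be scalar or array (nM); ``s_total`` and ``kd`` are in
    nM.  The discriminant is clamped at zero against floating-point rounding.
    """
    if s_total <= 0:
        raise ValueError("total target concentration must be positive")
    if kd <= 0:
        raise ValueError("K_D must be positive")
    e = np.asarray(e_total, dtype=float)
    if np.any(e < 0):
        raise ValueError("enzyme concentrations must be non-negative")
    s = e + s_total + kd
    disc = np.maximum(s * s - 4.0 * e * s_total, 0.0)
    return bmax * (s - np.sqrt(disc)) / (2.0 * s_total)


def fit_equilibrium(
    e_total,
    f_obs,
    s_total: float,
    bmax_upper: float = 1.2,
) -> EquilibriumFit:
    """Fit K_D and B_max to a titration by bounded nonlinear least squares.

    Initialization: K_D at the enzyme concentration nearest half-maximal
    binding, B_max at the maximal observed F.  Degenerate inputs (flat
    response, fewer than 4 distinct concentrations) are reported via the
    ``converged`` flag rather than raised.
    """
    e = np.asarray(e_total, dtype=float)
    f = np.asarray(f_obs, dtype=float)
    if e.shape != f.shape:
        raise ValueError("e_total and f_obs must have matching shapes")
    if len(np.unique(e)) < 4:
        raise ValueError("need at least 4 distinct enzyme concentrations")

    fmax = float(np.max(f))
    if fmax <= 0 or np.ptp(f) < 1e-12:
        return EquilibriumFit(np.nan, np.nan, np.nan, np.nan, float(np.sum(f**2)), False)

    half = 0.5 * fmax
    kd0 = float(e[np.argmin(np.abs(f - half))])
    kd0 = max(kd0, 1e-6)
    p0 = [kd0, min(fmax, bmax_upper)]

    def resid(p):
        return equilibrium_model(e, s_total, p[0], p[1]) - f

    try:
        sol = optimize.least_squares(
            resid, p0, bounds=([1e-9, 1e-6], [np.inf, bmax_upper]), method="trf"
        )
    except Exception:
        return EquilibriumFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    kd, bmax = sol.x
    rss = float(2 * sol.cost)
    se = _se_from_jacobian(sol.jac, rss, len(e))
    return EquilibriumFit(float(kd), float(bmax), se[0], se[1], rss, bool(sol.success))


def _se_from_jacobian(jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    """Asymptotic standard errors from the least-squares Jacobian."""
    p = jac.shape[1]
    dof = max(n - p, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def biexp_decay_model(t, a_fast: float, k_fast: float, k_slow: float, plateau: float = 0.0):
    """Two-phase decay normalized to 1 at t = 0.

    F(t) = A_f exp(-k_fast t) + (1 - A_f - plateau) exp(-k_slow t) + plateau.
    """
    if k_fast <= 0 or k_slow <= 0:
        raise ValueError("rates must be positive")
    if not 0.0 <= a_fast <= 1.0:
        raise ValueError("fast-phase amplitude must be in [0, 1]")
    if plateau < 0 or a_fast + plateau > 1.0 + 1e-12:
        raise ValueError("amplitudes and plateau must sum to at most 1")
    t = np.asarray(t, dtype=float)
    a_slow = 1.0 - a_fast - plateau
    return a_fast * np.exp(-k_fast * t) + a_slow * np.exp(-k_slow * t) + plateau


def _init_decay_rates(t: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Heuristic rate initialization from log-linear fits of the early and
    late halves of the time course (deterministic)."""
    pos = (f > 1e-6) & (t > 0)
    if pos.sum() < 2:
        return 1.0, 0.1
    tp, lf = t[pos], np.log(f[pos])
    mid = max(2, len(tp) // 2)
    k_early = -np.polyfit(tp[:mid], lf[:mid], 1)[0]
    k_late = -np.polyfit(tp[mid - 1 :], lf[mid - 1 :], 1)[0] if len(tp) - mid + 1 >= 2 else k_early
    k_fast0 = max(float(k_early), 1e-4)
    k_slow0 = min(max(float(k_late), 1e-6), k_fast0 / 5)
    return k_fast0, max(k_slow0, 1e-6)


def fit_dissociation(t, f_obs, free_plateau: bool = False) -> DecayFit:
    """Fit a two-phase decay with an identifiability guard.

    Requires >= 5 time points including t = 0 with values normalized to the
    zero point.  If the biphasic solution has k_fast/k_slow below
    ``PHASE_SEPARATION_THRESHOLD``, or does not beat a single exponential,
    the single-exponential fit is returned with ``fallback`` set.  A
    non-decaying series is flagged as non-converged.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f_obs, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    if t.min() > 0:
        raise ValueError("time course must include t = 0")
    order = np.argsort(t)
    t, f = t[order], f[order]

    # a series that trends upward is not a decay
    slope = np.polyfit(t, f, 1)[0]
    if slope >= 0:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, np.nan, False)

    k_fast0, k_slow0 = _init_decay_rates(t, f)

    def resid_bi(p):
        a, kf, ks, c = p
        a_slow = 1.0 - a - c
        return a * np.exp(-kf * t) + a_slow * np.exp(-ks * t) + c - f

    c_hi = 1.0 if free_plateau else 1e-12
    sol_bi = optimize.least_squares(
        resid_bi,
        [0.5, k_fast0, k_slow0, 0.0],
        bounds=([0.0, 1e-9, 1e-9, 0.0], [1.0, np.inf, np.inf, c_hi]),
        method="trf",
    )

    def resid_single(p):
        k, c = p
        return (1.0 - c) * np.exp(-k * t) + c - f

    sol_s = optimize.least_squares(
        resid_single,
        [max(k_fast0, 1e-3), 0.0],
        bounds=([1e-9, 0.0], [np.inf, c_hi]),
        method="trf",
    )
    k_single = float(sol_s.x[0])
    rss_s = float(2 * sol_s.cost)

    a, kf, ks, c = sol_bi.x
    if kf < ks:  # keep the fast phase first
        kf, ks = ks, kf
        a = 1.0 - a - c
    rss_bi = float(2 * sol_bi.cost)

    separable = ks > 0 and kf / ks >= PHASE_SEPARATION_THRESHOLD
    # two phases must also carry weight in both amplitudes to be meaningful
    informative = min(a, 1.0 - a - c) > 0.01
    if separable and informative and rss_bi < rss_s:
        return DecayFit(float(a), float(kf), float(ks), float(c), rss_bi, bool(sol_bi.success))
    return DecayFit(
        1.0,
        k_single,
        k_single,
        float(sol_s.x[1]),
        rss_s,
        bool(sol_s.success),
        single_phase=True,
        fallback=True,
    )


def association_model(t, k_obs: float, f_max: float = 1.0):
    """One-phase exponential approach to equilibrium: F_max (1 - e^(-k_obs t))."""
    t = np.asarray(t, dtype=float)
    return f_max * (1.0 - np.exp(-k_obs * t))


def fit_association_single(t, f_obs) -> AssociationFit:
    """Fit k_obs for one enzyme concentration.

    Requires >= 4 time points including t = 0.  An all-zero (no binding)
    response is flagged rather than fit.  A nonzero F at t = 0 is tolerated;
    the misfit simply shows up in the residuals.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f_obs, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    if t.min() > 0:
        raise ValueError("time course must include t = 0")
    if np.all(np.abs(f) < 1e-12):
        return AssociationFit(np.nan, 0.0, 0.0, False, flat=True)

    fmax0 = max(float(np.max(f)), 1e-6)
    # initialize from the earliest substantial rise
    pos = (t > 0) & (f > 0) & (f < fmax0)
    k0 = 1.0 / np.median(t[t > 0]) if not pos.any() else float(
        np.median(-np.log(np.clip(1 - f[pos] / (fmax0 * 1.05), 1e-9, None)) / t[pos])
    )

    def resid(p):
        return association_model(t, p[0], p[1]) - f

    sol = optimize.least_squares(
        resid, [max(k0, 1e-6), fmax0], bounds=([1e-12, 1e-9], [np.inf, 1.5]), method="trf"
    )
    return AssociationFit(
        float(sol.x[0]), float(sol.x[1]), float(2 * sol.cost), bool(sol.success)
    )


def kon_from_kobs(concentrations, k_obs, fit_intercept: bool = True) -> LineFit:
    """Second-order k_on from the line k_obs = k_on [E] + intercept.

    Ordinary least squares over >= 3 distinct concentrations; the slope is
    k_on in (concentration unit)^-1 (time unit)^-1 and the intercept is the
    theoretical k_off.  ``fit_intercept=False`` forces the line through the
    origin.  A slope indistinguishable from zero is flagged.
    """
    e = np.asarray(concentrations, dtype=float)
    k = np.asarray(k_obs, dtype=float)
    if len(np.unique(e)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if fit_intercept:
        res = stats.linregress(e, k)
        slope, intercept = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
        slope_se, int_se = float(res.stderr), float(res.intercept_stderr)
    else:
        slope = float(np.dot(e, k) / np.dot(e, e))
        intercept = 0.0
        resid = k - slope * e
        dof = max(len(e) - 1, 1)
        slope_se = float(np.sqrt(np.sum(resid**2) / dof / np.dot(e, e)))
        sst = float(np.sum((k - k.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
        int_se = 0.0
    flat = abs(slope) < 1e-12 or (np.isfinite(slope_se) and slope_se > 0 and abs(slope) < 2 * slope_se)
    return LineFit(slope, intercept, r2, slope_se, int_se, flat=flat)


def kd_from_rates(k_off: float, k_on: float) -> float:
    """K_D = k_off / k_on.

    With k_off in s^-1 and k_on in M^-1 s^-1 the result is molar; with k_on
    in nM^-1 s^-1 the result is nM.  Unit bookkeeping is the caller's.
    """
    if k_off <= 0 or k_on <= 0:
        raise ValueError("rate constants must be positive")
    return k_off / k_on
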