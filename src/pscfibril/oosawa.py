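"""Classical nucleated polymerisation (Oosawa) kinetics.

The fibril mass fraction after homogeneous nucleation of an ``n``-mer
nucleus followed by monomer-addition elongation follows the closed form

    f(t) = 1 - sech^{2/n}( sqrt(n/2) * lambda * t ),
    lambda = sqrt(2) * k_eff * m0^{n/2},

where ``m0`` is the initial monomer mass concentration and ``k_eff`` the
effective rate constant combining the nucleation and elongation rates
(k_eff = sqrt(k_plus * k_n); only this composite is identifiable from
mass-fraction data).  The half-time of the reaction scales as the power
law t_half ∝ m0^{-n/2}, which gives an independent estimate of the
nucleus size from half-times measured at several concentrations.

Fitting is organised statsmodels-style: :class:`OosawaModel` is built from
one or more mass-fraction curves and ``fit()`` returns an
:class:`OosawaResults` carrying estimates, uncertainties, the RSS profile
over fixed nucleus sizes (the single-curve degeneracy diagnostic) and a
``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .clusters import MassFractionCurve

N_BOUNDS = (1.0, 8.0)


@dataclass(frozen=True)
class OosawaParams:
    """Identifiable parameters of the closed-form growth curve."""

    n: float                 # nucleus size (real-valued in fits)
    k_eff: float             # effective rate, time^-1 * conc^(-n/2)
    m0: float | None = None  # mM; per-curve in global fits

    def __post_init__(self):
        if self.n <= 0 or self.k_eff <= 0:
            raise ValueError("n and k_eff must be positive")


def oosawa_curve(t, n: float, k_eff: float, m0: float):
    """Fibril mass fraction at times ``t`` (array or scalar).

    f(0) = 0, f is monotone increasing and f -> 1 as t -> inf.
    """
    if n <= 0 or k_eff <= 0:
        raise ValueError("n and k_eff must be positive")
    t = np.asarray(t, dtype=float)
    lam = math.sqrt(2.0) * k_eff * m0 ** (0.5 * n)
    u = math.sqrt(0.5 * n) * lam * t
    # sech^{2/n}(u) via logs to stay finite for large u:
    # log sech(u) = log 2 - |u| - log1p(exp(-2|u|))
    au = np.abs(u)
    log_sech = math.log(2.0) - au - np.log1p(np.exp(-2.0 * au))
    return 1.0 - np.exp((2.0 / n) * log_sech)


def analytic_halftime(n: float, k_eff: float, m0: float) -> float:
    """Exact inversion of the closed form at f = 1/2:
    t_half = arccosh(2^{n/2}) / (sqrt(n/2) * lambda)."""
    lam = math.sqrt(2.0) * k_eff * m0 ** (0.5 * n)
    return math.acosh(2.0 ** (0.5 * n)) / (math.sqrt(0.5 * n) * lam)


class FitError(RuntimeError):
    """Raised when a growth curve cannot be fitted (e.g. non-sigmoidal)."""


class OosawaModel:
    """Nucleated-polymerisation model for one or several growth curves.

    Parameters
    ----------
    curves:
        One :class:`MassFractionCurve` or a list of them.  A single curve
        gives the (degenerate) single-concentration fit; several curves at
        distinct ``m0`` constitute a global fit with shared (n, k_eff).
    """

    def __init__(self, curves):
        if isinstance(curves, MassFractionCurve):
            curves = [curves]
        if not curves:
            raise ValueError("need at least one curve")
        self.curves = list(curves)
        m0s = [c.m0 for c in self.curves]
        if len(self.curves) > 1 and len(set(np.round(m0s, 12))) < len(m0s):
            warnings.warn("duplicate m0 values collapse the global fit to "
                          "single-curve degeneracy", stacklevel=2)
        for c in self.curves:
            if np.nanmax(c.fibril_mass_fraction) < 0.05:
                raise FitError(
                    "curve shows no significant growth; a sigmoidal "
                    "mass-fraction trace is required")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, m0_col: str = "m0_mM",
                       time_col: str = "time_ns",
                       frac_col: str = "fibril_fraction") -> "OosawaModel":
        """Build from a tidy frame with one row per (curve, time) point."""
        curves = []
        for m0, g in df.groupby(m0_col):
            f = g[frac_col].to_numpy(dtype=float)
            curves.append(MassFractionCurve(
                times_ns=g[time_col].to_numpy(dtype=float),
                fibril_mass_fraction=f,
                monomer_mM=(1.0 - f) * m0, oligomer_mM=np.zeros_like(f),
                fibril_mM=f * m0, m0=float(m0)))
        return cls(curves)

    # -- internals ---------------------------------------------------------

    def _residuals(self, n, log_k):
        k = math.exp(log_k)
        res = []
        for c in self.curves:
            res.append(oosawa_curve(c.times_ns, n, k, c.m0)
                       - c.fibril_mass_fraction)
        return np.concatenate(res)

    def _guess_log_k(self, n):
        """Initial k from the observed half-time of the first curve."""
        for c in self.curves:
            try:
                from .clusters import halftime
                th = halftime(c)
            except ValueError:
                continue
            lam = math.acosh(2.0 ** (0.5 * n)) / (math.sqrt(0.5 * n) * th)
            return math.log(lam / (math.sqrt(2.0) * c.m0 ** (0.5 * n)))
        return 0.0

    def _fit_fixed_n(self, n):
        res = least_squares(lambda p: self._residuals(n, p[0]),
                            x0=[self._guess_log_k(n)], method="lm")
        return res

    def fit(self, n_starts=(1.5, 2.5, 3.5, 4.5, 6.0),
            profile_grid: np.ndarray | None = None) -> "OosawaResults":
        """Bounded multi-start least squares over (n, log k_eff).

        Ties are broken by lowest RSS, then lowest n.  The returned results
        carry an RSS profile over fixed n (defaults to a grid on [1, 8]),
        exposing the n-k_eff degeneracy of single-curve fits.
        """
        best = None
        for n0 in n_starts:
            try:
                res = least_squares(
                    lambda p: self._residuals(p[0], p[1]),
                    x0=[n0, self._guess_log_k(n0)],
                    bounds=([N_BOUNDS[0], -np.inf], [N_BOUNDS[1], np.inf]))
            except Exception:
                continue
            if best is None or res.cost < best.cost - 1e-12 or \
                    (abs(res.cost - best.cost) <= 1e-12
                     and res.x[0] < best.x[0]):
                best = res
        if best is None or not best.success:
            raise FitError("least-squares fit failed to converge")
        n_hat, log_k = best.x
        rss = float(2.0 * best.cost)
        # covariance from the Jacobian at the optimum
        jac = best.jac
        dof = max(1, sum(len(c.times_ns) for c in self.curves) - 2)
        s2 = rss / dof
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
        except np.linalg.LinAlgError:
            cov = np.full((2, 2), np.nan)
        if profile_grid is None:
            profile_grid = np.linspace(N_BOUNDS[0], N_BOUNDS[1], 29)
        profile = []
        for n in profile_grid:
            r = self._fit_fixed_n(n)
            profile.append((float(n), float(2.0 * r.cost),
                            math.exp(r.x[0])))
        profile = pd.DataFrame(profile, columns=["n", "rss", "k_eff"])
        return OosawaResults(self, OosawaParams(n_hat, math.exp(log_k)),
                             rss, cov, profile)


@dataclass
class OosawaResults:
    """Estimates, uncertainties and diagnostics of an Oosawa fit."""

    model: OosawaModel
    params: OosawaParams
    rss: float
    cov: np.ndarray          # covariance of (n, log k_eff)
    degeneracy_profile: pd.DataFrame

    @property
    def n(self) -> float:
        return self.params.n

    @property
    def k_eff(self) -> float:
        return self.params.k_eff

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of (n, log k_eff)."""
        return np.sqrt(np.diag(self.cov))

    def predict(self, curve_index: int = 0, times=None) -> np.ndarray:
        c = self.model.curves[curve_index]
        t = c.times_ns if times is None else times
        return oosawa_curve(t, self.n, self.k_eff, c.m0)

    def predicted_curves(self) -> list:
        return [self.predict(i) for i in range(len(self.model.curves))]

    def residuals(self, curve_index: int) -> np.ndarray:
        c = self.model.curves[curve_index]
        return c.fibril_mass_fraction - self.predict(curve_index)

    def halftimes(self) -> list:
        return [analytic_halftime(self.n, self.k_eff, c.m0)
                for c in self.model.curves]

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Nucleated polymerisation (Oosawa) fit",
            "=" * 46,
            f"curves:             {len(self.model.curves)}",
            f"concentrations mM:  "
            + ", ".join(f"{c.m0:.3g}" for c in self.model.curves),
            f"nucleus size n:     {self.n:.3f} +/- {se[0]:.3f}",
            f"k_eff:              {self.k_eff:.4g} "
            f"(ns^-1 mM^(-n/2)) +/- {se[1]:.2g} (log scale)",
            f"RSS:                {self.rss:.5g}",
            f"profile RSS ratio n=2 vs n=5: "
            f"{self._profile_ratio():.3g}",
        ]
        return "\n".join(lines)

    def _profile_ratio(self):
        prof = self.degeneracy_profile
        r2 = np.interp(2.0, prof["n"], prof["rss"])
        r5 = np.interp(5.0, prof["n"], prof["rss"])
        return max(r2, r5) / max(min(r2, r5), 1e-300)


def fit_single(curve: MassFractionCurve) -> OosawaResults:
    """Least-squares fit of one concentration (degenerate in n)."""
    return OosawaModel(curve).fit()


def fit_global(curves) -> OosawaResults:
    """Shared-(n, k_eff) fit across curves at distinct concentrations."""
    if len(curves) < 3:
        warnings.warn("global fits are reliable from >= 3 distinct "
                      "concentrations", stacklevel=2)
    return OosawaModel(curves).fit()


@dataclass
class HalftimeScaling:
    """Half-time power-law fit t_half = t_half_ref * (m0/c_std)^{-n/2}."""

    n_scaling: float
    n_scaling_se: float
    slope: float
    slope_se: float
    t_half_ref: float
    c_std: float
    non_nucleated: bool = False

    def summary(self) -> str:
        return (
            "Half-time scaling (log-log OLS)\n"
            + "=" * 38 + "\n"
            f"slope:      {self.slope:.4f} +/- {self.slope_se:.4f}\n"
            f"n_scaling:  {self.n_scaling:.3f} +/- {self.n_scaling_se:.3f}\n"
            f"t_half at {self.c_std:g} mM: {self.t_half_ref:.4g} ns\n"
            + ("flag: no concentration dependence (non-nucleated)\n"
               if self.non_nucleated else "")
        )


def fit_halftime_powerlaw(halftimes, c_std: float = 1.0) -> HalftimeScaling:
    """OLS of log t_half against log m0; the nucleus size is -2x the slope.

    ``halftimes`` is a sequence of (m0_mM, t_half) pairs; at least three
    distinct concentrations with positive half-times are required.
    """
    pts = [(float(m), float(t)) for m, t in halftimes]
    if len(pts) < 3:
        raise ValueError("need at least 3 (m0, t_half) points")
    if any(t <= 0 or m <= 0 for m, t in pts):
        raise ValueError("concentrations and half-times must be positive")
    x = np.log(np.array([m for m, _ in pts]) / c_std)
    y = np.log([t for _, t in pts])
    A = np.column_stack([x, np.ones_like(x)])
    coef, res_ss, *_ = np.linalg.lstsq(A, y, rcond=None)
    slope, intercept = coef
    resid = y - A @ coef
    dof = len(pts) - 2
    s2 = float(resid @ resid) / dof if dof > 0 else 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_se = math.sqrt(s2 / sxx) if sxx > 0 else float("inf")
    non_nucleated = abs(slope) <= 2.0 * slope_se and abs(slope) < 1e-8
    return HalftimeScaling(
        n_scaling=-2.0 * slope, n_scaling_se=2.0 * slope_se,
        slope=float(slope), slope_se=slope_se,
        t_half_ref=float(math.exp(intercept)), c_std=c_std,
        non_nucleated=bool(abs(slope) < 1e-8))


@dataclass
class ResidualDiagnostics:
    per_curve: pd.DataFrame
    systematic_deviation: bool


def goodness_of_fit_report(fit: OosawaResults,
                           sign_threshold: float = 0.7,
                           tol: float = 1e-10) -> ResidualDiagnostics:
    """Early/late signed-residual split per curve.

    Raises the systematic-deviation flag when early residuals (before the
    fitted half-time) are predominantly positive and late ones negative --
    the signature of ring formation and fibril fusion, which remove growth
    ends and are absent from the closed-form theory."""
    rows = []
    early_pos = late_neg = curves_used = 0
    for i, c in enumerate(fit.model.curves):
        r = fit.residuals(i)
        th = analytic_halftime(fit.n, fit.k_eff, c.m0)
        early = r[c.times_ns < th]
        late = r[c.times_ns >= th]
        early = early[np.abs(early) > tol]
        late = late[np.abs(late) > tol]
        fe = float(np.mean(early > 0)) if len(early) else np.nan
        fl = float(np.mean(late < 0)) if len(late) else np.nan
        rows.append((c.m0, float(np.mean(early)) if len(early) else 0.0,
                     float(np.mean(late)) if len(late) else 0.0, fe, fl))
        if len(early) and len(late):
            curves_used += 1
            if fe >= sign_threshold:
                early_pos += 1
            if fl >= sign_threshold:
                late_neg += 1
    df = pd.DataFrame(rows, columns=["m0_mM", "early_mean_residual",
                                     "late_mean_residual",
                                     "frac_early_positive",
                                     "frac_late_negative"])
    flag = curves_used > 0 and early_pos == curves_used \
        and late_neg == curves_used
    return ResidualDiagnostics(df, bool(flag))
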