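"""Least-squares NTCP model fitting, goodness of fit, and model comparison.

The central objects follow the Model / Results pattern:

>>> from lungntcp.fitting import NTCPModel
>>> res = NTCPModel(dose_gy, response, model="lyman").fit()
>>> res.d50, res.gamma50
>>> print(res.summary())

``NTCPModel.fit`` minimizes the sum of squared residuals between the
chosen sigmoid and the normalized binned responses over (d50, gamma50),
using bounded trust-region least squares started from a small grid of
initial guesses (a deterministic stand-in for a spreadsheet
generalized-reduced-gradient solve of the same objective).  The Results
object carries SSR, adjusted R^2, AIC, BIC (Gaussian least-squares
forms with k = 2 parameters), asymptotic standard errors, and an
extra-sum-of-squares F test of the sigmoid against the constant-mean
null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import models as m
from .curves import DoseResponseCurve
from .exceptions import FitError

__all__ = [
    "NTCPModel",
    "NTCPResults",
    "ComparisonReport",
    "fit_model",
    "compare_models",
    "goodness_stats",
    "fit_significance_anova",
    "cross_model_anova",
    "rank_models",
]

#: Parameter bounds: d50 in [1, 200] Gy, gamma50 in [0.05, 20].
DEFAULT_BOUNDS = ((1.0, 200.0), (0.05, 20.0))
#: Multi-start grid (5 d50 values x 4 gamma50 values).
DEFAULT_D50_STARTS = (15.0, 25.0, 35.0, 45.0, 55.0)
DEFAULT_GAMMA_STARTS = (0.5, 1.0, 2.0, 4.0)
_SSR_FLOOR = 1e-12
_SSR_AGREE_TOL = 1e-6


def goodness_stats(residuals, n: int, k: int = 2, sst: float | None = None):
    """SSR, adjusted R^2, AIC and BIC from least-squares residuals.

    AIC = n*ln(SSR/n) + 2k and BIC = n*ln(SSR/n) + k*ln(n), the Gaussian
    least-squares forms; their difference is k*ln(n) - 2k identically.
    SSR is floored at 1e-12 (with a warning) so the logs stay finite.
    ``sst`` is the total sum of squares about the response mean; when not
    given it cannot be inferred from residuals alone and R^2 is NaN.
    """
    r = np.asarray(residuals, dtype=float)
    if n <= k + 1:
        raise ValueError(f"need n > k+1 data points (n={n}, k={k})")
    ssr = float((r * r).sum())
    if ssr < _SSR_FLOOR:
        warnings.warn("SSR below 1e-12; floored to keep information criteria finite")
        ssr = _SSR_FLOOR
    if sst is not None:
        if sst <= 0:
            raise ValueError("degenerate response variance (SST <= 0)")
        r2 = 1.0 - ssr / sst
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    else:
        adj_r2 = np.nan
    aic = n * np.log(ssr / n) + 2 * k
    bic = n * np.log(ssr / n) + k * np.log(n)
    return ssr, float(adj_r2), float(aic), float(bic)


class NTCPModel:
    """One NTCP sigmoid to be fitted to binned dose-response data.

    Parameters
    ----------
    dose : array of bin-representative doses (Gy), strictly positive.
    response : array of normalized bin responses (0-1 scale).
    model : one of ``lyman``, ``logit``, ``weibull``, ``poisson``.
    """

    def __init__(self, dose, response, model: str = "lyman"):
        self.model_id = m.parse_model_id(model)
        dose = np.asarray(dose, dtype=float)
        response = np.asarray(response, dtype=float)
        ok = np.isfinite(dose) & np.isfinite(response)
        self.dose = dose[ok]
        self.response = response[ok]
        if self.dose.size < 3:
            raise ValueError("need at least 3 nonempty bins to fit")
        if np.any(self.dose <= 0):
            raise ValueError("bin doses must be > 0")
        peak = self.response.max()
        if not (0.2 <= peak <= 2.0):
            raise ValueError(
                f"responses look unnormalized (max={peak:.3g}); fit expects the "
                "0-1 normalized scale"
            )

    @classmethod
    def from_curve(cls, curve: DoseResponseCurve, model: str = "lyman") -> "NTCPModel":
        if not curve.normalized:
            raise ValueError("curve must be normalized before fitting")
        ok = curve.nonempty
        mdl = cls(curve.bin_dose[ok], curve.response[ok], model=model)
        return mdl

    def predict(self, params: m.NTCPParams, dose=None):
        return m.evaluate(self.model_id, params, self.dose if dose is None else dose)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        p = m.NTCPParams(x[0], x[1])
        return m.evaluate(self.model_id, p, self.dose) - self.response

    def _jac(self, x: np.ndarray) -> np.ndarray:
        return m.param_jacobian(self.model_id, m.NTCPParams(x[0], x[1]), self.dose)

    def fit(
        self,
        d50_starts=DEFAULT_D50_STARTS,
        gamma_starts=DEFAULT_GAMMA_STARTS,
        bounds=DEFAULT_BOUNDS,
    ) -> "NTCPResults":
        """Bounded nonlinear least squares from a multi-start grid."""
        lo = np.array([bounds[0][0], bounds[1][0]])
        hi = np.array([bounds[0][1], bounds[1][1]])
        best = None
        ssrs = []
        for d0 in d50_starts:
            for g0 in gamma_starts:
                x0 = np.clip(np.array([d0, g0], dtype=float), lo, hi)
                try:
                    sol = optimize.least_squares(
                        self._residuals,
                        x0,
                        jac=self._jac,
                        bounds=(lo, hi),
                        method="trf",
                        xtol=1e-12,
                        ftol=1e-12,
                        gtol=1e-12,
                    )
                except Exception:
                    continue
                ssr = 2.0 * sol.cost
                ssrs.append(ssr)
                if best is None or ssr < best[0] - 1e-15:
                    best = (ssr, sol)
        if best is None:
            raise FitError(f"no start converged for model {self.model_id}")
        ssr_best, sol = best
        n_agree = int(sum(s <= ssr_best + _SSR_AGREE_TOL for s in ssrs))
        params = m.NTCPParams(float(sol.x[0]), float(sol.x[1]))
        at_bounds = bool(
            np.any(np.isclose(sol.x, lo, rtol=0, atol=1e-9))
            or np.any(np.isclose(sol.x, hi, rtol=0, atol=1e-9))
        )
        return NTCPResults(
            model=self,
            params=params,
            residuals=sol.fun,
            jacobian=sol.jac,
            converged=bool(sol.success),
            n_starts=len(ssrs),
            n_starts_agreeing=n_agree,
            at_bounds=at_bounds,
        )


class NTCPResults:
    """Fit results: parameter estimates, uncertainties and fit statistics."""

    def __init__(
        self,
        model: NTCPModel,
        params: m.NTCPParams,
        residuals: np.ndarray,
        jacobian: np.ndarray,
        converged: bool,
        n_starts: int,
        n_starts_agreeing: int,
        at_bounds: bool,
    ):
        self.model = model
        self.model_id = model.model_id
        self.params = params
        self.residuals = np.asarray(residuals, dtype=float)
        self.converged = converged
        self.n_starts = n_starts
        self.n_starts_agreeing = n_starts_agreeing
        self.at_bounds = at_bounds
        self.nobs = self.n_bins_used = int(self.residuals.size)
        self.k_params = 2

        y = model.response
        sst = float(((y - y.mean()) ** 2).sum())
        self.ssr, self.adj_r2, self.aic, self.bic = goodness_stats(
            self.residuals, self.nobs, self.k_params, sst=sst if sst > 0 else None
        )
        self.sst = sst
        # Asymptotic covariance from the Gauss-Newton approximation.
        dof = self.nobs - self.k_params
        try:
            jtj_inv = np.linalg.pinv(jacobian.T @ jacobian)
            self.cov_params = jtj_inv * (self.ssr / max(dof, 1))
            self.bse = np.sqrt(np.diag(self.cov_params))
        except np.linalg.LinAlgError:  # pragma: no cover
            self.cov_params = np.full((2, 2), np.nan)
            self.bse = np.array([np.nan, np.nan])
        # Significance of fit vs the constant-mean null.
        self.fvalue, self.f_pvalue, self.p_underflow = _fit_f_test(
            sst, self.ssr, self.nobs
        )

    @property
    def d50(self) -> float:
        return self.params.d50

    @property
    def gamma50(self) -> float:
        return self.params.gamma50

    def predict(self, dose):
        return m.evaluate(self.model_id, self.params, dose)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald intervals from the asymptotic standard errors."""
        q = stats.t.ppf(1 - alpha / 2, max(self.nobs - self.k_params, 1))
        est = self.params.as_array()
        return np.column_stack([est - q * self.bse, est + q * self.bse])

    def to_dict(self) -> dict:
        return {
            "model": self.model_id,
            "d50": self.d50,
            "gamma50": self.gamma50,
            "ssr": self.ssr,
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "bic": self.bic,
            "n_bins_used": self.n_bins_used,
            "converged": self.converged,
            "n_starts_agreeing": self.n_starts_agreeing,
            "at_bounds": self.at_bounds,
            "f_value": self.fvalue,
            "f_pvalue": self.f_pvalue,
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"NTCP dose-response fit: {self.model_id}",
            "=" * 46,
            f"{'n bins used':<22}{self.nobs:>10d}",
            f"{'converged':<22}{str(self.converged):>10}",
            f"{'starts agreeing':<22}{self.n_starts_agreeing:>7d}/{self.n_starts}",
            "-" * 46,
            f"{'':<10}{'estimate':>10}{'std err':>10}{'95% CI':>16}",
            f"{'D50 (Gy)':<10}{self.d50:>10.3f}{self.bse[0]:>10.3f}"
            f"   [{ci[0,0]:6.2f}, {ci[0,1]:6.2f}]",
            f"{'gamma50':<10}{self.gamma50:>10.3f}{self.bse[1]:>10.3f}"
            f"   [{ci[1,0]:6.2f}, {ci[1,1]:6.2f}]",
            "-" * 46,
            f"{'SSR':<12}{self.ssr:>12.4g}    {'adj-R2':<8}{self.adj_r2:>10.4f}",
            f"{'AIC':<12}{self.aic:>12.2f}    {'BIC':<8}{self.bic:>10.2f}",
            f"{'F (vs const)':<12}{self.fvalue:>12.3f}    {'p':<8}{self.f_pvalue:>10.3g}",
        ]
        if self.at_bounds:
            lines.append("warning: a parameter sits at a bound (non-informative fit)")
        return "\n".join(lines)

    def plot(self, ax=None, dose_grid=None, **kwargs):
        """Plot the data points and fitted sigmoid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.model.dose, self.model.response, "o", label="data")
        dg = (
            np.linspace(0.1, self.model.dose.max() * 1.1, 200)
            if dose_grid is None
            else np.asarray(dose_grid)
        )
        ax.plot(dg, self.predict(dg), "-", label=f"{self.model_id} fit", **kwargs)
        ax.set_xlabel("dose (Gy)")
        ax.set_ylabel("normalized response")
        ax.legend()
        return ax


def _fit_f_test(sst: float, ssr_fit: float, n: int):
    """Extra-sum-of-squares F test of the sigmoid vs the constant mean."""
    dof = n - 2
    underflow = False
    if ssr_fit <= _SSR_FLOOR:
        underflow = True
    fval = ((sst - ssr_fit) / 1.0) / (ssr_fit / dof)
    pval = float(stats.f.sf(fval, 1, dof))
    return float(fval), pval, underflow


def fit_model(model: str, curve: DoseResponseCurve, **fit_kwargs) -> NTCPResults:
    """Fit one named model to a normalized curve (convenience wrapper)."""
    return NTCPModel.from_curve(curve, model=model).fit(**fit_kwargs)


def fit_significance_anova(curve_or_results, results: NTCPResults | None = None):
    """(F, p) for the significance of a model fit against the flat null.

    Accepts either a fitted :class:`NTCPResults` or (curve, results).
    """
    res = curve_or_results if results is None else results
    if not isinstance(res, NTCPResults):
        raise TypeError("expected an NTCPResults")
    return res.fvalue, res.f_pvalue


def cross_model_anova(per_patient_fits: dict[str, list[NTCPResults]]):
    """One-way ANOVA of fitted d50 and gamma50 across the four model groups.

    ``per_patient_fits`` maps model id -> list of per-patient fits; the
    lists must be the same length across models (balanced design).
    """
    keys = sorted(per_patient_fits)
    lengths = {k: len(per_patient_fits[k]) for k in keys}
    if len(set(lengths.values())) != 1 or min(lengths.values()) < 2:
        raise ValueError(f"need balanced groups with >= 2 patients each: {lengths}")
    d50_groups = [[f.d50 for f in per_patient_fits[k]] for k in keys]
    g50_groups = [[f.gamma50 for f in per_patient_fits[k]] for k in keys]
    f_d, p_d = _one_way_anova(d50_groups)
    f_g, p_g = _one_way_anova(g50_groups)
    return f_d, p_d, f_g, p_g


def _one_way_anova(groups) -> tuple[float, float]:
    """Standard one-way ANOVA; identical group means give F = 0, p = 1."""
    means = [np.mean(g) for g in groups]
    if np.ptp(means) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class ComparisonReport:
    """All-model fits to one curve, ranked by each fit criterion."""

    fits: dict[str, NTCPResults]
    cross_model: tuple[float, float, float, float] | None = None

    @property
    def best_by(self) -> dict[str, str]:
        out = {}
        for crit, reverse in (("ssr", False), ("aic", False), ("bic", False), ("adj_r2", True)):
            ranked = self.rank(crit)
            out[crit] = ranked[0]
        return out

    def rank(self, criterion: str) -> list[str]:
        """Model ids ordered best-first; ties break lexicographically."""
        reverse = criterion == "adj_r2"
        sign = -1.0 if reverse else 1.0
        return sorted(
            self.fits, key=lambda k: (sign * getattr(self.fits[k], criterion), k)
        )

    @property
    def consensus_best(self) -> str | None:
        winners = set(self.best_by.values())
        return winners.pop() if len(winners) == 1 else None

    def to_frame(self) -> pd.DataFrame:
        rows = [self.fits[k].to_dict() for k in sorted(self.fits)]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["Model comparison", df.to_string(index=False, float_format="%.4g")]
        for crit in ("ssr", "adj_r2", "aic", "bic"):
            lines.append(f"best by {crit:>7}: {self.best_by[crit]}")
        cons = self.consensus_best
        lines.append(
            f"consensus best: {cons}" if cons else "consensus best: none (criteria disagree)"
        )
        return "\n".join(lines)


def compare_models(
    curve: DoseResponseCurve, model_ids=m.MODEL_IDS, **fit_kwargs
) -> ComparisonReport:
    """Fit every requested model to one normalized curve."""
    fits = {
        mid: fit_model(mid, curve, **fit_kwargs)
        for mid in (m.parse_model_id(x) for x in model_ids)
    }
    return ComparisonReport(fits=fits)


def rank_models(report: ComparisonReport) -> pd.DataFrame:
    """Per-criterion ranking table (rank 1 = best) with a consensus flag."""
    if len(report.fits) < 2:
        raise ValueError("ranking needs at least two fitted models")
    data = {}
    for crit in ("ssr", "adj_r2", "aic", "bic"):
        order = report.rank(crit)
        data[crit] = {mid: order.index(mid) + 1 for mid in report.fits}
    df = pd.DataFrame(data).sort_index()
    df.index.name = "model"
    df.attrs["consensus_best"] = report.consensus_best
    return df
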