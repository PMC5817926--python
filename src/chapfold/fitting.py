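"""Chi-square fitting of the five-state model to refolding-yield curves.

The estimation problem mirrors the experimental one: refolding yields
measured along quench-time (t_q), extended-time (t_ext) and stretching
force sweeps are fitted jointly by the deterministic five-state model.
The two no-chaperone reference rates (folded -> extended unfolding, and
collapsed -> folded folding) are held at their measured values while the
chaperone binding constants are optimized; the dissociation constant for
each chaperone-conformation pair follows as K_d = k_off / k_on.

Modelled after the statsmodels pattern: build a
:class:`ChaperoneBindingModel` from data, call :meth:`fit`, inspect the
returned :class:`ChaperoneBindingResults` (estimates, uncertainties,
per-start table, ``summary()``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .kinetics import KineticScheme, predict_yield_curve

__all__ = [
    "YieldCurveData",
    "ChaperoneBindingModel",
    "ChaperoneBindingResults",
    "DEFAULT_BOUNDS",
    "chi_square",
    "fit_model",
    "identifiability_sweep",
    "IdentifiabilityWarning",
]

#: Bound-constrained search ranges (linear scale; optimization is in log10).
#: Association rates span 1e2-1e8 / (M s), dissociation 1e-4-1e2 / s —
#: generous around reported chaperone-substrate values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "k_on_ext": (1e2, 1e8),
    "k_on_coll": (1e2, 1e8),
    "k_off_ext": (1e-4, 1e2),
    "k_off_coll": (1e-4, 1e2),
    "k_u": (1e-3, 1e2),
    "k_c": (1e-2, 1e3),
    "k_f0": (1e-3, 1e2),
    "k_uc": (1e-1, 1e4),
}

_RATE_NAMES = tuple(DEFAULT_BOUNDS)


class IdentifiabilityWarning(UserWarning):
    pass


@dataclass(frozen=True)
class YieldCurveData:
    """One measured yield curve along a protocol sweep.

    ``family`` is ``'t_q'``, ``'t_ext'`` or ``'force'``; the remaining
    protocol settings (extended time before the quench, extend force,
    quench duration) are fixed per curve.  ``sems`` are the bootstrap
    standard errors used as chi-square weights; zero entries are replaced
    by the median positive SEM.
    """

    family: str
    grid: np.ndarray
    yields: np.ndarray
    sems: np.ndarray
    t_ext_s: float = 0.0
    extend_force_pn: float = 120.0
    t_q_s: float = 5.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("t_q", "t_ext", "force"):
            raise ValueError(f"unknown protocol family {self.family!r}")
        g = np.asarray(self.grid, dtype=float)
        y = np.asarray(self.yields, dtype=float)
        s = np.asarray(self.sems, dtype=float)
        if not (len(g) == len(y) == len(s)):
            raise ValueError("grid, yields, sems must have equal length")
        if np.any(s < 0):
            raise ValueError("sems must be >= 0")
        if np.all(s == 0):
            raise ValueError("every point has zero SEM; weights undefined")
        s = np.where(s > 0, s, np.median(s[s > 0]))
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "yields", y)
        object.__setattr__(self, "sems", s)

    @property
    def n_points(self) -> int:
        return len(self.grid)


class ChaperoneBindingModel:
    """Five-state model bound to yield-curve data with a free/fixed split.

    Parameters
    ----------
    curves : sequence of YieldCurveData
        Measured curves, ideally spanning >= 2 protocol families (a single
        family leaves binding constants poorly identified; a warning is
        raised).
    base_scheme : KineticScheme
        Holds the fixed reference rates and the chaperone concentration;
        entries for free parameters serve only as fallbacks.
    free : sequence of str
        Rate names optimized (non-empty).  All other rates stay at their
        ``base_scheme`` values.
    bounds : mapping, optional
        Per-parameter (lo, hi) overrides of :data:`DEFAULT_BOUNDS`.
    per_force_kon : bool
        For ``'force'``-family curves, fit an independent k_on_ext at each
        grid force (named ``k_on_ext@<force>``) instead of a single value.
    """

    def __init__(self, curves, base_scheme: KineticScheme,
                 free=("k_on_ext", "k_off_ext"), bounds=None,
                 per_force_kon: bool = False) -> None:
        self.curves = list(curves)
        if not self.curves:
            raise ValueError("need at least one yield curve")
        self.base_scheme = base_scheme
        self.per_force_kon = per_force_kon
        free = list(free)  # may be empty: fit() then just scores base_scheme
        for name in free:
            if name not in _RATE_NAMES:
                raise ValueError(f"unknown rate {name!r}; choose from {_RATE_NAMES}")
        self.bounds = dict(DEFAULT_BOUNDS)
        if bounds:
            for k, (lo, hi) in bounds.items():
                if not 0 < lo < hi:
                    raise ValueError("bounds must be positive and ordered")
                self.bounds[k] = (lo, hi)
        self.free_names: list[str] = list(free)
        if per_force_kon:
            if "k_on_ext" not in free:
                raise ValueError("per_force_kon requires k_on_ext to be free")
            self.free_names.remove("k_on_ext")
            for c in self.curves:
                if c.family == "force":
                    for f in c.grid:
                        name = f"k_on_ext@{f:g}"
                        if name not in self.free_names:
                            self.free_names.append(name)
                            self.bounds[name] = self.bounds["k_on_ext"]
            if not any(c.family == "force" for c in self.curves):
                raise ValueError("per_force_kon requires a 'force'-family curve")
            if any(c.family != "force" for c in self.curves):
                # non-force curves still need a global k_on_ext
                self.free_names.insert(0, "k_on_ext")
        families = {c.family for c in self.curves}
        if len(families) < 2:
            warnings.warn(
                "yield curves span a single protocol family; binding "
                "constants may be non-identifiable", IdentifiabilityWarning,
                stacklevel=2)
        self.n_points = sum(c.n_points for c in self.curves)

    # -- parameter plumbing -------------------------------------------------

    def _scheme_with(self, params: dict[str, float]) -> KineticScheme:
        plain = {k: v for k, v in params.items() if "@" not in k}
        return self.base_scheme.replace(**plain)

    def predicted(self, params: dict[str, float]) -> list[np.ndarray]:
        """Model yields for every curve at the given free-parameter values."""
        scheme = self._scheme_with(params)
        out = []
        for c in self.curves:
            if c.family == "force" and self.per_force_kon:
                vals = np.empty(c.n_points)
                for i, f in enumerate(c.grid):
                    kon = params.get(f"k_on_ext@{f:g}", scheme.k_on_ext)
                    sc = scheme.replace(k_on_ext=kon)
                    vals[i] = predict_yield_curve(
                        sc, [f], vary="force", t_ext_s=c.t_ext_s,
                        t_q_s=c.t_q_s)[0]
                out.append(vals)
            else:
                out.append(predict_yield_curve(
                    scheme, c.grid, vary=c.family, t_ext_s=c.t_ext_s,
                    extend_force_pn=c.extend_force_pn, t_q_s=c.t_q_s))
        return out

    def chi_square(self, params: dict[str, float] | None = None) -> float:
        """Sum over points of ((observed - predicted) / sem)^2."""
        preds = self.predicted(params or {})
        return float(sum(np.sum(((c.yields - p) / c.sems) ** 2)
                         for c, p in zip(self.curves, preds)))

    # -- fitting ------------------------------------------------------------

    def _objective(self, x: np.ndarray) -> float:
        params = {n: 10.0 ** xi for n, xi in zip(self.free_names, x)}
        try:
            return self.chi_square(params)
        except (ValueError, np.linalg.LinAlgError):  # pragma: no cover
            return 1e12

    def fit(self, seed: int = 0, n_starts: int = 16, tol: float = 1e-8,
            ) -> "ChaperoneBindingResults":
        """Multi-start bound-constrained minimization in log10-rate space.

        Starts are Latin-hypercube samples of the log bounds plus the
        base-scheme values; each start runs L-BFGS-B.  Reproducible for a
        given seed.
        """
        names = self.free_names
        if not names:
            # every rate fixed: no optimization, just score the base scheme
            chi2 = self.chi_square({})
            return ChaperoneBindingResults(
                model=self, params={}, chi2=chi2,
                starts=pd.DataFrame([{"start": 0, "chi2": chi2,
                                      "converged": True}]),
                converged=True, bse_log10={})
        lo = np.log10([self.bounds[n][0] for n in names])
        hi = np.log10([self.bounds[n][1] for n in names])
        starts = [np.clip(np.log10([max(getattr(self.base_scheme,
                                                n.split("@")[0], 1.0) or
                                        10 ** lo[i], 10 ** lo[i])
                                    for i, n in enumerate(names)]), lo, hi)]
        if n_starts > 1:
            sampler = qmc.LatinHypercube(d=len(names), seed=seed)
            starts += list(lo + sampler.random(n_starts - 1) * (hi - lo))
        rows = []
        best = None
        for i, x0 in enumerate(starts):
            res = minimize(self._objective, x0, method="L-BFGS-B",
                           bounds=list(zip(lo, hi)),
                           options={"ftol": tol, "maxiter": 500})
            rows.append({"start": i, "chi2": float(res.fun),
                         "converged": bool(res.success),
                         **{n: 10.0 ** v for n, v in zip(names, res.x)}})
            if res.success and (best is None or res.fun < best.fun):
                best = res
        table = pd.DataFrame(rows)
        if best is None:
            return ChaperoneBindingResults(
                model=self, params={}, chi2=float("nan"), starts=table,
                converged=False, bse_log10={},
                message="no start converged")
        params = {n: 10.0 ** v for n, v in zip(names, best.x)}
        bse = self._log10_bse(best.x, lo, hi)
        return ChaperoneBindingResults(model=self, params=params,
                                       chi2=float(best.fun), starts=table,
                                       converged=True, bse_log10=bse)

    def _log10_bse(self, x: np.ndarray, lo, hi) -> dict[str, float]:
        """Approximate SEs of log10 rates from the chi2 Hessian (cov = 2 H^-1)."""
        n = len(x)
        h = 1e-3
        H = np.empty((n, n))
        f0 = self._objective(x)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h
                ej = np.zeros(n); ej[j] = h
                fpp = self._objective(np.clip(x + ei + ej, lo, hi))
                fpm = self._objective(np.clip(x + ei - ej, lo, hi))
                fmp = self._objective(np.clip(x - ei + ej, lo, hi))
                fmm = self._objective(np.clip(x - ei - ej, lo, hi))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
        try:
            cov = 2.0 * np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d <= 0):
                raise np.linalg.LinAlgError
            return {nme: float(np.sqrt(di)) for nme, di in zip(self.free_names, d)}
        except np.linalg.LinAlgError:
            return {}

    def profile(self, parameter: str, grid, seed: int = 0, n_starts: int = 4
                ) -> pd.DataFrame:
        """Chi-square profile: refit all other free parameters at each value.

        The standard identifiability diagnostic — a flat profile means the
        data do not constrain the parameter.
        """
        if parameter not in self.free_names:
            raise ValueError(f"{parameter!r} is not a free parameter")
        rows = []
        rest = [n for n in self.free_names if n != parameter]
        for v in np.asarray(grid, dtype=float):
            if rest:
                sub = _FixedSubModel(self, parameter, v)
                res = sub.fit(seed=seed, n_starts=n_starts)
                chi2 = res.chi2
            else:
                chi2 = self.chi_square({parameter: v})
            rows.append({parameter: v, "chi2": chi2})
        df = pd.DataFrame(rows)
        if len(df) >= 3 and np.ptp(df.chi2.to_numpy()) < 1e-6 * max(1.0, df.chi2.min()):
            warnings.warn(f"chi2 profile of {parameter} is flat: parameter "
                          "not identifiable from the supplied data",
                          IdentifiabilityWarning, stacklevel=2)
        return df


class _FixedSubModel(ChaperoneBindingModel):
    """Clone of a model with one free parameter pinned (for profiling)."""

    def __init__(self, parent: ChaperoneBindingModel, name: str, value: float):
        self.curves = parent.curves
        self.base_scheme = parent.base_scheme
        self.per_force_kon = parent.per_force_kon
        self.bounds = parent.bounds
        self.free_names = [n for n in parent.free_names if n != name]
        self.n_points = parent.n_points
        self._pin = (name, value)

    def predicted(self, params):
        name, value = self._pin
        return super().predicted({**params, name: value})


@dataclass
class ChaperoneBindingResults:
    """Fit outcome: estimates, chi2, per-start table, derived K_d values."""

    model: ChaperoneBindingModel
    params: dict[str, float]
    chi2: float
    starts: pd.DataFrame
    converged: bool
    bse_log10: dict[str, float] = field(default_factory=dict)
    message: str = ""

    @property
    def scheme(self) -> KineticScheme:
        return self.model._scheme_with(self.params)

    @property
    def df_resid(self) -> int:
        return self.model.n_points - len(self.model.free_names)

    @property
    def kd_ext(self) -> float | None:
        s = self.scheme
        return s.kd_ext if s.k_on_ext > 0 else None

    @property
    def kd_coll(self) -> float | None:
        s = self.scheme
        return s.kd_coll if s.k_on_coll > 0 else None

    def predicted_curves(self) -> list[np.ndarray]:
        return self.model.predicted(self.params)

    def summary(self) -> str:
        lines = ["Chaperone binding kinetics: chi-square fit",
                 "=" * 58,
                 f"curves: {len(self.model.curves)}   points: "
                 f"{self.model.n_points}   free parameters: "
                 f"{len(self.model.free_names)}",
                 f"chi2 = {self.chi2:.3f}   df = {self.df_resid}   "
                 f"converged: {self.converged}",
                 "-" * 58,
                 f"{'parameter':<18}{'estimate':>14}{'se(log10)':>12}"]
        for n in self.model.free_names:
            v = self.params.get(n, float("nan"))
            se = self.bse_log10.get(n)
            lines.append(f"{n:<18}{v:>14.4g}"
                         f"{se:>12.3f}" if se is not None else
                         f"{n:<18}{v:>14.4g}{'--':>12}")
        lines.append("-" * 58)
        for lbl, kd in (("K_d(ext)", self.kd_ext), ("K_d(coll)", self.kd_coll)):
            if kd is not None:
                lines.append(f"{lbl:<18}{kd:>14.4g} M")
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)

    def plot(self, ax=None):  # pragma: no cover - visual aid
        """Observed vs fitted yield curves (one panel per curve)."""
        import matplotlib.pyplot as plt

        preds = self.predicted_curves()
        if ax is None:
            _, axes = plt.subplots(1, len(self.model.curves), squeeze=False,
                                   figsize=(4 * len(self.model.curves), 3))
            axes = axes[0]
        else:
            axes = np.atleast_1d(ax)
        for a, c, p in zip(axes, self.model.curves, preds):
            a.errorbar(c.grid, c.yields, yerr=c.sems, fmt="o", label="observed")
            a.plot(c.grid, p, "-", label="fit")
            a.set_xlabel({"t_q": "t_q (s)", "t_ext": "t_ext (s)",
                          "force": "force (pN)"}[c.family])
            a.set_ylabel("refolding yield")
            a.set_title(c.label or c.family)
            a.legend()
        return axes


# -- spec-style functional surface ------------------------------------------

def chi_square(params: dict[str, float], model: ChaperoneBindingModel) -> float:
    """Chi-square of the model at explicit parameter values."""
    return model.chi_square(params)


def fit_model(model: ChaperoneBindingModel, seed: int = 0,
              **kwargs) -> ChaperoneBindingResults:
    return model.fit(seed=seed, **kwargs)


def identifiability_sweep(model: ChaperoneBindingModel, parameter: str,
                          grid, **kwargs) -> pd.DataFrame:
    return model.profile(parameter, grid, **kwargs)
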