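"""Two-parameter concentration-response curves (CRCs).

The two classical families used for algal growth-inhibition data are

* Weibull:  ``E = 1 - exp(-exp(alpha + beta * log10(x)))``
* Hill:     ``E = alpha * x / (beta + x)``

with ``x`` a molar concentration. For the Weibull family ``alpha`` is a
location and ``beta`` a slope (both dimensionless, on the log10
concentration axis); for the Hill family ``alpha`` is the maximum effect
(fraction in (0, 1]) and ``beta`` the EC50 in mol/L.

The module provides vectorised evaluation and closed-form inversion of
both families, least-squares fitting with goodness-of-fit (R², RMSE),
model selection by maximum R², nonparametric bootstrap confidence
intervals on effect concentrations, and the scalar helpers ``pec`` and
``mass_to_molar``. :class:`DoseResponseCurve` wraps fitting and model
selection as a scikit-learn style estimator.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CurveFamily",
    "CurveParams",
    "FitResult",
    "ECEstimate",
    "FitError",
    "weibull_effect",
    "hill_effect",
    "invert_curve",
    "fit_curve",
    "select_model",
    "ec_with_oci",
    "bootstrap_ec",
    "pec",
    "mass_to_molar",
    "DoseResponseCurve",
]


class FitError(RuntimeError):
    """Raised when no usable curve fit can be produced."""


class CurveFamily(str, enum.Enum):
    """Enumeration of the supported CRC families."""

    WEIBULL = "weibull"
    HILL = "hill"

    @classmethod
    def coerce(cls, value: "CurveFamily | str") -> "CurveFamily":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


# Family order used for deterministic tie-breaking in model selection.
_FAMILY_ORDER = (CurveFamily.WEIBULL, CurveFamily.HILL)


def _check_positive_conc(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0.0):
        raise ValueError("concentrations must be finite and strictly positive")
    return x


def weibull_effect(alpha: float, beta: float, x) -> np.ndarray | float:
    """Weibull CRC: ``E = 1 - exp(-exp(alpha + beta*log10(x)))``.

    Strictly increasing in ``x`` for ``beta > 0``; values lie in (0, 1).
    """
    xa = _check_positive_conc(x)
    e = 1.0 - np.exp(-np.exp(alpha + beta * np.log10(xa)))
    return e if np.ndim(x) else float(e)


def hill_effect(alpha: float, beta: float, x) -> np.ndarray | float:
    """Hill CRC: ``E = alpha*x/(beta + x)``; half-maximal at ``x = beta``."""
    if beta <= 0:
        raise ValueError("Hill beta (EC50) must be > 0")
    xa = _check_positive_conc(x)
    e = alpha * xa / (beta + xa)
    return e if np.ndim(x) else float(e)


@dataclass(frozen=True)
class CurveParams:
    """Parameters of a fitted (or truth) two-parameter CRC."""

    family: CurveFamily
    alpha: float
    beta: float

    def __post_init__(self):
        object.__setattr__(self, "family", CurveFamily.coerce(self.family))
        if self.family is CurveFamily.HILL:
            if not (self.beta > 0):
                raise ValueError("Hill beta (EC50) must be > 0")
            if not (0.0 < self.alpha <= 1.0):
                raise ValueError("Hill alpha (max effect) must be in (0, 1]")
        else:
            if not (np.isfinite(self.beta) and self.beta != 0.0):
                raise ValueError("Weibull beta must be finite and nonzero")

    @property
    def max_effect(self) -> float:
        """Supremum of the attainable effect (1 for Weibull, alpha for Hill)."""
        return 1.0 if self.family is CurveFamily.WEIBULL else self.alpha

    def effect(self, x) -> np.ndarray | float:
        if self.family is CurveFamily.WEIBULL:
            return weibull_effect(self.alpha, self.beta, x)
        return hill_effect(self.alpha, self.beta, x)

    def inverse(self, effect: float) -> float:
        """Closed-form effect concentration EC_x for effect level ``effect``."""
        return invert_curve(self, effect)


def invert_curve(params: CurveParams, effect: float) -> float:
    """Closed-form inversion of a CRC: the concentration producing ``effect``.

    Weibull: ``x = 10**((ln(-ln(1-E)) - alpha)/beta)``;
    Hill:    ``x = beta*E/(alpha - E)``.
    """
    e = float(effect)
    if params.family is CurveFamily.WEIBULL:
        if not (0.0 < e < 1.0):
            raise ValueError(f"effect level {e!r} outside (0, 1) for Weibull inversion")
        return 10.0 ** ((math.log(-math.log(1.0 - e)) - params.alpha) / params.beta)
    if not (0.0 < e < params.alpha):
        raise ValueError(
            f"effect level {e!r} outside (0, {params.alpha}) attainable by Hill curve"
        )
    return params.beta * e / (params.alpha - e)


@dataclass
class FitResult:
    """A fitted CRC with goodness-of-fit and optional bootstrap replicates.

    ``r_squared`` is ``1 - SSres/SStot`` (NaN when all observed effects are
    identical, i.e. SStot = 0); ``rmse`` uses denominator ``n``.
    """

    params: CurveParams
    r_squared: float
    rmse: float
    n_points: int
    converged: bool = True
    message: str = ""
    bootstrap_params: list = field(default_factory=list)
    seed: int | None = None

    @property
    def family(self) -> CurveFamily:
        return self.params.family

    def to_record(self) -> dict:
        return {
            "family": self.params.family.value,
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n_points": self.n_points,
            "converged": self.converged,
        }


@dataclass
class ECEstimate:
    """An effect concentration with 95% observed confidence bounds.

    ``ec_low``/``ec_up`` are the 2.5th/97.5th percentiles of EC_x over
    nonparametric bootstrap resamples (None when no bootstrap requested).
    """

    effect_level: float
    ec: float
    ec_low: float | None = None
    ec_up: float | None = None
    n_boot: int = 0
    seed: int | None = None

    def to_record(self) -> dict:
        return {
            "effect_level": self.effect_level,
            "ec": self.ec,
            "ec_low": self.ec_low,
            "ec_up": self.ec_up,
            "n_boot": self.n_boot,
        }


# ---------------------------------------------------------------------------
# fitting


def _validate_fit_data(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("concentration and effect arrays must have equal length")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("concentrations must be finite and strictly positive")
    if np.any(~np.isfinite(y)):
        raise ValueError("effects must be finite")
    if x.size < 3:
        raise ValueError("need at least 3 observations to fit a two-parameter CRC")
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    return x, y


def _init_weibull(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Linearise ln(-ln(1-E)) vs log10(x) on interior effects; this keeps the
    # optimiser away from flat (beta -> 0) solutions.
    mask = (y > 1e-6) & (y < 1.0 - 1e-6)
    if mask.sum() >= 2 and np.unique(x[mask]).size >= 2:
        z = np.log(-np.log(1.0 - y[mask]))
        slope, intercept = np.polyfit(np.log10(x[mask]), z, 1)
        if np.isfinite(slope) and np.isfinite(intercept) and slope != 0.0:
            return float(intercept), float(slope)
    return float(-np.median(np.log10(x))), 1.0


def _init_hill(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    a0 = float(np.clip(np.max(y), 0.05, 1.0))
    half = a0 / 2.0
    b0 = float(x[np.argmin(np.abs(y - half))])
    return a0, b0


def fit_curve(
    x,
    y,
    family: CurveFamily | str,
    x0: tuple[float, float] | None = None,
) -> FitResult:
    """Least-squares fit of one CRC family to (concentration, effect) data.

    Effects outside [0, 1] (hormesis) are not clipped; the optimiser sees
    the raw observations. Non-convergence is reported via
    ``FitResult.converged`` rather than raising.
    """
    family = CurveFamily.coerce(family)
    x, y = _validate_fit_data(x, y)
    lx = np.log10(x)

    if family is CurveFamily.WEIBULL:

        def resid(p):
            return (1.0 - np.exp(-np.exp(p[0] + p[1] * lx))) - y

        p0 = np.asarray(x0 if x0 is not None else _init_weibull(x, y), dtype=float)
        sol = optimize.least_squares(
            resid, p0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000
        )
        alpha, beta = sol.x
        ok = bool(sol.success and np.isfinite(sol.x).all() and beta != 0.0)
        params = CurveParams(family, float(alpha), float(beta) if beta != 0 else 1.0)
    else:

        def resid(p):
            return p[0] * x / (p[1] + x) - y

        p0 = np.asarray(x0 if x0 is not None else _init_hill(x, y), dtype=float)
        p0[0] = np.clip(p0[0], 1e-6, 1.0)
        p0[1] = max(p0[1], 1e-300)
        sol = optimize.least_squares(
            resid,
            p0,
            bounds=([1e-9, 1e-300], [1.0, np.inf]),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
        alpha, beta = sol.x
        ok = bool(sol.success and np.isfinite(sol.x).all() and beta > 0)
        params = CurveParams(family, float(np.clip(alpha, 1e-9, 1.0)), float(max(beta, 1e-300)))

    residuals = resid(sol.x)
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = math.sqrt(ss_res / y.size)
    return FitResult(
        params=params,
        r_squared=r2,
        rmse=rmse,
        n_points=int(y.size),
        converged=ok,
        message=str(sol.message),
    )


def select_model(fits: list[FitResult], tie_tol: float = 1e-6) -> FitResult:
    """Pick the best fit: maximum R², ties broken by minimum RMSE, then
    by family order (Weibull first)."""
    usable = [f for f in fits if f.converged]
    if not usable:
        raise FitError("no successful fits to select from")

    def r2_key(f: FitResult) -> float:
        return -np.inf if math.isnan(f.r_squared) else f.r_squared

    best_r2 = max(r2_key(f) for f in usable)
    tied = [f for f in usable if r2_key(f) >= best_r2 - tie_tol]
    min_rmse = min(f.rmse for f in tied)
    tied = [f for f in tied if f.rmse <= min_rmse + tie_tol]
    tied.sort(key=lambda f: _FAMILY_ORDER.index(f.params.family))
    return tied[0]


# ---------------------------------------------------------------------------
# bootstrap confidence intervals on effect concentrations


def bootstrap_ec(
    fit: FitResult,
    x,
    y,
    effect_levels,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> dict[float, ECEstimate]:
    """Nonparametric percentile-bootstrap OCIs for several effect levels.

    Uses a pooled residual bootstrap: the centred residuals of the point
    fit are resampled with replacement across all wells, added back to the
    fitted values, the curve is refit (same family, warm-started at the
    point estimate) and inverted at every requested level. The 2.5th and
    97.5th percentiles of the resampled EC_x form the 95% observed
    confidence interval. Pooling the residuals matters with triplicate
    designs, where any within-group scheme underestimates the noise scale.
    The interval is widened, if necessary, to contain the point estimate so
    that ``ec_low <= ec <= ec_up`` always holds. Deterministic given seed;
    noise-free data give a degenerate (zero-width) interval.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    levels = [float(e) for e in np.atleast_1d(effect_levels)]
    point = {e: invert_curve(fit.params, e) for e in levels}
    if n_boot is None or n_boot <= 0:
        return {
            e: ECEstimate(effect_level=e, ec=point[e], n_boot=0, seed=seed)
            for e in levels
        }

    rng = np.random.default_rng(seed)
    warm = (fit.params.alpha, fit.params.beta)
    yhat = np.asarray(fit.params.effect(x), dtype=float)
    resid = y - yhat
    resid = resid - resid.mean()
    samples: dict[float, list[float]] = {e: [] for e in levels}
    for _ in range(int(n_boot)):
        yb = yhat + resid[rng.integers(0, resid.size, size=resid.size)]
        fb = fit_curve(x, yb, fit.params.family, x0=warm)
        if not fb.converged:
            continue
        for e in levels:
            try:
                samples[e].append(invert_curve(fb.params, e))
            except ValueError:
                # resampled curve cannot attain this level (e.g. Hill ceiling)
                continue
    out = {}
    for e in levels:
        if samples[e]:
            lo, hi = np.percentile(samples[e], [2.5, 97.5])
            lo = min(float(lo), point[e])
            hi = max(float(hi), point[e])
        else:
            lo = hi = point[e]
        out[e] = ECEstimate(
            effect_level=e, ec=point[e], ec_low=lo, ec_up=hi,
            n_boot=int(n_boot), seed=seed,
        )
    return out


def ec_with_oci(
    fit: FitResult,
    x,
    y,
    effect_level: float,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> ECEstimate:
    """EC_x with a 95% observed confidence interval for one effect level."""
    return bootstrap_ec(fit, x, y, [effect_level], n_boot=n_boot, seed=seed)[
        float(effect_level)
    ]


# ---------------------------------------------------------------------------
# scalar helpers


def pec(ec: float, ndigits: int | None = None) -> float:
    """Negative log10 effect concentration (pEC_x); reports use 2 decimals."""
    if not (ec > 0):
        raise ValueError("effect concentration must be > 0")
    v = -math.log10(ec)
    return round(v, ndigits) if ndigits is not None else v


def mass_to_molar(mass_conc: float, molar_mass: float) -> float:
    """Convert a mass concentration (g/L) to molarity (mol/L)."""
    if not (mass_conc > 0 and molar_mass > 0):
        raise ValueError("mass concentration and molar mass must be > 0")
    return mass_conc / molar_mass


# ---------------------------------------------------------------------------
# estimator


class DoseResponseCurve(RegressorMixin, BaseEstimator):
    """scikit-learn style estimator for a two-parameter CRC.

    Parameters
    ----------
    family : {"auto", "weibull", "hill"}, default="auto"
        CRC family to fit. ``"auto"`` fits every candidate family and keeps
        the one with maximum R² (ties: minimum RMSE, then Weibull first).

    Attributes
    ----------
    family_ : CurveFamily
        Selected family.
    alpha_, beta_ : float
        Fitted parameters of the selected family.
    r_squared_, rmse_ : float
        Goodness-of-fit of the selected curve.
    fit_result_ : FitResult
        Full record of the selected fit.
    candidate_fits_ : list of FitResult
        One entry per family tried.

    Examples
    --------
    >>> import numpy as np
    >>> from mixtox.dose_response import CurveParams, DoseResponseCurve
    >>> truth = CurveParams("weibull", 11.4, 3.0)
    >>> x = np.geomspace(1e-6, 1e-3, 7)
    >>> model = DoseResponseCurve().fit(x.reshape(-1, 1), truth.effect(x))
    >>> round(model.pec50(), 2)
    3.93
    """

    def __init__(self, family: str = "auto"):
        self.family = family

    def _families(self) -> tuple[CurveFamily, ...]:
        if self.family == "auto":
            return _FAMILY_ORDER
        return (CurveFamily.coerce(self.family),)

    def fit(self, X, y):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single concentration column")
            x = x[:, 0]
        fits = [fit_curve(x, y, fam) for fam in self._families()]
        self.candidate_fits_ = fits
        self.fit_result_ = select_model(fits)
        self.family_ = self.fit_result_.params.family
        self.alpha_ = self.fit_result_.params.alpha
        self.beta_ = self.fit_result_.params.beta
        self.r_squared_ = self.fit_result_.r_squared
        self.rmse_ = self.fit_result_.rmse
        self.n_points_ = self.fit_result_.n_points
        self._x_train = x
        self._y_train = np.asarray(y, dtype=float).ravel()
        return self

    @property
    def params_(self) -> CurveParams:
        check_is_fitted(self, "fit_result_")
        return self.fit_result_.params

    def predict(self, X):
        check_is_fitted(self, "fit_result_")
        x = np.asarray(X, dtype=float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[:, 0]
        return np.asarray(self.params_.effect(x), dtype=float)

    def effect_concentration(self, effect_level: float) -> float:
        """Closed-form EC_x of the selected curve."""
        return invert_curve(self.params_, effect_level)

    def ec_with_oci(
        self, effect_level: float, n_boot: int = 1000, seed: int | None = 0
    ) -> ECEstimate:
        """Bootstrap OCI for EC_x using the training data."""
        check_is_fitted(self, "fit_result_")
        return ec_with_oci(
            self.fit_result_, self._x_train, self._y_train, effect_level,
            n_boot=n_boot, seed=seed,
        )

    def pec50(self, ndigits: int | None = None) -> float:
        """pEC50 of the selected curve (−log10 of the EC50 in mol/L)."""
        return pec(self.effect_concentration(0.5), ndigits=ndigits)
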