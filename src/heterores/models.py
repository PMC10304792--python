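"""Model classes fitting the single-cell resistance distribution to data.

Two assays identify the same two parameters (IC50 and heteroresistance):

* :class:`InoculumEffectModel` — MIC readings at several inoculum sizes.
  The expected MIC of an ``n``-cell inoculum is the expected maximum of
  ``n`` single-cell resistances, ``mu + sigma * z(n)`` on the log10 scale,
  which is *linear* in ``(mu, sigma)`` given the order-statistic quantile
  ``z(n)``.  The nonlinear least-squares problem therefore has an exact
  constrained ordinary-least-squares solution, used here instead of an
  iterative optimiser (same optimum, no initialisation sensitivity).
* :class:`DoseResponseModel` — percent-survival versus concentration from
  plate counts, fitted to ``100 * (1 - Phi((log10 c - mu)/sigma))`` by
  nonlinear least squares.

Both ``fit()`` methods return a :class:`ResistanceFitResults` carrying the
estimates, diagnostics, a ``summary()`` table and a case-resampling
``bootstrap()``.  Per-biological-replicate results are combined with
:func:`aggregate_fits` (mean and SEM per parameter; MIC_MODEL is averaged
over per-replicate values, not recomputed from mean parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from .distribution import MIC_MODEL_PERCENTILE, ResistanceDistribution, expected_max_quantile
from .exceptions import (
    BootstrapUnstableError,
    ConvergenceError,
    HeteroresError,
    UnderDeterminedFitError,
)

__all__ = [
    "InoculumMicObservation",
    "DoseResponseObservation",
    "InoculumEffectModel",
    "DoseResponseModel",
    "ResistanceFitResults",
    "AggregateFit",
    "BootstrapResult",
    "fit_inoculum_effect",
    "fit_dose_response",
    "aggregate_fits",
    "bootstrap_fit",
]


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InoculumMicObservation:
    """One experimental MIC reading at a known inoculum size.

    ``inoculum_cells`` is cells per well and may be a colony-count-corrected
    value; ``mic_exp_mM`` is the lowest fully inhibitory concentration.
    ``censored`` marks simulated observations whose concentration grid was
    exhausted before growth stopped; they are excluded from fits.
    """

    strain_id: str
    replicate_id: str
    inoculum_cells: float
    mic_exp_mM: float
    censored: bool = False

    def __post_init__(self):
        if not self.censored:
            if not np.isfinite(self.inoculum_cells) or self.inoculum_cells < 1:
                raise ValueError(f"inoculum_cells must be >= 1, got {self.inoculum_cells!r}")
            if not np.isfinite(self.mic_exp_mM) or self.mic_exp_mM <= 0:
                raise ValueError(f"mic_exp_mM must be > 0, got {self.mic_exp_mM!r}")


@dataclass(frozen=True)
class DoseResponseObservation:
    """One (concentration, percent survival) point from a plating assay.

    ``percent_survival`` is CFU(c)/CFU(0) x 100; values slightly above 100
    are tolerated (plate-count noise).  ``concentration_mM == 0`` rows are
    the normalisation controls and are excluded from fitting.
    """

    strain_id: str
    replicate_id: str
    concentration_mM: float
    percent_survival: float

    def __post_init__(self):
        if not np.isfinite(self.concentration_mM) or self.concentration_mM < 0:
            raise ValueError(f"concentration_mM must be >= 0, got {self.concentration_mM!r}")
        if not np.isfinite(self.percent_survival) or self.percent_survival < 0:
            raise ValueError(f"percent_survival must be >= 0, got {self.percent_survival!r}")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

class ResistanceFitResults:
    """Fitted resistance-distribution parameters with diagnostics.

    Attributes
    ----------
    mu, sigma : float
        Location and spread on the fitting scale (log10 mM for the default
        lognormal model; raw mM for the linear-normal variant).
    scale : {"log10", "linear"}
    rss : float
        Residual sum of squares on the fitting scale (percent scale for
        dose-response fits).
    converged : bool
    sigma_clamped : bool
        True when the unconstrained spread estimate was negative and was
        clamped to zero.
    ci : dict or None
        Per-parameter 95% percentile intervals, set by :meth:`bootstrap`.
    """

    def __init__(self, model, mu, sigma, rss, converged, sigma_clamped=False):
        self.model = model
        self.mu = float(mu)
        self.sigma = float(sigma)
        self.scale = model.scale
        self.nobs = model.nobs
        self.strain_id = model.strain_id
        self.replicate_id = model.replicate_id
        self.rss = float(rss)
        self.converged = bool(converged)
        self.sigma_clamped = bool(sigma_clamped)
        self.ci = None

    # -- parameter views ----------------------------------------------------

    @property
    def ic50_mM(self) -> float:
        return 10.0 ** self.mu if self.scale == "log10" else self.mu

    @property
    def heteroresistance(self) -> float:
        """Spread estimate: log10-scale SD (default) or mM-scale SD (linear)."""
        return self.sigma

    def mic_model_mM(self, percentile: float = MIC_MODEL_PERCENTILE) -> float:
        zp = norm.ppf(percentile)
        if not (0.0 < percentile < 1.0):
            raise ValueError(f"percentile must lie in (0, 1), got {percentile!r}")
        if self.scale == "log10":
            return 10.0 ** (self.mu + self.sigma * zp)
        return self.mu + self.sigma * zp

    @property
    def distribution(self) -> ResistanceDistribution:
        """The fitted lognormal single-cell distribution (log10 scale only)."""
        if self.scale != "log10":
            raise HeteroresError(
                "a linear-normal fit does not define a lognormal distribution"
            )
        return ResistanceDistribution(self.mu, self.sigma)

    # -- interfaces ----------------------------------------------------------

    def predict(self, x):
        """Model prediction at ``x`` (inoculum size or concentration)."""
        return self.model.predict([self.mu, self.sigma], x)

    def bootstrap(self, B: int = 1000, seed=None, envelope_points: int = 50):
        """Case-resampling bootstrap; attaches ``self.ci`` and returns it."""
        result = bootstrap_fit(
            self.model.observations(),
            fitter=self.model.fitter_name,
            B=B,
            seed=seed,
            scale=self.scale,
            envelope_points=envelope_points,
        )
        self.ci = result.conf_int
        return result

    def to_row(self) -> dict:
        row = {
            "strain_id": self.strain_id,
            "replicate_id": self.replicate_id,
            "ic50_mM": self.ic50_mM,
            "heteroresistance": self.heteroresistance,
            "mic_model_mM": self.mic_model_mM(),
            "rss": self.rss,
            "n_points": self.nobs,
            "converged": self.converged,
            "sigma_clamped": self.sigma_clamped,
        }
        if self.ci is not None:
            for name, (lo, hi) in self.ci.items():
                row[f"{name}_ci_lo"] = lo
                row[f"{name}_ci_hi"] = hi
        return row

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} fit "
            f"(strain={self.strain_id}, replicate={self.replicate_id}, scale={self.scale})",
            "-" * 64,
            f"{'IC50 (mM)':<24}{self.ic50_mM:12.4f}",
            f"{'heteroresistance':<24}{self.heteroresistance:12.4f}",
            f"{'MIC_MODEL (mM)':<24}{self.mic_model_mM():12.4f}",
            f"{'n points':<24}{self.nobs:12d}",
            f"{'RSS (fit scale)':<24}{self.rss:12.6g}",
            f"{'converged':<24}{str(self.converged):>12}",
        ]
        if self.sigma_clamped:
            lines.append("note: spread estimate clamped at 0 (flat response)")
        if self.ci is not None:
            lines.append("95% bootstrap percentile intervals:")
            for name, (lo, hi) in self.ci.items():
                lines.append(f"  {name:<22}[{lo:10.4f}, {hi:10.4f}]")
        return "\n".join(lines)

    def __repr__(self):
        return (
            f"<ResistanceFitResults ic50={self.ic50_mM:.4g} mM, "
            f"heteroresistance={self.heteroresistance:.4g}, "
            f"mic_model={self.mic_model_mM():.4g} mM>"
        )


# ---------------------------------------------------------------------------
# Inoculum-effect model
# ---------------------------------------------------------------------------

def _check_single_strain(observations):
    strains = {o.strain_id for o in observations}
    if len(strains) > 1:
        raise HeteroresError(
            f"observations must come from a single strain, got {sorted(strains)}"
        )


class InoculumEffectModel:
    """Order-statistic model for MIC versus inoculum size.

    ``log10(MIC_EXP) = mu + sigma * z(n) + error`` (default ``scale='log10'``),
    or ``MIC_EXP = mu + sigma * z(n) + error`` for the plain-normal
    comparison variant (``scale='linear'``).
    """

    fitter_name = "inoculum"

    def __init__(self, mic_mM, inoculum_cells, scale="log10",
                 strain_id="", replicate_id=""):
        mic = np.asarray(mic_mM, dtype=float)
        n = np.asarray(inoculum_cells, dtype=float)
        if mic.shape != n.shape or mic.ndim != 1:
            raise ValueError("mic_mM and inoculum_cells must be 1-d and equal length")
        if np.any(~np.isfinite(mic)) or np.any(mic <= 0):
            raise ValueError("all MIC values must be finite and > 0")
        if np.any(~np.isfinite(n)) or np.any(n < 1):
            raise ValueError("all inoculum sizes must be finite and >= 1")
        if scale not in ("log10", "linear"):
            raise ValueError(f"scale must be 'log10' or 'linear', got {scale!r}")
        self.mic_mM = mic
        self.inoculum_cells = n
        self.scale = scale
        self.strain_id = strain_id
        self.replicate_id = replicate_id
        self.nobs = len(mic)

    @classmethod
    def from_observations(cls, observations, scale="log10"):
        observations = list(observations)
        if not observations:
            raise HeteroresError("no observations supplied")
        _check_single_strain(observations)
        usable = [o for o in observations if not o.censored]
        if len(usable) < len(observations):
            warnings.warn(
                f"excluded {len(observations) - len(usable)} censored observation(s) "
                "(concentration grid exhausted)",
                stacklevel=2,
            )
        if not usable:
            raise UnderDeterminedFitError("all observations are censored")
        reps = {o.replicate_id for o in usable}
        return cls(
            [o.mic_exp_mM for o in usable],
            [o.inoculum_cells for o in usable],
            scale=scale,
            strain_id=usable[0].strain_id,
            replicate_id=reps.pop() if len(reps) == 1 else "pooled",
        )

    @classmethod
    def from_dataframe(cls, df, scale="log10", mic_col="mic_exp_mM",
                       inoculum_col="inoculum_cells"):
        strain = str(df["strain_id"].iloc[0]) if "strain_id" in df else ""
        reps = set(df["replicate_id"].astype(str)) if "replicate_id" in df else set()
        return cls(
            df[mic_col].to_numpy(float),
            df[inoculum_col].to_numpy(float),
            scale=scale,
            strain_id=strain,
            replicate_id=reps.pop() if len(reps) == 1 else "pooled",
        )

    def observations(self):
        return [
            InoculumMicObservation(self.strain_id, self.replicate_id, n, m)
            for n, m in zip(self.inoculum_cells, self.mic_mM)
        ]

    def predict(self, params, inoculum_cells):
        """Predicted MIC (mM) at the given inoculum size(s)."""
        mu, sigma = params
        z = expected_max_quantile(inoculum_cells)
        if self.scale == "log10":
            return 10.0 ** (mu + sigma * z)
        return mu + sigma * z

    def fit(self) -> ResistanceFitResults:
        if len(np.unique(self.inoculum_cells)) < 2:
            raise UnderDeterminedFitError(
                "need MIC readings at >= 2 distinct inoculum sizes to identify "
                "both IC50 and heteroresistance"
            )
        x = expected_max_quantile(self.inoculum_cells)
        y = np.log10(self.mic_mM) if self.scale == "log10" else self.mic_mM
        mu, sigma, rss, clamped = _fit_linear_constrained(x, y)
        return ResistanceFitResults(self, mu, sigma, rss, True, clamped)


def _fit_linear_constrained(x, y):
    """Exact OLS of y on x with the slope constrained to be >= 0.

    The constrained optimum is either the unconstrained OLS solution (if its
    slope is non-negative) or the boundary solution slope=0, intercept=mean(y).
    """
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    clamped = slope < 0.0
    if clamped:
        slope = 0.0
        intercept = ym
    else:
        intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    return intercept, slope, float(resid @ resid), clamped


# ---------------------------------------------------------------------------
# Dose-response model
# ---------------------------------------------------------------------------

class DoseResponseModel:
    """Probit-style survival model: pct = 100 * (1 - Phi((log10 c - mu)/sigma)).

    Zero-concentration rows are normalisation controls and are dropped from
    the residuals at construction.
    """

    fitter_name = "dose"
    scale = "log10"
    _SIGMA_FLOOR = 1e-9
    _RESTART_JITTER = ((0.0, 1.0), (0.1, 2.0), (-0.1, 0.5), (0.2, 4.0), (-0.2, 0.25))

    def __init__(self, percent_survival, concentration_mM,
                 strain_id="", replicate_id=""):
        pct = np.asarray(percent_survival, dtype=float)
        c = np.asarray(concentration_mM, dtype=float)
        if pct.shape != c.shape or pct.ndim != 1:
            raise ValueError("percent_survival and concentration_mM must be 1-d and equal length")
        if np.any(~np.isfinite(pct)) or np.any(pct < 0):
            raise ValueError("percent_survival must be finite and >= 0")
        if np.any(~np.isfinite(c)) or np.any(c < 0):
            raise ValueError("concentration_mM must be finite and >= 0")
        keep = c > 0
        self.n_controls = int(np.sum(~keep))
        self.percent_survival = pct[keep]
        self.concentration_mM = c[keep]
        self.strain_id = strain_id
        self.replicate_id = replicate_id
        self.nobs = int(keep.sum())

    @classmethod
    def from_observations(cls, observations):
        observations = list(observations)
        if not observations:
            raise HeteroresError("no observations supplied")
        _check_single_strain(observations)
        reps = {o.replicate_id for o in observations}
        return cls(
            [o.percent_survival for o in observations],
            [o.concentration_mM for o in observations],
            strain_id=observations[0].strain_id,
            replicate_id=reps.pop() if len(reps) == 1 else "pooled",
        )

    @classmethod
    def from_dataframe(cls, df, survival_col="percent_survival",
                       concentration_col="concentration_mM"):
        strain = str(df["strain_id"].iloc[0]) if "strain_id" in df else ""
        reps = set(df["replicate_id"].astype(str)) if "replicate_id" in df else set()
        return cls(
            df[survival_col].to_numpy(float),
            df[concentration_col].to_numpy(float),
            strain_id=strain,
            replicate_id=reps.pop() if len(reps) == 1 else "pooled",
        )

    def observations(self):
        return [
            DoseResponseObservation(self.strain_id, self.replicate_id, c, p)
            for c, p in zip(self.concentration_mM, self.percent_survival)
        ]

    def predict(self, params, concentration_mM):
        mu, sigma = params
        logc = np.log10(np.asarray(concentration_mM, dtype=float))
        sigma = max(sigma, self._SIGMA_FLOOR)
        return 100.0 * norm.sf((logc - mu) / sigma)

    def _residuals(self, params):
        return self.percent_survival - self.predict(params, self.concentration_mM)

    def fit(self) -> ResistanceFitResults:
        if self.nobs < 3:
            raise UnderDeterminedFitError(
                "need >= 3 non-control dose-response points"
            )
        above = self.percent_survival > 50.0
        if above.all() or (~above).all():
            raise UnderDeterminedFitError(
                "dose-response data must span both sides of 50% survival "
                "(all-surviving or all-dead data carry no information on the median)"
            )
        # init: log10 of the concentration whose survival is nearest 50%
        mu0 = float(np.log10(
            self.concentration_mM[np.argmin(np.abs(self.percent_survival - 50.0))]
        ))
        sigma0 = 0.05
        best = None
        for dmu, fsig in self._RESTART_JITTER:  # first entry = plain start
            sol = least_squares(
                self._residuals,
                x0=[mu0 + dmu, sigma0 * fsig],
                bounds=([-6.0, self._SIGMA_FLOOR], [6.0, 5.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if sol.success:
                best = sol
                break
        if best is None:
            raise ConvergenceError(
                f"dose-response fit failed to converge after "
                f"{len(self._RESTART_JITTER)} restarts (strain={self.strain_id})"
            )
        mu, sigma = best.x
        clamped = sigma <= 10 * self._SIGMA_FLOOR
        if clamped:
            sigma = 0.0
        rss = float(2.0 * best.cost)
        return ResistanceFitResults(self, mu, sigma, rss, True, clamped)


# ---------------------------------------------------------------------------
# Aggregation across biological replicates
# ---------------------------------------------------------------------------

_AGG_PARAMS = ("ic50_mM", "heteroresistance", "mic_model_mM")


@dataclass
class AggregateFit:
    """Mean and SEM of fitted parameters across biological replicates."""

    strain_id: str
    n_fits: int
    mean: dict
    sem: dict
    sem_defined: bool

    def summary(self) -> str:
        lines = [
            f"Aggregate over {self.n_fits} replicate fit(s) (strain={self.strain_id})",
            "-" * 56,
        ]
        for p in _AGG_PARAMS:
            lines.append(f"{p:<20}{self.mean[p]:12.4f} +/- {self.sem[p]:.4f} (SEM)")
        if not self.sem_defined:
            lines.append("note: single fit, SEM reported as 0 (undefined)")
        return "\n".join(lines)

    def to_row(self) -> dict:
        row = {"strain_id": self.strain_id, "replicate_id": "mean", "n_fits": self.n_fits}
        for p in _AGG_PARAMS:
            row[p] = self.mean[p]
            row[f"{p}_sem"] = self.sem[p]
        return row


def aggregate_fits(per_replicate_fits) -> AggregateFit:
    """Arithmetic mean and SEM (sample SD / sqrt(k)) of each parameter.

    MIC_MODEL is averaged over per-replicate values, not recomputed from the
    mean location and spread.
    """
    fits = list(per_replicate_fits)
    if not fits:
        raise HeteroresError("aggregate_fits requires at least one fit")
    values = {
        "ic50_mM": np.array([f.ic50_mM for f in fits]),
        "heteroresistance": np.array([f.heteroresistance for f in fits]),
        "mic_model_mM": np.array([f.mic_model_mM() for f in fits]),
    }
    k = len(fits)
    mean = {p: float(v.mean()) for p, v in values.items()}
    if k > 1:
        sem = {p: float(v.std(ddof=1) / np.sqrt(k)) for p, v in values.items()}
    else:
        sem = {p: 0.0 for p in values}
    strains = {f.strain_id for f in fits}
    return AggregateFit(
        strain_id=strains.pop() if len(strains) == 1 else "mixed",
        n_fits=k,
        mean=mean,
        sem=sem,
        sem_defined=k > 1,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Percentile intervals and prediction envelope from a case bootstrap."""

    B: int
    n_failed: int
    conf_int: dict
    estimates: "np.ndarray" = field(repr=False)
    envelope_x: "np.ndarray" = field(repr=False)
    envelope_lo: "np.ndarray" = field(repr=False)
    envelope_hi: "np.ndarray" = field(repr=False)


def _build_model(observations, fitter, scale):
    if fitter == "inoculum":
        return InoculumEffectModel.from_observations(observations, scale=scale)
    if fitter == "dose":
        return DoseResponseModel.from_observations(observations)
    raise ValueError(f"unknown fitter {fitter!r}; expected 'inoculum' or 'dose'")


def bootstrap_fit(observations, fitter="inoculum", B=1000, seed=None,
                  scale="log10", envelope_points=50) -> BootstrapResult:
    """Case-resampling bootstrap of a resistance fit.

    Rows (observations) are resampled with replacement within the dataset and
    the chosen fitter is re-run on each resample.  Per-parameter 95%
    percentile intervals (2.5/97.5) are reported for IC50, heteroresistance
    and MIC_MODEL, together with a 95% envelope of predicted curves over the
    observed range.  Deterministic for a given ``seed``.  Resamples that fail
    to fit are dropped and counted; more than 20% failures raises
    :class:`BootstrapUnstableError`.
    """
    if B < 100:
        raise ValueError(f"B must be >= 100, got {B}")
    observations = list(observations)
    model = _build_model(observations, fitter, scale)
    base = model.fit()  # validates the data before resampling

    if fitter == "inoculum":
        xs = model.inoculum_cells
        grid = np.logspace(np.log10(xs.min()), np.log10(xs.max()), envelope_points)
    else:
        xs = model.concentration_mM
        grid = np.linspace(xs.min(), xs.max(), envelope_points)

    rng = np.random.default_rng(seed)
    n = len(observations)
    estimates = []
    curves = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        resample = [observations[i] for i in idx]
        try:
            res = _build_model(resample, fitter, scale).fit()
        except HeteroresError:
            n_failed += 1
            continue
        estimates.append([res.ic50_mM, res.heteroresistance, res.mic_model_mM()])
        curves.append(res.model.predict([res.mu, res.sigma], grid))
    if n_failed > 0.2 * B:
        raise BootstrapUnstableError(
            f"{n_failed}/{B} bootstrap resamples failed to fit"
        )
    est = np.asarray(estimates)
    lo, hi = np.percentile(est, [2.5, 97.5], axis=0)
    conf_int = {
        name: (float(lo[j]), float(hi[j]))
        for j, name in enumerate(_AGG_PARAMS)
    }
    curves = np.asarray(curves)
    env_lo, env_hi = np.percentile(curves, [2.5, 97.5], axis=0)
    base.ci = conf_int
    return BootstrapResult(
        B=B,
        n_failed=n_failed,
        conf_int=conf_int,
        estimates=est,
        envelope_x=grid,
        envelope_lo=env_lo,
        envelope_hi=env_hi,
    )


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_inoculum_effect(observations, distribution_scale="log10") -> ResistanceFitResults:
    """Fit IC50 and heteroresistance to MIC-versus-inoculum observations."""
    return InoculumEffectModel.from_observations(
        observations, scale=distribution_scale
    ).fit()


def fit_dose_response(observations) -> ResistanceFitResults:
    """Fit IC50 and heteroresistance to percent-survival observations."""
    return DoseResponseModel.from_observations(observations).fit()
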