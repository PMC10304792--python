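"""The lognormal single-cell resistance distribution and its closed forms.

A clonal microbial population is modelled as having lognormally distributed
single-cell resistances: ``log10(resistance in mM) ~ Normal(mu, sigma)``.
Two population parameters follow:

* **IC50** = ``10**mu`` — the population-median resistance (mM), the
  concentration inhibiting half the cells;
* **heteroresistance** = ``sigma`` — the cell-to-cell spread of resistance
  on the log10(mM) scale.

The inoculum effect falls out of extreme-value statistics: an inoculum of
``n`` cells grows at concentration ``c`` iff its *most resistant* cell
exceeds ``c``, so the experimentally observed MIC tracks the expected
maximum of ``n`` draws.  For normal samples, Blom's classical approximation
gives

    E[max(x1..xn)] = mu + sigma * Phi^-1((n - pi/8) / (n - pi/4 + 1))

which this module exposes as :func:`expected_max_quantile` (the standard
normal quantile ``z(n)``) and :meth:`ResistanceDistribution.predicted_mic_exp`
(the concentration scale version).

The MIC of a standard 10^4-cell inoculum is conventionally summarised as
MIC_MODEL, the 99.99th percentile of the single-cell distribution
(``z = Phi^-1(0.9999) ~= 3.7190``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = ["expected_max_quantile", "ResistanceDistribution", "MIC_MODEL_PERCENTILE"]

#: Percentile of the single-cell distribution defining MIC_MODEL.
MIC_MODEL_PERCENTILE = 0.9999


def expected_max_quantile(n):
    """Standard-normal quantile of the expected maximum of ``n`` draws.

    Returns ``z(n) = Phi^-1((n - pi/8) / (n - pi/4 + 1))``, Blom's
    approximation to ``E[max of n iid standard normals]``.  ``z(1) == 0``
    exactly and ``z`` is strictly increasing in ``n``.

    Parameters
    ----------
    n : float or array_like
        Cell count(s); need not be integral. Must be finite and >= 1.
    """
    arr = np.asarray(n, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 1):
        raise ValueError(f"cell count n must be finite and >= 1, got {n!r}")
    z = norm.ppf((arr - math.pi / 8.0) / (arr - math.pi / 4.0 + 1.0))
    return float(z) if np.isscalar(n) or arr.ndim == 0 else z


@dataclass(frozen=True)
class ResistanceDistribution:
    """Lognormal distribution of single-cell resistances.

    Parameters
    ----------
    mu_log10 : float
        Location of log10(single-cell resistance), in log10(mM).
        ``10**mu_log10`` is the IC50.
    sigma_log10 : float
        Spread of log10(single-cell resistance) — the heteroresistance.
        Must be >= 0; zero describes a perfectly homogeneous population
        (no inoculum effect).
    """

    mu_log10: float
    sigma_log10: float

    def __post_init__(self):
        if not math.isfinite(self.mu_log10):
            raise ValueError(f"mu_log10 must be finite, got {self.mu_log10!r}")
        if not math.isfinite(self.sigma_log10) or self.sigma_log10 < 0:
            raise ValueError(
                f"sigma_log10 (heteroresistance) must be finite and >= 0, "
                f"got {self.sigma_log10!r}"
            )

    @property
    def ic50_mM(self) -> float:
        """Population-median resistance, ``10**mu_log10`` (mM)."""
        return 10.0 ** self.mu_log10

    @property
    def heteroresistance(self) -> float:
        """Alias for ``sigma_log10`` under its field name."""
        return self.sigma_log10

    def predicted_mic_exp(self, n):
        """Expected MIC (mM) of an ``n``-cell inoculum.

        ``10**(mu + sigma * z(n))`` with ``z`` from
        :func:`expected_max_quantile`; equals the IC50 at ``n = 1`` and is
        non-decreasing in ``n``.
        """
        return 10.0 ** (self.mu_log10 + self.sigma_log10 * expected_max_quantile(n))

    def mic_model(self, percentile: float = MIC_MODEL_PERCENTILE) -> float:
        """Concentration (mM) inhibiting the given fraction of cells.

        With the default percentile (0.9999) this is MIC_MODEL, the
        conventional model-predicted MIC for a 10^4-cell inoculum:
        ``10**(mu + sigma * Phi^-1(0.9999))``.  Always >= IC50, with
        equality iff ``sigma_log10 == 0``.
        """
        if not (0.0 < percentile < 1.0):
            raise ValueError(f"percentile must lie in (0, 1), got {percentile!r}")
        return 10.0 ** (self.mu_log10 + self.sigma_log10 * norm.ppf(percentile))

    def survival_fraction(self, c):
        """Fraction of cells whose resistance exceeds concentration ``c`` (mM).

        ``1 - Phi((log10 c - mu) / sigma)``.  For a homogeneous population
        (``sigma == 0``) this degenerates to a step function: 1 below the
        IC50, 0 above it, and 0.5 at exactly the IC50.
        """
        arr = np.asarray(c, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"concentration must be finite and > 0, got {c!r}")
        logc = np.log10(arr)
        if self.sigma_log10 == 0.0:
            s = np.where(
                logc < self.mu_log10, 1.0, np.where(logc > self.mu_log10, 0.0, 0.5)
            )
        else:
            s = norm.sf((logc - self.mu_log10) / self.sigma_log10)
        return float(s) if np.isscalar(c) or arr.ndim == 0 else s

    def cdf_log10(self, z):
        """CDF of log10(resistance) at log10-concentration ``z`` (internal)."""
        if self.sigma_log10 == 0.0:
            return np.where(
                z > self.mu_log10, 1.0, np.where(z < self.mu_log10, 0.0, 0.5)
            )
        return norm.cdf((np.asarray(z, dtype=float) - self.mu_log10) / self.sigma_log10)
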