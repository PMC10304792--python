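"""Synthetic single-cell populations and in-silico versions of both assays.

The simulator emulates

* the **broth microdilution inoculum-effect assay**: for each biological
  replicate and inoculum size, wells along an arithmetic concentration grid
  are inoculated (cell numbers optionally Poisson-distributed around the
  nominal size) and scored for growth; the MIC_EXP is the lowest
  concentration at which the chosen scoring rule is met;
* the **agar dose-response assay**: cells plated at each concentration,
  CFU ~ Binomial(cells, survival fraction), percent survival normalised to
  the zero-concentration control.

A well grows iff at least one of its cells has resistance strictly above
the well concentration.  Rather than materialising every cell, wells draw
the population *maximum* directly through the inverse CDF of the max order
statistic (``max = mu + sigma * Phi^-1(U^(1/n))``), which is exact and O(1)
per well.  Growth dynamics are not modelled: growth is a binary endpoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .distribution import ResistanceDistribution
from .exceptions import HeteroresError, SimulationDesignError
from .models import DoseResponseObservation, InoculumMicObservation

__all__ = [
    "AssayDesign",
    "PanelData",
    "sample_population",
    "simulate_well",
    "simulate_mic_exp",
    "simulate_dose_response",
    "generate_panel",
]


@dataclass(frozen=True)
class AssayDesign:
    """Design of the simulated inoculum-effect assay.

    Defaults mirror the broth microdilution protocol: inoculum sizes 10^2 to
    10^5 cells/well, an arithmetic concentration grid in steps of 0.125 mM up
    to the 20 mM stock, four technical replicate wells per concentration, six
    biological replicates, and Poisson variation of the actual cell number
    around the nominal inoculum.

    ``scoring_rule``:

    * ``"any-clear"`` (default) — MIC_EXP is the lowest concentration with no
      growth in at least one of the technical replicate wells (the literal
      protocol rule);
    * ``"all-clear"`` — lowest concentration with no growth in *any* well
      (the conventional MIC reading).
    """

    inoculum_sizes: tuple = (1e2, 1e3, 1e4, 1e5)
    concentration_start: float = 0.125
    concentration_increment: float = 0.125
    concentration_max: float = 20.0
    technical_replicates: int = 4
    biological_replicates: int = 6
    poisson_inoculum: bool = True
    scoring_rule: str = "any-clear"

    def __post_init__(self):
        if self.concentration_increment <= 0:
            raise ValueError("concentration increment must be > 0")
        if self.concentration_start <= 0 or self.concentration_max < self.concentration_start:
            raise ValueError("concentration grid must span positive values")
        if any(n < 1 for n in self.inoculum_sizes) or not self.inoculum_sizes:
            raise ValueError("inoculum sizes must all be >= 1")
        if self.technical_replicates < 1 or self.biological_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.scoring_rule not in ("any-clear", "all-clear"):
            raise ValueError(
                f"scoring_rule must be 'any-clear' or 'all-clear', got {self.scoring_rule!r}"
            )

    @property
    def concentration_grid(self) -> np.ndarray:
        return np.arange(
            self.concentration_start,
            self.concentration_max + 1e-12,
            self.concentration_increment,
        )


def sample_population(dist: ResistanceDistribution, n, rng) -> np.ndarray:
    """Draw ``n`` independent single-cell resistances (mM)."""
    n = int(n)
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    return 10.0 ** (dist.mu_log10 + dist.sigma_log10 * rng.standard_normal(n))


def _max_log10_resistance(dist, n_cells, rng):
    """log10 of the maximum resistance among ``n_cells`` cells, exactly.

    Uses the inverse CDF of the max order statistic: if U ~ Uniform(0,1),
    Phi^-1(U^(1/n)) is distributed as the maximum of n standard normals.
    Wells with 0 cells get -inf (no cell, no growth).
    """
    n_cells = np.asarray(n_cells)
    u = rng.random(n_cells.shape)
    with np.errstate(divide="ignore"):
        # exp(log(u)/n) is a numerically stable u**(1/n) for large n
        zmax = norm.ppf(np.exp(np.log(u) / np.maximum(n_cells, 1)))
    out = dist.mu_log10 + dist.sigma_log10 * zmax
    return np.where(n_cells > 0, out, -np.inf)


def simulate_well(dist: ResistanceDistribution, n_cells, c, rng, size=None):
    """Growth outcome of a well with ``n_cells`` cells at concentration ``c`` (mM).

    Growth occurs iff at least one cell's resistance strictly exceeds ``c``,
    i.e. with probability ``1 - Phi((log10 c - mu)/sigma)**n_cells``.
    With ``size`` given, returns a boolean array of that many independent wells.
    """
    if n_cells < 0:
        raise ValueError(f"n_cells must be >= 0, got {n_cells}")
    if c <= 0:
        raise ValueError(f"concentration must be > 0, got {c}")
    shape = () if size is None else (int(size),)
    counts = np.full(shape if shape else (1,), int(n_cells))
    grown = _max_log10_resistance(dist, counts, rng) > np.log10(c)
    return bool(grown[0]) if size is None else grown


def _score_mic(clear_counts, grid, technical_replicates, scoring_rule):
    """Lowest grid concentration meeting the scoring rule, or NaN if none.

    ``clear_counts[i]`` is the number of non-growing wells at ``grid[i]``.
    Because an any-clear success is implied by an all-clear success on the
    same wells, any-clear MIC <= all-clear MIC on identical draws.
    """
    need = 1 if scoring_rule == "any-clear" else technical_replicates
    ok = clear_counts >= need
    if not ok.any():
        return float("nan")
    return float(grid[int(np.argmax(ok))])


def simulate_mic_exp(dist: ResistanceDistribution, design: AssayDesign, rng,
                     strain_id="sim"):
    """Simulate the inoculum-effect assay; returns InoculumMicObservation list.

    Every concentration x technical-replicate combination is an independent
    well (fresh cells), as on a real microplate.  Observations whose grid was
    exhausted without meeting the scoring rule are returned flagged
    ``censored=True`` with a warning; if *every* observation is censored a
    :class:`SimulationDesignError` is raised.
    """
    grid = design.concentration_grid
    log_grid = np.log10(grid)
    p_tail = dist.survival_fraction(grid[-1])
    if p_tail > 1e-9 * max(design.inoculum_sizes):
        warnings.warn(
            f"concentration grid may not cover the resistance tail: "
            f"P(cell resists {grid[-1]:g} mM) = {p_tail:.3g}",
            stacklevel=2,
        )
    observations = []
    n_censored = 0
    for b in range(design.biological_replicates):
        rep = f"b{b + 1}"
        for nominal in design.inoculum_sizes:
            shape = (len(grid), design.technical_replicates)
            if design.poisson_inoculum:
                n_cells = rng.poisson(nominal, size=shape)
            else:
                n_cells = np.full(shape, int(round(nominal)))
            max_res = _max_log10_resistance(dist, n_cells, rng)
            grown = max_res > log_grid[:, None]
            clear = design.technical_replicates - grown.sum(axis=1)
            mic = _score_mic(clear, grid, design.technical_replicates,
                             design.scoring_rule)
            censored = not np.isfinite(mic)
            n_censored += censored
            observations.append(
                InoculumMicObservation(
                    strain_id=strain_id,
                    replicate_id=rep,
                    inoculum_cells=float(nominal),
                    mic_exp_mM=mic,
                    censored=censored,
                )
            )
    if n_censored == len(observations):
        raise SimulationDesignError(
            "concentration grid exhausted for every replicate; extend the grid"
        )
    if n_censored:
        warnings.warn(
            f"{n_censored} observation(s) censored (grid exhausted); "
            "they are excluded from fits",
            stacklevel=2,
        )
    return observations


def simulate_dose_response(dist: ResistanceDistribution, concentrations, rng,
                           inoculum_sizes=(1e4, 1e2), biological_replicates=3,
                           poisson_inoculum=True, strain_id="sim"):
    """Simulate the plating dose-response assay.

    ``concentrations`` must include 0 (the normalisation control).  For each
    biological replicate and nominal inoculum, CFU at concentration ``c`` is
    Binomial(cells plated, survival fraction at c) and percent survival is
    ``100 * CFU(c) / CFU(0)``.  The two default inocula resolve different
    survival ranges (10^4 cells resolves the deep tail, 10^2 the upper range).
    Replicates whose control plate has zero CFU are dropped with a warning.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if not np.any(concentrations == 0):
        raise ValueError("concentrations must include 0 (the control plate)")
    test_c = concentrations[concentrations > 0]
    observations = []
    for b in range(biological_replicates):
        rep = f"b{b + 1}"
        for nominal in inoculum_sizes:
            surv = np.array([dist.survival_fraction(c) for c in test_c])
            if poisson_inoculum:
                plated0 = int(rng.poisson(nominal))
                plated = rng.poisson(nominal, size=len(test_c))
            else:
                plated0 = int(round(nominal))
                plated = np.full(len(test_c), plated0)
            cfu0 = plated0  # survival fraction at c=0 is 1
            if cfu0 == 0:
                warnings.warn(
                    f"control plate with zero CFU in replicate {rep}; dropped",
                    stacklevel=2,
                )
                continue
            cfu = rng.binomial(plated, surv)
            observations.append(
                DoseResponseObservation(strain_id, rep, 0.0, 100.0)
            )
            for c, k in zip(test_c, cfu):
                observations.append(
                    DoseResponseObservation(
                        strain_id, rep, float(c), 100.0 * k / cfu0
                    )
                )
    return observations


@dataclass
class PanelData:
    """Full synthetic dataset for a strain panel plus the ground truth."""

    mic_observations: list
    dose_observations: list
    truth: "pd.DataFrame" = field(repr=False)


def generate_panel(strain_specs, design: AssayDesign, rng,
                   dose_concentrations=None) -> PanelData:
    """Simulate both assays for a panel of strains.

    ``strain_specs`` is an iterable of ``(strain_id, species, mu_log10,
    sigma_log10)``.  Returns simulated MIC and dose-response observations for
    every strain together with the ground-truth parameter table (for
    parameter-recovery scoring).  Duplicate strain ids are rejected.
    """
    specs = list(strain_specs)
    if not specs:
        raise HeteroresError("panel needs at least one strain")
    ids = [s[0] for s in specs]
    if len(set(ids)) != len(ids):
        raise HeteroresError("duplicate strain_id in panel specification")
    mic_obs, dose_obs, truth_rows = [], [], []
    for strain_id, species, mu, sigma in specs:
        dist = ResistanceDistribution(mu, sigma)
        mic_obs.extend(simulate_mic_exp(dist, design, rng, strain_id=strain_id))
        if dose_concentrations is None:
            hi = dist.mic_model() * 1.5
            conc = np.concatenate([[0.0], np.linspace(dist.ic50_mM * 0.5, hi, 10)])
        else:
            conc = np.asarray(dose_concentrations, dtype=float)
        dose_obs.extend(
            simulate_dose_response(dist, conc, rng, strain_id=strain_id)
        )
        truth_rows.append(
            {
                "strain_id": strain_id,
                "species": species,
                "true_mu_log10": mu,
                "true_sigma_log10": sigma,
            }
        )
    return PanelData(mic_obs, dose_obs, pd.DataFrame(truth_rows))
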