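"""Cross-strain panel statistics.

Given per-strain resistance parameters (heteroresistance, IC50, MIC_MODEL),
this module computes the panel-level comparisons used to relate the three
quantities: Pearson correlations (one- or two-tailed t-based p-values),
Welch two-sample t-tests between species groups, sample standard deviations
(optionally on log10-transformed values — the natural scale for comparing
IC50 variation), and a combined report with optional strain exclusion for
outlier re-analysis.

A transcription of the 29-strain Zygosaccharomyces sorbic acid panel ships
with the package (:func:`load_zygo_panel`).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateCorrelationError, HeteroresError

__all__ = [
    "StrainRecord",
    "CorrelationResult",
    "pearson",
    "welch_t",
    "sample_sd",
    "panel_report",
    "PanelReport",
    "load_zygo_panel",
    "records_to_frame",
]

PARAMETERS = ("heteroresistance", "ic50_mM", "mic_model_mM")
PAIRS = tuple(combinations(PARAMETERS, 2))


@dataclass(frozen=True)
class StrainRecord:
    """One strain's resistance parameters (a row of a panel table)."""

    strain_id: str
    species: str
    heteroresistance: float
    ic50_mM: float
    mic_model_mM: float

    def __post_init__(self):
        if not self.species:
            raise ValueError("species must be non-empty")
        for name in PARAMETERS:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with t-distribution p-values.

    ``p_one_tailed`` is for the observed direction of association, i.e.
    half the two-tailed value.
    """

    pair: tuple
    n: int
    r: float
    p_two_tailed: float
    p_one_tailed: float


def pearson(x, y, tail="two", pair=("x", "y")) -> CorrelationResult:
    """Pearson correlation with p from t = r*sqrt((n-2)/(1-r^2)), df = n-2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 for a correlation, got n={len(x)}")
    if tail not in ("two", "one"):
        raise ValueError(f"tail must be 'two' or 'one', got {tail!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateCorrelationError("correlation undefined for constant input")
    r, p_two = stats.pearsonr(x, y)
    return CorrelationResult(
        pair=tuple(pair),
        n=len(x),
        r=float(r),
        p_two_tailed=float(p_two),
        p_one_tailed=float(p_two) / 2.0,
    )


def welch_t(a, b):
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, df, p_two_tailed)`` with the Welch–Satterthwaite degrees of
    freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        df = float(len(a) + len(b) - 2)  # identical constant groups
    else:
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def sample_sd(x, log10_transform=False) -> float:
    """Sample standard deviation (n-1 denominator), optionally of log10(x)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError(f"need n >= 2 for a standard deviation, got n={len(x)}")
    if log10_transform:
        x = np.log10(x)
    return float(np.std(x, ddof=1))


# ---------------------------------------------------------------------------
# Panel report
# ---------------------------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_id": r.strain_id,
                "species": r.species,
                "heteroresistance": r.heteroresistance,
                "ic50_mM": r.ic50_mM,
                "mic_model_mM": r.mic_model_mM,
            }
            for r in records
        ]
    )


@dataclass
class PanelReport:
    """Deterministic tabular report of panel-level statistics."""

    correlations: pd.DataFrame
    group_summary: pd.DataFrame
    welch_tests: pd.DataFrame
    ranges: pd.DataFrame
    excluded: tuple
    notices: tuple

    def to_text(self) -> str:
        parts = []
        if self.excluded:
            parts.append(f"Excluded strains: {', '.join(self.excluded)}")
        parts += [
            "== Pairwise Pearson correlations ==",
            self.correlations.to_string(index=False),
            "",
            "== Group summaries (mean / sample SD / SEM) ==",
            self.group_summary.to_string(index=False),
            "",
            "== Welch t-tests between species ==",
            self.welch_tests.to_string(index=False)
            if len(self.welch_tests)
            else "(no species pair with n >= 2 in both groups)",
            "",
            "== Parameter ranges ==",
            self.ranges.to_string(index=False),
        ]
        if self.notices:
            parts += ["", "Notices:"] + [f"  - {n}" for n in self.notices]
        return "\n".join(parts)


def _correlations_for(df, group, tail, notices):
    rows = []
    for a, b in PAIRS:
        try:
            res = pearson(df[a], df[b], tail=tail, pair=(a, b))
            rows.append(
                {
                    "group": group,
                    "x": a,
                    "y": b,
                    "n": res.n,
                    "r": res.r,
                    "p_two_tailed": res.p_two_tailed,
                    "p_one_tailed": res.p_one_tailed,
                }
            )
        except DegenerateCorrelationError:
            notices.append(f"{group}: correlation {a} vs {b} degenerate (constant input)")
            rows.append(
                {
                    "group": group,
                    "x": a,
                    "y": b,
                    "n": len(df),
                    "r": np.nan,
                    "p_two_tailed": np.nan,
                    "p_one_tailed": np.nan,
                }
            )
    return rows


def panel_report(records, exclude=None, group_by_species=True, tail="two") -> PanelReport:
    """All pairwise correlations, species summaries and Welch tests.

    ``exclude`` removes strains by id before any computation (outlier
    re-analysis); unknown ids raise.  Species subgroups with fewer than
    3 records are skipped for correlations with a notice.
    """
    records = list(records)
    exclude = tuple(str(e) for e in (exclude or ()))
    ids = {r.strain_id for r in records}
    unknown = [e for e in exclude if e not in ids]
    if unknown:
        raise HeteroresError(f"unknown strain id(s) in exclusion list: {unknown}")
    records = [r for r in records if r.strain_id not in exclude]
    if len(records) < 3:
        raise HeteroresError("need >= 3 records after exclusion for correlations")
    df = records_to_frame(records)

    notices: list = []
    corr_rows = _correlations_for(df, "all", tail, notices)
    summary_rows = []
    welch_rows = []
    range_rows = []

    def summarize(sub, label):
        for p in PARAMETERS:
            v = sub[p].to_numpy()
            summary_rows.append(
                {
                    "group": label,
                    "parameter": p,
                    "n": len(v),
                    "mean": float(v.mean()),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                    "sem": float(np.std(v, ddof=1) / np.sqrt(len(v)))
                    if len(v) > 1
                    else np.nan,
                }
            )

    summarize(df, "all")
    for p in PARAMETERS:
        range_rows.append(
            {"parameter": p, "min": float(df[p].min()), "max": float(df[p].max())}
        )

    if group_by_species:
        species = sorted(df["species"].unique())
        for sp in species:
            sub = df[df["species"] == sp]
            summarize(sub, sp)
            if len(sub) >= 3:
                corr_rows += _correlations_for(sub, sp, tail, notices)
            else:
                notices.append(f"{sp}: n={len(sub)} < 3, correlations skipped")
        for sp_a, sp_b in combinations(species, 2):
            a = df.loc[df["species"] == sp_a]
            b = df.loc[df["species"] == sp_b]
            if len(a) < 2 or len(b) < 2:
                notices.append(f"Welch test skipped for {sp_a} vs {sp_b} (n < 2)")
                continue
            for p in PARAMETERS:
                t, dof, pval = welch_t(a[p], b[p])
                welch_rows.append(
                    {
                        "parameter": p,
                        "group_a": sp_a,
                        "group_b": sp_b,
                        "n_a": len(a),
                        "n_b": len(b),
                        "mean_a": float(a[p].mean()),
                        "mean_b": float(b[p].mean()),
                        "t": t,
                        "df": dof,
                        "p_two_tailed": pval,
                    }
                )

    return PanelReport(
        correlations=pd.DataFrame(corr_rows),
        group_summary=pd.DataFrame(summary_rows),
        welch_tests=pd.DataFrame(welch_rows),
        ranges=pd.DataFrame(range_rows),
        excluded=exclude,
        notices=tuple(notices),
    )


def load_zygo_panel():
    """The bundled 29-strain Zygosaccharomyces sorbic acid panel."""
    with resources.files("heterores.data").joinpath("zygo_panel.csv").open() as fh:
        df = pd.read_csv(fh, comment="#", dtype={"strain_id": str})
    return [
        StrainRecord(
            strain_id=row.strain_id,
            species=row.species,
            heteroresistance=row.heteroresistance,
            ic50_mM=row.ic50_mM,
            mic_model_mM=row.mic_model_mM,
        )
        for row in df.itertuples()
    ]
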