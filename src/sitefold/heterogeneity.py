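"""Per-site heterogeneity of clinical and image features.

Categorical outcomes are tested for site association with a Pearson
chi-squared test (no continuity correction) on the site-by-class
contingency table, restricted to sites contributing at least a minimum
number of slides (default 20) so small sites do not dominate the variance
estimates.  Continuous image features are tested with one-way ANOVA across
sites (F = MS_between / MS_within, df_between = sites - 1).  Within one
report, p values are adjusted with the Benjamini-Hochberg step-up false
discovery rate at alpha = 0.05; missing outcome values are dropped
per-feature before tabulation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .manifest import MISSING, CATEGORICAL, CohortManifest

__all__ = [
    "ContingencyTable",
    "HeterogeneityResult",
    "AnovaResult",
    "filter_sites",
    "contingency_table",
    "chi_squared_heterogeneity",
    "bh_fdr",
    "anova_f",
    "heterogeneity_report",
    "DEFAULT_MIN_SLIDES",
    "DEFAULT_ALPHA",
]

DEFAULT_MIN_SLIDES = 20
DEFAULT_ALPHA = 0.05


@dataclass
class ContingencyTable:
    """Sites x classes count matrix for one categorical outcome."""

    counts: np.ndarray
    site_ids: list[str]
    class_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (sites x classes)")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")


@dataclass
class HeterogeneityResult:
    statistic: float
    df: int
    p: float
    q: float = float("nan")  # filled in by the FDR pass
    significant: bool = False


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    q: float = float("nan")
    significant: bool = False


def filter_sites(manifest: CohortManifest, min_slides: int = DEFAULT_MIN_SLIDES) -> CohortManifest:
    """Keep only sites contributing at least ``min_slides`` slides."""
    counts = manifest.slides_per_site()
    keep = [s for s, n in counts.items() if n >= min_slides]
    if not keep:
        raise ValueError(
            f"no site reaches the {min_slides}-slide inclusion threshold "
            f"(largest has {max(counts.values())})"
        )
    return manifest.subset(keep)


def contingency_table(manifest: CohortManifest, outcome: str) -> ContingencyTable:
    """Site-by-class slide counts for one categorical outcome.

    Missing outcome values are excluded before tabulation.
    """
    if manifest.column(outcome).kind != CATEGORICAL:
        raise ValueError(f"outcome {outcome!r} is not categorical")
    sites = manifest.site_ids
    classes = sorted(
        {r.outcomes.get(outcome) for r in manifest.records if r.outcomes.get(outcome) is not MISSING}
    )
    if not classes:
        raise ValueError(f"outcome {outcome!r} has no non-missing values")
    counts = np.zeros((len(sites), len(classes)), dtype=np.int64)
    s_idx = {s: i for i, s in enumerate(sites)}
    c_idx = {c: j for j, c in enumerate(classes)}
    for r in manifest.records:
        v = r.outcomes.get(outcome)
        if v is not MISSING:
            counts[s_idx[r.site_id], c_idx[v]] += 1
    return ContingencyTable(counts, list(sites), [str(c) for c in classes])


def chi_squared_heterogeneity(table: ContingencyTable) -> HeterogeneityResult:
    """Pearson chi-squared test of site-by-class homogeneity.

    No continuity correction; df = (rows - 1)(cols - 1).  A zero marginal
    (hence a zero expected count) is an error: merge sparse classes first.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 sites and 2 classes with positive totals")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError(
            "zero row/column marginal gives an expected count of 0; "
            "merge sparse classes or drop empty sites before testing"
        )
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return HeterogeneityResult(statistic=float(stat), df=int(df), p=float(p))


def bh_fdr(pvals: Sequence[float], alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: returns (q values, rejection flags).

    q values are monotone (step-up enforced); a test is rejected iff
    q <= alpha.
    """
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def anova_f(values_by_site: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way ANOVA of a continuous feature across sites.

    F = MS_between / MS_within with df_between = sites - 1 and
    df_within = N - sites.  Zero within-site variance yields +inf (perfect
    separation) or NaN (all values identical everywhere) markers.
    """
    groups = [np.asarray(v, dtype=np.float64) for v in values_by_site.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 sites")
    if any(g.size < 2 for g in groups):
        raise ValueError("every site needs at least 2 values")
    n_total = sum(g.size for g in groups)
    df_b = len(groups) - 1
    df_w = n_total - len(groups)
    grand = np.concatenate(groups).mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_w <= 1e-300:
        if ss_b <= 1e-300:
            return AnovaResult(float("nan"), df_b, df_w, float("nan"))
        return AnovaResult(float("inf"), df_b, df_w, 0.0)
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), df_b, df_w, p)


def heterogeneity_report(
    manifest: CohortManifest,
    features: pd.DataFrame | None = None,
    min_slides: int = DEFAULT_MIN_SLIDES,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-feature heterogeneity table with a single FDR family.

    Categorical outcome columns of the manifest are tested with the
    chi-squared test; columns of ``features`` (one row per slide, indexed
    or keyed by ``slide_id``) are tested with ANOVA across sites.  The BH
    correction is applied across all rows of one report.  Features that
    cannot be tested (all missing, single class, zero marginals) appear as
    ``status='skipped'`` rows rather than being dropped silently.
    """
    kept = filter_sites(manifest, min_slides)
    site_of_slide = {r.slide_id: r.site_id for r in kept.records}

    rows: list[dict] = []
    for col in kept.outcome_columns:
        if col.kind != CATEGORICAL:
            continue
        row = {"feature": col.name, "test": "chi2", "status": "ok"}
        try:
            res = chi_squared_heterogeneity(contingency_table(kept, col.name))
            row.update(statistic=res.statistic, df=float(res.df), p=res.p)
        except ValueError as exc:
            row.update(status="skipped", statistic=math.nan, df=math.nan, p=math.nan,
                       reason=str(exc))
        rows.append(row)

    if features is not None:
        feats = features.copy()
        if "slide_id" in feats.columns:
            feats = feats.set_index("slide_id")
        feats = feats.loc[[s for s in feats.index if s in site_of_slide]]
        site_series = pd.Series({s: site_of_slide[s] for s in feats.index})
        for col in feats.columns:
            row = {"feature": col, "test": "anova", "status": "ok"}
            values = pd.to_numeric(feats[col], errors="coerce")
            ok = values.notna()
            groups = {
                site: values[ok][site_series[ok] == site].to_numpy()
                for site in sorted(site_series[ok].unique())
            }
            groups = {s: v for s, v in groups.items() if v.size >= 2}
            try:
                if len(groups) < 2:
                    raise ValueError("fewer than 2 sites with >=2 values")
                res = anova_f(groups)
                row.update(statistic=res.F, df=float(res.df_between), p=res.p)
            except ValueError as exc:
                row.update(status="skipped", statistic=math.nan, df=math.nan,
                           p=math.nan, reason=str(exc))
            rows.append(row)

    report = pd.DataFrame(rows)
    report["q"] = math.nan
    report["significant"] = False
    testable = report["status"] == "ok"
    finite_p = testable & report["p"].notna()
    if finite_p.any():
        q, rej = bh_fdr(report.loc[finite_p, "p"].to_numpy(), alpha=alpha)
        report.loc[finite_p, "q"] = q
        report.loc[finite_p, "significant"] = rej
    n_skipped = int((~testable).sum())
    if n_skipped:
        warnings.warn(f"{n_skipped} feature(s) skipped in heterogeneity report", stacklevel=2)
    return report
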