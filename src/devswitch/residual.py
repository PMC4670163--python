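"""Age-corrected (residual) correlation between gene pairs.

Two complementary quantities for a pair of genes in one region:

* trend correlation — the correlation of the two fitted population trends
  evaluated at the shared sample ages; it captures whether one variant rises
  as the other falls across life.
* residual (age-corrected) correlation — the correlation of subject-level
  fluctuations around each trend; after the population effect of age is
  removed it captures whether the two genes co-vary from subject to subject.
  When trends are linear in the covariate this reduces to the classical
  partial correlation given age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionProfile
from .detrend import fit_trend_spline
from .screen import CorrelationResult, Method, fdr_bh


@dataclass
class AgeCorrectedResult:
    gene_a: str
    gene_b: str
    region: str
    raw: CorrelationResult
    trend_corr: float
    residual: CorrelationResult | None
    n_samples: int
    age_window: tuple[float, float] | None = None
    relaxed_fit: bool = False  # either gene's trend needed the relaxed noise bound


def _corr(x: np.ndarray, y: np.ndarray, method: Method) -> tuple[float, float]:
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def _restrict(profile: ExpressionProfile, lo: float, hi: float) -> ExpressionProfile:
    keep = [i for i, s in enumerate(profile.samples) if lo <= s.age_pcd <= hi]
    return ExpressionProfile(
        gene=profile.gene,
        values=profile.values[keep],
        samples=[profile.samples[i] for i in keep],
    )


def age_corrected_correlation(
    x: ExpressionProfile,
    y: ExpressionProfile,
    method: Method = "pearson",
    age_window: tuple[float, float] | None = None,
    **fit_kwargs,
) -> AgeCorrectedResult:
    """Raw, trend, and residual correlation for one gene pair.

    Trends are fitted to each gene independently on the (optionally
    age-windowed) shared samples; windowed analyses refit the trend inside
    the window rather than reusing a whole-life fit.
    """
    if [(s.sample_id, s.age_pcd) for s in x.samples] != [
        (s.sample_id, s.age_pcd) for s in y.samples
    ]:
        raise ValueError(
            f"profiles {x.gene!r} and {y.gene!r} have mismatched samples"
        )
    if age_window is not None:
        lo, hi = age_window
        x = _restrict(x, lo, hi)
        y = _restrict(y, lo, hi)
    if x.n < 8:
        raise ValueError(
            f"only {x.n} samples available (after windowing); need >= 8"
        )
    raw_r, raw_p = _corr(x.values, y.values, method)
    raw = CorrelationResult(rho=raw_r, p_value=raw_p, method=method, n_samples=x.n)

    model_x = fit_trend_spline(x, **fit_kwargs)
    model_y = fit_trend_spline(y, **fit_kwargs)
    if np.ptp(model_x.fitted) == 0 or np.ptp(model_y.fitted) == 0:
        trend_corr = float("nan")
    else:
        trend_corr = float(np.corrcoef(model_x.fitted, model_y.fitted)[0, 1])

    residual: CorrelationResult | None
    if np.ptp(model_x.residuals) == 0 or np.ptp(model_y.residuals) == 0:
        residual = None
    else:
        res_r, res_p = _corr(model_x.residuals, model_y.residuals, method)
        residual = CorrelationResult(
            rho=res_r, p_value=res_p, method=method, n_samples=x.n
        )
    return AgeCorrectedResult(
        gene_a=x.gene,
        gene_b=y.gene,
        region=x.samples[0].region if x.samples else "",
        raw=raw,
        trend_corr=trend_corr,
        residual=residual,
        n_samples=x.n,
        age_window=age_window,
        relaxed_fit=model_x.relaxed or model_y.relaxed,
    )


def partial_correlation(x, y, z) -> float:
    """Correlation of x and y after linearly removing z from both.

    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the linear-trend
    limit of the residual correlation.
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not len(x) == len(y) == len(z):
        raise ValueError("x, y, z must have equal length")
    if len(x) < 4:
        raise ValueError("need >= 4 observations")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom_sq = (1 - r_xz**2) * (1 - r_yz**2)
    if denom_sq <= 0:
        raise ValueError(
            "partial correlation undefined: a variable is collinear with z"
        )
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom_sq))


def apply_fdr_by_region(results: list[AgeCorrectedResult], alpha: float = 0.01) -> None:
    """BH-adjust residual p-values within each region's family of tested pairs."""
    by_region: dict[str, list[AgeCorrectedResult]] = {}
    for r in results:
        if r.residual is not None:
            by_region.setdefault(r.region, []).append(r)
    for group in by_region.values():
        qs = fdr_bh([r.residual.p_value for r in group])
        for r, q in zip(group, qs):
            r.residual.q_value = float(q)


def rank_pairs(
    table: pd.DataFrame,
    score: str = "neglog10_q",
    value_col: str = "q_value",
) -> pd.DataFrame:
    """Rank pairs by mean score across regions (missing regions excluded).

    ``table`` is long-format with columns gene_a, gene_b, region and the
    score source column. ``score`` is ``neglog10_q`` (mean -log10 of
    ``value_col``) or ``abs_rho`` (mean |value_col|). Ties break
    lexicographically on (gene_a, gene_b).
    """
    df = table.copy()
    if score == "neglog10_q":
        df["_score"] = -np.log10(df[value_col])
    elif score == "abs_rho":
        df["_score"] = df[value_col].abs()
    else:
        raise ValueError(f"unknown score {score!r}")
    means = (
        df.dropna(subset=["_score"])
        .groupby(["gene_a", "gene_b"])["_score"]
        .mean()
        .reset_index()
        .rename(columns={"_score": "mean_score"})
    )
    means = means.sort_values(
        by=["mean_score", "gene_a", "gene_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    means["rank"] = np.arange(1, len(means) + 1)
    return means
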