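"""Life-long trend anti-correlation screen.

For every candidate pair, in every brain region, correlate the two raw
expression profiles across age-sorted samples. Genes whose expression range
(max - min, log2 units) is below 1.5 are excluded as not differentially
expressed. p-values are FDR-adjusted (Benjamini-Hochberg) within the family
of all pairs tested in one region; a pair is a significant "switch" when its
adjusted q-value is below alpha and the correlation is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .candidates import CandidatePair
from .datatypes import ExpressionMatrix, ExpressionProfile

MIN_RANGE_DEFAULT = 1.5
ALPHA_DEFAULT = 0.01

Method = Literal["pearson", "spearman"]


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    method: str
    n_samples: int
    q_value: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"rho {self.rho} outside [-1, 1]")


@dataclass
class ScreenRecord:
    pair: CandidatePair
    region: str
    passed_range_filter: dict[str, bool]
    trend: CorrelationResult | None = None
    significant_anticorrelation: bool = False
    significant_correlation: bool = False  # on |rho|, sign ignored


def range_filter(profile: ExpressionProfile, min_range: float = MIN_RANGE_DEFAULT) -> bool:
    """True iff the profile's expression range (max - min) >= min_range."""
    if profile.n < 2:
        raise ValueError(f"profile {profile.gene!r} needs >= 2 samples")
    return profile.expression_range() >= min_range


def trend_correlation(
    x: ExpressionProfile, y: ExpressionProfile, method: Method = "pearson"
) -> CorrelationResult:
    """Correlation between two profiles over identical sample lists."""
    if [(s.sample_id, s.age_pcd) for s in x.samples] != [
        (s.sample_id, s.age_pcd) for s in y.samples
    ]:
        raise ValueError(
            f"profiles {x.gene!r} and {y.gene!r} have mismatched samples"
        )
    if x.n < 4:
        raise ValueError("need at least 4 shared samples")
    for p in (x, y):
        if np.ptp(p.values) == 0:
            raise ValueError(f"profile {p.gene!r} has zero variance")
    if method == "pearson":
        rho, p = stats.pearsonr(x.values, y.values)
    elif method == "spearman":
        rho, p = stats.spearmanr(x.values, y.values)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        rho=float(rho), p_value=float(p), method=method, n_samples=x.n
    )


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_region(
    matrix: ExpressionMatrix,
    pairs: list[CandidatePair],
    region: str,
    method: Method = "pearson",
    min_range: float = MIN_RANGE_DEFAULT,
    alpha: float = ALPHA_DEFAULT,
) -> list[ScreenRecord]:
    """Screen all candidate pairs in one region for anti-correlated trends.

    The FDR family is the set of pairs actually correlated in this region
    (both genes passing the range filter).
    """
    region_samples = [s for s in matrix.samples if s.region == region]
    if len(region_samples) < 4:
        raise ValueError(
            f"region {region!r} has {len(region_samples)} samples; need >= 4"
        )
    profile_cache: dict[str, ExpressionProfile] = {}
    passed_cache: dict[str, bool] = {}

    def get_profile(gene: str) -> ExpressionProfile:
        if gene not in profile_cache:
            profile_cache[gene] = matrix.profile(gene, region)
        return profile_cache[gene]

    def passed(gene: str) -> bool:
        if gene not in passed_cache:
            prof = get_profile(gene)
            passed_cache[gene] = (
                range_filter(prof, min_range) and np.ptp(prof.values) > 0
            )
        return passed_cache[gene]

    records: list[ScreenRecord] = []
    tested: list[ScreenRecord] = []
    for pair in pairs:
        flags = {pair.gene_a: passed(pair.gene_a), pair.gene_b: passed(pair.gene_b)}
        rec = ScreenRecord(pair=pair, region=region, passed_range_filter=flags)
        if all(flags.values()):
            rec.trend = trend_correlation(
                get_profile(pair.gene_a), get_profile(pair.gene_b), method
            )
            tested.append(rec)
        records.append(rec)
    if tested:
        qs = fdr_bh([r.trend.p_value for r in tested])
        for rec, q in zip(tested, qs):
            rec.trend.q_value = float(q)
            rec.significant_anticorrelation = q < alpha and rec.trend.rho < 0
            rec.significant_correlation = q < alpha
    return records
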