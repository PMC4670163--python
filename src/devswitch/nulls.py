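"""Null models and significance machinery for the switch screen.

* random-pairing baseline: the distribution of trend-correlation p-values
  over pairs drawn uniformly at random from the measured genes;
* paralog binning by sequence-overlap percentage, each bin yielding its own
  p-value distribution;
* a permutation enrichment test comparing the observed binned distribution
  against redrawn random pair sets, with add-one p-value estimates;
* a housekeeping-gene baseline for the residual-correlation analysis;
* uniform subject subsampling to bring a large cohort to a common scale.

All stochastic operations take an explicit seed or Generator and are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix

#: Default histogram edges on the -log10(p) axis; last bin is open-ended.
DEFAULT_BIN_EDGES = tuple(float(e) for e in range(11)) + (float("inf"),)


@dataclass
class PValueDistribution:
    label: str
    bin_edges: np.ndarray  # on the -log10(p) axis, left-closed/right-open
    bin_fractions: np.ndarray
    n_pairs: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.bin_fractions = np.asarray(self.bin_fractions, dtype=float)
        if self.n_pairs > 0:
            total = float(self.bin_fractions.sum())
            if np.any(self.bin_fractions < 0) or abs(total - 1.0) > 1e-12:
                raise ValueError("bin fractions must be nonnegative and sum to 1")

    @property
    def counts(self) -> np.ndarray:
        return np.rint(self.bin_fractions * self.n_pairs).astype(int)


@dataclass
class BinEnrichmentResult:
    bin_edges: np.ndarray
    observed_counts: np.ndarray
    null_mean: np.ndarray
    perm_p: np.ndarray
    n_permutations: int
    threshold: float

    @property
    def flagged(self) -> np.ndarray:
        """Indices of bins significantly enriched over the null."""
        return np.flatnonzero(self.perm_p < self.threshold)


def pearson_pvalues_for_pairs(
    values: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> np.ndarray:
    """Two-sided Pearson p-values for many (row_a, row_b) pairs, vectorized."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    if n < 4:
        raise ValueError("need >= 4 samples per profile")
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("zero-variance profiles present; filter them first")
    z = centered / norms[:, None]
    r = np.einsum("ij,ij->i", z[idx_a], z[idx_b])
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.maximum(p, np.finfo(float).tiny)


def _bin_pvalues(p: np.ndarray, bin_edges, label: str) -> PValueDistribution:
    edges = np.asarray(bin_edges, dtype=float)
    neglog = -np.log10(p)
    # np.histogram bins are [lo, hi) with the final bin closed; the default
    # final edge is +inf so the convention matches left-closed/right-open
    counts, _ = np.histogram(neglog, bins=edges)
    n = len(p)
    fractions = counts / n if n else counts.astype(float)
    return PValueDistribution(
        label=label, bin_edges=edges, bin_fractions=fractions, n_pairs=n
    )


def draw_random_pairs(
    n_genes: int, n_pairs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform unordered pairs without self-pairs (repeats across draws allowed)."""
    a = rng.integers(0, n_genes, size=n_pairs)
    b = rng.integers(0, n_genes - 1, size=n_pairs)
    b = np.where(b >= a, b + 1, b)  # uniform over the n_genes-1 non-self partners
    return a, b


def random_pair_baseline(
    matrix: ExpressionMatrix,
    region: str,
    n_pairs: int = 100_000,
    seed: int | None = None,
    bin_edges=DEFAULT_BIN_EDGES,
    label: str = "random",
) -> PValueDistribution:
    """Trend-correlation p-value distribution over random gene pairs in a region."""
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    idx = [i for i, s in enumerate(matrix.samples) if s.region == region]
    if not idx:
        raise KeyError(f"no samples for region {region!r}")
    values = matrix.values[:, idx]
    if values.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    rng = np.random.default_rng(seed)
    a, b = draw_random_pairs(values.shape[0], n_pairs, rng)
    p = pearson_pvalues_for_pairs(values, a, b)
    return _bin_pvalues(p, bin_edges, label)


def bin_paralogs_by_overlap(
    pairs: pd.DataFrame, bin_edges=(0.0, 30.0, 60.0, 100.0), overlap_col: str = "overlap"
) -> dict[str, pd.DataFrame]:
    """Group paralog pairs by sequence-overlap percentage.

    Bins are left-closed/right-open except the last, which includes its
    upper edge so overlap = 100 is kept.
    """
    edges = np.asarray(bin_edges, dtype=float)
    ov = pairs[overlap_col].to_numpy(dtype=float)
    if np.any((ov < 0) | (ov > 100)):
        raise ValueError("overlap values must lie in [0, 100]")
    groups: dict[str, pd.DataFrame] = {}
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        last = i == len(edges) - 2
        mask = (ov >= lo) & ((ov <= hi) if last else (ov < hi))
        key = f"[{lo:g},{hi:g}{']' if last else ')'}"
        groups[key] = pairs.loc[mask]
    return groups


def bin_enrichment_test(
    observed: PValueDistribution,
    null_sampler,
    n_permutations: int = 10_000,
    seed: int | None = None,
    threshold: float = 1e-3,
) -> BinEnrichmentResult:
    """Permutation test for per-bin enrichment of the observed distribution.

    ``null_sampler(rng, n_pairs)`` must return p-values for one redrawn
    random pair set of the observed size. Per bin,
    perm_p = (1 + #{permutations with count >= observed}) / (n_permutations + 1).
    """
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    if 1.0 / (n_permutations + 1) > threshold:
        raise ValueError(
            f"threshold {threshold} unreachable with {n_permutations} permutations"
        )
    rng = np.random.default_rng(seed)
    obs_counts = observed.counts
    exceed = np.zeros_like(obs_counts)
    total = np.zeros(len(obs_counts), dtype=float)
    for _ in range(n_permutations):
        p = null_sampler(rng, observed.n_pairs)
        counts = _bin_pvalues(p, observed.bin_edges, "perm").counts
        exceed += counts >= obs_counts
        total += counts
    perm_p = (1.0 + exceed) / (n_permutations + 1.0)
    return BinEnrichmentResult(
        bin_edges=observed.bin_edges,
        observed_counts=obs_counts,
        null_mean=total / n_permutations,
        perm_p=perm_p,
        n_permutations=n_permutations,
        threshold=threshold,
    )


def housekeeping_baseline(
    hkg_pvalues, pathway_pvalues, thresholds=None
) -> pd.DataFrame:
    """Fraction of pairs with residual-correlation p < 10^-theta, per threshold.

    Takes precomputed residual-correlation p-values for housekeeping-gene
    pairs and for pathway pairs, and returns the two fraction-vs-threshold
    curves plus their ratio (pathway / housekeeping).
    """
    if thresholds is None:
        thresholds = np.arange(1.0, 11.0)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid is empty")
    hkg = np.asarray(hkg_pvalues, dtype=float)
    path = np.asarray(pathway_pvalues, dtype=float)
    rows = []
    for theta in thresholds:
        cut = 10.0 ** (-theta)
        f_h = float(np.mean(hkg < cut)) if hkg.size else np.nan
        f_p = float(np.mean(path < cut)) if path.size else np.nan
        ratio = f_p / f_h if f_h and f_h > 0 else np.inf if f_p else np.nan
        rows.append(
            {
                "theta": theta,
                "frac_housekeeping": f_h,
                "frac_pathway": f_p,
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows)


def subsample_subjects(
    matrix: ExpressionMatrix, n_subjects: int, seed: int | None = None
) -> ExpressionMatrix:
    """Uniform draw of subjects without replacement; all their samples kept."""
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    subjects = matrix.subjects()
    if n_subjects > len(subjects):
        raise ValueError(
            f"requested {n_subjects} subjects but only {len(subjects)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(subjects, size=n_subjects, replace=False))
    keep = [i for i, s in enumerate(matrix.samples) if s.subject_id in chosen]
    return ExpressionMatrix(
        genes=list(matrix.genes),
        samples=[matrix.samples[i] for i in keep],
        values=matrix.values[:, keep],
    )
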