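"""End-to-end orchestration: candidates -> trend screen -> detrend -> residual
correlation -> ranked report.

Every stage parameter defaults to the analysis' standard values (30%
similarity, 1.5 log2 range, alpha 0.01, noise window 10). Outputs are TSVs
plus a JSON manifest recording the configuration and input checksums so any
stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .candidates import MIN_SIMILARITY_DEFAULT, enumerate_candidates, write_pairs
from .detrend import WINDOW_DEFAULT, loo_r2
from .io import read_expression, read_fasta, read_pathway_elements
from .residual import age_corrected_correlation, apply_fdr_by_region, rank_pairs
from .screen import ALPHA_DEFAULT, MIN_RANGE_DEFAULT, screen_region

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, entity: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {entity!r}: {cause}")
        self.stage = stage
        self.entity = entity


@dataclass
class PipelineConfig:
    expression: str
    metadata: str
    fasta: str
    elements: str
    outdir: str
    regions: tuple[str, ...] | None = None  # None = all regions in metadata
    method: str = "pearson"
    min_similarity: float = MIN_SIMILARITY_DEFAULT
    min_range: float = MIN_RANGE_DEFAULT
    alpha: float = ALPHA_DEFAULT
    window: int = WINDOW_DEFAULT
    age_transform: str = "log2"
    compute_loo: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, entity: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(name, entity, exc) from exc


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run all stages; returns the per-pair-per-region report, writes outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sequences = _stage("read_fasta", config.fasta, read_fasta, config.fasta)
    elements = _stage(
        "read_pathway_elements", config.elements, read_pathway_elements, config.elements
    )
    pairs = _stage(
        "enumerate_candidates",
        "candidate enumeration",
        enumerate_candidates,
        elements,
        sequences,
        config.min_similarity,
    )
    logger.info("candidates: %d pairs pass similarity >= %.2f",
                len(pairs), config.min_similarity)
    write_pairs(pairs, outdir / "pairs.tsv")

    matrix = _stage(
        "read_expression", config.expression, read_expression,
        config.expression, config.metadata,
    )
    regions = list(config.regions) if config.regions else matrix.regions

    rows = []
    all_results = []
    loo_cache: dict[tuple[str, str], float | None] = {}

    def loo_for(gene: str, region: str) -> float | None:
        key = (gene, region)
        if key not in loo_cache:
            prof = matrix.profile(gene, region)
            try:
                loo_cache[key] = loo_r2(
                    prof, window=config.window, age_transform=config.age_transform
                )
            except ValueError:
                loo_cache[key] = None
        return loo_cache[key]

    for region in regions:
        records = _stage(
            "screen_region", region, screen_region,
            matrix, pairs, region, config.method, config.min_range, config.alpha,
        )
        region_results = []
        for rec in records:
            result = None
            if rec.trend is not None:
                result = _stage(
                    "age_corrected_correlation",
                    f"{rec.pair.gene_a}/{rec.pair.gene_b} in {region}",
                    age_corrected_correlation,
                    matrix.profile(rec.pair.gene_a, region),
                    matrix.profile(rec.pair.gene_b, region),
                    config.method,
                    window=config.window,
                    age_transform=config.age_transform,
                )
                region_results.append(result)
            rows.append((rec, result))
        apply_fdr_by_region(region_results, alpha=config.alpha)
        all_results.extend(region_results)
        n_tested = sum(r.trend is not None for r in records)
        logger.info(
            "region %s: %d/%d pairs tested (range filter), %d significant switches",
            region, n_tested, len(records),
            sum(r.significant_anticorrelation for r in records),
        )

    report_rows = []
    for rec, result in rows:
        tested = rec.trend is not None
        resid = result.residual if result is not None else None
        sig_resid = bool(resid is not None and resid.q_value is not None
                         and resid.q_value < config.alpha)
        report_rows.append(
            {
                "gene_a": rec.pair.gene_a,
                "gene_b": rec.pair.gene_b,
                "region": rec.region,
                "similarity": rec.pair.similarity,
                "n_samples": rec.trend.n_samples if tested else 0,
                "trend_rho": rec.trend.rho if tested else np.nan,
                "trend_q": rec.trend.q_value if tested else np.nan,
                "trend_corr": result.trend_corr if result else np.nan,
                "resid_rho": resid.rho if resid else np.nan,
                "resid_p": resid.p_value if resid else np.nan,
                "resid_q": resid.q_value if resid else np.nan,
                "r2_loo_a": loo_for(rec.pair.gene_a, rec.region)
                if tested and config.compute_loo else np.nan,
                "r2_loo_b": loo_for(rec.pair.gene_b, rec.region)
                if tested and config.compute_loo else np.nan,
                "range_filtered": not tested,
                "relaxed_fit": result.relaxed_fit if result else False,
                "significant_switch": rec.significant_anticorrelation,
                "significant_residual": sig_resid,
            }
        )
    report_columns = [
        "gene_a", "gene_b", "region", "similarity", "n_samples",
        "trend_rho", "trend_q", "trend_corr", "resid_rho", "resid_p",
        "resid_q", "r2_loo_a", "r2_loo_b", "range_filtered", "relaxed_fit",
        "significant_switch", "significant_residual",
    ]
    report = pd.DataFrame(report_rows, columns=report_columns)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")

    ranking = rank_switches(report)
    ranking.to_csv(outdir / "ranking.tsv", sep="\t", index=False, float_format="%.6g")

    manifest = {
        "config": config.to_dict(),
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("expression", "metadata", "fasta", "elements")
        },
        "devswitch_version": __version__,
        "n_candidate_pairs": len(pairs),
        "regions": regions,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def rank_switches(report: pd.DataFrame) -> pd.DataFrame:
    """Rank pairs by mean anti-correlation significance across regions.

    A region contributes -log10(trend q) only where the pair was tested and
    the correlation is negative; other cells are treated as missing (the
    heat-map gray rule). Pairs gray everywhere are excluded.
    """
    df = report.copy()
    usable = (~df["range_filtered"]) & (df["trend_rho"] < 0)
    df.loc[~usable, "trend_q"] = np.nan
    df = df.dropna(subset=["trend_q"])
    if df.empty:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "mean_score", "rank"]
        )
    return rank_pairs(df, score="neglog10_q", value_col="trend_q")


def render_heatmap_table(
    report: pd.DataFrame, top_n: int = 20, alpha: float = ALPHA_DEFAULT
) -> pd.DataFrame:
    """Long-format pair x region table of -log10(trend q) with MISSING markers.

    A cell is MISSING (gray) when a gene failed the range filter or the
    q-value is not significant at alpha. Only the top_n pairs by cross-region
    mean score are kept.
    """
    if report.empty:
        raise ValueError("report is empty")
    ranking = rank_switches(report)
    keep = set(
        zip(ranking["gene_a"].head(top_n), ranking["gene_b"].head(top_n))
    )
    rows = []
    for row in report.itertuples():
        if (row.gene_a, row.gene_b) not in keep:
            continue
        gray = (
            row.range_filtered
            or not np.isfinite(row.trend_q)
            or row.trend_q >= alpha
            or row.trend_rho >= 0
        )
        rows.append(
            {
                "gene_a": row.gene_a,
                "gene_b": row.gene_b,
                "region": row.region,
                "score": "MISSING" if gray else f"{-np.log10(row.trend_q):.4g}",
            }
        )
    return pd.DataFrame(rows)
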