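"""Synthetic developmental cohorts with known ground truth.

The generator produces the statistical structure the analysis assumes:
smooth age trends (including anti-correlated logistic "switch" pairs),
a shared subject-level latent factor that induces residual correlation,
flat housekeeping-like profiles, and i.i.d. per-sample Gaussian noise:

    y_g(s) = trend_g(age_s) + lambda_g * u_s + eps_gs,
    u_s ~ N(0, shared_factor_sd^2),  eps_gs ~ N(0, noise_sd^2)

Trends are functions of log2 age (PCD), mirroring the detrending default.
The implied residual correlation between the two genes of a pair is

    lambda_a lambda_b su^2 / sqrt((lambda_a^2 su^2 + s^2)(lambda_b^2 su^2 + s^2))

which the pipeline should recover after detrending. Defaults describe a
cohort resembling the postmortem-brain studies this package targets: log2
intensities with baseline ~6, switch amplitudes of ~4 log2 units centred
perinatally, noise of ~0.5 log2 units, and ages spanning 10 post-conception
weeks to late adulthood with every developmental stage represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AGE_GROUPS, BIRTH_PCD, ExpressionMatrix, ProteinSequence, Sample

AGE_MIN_PCD = 70.0
AGE_MAX_PCD = 30_000.0  # ~81 years

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class TrendSpec:
    """A parametric population trend evaluated on log2 age."""

    kind: str = "logistic"  # constant | linear | logistic
    baseline: float = 6.0
    amplitude: float = 4.0      # logistic rise (negative = decline)
    midpoint_pcd: float = BIRTH_PCD
    tau: float = 0.5            # logistic slope, log2-age units
    slope: float = 0.0          # linear slope per log2-age unit

    def __call__(self, ages_pcd: np.ndarray) -> np.ndarray:
        u = np.log2(np.asarray(ages_pcd, dtype=float))
        if self.kind == "constant":
            return np.full_like(u, self.baseline)
        if self.kind == "linear":
            return self.baseline + self.slope * (u - math.log2(AGE_MIN_PCD))
        if self.kind == "logistic":
            z = (u - math.log2(self.midpoint_pcd)) / self.tau
            return self.baseline + self.amplitude / (1.0 + np.exp(-z))
        raise ValueError(f"unknown trend kind {self.kind!r}")


@dataclass(frozen=True)
class SwitchPairSpec:
    """Generative parameters for one gene pair."""

    trend_a: TrendSpec = TrendSpec(kind="logistic", amplitude=-4.0)
    trend_b: TrendSpec = TrendSpec(kind="logistic", amplitude=4.0)
    shared_factor_sd: float = 0.5
    loading_a: float = 1.0
    loading_b: float = 1.0
    noise_sd: float = 0.5

    @property
    def target_residual_corr(self) -> float:
        su2 = self.shared_factor_sd**2
        s2 = self.noise_sd**2
        num = self.loading_a * self.loading_b * su2
        den = math.sqrt(
            (self.loading_a**2 * su2 + s2) * (self.loading_b**2 * su2 + s2)
        )
        return num / den


@dataclass
class CohortConfig:
    regions: tuple[str, ...] = ("CBC",)
    n_subjects: int = 100
    pairs: dict[tuple[str, str], SwitchPairSpec] = field(default_factory=dict)
    n_noise_genes: int = 10
    n_housekeeping: int = 10
    noise_gene_sd: float = 1.0
    housekeeping_sd: float = 0.2
    baseline: float = 6.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("config.n_subjects: need >= 2")
        if not self.regions:
            raise ValueError("config.regions: need >= 1 region")
        for (a, b), spec in self.pairs.items():
            if a >= b:
                raise ValueError(f"config.pairs[{a},{b}]: genes must be ordered")
            if spec.noise_sd <= 0:
                raise ValueError(f"config.pairs[{a},{b}].noise_sd: must be > 0")
            if spec.shared_factor_sd < 0:
                raise ValueError(
                    f"config.pairs[{a},{b}].shared_factor_sd: must be >= 0"
                )


@dataclass
class SyntheticCohort:
    matrix: ExpressionMatrix
    trend_truth: dict[str, TrendSpec]
    pair_truth: dict[tuple[str, str], float]  # target residual correlation
    latent: dict[tuple[str, str, str], np.ndarray]  # (region, gene_a, gene_b) -> u_s
    ages: np.ndarray
    seed: int


def sample_ages(
    n_subjects: int, seed: int | np.random.Generator, design: str = "mixed"
) -> np.ndarray:
    """Subject ages in PCD covering the full developmental range.

    In the ``mixed`` design, when n >= 26 two subjects are placed uniformly
    inside each of the 13 developmental age groups and the remainder drawn
    log-uniform on [70, 30000] PCD; smaller cohorts are purely log-uniform.
    """
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    ages: list[float] = []
    if design == "mixed" and n_subjects >= 2 * len(AGE_GROUPS):
        for g in AGE_GROUPS:
            hi = min(g.upper_pcd, AGE_MAX_PCD)
            ages.extend(rng.uniform(g.lower_pcd, hi, size=2))
    n_rest = n_subjects - len(ages)
    lo, hi = math.log(AGE_MIN_PCD), math.log(AGE_MAX_PCD)
    ages.extend(np.exp(rng.uniform(lo, hi, size=n_rest)))
    return np.sort(np.asarray(ages))


def simulate_switch_pair(
    spec: SwitchPairSpec, ages: np.ndarray, seed: int | np.random.Generator
):
    """One pair's expression values plus the latent subject factor.

    Returns (values_a, values_b, u) aligned to ``ages``.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    u = rng.normal(0.0, spec.shared_factor_sd, size=n)
    eps_a = rng.normal(0.0, spec.noise_sd, size=n)
    eps_b = rng.normal(0.0, spec.noise_sd, size=n)
    values_a = spec.trend_a(ages) + spec.loading_a * u + eps_a
    values_b = spec.trend_b(ages) + spec.loading_b * u + eps_b
    return values_a, values_b, u


def simulate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """A full multi-region cohort matrix with its ground-truth ledger."""
    config.validate()
    rng = np.random.default_rng(seed)
    ages = sample_ages(config.n_subjects, rng)
    subjects = [f"S{i+1:03d}" for i in range(config.n_subjects)]

    genes: list[str] = []
    trend_truth: dict[str, TrendSpec] = {}
    for (a, b), spec in config.pairs.items():
        genes.extend([a, b])
        trend_truth[a] = spec.trend_a
        trend_truth[b] = spec.trend_b
    noise_genes = [f"NS{i+1:03d}" for i in range(config.n_noise_genes)]
    hk_genes = [f"HK{i+1:03d}" for i in range(config.n_housekeeping)]
    flat = TrendSpec(kind="constant", baseline=config.baseline)
    for g in noise_genes + hk_genes:
        trend_truth[g] = flat
    genes = genes + noise_genes + hk_genes

    samples: list[Sample] = []
    columns: list[np.ndarray] = []
    latent: dict[tuple[str, str, str], np.ndarray] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    for region in config.regions:
        block = np.empty((len(genes), config.n_subjects))
        for (a, b), spec in config.pairs.items():
            va, vb, u = simulate_switch_pair(spec, ages, rng)
            block[gene_index[a]] = va
            block[gene_index[b]] = vb
            latent[(region, a, b)] = u
        for g in noise_genes:
            block[gene_index[g]] = config.baseline + rng.normal(
                0.0, config.noise_gene_sd, size=config.n_subjects
            )
        for g in hk_genes:
            block[gene_index[g]] = config.baseline + rng.normal(
                0.0, config.housekeeping_sd, size=config.n_subjects
            )
        for subj, age in zip(subjects, ages):
            samples.append(
                Sample(
                    sample_id=f"{subj}_{region}",
                    subject_id=subj,
                    region=region,
                    age_pcd=float(age),
                )
            )
        columns.append(block)

    matrix = ExpressionMatrix(
        genes=genes, samples=samples, values=np.hstack(columns)
    )
    pair_truth = {
        key: spec.target_residual_corr for key, spec in config.pairs.items()
    }
    return SyntheticCohort(
        matrix=matrix,
        trend_truth=trend_truth,
        pair_truth=pair_truth,
        latent=latent,
        ages=ages,
        seed=seed,
    )


def synthetic_sequences(
    paired: list[tuple[str, str]],
    singletons: list[str],
    seed: int | np.random.Generator,
    length: int = 240,
    divergence: float = 0.2,
) -> list[ProteinSequence]:
    """Synthetic protein sequences: each pair diverges from a common ancestor.

    Paired genes share ~(1 - divergence)^2 identity (well above the 30%
    candidate threshold); singleton genes get independent random sequences,
    which align far below it.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed

    def random_seq() -> np.ndarray:
        return rng.integers(0, len(_AA), size=length)

    def mutate(codes: np.ndarray) -> np.ndarray:
        out = codes.copy()
        hit = rng.random(length) < divergence
        out[hit] = rng.integers(0, len(_AA), size=int(hit.sum()))
        return out

    def to_str(codes: np.ndarray) -> str:
        return "".join(_AA[c] for c in codes)

    sequences = []
    for a, b in paired:
        ancestor = random_seq()
        sequences.append(ProteinSequence(id=a, residues=to_str(mutate(ancestor))))
        sequences.append(ProteinSequence(id=b, residues=to_str(mutate(ancestor))))
    for g in singletons:
        sequences.append(ProteinSequence(id=g, residues=to_str(random_seq())))
    return sequences


def demo_config() -> CohortConfig:
    """The bundled demonstration cohort: one planted switch pair plus decoys.

    The planted pair has anti-correlated logistic trends and a shared
    subject factor implying residual correlation 0.5. Two decoy pairs have
    co-directed linear trends (range above the differential-expression
    filter) and no shared factor, so neither screen should flag them.
    """
    up = dict(kind="linear", baseline=5.0)
    return CohortConfig(
        regions=("CBC",),
        n_subjects=100,
        pairs={
            ("SW1A", "SW1B"): SwitchPairSpec(),
            ("DC1A", "DC1B"): SwitchPairSpec(
                trend_a=TrendSpec(slope=0.30, **up),
                trend_b=TrendSpec(slope=0.25, **up),
                shared_factor_sd=0.0,
            ),
            ("DC2A", "DC2B"): SwitchPairSpec(
                trend_a=TrendSpec(slope=-0.30, **up),
                trend_b=TrendSpec(slope=-0.25, **up),
                shared_factor_sd=0.0,
            ),
        },
        n_noise_genes=10,
        n_housekeeping=10,
    )


def demo_elements_table() -> pd.DataFrame:
    """Pathway-element rows for the demo cohort (one element per planted pair)."""
    rows = []
    for i, (a, b) in enumerate([("SW1A", "SW1B"), ("DC1A", "DC1B"), ("DC2A", "DC2B")]):
        for g in (a, b):
            rows.append(
                {"pathway_id": "04724", "element_id": f"E{i+1}", "gene_symbol": g}
            )
    return pd.DataFrame(rows)
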