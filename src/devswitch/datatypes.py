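"""Core data containers for developmental expression analysis.

All ages are stored internally in post-conception days (PCD). Expression
values are assumed to be on a log2 scale throughout (the upstream datasets
this package targets are quantile-normalized and log2-transformed before
they reach us).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Days per post-conception week.
DAYS_PER_PCW = 7.0
#: Post-conception day of birth (40 weeks).
BIRTH_PCD = 280.0
#: Mean days per month / per year used for postnatal age conversion.
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25

#: Region vocabulary: 16 regions of the multi-region microarray cohort plus
#: the single prefrontal region of the large single-region cohort.
DEFAULT_REGIONS = (
    "DFC", "OFC", "VFC", "MFC",          # prefrontal
    "M1C", "S1C", "IPC",                 # frontal-parietal
    "ITC", "STC", "A1C", "V1C",          # temporal-occipital
    "AMY", "CBC", "HIP", "MD", "STR",    # subcortical
    "PFC",                               # prefrontal, second dataset
)

#: The 17 KEGG brain-related pathway accessions used for candidate pairing.
DEFAULT_KEGG_PATHWAYS = (
    "04020",  # Long-term potentiation
    "04724",  # Glutamatergic synapse
    "04725",  # Cholinergic synapse
    "04726",  # Serotonergic synapse
    "04727",  # GABAergic synapse
    "04728",  # Dopaminergic synapse
    "04730",  # Long-term depression
    "05010",  # Alzheimer's disease
    "05012",  # Parkinson's disease
    "05014",  # Amyotrophic lateral sclerosis
    "05016",  # Huntington's disease
    "05030",  # Cocaine addiction
    "05031",  # Amphetamine addiction
    "05032",  # Morphine addiction
    "05033",  # Nicotine addiction
    "05034",  # Alcoholism
    "04080",  # Neuroactive ligand-receptor interaction
)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass(frozen=True)
class Sample:
    """One tissue sample: a (subject, region) observation at a given age."""

    sample_id: str
    subject_id: str
    region: str
    age_pcd: float

    def __post_init__(self) -> None:
        if not self.age_pcd > 0:
            raise ValueError(
                f"sample {self.sample_id!r}: age_pcd must be positive, "
                f"got {self.age_pcd}"
            )


@dataclass
class ExpressionProfile:
    """One gene's log2 expression across the samples of one region.

    Samples are kept sorted ascending by age (ties allowed); ``values`` is
    aligned to ``samples``.
    """

    gene: str
    values: np.ndarray
    samples: list[Sample]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != len(self.samples):
            raise ValueError(
                f"profile {self.gene!r}: values and samples lengths differ"
            )
        ages = self.ages
        if np.any(np.diff(ages) < 0):
            order = np.argsort(ages, kind="stable")
            self.values = self.values[order]
            self.samples = [self.samples[i] for i in order]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def ages(self) -> np.ndarray:
        return np.array([s.age_pcd for s in self.samples], dtype=float)

    @property
    def mean_value(self) -> float:
        return float(np.mean(self.values))

    def expression_range(self) -> float:
        """max - min of the log2 values."""
        if self.n == 0:
            raise ValueError(f"profile {self.gene!r} is empty")
        return float(np.max(self.values) - np.min(self.values))


@dataclass
class ExpressionMatrix:
    """genes x samples log2 expression with sample metadata."""

    genes: list[str]
    samples: list[Sample]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene identifiers: {dupes}")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.region, None)
        return list(seen)

    def profile(self, gene: str, region: str) -> ExpressionProfile:
        """Extract one gene's profile in one region, age-sorted."""
        if gene not in self._gene_index:
            raise KeyError(f"unknown gene {gene!r}")
        idx = [i for i, s in enumerate(self.samples) if s.region == region]
        if not idx:
            raise KeyError(f"no samples for region {region!r}")
        row = self.values[self._gene_index[gene], idx]
        samples = [self.samples[i] for i in idx]
        return ExpressionProfile(gene=gene, values=row, samples=samples)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.subject_id, None)
        return list(seen)


@dataclass(frozen=True)
class AgeGroup:
    """A developmental age stratum; presentation only, never used in fitting."""

    label: str
    lower_pcd: float
    upper_pcd: float  # +inf for the last group; interval is [lower, upper)


def _pcw(w: float) -> float:
    return w * DAYS_PER_PCW


def _postnatal_months(m: float) -> float:
    return BIRTH_PCD + m * DAYS_PER_MONTH


def _postnatal_years(y: float) -> float:
    return BIRTH_PCD + y * DAYS_PER_YEAR


#: Thirteen contiguous developmental age groups (left-closed, right-open).
#: The late-fetal group runs to birth so the partition covers [10 PCW, inf).
AGE_GROUPS = (
    AgeGroup("EF3", _pcw(10), _pcw(13)),
    AgeGroup("EMF4", _pcw(13), _pcw(16)),
    AgeGroup("EMF5", _pcw(16), _pcw(19)),
    AgeGroup("LMF6", _pcw(19), _pcw(24)),
    AgeGroup("LF7", _pcw(24), BIRTH_PCD),
    AgeGroup("EI8", BIRTH_PCD, _postnatal_months(6)),
    AgeGroup("LI9", _postnatal_months(6), _postnatal_years(1)),
    AgeGroup("EC10", _postnatal_years(1), _postnatal_years(6)),
    AgeGroup("MLC11", _postnatal_years(6), _postnatal_years(12)),
    AgeGroup("Adol12", _postnatal_years(12), _postnatal_years(20)),
    AgeGroup("YA13", _postnatal_years(20), _postnatal_years(40)),
    AgeGroup("MA14", _postnatal_years(40), _postnatal_years(60)),
    AgeGroup("LA15", _postnatal_years(60), float("inf")),
)


@dataclass(frozen=True)
class ProteinSequence:
    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = sorted(set(self.residues) - AMINO_ACIDS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal residue characters: {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PathwayElement:
    """A pathway-diagram node grouping functionally interchangeable proteins."""

    pathway_id: str
    element_id: str
    genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(
                f"element {self.element_id!r} of pathway {self.pathway_id!r} "
                "has no genes"
            )
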