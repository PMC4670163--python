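"""Candidate variant-pair enumeration.

Pairs are formed only within a pathway element (a diagram node grouping
functionally interchangeable proteins) and kept when global-alignment
similarity reaches the threshold (default 30%; pairs strictly below are
excluded). A pair found in several elements is reported once with the
element ids unioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .align import align_global
from .datatypes import PathwayElement, ProteinSequence

logger = logging.getLogger(__name__)

MIN_SIMILARITY_DEFAULT = 0.30


@dataclass
class CandidatePair:
    gene_a: str
    gene_b: str
    similarity: float
    element_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must be lexicographically before gene_b")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def enumerate_candidates(
    elements: list[PathwayElement],
    sequences: list[ProteinSequence],
    min_similarity: float = MIN_SIMILARITY_DEFAULT,
) -> list[CandidatePair]:
    """All within-element gene pairs whose protein similarity >= threshold.

    Genes lacking a sequence are skipped with a warning. Output is sorted by
    (gene_a, gene_b) and deduplicated across elements.
    """
    seq_by_id = {s.id: s for s in sequences}
    pairs: dict[tuple[str, str], CandidatePair] = {}
    sim_cache: dict[tuple[str, str], float] = {}
    missing_reported: set[str] = set()
    for element in elements:
        genes = sorted(element.genes)
        usable = []
        for g in genes:
            if g in seq_by_id:
                usable.append(g)
            elif g not in missing_reported:
                logger.warning(
                    "gene %s in element %s has no sequence; skipped",
                    g,
                    element.element_id,
                )
                missing_reported.add(g)
        for i, a in enumerate(usable):
            for b in usable[i + 1 :]:
                key = (a, b)
                if key not in sim_cache:
                    sim_cache[key] = align_global(
                        seq_by_id[a].residues, seq_by_id[b].residues
                    ).similarity
                sim = sim_cache[key]
                if sim < min_similarity:
                    continue
                if key in pairs:
                    pairs[key].element_ids.add(element.element_id)
                else:
                    pairs[key] = CandidatePair(
                        gene_a=a,
                        gene_b=b,
                        similarity=sim,
                        element_ids={element.element_id},
                    )
    return [pairs[k] for k in sorted(pairs)]


def write_pairs(pairs: list[CandidatePair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in pairs],
            "gene_b": [p.gene_b for p in pairs],
            "similarity": [p.similarity for p in pairs],
            "element_ids": [",".join(sorted(p.element_ids)) for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pairs(path: str | Path) -> list[CandidatePair]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    return [
        CandidatePair(
            gene_a=row.gene_a,
            gene_b=row.gene_b,
            similarity=float(row.similarity),
            element_ids=set(str(row.element_ids).split(",")),
        )
        for row in df.itertuples()
    ]
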