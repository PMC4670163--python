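"""Readers and writers for expression matrices, metadata, FASTA and pathway tables.

All tabular inputs are TSV (gzip transparently supported); ages in metadata
may be given directly in post-conception days or as (age_value, age_unit)
pairs which are converted to PCD on read.
"""

from __future__ import annotations

import gzip
import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    AGE_GROUPS,
    BIRTH_PCD,
    DAYS_PER_MONTH,
    DAYS_PER_PCW,
    DAYS_PER_YEAR,
    ExpressionMatrix,
    PathwayElement,
    ProteinSequence,
    Sample,
)

logger = logging.getLogger(__name__)

AGE_UNIT_FACTORS = {"pcd": 1.0, "pcw": DAYS_PER_PCW}


def convert_age(value: float, unit: str) -> float:
    """Convert an age to post-conception days.

    Prenatal units (``pcw``/``pcd``) count from conception; postnatal units
    (``months``/``years``) count from birth, fixed at 280 PCD.
    """
    unit = unit.lower()
    if unit in AGE_UNIT_FACTORS:
        return value * AGE_UNIT_FACTORS[unit]
    if unit == "months":
        return BIRTH_PCD + value * DAYS_PER_MONTH
    if unit == "years":
        return BIRTH_PCD + value * DAYS_PER_YEAR
    raise ValueError(f"unknown age unit {unit!r} (expected pcw/pcd/months/years)")


def assign_age_group(age_pcd: float) -> str:
    """Map an age in PCD to its developmental age-group label.

    Labels are a reporting convenience only; nothing downstream fits or
    filters on them.
    """
    if age_pcd < AGE_GROUPS[0].lower_pcd:
        raise ValueError(
            f"age {age_pcd} PCD is below 10 PCW; such subjects are excluded"
        )
    for g in AGE_GROUPS:
        if g.lower_pcd <= age_pcd < g.upper_pcd:
            return g.label
    raise AssertionError("age groups should cover [70, inf)")  # pragma: no cover


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_metadata(path: str | Path) -> dict[str, Sample]:
    """Read sample metadata TSV into a sample_id -> Sample mapping."""
    meta = pd.read_csv(path, sep="\t", dtype=str, float_precision="round_trip")
    required = {"sample_id", "subject_id", "region"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if "age_pcd" in meta.columns:
        ages = meta["age_pcd"].astype(float)
    elif {"age_value", "age_unit"} <= set(meta.columns):
        ages = pd.Series(
            [
                convert_age(float(v), u)
                for v, u in zip(meta["age_value"], meta["age_unit"])
            ],
            index=meta.index,
        )
    else:
        raise ValueError(
            "metadata must provide age_pcd or age_value + age_unit columns"
        )
    samples: dict[str, Sample] = {}
    seen_subject_region: set[tuple[str, str]] = set()
    for i, row in meta.iterrows():
        key = (row["subject_id"], row["region"])
        if key in seen_subject_region:
            raise ValueError(f"duplicate (subject, region) pair: {key}")
        seen_subject_region.add(key)
        samples[row["sample_id"]] = Sample(
            sample_id=row["sample_id"],
            subject_id=row["subject_id"],
            region=row["region"],
            age_pcd=float(ages.loc[i]),
        )
    return samples


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV plus metadata TSV into an ExpressionMatrix.

    The first matrix column is the gene id; remaining column names must each
    match a metadata sample_id. Values are taken as-is (assumed log2).
    """
    df = pd.read_csv(
        matrix_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene ids in expression matrix: {dupes}")
    samples = read_metadata(metadata_path)
    unmatched = [c for c in df.columns if c not in samples]
    if unmatched:
        raise ValueError(
            f"expression columns absent from metadata: {unmatched}"
        )
    non_numeric = df.apply(pd.to_numeric, errors="coerce")
    if non_numeric.isna().values.any() and not df.isna().values.any():
        bad = np.argwhere(non_numeric.isna().values)
        r, c = bad[0]
        raise ValueError(
            f"non-numeric expression cell at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[samples[c] for c in df.columns],
        values=non_numeric.to_numpy(dtype=float),
    )


def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write an ExpressionMatrix back to matrix + metadata TSVs (round-trip safe)."""
    df = pd.DataFrame(
        matrix.values,
        index=pd.Index(matrix.genes, name="gene"),
        columns=[s.sample_id for s in matrix.samples],
    )
    df.to_csv(matrix_path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in matrix.samples],
            "subject_id": [s.subject_id for s in matrix.samples],
            "region": [s.region for s in matrix.samples],
            "age_pcd": [s.age_pcd for s in matrix.samples],
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.17g")


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences; ids are the first header token, residues uppercased."""
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append(ProteinSequence(id=rec.id, residues=str(rec.seq).upper()))
    return out


def write_fasta(sequences: list[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i : i + 60] + "\n")


def read_pathway_elements(path: str | Path) -> list[PathwayElement]:
    """Read a pathway_id / element_id / gene_symbol TSV into grouped elements."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"pathway_id", "element_id", "gene_symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pathway table missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"pathway table {path} is empty")
    elements = []
    for (pid, eid), grp in df.groupby(["pathway_id", "element_id"], sort=True):
        elements.append(
            PathwayElement(
                pathway_id=pid, element_id=eid, genes=set(grp["gene_symbol"])
            )
        )
    return elements
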