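"""Expression-energy tables: I/O, the energy statistic, and normalisation.

In situ hybridisation signal is summarised per anatomical structure as
*expression energy*: the mean intensity of expressing pixels multiplied by
the fraction of expressing pixels, i.e. total expressing intensity divided
by the total pixel count of the structure volume. Voxel-level summaries from
multiple tissue sections are pooled by component-wise summation
("unionisation") before the energy is formed, which makes the statistic
independent of how a structure happens to be split across sections.

Energies are comparable across structures for one gene. Because ISH probes
are not calibrated against a common mRNA standard, quantitative differences
*between* genes are only suggestive; cross-gene comparisons in this package
therefore happen downstream, in the adhesion module, where binding
affinities re-weight them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateRecordError,
    EmptyQueryError,
    EmptyUnionError,
    ExpressionTableError,
    NegativeEnergyError,
    ReferenceGeneError,
    UnknownAgeError,
    ZeroPixelsError,
)
from .ontology import AGE_STAGES

#: Allen-style RMA query endpoint and experiment-browse prefix (documentation
#: of the URL dialect; the pipeline itself only consumes local CSV).
RMA_ENDPOINT = "http://api.brain-map.org/api/v2/data/query.csv"
EXPERIMENT_SHOW_PREFIX = "http://developingmouse.brain-map.org/experiment/show/"

EXPRESSION_CSV_COLUMNS = (
    "gene",
    "structure_id",
    "age",
    "energy",
    "density",
    "intensity",
    "experiment_id",
)


@dataclass(frozen=True)
class PixelSummary:
    """Pixel-level summary of one structure volume (or part of it)."""

    sum_expressing_intensity: float
    n_expressing_pixels: int
    n_total_pixels: int

    def __post_init__(self) -> None:
        if self.n_total_pixels <= 0:
            raise ZeroPixelsError("n_total_pixels must be positive")
        if self.n_expressing_pixels < 0 or self.n_expressing_pixels > self.n_total_pixels:
            raise ValueError("n_expressing_pixels must lie in [0, n_total_pixels]")
        if self.sum_expressing_intensity < 0:
            raise ValueError("sum_expressing_intensity must be non-negative")
        if self.n_expressing_pixels == 0 and self.sum_expressing_intensity != 0:
            raise ValueError("intensity must be 0 when no pixel expresses")


def expression_energy(p: PixelSummary) -> float:
    """Expression energy of one pixel summary.

    (mean intensity of expressing pixels) x (expressing-pixel fraction),
    which reduces to total expressing intensity over total pixels; 0 when
    nothing expresses.
    """
    if p.n_expressing_pixels == 0:
        return 0.0
    mean_intensity = p.sum_expressing_intensity / p.n_expressing_pixels
    fraction = p.n_expressing_pixels / p.n_total_pixels
    return mean_intensity * fraction


def unionize(parts: Sequence[PixelSummary]) -> PixelSummary:
    """Pool pixel summaries across sections by component-wise summation."""
    if len(parts) == 0:
        raise EmptyUnionError("cannot unionize an empty list of pixel summaries")
    return PixelSummary(
        sum_expressing_intensity=float(sum(p.sum_expressing_intensity for p in parts)),
        n_expressing_pixels=int(sum(p.n_expressing_pixels for p in parts)),
        n_total_pixels=int(sum(p.n_total_pixels for p in parts)),
    )


@dataclass(frozen=True)
class ExpressionRecord:
    """One (gene, structure, age) expression measurement."""

    gene: str
    structure_id: str
    age: str
    energy: float
    density: float | None = None
    intensity: float | None = None
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        if self.energy < 0:
            raise NegativeEnergyError(
                f"negative energy for ({self.gene}, {self.structure_id}, {self.age})"
            )
        if self.age not in AGE_STAGES:
            raise UnknownAgeError(
                f"unknown age {self.age!r}; expected one of {AGE_STAGES}"
            )

    @property
    def key(self) -> tuple[str, str, str, str | None]:
        return (self.gene, self.structure_id, self.age, self.experiment_id)


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read the long-format expression CSV.

    Header ``gene,structure_id,age,energy,density,intensity,experiment_id``;
    empty fields are missing. Invalid rows raise named errors listing the
    offending 1-based data-row numbers.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing_cols = set(EXPRESSION_CSV_COLUMNS[:4]) - set(df.columns)
    if missing_cols:
        raise ExpressionTableError(
            f"missing required columns {sorted(missing_cols)} in {path}"
        )
    records: list[ExpressionRecord] = []
    bad_age: list[int] = []
    bad_energy: list[int] = []
    seen: dict[tuple, int] = {}
    dupes: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        age = row.age
        if age not in AGE_STAGES:
            bad_age.append(i)
            continue
        energy = float(row.energy)
        if energy < 0:
            bad_energy.append(i)
            continue
        rec = ExpressionRecord(
            gene=row.gene,
            structure_id=row.structure_id,
            age=age,
            energy=energy,
            density=_opt_float(getattr(row, "density", "")),
            intensity=_opt_float(getattr(row, "intensity", "")),
            experiment_id=(getattr(row, "experiment_id", "") or None),
        )
        if rec.key in seen:
            dupes.append(i)
            continue
        seen[rec.key] = i
        records.append(rec)
    if bad_age:
        raise UnknownAgeError(f"unknown age labels in {path}", rows=bad_age)
    if bad_energy:
        raise NegativeEnergyError(f"negative energies in {path}", rows=bad_energy)
    if dupes:
        raise DuplicateRecordError(
            f"duplicate (gene, structure, age, experiment) keys in {path}", rows=dupes
        )
    return records


def _opt_float(value: str) -> float | None:
    return None if value in ("", None) else float(value)


def write_expression_table(
    records: Iterable[ExpressionRecord], path: str | Path, header_comment: str = ""
) -> None:
    """Write records to the expression CSV dialect (lossless round-trip)."""
    rows = [
        {
            "gene": r.gene,
            "structure_id": r.structure_id,
            "age": r.age,
            "energy": repr(r.energy),
            "density": "" if r.density is None else repr(r.density),
            "intensity": "" if r.intensity is None else repr(r.intensity),
            "experiment_id": r.experiment_id or "",
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(EXPRESSION_CSV_COLUMNS))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# -- matrices ----------------------------------------------------------------


def records_to_matrix(
    records: Iterable[ExpressionRecord],
    age: str,
    structures: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pivot records of one age stage into a genes x structures matrix.

    Missing (gene, structure) combinations stay NaN; they are never imputed
    as zero. ``structures`` restricts and orders the columns.
    """
    if age not in AGE_STAGES:
        raise UnknownAgeError(f"unknown age {age!r}")
    rows = [
        (r.gene, r.structure_id, r.energy) for r in records if r.age == age
    ]
    df = pd.DataFrame(rows, columns=["gene", "structure_id", "energy"])
    matrix = df.pivot_table(
        index="gene", columns="structure_id", values="energy", aggfunc="mean"
    )
    if structures is not None:
        matrix = matrix.reindex(columns=list(structures))
    return matrix


def normalize_to_gene(matrix: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Divide every column by the reference gene's value in that column.

    The reference row becomes all ones. Columns where the reference is
    missing or non-positive raise :class:`ReferenceGeneError` naming them.
    """
    if reference_gene not in matrix.index:
        raise ReferenceGeneError(f"reference gene {reference_gene!r} not in matrix")
    ref = matrix.loc[reference_gene]
    bad = [str(c) for c in matrix.columns if not (ref[c] > 0)]
    if bad:
        raise ReferenceGeneError(
            f"reference gene {reference_gene!r} missing or zero", columns=bad
        )
    return matrix.div(ref, axis=1)


def significant_expression_flags(
    matrix: pd.DataFrame, threshold: float = 1.0
) -> pd.DataFrame:
    """Boolean mask of significant expression (energy >= threshold, inclusive).

    The conventional cutoff is one unit of expression energy. Missing values
    stay missing (NA), not False.
    """
    flags = matrix >= threshold
    return flags.where(matrix.notna(), other=pd.NA).astype("boolean")


# -- RMA query construction --------------------------------------------------


def build_rma_query(
    structure_ids: Sequence[int | str], section_data_set_id: str | int
) -> str:
    """Deterministic RMA query URL for structure-unionize records.

    Embeds the anatomical ``structure_id`` list and the ISH experiment's
    ``section_data_set_id``. Construction is pure string building; nothing
    here performs network access.
    """
    if len(structure_ids) == 0:
        raise EmptyQueryError("structure_ids must be non-empty")
    ids = ",".join(str(s) for s in structure_ids)
    criteria = (
        "model::DevelopingStructureUnionize,"
        f"rma::criteria,[structure_id$in{ids}],"
        f"section_data_set[id$eq{section_data_set_id}]"
    )
    return f"{RMA_ENDPOINT}?criteria={criteria}"


def experiment_show_url(section_data_set_id: str | int) -> str:
    """Browser URL of one ISH experiment's tissue-section images."""
    return f"{EXPERIMENT_SHOW_PREFIX}{section_data_set_id}"
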