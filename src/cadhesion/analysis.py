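"""Correlation, ratio and comparison analyses over expression tables.

Covers the ontology-aware statistics used downstream of the expression
tables: Pearson correlation between gene profiles across structures (with
pairwise-complete observations and a minimum of three pairs), correlation
of cadherin-panel vectors between cortical (area, layer) units and
subpallial nuclei, log2 alar/basal plate expression ratios along the
anterior-posterior axis, and the paired ISH vs scRNA-seq sanity check on
housekeeping-normalised means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConstantVectorError,
    EmptyMatrixError,
    InsufficientDataError,
    ReferenceGeneError,
)
from .expression import ExpressionRecord, normalize_to_gene, records_to_matrix
from .ontology import StructureGraph

import logging

logger = logging.getLogger(__name__)

#: The default 12-cadherin panel: Cdh2, the atypical Cdh13, and the three
#: type II specificity groups (A: Cdh6/9/10, B: Cdh7/12/18/20, C: Cdh8/11/24).
DEFAULT_PANEL: tuple[str, ...] = (
    "Cdh2",
    "Cdh13",
    "Cdh6",
    "Cdh9",
    "Cdh10",
    "Cdh7",
    "Cdh12",
    "Cdh18",
    "Cdh20",
    "Cdh8",
    "Cdh11",
    "Cdh24",
)

#: Correlation-strength bins. Half-open intervals close the gaps of the
#: verbal convention (low below 0.70, intermediate up to 0.90, high above).
CORRELATION_BINS: tuple[tuple[str, float, float], ...] = (
    ("low", -1.0, 0.70),
    ("intermediate", 0.70, 0.90),
    ("high", 0.90, math.inf),
)


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson product-moment correlation on pairwise-complete pairs.

    Missing values (NaN) are dropped pairwise. Requires at least three
    complete pairs and non-zero variance on both sides; a constant vector
    raises :class:`ConstantVectorError` rather than returning r = 0. The
    two-sided p-value is the t-transform with n - 2 degrees of freedom.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same length")
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    n = int(xa.size)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 pairwise-complete pairs, got {n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ConstantVectorError("constant vector: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return PearsonResult(float(r), float(p), n)


def fisher_z_interval(r: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a sample correlation at size n."""
    if n < 4:
        raise InsufficientDataError("Fisher-z interval needs n >= 4")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    return (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))


def classify_correlation(r: float) -> str:
    """Bin a correlation into {low, intermediate, high}.

    low: r < 0.70; intermediate: 0.70 <= r < 0.90; high: r >= 0.90.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    for label, lo, hi in CORRELATION_BINS:
        if lo <= r < hi:
            return label
    return CORRELATION_BINS[0][0]  # pragma: no cover - bins are total


def gene_pair_correlation_by_age(
    records: Iterable[ExpressionRecord],
    gene_a: str,
    gene_b: str,
    graph: StructureGraph | None = None,
    level: int | None = None,
    ages: Sequence[str] | None = None,
) -> dict[str, PearsonResult]:
    """Per-age correlation between two genes across structures.

    Observations are structures (optionally restricted to one ontological
    level of ``graph``); pairs with a missing side are dropped. Ages where
    either gene is absent or fewer than three pairs remain are omitted with
    a logged warning.
    """
    records = list(records)
    from .ontology import AGE_STAGES

    if ages is None:
        ages = [a for a in AGE_STAGES if any(r.age == a for r in records)]
    structures = None
    if graph is not None and level is not None:
        structures = [s.id for s in graph.segments_at_level(level)]
    out: dict[str, PearsonResult] = {}
    for age in ages:
        matrix = records_to_matrix(records, age, structures)
        if gene_a not in matrix.index or gene_b not in matrix.index:
            logger.warning("age %s: %s or %s missing; omitted", age, gene_a, gene_b)
            continue
        try:
            out[age] = pearson(matrix.loc[gene_a], matrix.loc[gene_b])
        except (InsufficientDataError, ConstantVectorError) as exc:
            logger.warning("age %s omitted: %s", age, exc)
    return out


@dataclass
class CorrelationMatrix:
    """Labelled Pearson r / p / n matrices between two structure sets."""

    row_labels: list[str]
    col_labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        """Long-format (row, col, r, p, n, bin) table."""
        rows = []
        for row in self.row_labels:
            for col in self.col_labels:
                r = self.r.at[row, col]
                rows.append(
                    {
                        "row": row,
                        "col": col,
                        "r": r,
                        "p": self.p.at[row, col],
                        "n": self.n.at[row, col],
                        "bin": classify_correlation(r) if np.isfinite(r) else "na",
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, header_comment: str = "") -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
            self.to_long().to_csv(fh, index=False)


def cortex_subpallium_correlation(
    records: Iterable[ExpressionRecord],
    graph: StructureGraph,
    panel: Sequence[str] = DEFAULT_PANEL,
    age: str = "P56",
    max_missing_fraction: float = 0.25,
    normalize_within_unit: bool = False,
) -> CorrelationMatrix:
    """Correlate cadherin-panel vectors between cortex units and nuclei.

    For every cortical (area, layer) unit and every subpallial nucleus, the
    cell holds the Pearson r between the two panel-length expression
    vectors (observations are the panel genes). Units missing more than
    ``max_missing_fraction`` of panel values are excluded with a warning.
    ``normalize_within_unit`` rescales each unit's vector by its mean first
    (off by default; correlations pair raw energies).
    """
    records = list(records)
    panel = list(panel)
    matrix = records_to_matrix(records, age)
    cortical = [s.id for s in graph.cortical_units()]
    nuclei = [s.id for s in graph.subpallial_nuclei()]

    def unit_vector(structure_id: str) -> pd.Series | None:
        if structure_id not in matrix.columns:
            logger.warning("unit %s has no expression data; excluded", structure_id)
            return None
        vec = matrix[structure_id].reindex(panel)
        if vec.isna().mean() > max_missing_fraction:
            logger.warning(
                "unit %s misses >%.0f%% of the panel; excluded",
                structure_id,
                100 * max_missing_fraction,
            )
            return None
        if normalize_within_unit:
            vec = vec / vec.mean(skipna=True)
        return vec

    row_vectors = {u: v for u in cortical if (v := unit_vector(u)) is not None}
    col_vectors = {u: v for u in nuclei if (v := unit_vector(u)) is not None}
    if not row_vectors or not col_vectors:
        raise EmptyMatrixError("no usable cortical units or subpallial nuclei")
    row_labels = list(row_vectors)
    col_labels = list(col_vectors)
    r = pd.DataFrame(index=row_labels, columns=col_labels, dtype=float)
    p = pd.DataFrame(index=row_labels, columns=col_labels, dtype=float)
    n = pd.DataFrame(index=row_labels, columns=col_labels, dtype=float)
    for row, rv in row_vectors.items():
        for col, cv in col_vectors.items():
            res = pearson(rv, cv)
            r.at[row, col] = res.r
            p.at[row, col] = res.p
            n.at[row, col] = res.n
    return CorrelationMatrix(row_labels, col_labels, r, p, n)


@dataclass
class RatioProfile:
    """Per-segment log2(alar/basal) expression ratio along the AP axis.

    Zero on the log2 scale means equal expression in both plates ("the zero
    line"); positive values mean alar excess. ``zero_convention`` documents
    the handling of one-sided zeros: the value is a +/- inf sentinel and the
    segment is flagged; both-zero segments are missing.
    """

    gene: str
    age: str
    values: pd.Series  # index: segment acronym, ordered anterior -> posterior
    flags: pd.Series  # True where one plate was exactly zero
    zero_convention: str = "one-sided zero -> +/-inf sentinel, flagged; both-zero -> missing"


def alar_basal_ratio(
    records: Iterable[ExpressionRecord],
    gene: str,
    age: str,
    graph: StructureGraph,
) -> RatioProfile:
    """log2 ratio of alar over basal plate energy per transverse segment."""
    records = [r for r in records if r.gene == gene and r.age == age]
    if not records:
        raise KeyError(f"no records for gene {gene!r} at age {age!r}")
    by_structure = {r.structure_id: r.energy for r in records}
    segments = graph.segments_at_level(3)
    values: dict[str, float] = {}
    flags: dict[str, bool] = {}
    for seg in segments:
        plates = {
            s.plate: s.id
            for s in graph.select(level=5)
            if s.parent_id == seg.id and s.plate in ("alar", "basal")
        }
        alar = by_structure.get(plates.get("alar", ""))
        basal = by_structure.get(plates.get("basal", ""))
        if alar is None or basal is None:
            continue
        if alar == 0.0 and basal == 0.0:
            continue  # missing by convention
        if alar == 0.0 or basal == 0.0:
            values[seg.acronym] = math.inf if basal == 0.0 else -math.inf
            flags[seg.acronym] = True
        else:
            values[seg.acronym] = math.log2(alar / basal)
            flags[seg.acronym] = False
    return RatioProfile(
        gene=gene,
        age=age,
        values=pd.Series(values, dtype=float),
        flags=pd.Series(flags, dtype=bool),
    )


@dataclass
class ComparisonResult:
    """Paired comparison of housekeeping-normalised ISH and scRNA-seq means."""

    ish_means: pd.Series  # per gene
    sc_means: pd.Series  # per gene
    statistic: float
    p_value: float
    n_clusters_used: int
    test: str


def ish_scrnaseq_comparison(
    ish_matrix: pd.DataFrame,
    sc_table: pd.DataFrame,
    reference_gene: str = "Actb",
    non_neuronal_labels: Sequence[str] = (),
    test: str = "wilcoxon",
) -> ComparisonResult:
    """Compare per-gene ISH and scRNA-seq means after Actb normalisation.

    ISH side: each column (a cortical layer x area cell) of ``ish_matrix``
    is divided by the reference gene, then averaged per gene. scRNA-seq
    side: ``sc_table`` is long-format ``cluster_id,class_label,gene,
    mean_expression``; clusters whose class label is in
    ``non_neuronal_labels`` are removed, each remaining cluster is
    reference-normalised, and the normalised values are averaged per gene.
    The two per-gene mean vectors are compared with a paired two-sided test
    (Wilcoxon signed-rank by default, ``test="ttest"`` for paired t).
    """
    ish_norm = normalize_to_gene(ish_matrix, reference_gene)
    ish_means = ish_norm.drop(index=reference_gene).mean(axis=1, skipna=True)

    required = {"cluster_id", "class_label", "gene", "mean_expression"}
    if not required.issubset(sc_table.columns):
        raise ValueError(f"sc_table must have columns {sorted(required)}")
    neuronal = sc_table[~sc_table["class_label"].isin(set(non_neuronal_labels))]
    sc_matrix = neuronal.pivot_table(
        index="gene", columns="cluster_id", values="mean_expression", aggfunc="mean"
    )
    if reference_gene not in sc_matrix.index:
        raise ReferenceGeneError(f"{reference_gene!r} absent from scRNA-seq table")
    sc_norm = normalize_to_gene(sc_matrix, reference_gene)
    sc_means = sc_norm.drop(index=reference_gene).mean(axis=1, skipna=True)
    n_clusters_used = int(sc_matrix.shape[1])

    genes = sorted(set(ish_means.index) & set(sc_means.index))
    if len(genes) < 3:
        raise InsufficientDataError("need >= 3 shared genes for the paired test")
    a = ish_means.reindex(genes).to_numpy()
    b = sc_means.reindex(genes).to_numpy()
    if test == "wilcoxon":
        if np.allclose(a, b):
            statistic, p_value = 0.0, 1.0  # identical profiles: no evidence
        else:
            res = stats.wilcoxon(a, b, alternative="two-sided")
            statistic, p_value = float(res.statistic), float(res.pvalue)
    elif test == "ttest":
        res = stats.ttest_rel(a, b)
        statistic, p_value = float(res.statistic), float(res.pvalue)
        if math.isnan(p_value):  # zero-variance differences (identical)
            statistic, p_value = 0.0, 1.0
    else:
        raise ValueError(f"unknown test {test!r}")
    logger.info("paired %s test across %d genes: p=%.4g", test, len(genes), p_value)
    return ComparisonResult(
        ish_means=ish_means.reindex(genes),
        sc_means=sc_means.reindex(genes),
        statistic=statistic,
        p_value=p_value,
        n_clusters_used=n_clusters_used,
        test=test,
    )


def heatmap_export(
    matrix: pd.DataFrame | CorrelationMatrix,
    path: str | Path,
    cmap: str = "coolwarm",
    title: str = "",
) -> None:
    """Render a matrix (or a CorrelationMatrix's r) as a deterministic SVG/PNG.

    SVG output is byte-reproducible for identical inputs (fixed hash salt,
    date metadata suppressed).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(matrix, CorrelationMatrix):
        matrix = matrix.r
    if matrix.size == 0:
        raise EmptyMatrixError("cannot render an empty matrix")
    with plt.rc_context({"svg.hashsalt": "cadhesion"}):
        fig, ax = plt.subplots(
            figsize=(max(3.0, 0.22 * matrix.shape[1]), max(2.5, 0.22 * matrix.shape[0]))
        )
        im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap)
        ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns],
                      rotation=90, fontsize=6)
        ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index],
                      fontsize=6)
        if title:
            ax.set_title(title, fontsize=9)
        fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
        plt.close(fig)
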