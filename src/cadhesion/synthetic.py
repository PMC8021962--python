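"""Synthetic expression data with controlled statistical structure.

Generates every input the pipeline consumes — pixel summaries with
analytically known energies, long-format expression tables, and scRNA-seq
cluster means — so all stages are testable without any atlas download.

Energies are drawn from a log-normal model: non-negative, with
multiplicative structure-to-structure variation, which is a reasonable
stand-in for ISH expression energies (no distributional claim is made for
the real data). Between-gene Pearson correlations are embedded via a
Gaussian copula on the log scale. Because exponentiation attenuates linear
correlation, the log-scale correlation is back-computed from the requested
energy-scale (linear) target with the exact bivariate-lognormal relation

    rho_log = ln(1 + r (e^{sigma^2} - 1)) / sigma^2,

so the sample Pearson r of the energies converges to the target for any
noise level. Planted fold-differences multiply one gene's energies on the
posterior side of a named segment boundary, giving known ground truth for
boundary detection and for the downstream relative-adhesion ratio.

All randomness flows from one named generator seeded by the spec; identical
spec + seed reproduce identical tables (and identical CSV bytes).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.correlation_tools import corr_nearest

from .analysis import DEFAULT_PANEL
from .errors import InfeasibleCorrelationError, SpecError
from .expression import ExpressionRecord, PixelSummary, expression_energy
from .ontology import AGE_STAGES

import logging

logger = logging.getLogger(__name__)

#: Tolerance on the deviation between requested and embedded correlations
#: after nearest-positive-definite repair.
CORRELATION_REPAIR_TOL = 0.05


@dataclass(frozen=True)
class PlantedFold:
    """A known fold-step in one gene at one segment boundary.

    ``boundary`` is the index of the first structure on the posterior side;
    all structures at positions >= boundary get their energy multiplied by
    ``fold``. In the output of ``adjacent_fold_changes`` this is the
    boundary between positions ``boundary - 1`` and ``boundary``.
    """

    gene: str
    boundary: int
    fold: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic expression dataset.

    Defaults describe a moderately noisy, atlas-like table: the standard
    12-cadherin panel plus Actb, 19 structures (the level-3 segment count),
    all seven age stages, baseline energy 5 units (mid-range of observed
    ISH energies), and log-normal noise sigma = 0.5 (roughly two-fold
    scatter between structures).
    """

    seed: int = 0
    n_structures: int = 19
    ages: tuple[str, ...] = AGE_STAGES
    genes: tuple[str, ...] = DEFAULT_PANEL + ("Actb",)
    target_correlations: tuple[tuple[str, str, float], ...] = ()
    noise_sigma: float = 0.5
    planted_folds: tuple[PlantedFold, ...] = ()
    baseline_energy: float = 5.0

    def __post_init__(self) -> None:
        if self.n_structures < 1:
            raise SpecError("n_structures must be >= 1")
        if self.noise_sigma < 0:
            raise SpecError("noise_sigma must be >= 0")
        if self.baseline_energy <= 0:
            raise SpecError("baseline_energy must be positive")
        unknown_ages = set(self.ages) - set(AGE_STAGES)
        if unknown_ages:
            raise SpecError(f"unknown ages {sorted(unknown_ages)}")
        for a, b, r in self.target_correlations:
            if not -1 < r < 1:
                raise SpecError(f"target correlation ({a}, {b}) must satisfy |r| < 1")
            if a not in self.genes or b not in self.genes:
                raise SpecError(f"correlation target ({a}, {b}) names unknown genes")
            if self.noise_sigma == 0:
                raise SpecError("target correlations require noise_sigma > 0")
        for f in self.planted_folds:
            if f.fold <= 0:
                raise SpecError(f"planted fold for {f.gene} must be positive")
            if f.gene not in self.genes:
                raise SpecError(f"planted fold names unknown gene {f.gene!r}")
            if not 1 <= f.boundary <= self.n_structures - 1:
                raise SpecError(
                    f"planted boundary {f.boundary} outside [1, {self.n_structures - 1}]"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        payload = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(payload, dict):
            raise SpecError(f"{path}: expected a mapping")
        if "planted_folds" in payload:
            payload["planted_folds"] = tuple(
                PlantedFold(str(f["gene"]), int(f["boundary"]), float(f["fold"]))
                for f in payload["planted_folds"]
            )
        if "target_correlations" in payload:
            payload["target_correlations"] = tuple(
                (str(a), str(b), float(r)) for a, b, r in payload["target_correlations"]
            )
        for key in ("ages", "genes"):
            if key in payload:
                payload[key] = tuple(str(x) for x in payload[key])
        try:
            return cls(**payload)
        except TypeError as exc:
            raise SpecError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["ages"] = list(self.ages)
        payload["genes"] = list(self.genes)
        payload["target_correlations"] = [list(t) for t in self.target_correlations]
        payload["planted_folds"] = [asdict(f) for f in self.planted_folds]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")

    def config_hash(self) -> str:
        digest = hashlib.sha256(repr(asdict(self)).encode()).hexdigest()
        return digest[:12]


def _linear_to_log_correlation(r: float, sigma: float) -> float:
    """Log-scale (copula) correlation giving linear correlation r after
    exponentiation of N(0, sigma^2) margins (exact lognormal relation)."""
    if sigma == 0:
        return r
    v = math.expm1(sigma**2)
    arg = 1.0 + r * v
    if arg <= 0:
        raise InfeasibleCorrelationError(
            f"linear target r={r} infeasible at sigma={sigma}"
        )
    rho = math.log(arg) / sigma**2
    if not -1.0 <= rho <= 1.0:
        raise InfeasibleCorrelationError(
            f"linear target r={r} maps to log-scale rho={rho:.4f} outside [-1, 1]"
        )
    return rho


def _build_log_correlation(spec: SyntheticSpec) -> np.ndarray:
    """Assemble, repair and validate the gene-gene log-scale correlation."""
    genes = list(spec.genes)
    k = len(genes)
    corr = np.eye(k)
    for a, b, r in spec.target_correlations:
        rho = _linear_to_log_correlation(r, spec.noise_sigma)
        i, j = genes.index(a), genes.index(b)
        corr[i, j] = corr[j, i] = rho
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < 1e-10:
        repaired = corr_nearest(corr, threshold=1e-8)
        deviation = np.abs(repaired - corr).max()
        logger.info(
            "correlation matrix repaired to nearest PD (max deviation %.4f)", deviation
        )
        if deviation > CORRELATION_REPAIR_TOL:
            raise InfeasibleCorrelationError(
                f"targets jointly infeasible: PD repair moved a correlation by "
                f"{deviation:.3f} (> {CORRELATION_REPAIR_TOL})"
            )
        corr = repaired
    return corr


def generate_expression_table(
    spec: SyntheticSpec,
    structures: Sequence[str] | None = None,
) -> list[ExpressionRecord]:
    """Generate a long-format expression table per the spec.

    ``structures`` supplies the ordered structure ids (anterior first);
    defaults to synthetic ids ``S0000..``. Per age, log-energies are drawn
    from a multivariate normal embedding the target correlations,
    exponentiated and scaled so the expected energy equals
    ``baseline_energy``; planted folds then multiply energies on the
    posterior side of their boundary. Fully deterministic under a fixed
    seed.
    """
    if structures is None:
        structures = [f"S{i:04d}" for i in range(spec.n_structures)]
    elif len(structures) != spec.n_structures:
        raise SpecError(
            f"got {len(structures)} structures, spec says {spec.n_structures}"
        )
    genes = list(spec.genes)
    rng = np.random.default_rng(spec.seed)
    corr = _build_log_correlation(spec)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(genes)))
    records: list[ExpressionRecord] = []
    for age in spec.ages:
        z = rng.standard_normal((spec.n_structures, len(genes))) @ chol.T
        # mean-preserving lognormal: E[exp(sigma z - sigma^2/2)] = 1
        energies = spec.baseline_energy * np.exp(
            spec.noise_sigma * z - spec.noise_sigma**2 / 2.0
        )
        for f in spec.planted_folds:
            j = genes.index(f.gene)
            energies[f.boundary :, j] *= f.fold
        for j, gene in enumerate(genes):
            for i, structure in enumerate(structures):
                records.append(
                    ExpressionRecord(
                        gene=gene,
                        structure_id=str(structure),
                        age=age,
                        energy=float(energies[i, j]),
                        experiment_id=f"sim{spec.seed}",
                    )
                )
    return records


def generate_pixel_grids(
    seed: int, n: int = 20, max_pixels: int = 2000
) -> list[tuple[PixelSummary, float]]:
    """Random pixel summaries paired with their analytically known energy.

    The known energy is total expressing intensity over total pixels, the
    quantity the energy statistic must reproduce exactly. One grid in ten
    is fully non-expressing so the zero-energy branch is always exercised.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[PixelSummary, float]] = []
    for i in range(n):
        n_total = int(rng.integers(1, max_pixels + 1))
        n_expr = 0 if i % 10 == 0 else int(rng.integers(0, n_total + 1))
        total_intensity = float(rng.uniform(0, 255) * n_expr)
        summary = PixelSummary(total_intensity, n_expr, n_total)
        out.append((summary, total_intensity / n_total))
    return out


def generate_scrnaseq_clusters(
    spec: SyntheticSpec,
    n_clusters: int = 377,
    n_non_neuronal: int = 24,
    effect: Mapping[str, float] | None = None,
    gene_means: Mapping[str, float] | None = None,
    reference_gene: str = "Actb",
    reference_sigma: float | None = None,
) -> pd.DataFrame:
    """Synthetic scRNA-seq cluster-mean table.

    Emulates a cortical taxonomy of ``n_clusters`` cell types of which
    ``n_non_neuronal`` carry the class label ``"non-neuronal"`` (removed
    downstream, leaving the neuronal groups). Cluster means are log-normal
    around per-gene baselines; ``gene_means`` pins those baselines (shared
    with an ISH generator to build an exact null for the paired
    comparison), and ``effect`` applies per-gene multiplicative shifts to
    the neuronal clusters. A non-positive reference draw would be resampled
    and logged; the log-normal model makes this a no-op guard.

    ``reference_sigma`` overrides the noise level of the reference gene
    alone. Normalising by a noisy reference induces a shared multiplicative
    shift across all genes of one cluster/unit, which correlates the paired
    per-gene differences downstream; setting ``reference_sigma=0`` on both
    modalities yields an exact null with independent differences.
    """
    if not n_non_neuronal < n_clusters:
        raise SpecError("n_non_neuronal must be < n_clusters")
    genes = list(spec.genes)
    if reference_gene not in genes:
        genes = genes + [reference_gene]
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the table
    if gene_means is None:
        gene_means = {
            g: float(spec.baseline_energy * rng.lognormal(0.0, 0.5)) for g in genes
        }
    effect = dict(effect or {})
    rows = []
    for c in range(n_clusters):
        non_neuronal = c < n_non_neuronal
        label = "non-neuronal" if non_neuronal else f"neuronal-{c - n_non_neuronal}"
        cluster_id = f"C{c:04d}"
        for g in genes:
            sigma = spec.noise_sigma or 0.25
            if g == reference_gene and reference_sigma is not None:
                sigma = reference_sigma
            mean = gene_means[g] * (rng.lognormal(0.0, sigma) if sigma else 1.0)
            if not non_neuronal and g in effect:
                mean *= effect[g]
            while g == reference_gene and mean <= 0:  # pragma: no cover - guard
                logger.info("non-positive reference draw resampled for %s", cluster_id)
                mean = gene_means[g] * rng.lognormal(0.0, sigma or 0.25)
            rows.append(
                {
                    "cluster_id": cluster_id,
                    "class_label": label,
                    "gene": g,
                    "mean_expression": mean,
                }
            )
    return pd.DataFrame(rows)


def generate_ish_cortex_matrix(
    spec: SyntheticSpec,
    gene_means: Mapping[str, float],
    units: Sequence[str] = (),
    n_units: int = 24,
    reference_gene: str = "Actb",
    reference_sigma: float | None = None,
) -> pd.DataFrame:
    """Synthetic ISH genes x cortical-unit matrix around shared gene means.

    Pairs with :func:`generate_scrnaseq_clusters` (same ``gene_means``) to
    construct a true null for the paired ISH vs scRNA-seq comparison:
    both modalities then share every per-gene expected value.
    ``reference_sigma`` plays the same role as in the cluster generator.
    """
    genes = list(spec.genes)
    if reference_gene not in genes:
        genes = genes + [reference_gene]
    if not units:
        units = [f"U{i:02d}" for i in range(n_units)]
    rng = np.random.default_rng(spec.seed + 2)

    def draw(g: str) -> float:
        sigma = spec.noise_sigma or 0.25
        if g == reference_gene and reference_sigma is not None:
            sigma = reference_sigma
        return gene_means[g] * (rng.lognormal(0.0, sigma) if sigma else 1.0)

    data = {u: [draw(g) for g in genes] for u in units}
    return pd.DataFrame(data, index=genes)
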