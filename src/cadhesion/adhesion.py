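"""Cadherin-mediated relative adhesion from expression level and affinity.

The model estimates the work of separation W between two apposed cells from
the number of cadherin molecules on the surface and the homophilic trans-
dimer dissociation constant K_D:

1. An expression-energy unit is equated to a fixed number of surface
   molecules (25,000 by default, an arbitrary calibration).
2. A spherical cell (diameter ~10 um) touching 12 neighbours devotes a
   fraction 1/12 (~8%) of its surface, hence of its cadherins, to one
   contact; half of those are assumed to participate in trans-dimerisation.
   The participating EC1 domains live in a slab of ~12 nm (the intermembrane
   gap accessible to the membrane-distal EC1 domain), giving a molar
   concentration C_T in the contact volume.
3. Monomer/dimer partitioning follows mass action, K_D = C_M^2 / C_D with
   conservation C_M + 2 C_D = C_T, solved in closed form.
4. Each dimer contributes a Gibbs free energy dg = -(RT/n) ln(K_D/1 M)
   (n = Avogadro's number, i.e. per molecule not per mole), and
   W = N_dimers * dg.
5. W is normalised to the W of a reference configuration (25,000 molecules
   of Cdh2), yielding the dimensionless *relative adhesion*.

Because dg is a common factor per cadherin pairing, relative adhesion for a
single cadherin reduces to a ratio of dimer numbers and is exactly
temperature-independent; only C_T/K_D matters. Note that C_T itself is
independent of the contact fraction: the participating-molecule count and
the contact volume both scale linearly with it.

The statsmodels-style entry point is :class:`AdhesionModel` (built from a
genes x structures energy matrix plus a K_D table) whose :meth:`~AdhesionModel.fit`
returns :class:`AdhesionResults` with the full audit trail of every
intermediate quantity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AdhesionInputError,
    MissingKdError,
    ProfileLengthError,
)

logger = logging.getLogger(__name__)

#: Gas constant in cal mol^-1 K^-1 and Avogadro's number in mol^-1.
GAS_CONSTANT_CAL = 1.987
AVOGADRO = 6.022e23

#: Type II specificity groups (high-affinity heterophilic partners).
SPECIFICITY_GROUPS = {
    "A": ("Cdh6", "Cdh9", "Cdh10"),
    "B": ("Cdh7", "Cdh12", "Cdh18", "Cdh20", "Cdh22"),
    "C": ("Cdh8", "Cdh11", "Cdh24"),
}


@dataclass(frozen=True)
class KdEntry:
    """Homophilic dissociation constant of one cadherin."""

    cadherin: str
    kd: float  # molar
    cadherin_type: str = "type II"  # {"type I", "type II", "atypical"}
    specificity_group: str = "none"  # {"A", "B", "C", "none"}
    source: str = ""

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise AdhesionInputError(f"{self.cadherin}: K_D must be positive")


class KdTable:
    """Lookup of homophilic K_D values by cadherin symbol.

    Values are replaceable inputs carried in a CSV with per-entry source
    tags (``cadherin,kd_molar,cadherin_type,specificity_group,source``),
    never hard-coded model constants.
    """

    def __init__(self, entries: Iterable[KdEntry]):
        self._entries: dict[str, KdEntry] = {}
        for e in entries:
            if e.cadherin in self._entries:
                raise AdhesionInputError(f"duplicate K_D entry for {e.cadherin}")
            self._entries[e.cadherin] = e

    @classmethod
    def from_csv(cls, path: str | Path) -> "KdTable":
        df = pd.read_csv(path, comment="#")
        return cls(
            KdEntry(
                cadherin=str(row.cadherin),
                kd=float(row.kd_molar),
                cadherin_type=str(row.cadherin_type),
                specificity_group=str(row.specificity_group),
                source=str(row.source),
            )
            for row in df.itertuples(index=False)
        )

    def __contains__(self, cadherin: str) -> bool:
        return cadherin in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __getitem__(self, cadherin: str) -> KdEntry:
        try:
            return self._entries[cadherin]
        except KeyError:
            raise MissingKdError(f"no K_D entry for {cadherin!r}") from None

    def kd(self, cadherin: str) -> float:
        return self[cadherin].kd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.cadherin, e.kd, e.cadherin_type, e.specificity_group, e.source)
                for e in self._entries.values()
            ],
            columns=["cadherin", "kd_molar", "cadherin_type", "specificity_group", "source"],
        )


def load_packaged_kd_table() -> KdTable:
    """The K_D CSV shipped with the package (see its source column for
    provenance; entries tagged ``synthetic-placeholder`` are stand-ins to be
    replaced with measured affinities)."""
    ref = resources.files("cadhesion.data").joinpath("kd_homophilic.csv")
    with resources.as_file(ref) as path:
        return KdTable.from_csv(path)


@dataclass(frozen=True)
class AdhesionParams:
    """Geometry, calibration and thermodynamic constants of the model.

    Defaults encode the standard configuration: 25,000 molecules per energy
    unit, a 10 um spherical cell with 12 neighbours (contact fraction 1/12,
    about 8%), half of the contact-zone molecules participating, a 12 nm
    EC1 slab, molecules counted from a single cell, physiological
    temperature, and normalisation to 25,000 molecules of Cdh2
    (K_D = 25.8 uM).
    """

    molecules_per_energy_unit: float = 25_000.0
    cell_diameter: float = 10e-6  # m
    contact_thickness: float = 12e-9  # m
    n_neighbors: int = 12
    contact_fraction: float = 1.0 / 12.0
    participation_fraction: float = 0.5
    count_both_cells: bool = False
    temperature: float = 310.15  # K
    gas_constant: float = GAS_CONSTANT_CAL  # cal mol^-1 K^-1
    avogadro: float = AVOGADRO  # mol^-1
    reference_cadherin: str = "Cdh2"
    reference_molecules: float = 25_000.0
    reference_kd: float = 25.8e-6  # molar; overridden by the K_D table in profiles
    kd_reference_state: float = 1.0  # molar, makes ln(K_D) dimensionless

    def __post_init__(self) -> None:
        for name in (
            "molecules_per_energy_unit",
            "cell_diameter",
            "contact_thickness",
            "temperature",
            "gas_constant",
            "avogadro",
            "reference_molecules",
            "reference_kd",
            "kd_reference_state",
        ):
            if not getattr(self, name) > 0:
                raise AdhesionInputError(f"{name} must be positive")
        if not 0 < self.contact_fraction <= 1:
            raise AdhesionInputError("contact_fraction must be in (0, 1]")
        if not 0 < self.participation_fraction <= 1:
            raise AdhesionInputError("participation_fraction must be in (0, 1]")

    @property
    def contact_volume_liters(self) -> float:
        """Volume of the EC1 slab over one cell-cell contact, in liters."""
        sphere_surface = math.pi * self.cell_diameter**2  # m^2
        contact_area = self.contact_fraction * sphere_surface
        return contact_area * self.contact_thickness * 1e3  # m^3 -> L


DEFAULT_PARAMS = AdhesionParams()


@dataclass(frozen=True)
class AdhesionState:
    """Equilibrium composition of the contact zone."""

    c_total: float  # molar, total EC1 concentration C_T
    c_monomer: float  # molar, C_M
    c_dimer: float  # molar, C_D
    contact_volume: float  # liters
    n_dimers: float  # count of trans-dimers in the contact


@dataclass(frozen=True)
class AdhesionResult:
    """Full trace of one adhesion computation."""

    cadherin: str
    molecules: float
    state: AdhesionState
    delta_g: float  # cal per dimer
    work: float  # cal
    relative_adhesion: float


# -- elementary operations ----------------------------------------------------


def molecules_from_energy(energy: float, params: AdhesionParams = DEFAULT_PARAMS) -> float:
    """Surface-molecule count implied by an expression-energy value (linear)."""
    if energy < 0 or not math.isfinite(energy):
        raise AdhesionInputError("energy must be finite and non-negative")
    return energy * params.molecules_per_energy_unit


def contact_concentration(
    molecules: float, params: AdhesionParams = DEFAULT_PARAMS
) -> tuple[float, float]:
    """Total EC1 concentration in one contact and the contact volume.

    Returns ``(c_total [M], contact_volume [L])``. With
    ``count_both_cells=True`` the participating molecules of both apposed
    cells enter C_T; only the C_T/K_D ratio matters for relative adhesion,
    so the two conventions differ by an overall rescaling.
    """
    if molecules < 0 or not math.isfinite(molecules):
        raise AdhesionInputError("molecule count must be finite and non-negative")
    volume = params.contact_volume_liters
    participating = molecules * params.contact_fraction * params.participation_fraction
    if params.count_both_cells:
        participating *= 2.0
    c_total = participating / (params.avogadro * volume)
    return c_total, volume


def solve_dimer_equilibrium(
    c_total: float, kd: float, contact_volume: float = 0.0,
    avogadro: float = AVOGADRO,
) -> AdhesionState:
    """Closed-form monomer/dimer equilibrium in the contact zone.

    Solves K_D = C_M^2 / C_D with conservation C_M + 2 C_D = C_T, i.e. the
    unique non-negative root of 2 C_M^2 / K_D + C_M - C_T = 0:

        C_M = (K_D / 4) * (sqrt(1 + 8 C_T / K_D) - 1),   C_D = C_M^2 / K_D.

    The form above is numerically stable for small C_T/K_D because the
    subtraction is done inside ``expm1``-free sqrt arithmetic at O(1) scale.
    ``n_dimers`` is populated when a contact volume is supplied.
    """
    if not (math.isfinite(c_total) and math.isfinite(kd)) or c_total < 0 or kd <= 0:
        raise AdhesionInputError("require finite c_total >= 0 and kd > 0")
    x = c_total / kd
    c_monomer = kd * (math.sqrt(1.0 + 8.0 * x) - 1.0) / 4.0
    c_dimer = c_monomer**2 / kd
    n_dimers = c_dimer * contact_volume * avogadro
    return AdhesionState(
        c_total=c_total,
        c_monomer=c_monomer,
        c_dimer=c_dimer,
        contact_volume=contact_volume,
        n_dimers=n_dimers,
    )


def free_energy_per_dimer(kd: float, params: AdhesionParams = DEFAULT_PARAMS) -> float:
    """Gibbs free energy of adhesion per trans-dimer, in calories.

    dg = -(R T / n) ln(K_D / c0) with an explicit 1 M reference state c0
    keeping the logarithm dimensionless; positive whenever K_D < c0.
    """
    if not math.isfinite(kd) or kd <= 0:
        raise AdhesionInputError("kd must be finite and positive")
    rt_per_molecule = params.gas_constant * params.temperature / params.avogadro
    return -rt_per_molecule * math.log(kd / params.kd_reference_state)


def adhesion_work(
    molecules: float,
    kd: float,
    params: AdhesionParams = DEFAULT_PARAMS,
    cadherin: str = "",
    reference_kd: float | None = None,
) -> AdhesionResult:
    """Work of separation and relative adhesion for one configuration.

    Composes concentration, equilibrium and per-dimer free energy:
    W = N_dimers * dg, normalised to the work of the reference
    configuration (``params.reference_molecules`` molecules of the
    reference cadherin, K_D ``reference_kd`` or ``params.reference_kd``).
    """
    c_total, volume = contact_concentration(molecules, params)
    state = solve_dimer_equilibrium(c_total, kd, volume, params.avogadro)
    dg = free_energy_per_dimer(kd, params)
    work = state.n_dimers * dg

    ref_kd = params.reference_kd if reference_kd is None else reference_kd
    ref_c_total, _ = contact_concentration(params.reference_molecules, params)
    ref_state = solve_dimer_equilibrium(ref_c_total, ref_kd, volume, params.avogadro)
    ref_work = ref_state.n_dimers * free_energy_per_dimer(ref_kd, params)
    relative = work / ref_work
    return AdhesionResult(
        cadherin=cadherin,
        molecules=molecules,
        state=state,
        delta_g=dg,
        work=work,
        relative_adhesion=relative,
    )


def adhesion_profile(
    matrix: pd.DataFrame,
    kd_table: KdTable,
    params: AdhesionParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Relative adhesion for every (cadherin, structure) with observed energy.

    ``matrix`` is genes x structures expression energy. Genes missing from
    the K_D table are skipped with a logged warning; an empty intersection
    raises :class:`MissingKdError`. Returns a long, deterministically
    ordered frame with the full audit trail.
    """
    genes = [g for g in matrix.index if g in kd_table]
    skipped = [g for g in matrix.index if g not in kd_table]
    for g in skipped:
        logger.warning("gene %s absent from K_D table; skipped", g)
    if not genes:
        raise MissingKdError("no gene of the matrix has a K_D entry")
    if params.reference_cadherin not in kd_table:
        raise MissingKdError(
            f"reference cadherin {params.reference_cadherin!r} absent from K_D table"
        )
    ref_kd = kd_table.kd(params.reference_cadherin)
    rows = []
    for gene in genes:
        kd = kd_table.kd(gene)
        for structure in matrix.columns:
            energy = matrix.at[gene, structure]
            if pd.isna(energy):
                continue
            molecules = molecules_from_energy(float(energy), params)
            res = adhesion_work(molecules, kd, params, gene, reference_kd=ref_kd)
            rows.append(
                {
                    "cadherin": gene,
                    "structure": structure,
                    "energy": float(energy),
                    "molecules": molecules,
                    "kd_molar": kd,
                    "c_total": res.state.c_total,
                    "c_monomer": res.state.c_monomer,
                    "c_dimer": res.state.c_dimer,
                    "n_dimers": res.state.n_dimers,
                    "delta_g_cal": res.delta_g,
                    "work_cal": res.work,
                    "relative_adhesion": res.relative_adhesion,
                }
            )
    frame = pd.DataFrame(rows)
    return frame.sort_values(["cadherin", "structure"], kind="stable").reset_index(
        drop=True
    )


def adjacent_fold_changes(
    profile: pd.Series | Sequence[float],
    threshold: float = 4.0,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fold differences between adjacent segments of an ordered profile.

    ``profile`` must already be ordered along the anterior-posterior axis.
    fold = max(a, b) / min(a, b); by convention inf when exactly one side is
    zero and 1.0 when both are. A boundary is flagged when fold >= threshold
    (a four-fold difference between adjacent segments is the conventional
    cutoff for adhesion-relevant steps).
    """
    if isinstance(profile, pd.Series):
        values = profile.to_numpy(dtype=float)
        labels = list(profile.index) if labels is None else list(labels)
    else:
        values = np.asarray(list(profile), dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(values))]
    if len(values) < 2:
        raise ProfileLengthError("need at least two segments to compare")
    if np.any(values < 0) or np.any(~np.isfinite(values)):
        raise AdhesionInputError("profile values must be finite and non-negative")
    records = []
    for i in range(len(values) - 1):
        a, b = values[i], values[i + 1]
        if a == 0.0 and b == 0.0:
            fold = 1.0
        elif a == 0.0 or b == 0.0:
            fold = math.inf
        else:
            fold = max(a, b) / min(a, b)
        records.append(
            {
                "boundary": f"{labels[i]}|{labels[i + 1]}",
                "left": labels[i],
                "right": labels[i + 1],
                "fold": fold,
                "flagged": fold >= threshold,
            }
        )
    return pd.DataFrame(records)


# -- Model / Results ----------------------------------------------------------


class AdhesionModel:
    """Relative-adhesion model over an expression-energy matrix.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Genes x structures expression energies (missing allowed).
    kd_table : KdTable, optional
        Homophilic dissociation constants; defaults to the packaged table.
    params : AdhesionParams, optional
        Geometry/calibration parameters; defaults to the standard
        configuration.

    Examples
    --------
    >>> model = AdhesionModel(matrix)
    >>> results = model.fit()
    >>> results.relative_adhesion.loc["Cdh2"]
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        kd_table: KdTable | None = None,
        params: AdhesionParams | None = None,
    ):
        self.matrix = matrix
        self.kd_table = kd_table if kd_table is not None else load_packaged_kd_table()
        self.params = params if params is not None else DEFAULT_PARAMS

    @classmethod
    def from_records(
        cls,
        records,
        age: str,
        structures: Sequence[str] | None = None,
        kd_table: KdTable | None = None,
        params: AdhesionParams | None = None,
    ) -> "AdhesionModel":
        """Build the model from long-format expression records at one age."""
        from .expression import records_to_matrix

        return cls(records_to_matrix(records, age, structures), kd_table, params)

    def fit(self) -> "AdhesionResults":
        """Evaluate the adhesion model on every observed (gene, structure)."""
        frame = adhesion_profile(self.matrix, self.kd_table, self.params)
        return AdhesionResults(self, frame)


class AdhesionResults:
    """Results of :meth:`AdhesionModel.fit`.

    ``frame`` carries the full audit trail (energy, molecules, C_T, C_M,
    C_D, N_dimers, dg, W, relative adhesion) in long format; accessors
    pivot it per cadherin.
    """

    def __init__(self, model: AdhesionModel, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def relative_adhesion(self) -> pd.DataFrame:
        """Cadherins x structures matrix of relative adhesion."""
        return self.frame.pivot(
            index="cadherin", columns="structure", values="relative_adhesion"
        )

    def profile(
        self, cadherin: str, ordered_structures: Sequence[str] | None = None
    ) -> pd.Series:
        """Relative adhesion of one cadherin, optionally in a given
        (e.g. anterior-posterior) structure order."""
        sub = self.frame[self.frame["cadherin"] == cadherin]
        series = sub.set_index("structure")["relative_adhesion"]
        if ordered_structures is not None:
            series = series.reindex(list(ordered_structures)).dropna()
        series.name = cadherin
        return series

    def adjacent_fold_changes(
        self,
        cadherin: str,
        ordered_structures: Sequence[str],
        threshold: float = 4.0,
    ) -> pd.DataFrame:
        """Boundary fold-changes of one cadherin's ordered profile."""
        return adjacent_fold_changes(
            self.profile(cadherin, ordered_structures), threshold
        )

    def summary(self) -> str:
        """Plain-text summary of the fitted configuration and results."""
        p = self.model.params
        lines = [
            "Cadherin relative-adhesion model",
            "=" * 48,
            f"genes: {self.frame['cadherin'].nunique():>5}   "
            f"structures: {self.frame['structure'].nunique():>5}   "
            f"observations: {len(self.frame):>6}",
            f"molecules per energy unit: {p.molecules_per_energy_unit:,.0f}",
            f"cell diameter: {p.cell_diameter * 1e6:.1f} um   "
            f"contact thickness: {p.contact_thickness * 1e9:.1f} nm",
            f"contact fraction: {p.contact_fraction:.4f}   "
            f"participation: {p.participation_fraction:.2f}   "
            f"count both cells: {p.count_both_cells}",
            f"reference: {p.reference_molecules:,.0f} molecules of "
            f"{p.reference_cadherin}",
            "-" * 48,
            "relative adhesion by cadherin (min / median / max):",
        ]
        for gene, sub in self.frame.groupby("cadherin"):
            vals = sub["relative_adhesion"]
            lines.append(
                f"  {gene:<8} {vals.min():>8.3f} {vals.median():>8.3f} "
                f"{vals.max():>8.3f}   (n={len(vals)})"
            )
        return "\n".join(lines)

    def to_csv(self, path: str | Path, header_comment: str = "") -> None:
        """Export the audit-trail frame as CSV."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, index=False)

    def plot_profile(
        self,
        cadherins: Sequence[str],
        ordered_structures: Sequence[str],
        ax=None,
    ):
        """Line plot of relative adhesion along an ordered structure axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3.5))
        for gene in cadherins:
            series = self.profile(gene, ordered_structures)
            ax.plot(series.index, series.values, marker="o", label=gene)
        ax.set_xlabel("structure (anterior to posterior)")
        ax.set_ylabel("relative adhesion")
        ax.legend(fontsize=8)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
        return ax
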