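"""Exception hierarchy.

Every documented failure mode raises a distinct, named exception so callers
(and the CLI) can map validation failures to exit codes without string
matching.
"""

from __future__ import annotations


class CadhesionError(Exception):
    """Base class for all package errors."""


# --- ontology ---------------------------------------------------------------

class OntologyError(CadhesionError):
    """Base class for ontology construction/validation failures."""


class OntologyParseError(OntologyError):
    """The ontology file could not be parsed against the documented schema."""


class CycleError(OntologyError):
    """The parent relation contains a cycle (includes self-parenting)."""


class DuplicateAcronymError(OntologyError):
    """Two structures at the same ontological level share an acronym."""


class DanglingParentError(OntologyError):
    """A structure references a parent_id that does not exist."""


class UnknownVocabularyError(CadhesionError):
    """A filter value is outside the enumerated vocabulary (plate/stratum)."""


# --- expression tables ------------------------------------------------------

class ExpressionTableError(CadhesionError):
    """Base class for expression-table validation failures.

    ``rows`` lists the offending 1-based data-row numbers where known.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        super().__init__(message if not rows else f"{message} (rows: {rows})")
        self.rows = rows or []


class NegativeEnergyError(ExpressionTableError):
    """An expression-energy value is negative."""


class UnknownAgeError(ExpressionTableError):
    """An age label is not one of the seven developmental stages."""


class DuplicateRecordError(ExpressionTableError):
    """Two records share the (gene, structure, age, experiment) key."""


class ZeroPixelsError(CadhesionError):
    """A pixel summary reports zero total pixels."""


class EmptyUnionError(CadhesionError):
    """unionize() was called with no pixel summaries."""


class EmptyQueryError(CadhesionError):
    """An RMA query was requested with no structure ids."""


class ReferenceGeneError(CadhesionError):
    """The normalisation reference gene is absent or zero in a used column."""

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message if not columns else f"{message} (columns: {columns})")
        self.columns = columns or []


# --- adhesion model ---------------------------------------------------------

class AdhesionInputError(CadhesionError):
    """Invalid input to the adhesion computation (negative counts, bad K_D)."""


class MissingKdError(CadhesionError):
    """A required cadherin (e.g. the reference) is absent from the K_D table."""


class ProfileLengthError(CadhesionError):
    """An adhesion profile has fewer than two segments."""


# --- analysis ---------------------------------------------------------------

class ConstantVectorError(CadhesionError):
    """Pearson correlation requested on a zero-variance vector."""


class InsufficientDataError(CadhesionError):
    """Fewer than three pairwise-complete observations."""


class EmptyMatrixError(CadhesionError):
    """An empty matrix was passed where data are required."""


# --- synthetic data ---------------------------------------------------------

class InfeasibleCorrelationError(CadhesionError):
    """Target correlations cannot be embedded within tolerance after repair."""


class SpecError(CadhesionError):
    """A synthetic-data specification violates its invariants."""
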