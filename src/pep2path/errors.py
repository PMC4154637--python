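"""Exception hierarchy.

Every error raised on bad user input derives from :class:`Pep2PathError`,
so the CLI can map data problems to a single exit code (3) while
programming errors propagate normally.
"""


class Pep2PathError(Exception):
    """Base class for all user-facing errors."""


class SchemaError(Pep2PathError):
    """A database document or prediction table violates the schema."""


class MergeConflictError(Pep2PathError):
    """Two databases define the same cluster_id with different content."""


class UnknownMonomerError(Pep2PathError):
    """A monomer name or one-letter code is not in the active alphabet."""


class TagGrammarError(Pep2PathError):
    """A sequence-tag string does not match the tag grammar."""


class UnmatchedMassError(Pep2PathError):
    """A mass shift matches no row of the conversion table."""


class ExpansionCapError(Pep2PathError):
    """Expanding a degenerate tag would exceed the configured cap."""


class EmptyDatabaseError(Pep2PathError):
    """Scoring was requested against an empty (or fully filtered) database."""


class InfeasibleSimulationError(Pep2PathError):
    """Synthetic-data generator parameters are contradictory."""
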