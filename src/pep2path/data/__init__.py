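"""Shipped, user-replaceable data tables.

``monomer_frequencies.synthetic.tsv`` is a synthetic stand-in for a
background monomer-frequency snapshot of known nonribosomal peptides
(the kind of table one would derive from the NORINE database): the
relative abundances are hand-set to be realistic for NRP chemistry, not
derived from any database export.  The two mass-conversion tables are
best-effort reconstructions from standard monoisotopic residue masses,
versioned in their headers; users with their own tables can point the
CLI at replacements.
"""

from __future__ import annotations

from importlib.resources import files

from ..scoring import MonomerFrequencyTable, load_frequency_table
from ..tags import DEFAULT_MASS_TOLERANCE, MassConversionTable, load_conversion_table

_FREQ = "monomer_frequencies.synthetic.tsv"
_NRP_MASSES = "nrp_residue_masses.tsv"
_RIPP_MASSES = "ripp_residue_masses.tsv"


def _path(name: str):
    return files(__package__).joinpath(name)


def default_frequency_table() -> MonomerFrequencyTable:
    return load_frequency_table(_path(_FREQ))


def nrp_conversion_table(
    tolerance: float = DEFAULT_MASS_TOLERANCE,
) -> MassConversionTable:
    return load_conversion_table(_path(_NRP_MASSES), tolerance=tolerance)


def ripp_conversion_table(
    tolerance: float = DEFAULT_MASS_TOLERANCE,
) -> MassConversionTable:
    return load_conversion_table(_path(_RIPP_MASSES), tolerance=tolerance)
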