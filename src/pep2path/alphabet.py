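"""The monomer alphabet.

Nonribosomal peptides are built from proteinogenic amino acids plus a
long tail of nonproteinogenic monomers (ornithine, homotyrosine,
valinol, ...).  Monomers are represented as lower-case name strings
(NORINE-style three-plus-letter identifiers); the twenty proteinogenic
residues additionally carry the usual one-letter codes, which is what
six-frame genome translations produce.
"""

from __future__ import annotations

from .errors import UnknownMonomerError

# name -> one-letter code for the twenty proteinogenic residues
PROTEINOGENIC: dict[str, str] = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

ONE_LETTER_TO_NAME: dict[str, str] = {c: n for n, c in PROTEINOGENIC.items()}

# Common nonproteinogenic NRPS substrates (adenylation-domain specificity
# prediction vocabularies and NORINE use these identifiers).
NONPROTEINOGENIC: tuple[str, ...] = (
    "orn",      # ornithine
    "hty",      # homotyrosine
    "allothr",  # allo-threonine
    "vol",      # valinol
    "abu",      # 2-aminobutyric acid
    "iva",      # isovaline
    "dab",      # 2,4-diaminobutyric acid
    "dhb",      # 2,3-dihydroxybenzoic acid
    "sal",      # salicylic acid
    "pip",      # pipecolic acid
    "aad",      # 2-aminoadipic acid
    "bht",      # beta-hydroxytyrosine
    "hpg",      # 4-hydroxyphenylglycine
    "dhpg",     # 3,5-dihydroxyphenylglycine
    "cit",      # citrulline
    "kyn",      # kynurenine
)

DEFAULT_ALPHABET: frozenset[str] = frozenset(PROTEINOGENIC) | frozenset(NONPROTEINOGENIC)


def normalize_monomer(token: str, alphabet: frozenset[str] = DEFAULT_ALPHABET) -> str:
    """Resolve ``token`` (a name in any case, or a one-letter code) to a
    canonical lower-case monomer name in ``alphabet``.

    Raises
    ------
    UnknownMonomerError
        If the token resolves to nothing, or to a name outside the alphabet.
    """
    tok = token.strip()
    if not tok:
        raise UnknownMonomerError("empty monomer token")
    if len(tok) == 1:
        name = ONE_LETTER_TO_NAME.get(tok.upper())
        if name is None:
            raise UnknownMonomerError(f"unknown one-letter code {tok!r}")
    else:
        name = tok.lower()
    if name not in alphabet:
        raise UnknownMonomerError(f"monomer {name!r} is not in the active alphabet")
    return name


def one_letter(name: str) -> str | None:
    """One-letter code for a proteinogenic monomer, else None."""
    return PROTEINOGENIC.get(name)
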