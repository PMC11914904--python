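"""The 20 proteinogenic amino acids, addressed by canonical 3-letter code.

Auxotrophy calls, community metrics and the statistics layer all index by
these codes, so the canonical ordering is fixed here once.
"""

from __future__ import annotations

AMINO_ACIDS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys",
    "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro",
    "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: one-letter codes, aligned with :data:`AMINO_ACIDS`
AA_ONE_LETTER: tuple[str, ...] = (
    "A", "R", "N", "D", "C",
    "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P",
    "S", "T", "W", "Y", "V",
)

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def check_amino_acid(code: str) -> str:
    """Return *code* if it is one of the 20 canonical codes, else raise."""
    from .errors import InputError

    if code not in AA_INDEX:
        raise InputError(f"unknown amino acid code: {code!r}")
    return code
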