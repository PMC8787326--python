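"""Base-21 numerical encoding of amino-acid sequences.

Each of the 20 proteinogenic amino acids is assigned an integer 1-20 (in
alphabetical order of the one-letter codes); a peptide sequence is then read
as a base-21 number with the N-terminal residue as the most-significant
digit.  The digit 0 is never assigned, which keeps codes of different
sequence lengths in disjoint ranges and makes the encoding injective.  The
natural logarithm of the code is the scale used throughout the rest of the
package, alongside ln(EC50) for the activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "AMINO_ACIDS",
    "RESIDUE_VALUES",
    "PeptideRecord",
    "EncodedPeptide",
    "InvalidResidueError",
    "residue_value",
    "encode_sequence",
    "decode_code",
    "ln_activity",
]

#: The 20 standard amino acids, ordered by their numerical definition (1-20).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: One-letter code -> digit in [1, 20].
RESIDUE_VALUES: dict[str, int] = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}

_VALUE_RESIDUES: dict[int, str] = {v: k for k, v in RESIDUE_VALUES.items()}

BASE: int = 21

MAX_LENGTH: int = 20


class InvalidResidueError(ValueError):
    """Raised for characters outside the 20-letter amino-acid alphabet."""


def residue_value(residue: str) -> int:
    """Return the numerical definition (1-20) of a single amino acid.

    Case-insensitive.  Ambiguity/non-standard codes (B, J, O, U, X, Z) are
    rejected rather than skipped, because a silently dropped residue would
    corrupt the positional code.
    """
    if not isinstance(residue, str) or len(residue) != 1:
        raise InvalidResidueError(f"expected a single letter, got {residue!r}")
    try:
        return RESIDUE_VALUES[residue.upper()]
    except KeyError:
        raise InvalidResidueError(
            f"unknown amino-acid letter {residue!r}; expected one of {AMINO_ACIDS}"
        ) from None


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide sequence together with its measured EC50 activity.

    EC50 is the concentration at which ACE inhibition reaches 50%; units are
    treated as opaque but must be consistent across a dataset (only ratios
    and logs are ever used).
    """

    id: str
    sequence: str
    ec50: float

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if len(seq) > MAX_LENGTH:
            raise ValueError(
                f"record {self.id!r}: sequence length {len(seq)} exceeds {MAX_LENGTH}"
            )
        for ch in seq:
            if ch not in RESIDUE_VALUES:
                raise InvalidResidueError(
                    f"record {self.id!r}: unknown amino-acid letter {ch!r}"
                )
        object.__setattr__(self, "sequence", seq)
        if not (self.ec50 > 0):
            raise ValueError(
                f"record {self.id!r}: ec50 must be positive, got {self.ec50}"
            )

    @property
    def ln_ec50(self) -> float:
        return math.log(self.ec50)


@dataclass(frozen=True)
class EncodedPeptide:
    """Digit vector, base-21 integer code and its natural log for one peptide.

    ``code`` is an exact Python integer (length-20 codes exceed 64-bit range);
    ``log_code`` is computed from the exact integer, which ``math.log``
    handles without overflow.
    """

    sequence: str
    digits: tuple[int, ...]
    code: int = field(default=0)
    log_code: float = field(default=0.0)


def encode_sequence(sequence: str) -> EncodedPeptide:
    """Encode a peptide string as a base-21 positional number.

    The first (N-terminal) residue is the most-significant digit; digits are
    the per-residue numerical definitions, so no digit is ever 0 and no code
    collides across lengths.
    """
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    seq = sequence.upper()
    digits = tuple(residue_value(ch) for ch in seq)
    code = 0
    for d in digits:
        code = code * BASE + d
    return EncodedPeptide(sequence=seq, digits=digits, code=code, log_code=math.log(code))


def decode_code(code: int) -> str:
    """Invert :func:`encode_sequence`: recover the peptide string from a code.

    A 0 digit in the base-21 expansion means the integer is not the code of
    any peptide (digit 0 is never assigned).
    """
    if not isinstance(code, int) or code < 1:
        raise ValueError(f"peptide codes are positive integers, got {code!r}")
    residues: list[str] = []
    rest = code
    while rest > 0:
        rest, d = divmod(rest, BASE)
        if d == 0:
            raise ValueError(
                f"{code} is not a valid peptide code: its base-21 expansion contains a 0 digit"
            )
        residues.append(_VALUE_RESIDUES[d])
    return "".join(reversed(residues))


def ln_activity(ec50: float) -> float:
    """Natural log of an EC50 value; the activity scale used for modeling."""
    if not (ec50 > 0):
        raise ValueError(f"ec50 must be positive to take its natural log, got {ec50}")
    return math.log(ec50)
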