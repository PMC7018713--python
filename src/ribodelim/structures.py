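"""RNA secondary-structure primitives for ITS2 sequence-structure analysis.

An ITS2 transcript folds into a conserved four-helix hairpin scaffold.  The
unit of analysis here is a :class:`StructuredSequence` — a nucleotide string
together with its dot-bracket (Vienna) structure — which is re-encoded into a
12-letter alphabet that carries, per position, both the nucleotide identity
and the structural state (unpaired, pair-opening, pair-closing).  Downstream
alignment, distance and compensatory-base-change routines all operate on
this joint encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NUCLEOTIDES = "ACGU"
#: structural states, in code order
STATES = ".()"

#: the 12-letter joint alphabet, indexed by ``3*nt + state``:
#: unpaired lowercase (a c g u), pair-opening uppercase (A C G U),
#: pair-closing B D H V (mnemonic: the IUPAC "not-X" letter of its base).
ALPHABET12 = "aABcCDgGHuUV"

_CANONICAL_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}


class StructureError(ValueError):
    """Raised for malformed dot-bracket strings or inconsistent records."""


def parse_dotbracket(structure: str) -> np.ndarray:
    """Parse a pseudoknot-free dot-bracket string into a pair table.

    Returns an int array ``partner`` with ``partner[i] == j`` when positions
    ``i`` and ``j`` (0-based) pair, and ``-1`` for unpaired positions.

    Raises
    ------
    StructureError
        On unbalanced brackets (the offending 0-based index is named) or on
        any character outside ``().``; multi-bracket pseudoknot notation is
        rejected as unsupported.
    """
    partner = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif ch != ".":
            if ch in "[]{}<>":
                raise StructureError(
                    f"pseudoknot bracket {ch!r} at position {i} is unsupported"
                )
            raise StructureError(f"invalid structure character {ch!r} at position {i}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return partner


@dataclass(frozen=True)
class StructuredSequence:
    """An ITS2 nucleotide sequence with its dot-bracket secondary structure.

    ``T`` is mapped to ``U`` on construction (transcript convention); the
    pair table is derived eagerly so invalid structures fail fast.
    """

    id: str
    nucleotides: str
    structure: str
    pair_table: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        nts = self.nucleotides.upper().replace("T", "U")
        object.__setattr__(self, "nucleotides", nts)
        if len(nts) != len(self.structure):
            raise StructureError(
                f"{self.id}: sequence length {len(nts)} != structure length "
                f"{len(self.structure)}"
            )
        for i, ch in enumerate(nts):
            if ch not in NUCLEOTIDES:
                raise StructureError(f"{self.id}: invalid nucleotide {ch!r} at position {i}")
        object.__setattr__(self, "pair_table", parse_dotbracket(self.structure))

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass(frozen=True)
class EncodedSequence:
    """A sequence over the 12-letter nucleotide x structural-state alphabet.

    ``codes`` holds integer codes ``3*nt + state`` (nt in ACGU order, state
    in ``. ( )`` order); ``letters`` renders them in :data:`ALPHABET12`.
    The encoding is lossless: :meth:`decode` recovers the original record.
    """

    id: str
    codes: np.ndarray

    @property
    def letters(self) -> str:
        return "".join(ALPHABET12[c] for c in self.codes)

    def decode(self) -> StructuredSequence:
        nts = "".join(NUCLEOTIDES[c // 3] for c in self.codes)
        struct = "".join(STATES[c % 3] for c in self.codes)
        return StructuredSequence(self.id, nts, struct)

    def __len__(self) -> int:
        return len(self.codes)


def encode12(seq: StructuredSequence) -> EncodedSequence:
    """Jointly encode nucleotides and structural states into 12 letters."""
    nt_idx = np.fromiter(
        (NUCLEOTIDES.index(c) for c in seq.nucleotides), dtype=np.int64, count=len(seq)
    )
    st_idx = np.fromiter(
        (STATES.index(c) for c in seq.structure), dtype=np.int64, count=len(seq)
    )
    return EncodedSequence(seq.id, nt_idx * 3 + st_idx)


def is_canonical(nt_a: str, nt_b: str) -> bool:
    """True when two nucleotides form a canonical pair (Watson-Crick or G·U)."""
    return nt_a + nt_b in _CANONICAL_PAIRS
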