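"""Peptide mass arithmetic and the residue token vocabulary.

All masses are monoisotopic and expressed in daltons (Da). Modified
residues are first-class vocabulary tokens written in bracket notation
(e.g. ``C[+57.02146]`` for carbamidomethyl-cysteine), so a decoder can
predict them exactly like unmodified residues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

__all__ = [
    "PROTON",
    "WATER",
    "RESIDUE_MASSES",
    "ResidueVocabulary",
    "parse_peptide",
    "peptide_mass",
    "residue_sum",
    "mz_from_mass",
    "mass_from_mz",
    "ppm_diff",
]

# Fixed monoisotopic constants (Da); compiled in, never recomputed.
PROTON: float = 1.007276
WATER: float = 18.010565

# Monoisotopic residue masses of the 20 canonical amino acids (Da).
RESIDUE_MASSES: Dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# Modification deltas (Da). Keys are the bracket strings used in tokens.
CARBAMIDOMETHYL = 57.021464
OXIDATION = 15.994915
DEAMIDATION = 0.984016

#: The variable modifications supported throughout: carbamidomethylation of
#: cysteine, oxidation of methionine, deamidation of asparagine/glutamine.
PTM_TOKENS: Dict[str, float] = {
    "C[+57.02146]": RESIDUE_MASSES["C"] + CARBAMIDOMETHYL,
    "M[+15.99491]": RESIDUE_MASSES["M"] + OXIDATION,
    "N[+0.98402]": RESIDUE_MASSES["N"] + DEAMIDATION,
    "Q[+0.98402]": RESIDUE_MASSES["Q"] + DEAMIDATION,
}

_TOKEN_RE = re.compile(r"([A-Z])(\[[+-][0-9.]+\])?")


def parse_peptide(peptide: str) -> List[str]:
    """Split a peptide string in bracket notation into residue tokens.

    ``"AC[+57.02146]GK"`` -> ``["A", "C[+57.02146]", "G", "K"]``.
    """
    tokens: List[str] = []
    pos = 0
    while pos < len(peptide):
        m = _TOKEN_RE.match(peptide, pos)
        if m is None:
            raise ValueError(
                f"cannot parse peptide {peptide!r} at position {pos}: {peptide[pos:]!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


@dataclass(frozen=True)
class ResidueVocabulary:
    """Token <-> monoisotopic-mass mapping shared by all models.

    Parameters
    ----------
    tokens
        Ordered residue symbols (canonical amino acids plus PTM variants).
    masses
        Token -> monoisotopic residue mass (Da); strictly positive.
    sos, eos, pad
        Mass-less special tokens. They never occur inside a peptide body.
    """

    tokens: Tuple[str, ...]
    masses: Dict[str, float] = field(hash=False)
    sos: str = "<s>"
    eos: str = "</s>"
    pad: str = "<pad>"

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        for tok in self.tokens:
            if tok in (self.sos, self.eos, self.pad):
                raise ValueError(f"special token {tok!r} listed as residue")
            if self.masses.get(tok, 0.0) <= 0.0:
                raise ValueError(f"token {tok!r} must have strictly positive mass")

    # ---- construction ----------------------------------------------------

    @classmethod
    def default(cls, fixed_carbamidomethyl: bool = True) -> "ResidueVocabulary":
        """The standard vocabulary: canonical residues + the three PTMs.

        By default cysteine always carries the +57.02146 carbamidomethyl
        group (alkylation is ubiquitous in sample prep) and bare ``C`` is
        absent; pass ``fixed_carbamidomethyl=False`` to keep both.
        """
        masses = dict(RESIDUE_MASSES)
        if fixed_carbamidomethyl:
            del masses["C"]
        masses.update(PTM_TOKENS)
        order = sorted(masses)  # deterministic, independent of insertion
        return cls(tokens=tuple(order), masses=masses)

    # ---- mapping helpers -------------------------------------------------

    @property
    def specials(self) -> Tuple[str, str, str]:
        return (self.pad, self.sos, self.eos)

    def index(self) -> Dict[str, int]:
        """Token -> integer id with pad=0, sos=1, eos=2, residues from 3."""
        out = {self.pad: 0, self.sos: 1, self.eos: 2}
        for i, tok in enumerate(self.tokens):
            out[tok] = 3 + i
        return out

    def __len__(self) -> int:
        return len(self.tokens) + 3

    def mass(self, token: str) -> float:
        try:
            return self.masses[token]
        except KeyError:
            raise KeyError(f"unknown residue token: {token!r}") from None

    def mass_array(self) -> "list[float]":
        return [self.masses[t] for t in self.tokens]

    # ---- serialization ---------------------------------------------------

    def to_table(self, path: str | Path) -> None:
        """Write the vocabulary as a two-column (token, mass) text table."""
        lines = [f"{tok}\t{self.masses[tok]:.6f}" for tok in self.tokens]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "ResidueVocabulary":
        masses: Dict[str, float] = {}
        order: List[str] = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tok, mass = line.split("\t")
            order.append(tok)
            masses[tok] = float(mass)
        return cls(tokens=tuple(order), masses=masses)


def _as_tokens(seq: str | Sequence[str]) -> List[str]:
    if isinstance(seq, str):
        return parse_peptide(seq)
    return list(seq)


def residue_sum(seq: str | Sequence[str], vocab: ResidueVocabulary) -> float:
    """Sum of residue masses (Da), without the terminal water."""
    total = 0.0
    for tok in _as_tokens(seq):
        total += vocab.mass(tok)
    return total


def peptide_mass(seq: str | Sequence[str], vocab: ResidueVocabulary) -> float:
    """Neutral monoisotopic peptide mass: residue masses + water (Da).

    The empty sequence evaluates to the mass of water. Unknown tokens are
    rejected with the offending symbol named.
    """
    return residue_sum(seq, vocab) + WATER


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a [M + zH]^z+ ion."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON) / charge


def mass_from_mz(mz: float, charge: int) -> float:
    """Neutral mass from observed m/z and charge; inverse of mz_from_mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * PROTON


def ppm_diff(observed: float, expected: float) -> float:
    """Absolute relative mass difference in parts per million."""
    if expected <= 0:
        raise ValueError(f"expected mass must be positive, got {expected}")
    return abs(observed - expected) / expected * 1e6
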