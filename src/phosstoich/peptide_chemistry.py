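"""Peptide bracket-notation parsing and monoisotopic precursor m/z.

Analytes are tryptic peptides written in a compact bracket dialect:
``S[+80]GTATPQR`` is the peptide SGTATPQR carrying a phosphate on the
first serine, ``C[−1]...C[−1]...`` marks two cysteines that have each
lost a hydrogen (an intramolecular disulfide).  A bracket always
modifies the residue immediately before it.

The mass model is the standard one for singly-to-quadruply protonated
tryptic peptides: monoisotopic residue masses, one water for the
termini, and ``(M + z * m_proton) / z`` for the precursor m/z.  The
``[+80]`` label maps to the exact phospho monoisotopic delta
(79.96633 Da), not a literal 80, and ``[−1]`` to the loss of one
hydrogen atom; both are required to match observed phosphopeptide
precursors to four decimal places.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from types import MappingProxyType

from pyteomics import mass as _ptmass

__all__ = [
    "MASS_WATER",
    "MASS_PROTON",
    "DELTA_PHOSPHO",
    "DELTA_H_LOSS",
    "RESIDUE_MASSES",
    "Modification",
    "ModifiedPeptide",
    "PeptideParseError",
    "parse_peptide_string",
    "monoisotopic_mass",
    "precursor_mz",
]

MASS_WATER = 18.0105646863
MASS_PROTON = 1.00727646688
DELTA_PHOSPHO = 79.96633
DELTA_H_LOSS = -1.0078250319

#: Monoisotopic masses of the 20 standard residues, Da.
RESIDUE_MASSES = MappingProxyType(
    {aa: _ptmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}
)

# Recognised bracket labels -> exact monoisotopic delta.  The label key
# is normalised to an ASCII sign; the original spelling is preserved on
# the Modification for byte-exact round-tripping.
_KNOWN_DELTAS = {"+80": DELTA_PHOSPHO, "-1": DELTA_H_LOSS}

_TOKEN = re.compile(r"([A-Za-z])(?:\[([+−-])(\d+)\])?")


class PeptideParseError(ValueError):
    """Raised when a peptide string does not match the bracket grammar."""


@dataclass(frozen=True)
class Modification:
    """A positioned mass delta on a peptide.

    position is the 1-based residue index; label is the bracket text as
    written (sign included, unicode minus preserved).
    """

    position: int
    delta: float
    label: str


@dataclass(frozen=True)
class ModifiedPeptide:
    residues: str
    mods: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise PeptideParseError("empty peptide")
        for aa in self.residues:
            if aa not in RESIDUE_MASSES:
                raise PeptideParseError(f"unknown residue {aa!r}")
        for m in self.mods:
            if not 1 <= m.position <= len(self.residues):
                raise PeptideParseError(
                    f"modification position {m.position} outside peptide "
                    f"of length {len(self.residues)}"
                )

    @property
    def n_phospho(self) -> int:
        """Number of phospho (+80) modifications carried."""
        return sum(1 for m in self.mods if abs(m.delta - DELTA_PHOSPHO) < 1e-6)

    def serialize(self) -> str:
        """Render back to the bracket dialect, byte-identical to the input."""
        by_pos = {m.position: m for m in self.mods}
        out = []
        for i, aa in enumerate(self.residues, start=1):
            out.append(aa)
            if i in by_pos:
                out.append(f"[{by_pos[i].label}]")
        return "".join(out)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def parse_peptide_string(s: str, *, permissive: bool = False) -> ModifiedPeptide:
    """Parse the bracket dialect into a :class:`ModifiedPeptide`.

    Parameters
    ----------
    s:
        Peptide string, e.g. ``"S[+80]GTATPQR"``.  Unicode minus and
        ASCII hyphen are both accepted inside brackets.
    permissive:
        If true, bracket labels other than ``+80``/``−1`` are kept with
        their literal integer value as the mass delta.  Otherwise they
        are an error.
    """
    if not s:
        raise PeptideParseError("empty peptide string")
    if s[0] == "[":
        raise PeptideParseError("bracket modification before any residue")
    residues: list[str] = []
    mods: list[Modification] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            raise PeptideParseError(
                f"unexpected character {s[pos]!r} at position {pos} in {s!r}"
            )
        aa, sign, digits = m.groups()
        if aa not in RESIDUE_MASSES:
            raise PeptideParseError(f"unknown residue {aa!r} at position {pos}")
        residues.append(aa)
        if sign is not None:
            ascii_sign = "-" if sign in "−-" else "+"
            key = ascii_sign + digits
            label = sign + digits
            if key in _KNOWN_DELTAS:
                delta = _KNOWN_DELTAS[key]
            elif permissive:
                delta = float(int(ascii_sign + digits))
            else:
                raise PeptideParseError(
                    f"unknown modification label [{label}] "
                    "(pass permissive=True to accept the literal value)"
                )
            mods.append(Modification(len(residues), delta, label))
        pos = m.end()
    return ModifiedPeptide("".join(residues), tuple(mods))


def monoisotopic_mass(p: ModifiedPeptide | str) -> float:
    """Neutral monoisotopic mass in Da: residues + water + mod deltas."""
    if isinstance(p, str):
        p = parse_peptide_string(p)
    return (
        sum(RESIDUE_MASSES[aa] for aa in p.residues)
        + MASS_WATER
        + sum(m.delta for m in p.mods)
    )


def precursor_mz(p: ModifiedPeptide | str, z: int) -> float:
    """Precursor m/z of the z-fold protonated peptide, (M + z·m_p)/z."""
    if not isinstance(z, int) or isinstance(z, bool) or z < 1:
        raise ValueError(f"charge must be a positive integer, got {z!r}")
    return (monoisotopic_mass(p) + z * MASS_PROTON) / z
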