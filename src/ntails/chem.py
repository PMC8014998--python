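"""Modification delta masses and truncated-proteoform mass prediction."""

from __future__ import annotations

from dataclasses import dataclass

from ._constants import (ATOMIC_MONO, MODIFICATION_COMPOSITIONS,
                         RESIDUE_AVERAGE, RESIDUE_COMPOSITION,
                         WATER_AVERAGE, WATER_MONO)
from .proteins import ProteinRecord


def mod_delta_mass(net_composition: dict[str, int]) -> float:
    """Signed monoisotopic delta mass of a net elemental composition.

    Supports 13C and D as elements distinct from C and H, and negative
    counts (losses), e.g. pyro-Glu formation from Gln is N -1, H -3.
    """
    total = 0.0
    for element, count in net_composition.items():
        if element not in ATOMIC_MONO:
            raise ValueError(f"unknown element {element!r}")
        total += count * ATOMIC_MONO[element]
    return total


@dataclass(frozen=True)
class ModificationDef:
    """A named modification with a recomputable monoisotopic delta."""

    name: str
    net_composition: dict[str, int]

    @property
    def delta_monoisotopic(self) -> float:
        return mod_delta_mass(self.net_composition)


#: the five modifications considered by the terminal-peptide search
STANDARD_MODIFICATIONS = {
    name: ModificationDef(name, comp)
    for name, comp in MODIFICATION_COMPOSITIONS.items()
}

_RESIDUE_MONO = {
    aa: mod_delta_mass(comp) for aa, comp in RESIDUE_COMPOSITION.items()
}


def residue_mass(residue: str, scale: str = "monoisotopic") -> float:
    table = _RESIDUE_MONO if scale == "monoisotopic" else RESIDUE_AVERAGE
    if residue not in table:
        raise ValueError(f"unknown residue {residue!r}")
    return table[residue]


def peptide_mass(sequence: str, scale: str = "average") -> float:
    """Unmodified peptide mass: sum of residue masses plus one water."""
    if scale not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass scale {scale!r}")
    water = WATER_MONO if scale == "monoisotopic" else WATER_AVERAGE
    return sum(residue_mass(aa, scale) for aa in sequence) + water


def proteoform_mass(protein: ProteinRecord, start: int,
                    scale: str = "average") -> float:
    """Mass of the truncated proteoform beginning at ``start`` (1-based).

    Average scale by default, matching the kDa-scale values quoted for
    intact truncation products; modifications are not included (add
    :func:`mod_delta_mass` of the retained N-terminal label if needed).
    """
    if not 1 <= start <= len(protein):
        raise ValueError(
            f"{protein.accession}: start {start} out of range")
    return peptide_mass(protein.sequence[start - 1:], scale)
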