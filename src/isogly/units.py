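"""Conversion between molecules per cell and molar concentration.

All intracellular quantities in the model are expressed in mM and mM/s.
Absolute proteomics and metabolomics report molecules per cell, so the
bridge between the two is the *effective cytoplasmic volume*: the volume
of solvent actually available to metabolites and enzymes. Because of
macromolecular crowding and the vacuole, this is considerably smaller
than the total cell volume; the default of 5 fl (versus a naive estimate
of 20 fl, i.e. half of a 40 fl cell) is the value that reconciles the
measured copy numbers with the kinetic model.
"""

from __future__ import annotations

from dataclasses import dataclass

#: CODATA value, exact since the 2019 SI redefinition (1/mol).
AVOGADRO = 6.02214076e23

__all__ = [
    "AVOGADRO",
    "CellGeometry",
    "copies_to_mM",
    "mM_to_copies",
    "limiting_rate",
]


@dataclass(frozen=True)
class CellGeometry:
    """Effective cytoplasmic volume used for copy-number conversions.

    Parameters
    ----------
    cytoplasmic_volume_fl:
        Effective cytoplasmic volume in femtolitres. Default 5 fl (the
        fitted value); 20 fl reproduces the pre-fit parameterisation.
    """

    cytoplasmic_volume_fl: float = 5.0

    def __post_init__(self) -> None:
        if not self.cytoplasmic_volume_fl > 0:
            raise ValueError(
                f"cytoplasmic volume must be positive, got {self.cytoplasmic_volume_fl} fl"
            )

    @property
    def volume_litres(self) -> float:
        return self.cytoplasmic_volume_fl * 1e-15


def copies_to_mM(copies: float, geometry: CellGeometry) -> float:
    """Convert molecules per cell to concentration in mM.

    ``conc = copies / (N_A * V)``, with V the effective cytoplasmic
    volume; exact arithmetic, no internal rounding.
    """
    if copies < 0:
        raise ValueError(f"copies per cell must be nonnegative, got {copies}")
    molar = copies / (AVOGADRO * geometry.volume_litres)
    return molar * 1e3


def mM_to_copies(conc_mM: float, geometry: CellGeometry) -> float:
    """Exact inverse of :func:`copies_to_mM`."""
    if conc_mM < 0:
        raise ValueError(f"concentration must be nonnegative, got {conc_mM} mM")
    return conc_mM * 1e-3 * AVOGADRO * geometry.volume_litres


def limiting_rate(copies: float, kcat: float, geometry: CellGeometry) -> float:
    """Limiting rate V = [E]·kcat in mM/s from enzyme copies per cell.

    Separating [E] (quantitative proteomics) from kcat (in vitro enzyme
    kinetics) is what lets the model represent isoenzymes individually.
    """
    if kcat < 0:
        raise ValueError(f"kcat must be nonnegative, got {kcat}")
    return copies_to_mM(copies, geometry) * kcat
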